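"""Efficiency-corrected relative quantification for qPCR.

Primer efficiency is calibrated from a dilution-series standard curve: the
threshold cycle Ct is regressed on log10 template quantity and the
efficiency is ``E = 10**(-1/m)`` with ``m`` the slope (``m = -3.3219``
corresponds to perfect doubling, ``E = 2``).

Relative quantity of a target gene in a sample versus a calibrator, with one
or more single-copy reference genes, is

    n = E_target**dCt_target / combine_x( E_x**dCt_x )

where ``dCt_x = Ct(calibrator, x) - Ct(sample, x)`` and ``combine`` is the
geometric mean over reference genes (the standard multi-reference
normalisation) or, optionally, their plain product.  With this sign
convention an amplified target (earlier Ct in the sample) gives ``n > 1``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "RelativeQuantity",
    "fit_standard_curve",
    "mean_ct",
    "relative_quantity",
]

logger = logging.getLogger(__name__)

#: efficiencies outside this open/closed interval trigger a warning
EFFICIENCY_RANGE = (1.0, 2.2)
#: replicate Ct range above this (cycles) triggers a QC warning
REPLICATE_QC_RANGE = 0.5


@dataclass(frozen=True)
class StandardCurve:
    """Per-primer calibration from a dilution series."""

    slope_m: float            # cycles per log10 template unit, < 0
    intercept: float          # Ct at log10 quantity 0
    efficiency: float         # fold amplification per cycle
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope_m >= 0:
            raise ValueError("invalid standard curve: slope must be negative")
        lo, hi = EFFICIENCY_RANGE
        if not (lo < self.efficiency <= hi):
            logger.warning(
                "primer efficiency %.3f outside (%g, %g]", self.efficiency, lo, hi
            )


@dataclass(frozen=True)
class RelativeQuantity:
    """Efficiency-corrected ratio (copy number or expression fold-change)."""

    target_gene: str
    reference_genes: tuple[str, ...]
    value: float
    method: Literal["geomean", "product"]

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("relative quantity must be positive")


def fit_standard_curve(points: Iterable[tuple[float, float]]) -> StandardCurve:
    """Fit Ct on log10 quantity by ordinary least squares.

    ``points`` are ``(log10_quantity, ct)`` pairs from at least three
    distinct template amounts.  Returns the slope, intercept, efficiency
    ``10**(-1/m)`` and R^2.
    """
    pts = [(float(q), float(c)) for q, c in points]
    if len({q for q, _ in pts}) < 3:
        raise ValueError("standard curve needs >= 3 distinct template quantities")
    logq = np.array([q for q, _ in pts])
    ct = np.array([c for _, c in pts])
    res = stats.linregress(logq, ct)
    if res.slope >= 0:
        raise ValueError("invalid standard curve: Ct does not decrease with template amount")
    return StandardCurve(
        slope_m=float(res.slope),
        intercept=float(res.intercept),
        efficiency=float(10.0 ** (-1.0 / res.slope)),
        r_squared=float(res.rvalue**2),
    )


def mean_ct(cts: float | Sequence[float], label: str = "") -> float:
    """Average replicate Ct values, warning when their range exceeds the QC
    limit of 0.5 cycles."""
    arr = np.atleast_1d(np.asarray(cts, dtype=float))
    if arr.size == 0 or np.any(arr <= 0):
        raise ValueError(f"Ct values must be positive and nonempty ({label})")
    if arr.size > 1 and float(arr.max() - arr.min()) > REPLICATE_QC_RANGE:
        logger.warning(
            "replicate Ct range %.2f cycles exceeds QC limit %.2f (%s)",
            float(arr.max() - arr.min()), REPLICATE_QC_RANGE, label,
        )
    return float(arr.mean())


def relative_quantity(
    calibrator_cts: Mapping[str, float | Sequence[float]],
    sample_cts: Mapping[str, float | Sequence[float]],
    curves: Mapping[str, StandardCurve | float],
    target: str,
    references: Sequence[str],
    combine: Literal["geomean", "product"] = "geomean",
) -> RelativeQuantity:
    """Efficiency-corrected relative quantity of ``target`` in the sample.

    Parameters
    ----------
    calibrator_cts, sample_cts:
        Ct per primer set (scalar or replicate list; replicates are averaged
        before the delta is taken) for the calibrator and the sample.
    curves:
        Per-primer :class:`StandardCurve` (or bare efficiency values).
    target, references:
        Target primer set and one or more single-copy reference primer sets.
    combine:
        How reference terms are combined: ``"geomean"`` (default) or
        ``"product"``.
    """
    if combine not in ("geomean", "product"):
        raise ValueError(f"unknown combine mode {combine!r}")
    if not references:
        raise ValueError("at least one reference gene is required")

    def term(primer: str) -> float:
        for cts, who in ((calibrator_cts, "calibrator"), (sample_cts, "sample")):
            if primer not in cts:
                raise KeyError(f"primer set {primer!r} missing from {who} Ct records")
        if primer not in curves:
            raise KeyError(f"no standard curve / efficiency for primer set {primer!r}")
        curve = curves[primer]
        eff = curve.efficiency if isinstance(curve, StandardCurve) else float(curve)
        lo, hi = EFFICIENCY_RANGE
        if not (lo < eff <= hi):
            logger.warning("efficiency %.3f for %s outside (%g, %g]; proceeding", eff, primer, lo, hi)
        dct = mean_ct(calibrator_cts[primer], f"calibrator/{primer}") - mean_ct(
            sample_cts[primer], f"sample/{primer}"
        )
        return eff**dct

    num = term(target)
    ref_terms = [term(r) for r in references]
    if combine == "geomean":
        denom = math.exp(sum(math.log(t) for t in ref_terms) / len(ref_terms))
    else:
        denom = math.prod(ref_terms)
    return RelativeQuantity(
        target_gene=target,
        reference_genes=tuple(references),
        value=num / denom,
        method=combine,
    )
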