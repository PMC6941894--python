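"""Relative fitness from two-colour competition assays.

Two strains carrying distinguishable fluorescent labels (e.g. YFP test vs
CFP reference) are mixed, grown for ``t`` generations, and counted by flow
cytometry at the start and the end.  With ``R = test/reference`` count
ratios, the per-generation relative fitness is

    w = ln(R(t) / R(0)) / t + 1

so ``w = 1`` is neutral.  Raw ``w`` is normalised by dividing by the ``w``
of a label-control competition (reference vs reference with swapped
labels), which cancels any fitness cost of the label itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CompetitionAssay",
    "FitnessEstimate",
    "relative_fitness",
    "estimate_generations",
    "normalize_fitness",
    "fitness_estimate",
]


@dataclass(frozen=True)
class CompetitionAssay:
    """Label counts at the start and end of a competition."""

    counts_test_initial: float
    counts_ref_initial: float
    counts_test_final: float
    counts_ref_final: float
    generations_t: float

    def __post_init__(self) -> None:
        for name in ("counts_test_initial", "counts_ref_initial",
                     "counts_test_final", "counts_ref_final"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 for a computable ratio")
        if self.generations_t <= 0:
            raise ValueError("generations_t must be > 0")


@dataclass(frozen=True)
class FitnessEstimate:
    w_raw: float
    control_w: float
    w_normalized: float
    se_w: float | None = None  # delta-method SE from Poisson counting error


def relative_fitness(assay: CompetitionAssay) -> float:
    """Raw relative fitness ``w = ln(R(t)/R(0))/t + 1``."""
    r0 = assay.counts_test_initial / assay.counts_ref_initial
    rt = assay.counts_test_final / assay.counts_ref_final
    return math.log(rt / r0) / assay.generations_t + 1.0


def fitness_standard_error(assay: CompetitionAssay) -> float:
    """Delta-method standard error of w under Poisson counting noise.

    Each count c contributes Var(ln c) ~ 1/c, so
    ``se_w = sqrt(sum(1/c)) / t`` over the four counts.
    """
    var_ln = (
        1.0 / assay.counts_test_initial
        + 1.0 / assay.counts_ref_initial
        + 1.0 / assay.counts_test_final
        + 1.0 / assay.counts_ref_final
    )
    return math.sqrt(var_ln) / assay.generations_t


def estimate_generations(
    total_initial: float, total_final: float, dilution_factor_total: float = 1.0
) -> float:
    """Population doublings across all passages.

    ``t = log2(total_final * dilution_factor_total / total_initial)`` where
    ``dilution_factor_total`` is the product of all dilution factors applied
    between the two counts.
    """
    if total_initial <= 0 or total_final <= 0 or dilution_factor_total <= 0:
        raise ValueError("counts and dilution factor must be positive")
    expansion = total_final * dilution_factor_total / total_initial
    if expansion < 1.0:
        raise ValueError(f"nonpositive net expansion (x{expansion:.3g})")
    return math.log2(expansion)


def normalize_fitness(w_raw: float, control_w: float) -> float:
    """Normalise against the label-control competition by division."""
    if control_w <= 0:
        raise ValueError("control_w must be > 0")
    return w_raw / control_w


def fitness_estimate(assay: CompetitionAssay, control_w: float = 1.0) -> FitnessEstimate:
    """Full fitness estimate for one assay: raw w, normalised w, and the
    Poisson delta-method standard error (reported, not used for filtering)."""
    w_raw = relative_fitness(assay)
    return FitnessEstimate(
        w_raw=w_raw,
        control_w=control_w,
        w_normalized=normalize_fitness(w_raw, control_w),
        se_w=fitness_standard_error(assay),
    )
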