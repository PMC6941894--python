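"""Enzyme kinetics: burst-phase progress curves, Michaelis–Menten fits, and
hyperbolic allosteric-effector fits.

Burst phase
-----------
For NADP+-dependent dehydrogenase assays on semialdehyde substrates that
exist mostly as unreactive hydrates, the A340 progress curve shows a rapid
burst (reduction of the pre-existing free aldehyde) followed by a slow
linear phase (limited by dehydration).  Two models quantify the burst
amplitude ``b`` (absorbance units):

    linear       f(x) = m*x + b          (fit to the linear portion only)
    exponential  f(x) = m*x + b*(1 - exp(-x))

The free-aldehyde fraction of the substrate stock is then
``(b / (epsilon * pathlength)) / total_substrate``.

Initial-rate models
-------------------
Michaelis–Menten ``v = Vmax*S/(Km+S)`` is fitted by unweighted nonlinear
least squares with replicate points fitted individually; ``kcat = Vmax/E0``.
Allosteric-effector titrations are fitted to the hyperbola

    v/v0 = (a*L + Kd) / (L + Kd)

with ``a`` the activity at saturating ligand (a < 1: inhibitor, a > 1:
activator) and ``Kd`` the apparent dissociation constant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "EPSILON_NADPH",
    "EPSILON_CITRULLINE_464",
    "ProgressCurve",
    "BurstFit",
    "MMFit",
    "AllostericFit",
    "KineticsFitError",
    "fit_burst",
    "fit_michaelis_menten",
    "fit_allosteric",
    "fold_change",
    "percent_change",
    "citrulline_concentration",
    "coupling_ratio",
]

logger = logging.getLogger(__name__)

#: NADPH molar extinction coefficient at 340 nm (M^-1 cm^-1), standard value.
EPSILON_NADPH = 6220.0
#: Citrulline colorimetric product extinction coefficient at 464 nm (M^-1 cm^-1).
EPSILON_CITRULLINE_464 = 37800.0


class KineticsFitError(RuntimeError):
    """Raised when a kinetic fit fails to converge; carries the best iterate."""

    def __init__(self, message: str, best: object | None = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class ProgressCurve:
    """A340-versus-time progress curve plus the assay constants needed to
    convert absorbance to concentration."""

    time_s: np.ndarray
    a340: np.ndarray
    total_substrate: float          # molar: aldehyde + hydrate (+ P5C)
    pathlength_cm: float = 1.0
    epsilon_nadph: float = EPSILON_NADPH

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        a = np.asarray(self.a340, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "a340", a)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("time_s and a340 must be 1-D arrays of equal length")
        if t[0] != 0 or not np.all(np.diff(t) > 0):
            raise ValueError("time must start at 0 and be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance must be finite")
        if self.epsilon_nadph <= 0 or self.pathlength_cm <= 0 or self.total_substrate <= 0:
            raise ValueError("assay constants must be positive")


@dataclass(frozen=True)
class BurstFit:
    slope_m: float                  # absorbance s^-1 (linear phase)
    burst_b: float                  # absorbance (burst amplitude)
    model: Literal["linear", "exponential"]
    free_fraction: float            # burst concentration / total substrate
    rate_k: float | None = None     # only when the exponential rate was floated


@dataclass(frozen=True)
class MMFit:
    kcat: float                     # s^-1
    km: float                       # molar (free-aldehyde basis where applicable)
    kcat_over_km: float             # M^-1 s^-1
    se_kcat: float
    se_km: float

    def __post_init__(self) -> None:
        if self.kcat <= 0 or self.km <= 0:
            raise ValueError("kcat and km must be positive")


@dataclass(frozen=True)
class AllostericFit:
    kd: float                       # molar; nan when not determined
    a: float                        # v/v0 at infinite ligand
    ligand: str = ""
    determined: bool = True         # False mirrors 'na' table entries

    @property
    def is_inhibitor(self) -> bool:
        return self.a < 1.0


def _free_fraction(b: float, curve: ProgressCurve) -> float:
    conc = b / (curve.epsilon_nadph * curve.pathlength_cm)
    frac = conc / curve.total_substrate
    if frac < 0:
        logger.warning("negative burst amplitude %.4g; clamping free fraction to 0", b)
        return 0.0
    return min(frac, 1.0)


def _auto_linear_window(t: np.ndarray, a: np.ndarray, r2_min: float = 0.995) -> tuple[float, float]:
    """Longest suffix of the curve whose straight-line fit has R^2 >= r2_min."""
    n = t.size
    for start in range(0, n - 2):
        seg_t, seg_a = t[start:], a[start:]
        r = stats.linregress(seg_t, seg_a)
        if r.rvalue**2 >= r2_min:
            return float(seg_t[0]), float(seg_t[-1])
    return float(t[n - 3]), float(t[-1])


def fit_burst(
    curve: ProgressCurve,
    model: Literal["linear", "exponential"] = "exponential",
    linear_window: tuple[float, float] | None = None,
    float_rate_constant: bool = False,
) -> BurstFit:
    """Fit the burst amplitude of a progress curve.

    For ``model="linear"`` only points inside ``linear_window`` (seconds,
    inclusive) are used; when no window is given, the longest suffix whose
    linear fit has R^2 >= 0.995 is chosen automatically.  For
    ``model="exponential"`` the whole curve is fitted to
    ``m*x + b*(1-exp(-k*x))`` with the rate constant fixed at ``k = 1`` s^-1
    unless ``float_rate_constant`` is set.
    """
    t, a = curve.time_s, curve.a340
    if t.size < 6:
        raise ValueError("progress curve needs >= 6 points")
    if model == "linear":
        if linear_window is None:
            linear_window = _auto_linear_window(t, a)
        lo, hi = linear_window
        mask = (t >= lo) & (t <= hi)
        if mask.sum() < 3:
            raise ValueError(f"linear window {linear_window} contains < 3 points")
        res = stats.linregress(t[mask], a[mask])
        m, b = float(res.slope), float(res.intercept)
        return BurstFit(m, b, "linear", _free_fraction(b, curve))
    if model != "exponential":
        raise ValueError(f"unknown burst model {model!r}")
    if float_rate_constant:
        def f(x, m, b, k):
            return m * x + b * (1.0 - np.exp(-k * x))
        p0 = (max((a[-1] - a[-2]) / (t[-1] - t[-2]), 1e-9), max(a[1], 1e-3), 1.0)
        try:
            popt, _ = curve_fit(f, t, a, p0=p0, maxfev=20000)
        except RuntimeError as exc:
            raise KineticsFitError(f"burst fit did not converge: {exc}") from exc
        m, b, k = (float(v) for v in popt)
        return BurstFit(m, b, "exponential", _free_fraction(b, curve), rate_k=k)
    # printed form: time constant fixed at 1 s, so the model is linear in (m, b)
    design = np.column_stack([t, 1.0 - np.exp(-t)])
    (m, b), *_ = np.linalg.lstsq(design, a, rcond=None)
    return BurstFit(float(m), float(b), "exponential", _free_fraction(float(b), curve))


def michaelis_menten(s: np.ndarray, vmax: float, km: float) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def fit_michaelis_menten(
    substrate: Sequence[float],
    rates: Sequence[float],
    enzyme_conc: float,
) -> MMFit:
    """Nonlinear least-squares Michaelis–Menten fit.

    ``substrate`` in molar (free-aldehyde basis where the substrate stock is
    mostly hydrated), ``rates`` in molar s^-1 (replicates listed
    individually), ``enzyme_conc`` in molar.  Standard errors come from the
    fit covariance; ``se_kcat = se_Vmax / enzyme_conc``.
    """
    s = np.asarray(substrate, dtype=float)
    v = np.asarray(rates, dtype=float)
    if s.size != v.size or np.unique(s).size < 4:
        raise ValueError("need rates at >= 4 distinct substrate concentrations")
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be positive")
    # fit in rescaled units (the model commutes with unit changes exactly);
    # raw molar rates can be ~1e-8, far below the optimizer's step scales
    s_ref, v_ref = float(s.max()), float(np.abs(v).max())
    if v_ref == 0:
        raise ValueError("all rates are zero")
    su, vu = s / s_ref, v / v_ref
    p0 = (float(vu.max()), float(np.median(su)))
    try:
        popt, pcov = curve_fit(
            michaelis_menten, su, vu, p0=p0,
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise KineticsFitError(f"Michaelis-Menten fit did not converge: {exc}", best=p0) from exc
    pcov = pcov * np.outer([v_ref, s_ref], [v_ref, s_ref])
    vmax, km = float(popt[0]) * v_ref, float(popt[1]) * s_ref
    if km > 10.0 * s.max():
        logger.warning("extrapolated Km: fitted Km %.3g exceeds 10x max substrate %.3g", km, s.max())
    perr = np.sqrt(np.diag(pcov))
    kcat = vmax / enzyme_conc
    return MMFit(
        kcat=kcat,
        km=km,
        kcat_over_km=kcat / km,
        se_kcat=float(perr[0]) / enzyme_conc,
        se_km=float(perr[1]),
    )


def allosteric_response(ligand: np.ndarray, kd: float, a: float) -> np.ndarray:
    """Hyperbolic effector model ``v/v0 = (a*L + Kd)/(L + Kd)``."""
    ligand = np.asarray(ligand, dtype=float)
    return (a * ligand + kd) / (ligand + kd)


def fit_allosteric(
    ligand: Sequence[float],
    v_over_v0: Sequence[float],
    ligand_name: str = "",
    flat_tol: float = 0.05,
) -> AllostericFit:
    """Fit the hyperbolic effector model to a ligand titration.

    Requires >= 4 ligand levels including (or near) zero.  A flat response
    (total modulation below ``flat_tol``) leaves Kd unidentifiable: the fit
    returns ``a = 1`` with ``kd = nan`` and ``determined = False``, the
    analogue of an 'na' table entry.
    """
    L = np.asarray(ligand, dtype=float)
    y = np.asarray(v_over_v0, dtype=float)
    if L.size != y.size or np.unique(L).size < 4:
        raise ValueError("need >= 4 distinct ligand concentrations")
    if L.min() > 0.05 * L.max():
        raise ValueError("titration must include a zero or near-zero ligand level")
    span = float(abs(y.max() - y.min()))
    if span < flat_tol:
        logger.info("flat effector response (span %.3g); Kd not determined", span)
        return AllostericFit(kd=math.nan, a=1.0, ligand=ligand_name, determined=False)
    a0 = float(y[np.argmax(L)])
    l_ref = float(L.max())  # fit ligand in rescaled units (model commutes exactly)
    lu = L / l_ref
    p0 = (float(np.median(lu[lu > 0])), a0)
    try:
        popt, _ = curve_fit(
            allosteric_response, lu, y, p0=p0,
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise KineticsFitError(f"allosteric fit did not converge: {exc}", best=p0) from exc
    return AllostericFit(kd=float(popt[0]) * l_ref, a=float(popt[1]), ligand=ligand_name)


# ---------------------------------------------------------------------------
# derived scalar statistics

def catalytic_efficiency(kcat: float, km: float) -> float:
    """kcat/Km in M^-1 s^-1 from kcat (s^-1) and Km (M)."""
    if km <= 0:
        raise ValueError("Km must be positive")
    return kcat / km


def fold_change(x: float, y: float) -> float:
    """x/y — e.g. the catalytic-efficiency ratio of two enzyme variants."""
    if y == 0:
        raise ZeroDivisionError("fold change undefined for zero denominator")
    return x / y


def percent_change(x: float, y: float) -> float:
    """100*(x/y - 1) — percent difference of x relative to y."""
    return 100.0 * (fold_change(x, y) - 1.0)


def citrulline_concentration(
    a464: float, pathlength_cm: float = 1.0, epsilon: float = EPSILON_CITRULLINE_464
) -> float:
    """Citrulline concentration (M) from the colorimetric A464 reading."""
    if epsilon <= 0 or pathlength_cm <= 0:
        raise ZeroDivisionError("extinction coefficient and pathlength must be positive")
    return a464 / (epsilon * pathlength_cm)


def coupling_ratio(mol_carbamoyl_phosphate: float, mol_atp_hydrolyzed: float) -> float:
    """Mol carbamoyl phosphate formed per mol ATP hydrolysed.

    Carbamoyl phosphate synthetase consumes two ATP per product, so a fully
    coupled enzyme gives ~0.5.
    """
    if mol_atp_hydrolyzed == 0:
        raise ZeroDivisionError("coupling ratio undefined without ATP turnover")
    return mol_carbamoyl_phosphate / mol_atp_hydrolyzed
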