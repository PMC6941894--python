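"""Synthetic-data generators with known ground truth for every input class.

Each generator emulates one measurement class of the adaptation study —
turbidostat OD sawtooth traces, plate-reader growth curves, qPCR Ct tables
with standard curves, two-colour competition counts, burst-phase progress
curves, and initial-rate tables — and returns a tidy table together with a
sidecar dict of the generating (true) parameters, so every estimator can be
tested by round-trip recovery without any external data.

Default noise magnitudes are plausible bench values: OD multiplicative
sigma 1%, Ct sigma 0.15 cycles, absorbance sigma 0.002, proportional rate
sigma 5%, and 10^4 counted events per flow-cytometry channel.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd

from . import growth as _growth
from . import kinetics as _kinetics

__all__ = [
    "GeneratorSpec",
    "turbidostat_trace",
    "growth_curve",
    "ct_table",
    "competition_counts",
    "progress_curve",
    "mm_rates",
    "allosteric_rates",
    "generate",
    "fixture_suite",
]

#: default noise magnitudes (all overridable per call)
OD_MULT_SIGMA = 0.01
CT_SIGMA = 0.15
A340_SIGMA = 0.002
RATE_CV = 0.05
EVENTS_PER_CHANNEL = 10_000


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one synthetic dataset."""

    kind: str
    true_params: dict[str, Any] = field(default_factory=dict)
    noise: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def turbidostat_trace(
    mu: float = 0.27,
    n_cycles: int = 1440,
    od_setpoint: float = 0.4,
    cycle_s: float = 60.0,
    read_interval_s: float = 3.0,
    noise_sigma: float = OD_MULT_SIGMA,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Exponential growth between dilutions, reset to the OD setpoint at every
    dilution, with multiplicative lognormal measurement noise per reading.

    Defaults mirror the device regime: a reading every ~3 s and a dilution
    every 60 s, so 1440 cycles span one day.
    """
    rng = np.random.default_rng(seed)
    reads = int(round(cycle_s / read_interval_s))
    t_within = np.arange(reads) * read_interval_s / 3600.0  # hours
    rows_t, rows_od, rows_dil = [], [], []
    for c in range(n_cycles):
        t0 = c * cycle_s / 3600.0
        od_true = od_setpoint * np.exp(mu * t_within)
        noise = np.exp(rng.normal(0.0, noise_sigma, size=reads)) if noise_sigma > 0 else 1.0
        rows_t.append(t0 + t_within)
        rows_od.append(od_true * noise)
        dil = np.zeros(reads, dtype=int)
        dil[0] = 1 if c > 0 else 0
        rows_dil.append(dil)
    df = pd.DataFrame(
        {
            "time_h": np.concatenate(rows_t),
            "od": np.concatenate(rows_od),
            "dilution": np.concatenate(rows_dil),
        }
    )
    truth = {
        "mu": mu, "n_cycles": n_cycles, "od_setpoint": od_setpoint,
        "cycle_s": cycle_s, "read_interval_s": read_interval_s,
        "noise_sigma": noise_sigma, "seed": seed,
    }
    return df, truth


def growth_curve(
    mu_max: float = 0.27,
    lag: float = 2.0,
    a_max: float = 0.5,
    baseline: float = 0.05,
    t_max_h: float = 24.0,
    interval_min: float = 20.0,
    noise_sigma: float = 0.01,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Modified-Gompertz growth curve on a constant baseline with additive
    Gaussian noise, sampled at the plate reader's cadence (20 min)."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max_h + 1e-9, interval_min / 60.0)
    y = baseline + _growth.gompertz(t, mu_max, lag, a_max)
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, size=t.size)
    df = pd.DataFrame({"time_h": t, "od": y})
    truth = {
        "mu_max": mu_max, "lag": lag, "a_max": a_max, "baseline": baseline,
        "noise_sigma": noise_sigma, "seed": seed,
    }
    return df, truth


def ct_table(
    copy_number: float = 7.0,
    efficiencies: dict[str, float] | None = None,
    target: str = "proA",
    references: Sequence[str] = ("gyrB", "icd"),
    calibrator_id: str = "AM187",
    sample_id: str = "sample",
    intercept_ct: float = 25.0,
    ct_sigma: float = CT_SIGMA,
    replicates: int = 3,
    n_standards: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, Any]]:
    """Ct table plus dilution-series standards generated from a true target
    copy number.

    The model is ``Ct = intercept - log_E(quantity)``: the calibrator carries
    every gene at quantity 1, the sample carries the target at quantity
    ``copy_number`` and the single-copy references at 1.  Standards span
    ``n_standards`` ten-fold dilutions.  Technical triplicates by default.
    """
    rng = np.random.default_rng(seed)
    genes = [target, *references]
    effs = dict(efficiencies or {})
    for g in genes:
        effs.setdefault(g, 2.0)

    def ct_of(quantity: float, gene: str) -> float:
        # Ct = intercept - log_E(quantity): more template crosses threshold earlier
        return intercept_ct - math.log(quantity) / math.log(effs[gene])

    rows = []
    for sid in (calibrator_id, sample_id):
        for gene in genes:
            q = copy_number if (sid == sample_id and gene == target) else 1.0
            for rep in range(replicates):
                noise = rng.normal(0.0, ct_sigma) if ct_sigma > 0 else 0.0
                rows.append(
                    {"sample_id": sid, "primer_set": gene, "replicate": rep + 1,
                     "ct": ct_of(q, gene) + noise}
                )
    cts = pd.DataFrame(rows)

    std_rows = []
    for gene in genes:
        for d in range(n_standards):
            logq = -float(d)  # 10-fold dilutions down from quantity 1
            for rep in range(replicates):
                noise = rng.normal(0.0, ct_sigma) if ct_sigma > 0 else 0.0
                std_rows.append(
                    {"primer_set": gene, "log10_quantity": logq,
                     "ct": ct_of(10.0**logq, gene) + noise}
                )
    standards = pd.DataFrame(std_rows)
    truth = {
        "copy_number": copy_number, "efficiencies": effs, "target": target,
        "references": list(references), "calibrator_id": calibrator_id,
        "sample_id": sample_id, "ct_sigma": ct_sigma, "replicates": replicates,
        "seed": seed,
    }
    return cts, standards, truth


def competition_counts(
    w_true: float = 1.05,
    generations: float = 20.0,
    init_ratio: float = 1.0,
    events_per_timepoint: int = EVENTS_PER_CHANNEL * 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Two-strain competition: deterministic selection at per-generation
    fitness ``w_true`` with binomially sampled two-colour counts.

    ``ln(R(t)/R(0)) = (w_true - 1) * t`` exactly, so the fitness estimator is
    closed-form unbiased up to counting noise.
    """
    rng = np.random.default_rng(seed)
    r0 = init_ratio
    rt = r0 * math.exp((w_true - 1.0) * generations)
    rows = []
    for timepoint, ratio in (("initial", r0), ("final", rt)):
        f_test = ratio / (1.0 + ratio)
        n_test = int(rng.binomial(events_per_timepoint, f_test))
        rows.append({"timepoint": timepoint, "channel": "test", "count": n_test})
        rows.append({"timepoint": timepoint, "channel": "ref", "count": events_per_timepoint - n_test})
    df = pd.DataFrame(rows)
    truth = {
        "w_true": w_true, "generations": generations, "init_ratio": init_ratio,
        "events_per_timepoint": events_per_timepoint, "seed": seed,
    }
    return df, truth


def progress_curve(
    slope_m: float = 1e-3,
    burst_b: float = 0.05,
    total_substrate: float = 2e-3,
    duration_s: float = 60.0,
    dt_s: float = 0.5,
    noise_sigma: float = A340_SIGMA,
    pathlength_cm: float = 1.0,
    epsilon_nadph: float = _kinetics.EPSILON_NADPH,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Burst-plus-linear progress curve ``m*x + b*(1 - exp(-x))`` with
    additive absorbance noise, followed for 60 s as in the assay."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + 1e-9, dt_s)
    a = slope_m * t + burst_b * (1.0 - np.exp(-t))
    if noise_sigma > 0:
        a = a + rng.normal(0.0, noise_sigma, size=t.size)
    df = pd.DataFrame({"time_s": t, "a340": a})
    truth = {
        "slope_m": slope_m, "burst_b": burst_b, "total_substrate": total_substrate,
        "pathlength_cm": pathlength_cm, "epsilon_nadph": epsilon_nadph,
        "free_fraction": (burst_b / (epsilon_nadph * pathlength_cm)) / total_substrate,
        "noise_sigma": noise_sigma, "seed": seed,
    }
    return df, truth


#: geometric ladder of substrate levels spanning well below to well above Km
MM_LEVELS_OVER_KM = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)


def mm_rates(
    kcat: float = 0.21,
    km: float = 9.5e-5,
    enzyme_conc: float = 2e-7,
    s_levels: Sequence[float] | None = None,
    noise_cv: float = RATE_CV,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Initial-rate table from the Michaelis–Menten model with proportional
    Gaussian noise, technical triplicates at eight substrate levels spanning
    0.25-32x Km by default."""
    rng = np.random.default_rng(seed)
    if s_levels is None:
        s_levels = [f * km for f in MM_LEVELS_OVER_KM]
    rows = []
    vmax = kcat * enzyme_conc
    for s in s_levels:
        v_true = vmax * s / (km + s)
        for rep in range(replicates):
            fac = 1.0 + (rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0)
            rows.append({"conc_M": s, "rate": v_true * fac, "replicate": rep + 1})
    df = pd.DataFrame(rows)
    truth = {
        "kcat": kcat, "km": km, "enzyme_conc": enzyme_conc,
        "s_levels": list(map(float, s_levels)), "noise_cv": noise_cv,
        "replicates": replicates, "seed": seed,
    }
    return df, truth


def allosteric_rates(
    kd: float = 0.81e-6,
    a: float = 0.27,
    l_levels: Sequence[float] | None = None,
    noise_cv: float = RATE_CV,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Effector titration ``v/v0 = (a*L + Kd)/(L + Kd)`` with proportional
    noise; levels span zero and 0.1-100x Kd by default."""
    rng = np.random.default_rng(seed)
    if l_levels is None:
        l_levels = [0.0] + [f * kd for f in (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)]
    rows = []
    for L in l_levels:
        y_true = float(_kinetics.allosteric_response(np.array([L]), kd, a)[0])
        for rep in range(replicates):
            fac = 1.0 + (rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0)
            rows.append({"conc_M": L, "v_over_v0": y_true * fac, "replicate": rep + 1})
    df = pd.DataFrame(rows)
    truth = {
        "kd": kd, "a": a, "l_levels": list(map(float, l_levels)),
        "noise_cv": noise_cv, "replicates": replicates, "seed": seed,
    }
    return df, truth


_GENERATORS: dict[str, Callable[..., tuple]] = {
    "trace": turbidostat_trace,
    "growth_curve": growth_curve,
    "ct_table": ct_table,
    "competition": competition_counts,
    "progress_curve": progress_curve,
    "mm_rates": mm_rates,
    "allosteric_rates": allosteric_rates,
}


def generate(spec: GeneratorSpec) -> tuple:
    """Dispatch on ``spec.kind``; returns the generator's tables followed by
    the ground-truth sidecar dict."""
    if spec.kind not in _GENERATORS:
        raise ValueError(
            f"unknown generator kind {spec.kind!r}; choose from {sorted(_GENERATORS)}"
        )
    return _GENERATORS[spec.kind](**spec.true_params, **spec.noise, seed=spec.seed)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def fixture_suite(seed: int, outdir: str | Path) -> dict[str, Any]:
    """Write one deterministic fixture per kind plus ``manifest.json`` with
    every true parameter and per-file checksums; byte-identical across runs
    for a given seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": seed, "fixtures": {}}
    for kind in sorted(_GENERATORS):
        result = generate(GeneratorSpec(kind=kind, seed=seed))
        *tables, truth = result
        files = []
        for i, table in enumerate(tables):
            suffix = "" if len(tables) == 1 else f"_{('main', 'standards')[i]}"
            path = outdir / f"{kind}{suffix}.tsv"
            table.to_csv(path, sep="\t", index=False, float_format="%.10g")
            files.append(path.name)
        manifest["fixtures"][kind] = {
            "files": files,
            "truth": truth,
            "sha256": {f: _sha256(outdir / f) for f in files},
        }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
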