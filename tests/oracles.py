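"""Independent oracles used by the test suite.

The agent-based simulator enumerates every cell explicitly and applies the
same per-cell event probabilities as the class-based engine (selection by
weighted parent choice, per-copy mutation, recombination through the
duplicated-pool hypergeometric kernel).  It is deliberately written against
the per-cell event definitions, not against the engine's matrix algebra, so
distributional agreement between the two is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np

from weaklink import iad


def agent_population(classes_counts: dict[tuple[int, int], int]) -> tuple[np.ndarray, np.ndarray]:
    ks, js = [], []
    for (k, j), n in classes_counts.items():
        ks.extend([k] * n)
        js.extend([j] * n)
    return np.array(ks, dtype=int), np.array(js, dtype=int)


def _lookup_tables(params: iad.SimParams) -> tuple[np.ndarray, np.ndarray]:
    """(k_max+1, k_max+1) tables of per-genotype fitness and mutation prob."""
    km = params.k_max
    fit = np.zeros((km + 1, km + 1))
    pmut = np.zeros((km + 1, km + 1))
    for k in range(1, km + 1):
        for j in range(k + 1):
            fit[k, j] = iad.genotype_fitness((k, j), params.fitness_map)
            if j < k:
                pmut[k, j] = iad.per_array_mutation_rate(params.mu_gene, k - j)
    return fit, pmut


def agent_step(
    k: np.ndarray, j: np.ndarray, params: iad.SimParams, rng: np.random.Generator,
    tables: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One Wright-Fisher generation over an explicit cell list."""
    n = k.size
    fit_t, pmut_t = tables if tables is not None else _lookup_tables(params)
    fit = fit_t[k, j]
    mu_max = fit.max()
    dt = math.log(2.0) / mu_max
    w = np.exp(fit * dt)
    parents = rng.choice(n, size=params.n_pop, p=w / w.sum())
    k, j = k[parents].copy(), j[parents].copy()
    # mutation: one wild-type copy converts, with the same per-array probability
    j = j + (rng.random(params.n_pop) < pmut_t[k, j])
    # recombination through the duplicated-pool kernel
    recomb = (rng.random(params.n_pop) < params.rec_rate) & (k >= 2)
    idx = np.flatnonzero(recomb)
    if idx.size:
        delta = rng.choice((-1, 0, 1), size=idx.size, p=params.copy_change_probs)
        k_new = np.clip(k[idx] + delta, 1, params.k_max)
        j_new = rng.hypergeometric(2 * j[idx], 2 * (k[idx] - j[idx]), k_new)
        k[idx], j[idx] = k_new, j_new
    return k, j


def agent_run_class_counts(
    init: dict[tuple[int, int], int],
    params: iad.SimParams,
    n_generations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Final per-class counts (canonical class order) of one agent replicate."""
    k, j = agent_population(init)
    tables = _lookup_tables(params)
    for _ in range(n_generations):
        k, j = agent_step(k, j, params, rng, tables)
    classes, index = iad.genotype_classes(params.k_max)
    counts = np.zeros(len(classes))
    for kk, jj in zip(k, j):
        counts[index[iad.ArrayGenotype(int(kk), int(jj))]] += 1
    return counts
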