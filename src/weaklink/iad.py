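"""Stochastic simulation of allelic sweeps in tandem gene-amplification arrays.

Under the innovation-amplification-divergence (IAD) scenario, a weak
promiscuous enzyme activity becomes essential, the gene amplifies to a
tandem array of ``k`` copies, and a beneficial point mutation arising in one
copy must spread both *within* the array and *through* the population.
Because homologous recombination between array repeats occurs in roughly 1
of every 100 cell divisions while point mutations in any single copy occur
at ~1e-5 to 1e-6 per division, recombination homogenizes the array (an
intra-array allelic sweep, visible as loss of heterozygosity) long before an
independent second mutation appears.

The engine is a discrete-generation Wright–Fisher model over genotype
classes ``(k, j)`` — array copy number ``k`` and mutant-copy count ``j`` —
with, per generation:

1. selection: expected offspring of a class proportional to
   ``count * exp(growth_rate * dt)`` with ``dt`` chosen so the fittest class
   present doubles per generation;
2. mutation: each class leaks probability ``(k - j) * mu_gene`` into
   ``(k, j+1)``;
3. recombination: a fraction ``rec_rate`` of each class with ``k >= 2`` is
   redrawn through the homogenization kernel — the array is duplicated to a
   ``2k``-copy pool containing ``2j`` mutant copies, the copy-number change
   ``delta`` is drawn from ``copy_change_probs``, and the daughter's mutant
   count is hypergeometric: ``j' ~ H(2k, 2j, k')``;
4. multinomial resampling back to constant population size ``n_pop``.

All per-class transformations (selection, mutation, recombination) act on
expected proportions, so the only sampling noise is the single multinomial
draw; on small instances the class-based engine is distributionally
equivalent to an explicit agent-based simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterator, Literal, NamedTuple

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "ArrayGenotype",
    "FitnessMap",
    "SimParams",
    "PopulationState",
    "Trajectory",
    "SweepOutcome",
    "per_array_mutation_rate",
    "genotype_fitness",
    "recombine",
    "recombination_matrix",
    "founder_state",
    "step",
    "expected_step",
    "run",
    "sweep_replicate",
    "single_lineage_homogenization_time",
    "replicate_rng",
]

LN2 = math.log(2.0)


class ArrayGenotype(NamedTuple):
    """A tandem array of ``k`` gene copies of which ``j`` carry the mutant allele."""

    k: int
    j: int

    def validate(self, k_max: int) -> "ArrayGenotype":
        if not (1 <= self.k <= k_max):
            raise ValueError(f"copy number {self.k} outside [1, {k_max}]")
        if not (0 <= self.j <= self.k):
            raise ValueError(f"mutant count {self.j} outside [0, {self.k}]")
        return self


@dataclass(frozen=True)
class FitnessMap:
    """Dosage-dependent growth-rate map for array genotypes.

    ``proportional`` mode: ``mu = mu0 * (1 + s_max * j/k) - cost * (k - 1)``,
    so a fully mutant array realises the full benefit ``s_max`` regardless of
    copy number.  ``saturating`` mode: total enzyme activity
    ``A = (k - j) * activity_wt + j * activity_mut`` feeds a Michaelis-like
    benefit ``mu0 * (1 + s_max * A / (A + k_half)) - cost * (k - 1)``.
    Growth rates are clamped at zero.
    """

    mu0: float = 0.24                  # base growth rate, h^-1 (turbidostat anchor)
    s_max: float = 0.75                # max fractional benefit (fully mutant array)
    mode: Literal["proportional", "saturating"] = "proportional"
    cost_per_copy: float = 0.0         # h^-1 penalty per extra array copy
    activity_wt: float = 1.0           # per-copy activity units (saturating mode)
    activity_mut: float = 10.0
    k_half: float = 10.0               # activity at half-maximal benefit

    def __post_init__(self) -> None:
        if self.mu0 <= 0 or self.cost_per_copy < 0:
            raise ValueError("mu0 must be > 0 and cost_per_copy >= 0")
        if self.mode not in ("proportional", "saturating"):
            raise ValueError(f"unknown dosage mode {self.mode!r}")


@dataclass(frozen=True)
class SimParams:
    """Parameters of the amplification-divergence simulation.

    Defaults encode the study conditions: point mutations at 1e-9 per
    nucleotide per division over a ~1 kb gene (1e-6 per gene), recombination
    in ~1 of every 100 divisions, arrays up to 20 copies, a 7-copy starting
    array, and a +75% growth benefit for a fully mutant array.
    """

    mu_nt: float = 1e-9                # mutations per nucleotide per division
    gene_length_nt: int = 1000
    rec_rate: float = 0.01             # recombination events per division
    n_pop: int = 100_000
    k_max: int = 20
    fitness_map: FitnessMap = field(default_factory=FitnessMap)
    copy_change_probs: tuple[float, float, float] = (0.25, 0.50, 0.25)  # delta -1/0/+1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu_nt <= 1.0) or self.gene_length_nt < 1:
            raise ValueError("invalid mutation parameters")
        if not (0.0 <= self.rec_rate <= 1.0):
            raise ValueError("rec_rate must lie in [0, 1]")
        if self.n_pop < 1 or self.k_max < 1:
            raise ValueError("n_pop and k_max must be >= 1")
        if len(self.copy_change_probs) != 3 or not math.isclose(
            sum(self.copy_change_probs), 1.0, abs_tol=1e-9
        ):
            raise ValueError("copy_change_probs must be three probabilities summing to 1")
        if any(p < 0 for p in self.copy_change_probs):
            raise ValueError("copy_change_probs must be nonnegative")

    @property
    def mu_gene(self) -> float:
        """Per-gene per-division mutation probability."""
        return min(self.mu_nt * self.gene_length_nt, 1.0)

    def with_mu_gene(self, mu_gene: float) -> "SimParams":
        """Convenience: set the per-gene rate directly (gene length 1 nt)."""
        return replace(self, mu_nt=mu_gene, gene_length_nt=1)


@dataclass
class PopulationState:
    """Counts per ``(k, j)`` genotype class at one generation.

    ``counts`` is indexed by the canonical class order of
    :func:`genotype_classes`; float counts are allowed in the deterministic
    (no-resampling) limit.
    """

    counts: np.ndarray
    generation: int = 0
    k_max: int = 20

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        classes, _ = genotype_classes(self.k_max)
        if self.counts.shape != (len(classes),):
            raise ValueError(
                f"counts must have length {len(classes)} for k_max={self.k_max}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    def count_of(self, g: ArrayGenotype | tuple[int, int]) -> float:
        _, index = genotype_classes(self.k_max)
        return float(self.counts[index[ArrayGenotype(*g)]])


class SweepOutcome(NamedTuple):
    """Result of a single sweep replicate run to absorption or a cap."""

    fixed: bool                 # every cell fully mutant (j == k)
    loh_generation: int | None  # first generation with no heterozygous cells
    #   while at least one fully mutant cell exists
    generations: int            # generations actually simulated


@dataclass
class Trajectory:
    """Per-generation summaries of one simulation replicate."""

    generation: np.ndarray
    mean_copy_number: np.ndarray
    mutant_freq_copy: np.ndarray   # mutant copies / all copies
    mutant_freq_cell: np.ndarray   # fraction of cells with >= 1 mutant copy
    heterozygosity: np.ndarray     # fraction of cells with 0 < j < k
    loh_generation: int | None
    fixed: bool
    replicate: int = 0


# ---------------------------------------------------------------------------
# class bookkeeping and cached model matrices

@lru_cache(maxsize=8)
def genotype_classes(k_max: int) -> tuple[tuple[ArrayGenotype, ...], dict[ArrayGenotype, int]]:
    """Canonical ordering of all ``(k, j)`` classes for a given ``k_max``."""
    classes = tuple(
        ArrayGenotype(k, j) for k in range(1, k_max + 1) for j in range(k + 1)
    )
    return classes, {g: i for i, g in enumerate(classes)}


@dataclass(frozen=True)
class _Model:
    classes: tuple[ArrayGenotype, ...]
    fit: np.ndarray            # growth rate per class, h^-1
    mut_src: np.ndarray        # classes with j < k
    mut_dst: np.ndarray        # corresponding (k, j+1)
    mut_rate: np.ndarray       # (k - j) * mu_gene
    rec_matrix: np.ndarray     # column-stochastic homogenization kernel
    k_arr: np.ndarray
    j_arr: np.ndarray


def per_array_mutation_rate(mu_gene: float, k: int) -> float:
    """Probability that at least one of ``k`` copies mutates in one division.

    ``k * mu_gene`` to first order; the exact ``1 - (1 - mu_gene)**k`` is
    used when ``mu_gene`` is large enough (> 1e-3) for the linearisation to
    matter.
    """
    if k < 1 or not (0.0 <= mu_gene <= 1.0):
        raise ValueError("need k >= 1 and 0 <= mu_gene <= 1")
    if mu_gene > 1e-3:
        return 1.0 - (1.0 - mu_gene) ** k
    return k * mu_gene


def genotype_fitness(g: ArrayGenotype | tuple[int, int], fm: FitnessMap) -> float:
    """Growth rate (h^-1) of an array genotype under the dosage map."""
    k, j = g
    if fm.mode == "proportional":
        mu = fm.mu0 * (1.0 + fm.s_max * j / k)
    else:
        activity = (k - j) * fm.activity_wt + j * fm.activity_mut
        mu = fm.mu0 * (1.0 + fm.s_max * activity / (activity + fm.k_half))
    return max(mu - fm.cost_per_copy * (k - 1), 0.0)


def recombine(
    g: ArrayGenotype | tuple[int, int], params: SimParams, rng: np.random.Generator
) -> ArrayGenotype:
    """One homologous-recombination event on a single array.

    The replicated ``2k``-copy pool holds ``2j`` mutant copies; the daughter
    array size changes by ``delta`` drawn from ``copy_change_probs`` and its
    mutant count is a hypergeometric draw of ``k'`` copies from that pool.
    Single-copy arrays (``k = 1``) are returned unchanged.
    """
    k, j = g
    if k < 2:
        return ArrayGenotype(k, j)
    delta = int(rng.choice((-1, 0, 1), p=params.copy_change_probs))
    k_new = min(max(k + delta, 1), params.k_max)
    j_new = int(rng.hypergeometric(2 * j, 2 * (k - j), k_new))
    return ArrayGenotype(k_new, j_new)


def recombination_matrix(params: SimParams) -> np.ndarray:
    """Column-stochastic matrix of the homogenization kernel over all classes.

    Column ``i`` is the distribution of daughter classes for a recombining
    cell of class ``i``; ``k = 1`` columns are identity (no recombination).
    """
    return _model(params).rec_matrix


@lru_cache(maxsize=8)
def _cached_model(
    k_max: int,
    mu_gene: float,
    copy_change_probs: tuple[float, float, float],
    fm: FitnessMap,
) -> _Model:
    classes, index = genotype_classes(k_max)
    n = len(classes)
    k_arr = np.array([g.k for g in classes])
    j_arr = np.array([g.j for g in classes])
    fit = np.array([genotype_fitness(g, fm) for g in classes])

    src, dst, rate = [], [], []
    for i, (k, j) in enumerate(classes):
        if j < k:
            src.append(i)
            dst.append(index[ArrayGenotype(k, j + 1)])
            rate.append(per_array_mutation_rate(mu_gene, k - j))
    mut_src = np.array(src, dtype=np.intp)
    mut_dst = np.array(dst, dtype=np.intp)
    mut_rate = np.array(rate)

    rec = np.zeros((n, n))
    for i, (k, j) in enumerate(classes):
        if k < 2:
            rec[i, i] = 1.0
            continue
        for delta, p_delta in zip((-1, 0, 1), copy_change_probs):
            if p_delta == 0.0:
                continue
            k_new = min(max(k + delta, 1), k_max)
            j_vals = np.arange(max(0, k_new - 2 * (k - j)), min(k_new, 2 * j) + 1)
            pmf = hypergeom.pmf(j_vals, 2 * k, 2 * j, k_new)
            for j_new, p in zip(j_vals, pmf):
                rec[index[ArrayGenotype(k_new, int(j_new))], i] += p_delta * p
    return _Model(classes, fit, mut_src, mut_dst, mut_rate, rec, k_arr, j_arr)


def _model(params: SimParams) -> _Model:
    return _cached_model(
        params.k_max, params.mu_gene, tuple(params.copy_change_probs), params.fitness_map
    )


# ---------------------------------------------------------------------------
# state construction

def founder_state(
    params: SimParams,
    resident: tuple[int, int] = (7, 0),
    founder: tuple[int, int] | None = (7, 1),
    n_founders: int = 1,
) -> PopulationState:
    """Population of ``n_pop`` resident cells with ``n_founders`` cells of the
    founder genotype substituted in."""
    classes, index = genotype_classes(params.k_max)
    counts = np.zeros(len(classes))
    res = ArrayGenotype(*resident).validate(params.k_max)
    counts[index[res]] = params.n_pop
    if founder is not None and n_founders > 0:
        fdr = ArrayGenotype(*founder).validate(params.k_max)
        counts[index[res]] -= n_founders
        counts[index[fdr]] += n_founders
    return PopulationState(counts=counts, generation=0, k_max=params.k_max)


# ---------------------------------------------------------------------------
# dynamics

def _expected_proportions(counts: np.ndarray, params: SimParams, model: _Model) -> np.ndarray:
    total = counts.sum()
    if total <= 0:
        raise RuntimeError("population extinct")
    present = counts > 0
    mu_max = model.fit[present].max()
    if mu_max <= 0:
        raise RuntimeError("population inviable: all present classes have zero fitness")
    dt = LN2 / mu_max  # the fittest class present doubles each generation
    p = counts * np.exp(model.fit * dt)
    p /= p.sum()
    # mutation: leak (k - j) * mu_gene of each class into (k, j + 1)
    if model.mut_rate.size and params.mu_gene > 0:
        flux = p[model.mut_src] * model.mut_rate
        p = p.copy()
        p[model.mut_src] -= flux
        p[model.mut_dst] += flux
    # recombination: fraction rec_rate redrawn through the kernel
    if params.rec_rate > 0:
        p = (1.0 - params.rec_rate) * p + params.rec_rate * (model.rec_matrix @ p)
    return p / p.sum()


def step(
    state: PopulationState, params: SimParams, rng: np.random.Generator
) -> PopulationState:
    """One Wright–Fisher generation: selection, mutation, recombination,
    multinomial resampling to ``n_pop``."""
    model = _model(params)
    p = _expected_proportions(state.counts, params, model)
    counts = rng.multinomial(params.n_pop, p).astype(float)
    return PopulationState(counts=counts, generation=state.generation + 1, k_max=params.k_max)


def expected_step(state: PopulationState, params: SimParams) -> PopulationState:
    """Deterministic (infinite-population) limit of :func:`step`: expected
    class proportions scaled to ``n_pop`` with no resampling noise."""
    model = _model(params)
    p = _expected_proportions(state.counts, params, model)
    return PopulationState(
        counts=p * params.n_pop, generation=state.generation + 1, k_max=params.k_max
    )


def _summaries(counts: np.ndarray, model: _Model) -> tuple[float, float, float, float]:
    n = counts.sum()
    copies = float((counts * model.k_arr).sum())
    mut_copies = float((counts * model.j_arr).sum())
    het = float(counts[(model.j_arr > 0) & (model.j_arr < model.k_arr)].sum())
    carrier = float(counts[model.j_arr > 0].sum())
    return copies / n, mut_copies / copies, carrier / n, het / n


def _loh_reached(counts: np.ndarray, model: _Model) -> bool:
    het = counts[(model.j_arr > 0) & (model.j_arr < model.k_arr)].sum()
    full = counts[model.j_arr == model.k_arr].sum()
    return het == 0 and full > 0


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Counter-based (Philox) generator keyed by (seed, replicate), so
    replicates are independent and order-insensitive."""
    key = np.array([seed, replicate], dtype=np.uint64)
    return np.random.Generator(np.random.Philox(key=key))


def run(
    params: SimParams,
    n_generations: int,
    n_replicates: int = 1,
    init: PopulationState | None = None,
    stop_on_fixation: bool = False,
) -> list[Trajectory]:
    """Simulate replicate trajectories and record per-generation summaries.

    ``loh_generation`` is the first generation at which no heterozygous cell
    (0 < j < k) remains while at least one fully mutant cell exists; it is
    ``None`` if that never happens within the run.  ``fixed`` means every
    cell ended fully mutant.  With ``stop_on_fixation`` a replicate stops
    early once fixed (the remaining generations are not recorded).
    """
    model = _model(params)
    if init is None:
        init = founder_state(params)
    out: list[Trajectory] = []
    for rep in range(n_replicates):
        rng = replicate_rng(params.seed, rep)
        state = PopulationState(init.counts.copy(), init.generation, init.k_max)
        gens, mk, fcopy, fcell, het = [], [], [], [], []
        loh: int | None = None
        for gen in range(n_generations + 1):
            a, b, c, d = _summaries(state.counts, model)
            gens.append(state.generation)
            mk.append(a)
            fcopy.append(b)
            fcell.append(c)
            het.append(d)
            if loh is None and _loh_reached(state.counts, model):
                loh = state.generation
            fixed = bool(np.all(state.counts[model.j_arr < model.k_arr] == 0))
            if gen == n_generations or (stop_on_fixation and fixed):
                break
            state = step(state, params, rng)
        out.append(
            Trajectory(
                generation=np.array(gens),
                mean_copy_number=np.array(mk),
                mutant_freq_copy=np.array(fcopy),
                mutant_freq_cell=np.array(fcell),
                heterozygosity=np.array(het),
                loh_generation=loh,
                fixed=fixed,
                replicate=rep,
            )
        )
    return out


def sweep_replicate(
    params: SimParams,
    replicate: int,
    init: PopulationState | None = None,
    max_generations: int = 2000,
) -> SweepOutcome:
    """Run one replicate until the mutant allele fixes (every cell fully
    mutant) or ``max_generations`` is reached; summaries are not stored, so
    this is the cheap path for sweep-time statistics."""
    model = _model(params)
    if init is None:
        init = founder_state(params)
    rng = replicate_rng(params.seed, replicate)
    state = PopulationState(init.counts.copy(), init.generation, init.k_max)
    loh: int | None = None
    for _ in range(max_generations):
        if loh is None and _loh_reached(state.counts, model):
            loh = state.generation
        if np.all(state.counts[model.j_arr < model.k_arr] == 0):
            return SweepOutcome(True, loh, state.generation)
        state = step(state, params, rng)
    fixed = bool(np.all(state.counts[model.j_arr < model.k_arr] == 0))
    if loh is None and _loh_reached(state.counts, model):
        loh = state.generation
    return SweepOutcome(fixed, loh, state.generation)


def single_lineage_homogenization_time(
    genotype: tuple[int, int],
    params: SimParams,
    rng: np.random.Generator,
    max_generations: int = 1_000_000,
) -> int:
    """Generations until a single tracked array becomes homogeneous
    (j = 0 or j = k), with a recombination event occurring each generation
    with probability ``rec_rate`` and selection switched off."""
    g = ArrayGenotype(*genotype).validate(params.k_max)
    for gen in range(1, max_generations + 1):
        if rng.random() < params.rec_rate:
            g = recombine(g, params, rng)
        if g.j == 0 or g.j == g.k:
            return gen
    raise RuntimeError(f"array not homogeneous after {max_generations} generations")
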