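# Methods

This note documents the models implemented in `weaklink`, the defaults and
why they were chosen, the numerical choices that affect results, and what
the synthetic-data tests do and do not demonstrate.

## Growth rates

**Turbidostat traces.** A turbidostat holds cells in exponential growth by
diluting back to an OD setpoint at fixed intervals (here a reading every
~3 s and a dilution every 60 s). Each dilution cycle yields one specific
growth rate from its endpoint readings,

    mu_i = ln(N_t1,i / N_t0,i) / (t1,i - t0,i)   [h^-1],

with `N_t0` the reading right after a dilution and `N_t1` the reading right
before the next. The natural logarithm is required for `mu` to carry units
of h⁻¹ and for consistency with the generations formula. Daily summaries
are the arithmetic mean `mu_bar` over the day's cycles and

    g = 24 * mu_bar / ln 2   [generations/day],

the only reading consistent with a doubling time of `ln 2 / mu` (at
`mu = ln 2` h⁻¹ it gives exactly 24 generations/day). Cycle boundaries come
from explicit dilution flags when present, otherwise from relative OD drops
exceeding 2% (configurable). Cycles whose rate lies more than 4 standard
deviations from the day's distribution are dropped with a log message;
measured traces contain occasional dilution hiccups and this guard is
deliberately loose.

A caution on precision: with 1% multiplicative reading noise, a two-point
rate over a 57-s interval has a standard deviation of
`0.01*sqrt(2)/dt ≈ 0.9 h^-1`, so even a full day of 60-s cycles (1440 of
them) pins the daily mean only to ±0.02–0.03 h⁻¹. Day-to-day comparisons
are meaningful; single-cycle rates are not.

**Plate-reader curves.** Batch curves are fitted to the modified Gompertz
model (Zwietering parameterisation)

    y(t) = A * exp(-exp((mu_max * e / A) * (lambda - t) + 1))

by bounded nonlinear least squares, after subtracting a baseline estimated
as the mean of the first B = 5 points of a width-3 moving average (both
configurable). Initial guesses: `mu_max` from the maximum slope of log OD,
`A` from the maximum OD, `lambda` from the time of maximum curvature. All
parameters are bounded below by zero; `y(lambda) = A*e^{-e}` and
`y(∞) = A` hold by construction.

## qPCR relative quantification

Primer efficiency comes from an ordinary least-squares fit of Ct on log10
template quantity over a dilution series: `E = 10^(-1/m)` with slope `m`
(perfect doubling gives `m = -3.32`, `E = 2`). Curves with non-negative
slope or fewer than three distinct quantities are rejected; efficiencies
outside (1, 2.2] produce a warning but are used.

Relative quantity of a target against reference genes is

    n = E_tgt^dCt_tgt / combine_x( E_x^dCt_x ),
    dCt_x = Ct(calibrator, x) - Ct(sample, x),

so an amplified target (earlier Ct in the sample) gives `n > 1`. Replicate
Cts are averaged before the delta; a replicate range above 0.5 cycles
triggers a QC warning. `combine` is the geometric mean by default — the
standard multi-reference normalization, which keeps the reference term on
the same scale as a single reference — with a plain-product mode provided
for compatibility with formulations that divide by the product of both
reference terms. With one reference the modes coincide; with two they
differ exactly by a square root.

## Competitive fitness

From two-colour counts with ratio `R = test/ref`,

    w = ln(R(t)/R(0)) / t + 1,

with `t` the number of generations elapsed. `t` must be supplied (or
estimated as total population doublings,
`t = log2(final * dilution_total / initial)`), because count ratios alone
do not determine it. Raw `w` is normalised by division with the
label-control `w` (reference vs reference with swapped fluorophores), which
cancels a multiplicative label cost and keeps neutrality at exactly 1. A
delta-method standard error under Poisson counting noise,
`se_w = sqrt(sum(1/count))/t`, is reported but never used for filtering.

## Enzyme kinetics

**Burst fits.** Semialdehyde substrates exist mostly as unreactive
hydrates; mixing excess enzyme with substrate and NADP⁺ produces an A340
burst proportional to the pre-existing free aldehyde, then a slow linear
phase limited by dehydration. Two models:

- linear `f(x) = m*x + b`, fitted to the post-burst linear portion only
  (user window, or automatically the longest suffix with R² ≥ 0.995 —
  note the heuristic tolerates a few percent of residual burst);
- exponential `f(x) = m*x + b*(1 - e^{-x})`, fitted to the whole curve.
  The exponential time constant is fixed at 1 s⁻¹, making the model linear
  in (m, b) and solved directly by least squares; an optional third
  parameter floats the rate when the burst relaxation is visibly slower.

The free-aldehyde fraction is `(b / (eps * l)) / [S]_total` with the NADPH
extinction coefficient `eps = 6220 M^-1 cm^-1` (standard value,
configurable). Negative fitted bursts are clamped to a fraction of 0 with
a warning.

**Michaelis–Menten.** Unweighted nonlinear least squares of
`v = Vmax*S/(Km+S)`, replicates fitted individually rather than averaged;
`kcat = Vmax/E0`; standard errors from the covariance of the fit. For
hydrated substrates, concentrations should be converted to the
free-aldehyde basis (fraction from the burst fit) before fitting. The fit
is performed in internally rescaled units (S by its maximum, v by its
maximum) because raw molar rates of order 1e-8 sit below the optimizer's
default step scales; the model commutes exactly with these rescalings, and
the covariance is transformed back. A Km more than 10× the largest assayed
S is flagged as extrapolated.

**Allosteric effectors.** `v/v0 = (a*L + Kd)/(L + Kd)` with `v/v0(0) = 1`
and asymptote `a` (inhibitor below 1, activator above). Titrations must
include a (near-)zero ligand level. A response spanning less than 5%
leaves Kd unidentifiable: the fit returns `a = 1` with `Kd = nan` and
`determined = False`, the analogue of an "na" table entry. Ligand
concentrations are rescaled internally as above.

**Derived statistics.** Fold change `x/y`, percent change `100*(x/y - 1)`,
citrulline concentration `A464 / (37800 * l)` from the colorimetric assay,
and the ATP coupling ratio (mol carbamoyl phosphate per mol ATP; ~0.5 for
a fully coupled synthetase consuming two ATP per product).

## The amplification–divergence simulator

State: counts of genotype classes `(k, j)` — tandem-array copy number
`1 ≤ k ≤ k_max` and mutant-copy count `0 ≤ j ≤ k`. Discrete, non-overlapping
generations (Wright–Fisher) rather than a Moran process, because the
experiment's observables are all reported in generations. Per generation,
in order:

1. **Selection.** Expected offspring of class g proportional to
   `count(g) * exp(mu(g) * dt)` with `dt = ln2 / mu_max` chosen so the
   fittest class present doubles per generation. Dosage fitness
   (proportional mode, default): `mu = mu0*(1 + s_max*j/k) - c*(k-1)`,
   clamped at 0. A saturating mode maps total per-cell activity
   `A = (k-j)*a_wt + j*a_mut` through `A/(A + K_half)` instead.
2. **Mutation.** Each class leaks probability
   `1-(1-mu_gene)^(k-j) ≈ (k-j)*mu_gene` into `(k, j+1)` (the exact form is
   used when `mu_gene > 1e-3`). Back-mutation is ignored.
3. **Recombination.** A fraction `rec_rate` of each class with `k ≥ 2` is
   redrawn through the homogenization kernel: the replicated array is a
   `2k`-copy pool with `2j` mutants; the daughter's size changes by
   `delta ∈ {-1, 0, +1}` with probabilities `copy_change_probs`
   (default 0.25/0.50/0.25) and its mutant count is hypergeometric
   `j' ~ H(2k, 2j, k')`. This kernel abstracts both inter-chromosome and
   intramolecular exchange; it conserves allele identity (j = 0 and j = k
   are absorbing under recombination alone) and keeps k in `[1, k_max]`.
4. **Resampling.** One multinomial draw returns the population to `n_pop`.

Steps 1–3 act on expected proportions, so the only sampling noise is the
single multinomial; on small instances the engine is distributionally
identical to an explicit agent-based simulation (verified in the tests
against an independently written per-cell implementation, and against the
haploid selection recursion and a Markov-chain absorption-time oracle in
the deterministic and single-lineage limits).

Defaults encode the study conditions: `mu_nt = 1e-9` per nucleotide per
division over a 1 kb gene (`mu_gene = 1e-6`, the upper end of the
10⁻⁶–10⁻⁷ per-gene range), `rec_rate = 0.01` per division, `k_max = 20`
(the largest observed array), `n_pop = 1e5`, a 7-copy starting array,
`mu0 = 0.24 h^-1` (the turbidostat growth rate of the parental strain —
the condition under which the adaptation ran; the plate-reader value is
~0.27), `s_max = 0.75` (the measured growth-rate gain of the strain whose
array is fully mutant), and zero per-copy cost. The initial state is
already amplified (the amplification step itself is upstream of the
questions the simulator addresses); introducing a duplication rate would
extend it to full innovation→amplification→divergence runs.

Random numbers use numpy's counter-based Philox generator keyed by
`(seed, replicate)`, so replicates are independent, order-insensitive and
bit-reproducible; per-generation sub-keying was not needed because each
replicate consumes its stream strictly sequentially.

**Headline quantity.** With one founder cell `(7, 1)` in a resident
`(7, 0)` population, replicates are run to fixation of the mutant allele
(every cell fully mutant) and the generation of population-wide loss of
heterozygosity — no cell left with `0 < j < k` while fully mutant cells
exist — is recorded. Under the defaults the fixation-conditioned median
over 200 replicates is ~330–345 generations (seeds 1, 2, 7), comfortably
within the ≤500 generations observed for the real array sweep. Because
recurrent mutation (`N*k*mu_gene ≈ 0.7` new origins per generation at
these defaults) re-seeds the mutant when a founder lineage dies,
essentially all replicates eventually fix; the conditioning matters at
smaller `N*mu`.

A related subtlety, documented because it is easy to get wrong: at
`N = 1e5` the population-level mutation supply is not rare, so
*population-wide* statements of the form "the sweep completes before any
independently arisen mutant lineage becomes common" are only marginally
true. The robust form of the rate argument is per array: a single array's
homogenization hazard (~1/300 per generation at `rec_rate = 0.01`) exceeds
its second-mutation hazard (`(k-j)*mu_gene ≈ 6e-6`) by about three orders
of magnitude, so an array essentially never accumulates two independent
mutations before recombination homogenizes it. The test suite asserts the
per-array race.

## Synthetic data

Each generator produces one input class from known parameters with
configurable noise (defaults: OD multiplicative σ = 1%, Ct σ = 0.15
cycles with technical triplicates, absorbance σ = 0.002, proportional rate
σ = 5% with triplicates at eight substrate levels spanning 0.25–32× Km,
10⁴ counted events per flow channel — plausible bench magnitudes). The
generators emulate the *measurement* models only: Gaussian/lognormal/
multinomial noise around the fitted deterministic models. They do not
emulate instrument drift, well-to-well or day effects, pipetting error
correlated across a dilution series, qPCR inhibitors, substrate
degradation during an assay, or gating error in cytometry. Passing the
round-trip tests therefore shows the estimators are correct and
well-calibrated under their own assumptions, not that real data meet those
assumptions.

## Problem sizes

The test suite and the acceptance script use: 200 Monte-Carlo replicates
for Michaelis–Menten recovery, 100 for qPCR copy number, 50 Gompertz
fits, 10⁴ engine-vs-agent replicates of a 100-cell instance, 1500–2000
draws for the absorption-time check, and 200 fixation-conditioned sweep
replicates at `N = 1e5`; the full suite runs in well under a minute on one
CPU. These sizes give Monte-Carlo standard errors comfortably below every
asserted tolerance.

## Known limitations

- The simulator's fitness map is a modeling choice anchored at two
  measured points (baseline growth rate, fully mutant benefit); the true
  dosage–response of the weak-link activity is not known, and the per-copy
  cost defaults to zero rather than asserting a deamplification mechanism.
- The recombination kernel's copy-number-change probabilities are not
  measured quantities; only the overall event rate is.
- Eq.-level choices (geometric-mean reference combination, natural log in
  the turbidostat rate, fixed burst time constant) are documented above
  and switchable where an alternative reading exists.
- The Gompertz `mu_max` is the maximum slope of the OD curve in OD/h, as
  in the standard modified-Gompertz usage on absorbance data; it is a
  growth-curve summary, not a specific growth rate of log-phase cells.
- No absolute qPCR quantification, no Ct calling from raw fluorescence,
  no flow-cytometry gating, no sequence-level simulation.
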