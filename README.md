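# weaklink

Quantitative analysis for laboratory-evolution experiments in which a
"weak-link" enzyme — an inefficient, newly recruited promiscuous activity —
limits growth, the encoding gene amplifies into a tandem array, and a
beneficial mutation sweeps the array by homologous recombination
(innovation–amplification–divergence, IAD).

The package is aimed at experimental-evolution and enzymology labs that
collect the standard desk-scale measurements of such a study and want a
tested, scriptable pipeline for all of them:

- **growth** — per-cycle growth rates from turbidostat OD sawtooth traces,
  `mu_i = ln(N_t1/N_t0)/(t1 - t0)`, daily means and generations per day
  `g = 24*mu/ln 2`; modified-Gompertz fits
  `y(t) = A*exp(-exp((mu_max*e/A)*(lambda - t) + 1))` of plate-reader curves.
- **qpcr** — primer efficiency `E = 10^(-1/m)` from dilution-series standard
  curves and efficiency-corrected copy number / expression
  `n = E_tgt^dCt_tgt / geomean_x(E_x^dCt_x)` against one or more
  single-copy reference genes.
- **fitness** — relative fitness from two-colour competition counts,
  `w = ln(R(t)/R(0))/t + 1`, with label-control normalization and a
  Poisson delta-method standard error.
- **kinetics** — burst-phase progress-curve fits `f(x) = m*x + b(1 - e^-x)`
  quantifying the free-aldehyde fraction of hydrated semialdehyde
  substrates; Michaelis–Menten `v = Vmax*S/(Km + S)` and hyperbolic
  allosteric-effector `v/v0 = (a*L + Kd)/(L + Kd)` fits with standard
  errors; derived efficiencies and fold changes.
- **iad** — a Wright–Fisher simulator over array genotypes `(k, j)`
  (copy number, mutant copies) with per-copy mutation, recombination-driven
  homogenization (hypergeometric resampling from the duplicated 2k-copy
  pool), dosage-dependent fitness and per-copy cost — the quantitative form
  of the allelic-sweep argument.
- **synth** — generators for every input class with known ground truth, so
  the whole pipeline is testable end to end without downloads.

## Worked example

Fit Michaelis–Menten parameters to a synthetic triplicate initial-rate
table generated at the evolved enzyme's parameters (kcat = 0.21 s⁻¹,
Km = 95 µM, 5% proportional noise), then ask the simulator how long an
intra-array allelic sweep takes:

```python
import numpy as np
from weaklink import synth, kinetics, iad

df, truth = synth.mm_rates(kcat=0.21, km=9.5e-5, seed=0)
fit = kinetics.fit_michaelis_menten(df["conc_M"], df["rate"], truth["enzyme_conc"])
print(f"kcat = {fit.kcat:.3f} +/- {fit.se_kcat:.3f} s^-1")
print(f"Km   = {fit.km*1e6:.1f} +/- {fit.se_km*1e6:.1f} uM")
print(f"kcat/Km = {fit.kcat_over_km:.3g} M^-1 s^-1")

outcomes = [iad.sweep_replicate(iad.SimParams(seed=1), rep) for rep in range(20)]
loh = [o.loh_generation for o in outcomes if o.fixed]
print(f"{len(loh)}/20 replicates fixed; median LOH = {np.median(loh):.0f} generations")
```

prints

```
kcat = 0.210 +/- 0.003 s^-1
Km   = 99.1 +/- 5.7 uM
kcat/Km = 2.12e+03 M^-1 s^-1
20/20 replicates fixed; median LOH = 329 generations
```

The fitted kcat and Km recover the generating values within their standard
errors, and the simulated populations lose array heterozygosity — every
mutant-carrying cell ends up with a fully mutant array — in roughly 330
generations, driven by recombination at ~1 of every 100 divisions rather
than by recurrent mutation (~10⁻⁶ per gene per division).

A command-line interface mirrors the library:

```bash
weaklink synth --kind ct_table --seed 0 --out fixtures/
weaklink qpcr copies --cts fixtures/ct_table_main.tsv \
    --standards fixtures/ct_table_standards.tsv \
    --target proA --refs gyrB,icd --calibrator AM187
weaklink simulate --generations 500 --replicates 10 --seed 1 --out traj.tsv
```

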