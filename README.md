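# matefit

Calibration, model selection, uncertainty analysis and prediction for
**batch filter-mating (plasmid conjugation) ODE models**.

When a plasmid-bearing donor strain and a plasmid-free recipient strain are
mixed on a membrane filter, recipients that acquire the conjugative plasmid
become transconjugants, which can themselves donate. `matefit` is for
quantitative microbiologists and bioengineers who want to go beyond a
single "transfer rate" number: it fits a family of donor / recipient /
transconjugant / resource ODE models to time-course subpopulation
densities, ranks model variants by corrected AIC, quantifies how well each
kinetic parameter is determined, and tests whether kinetics calibrated on
simultaneous-loading experiments extrapolate to staggered-loading ones.

## The model

State: densities D, R, T (cells/cm²) and a dimensionless resource fraction
C with C(0) = 1. The full model (variant V0, 19 kinetic parameters):

    dD/dt = ψ_D(t, C)·D
    dR/dt = ψ_R(t, C)·R − R·(γ_D(C)·D + γ_T(C)·T)
    dT/dt = ψ_T(t, C)·T + R·(γ_D(C)·D + γ_T(C)·T)
    dC/dt = −Σᵢ eᵢ·ψ_i(t, C)·popᵢ

    ψ_i(t, C) = ψ_i,max · tⁿⁱ/(K_L,iⁿⁱ + tⁿⁱ) · C/(K_G,i + C)
    γ_j(C)    = γ_j,max · C/(K_T,j + C)            (j ∈ {D, T})

Sixteen named variants V0–V15 reduce this by sharing, fixing or dropping
terms (`src/matefit/data/variants.yaml`); V14 is the classical
two-parameter mass-action model, and V15 — the variant selected by AICc —
keeps six kinetic parameters (ψ_R,max, ψ_D,max, K_L, γ_max, e_R, e_D) with
non-growing transconjugants. Calibration minimizes the σ-weighted sum of
squared errors over replicate means, with per-experiment initial donor and
recipient densities as free parameters; variants are compared with
AICc = 2m + n·ln(SSE/n) + 2m(m+1)/(n−m−1). Identifiability is scored by
greedy orthogonalization of the relative-sensitivity matrix, and 95%
confidence radii come from a nonlinear-regression bound and a Fisher
Information Matrix bound. See `docs/methods.md` for the details and
numerical choices.

## Worked example

Simulate the selected model at its published best-fit kinetics, generate a
noise-free synthetic dataset from the four training designs, and refit:

```python
import numpy as np
from matefit import (LoadingSchedule, NoiseModel, FitConfig, simulate,
                     get_variant, default_training_designs,
                     generate_dataset, fit_variant)

v15 = get_variant("V15")
truth = [0.0571, 0.0392, 145.0, 1.27e-10, 6.22e-10, 1.86e-9]
params = v15.resolve(truth)

sched = LoadingSchedule(donor_density=1.77e6, recipient_density=1.96e6)
traj = simulate(params, sched, np.arange(0, 361, 40.0))
print(traj.to_frame().head(3))

data = generate_dataset(truth, v15, default_training_designs(),
                        NoiseModel(cv={"D": 0, "R": 0, "T": 0}), seed=11)
fit = fit_variant(v15, data.observations,
                  FitConfig(n_starts=6, seed=3, stop_sse=1e-4))
print(f"SSE = {fit.sse:.3e}")
print({k: float(f"{v:.6g}") for k, v in fit.kinetics.items()})
```

Output:

```
   time_min             D             R             T         C
0       0.0  1.770000e+06  1.960000e+06      0.000000  1.000000
1      40.0  2.125783e+06  2.534767e+06  20791.421907  0.998968
2      80.0  3.347726e+06  4.845369e+06  69281.954321  0.995228
SSE = 1.017e-07
{'psi_max_R': 0.0571, 'psi_max_D': 0.0392, 'K_L': 145.0, 'gamma_max': 1.27e-10, 'e_R': 6.22e-10, 'e_D': 1.86e-09}
```

Reading this: donors and recipients barely grow for the first ~2 h (the
145-min lag half-time), transconjugants appear from the start at a rate
set by γ_max·C·R·(D+T), and the refit recovers all six generating
parameters essentially exactly (SSE ≈ 1e-7 against a floor of ~0 for
noise-free data), with the fitted initial conditions absorbing the t = 0
observations.

The same steps are available from the shell:

```sh
matefit synth --variant V15 --params table2.json --designs training --cv 0 --seed 11 --out obs.csv
matefit fit --variant V15 --data obs.csv --starts 6 --seed 3 --out fit.json
matefit uncertainty --fit fit.json --data obs.csv --out report.csv
matefit predict --fit fit.json --designs test --out pred.csv
```

`uncertainty` prints the per-parameter report (overall sensitivity,
identifiability score and rank, FIM and regression 95% CI radii as % of
the estimate); `predict` simulates the four staggered-loading test designs
— the second population loaded at 120 min, its lag clock starting at its
own load time — from kinetics fitted on simultaneous-loading data only.

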