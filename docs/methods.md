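# Methods

## The model

`matefit` models a batch filter mating between a plasmid-bearing donor
strain (D) and a plasmid-free recipient strain (R) on a membrane filter.
Recipients that acquire the conjugative plasmid become transconjugants (T),
which can themselves donate. Densities are in cells/cm² of filter area,
time in minutes. A dimensionless resource fraction C (C(0) = 1) couples
growth to nutrient depletion. The full model is

    dD/dt = ψ_D(t, C) · D
    dR/dt = ψ_R(t, C) · R − R·(γ_D(C)·D + γ_T(C)·T)
    dT/dt = ψ_T(t, C) · T + R·(γ_D(C)·D + γ_T(C)·T)
    dC/dt = −Σᵢ eᵢ · ψ_i(t, C) · popᵢ

with per-population growth ψ_i(t, C) = ψ_i,max · tⁿ/(K_L,iⁿ + tⁿ) ·
C/(K_G,i + C) (a Hill-type lag factor times a Monod resource factor) and
mass-action transfer rates γ_j(C) = γ_j,max · C/(K_T,j + C) for j ∈ {D, T}.
Model assumptions: transfer flux proportional to the product of
plasmid-bearing and plasmid-free densities; no segregative plasmid loss;
new transconjugants transfer immediately.

One published equation is internally inconsistent as printed: the reduced
model's resource equation shows the donor depletion term with a sign that
would let donors *replenish* the resource (and makes C diverge when
integrated). We implement the depletion equation as the sum of depletion
terms, consistent with the full model's resource equation.

### Parameters

| family | units | nominal magnitude | meaning |
|---|---|---|---|
| ψ_i,max | min⁻¹ | 5·10⁻² | maximal growth rate |
| K_L,i | min | 10² | lag half-time |
| n_i | — | 1 | abruptness of lag exit |
| K_G,i, K_T,j | — | 1 | Monod constants in C |
| e_i | cm²/cell | 10⁻⁹ | resource use per cell produced |
| γ_j,max | cm² cell⁻¹ min⁻¹ | 10⁻¹⁰ | maximal transfer rate |

The "nominal magnitude" column doubles as the optimizer's scaling (below).

### Variants

Sixteen named variants V0–V15 reduce the 19-parameter full model by
`share` / `fix` / `drop` constraints (`src/matefit/data/variants.yaml`).
Dropping a Monod factor means taking its large-K limit with the maximal
rate rescaled — `matefit` encodes this as a `linear` (γ·C) or `none`
(constant) functional form on the kinetics object, so one right-hand side
serves all variants. The selected model V15 has six kinetic parameters
(ψ_R,max, ψ_D,max, K_L, γ_max, e_R, e_D): shared lag, a single
resource-linear transfer rate, and transconjugants that neither grow nor
deplete resource. Several intermediate variants are described in the
source narrative only verbally; where more than one constraint set matches
the stated kinetic-parameter count (the three "equal growth-rate pair"
variants), the assignment in the YAML is one defensible choice and is
config-editable.

## Simulation

Stiff integration by LSODA with rtol 1e-8 and atol 1 cell/cm² for
populations, 1e-12 for C (tight enough that the weighted SSE is
reproducible across platforms). Staggered loading — the second population
placed on the filter 120 min after the first — is a two-segment
integration with a state jump at the load time; each population's lag
clock runs from its own load time, while C is shared and depleted from
t = 0 by whatever is present. At a load time the post-jump state is
reported. The lag factor is evaluated in log space (robust to steep Hill
coefficients) and defined as 1 when K_L = 0 (its continuous limit) and 0
at t = 0 otherwise.

The inner right-hand side is compiled with numba when available (a pure
Python fallback produces identical results). During calibration, all
simultaneous-loading experiments are integrated as one block-diagonal
system in a single solver call; this changes only step-size selection, not
the solution, and is ~4× faster than per-experiment solves.

## Calibration

The objective is the weighted sum of squared errors
SSE(p) = Σ (y_obs − y_sim)²/σ² over experiments, subpopulations and time
points, where y_obs is the replicate mean and σ the replicate standard
deviation. Initial transconjugant observations (pinned to zero by design)
are excluded; so are cells whose replicates are identically zero (a
population below any detection carries no weight information — these occur
in noise-free synthetic data when a population goes extinct). Initial
donor and recipient densities of every experiment are fitted jointly with
the kinetics (bounds 10³–10⁹ cells/cm², optimized in log10, started at the
observed t = 0 means); transconjugants start at zero.

Kinetic parameters span twelve orders of magnitude, so the optimizer works
on a nominal-magnitude-scaled space (each parameter divided by the nominal
value in the table above); bounds of [0, 500] apply per parameter on its
natural scale. The search is a seeded Latin-hypercube multistart (default
20 starts, drawn log-uniformly over 0.1–10 × nominal) of bounded
trust-region-reflective least-squares refinements (`scipy.optimize.
least_squares`), optionally preceded by a `dual_annealing` global stage.
A least-squares local stage exploits the sum-of-squares structure and
converges quadratically near an optimum, where a generic quasi-Newton
scalar minimizer is far slower. Solver failures map to a large finite
penalty (1e12) so global search stays total. The reported SSE is
re-evaluated independently from the returned parameters at tight
tolerance. Identical seed and configuration reproduce the fit exactly.

`VariantCalibrator` exposes this as a scikit-learn-style estimator
(`fit`/`predict`/`score`, `get_params`/`set_params`, fitted attributes
`kinetics_`, `sse_`, …); `fit_variant` is the functional wrapper.

## Model comparison

Variants are scored with the corrected Akaike Information Criterion,
AICc = 2m + n·ln(SSE/n) + 2m(m+1)/(n−m−1), with natural logarithm, m the
free-parameter count (kinetic + two initial conditions per experiment) and
n the observation count. The four-experiment training design yields
n = 116 (4 experiments × 10 time points × 3 subpopulations − 4 initial
transconjugant zeros). Ties break toward fewer free parameters.
Recomputing the published comparison table from its printed (SSE, m)
columns reproduces the printed AICc column to within print rounding once
the rounding of the SSE inputs themselves (±0.05, worth ±n/SSE·0.05 ≈
±0.014 in AICc) is propagated; two of sixteen rows need that extra
allowance.

## Uncertainty analysis

Sensitivities S_ij = ∂y_i/∂p_j are central finite differences with a 1%
relative step (central rather than one-sided: halves truncation error),
with initial conditions pinned at their fitted values. Relative
sensitivities (p_j/y_i)·S_ij are used for the overall sensitivity (the
column 2-norm) and for identifiability: a greedy orthogonalization that
repeatedly selects the largest residual column after projecting onto the
span of already-selected original columns. Scores below 0.04 flag
practically unidentifiable parameters. Observation rows at t = 0 are
excluded throughout (n = 108 for the training design), as are rows where
y_sim = 0 in the relative layer.

Two 95% confidence radii per parameter:

* **Regression bound**: Δp_j = √( m/(n−m) · SSE · F₀.₀₅(m, n−m) ·
  ((SᵀS)⁻¹)_jj ). As printed in the source, S here is the *absolute*
  sensitivity matrix while SSE is the σ-weighted sum — dimensionally
  inconsistent, and on synthetic data it produces radii of ~10⁻⁶ %.
  `ci_regression` implements the printed form by default and offers
  `weights=σ`, which substitutes the weighted Jacobian S/σ (the
  linearization consistent with a weighted SSE); `uncertainty_report` uses
  the weighted form.
* **FIM bound**: Δp_j = 1.96·√((FIM⁻¹)_jj) with FIM = SᵀWS, W diagonal
  with replicate-based 1/σ² (off-diagonal covariances are not estimable
  from triplicates and are set to zero). The source prints the algebraic
  variant Δp² = 1.96·(FIM⁻¹)_jj; that form is available via
  `form="as_printed"`, but the standard form is the default.

Normal matrices are inverted on unit-normalized columns (exact algebra;
the raw Gram matrix is catastrophically ill-conditioned because absolute
sensitivity columns differ by ~20 orders of magnitude). Singular systems
report infinite radii with a warning. m counts kinetic parameters only.

### A labeling discrepancy in the published uncertainty table

Recomputing sensitivities and identifiability at the published best-fit
parameters and initial conditions reproduces the published twelve
sensitivity/identifiability values as a multiset to ~2%, but the values
our computation attributes to (γ_max, ψ_D,max, ψ_R,max) appear in the
published table's (ψ_D,max, ψ_R,max, γ_max) rows respectively; the e and
K_L rows match their labels. No model reading we tried (swapped initial
densities, the printed resource-equation sign) reproduces the published
row assignment, which is consistent with a row/column indexing slip in the
original table. Consequently this package's tests assert the robust
properties — the lag half-time ranks least identifiable, the top-ranked
score equals its overall sensitivity, every score exceeds the 0.04
cut-off — rather than which of ψ_R,max and γ_max ranks first.

## Synthetic data

The generator reproduces the study's designs: four simultaneous-loading
training experiments and four staggered-loading test experiments (second
population at 120 min), ten time points (0–360 min, step 40), triplicates,
with the published initial densities. Noise is multiplicative lognormal
with unit mean and per-subpopulation CV (default 0.15 — the study's
replicate scatter is not tabulated, so the CV is an explicit knob chosen
because densities span four orders of magnitude and scatter grows with
the mean), plus a detection floor (default 10³ cells/cm²) applied to
noisy positive draws. CV = 0 returns exact trajectories. One master seed
spawns per-design, per-replicate streams, so datasets are bit-reproducible
and stable under design subsetting.

What the generator does *not* emulate: cytometry event-level sampling and
gating error, OD measurement error separate from count error, correlation
between subpopulation measurements taken from the same filter, and
heavy-tailed replicate scatter. Passing recovery tests on this generator
therefore demonstrates the estimator machinery (identifiability of the
parameters under the study design and noise of plausible magnitude), not
robustness to every feature of real measurements.

## Problem sizes used in tests

The test suite fits the two-parameter mass-action variant and the
six-parameter selected variant to noise-free synthetic data from the four
training designs (10 time points, triplicates) and checks 1% parameter
recovery; the prediction harness refits nothing, reusing the training fit
to predict the four staggered designs. Multistart counts in tests (8–12)
are smaller than the default 20; with noise-free data the first basin hit
ends the search via the early-stop threshold.

## Known limitations

* The variant ledger encodes V1–V13 from a verbal description; alternative
  constraint sets with the same parameter counts exist for V10–V12.
* The regression CI bound's printed form is dimensionally inconsistent
  with a weighted SSE (see above); both forms are exposed.
* Whether unloaded donors deplete resource before their load time in
  recipient-first staggered designs is unspecified in the source; here
  only loaded populations appear in every term.
* The published uncertainty table's row labeling could not be fully
  reconciled (see above).
* ODE-level description assumes dense, well-mixed surface populations; no
  spatial structure, stochasticity, or segregative loss.
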