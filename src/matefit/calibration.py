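"""Weighted least-squares calibration of model variants.

A variant is fitted to an :class:`~matefit.preprocessing.ObservationSet` by
minimizing

    SSE(p) = sum_i sum_k (y_obs_i(t_k) - y_sim_i(p, t_k))**2 / sigma_i(t_k)**2

over the variant's free kinetic parameters jointly with the initial donor
and recipient densities of every experiment (transconjugants start at
zero, and the initial transconjugant observations are excluded from the
sum).  Kinetic parameters span many orders of magnitude (a transfer rate
near 1e-10 against a lag half-time near 1e2), so the optimizer works on a
nominal-magnitude-scaled space; bounds of [0, 500] apply on the natural
scale of each parameter.  Initial densities are optimized in log10 within
[1e3, 1e9] cells/cm**2.

The search is a seeded Latin-hypercube multistart of bounded local
quasi-Newton refinements, optionally preceded by a global simulated-
annealing stage.  :class:`VariantCalibrator` packages this as a
scikit-learn style estimator; :func:`fit_variant` is the functional
wrapper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc
from sklearn.base import BaseEstimator

from .model import GeneralParameters, LoadingSchedule, SimulationError, simulate
from .preprocessing import ObservationSet
from .synthetic import ExperimentDesign
from .variants import VariantSpec, get_variant

logger = logging.getLogger(__name__)

#: nominal magnitude of each kinetic parameter family, used to scale the
#: optimizer's working space (typical values for E. coli filter matings:
#: growth rates ~5e-2 /min, lag half-times ~1e2 min, transfer rates
#: ~1e-10 cm^2/(cell min), depletion coefficients ~1e-9 cm^2/cell)
NOMINAL_SCALES = {
    "psi_max": 0.05,
    "K_L": 100.0,
    "n": 1.0,
    "K_G": 1.0,
    "e": 1e-9,
    "gamma_max": 1e-10,
    "K_T": 1.0,
}

PENALTY_SSE = 1e12  # finite objective returned when the solver fails


def nominal_scale(name: str) -> float:
    """Nominal magnitude for a free-parameter name (shared names included)."""
    for prefix in sorted(NOMINAL_SCALES, key=len, reverse=True):
        if name == prefix or name.startswith(prefix):
            return NOMINAL_SCALES[prefix]
    raise KeyError(f"no nominal scale for parameter {name!r}")


@dataclass
class FitConfig:
    """Search configuration for :func:`fit_variant`."""

    n_starts: int = 20
    seed: int = 0
    natural_bound: tuple = (0.0, 500.0)   # per kinetic parameter
    ic_bounds: tuple = (1e3, 1e9)         # initial densities, cells/cm^2
    start_window: tuple = (0.1, 10.0)     # LHS start range, x nominal scale
    global_stage: bool = False            # dual-annealing before local polish
    global_maxiter: int = 50
    local_maxiter: int = 150  # max residual evaluations per dimension
    grad_eps: float = 1e-6                # finite-difference step, scaled space
    sim_rtol: float = 1e-8
    stop_sse: float | None = None         # early exit once this SSE is reached

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.natural_bound[0] > self.natural_bound[1]:
            raise ValueError("natural_bound must be ordered")


@dataclass
class FitResult:
    """Outcome of a variant calibration."""

    variant: str
    free_names: tuple
    free_vector: np.ndarray               # kinetic parameters, natural scale
    parameters: GeneralParameters
    initial_conditions: dict              # experiment -> {"D0": .., "R0": ..}
    sse: float
    m: int                                # kinetic count + 2 per experiment
    n_obs: int
    trace: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def kinetics(self) -> dict:
        return dict(zip(self.free_names, self.free_vector))


def weighted_sse(sim: pd.DataFrame, obs: ObservationSet) -> float:
    """Eq.-style weighted sum of squared errors.

    ``sim`` holds columns experiment, subpopulation, time_min, sim.  Initial
    transconjugant points (pinned to zero by design) are excluded; every
    included observation must have a positive standard deviation.
    """
    merged = obs.frame.merge(sim, on=["experiment", "subpopulation",
                                      "time_min"], how="left")
    if merged["sim"].isna().any():
        missing = merged.loc[merged["sim"].isna(),
                             ["experiment", "subpopulation", "time_min"]]
        raise ValueError(f"simulation does not cover observations:\n"
                         f"{missing.to_string(index=False)}")
    keep = ~((merged["subpopulation"] == "T") & (merged["time_min"] == 0))
    # cells whose replicates are identically zero (population below any
    # detection) carry no weight information and are likewise excluded
    keep &= ~((merged["mean"] == 0) & (merged["sd"] == 0))
    merged = merged[keep]
    if (merged["sd"] <= 0).any():
        raise ValueError("nonpositive standard deviation in included "
                         "observations")
    z = (merged["mean"] - merged["sim"]) / merged["sd"]
    return float(np.sum(z * z))


def _default_designs(obs: ObservationSet) -> dict[str, ExperimentDesign]:
    """Simultaneous-loading designs at the observation times (densities are
    free parameters, so the schedule only fixes the load times)."""
    return {
        exp: ExperimentDesign(id=exp, schedule=LoadingSchedule(),
                              times=tuple(obs.times(exp)))
        for exp in obs.experiments
    }


def predict_observations(params: GeneralParameters,
                         initial_conditions: dict,
                         designs: dict[str, ExperimentDesign],
                         rtol: float = 1e-8) -> pd.DataFrame:
    """Simulate every experiment and tabulate (experiment, subpop, time, sim)."""
    rows = []
    for exp, design in designs.items():
        ics = initial_conditions[exp]
        sched = design.schedule
        sched = LoadingSchedule(
            donor_time=sched.donor_time, donor_density=ics["D0"],
            recipient_time=sched.recipient_time,
            recipient_density=ics["R0"], C0=sched.C0)
        traj = simulate(params, sched, np.asarray(design.times), rtol=rtol)
        for sub in ("D", "R", "T"):
            for t, val in zip(traj.t, traj.population(sub)):
                rows.append({"experiment": exp, "subpopulation": sub,
                             "time_min": t, "sim": val})
    return pd.DataFrame(rows)


def objective(free_vector, variant: VariantSpec, obs: ObservationSet,
              designs: dict[str, ExperimentDesign] | None = None,
              rtol: float = 1e-8) -> float:
    """SSE at a natural-scale free vector: kinetics then (D0, R0) per
    experiment in sorted experiment order.  Solver failures map to a large
    finite penalty so that global search stays total.
    """
    if designs is None:
        designs = _default_designs(obs)
    nk = variant.n_kinetic
    experiments = sorted(designs)
    expected = nk + 2 * len(experiments)
    free_vector = np.asarray(free_vector, dtype=float)
    if free_vector.shape != (expected,):
        raise ValueError(f"free vector must have length {expected} "
                         f"({nk} kinetic + 2 per experiment)")
    try:
        params = variant.resolve(free_vector[:nk])
        ics = {exp: {"D0": free_vector[nk + 2 * i],
                     "R0": free_vector[nk + 2 * i + 1]}
               for i, exp in enumerate(experiments)}
        sim = predict_observations(params, ics, designs, rtol=rtol)
        return weighted_sse(sim, obs)
    except (SimulationError, ValueError, OverflowError, FloatingPointError):
        return PENALTY_SSE


class _ResidualEvaluator:
    """Precomputed fast path for the multistart search.

    Binds the observation layout once (row selection, per-experiment time
    and subpopulation indices) so that each objective evaluation is one
    batched ODE solve plus numpy gathers, with no frame operations.
    Residual ordering differs from :func:`weighted_sse`'s frame order only
    by row permutation; the summed square is identical.
    """

    def __init__(self, variant: VariantSpec, obs: ObservationSet,
                 designs: dict[str, ExperimentDesign], rtol: float):
        from .model import simulate_batch  # local import keeps module light
        self._simulate_batch = simulate_batch
        self.variant = variant
        self.rtol = rtol
        self.experiments = sorted(designs)
        self.designs = designs
        frame = obs.frame
        keep = ~((frame["subpopulation"] == "T") & (frame["time_min"] == 0))
        keep &= ~((frame["mean"] == 0) & (frame["sd"] == 0))
        frame = frame[keep]
        if (frame["sd"] <= 0).any():
            raise ValueError("nonpositive standard deviation in included "
                             "observations")
        pop_index = {"D": 0, "R": 1, "T": 2}
        self.rows = []  # per experiment: (pop idx, time idx, means, sds)
        times0 = np.asarray(designs[self.experiments[0]].times, dtype=float)
        self.batchable = all(
            not designs[e].schedule.events
            and np.array_equal(np.asarray(designs[e].times, dtype=float),
                               times0)
            for e in self.experiments)
        self.times = times0
        self.n_residuals = len(frame)
        for exp in self.experiments:
            sub = frame[frame["experiment"] == exp]
            t_lookup = {t: i for i, t in
                        enumerate(np.asarray(designs[exp].times,
                                             dtype=float))}
            self.rows.append((
                sub["subpopulation"].map(pop_index).to_numpy(),
                np.array([t_lookup[t] for t in sub["time_min"]]),
                sub["mean"].to_numpy(),
                sub["sd"].to_numpy(),
            ))

    def __call__(self, natural_vector: np.ndarray) -> np.ndarray:
        nk = self.variant.n_kinetic
        try:
            params = self.variant.resolve(natural_vector[:nk])
            schedules = []
            for i, exp in enumerate(self.experiments):
                base = self.designs[exp].schedule
                schedules.append(LoadingSchedule(
                    donor_time=base.donor_time,
                    donor_density=natural_vector[nk + 2 * i],
                    recipient_time=base.recipient_time,
                    recipient_density=natural_vector[nk + 2 * i + 1],
                    C0=base.C0))
            if self.batchable:
                trajectories = self._simulate_batch(
                    params, schedules, self.times, rtol=self.rtol)
            else:
                from .model import simulate
                trajectories = [
                    simulate(params, sched,
                             np.asarray(self.designs[exp].times,
                                        dtype=float), rtol=self.rtol)
                    for exp, sched in zip(self.experiments, schedules)]
            out = np.empty(self.n_residuals)
            pos = 0
            for traj, (pops, t_idx, means, sds) in zip(trajectories,
                                                       self.rows):
                Y = np.vstack([traj.D, traj.R, traj.T])
                sim = Y[pops, t_idx]
                k = len(sim)
                out[pos:pos + k] = (means - sim) / sds
                pos += k
            return out
        except (SimulationError, ValueError, OverflowError,
                FloatingPointError):
            return np.full(self.n_residuals,
                           np.sqrt(PENALTY_SSE / max(self.n_residuals, 1)))


class VariantCalibrator(BaseEstimator):
    """Scikit-learn style estimator fitting one model variant to data.

    Parameters mirror :class:`FitConfig`; ``variant`` may be a name from the
    packaged ledger (``"V15"``) or a :class:`VariantSpec`.

    After ``fit`` the instance carries ``kinetics_`` (name -> value),
    ``parameters_`` (the resolved full kinetic structure),
    ``initial_conditions_``, ``sse_``, ``result_`` (the full
    :class:`FitResult`) and ``n_iter_`` (local-refinement count).
    """

    def __init__(self, variant="V15", n_starts=20, seed=0,
                 natural_bound=(0.0, 500.0), ic_bounds=(1e3, 1e9),
                 start_window=(0.1, 10.0), global_stage=False,
                 global_maxiter=50, local_maxiter=150, grad_eps=1e-6,
                 sim_rtol=1e-8, stop_sse=None):
        self.variant = variant
        self.n_starts = n_starts
        self.seed = seed
        self.natural_bound = natural_bound
        self.ic_bounds = ic_bounds
        self.start_window = start_window
        self.global_stage = global_stage
        self.global_maxiter = global_maxiter
        self.local_maxiter = local_maxiter
        self.grad_eps = grad_eps
        self.sim_rtol = sim_rtol
        self.stop_sse = stop_sse

    # -- scaled-space transforms ------------------------------------------
    def _spec(self) -> VariantSpec:
        return (self.variant if isinstance(self.variant, VariantSpec)
                else get_variant(self.variant))

    def _to_natural(self, x_scaled, scales, nk):
        x = np.asarray(x_scaled, dtype=float)
        kin = x[:nk] * scales
        ics = 10.0 ** x[nk:]
        return np.concatenate([kin, ics])

    def fit(self, observations: ObservationSet, y=None, designs=None):
        """Fit the variant; ``designs`` defaults to simultaneous loading at
        the observed time points."""
        spec = self._spec()
        if designs is None:
            designs = _default_designs(observations)
        elif not isinstance(designs, dict):
            designs = {d.id: d for d in designs}
        experiments = sorted(designs)
        nk = spec.n_kinetic
        scales = np.array([nominal_scale(name) for name in spec.free_names])

        lo, hi = self.natural_bound
        bounds = [(lo / s, hi / s) for s in scales]
        log_lo, log_hi = np.log10(self.ic_bounds)
        bounds += [(log_lo, log_hi)] * (2 * len(experiments))

        evaluator = _ResidualEvaluator(spec, observations, designs,
                                       rtol=self.sim_rtol)

        def resid(x_scaled):
            return evaluator(self._to_natural(x_scaled, scales, nk))

        def f(x_scaled):
            r = resid(x_scaled)
            return float(r @ r)

        rng = np.random.default_rng(self.seed)
        sampler = qmc.LatinHypercube(d=nk, seed=rng)
        w_lo, w_hi = np.log10(self.start_window)
        kin_starts = 10.0 ** (w_lo + (w_hi - w_lo)
                              * sampler.random(self.n_starts))

        ic_start = []
        floor, ceil = self.ic_bounds
        for exp in experiments:
            means = observations.initial_means(exp)
            for sub in ("D", "R"):
                val = means.get(sub, 1e6)
                ic_start.append(np.log10(np.clip(val if val > 0 else 1e6,
                                                 floor, ceil)))
        ic_start = np.array(ic_start)

        best = None
        trace = []
        n_local = 0
        for k in range(self.n_starts):
            x0 = np.concatenate([kin_starts[k], ic_start])
            if self.global_stage:
                ga = optimize.dual_annealing(
                    f, bounds=bounds, x0=x0, seed=int(rng.integers(2**31)),
                    maxiter=self.global_maxiter, no_local_search=True)
                x0 = ga.x
            lo_b = np.array([b[0] for b in bounds])
            hi_b = np.array([b[1] for b in bounds])
            res = optimize.least_squares(
                resid, np.clip(x0, lo_b, hi_b), bounds=(lo_b, hi_b),
                method="trf", x_scale="jac", diff_step=self.grad_eps,
                max_nfev=self.local_maxiter * (len(x0) + 1),
                ftol=1e-10, xtol=1e-12, gtol=1e-10)
            sse_k = float(np.sum(res.fun ** 2))
            n_local += 1
            trace.append({"start": k, "x0": x0.tolist(), "sse": sse_k,
                          "nfev": int(res.nfev),
                          "converged": bool(res.success)})
            logger.info("start %d/%d: SSE=%.6g (%d evaluations)",
                        k + 1, self.n_starts, sse_k, res.nfev)
            if best is None or sse_k < best[0]:
                best = (sse_k, res.x)
            if self.stop_sse is not None and best[0] <= self.stop_sse:
                break
        if best is None or best[0] >= PENALTY_SSE:
            raise RuntimeError(
                f"all {len(trace)} starts failed to produce a valid "
                f"simulation; trace: {trace}")

        natural = self._to_natural(best[1], scales, nk)
        free_vector = natural[:nk]
        ics = {exp: {"D0": float(natural[nk + 2 * i]),
                     "R0": float(natural[nk + 2 * i + 1])}
               for i, exp in enumerate(experiments)}
        params = spec.resolve(free_vector)
        # independent re-evaluation of the reported optimum at tight tolerance
        sim = predict_observations(params, ics, designs, rtol=1e-8)
        sse = weighted_sse(sim, observations)

        self.kinetics_ = dict(zip(spec.free_names, free_vector))
        self.parameters_ = params
        self.initial_conditions_ = ics
        self.sse_ = sse
        self.n_iter_ = n_local
        self.designs_ = designs
        self.result_ = FitResult(
            variant=spec.name, free_names=spec.free_names,
            free_vector=free_vector, parameters=params,
            initial_conditions=ics, sse=sse,
            m=nk + 2 * len(experiments),
            n_obs=observations.n_observations(),
            trace=trace, config=self.get_params(deep=False) | {
                "variant": spec.name})
        return self

    def predict(self, designs=None) -> pd.DataFrame:
        """Simulated observations for ``designs`` (default: the fitted ones),
        using fitted kinetics and initial conditions where available."""
        self._check_fitted()
        if designs is None:
            designs = self.designs_
        elif not isinstance(designs, dict):
            designs = {d.id: d for d in designs}
        ics = {}
        for exp, design in designs.items():
            if exp in self.initial_conditions_:
                ics[exp] = self.initial_conditions_[exp]
            else:
                ics[exp] = {"D0": design.schedule.donor_density,
                            "R0": design.schedule.recipient_density}
        return predict_observations(self.parameters_, ics, designs)

    def score(self, observations: ObservationSet, y=None) -> float:
        """Negative weighted SSE on ``observations`` (sklearn convention:
        larger is better)."""
        self._check_fitted()
        sim = self.predict()
        return -weighted_sse(sim, observations)

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise RuntimeError("this VariantCalibrator is not fitted yet")


def fit_variant(variant, obs: ObservationSet,
                config: FitConfig | None = None, designs=None) -> FitResult:
    """Fit a variant to an observation set; functional wrapper over
    :class:`VariantCalibrator`."""
    config = config or FitConfig()
    est = VariantCalibrator(variant=variant, **asdict(config))
    est.fit(obs, designs=designs)
    return est.result_
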