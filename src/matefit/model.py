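"""Batch filter-mating ODE model: donor, recipient, transconjugant, resource.

The state is (D, R, T, C): donor, recipient and transconjugant densities in
cells/cm**2 on the mating filter, and C, the fractional abundance of the
growth-limiting resource (dimensionless, C(0) = 1).  Growth of population
``i`` follows a lag-phase Hill factor in time multiplied by a Monod factor in
C; plasmid transfer from plasmid-bearing cells (donors and transconjugants)
to recipients is mass-action with a resource-dependent rate:

    dD/dt = psi_D(t, C) * D
    dR/dt = psi_R(t, C) * R - R * (gamma_D(C) * D + gamma_T(C) * T)
    dT/dt = psi_T(t, C) * T + R * (gamma_D(C) * D + gamma_T(C) * T)
    dC/dt = -sum_i e_i * psi_i(t, C) * pop_i

with psi_i(t, C) = psi_max * t^n / (K_L^n + t^n) * C / (K_G + C) and
gamma_j(C) = gamma_max * C / (K_T + C).  Reduced model variants replace the
Monod factors by their large-K linear limits or constants; those reductions
are encoded as functional *forms* on the kinetics objects so that a single
right-hand side serves every variant.

Staggered loading (a population added to the filter 120 min after the first)
is handled by segment-wise integration with a state jump at the load time;
each population's lag clock runs from its own load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

try:  # jit-compiled inner loop; plain Python fallback keeps results identical
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]

POPULATIONS = ("D", "R", "T")
DONOR_LIKE = ("D", "T")  # plasmid-bearing subpopulations that can donate

# functional forms selected by variant reduction
LAG_HILL = "hill"        # t^n / (K_L^n + t^n)
LAG_NONE = "none"        # 1
RES_MONOD = "monod"      # C / (K + C)
RES_LINEAR = "linear"    # C      (large-K limit with rescaled maximal rate)
RES_NONE = "none"        # 1      (no resource dependence)


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails; carries the offending parameters."""

    def __init__(self, message, params=None):
        super().__init__(message)
        self.params = params


@dataclass(frozen=True)
class GrowthKinetics:
    """Growth-rate kinetics of one subpopulation.

    psi_max : maximal growth rate (1/min)
    K_L     : lag half-time (min)
    n       : lag Hill coefficient (dimensionless)
    K_G     : growth Monod constant (dimensionless resource units)
    e       : resource-depletion coefficient (cm**2/cell); ``None`` when the
              variant removes the population's depletion term entirely
    """

    psi_max: float
    K_L: float = 0.0
    n: float = 1.0
    K_G: float = 0.0
    e: float | None = 0.0
    lag_form: str = LAG_HILL
    resource_form: str = RES_MONOD

    def __post_init__(self):
        for name in ("psi_max", "K_L", "n", "K_G"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.e is not None and self.e < 0:
            raise ValueError("e must be >= 0")


@dataclass(frozen=True)
class TransferKinetics:
    """Conjugative transfer kinetics mediated by one plasmid-bearing population.

    gamma_max : maximal transfer rate (cm**2/(cell*min))
    K_T       : transfer Monod constant (dimensionless resource units)
    """

    gamma_max: float
    K_T: float = 0.0
    resource_form: str = RES_MONOD

    def __post_init__(self):
        if self.gamma_max < 0 or self.K_T < 0:
            raise ValueError("transfer kinetics must be >= 0")


@dataclass(frozen=True)
class GeneralParameters:
    """Full kinetic parameter set: growth for D, R, T; transfer for D and T."""

    growth: dict[str, GrowthKinetics]
    transfer: dict[str, TransferKinetics]

    def __post_init__(self):
        if set(self.growth) != set(POPULATIONS):
            raise ValueError("growth kinetics required for D, R and T")
        if set(self.transfer) != set(DONOR_LIKE):
            raise ValueError("transfer kinetics required for D and T")


@dataclass(frozen=True)
class LoadingSchedule:
    """When and at what density each founding population reaches the filter.

    Transconjugants always start at zero.  ``t_load`` of 0 means the
    population is present from the start; 120 encodes the staggered designs.
    """

    donor_time: float = 0.0
    donor_density: float = 0.0
    recipient_time: float = 0.0
    recipient_density: float = 0.0
    C0: float = 1.0

    def __post_init__(self):
        if min(self.donor_density, self.recipient_density) < 0:
            raise ValueError("loaded densities must be >= 0")
        if min(self.donor_time, self.recipient_time) < 0:
            raise ValueError("load times must be >= 0")

    @property
    def load_times(self) -> dict[str, float]:
        # transconjugants arise in situ; their lag clock follows the recipient's
        return {"D": self.donor_time, "R": self.recipient_time,
                "T": self.recipient_time}

    @property
    def events(self) -> list[tuple[float, str, float]]:
        """Nonzero-time loading events as (time, population, density)."""
        out = []
        if self.donor_time > 0:
            out.append((self.donor_time, "D", self.donor_density))
        if self.recipient_time > 0:
            out.append((self.recipient_time, "R", self.recipient_density))
        return sorted(out)


@dataclass
class Trajectory:
    """Simulated states at requested output times."""

    t: np.ndarray
    D: np.ndarray
    R: np.ndarray
    T: np.ndarray
    C: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.t, "D": self.D, "R": self.R, "T": self.T,
             "C": self.C})

    def population(self, name: str) -> np.ndarray:
        return getattr(self, name)


def growth_rate(kin: GrowthKinetics, t_eff: float, C: float) -> float:
    """Per-capita growth rate at time ``t_eff`` since the population's load.

    The lag factor is t^n/(K_L^n + t^n) (1 when the variant drops lag, and 1
    in the K_L = 0 limit); the resource factor is C/(K_G + C), C, or 1
    depending on the variant's functional form.
    """
    if t_eff < 0 or C < 0:
        raise ValueError("t_eff and C must be >= 0")
    return kin.psi_max * _lag_factor(kin, t_eff) * _resource_factor(
        kin.resource_form, kin.K_G, C)


def transfer_rate(kin: TransferKinetics, C: float) -> float:
    """Per donor-recipient-pair conjugation rate at resource level ``C``."""
    if C < 0:
        raise ValueError("C must be >= 0")
    return kin.gamma_max * _resource_factor(kin.resource_form, kin.K_T, C)


def _lag_factor(kin: GrowthKinetics, t_eff):
    if kin.lag_form == LAG_NONE:
        return 1.0
    if kin.K_L == 0.0:
        return 1.0  # continuous limit of t^n/(K_L^n+t^n); avoids 0/0 at t=0
    if t_eff == 0.0:
        return 0.0
    # t^n/(K_L^n + t^n) = 1/(1 + (K_L/t)^n), evaluated in log space so that
    # steep Hill coefficients cannot overflow
    ln_ratio = kin.n * np.log(kin.K_L / t_eff)
    if ln_ratio > 700.0:
        return 0.0
    if ln_ratio < -700.0:
        return 1.0
    return 1.0 / (1.0 + np.exp(ln_ratio))


def _resource_factor(form, K, C):
    if form == RES_NONE:
        return 1.0
    if form == RES_LINEAR:
        return C
    if C == 0.0 and K == 0.0:
        return 0.0  # no resource, no activity (limit of C/(K+C))
    return C / (K + C)


def rhs(t: float, state, params: GeneralParameters,
        schedule: LoadingSchedule) -> np.ndarray:
    """Time derivative of (D, R, T, C) under ``params``.

    Conjugation moves density from R to T with identical flux on both sides;
    donors never change identity.  A population not yet loaded has zero
    density in ``state`` and therefore contributes nothing.
    """
    D, R, T, C = state
    D, R, T = max(D, 0.0), max(R, 0.0), max(T, 0.0)
    C = max(C, 0.0)
    loads = schedule.load_times
    psi = {}
    for pop, dens in zip(POPULATIONS, (D, R, T)):
        t_eff = max(t - loads[pop], 0.0)
        psi[pop] = growth_rate(params.growth[pop], t_eff, C) if dens > 0 else 0.0
    conj = R * (transfer_rate(params.transfer["D"], C) * D
                + transfer_rate(params.transfer["T"], C) * T)
    dD = psi["D"] * D
    dR = psi["R"] * R - conj
    dT = psi["T"] * T + conj
    dC = 0.0
    for pop, dens in zip(POPULATIONS, (D, R, T)):
        e = params.growth[pop].e
        if e is not None:
            dC -= e * psi[pop] * dens
    return np.array([dD, dR, dT, dC])


_LAG_CODE = {LAG_HILL: 0.0, LAG_NONE: 1.0}
_RES_CODE = {RES_MONOD: 0.0, RES_LINEAR: 1.0, RES_NONE: 2.0}


def _pack(params: GeneralParameters, schedule: LoadingSchedule) -> np.ndarray:
    """Flatten kinetics + schedule into the jit kernel's parameter vector."""
    th = np.empty(30)
    loads = schedule.load_times
    for i, pop in enumerate(POPULATIONS):
        g = params.growth[pop]
        th[8 * i:8 * i + 8] = (g.psi_max, g.K_L, g.n, g.K_G,
                               0.0 if g.e is None else g.e,
                               _LAG_CODE[g.lag_form],
                               _RES_CODE[g.resource_form], loads[pop])
    for k, j in enumerate(DONOR_LIKE):
        tr = params.transfer[j]
        th[24 + 3 * k:27 + 3 * k] = (tr.gamma_max, tr.K_T,
                                     _RES_CODE[tr.resource_form])
    return th


@njit
def _rhs_kernel(t, y, th):  # pragma: no cover - exercised via simulate
    out = np.empty(4)
    C = y[3] if y[3] > 0.0 else 0.0
    psi = np.empty(3)
    for i in range(3):
        dens = y[i] if y[i] > 0.0 else 0.0
        if dens <= 0.0:
            psi[i] = 0.0
            continue
        psi_max, K_L, n_hill, K_G, _, lag_form, res_form, load = th[8 * i:
                                                                    8 * i + 8]
        t_eff = t - load
        if t_eff < 0.0:
            t_eff = 0.0
        if lag_form == 1.0 or K_L == 0.0:
            lag = 1.0
        elif t_eff == 0.0:
            lag = 0.0
        else:
            ln_ratio = n_hill * np.log(K_L / t_eff)
            if ln_ratio > 700.0:
                lag = 0.0
            elif ln_ratio < -700.0:
                lag = 1.0
            else:
                lag = 1.0 / (1.0 + np.exp(ln_ratio))
        if res_form == 2.0:
            res = 1.0
        elif res_form == 1.0:
            res = C
        elif C == 0.0 and K_G == 0.0:
            res = 0.0
        else:
            res = C / (K_G + C)
        psi[i] = psi_max * lag * res
    D = y[0] if y[0] > 0.0 else 0.0
    R = y[1] if y[1] > 0.0 else 0.0
    T = y[2] if y[2] > 0.0 else 0.0
    conj = 0.0
    for k in range(2):
        gamma_max, K_T, form = th[24 + 3 * k:27 + 3 * k]
        if form == 2.0:
            g = gamma_max
        elif form == 1.0:
            g = gamma_max * C
        elif C == 0.0 and K_T == 0.0:
            g = 0.0
        else:
            g = gamma_max * C / (K_T + C)
        conj += g * (D if k == 0 else T)
    conj *= R
    out[0] = psi[0] * D
    out[1] = psi[1] * R - conj
    out[2] = psi[2] * T + conj
    out[3] = -(th[4] * psi[0] * D + th[12] * psi[1] * R
               + th[20] * psi[2] * T)
    return out


@njit
def _rhs_kernel_multi(t, y, thetas):  # pragma: no cover - via simulate_batch
    n_exp = thetas.shape[0]
    out = np.empty(4 * n_exp)
    for e in range(n_exp):
        out[4 * e:4 * e + 4] = _rhs_kernel(t, y[4 * e:4 * e + 4], thetas[e])
    return out


def simulate_batch(params: GeneralParameters, schedules, times,
                   rtol: float = 1e-8, atol=None) -> list[Trajectory]:
    """Integrate several simultaneous-loading experiments in one solver run.

    All schedules must load at t = 0 (no staggered events) and share the
    output times; the composite system is block-diagonal, so this equals
    per-schedule :func:`simulate` up to solver step-size selection.
    """
    times = np.asarray(times, dtype=float)
    if any(s.events for s in schedules):
        raise ValueError("simulate_batch handles simultaneous loading only")
    if atol is None:
        atol = [1.0, 1.0, 1.0, 1e-12]
    thetas = np.stack([_pack(params, s) for s in schedules])
    y0 = np.concatenate([[s.donor_density, s.recipient_density, 0.0, s.C0]
                         for s in schedules])
    t_eval = times if times[0] > 0 else times[1:]
    sol = solve_ivp(_rhs_kernel_multi, (0.0, times[-1]), y0, method="LSODA",
                    t_eval=t_eval if len(t_eval) else None, rtol=rtol,
                    atol=list(atol) * len(schedules), args=(thetas,))
    if not sol.success:
        raise SimulationError(f"ODE solver failed: {sol.message}",
                              params=params)
    trajectories = []
    for e in range(len(schedules)):
        block = sol.y[4 * e:4 * e + 4]
        if times[0] == 0.0:
            block = np.column_stack([y0[4 * e:4 * e + 4], block])
        block = block.clip(min=0.0)
        trajectories.append(Trajectory(t=times, D=block[0], R=block[1],
                                       T=block[2], C=block[3]))
    return trajectories


def simulate(params: GeneralParameters, schedule: LoadingSchedule,
             times, rtol: float = 1e-8, atol=None,
             method: str = "LSODA") -> Trajectory:
    """Integrate the model and report the state at ``times``.

    Integration restarts at every nonzero load time with the late
    population's density added to the state, so the loading discontinuity is
    handled exactly.  At a load time the *post-jump* state is reported.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be strictly increasing and nonnegative")
    if atol is None:
        atol = [1.0, 1.0, 1.0, 1e-12]  # 1 cell/cm^2 for populations
    theta = _pack(params, schedule)

    y = np.array([
        schedule.donor_density if schedule.donor_time == 0 else 0.0,
        schedule.recipient_density if schedule.recipient_time == 0 else 0.0,
        0.0,
        schedule.C0,
    ])
    t0 = 0.0
    breakpoints = [ev for ev in schedule.events if ev[0] <= times[-1]]
    out = np.empty((len(times), 4))
    filled = np.zeros(len(times), dtype=bool)

    def _record(mask, values):
        out[mask] = values
        filled[mask] = True

    if times[0] == 0.0:
        _record(times == 0.0, y)

    segments = []
    start = t0
    for ev_t, pop, dens in breakpoints:
        segments.append((start, ev_t, (pop, dens)))
        start = ev_t
    segments.append((start, float(times[-1]), None))

    for seg_start, seg_end, event_after in segments:
        if seg_end > seg_start:
            # report load-time states post-jump, hence strict left inequality
            mask = (times > seg_start) & (times < seg_end) if event_after \
                else (times > seg_start) & (times <= seg_end)
            t_req = times[mask]
            # integrate through to the segment boundary regardless of which
            # output times were requested, so the carried state is at seg_end
            t_eval = np.append(t_req, seg_end) if (len(t_req) == 0 or
                                                   t_req[-1] < seg_end) else t_req
            sol = solve_ivp(
                _rhs_kernel, (seg_start, seg_end), y, method=method,
                t_eval=t_eval, rtol=rtol, atol=atol, args=(theta,))
            if not sol.success:
                raise SimulationError(
                    f"ODE solver failed on [{seg_start}, {seg_end}]: "
                    f"{sol.message}", params=params)
            if len(t_req):
                _record(mask, sol.y[:, :len(t_req)].T)
            y = sol.y[:, -1].copy()
        if event_after is not None:
            pop, dens = event_after
            y[POPULATIONS.index(pop)] += dens
            _record(times == seg_end, y)

    if not filled.all():  # pragma: no cover - defensive
        raise SimulationError("output times not covered by integration",
                              params=params)
    out = out.clip(min=0.0)
    return Trajectory(t=times, D=out[:, 0], R=out[:, 1], T=out[:, 2],
                      C=out[:, 3])


def with_growth(params: GeneralParameters, pop: str,
                **changes) -> GeneralParameters:
    """Return a copy of ``params`` with one population's growth fields replaced."""
    growth = dict(params.growth)
    growth[pop] = replace(growth[pop], **changes)
    return GeneralParameters(growth=growth, transfer=dict(params.transfer))
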