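"""Synthetic observation sets with the structure of the mating experiments.

The study design comprises four simultaneous-loading training experiments
and four staggered-loading test experiments (second population loaded at
120 min), each observed at ten time points (0–360 min, step 40) in
triplicate.  This module reproduces those designs with their published
initial densities, simulates any model variant at chosen "true" parameters,
and draws replicate measurements under a multiplicative lognormal noise
model — so the calibration, model-selection, identifiability and prediction
machinery can be exercised end-to-end without the raw dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import GeneralParameters, LoadingSchedule, Trajectory, simulate
from .preprocessing import ObservationSet, aggregate_replicates
from .variants import VariantSpec

DEFAULT_TIMES = tuple(float(t) for t in range(0, 361, 40))
STAGGER_DELAY_MIN = 120.0


@dataclass(frozen=True)
class ExperimentDesign:
    """One filter-mating experiment: loading schedule and observation plan."""

    id: str
    schedule: LoadingSchedule
    times: tuple = DEFAULT_TIMES
    replicates: int = 3

    def __post_init__(self):
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if 0.0 not in self.times:
            raise ValueError("observation times must include 0")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal measurement noise.

    cv              : coefficient of variation per subpopulation (D, R, T)
    detection_floor : densities measured below this (cells/cm**2) are
                      reported at the floor; exact zeros stay zero
    """

    cv: dict = field(default_factory=lambda: {"D": 0.15, "R": 0.15, "T": 0.15})
    detection_floor: float = 1e3

    def __post_init__(self):
        if any(v < 0 for v in self.cv.values()) or self.detection_floor < 0:
            raise ValueError("cv and detection_floor must be >= 0")

    def draw(self, true_values: np.ndarray, subpop: str,
             rng: np.random.Generator) -> np.ndarray:
        """Noisy replicate of a vector of true densities."""
        c = self.cv.get(subpop, 0.0)
        vals = np.asarray(true_values, dtype=float)
        if c > 0:
            sigma2 = np.log1p(c * c)
            factors = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2),
                                    size=vals.shape)
            vals = vals * factors
            positive = vals > 0
            vals[positive] = np.maximum(vals[positive], self.detection_floor)
        return vals


@dataclass(frozen=True)
class SyntheticDataset:
    """An ObservationSet plus the provenance needed to regenerate it."""

    observations: ObservationSet
    replicate_frame: pd.DataFrame
    provenance: dict


def default_training_designs() -> list[ExperimentDesign]:
    """The four simultaneous-loading training experiments (#1–#4).

    Initial (R0, D0) densities follow the published best-fit initial
    conditions of the training fits; transconjugants start at zero.
    """
    initials = {  # id -> (R0, D0) in cells/cm**2
        "exp1": (1.96e6, 1.77e6),
        "exp2": (8.05e6, 8.42e6),
        "exp3": (4.02e6, 2.31e6),
        "exp4": (6.35e5, 5.57e6),
    }
    return [
        ExperimentDesign(
            id=name,
            schedule=LoadingSchedule(donor_density=d0, recipient_density=r0))
        for name, (r0, d0) in initials.items()
    ]


def default_test_designs() -> list[ExperimentDesign]:
    """The four staggered-loading test experiments (#5–#8).

    In #5 and #6 recipients are loaded first and donors at 120 min; in #7
    and #8 the order is reversed.  Densities are the observed loads.
    """
    return [
        ExperimentDesign("exp5", LoadingSchedule(
            recipient_density=5.92e6,
            donor_density=3.51e7, donor_time=STAGGER_DELAY_MIN)),
        ExperimentDesign("exp6", LoadingSchedule(
            recipient_density=5.24e6,
            donor_density=6.71e5, donor_time=STAGGER_DELAY_MIN)),
        ExperimentDesign("exp7", LoadingSchedule(
            donor_density=5.51e6,
            recipient_density=1.00e7, recipient_time=STAGGER_DELAY_MIN)),
        ExperimentDesign("exp8", LoadingSchedule(
            donor_density=4.34e5,
            recipient_density=8.07e6, recipient_time=STAGGER_DELAY_MIN)),
    ]


def generate_dataset(true_params, variant: VariantSpec,
                     designs, noise: NoiseModel | None = None,
                     seed: int = 0, sd_floor_fraction: float = 0.05,
                     ) -> SyntheticDataset:
    """Simulate the designs at the true parameters and draw replicates.

    ``true_params`` may be a :class:`GeneralParameters` or the variant's
    free-parameter vector.  One master seed spawns an independent stream per
    (design, replicate), so a dataset is reproducible under design
    subsetting.  With all CVs zero the replicates equal the simulated
    trajectories exactly.
    """
    if noise is None:
        noise = NoiseModel()
    params = (true_params if isinstance(true_params, GeneralParameters)
              else variant.resolve(true_params))
    master = np.random.SeedSequence(seed)
    design_seeds = master.spawn(len(designs))

    rows = []
    for design, dseed in zip(designs, design_seeds):
        traj = simulate(params, design.schedule, np.asarray(design.times))
        # populations below the detection floor are reported as absent,
        # as a cytometer with finite event counts would
        floor = max(noise.detection_floor, 1.0)
        for pop in ("D", "R", "T"):
            arr = traj.population(pop)
            arr[arr < floor] = 0.0
        rep_seeds = dseed.spawn(design.replicates)
        for rep, rseed in enumerate(rep_seeds, start=1):
            rng = np.random.default_rng(rseed)
            for sub in ("D", "R", "T"):
                noisy = noise.draw(traj.population(sub), sub, rng)
                for t, val in zip(traj.t, noisy):
                    rows.append({"experiment": design.id, "time_min": t,
                                 "replicate": rep, "subpopulation": sub,
                                 "density": val})
    tidy = pd.DataFrame(rows)
    obs = aggregate_replicates(tidy, sd_floor_fraction=sd_floor_fraction)
    provenance = {
        "variant": variant.name,
        "true_free_vector": [float(v) for v in true_params]
        if not isinstance(true_params, GeneralParameters) else None,
        "designs": [d.id for d in designs],
        "noise_cv": dict(noise.cv),
        "detection_floor": noise.detection_floor,
        "seed": seed,
    }
    return SyntheticDataset(observations=obs, replicate_frame=tidy,
                            provenance=provenance)


def predict_test(fit, designs, observations: ObservationSet | None = None):
    """Simulate test designs with previously fitted kinetics.

    ``fit`` is a FitResult (its kinetics are used) or a
    :class:`GeneralParameters`.  Initial densities come from the designs,
    not from the fit; transconjugants stay at zero until donors and
    recipients are both present, which the staggered schedule enforces.

    Returns ``(trajectories, residuals)``: a dict of per-design
    :class:`Trajectory`, and a tidy frame of weighted residuals
    ``(mean - sim) / sd`` when ``observations`` is given (else ``None``).
    """
    params = fit if isinstance(fit, GeneralParameters) else fit.parameters
    trajectories: dict[str, Trajectory] = {}
    for design in designs:
        trajectories[design.id] = simulate(params, design.schedule,
                                           np.asarray(design.times))
    residuals = None
    if observations is not None:
        rows = []
        for design in designs:
            traj = trajectories[design.id]
            sub_frame = observations.frame[
                observations.frame["experiment"] == design.id]
            lookup = {(r["subpopulation"], r["time_min"]): (r["mean"], r["sd"])
                      for _, r in sub_frame.iterrows()}
            for sub in ("D", "R", "T"):
                for t, sim_val in zip(traj.t, traj.population(sub)):
                    if (sub, t) not in lookup:
                        continue
                    mean, sd = lookup[(sub, t)]
                    rows.append({
                        "experiment": design.id, "subpopulation": sub,
                        "time_min": t, "observed": mean, "predicted": sim_val,
                        "weighted_residual": (mean - sim_val) / sd
                        if sd > 0 else np.nan,
                    })
        residuals = pd.DataFrame(rows)
    return trajectories, residuals
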