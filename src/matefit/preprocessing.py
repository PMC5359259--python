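"""Raw measurement conversion: OD600 + cytometry fractions -> cells/cm**2.

Each time-point measurement of a mating filter consists of the optical
density of the PBS-resuspended filter population, the suspension volume, and
the flow-cytometric fraction of events in each subpopulation gate (donor,
recipient, transconjugant).  The conversion chain is:

1. OD600 in PBS -> OD600 in LB by the linear calibration
   OD_LB = 0.869 * OD_PBS - 0.0057 (clamped at zero);
2. OD600 in LB -> total cells/ml by the E. coli rule of thumb
   1.0 OD600 = 8e8 cells/ml;
3. cells/ml * suspension volume * 2 (50% filter-recovery efficiency)
   / 17.35 cm**2 filter area -> total cells/cm**2 on the filter;
4. multiply by each gate fraction -> subpopulation densities.

Replicates are then aggregated into per-(experiment, subpopulation, time)
means and sample standard deviations, the weights of the calibration SSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# OD600(LB) as a linear function of OD600(PBS), calibrated over [0.073, 1.20]
OD_PBS_TO_LB_SLOPE = 0.869
OD_PBS_TO_LB_INTERCEPT = -0.0057
CELLS_PER_ML_PER_OD = 8e8          # E. coli in LB at OD600 = 1.0
RECOVERY_EFFICIENCY = 0.5          # fraction of filter cells recovered in PBS
FILTER_AREA_CM2 = 17.35

SUBPOPULATIONS = ("D", "R", "T")
_GATE_COLUMNS = {"D": "frac_donor", "R": "frac_recipient",
                 "T": "frac_transconjugant"}

#: suspension volume (ml) used at each observation time (min); volumes grow
#: with the population so that optical densities stay in calibration range
DEFAULT_VOLUME_SCHEDULE = {
    0: 2, 40: 2, 80: 2, 120: 2, 160: 2,
    200: 5, 240: 10, 280: 20, 320: 25, 360: 30,
}


@dataclass(frozen=True)
class RawObservation:
    """One replicate measurement before conversion to densities."""

    experiment: str
    time_min: float
    replicate: int
    od_pbs: float
    volume_ml: float
    fractions: dict[str, float]  # keyed by subpopulation D/R/T

    def __post_init__(self):
        if self.od_pbs < 0:
            raise ValueError("od_pbs must be >= 0")
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be > 0")
        fr = [self.fractions.get(s, 0.0) for s in SUBPOPULATIONS]
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("gate fractions must lie in [0, 1]")
        if sum(fr) > 1 + 1e-9:
            raise ValueError("gate fractions must sum to at most 1")


@dataclass(frozen=True)
class DensityObservation:
    """One replicate's subpopulation densities (cells/cm**2)."""

    experiment: str
    time_min: float
    replicate: int
    densities: dict[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.densities.values()):
            raise ValueError("densities must be >= 0")


class ObservationSet:
    """Replicate-aggregated densities: mean and SD per design cell.

    Thin wrapper around a tidy DataFrame with columns ``experiment``,
    ``subpopulation``, ``time_min``, ``mean``, ``sd``, ``n_replicates``.
    """

    COLUMNS = ["experiment", "subpopulation", "time_min", "mean", "sd",
               "n_replicates"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"ObservationSet frame missing columns {missing}")
        if (frame["sd"] < 0).any():
            raise ValueError("standard deviations must be >= 0")
        self.frame = (frame[self.COLUMNS]
                      .sort_values(["experiment", "subpopulation", "time_min"])
                      .reset_index(drop=True))

    @property
    def experiments(self) -> list[str]:
        return sorted(self.frame["experiment"].unique())

    def times(self, experiment) -> np.ndarray:
        sub = self.frame[self.frame["experiment"] == experiment]
        return np.array(sorted(sub["time_min"].unique()))

    def n_observations(self, *, exclude_initial_transconjugants: bool = True,
                       exclude_initial: bool = False) -> int:
        """Observation count under the bookkeeping used for scoring.

        With ``exclude_initial_transconjugants`` the t=0 transconjugant cells
        (pinned to zero by design) are not counted — the AICc convention.
        With ``exclude_initial`` no t=0 observation is counted — the
        confidence-interval convention.
        """
        f = self.frame
        if exclude_initial:
            return int((f["time_min"] > 0).sum())
        if exclude_initial_transconjugants:
            drop = (f["time_min"] == 0) & (f["subpopulation"] == "T")
            return int(len(f) - drop.sum())
        return len(f)

    def initial_means(self, experiment) -> dict[str, float]:
        """Observed t=0 mean density per subpopulation (fit-start heuristic)."""
        sub = self.frame[(self.frame["experiment"] == experiment)
                         & (self.frame["time_min"] == 0)]
        return dict(zip(sub["subpopulation"], sub["mean"]))

    def to_csv(self, path):
        out = self.frame.rename(columns={"mean": "mean_density",
                                         "sd": "sd_density"})
        out.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "ObservationSet":
        frame = pd.read_csv(path, float_precision="round_trip")
        frame = frame.rename(columns={"mean_density": "mean",
                                      "sd_density": "sd"})
        # integral values round-trip through CSV as int64; restore dtypes
        for col in ("time_min", "mean", "sd"):
            frame[col] = frame[col].astype(float)
        return cls(frame)

    def __len__(self):
        return len(self.frame)

    def __eq__(self, other):
        return isinstance(other, ObservationSet) and self.frame.equals(other.frame)


def od_pbs_to_lb(od_pbs: float) -> float:
    """Convert OD600 measured in PBS to the equivalent OD600 in LB.

    Linear calibration clamped at zero (the affine map crosses zero near
    OD_PBS = 0.0066).
    """
    od_pbs = np.asarray(od_pbs, dtype=float)
    if np.any(od_pbs < 0):
        raise ValueError("od_pbs must be >= 0")
    out = np.maximum(OD_PBS_TO_LB_SLOPE * od_pbs + OD_PBS_TO_LB_INTERCEPT, 0.0)
    return float(out) if out.ndim == 0 else out


def observation_to_density(raw: RawObservation) -> DensityObservation:
    """Convert one raw replicate measurement to subpopulation densities."""
    cells_per_ml = od_pbs_to_lb(raw.od_pbs) * CELLS_PER_ML_PER_OD
    total_per_cm2 = (cells_per_ml * raw.volume_ml / RECOVERY_EFFICIENCY
                     / FILTER_AREA_CM2)
    densities = {s: raw.fractions.get(s, 0.0) * total_per_cm2
                 for s in SUBPOPULATIONS}
    return DensityObservation(experiment=raw.experiment,
                              time_min=raw.time_min,
                              replicate=raw.replicate,
                              densities=densities)


def aggregate_replicates(observations, *, ddof: int = 1,
                         sd_floor_fraction: float = 0.05) -> ObservationSet:
    """Aggregate per-replicate densities into an :class:`ObservationSet`.

    Parameters
    ----------
    observations : iterable of DensityObservation, or tidy DataFrame with
        columns experiment, time_min, replicate, subpopulation, density.
    ddof : delta degrees of freedom of the standard deviation (1 = sample SD).
    sd_floor_fraction : SDs are floored at this fraction of the cell mean so
        that coincident replicates never produce infinite SSE weights.
    """
    if isinstance(observations, pd.DataFrame):
        tidy = observations.copy()
    else:
        rows = []
        for obs in observations:
            for sub, dens in obs.densities.items():
                rows.append({"experiment": obs.experiment,
                             "time_min": obs.time_min,
                             "replicate": obs.replicate,
                             "subpopulation": sub, "density": dens})
        tidy = pd.DataFrame(rows)
    if tidy.empty:
        raise ValueError("no observations to aggregate")

    grouped = tidy.groupby(["experiment", "subpopulation", "time_min"])
    agg = grouped["density"].agg(
        mean="mean", sd=lambda x: x.std(ddof=ddof), n_replicates="count"
    ).reset_index()
    agg["sd"] = agg["sd"].fillna(0.0)
    if (agg["n_replicates"] < 2).any():
        bad = agg.loc[agg["n_replicates"] < 2,
                      ["experiment", "subpopulation", "time_min"]]
        raise ValueError(
            "at least 2 replicates required per (experiment, subpopulation, "
            f"time); offending cells:\n{bad.to_string(index=False)}")
    agg["sd"] = np.maximum(agg["sd"], sd_floor_fraction * agg["mean"].abs())
    return ObservationSet(agg)


def convert_raw_frame(frame: pd.DataFrame, *, ddof: int = 1,
                      sd_floor_fraction: float = 0.05) -> ObservationSet:
    """Full chain on a raw CSV frame (experiment, time_min, replicate,
    od_pbs, volume_ml, frac_donor, frac_recipient, frac_transconjugant)."""
    observations = [
        observation_to_density(RawObservation(
            experiment=row["experiment"], time_min=row["time_min"],
            replicate=int(row["replicate"]), od_pbs=row["od_pbs"],
            volume_ml=row["volume_ml"],
            fractions={s: row[c] for s, c in _GATE_COLUMNS.items()}))
        for _, row in frame.iterrows()
    ]
    return aggregate_replicates(observations, ddof=ddof,
                                sd_floor_fraction=sd_floor_fraction)
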