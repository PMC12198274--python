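"""Lifetime stimulant-dose trajectories and treatment subgrouping.

Prescription records are expanded into a monthly mean-dose series from
birth to assessment (day-weighted within calendar months, dexamphetamine
converted to methylphenidate-equivalents). Six features summarize each
trajectory: onset age, stop age and total dose from the raw series;
treatment duration, maximum daily dose and dose variability from a
penalized cubic smoothing spline (GCV-selected penalty) fitted to the
raw series. Participants are then partitioned into treatment-trajectory
subgroups by Louvain community detection on a nonnegative Pearson
similarity graph over the z-scored features; communities below a minimum
size are flagged excluded, and modularity Q quantifies the separation
(0 = no subgroups, towards 1 = strong segregation).
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "PrescriptionRecord",
    "DoseTrajectory",
    "TrajectoryFeatures",
    "CommunityPartition",
    "TrajectoryCommunities",
    "build_monthly_trajectory",
    "extract_raw_features",
    "fit_smoothed_trajectory",
    "trajectory_features",
    "louvain_subgroups",
]

DAYS_PER_YEAR = 365.25

FEATURE_COLUMNS = (
    "onset_age",
    "stop_age",
    "total_dose",
    "duration",
    "max_daily_dose",
    "dose_sd",
)


@dataclass(frozen=True)
class PrescriptionRecord:
    """One prescription episode: constant daily dose over a date span."""

    participant_id: str
    start_date: dt.date
    end_date: dt.date
    drug: str
    dose_mg_per_day: float

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError(
                f"{self.participant_id}: end date {self.end_date} before start {self.start_date}"
            )
        if self.dose_mg_per_day < 0:
            raise ValueError(f"{self.participant_id}: negative dose {self.dose_mg_per_day}")
        if self.drug not in ("methylphenidate", "dexamphetamine"):
            raise ValueError(f"unknown drug {self.drug!r}")


@dataclass
class DoseTrajectory:
    """Monthly mean dose (mg/day) from birth month to assessment month."""

    participant_id: str
    birth: dt.date
    assessment: dt.date
    months: pd.PeriodIndex
    dose: np.ndarray  # mg/day, aligned with months

    def month_start_ages(self) -> np.ndarray:
        """Age in years at the first day of each month."""
        starts = self.months.to_timestamp().date
        return np.array([(d - self.birth).days / DAYS_PER_YEAR for d in starts])

    def month_mid_ages(self) -> np.ndarray:
        mids = self.months.to_timestamp().date
        return np.array(
            [
                (d - self.birth).days / DAYS_PER_YEAR + 0.5 / 12
                for d in mids
            ]
        )


@dataclass
class TrajectoryFeatures:
    """Six trajectory summaries; raw-series and smoothed-series halves."""

    participant_id: str
    onset_age: float | None
    stop_age: float | None
    total_dose: float
    duration: float
    max_daily_dose: float
    dose_sd: float
    never_treated: bool = False

    def as_row(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "onset_age": self.onset_age,
            "stop_age": self.stop_age,
            "total_dose": self.total_dose,
            "duration": self.duration,
            "max_daily_dose": self.max_daily_dose,
            "dose_sd": self.dose_sd,
            "never_treated": self.never_treated,
        }


def _overlap_days(a_start: dt.date, a_end: dt.date, b_start: dt.date, b_end: dt.date) -> int:
    """Days in the intersection of two inclusive date spans."""
    lo = max(a_start, b_start)
    hi = min(a_end, b_end)
    return max(0, (hi - lo).days + 1)


def build_monthly_trajectory(
    records: list[PrescriptionRecord],
    birth: dt.date,
    assessment: dt.date,
    participant_id: str = "",
    dex_equivalence: float = 2.0,
) -> DoseTrajectory:
    """Day-weighted monthly mean dose series over [birth, assessment].

    A month's value is the summed prescribed mg/day over its covered days
    divided by the month's calendar length; overlapping records add up.
    Dexamphetamine doses are multiplied by ``dex_equivalence``
    (default 2, yielding methylphenidate-equivalents).
    """
    if assessment < birth:
        raise ValueError("assessment date before birth date")
    months = pd.period_range(start=birth, end=assessment, freq="M")
    dose = np.zeros(len(months))
    for rec in records:
        eq = dex_equivalence if rec.drug == "dexamphetamine" else 1.0
        start = max(rec.start_date, birth)
        end = min(rec.end_date, assessment)
        if end < start:
            continue
        for k, m in enumerate(months):
            m_start = dt.date(m.year, m.month, 1)
            m_days = calendar.monthrange(m.year, m.month)[1]
            m_end = dt.date(m.year, m.month, m_days)
            days = _overlap_days(start, end, m_start, m_end)
            if days:
                dose[k] += rec.dose_mg_per_day * eq * days / m_days
    return DoseTrajectory(
        participant_id=participant_id or (records[0].participant_id if records else ""),
        birth=birth,
        assessment=assessment,
        months=months,
        dose=dose,
    )


def extract_raw_features(traj: DoseTrajectory) -> tuple[float | None, float | None, float]:
    """Onset age, stop age and total dose from the raw monthly series.

    Onset/stop are the ages at the first/last month with nonzero dose;
    total dose integrates monthly mg/day over calendar days. An all-zero
    trajectory has undefined onset/stop (returned as None).
    """
    if len(traj.dose) == 0:
        raise ValueError("empty trajectory")
    month_days = np.array(
        [calendar.monthrange(m.year, m.month)[1] for m in traj.months], dtype=float
    )
    total = float((traj.dose * month_days).sum())
    nz = np.flatnonzero(traj.dose > 0)
    if nz.size == 0:
        return None, None, total
    ages = traj.month_start_ages()
    return float(ages[nz[0]]), float(ages[nz[-1]]), total


def fit_smoothed_trajectory(
    traj: DoseTrajectory,
    duration_threshold: float = 1.0,
    grid_per_month: int = 4,
) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Penalized-spline smooth of the dose series and derived features.

    Fits a cubic smoothing spline of dose on age with the penalty chosen
    by generalized cross-validation, evaluates it on a fine age grid, and
    returns ``(grid_ages, smoothed, duration, max_daily_dose, dose_sd)``:
    duration is the total time (years) the curve exceeds
    ``duration_threshold`` mg/day (a smoothed curve never returns exactly
    to zero), the maximum is floored at 0, and the SD is taken over the
    treated span.
    """
    if len(traj.dose) < 8:
        raise ValueError(f"need >= 8 months of data, got {len(traj.dose)}")
    x = traj.month_mid_ages()
    y = traj.dose.astype(float)
    grid = np.linspace(x[0], x[-1], max(2, len(x) * grid_per_month))
    if np.allclose(y, y[0]):
        smooth = np.full_like(grid, y[0])  # constant series: spline is the constant
    else:
        spline = make_smoothing_spline(x, y)  # lam=None -> GCV
        smooth = spline(grid)
    step = (grid[-1] - grid[0]) / (len(grid) - 1)
    treated = smooth > duration_threshold
    duration = float(treated.sum() * step)
    max_dose = float(max(smooth.max(), 0.0))
    dose_sd = float(smooth[treated].std()) if treated.any() else 0.0
    return grid, smooth, duration, max_dose, dose_sd


def trajectory_features(
    records: list[PrescriptionRecord],
    birth: dt.date,
    assessment: dt.date,
    participant_id: str = "",
    dex_equivalence: float = 2.0,
    duration_threshold: float = 1.0,
) -> TrajectoryFeatures:
    """Full feature extraction for one participant's prescription history."""
    traj = build_monthly_trajectory(
        records, birth, assessment, participant_id=participant_id, dex_equivalence=dex_equivalence
    )
    onset, stop, total = extract_raw_features(traj)
    if onset is None:
        return TrajectoryFeatures(
            participant_id=traj.participant_id,
            onset_age=None, stop_age=None, total_dose=total,
            duration=0.0, max_daily_dose=0.0, dose_sd=0.0, never_treated=True,
        )
    _, _, duration, max_dose, dose_sd = fit_smoothed_trajectory(
        traj, duration_threshold=duration_threshold
    )
    return TrajectoryFeatures(
        participant_id=traj.participant_id,
        onset_age=onset, stop_age=stop, total_dose=total,
        duration=duration, max_daily_dose=max_dose, dose_sd=dose_sd,
    )


@dataclass
class CommunityPartition:
    """Louvain assignment over the trajectory-similarity graph."""

    labels: pd.Series  # participant -> community id (0 = largest)
    modularity: float
    community_sizes: pd.Series
    excluded: dict[int, str] = field(default_factory=dict)

    def retained(self) -> pd.Series:
        return self.labels[~self.labels.isin(list(self.excluded))]


class TrajectoryCommunities(BaseEstimator, ClusterMixin):
    """Louvain subgrouping of participants by trajectory features.

    Features are z-scored column-wise; participant similarity is the
    Pearson correlation between feature vectors with negative values set
    to zero; Louvain (resolution 1, seeded) maximizes weighted
    modularity. Communities smaller than ``min_community_size`` are
    flagged excluded rather than reassigned.
    """

    def __init__(self, min_community_size: int = 10, seed: int | None = 0):
        self.min_community_size = min_community_size
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None) -> "TrajectoryCommunities":
        X = pd.DataFrame(X)
        X = X.dropna()
        if len(X) < 2:
            raise ValueError("need >= 2 participants with complete features")
        Z = X.to_numpy(dtype=float)
        sd = Z.std(axis=0)
        Z = (Z - Z.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        S = np.corrcoef(Z)
        S = np.where(np.isfinite(S), S, 0.0)
        S[S < 0] = 0.0
        np.fill_diagonal(S, 0.0)
        if not S.any():
            raise ValueError("no structure: all pairwise similarities are zero")

        G = nx.Graph()
        G.add_nodes_from(range(len(Z)))
        ii, jj = np.nonzero(np.triu(S, k=1))
        G.add_weighted_edges_from((int(i), int(j), float(S[i, j])) for i, j in zip(ii, jj))
        comms = nx.community.louvain_communities(
            G, weight="weight", resolution=1.0, seed=self.seed
        )
        comms = sorted(comms, key=lambda c: (-len(c), min(c)))
        q = nx.community.modularity(G, comms, weight="weight")

        labels = np.empty(len(Z), dtype=int)
        for cid, members in enumerate(comms):
            for m in members:
                labels[m] = cid
        self.labels_ = pd.Series(labels, index=X.index, name="community")
        self.modularity_ = float(q)
        sizes = self.labels_.value_counts().sort_index()
        self.partition_ = CommunityPartition(
            labels=self.labels_,
            modularity=self.modularity_,
            community_sizes=sizes,
            excluded={
                int(cid): f"community size {int(n)} < {self.min_community_size}"
                for cid, n in sizes.items()
                if n < self.min_community_size
            },
        )
        self.graph_ = G
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_.to_numpy()


def louvain_subgroups(
    features: pd.DataFrame,
    min_community_size: int = 10,
    seed: int | None = 0,
) -> CommunityPartition:
    """Partition participants by Louvain on the trajectory-feature graph.

    ``features`` holds one row per participant and the six trajectory
    features as columns; rows with missing features are dropped.
    """
    est = TrajectoryCommunities(min_community_size=min_community_size, seed=seed)
    est.fit(features)
    return est.partition_
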