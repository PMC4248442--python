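"""Phenotype-microarray (Biolog PM) kinetic analysis.

Each well of a PM plate holds a different nutrient; cellular respiration
reduces a tetrazolium dye and the OmniLog reader reports arbitrary
respiration units (OU) over 0-96 h.  This module turns those curves into
scalar growth metrics, discretizes wells into high / moderate / no growth
against the plate negative control and a positive anchor well (D-glucose on
the carbon plate), checks replicate agreement, and clusters conditions by
the shape of their respiration profiles (1 - Pearson distance, average
linkage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PlateSet",
    "GrowthMetrics",
    "GrowthCall",
    "GrowthClassifier",
    "ConditionClusterer",
    "compute_metrics",
    "aggregate_replicates",
    "classify_growth",
    "correlation_at_time",
    "cluster_conditions",
    "condition_features",
    "GROWTH_CLASSES",
]

GROWTH_CLASSES = ("high", "moderate", "none")

KINETICS_COLUMNS = ["plate", "well", "condition", "replicate", "time_h", "omnilog_units"]
PLATE_MAP_COLUMNS = ["plate", "well", "condition", "role"]  # role: test | negative_control


@dataclass
class PlateSet:
    """Long-format respiration kinetics plus the plate maps.

    ``kinetics`` columns: plate, well, condition, replicate, time_h,
    omnilog_units.  ``plate_map`` columns: plate, well, condition, role.
    """

    kinetics: pd.DataFrame
    plate_map: pd.DataFrame

    def test_conditions(self) -> list[str]:
        sel = self.plate_map["role"] == "test"
        return self.plate_map.loc[sel, "condition"].tolist()

    def replicate(self, rep: int) -> pd.DataFrame:
        return self.kinetics[self.kinetics["replicate"] == rep]


@dataclass
class GrowthMetrics:
    max_signal: float
    auc: float  # OU*h, trapezoid over the native grid
    value_at_48h: float
    lag_time: float | None  # h; None when the curve never leaves baseline


@dataclass
class GrowthCall:
    condition: str
    growth_class: str


def compute_metrics(times, signal) -> GrowthMetrics:
    """Scalar kinetics for one respiration curve.

    Maximum signal, trapezoidal area under the curve, the linearly
    interpolated 48-h value and the lag time (first time the signal exceeds
    10% of the maximum; undefined for curves that stay at or below zero).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.ndim != 1 or t.shape != y.shape or t.size < 2:
        raise ValueError("need matching 1-D time/signal vectors with >= 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    max_signal = float(y.max())
    auc = float(np.trapezoid(y, t))
    at48 = float(np.interp(48.0, t, y)) if t[0] <= 48.0 <= t[-1] else float("nan")
    lag = None
    if max_signal > 0:
        above = np.flatnonzero(y > 0.1 * max_signal)
        lag = float(t[above[0]]) if above.size else None
    return GrowthMetrics(max_signal=max_signal, auc=auc, value_at_48h=at48, lag_time=lag)


def aggregate_replicates(plate_set: PlateSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pointwise mean and standard deviation across replicates.

    Returns two wide tables indexed by (plate, well, condition) with one
    column per time point.  Replicates must share the time grid.
    """
    wide = plate_set.kinetics.pivot_table(
        index=["plate", "well", "condition", "replicate"],
        columns="time_h",
        values="omnilog_units",
    )
    if wide.isna().any().any():
        raise ValueError("replicates do not share a common time grid")
    grouped = wide.groupby(level=["plate", "well", "condition"])
    return grouped.mean(), grouped.std(ddof=0)


def classify_growth(
    metrics: GrowthMetrics,
    neg_control: GrowthMetrics,
    pos_anchor: GrowthMetrics,
    delta_none: float = 50.0,
    rho_high: float = 0.6,
) -> str:
    """Discretize one condition against the plate controls.

    ``none`` when the maximum signal rises less than ``delta_none`` OU above
    the negative control's maximum; ``high`` when the AUC reaches
    ``rho_high`` of the positive anchor's AUC; ``moderate`` otherwise.
    """
    if metrics.max_signal - neg_control.max_signal < delta_none:
        return "none"
    if metrics.auc >= rho_high * pos_anchor.auc:
        return "high"
    return "moderate"


class GrowthClassifier(BaseEstimator):
    """Discretize PM wells into high / moderate / no growth.

    ``fit`` aggregates replicates and learns the per-plate negative-control
    metrics and the positive-anchor AUC (the D-glucose well of the carbon
    plate by default, mirroring the batch-culture validation well);
    ``predict`` returns one class per test condition.

    Parameters
    ----------
    delta_none : float, default 50.0
        Minimum rise of the maximum signal above the plate negative control
        (OU) for any growth at all.
    rho_high : float, default 0.6
        Fraction of the positive anchor's AUC from which growth counts as
        high.
    anchor_condition, anchor_plate : str
        Identify the positive anchor well.
    """

    def __init__(
        self,
        delta_none: float = 50.0,
        rho_high: float = 0.6,
        anchor_condition: str = "D-Glucose",
        anchor_plate: str = "PM1",
    ):
        self.delta_none = delta_none
        self.rho_high = rho_high
        self.anchor_condition = anchor_condition
        self.anchor_plate = anchor_plate

    def fit(self, X: PlateSet, y=None):
        mean, _sd = aggregate_replicates(X)
        times = mean.columns.to_numpy(dtype=float)
        metrics: dict[tuple[str, str, str], GrowthMetrics] = {
            key: compute_metrics(times, row.to_numpy()) for key, row in mean.iterrows()
        }
        controls = X.plate_map[X.plate_map["role"] == "negative_control"]
        if controls.empty:
            raise ValueError("plate map contains no negative_control wells")
        self.neg_metrics_: dict[str, GrowthMetrics] = {}
        for plate, grp in controls.groupby("plate"):
            ms = [
                metrics[(plate, r.well, r.condition)] for r in grp.itertuples()
            ]
            self.neg_metrics_[plate] = GrowthMetrics(
                max_signal=float(np.mean([m.max_signal for m in ms])),
                auc=float(np.mean([m.auc for m in ms])),
                value_at_48h=float(np.mean([m.value_at_48h for m in ms])),
                lag_time=None,
            )
        anchor_key = [
            k
            for k in metrics
            if k[0] == self.anchor_plate and k[2] == self.anchor_condition
        ]
        if not anchor_key:
            raise ValueError(
                f"positive anchor {self.anchor_condition!r} not found on plate "
                f"{self.anchor_plate}"
            )
        self.anchor_metrics_ = metrics[anchor_key[0]]
        self.metrics_ = metrics
        return self

    def predict(self, X: PlateSet) -> pd.DataFrame:
        """Per-test-condition growth calls as a DataFrame.

        Columns: plate, well, condition, growth_class.
        """
        check_is_fitted(self, "anchor_metrics_")
        mean, _sd = aggregate_replicates(X)
        times = mean.columns.to_numpy(dtype=float)
        tests = X.plate_map[X.plate_map["role"] == "test"]
        rows = []
        for r in tests.itertuples():
            m = compute_metrics(
                times, mean.loc[(r.plate, r.well, r.condition)].to_numpy()
            )
            if r.plate not in self.neg_metrics_:
                raise ValueError(f"no negative control fitted for plate {r.plate}")
            cls = classify_growth(
                m,
                self.neg_metrics_[r.plate],
                self.anchor_metrics_,
                delta_none=self.delta_none,
                rho_high=self.rho_high,
            )
            rows.append((r.plate, r.well, r.condition, cls))
        return pd.DataFrame(rows, columns=["plate", "well", "condition", "growth_class"])

    def fit_predict(self, X: PlateSet, y=None) -> pd.DataFrame:
        return self.fit(X).predict(X)


def correlation_at_time(plate_set: PlateSet, t: float = 48.0) -> float:
    """Pearson r of the interpolated t-hour values across all test wells."""
    tests = plate_set.plate_map[plate_set.plate_map["role"] == "test"]
    keys = list(zip(tests["plate"], tests["well"]))
    values = {}
    for rep, grp in plate_set.kinetics.groupby("replicate"):
        wide = grp.pivot_table(index=["plate", "well"], columns="time_h", values="omnilog_units")
        times = wide.columns.to_numpy(dtype=float)
        if not times.min() <= t <= times.max():
            raise ValueError(f"time {t} h outside the sampled range")
        at_t = wide.apply(lambda row: np.interp(t, times, row.to_numpy()), axis=1)
        values[rep] = at_t.loc[keys].to_numpy()
    reps = sorted(values)
    if len(reps) != 2:
        raise ValueError("correlation_at_time expects exactly two replicates")
    a, b = values[reps[0]], values[reps[1]]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for zero-variance replicate values")
    return float(stats.pearsonr(a, b).statistic)


class ConditionClusterer(ClusterMixin, BaseEstimator):
    """Hierarchical clustering of conditions by respiration profile.

    Distance is 1 - Pearson correlation between profiles; linkage is average
    (UPGMA).  ``fit`` expects a (conditions x time samples) DataFrame --
    typically the replicate-mean curves -- and exposes the scipy linkage
    matrix, flat labels at ``n_clusters``, and a Newick export of the
    dendrogram.  Constant profiles have no defined correlation and are
    dropped with a warning.
    """

    def __init__(self, n_clusters: int = 3):
        self.n_clusters = n_clusters

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        keep = X.std(axis=1) > 0
        if not keep.all():
            dropped = list(X.index[~keep])
            warnings.warn(f"dropping constant profiles: {dropped}")
            X = X.loc[keep]
        if len(X) < 2:
            raise ValueError("need at least two non-constant conditions to cluster")
        if len(X) < self.n_clusters:
            raise ValueError("fewer conditions than requested clusters")
        dist = pdist(X.to_numpy(dtype=float), metric="correlation")
        self.linkage_ = linkage(dist, method="average")
        flat = fcluster(self.linkage_, t=self.n_clusters, criterion="maxclust")
        self.labels_ = pd.Series(flat, index=X.index, name="cluster")
        self.condition_names_ = list(X.index)
        return self

    def to_newick(self) -> str:
        check_is_fitted(self, "linkage_")
        from skbio.tree import TreeNode

        names = [
            "|".join(map(str, c)) if isinstance(c, tuple) else str(c)
            for c in self.condition_names_
        ]
        tree = TreeNode.from_linkage_matrix(self.linkage_, names)
        return str(tree)


def cluster_conditions(features: pd.DataFrame, k: int = 3) -> ConditionClusterer:
    """Fit a :class:`ConditionClusterer` with ``k`` flat clusters."""
    return ConditionClusterer(n_clusters=k).fit(features)


def condition_features(
    plate_set: PlateSet, plate: str | None = None, bin_h: float = 4.0
) -> pd.DataFrame:
    """Replicate-mean respiration profiles as a conditions x time matrix.

    Point noise in the 15-min readout would otherwise dominate the Pearson
    distance of low-signal wells, so the mean curves are averaged into
    ``bin_h``-hour bins before clustering.  Restrict to one plate with
    ``plate``; only test wells are included.
    """
    mean, _sd = aggregate_replicates(plate_set)
    tests = plate_set.plate_map[plate_set.plate_map["role"] == "test"]
    if plate is not None:
        tests = tests[tests["plate"] == plate]
    keys = list(zip(tests["plate"], tests["well"], tests["condition"]))
    mean = mean.loc[keys]
    mean.index = mean.index.get_level_values("condition")
    if bin_h is None:
        return mean
    times = mean.columns.to_numpy(dtype=float)
    bins = np.floor(times / bin_h).astype(int)
    binned = mean.T.groupby(bins).mean().T
    binned.columns = [f"bin_{b}" for b in binned.columns]
    return binned
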