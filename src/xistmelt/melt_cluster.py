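"""Melt-profile clustering with the two HRM user parameters.

Wells are grouped by agglomerative merging under two constraints, mirroring
the instrument software's inputs:

* **curve-shape sensitivity** (percent, 1–100): mapped linearly to a
  complete-linkage shape-distance ceiling θ_shape = θ_max·(1 − (s − 1)/99);
  minimum sensitivity (1%) gives the broadest clusters (θ_max, default
  0.10), so presence/absence of a whole amplicon separates clusters while
  allele-level shape differences do not;
* **Tm difference threshold** (°C): two clusters may merge only while
  their mean primary Tm values differ by at most this threshold.

Merging is greedy and fully deterministic: at each step the qualifying pair
with the smallest complete-linkage shape distance merges (ties broken by
cluster id), until no pair qualifies. Clusters smaller than
``min_cluster_size`` are flagged as outliers — the analysis's mechanism for
setting aside primer-dimer and other aberrant wells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .hrm_core import DifferenceCurve, MeltPeaks, NormalizedCurve, curve_distance

__all__ = [
    "ClusterParams",
    "ClusterSummary",
    "ClusterResult",
    "ClusterDiagnostics",
    "shape_distance",
    "cluster_wells",
    "cluster_diagnostics",
]


@dataclass(frozen=True)
class ClusterParams:
    """User-facing clustering parameters.

    Defaults are the study settings: shape sensitivity at its minimum (1%)
    and Tm difference threshold at its maximum (1 °C), chosen to cluster by
    amplicon presence/absence rather than fine sequence differences.
    """

    shape_sensitivity: float = 1.0  # percent, in [1, 100]
    tm_threshold: float = 1.0  # °C, in (0, 2]
    min_cluster_size: int = 3  # below this a cluster is an outlier
    theta_max: float = 0.10  # shape ceiling at minimum sensitivity

    def __post_init__(self) -> None:
        if not 1.0 <= self.shape_sensitivity <= 100.0:
            raise ValueError("shape_sensitivity must be in [1, 100] percent")
        if not 0.0 < self.tm_threshold <= 2.0:
            raise ValueError("tm_threshold must be in (0, 2] °C")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")

    @property
    def shape_threshold(self) -> float:
        """θ_shape = θ_max · (1 − (s − 1)/99): the merge ceiling on
        complete-linkage shape distance."""
        return self.theta_max * (1.0 - (self.shape_sensitivity - 1.0) / 99.0)


@dataclass(frozen=True)
class ClusterSummary:
    cluster_id: int
    size: int
    mean_tm: float
    medoid_well_id: str
    is_outlier: bool


@dataclass(frozen=True)
class ClusterResult:
    """Well → cluster assignment with outlier flags and per-cluster summaries."""

    labels: dict[str, int]
    outlier_flags: dict[str, bool]
    summaries: dict[int, ClusterSummary]
    params: ClusterParams

    @property
    def primary_clusters(self) -> list[int]:
        """Ids of non-outlier clusters, ordered by id."""
        return sorted(c for c, s in self.summaries.items() if not s.is_outlier)

    def wells_in(self, cluster_id: int) -> list[str]:
        return sorted(w for w, c in self.labels.items() if c == cluster_id)


def shape_distance(a: NormalizedCurve, b: NormalizedCurve) -> float:
    """Shape distance between two normalized curves: the maximum absolute
    pointwise difference, dimensionless in [0, 1]."""
    return curve_distance(a, b)


def _primary_tms(
    wells: Sequence[str], peaks: Mapping[str, MeltPeaks]
) -> np.ndarray:
    tms = []
    for well in wells:
        peak = peaks.get(well)
        if peak is None or peak.primary_tm is None:
            raise ValueError(
                f"well {well!r} has no melt peak; exclude non-amplified wells "
                f"before clustering"
            )
        tms.append(peak.primary_tm)
    return np.asarray(tms)


def cluster_wells(
    curves: Mapping[str, NormalizedCurve] | Sequence[NormalizedCurve],
    peaks: Mapping[str, MeltPeaks],
    params: ClusterParams | None = None,
) -> ClusterResult:
    """Partition QC-passing wells into melt-profile clusters.

    Greedy agglomerative merging from singletons: repeatedly merge the pair
    of clusters with the smallest complete-linkage shape distance among
    pairs satisfying both the shape ceiling and the mean-primary-Tm
    threshold; stop when no pair qualifies. Deterministic and invariant to
    input order (wells are processed in sorted well-id order; ties break on
    (distance, smaller cluster id)). Final cluster ids are 1..k, primary
    clusters first, ordered by descending size then smallest member well id;
    clusters below ``min_cluster_size`` are flagged outliers.
    """
    params = params or ClusterParams()
    if not isinstance(curves, Mapping):
        curves = {c.well_id: c for c in curves}
    wells = sorted(curves)
    if not wells:
        raise ValueError("no wells to cluster")
    n = len(wells)
    tms = _primary_tms(wells, peaks)

    # pairwise shape distances, complete-linkage matrix maintained in place
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = curve_distance(curves[wells[i]], curves[wells[j]])

    theta = params.shape_threshold
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    link = dist.copy()  # complete linkage between live clusters
    mean_tm = tms.astype(float).copy()
    live = np.ones(n, dtype=bool)

    while True:
        ids = np.flatnonzero(live)
        if ids.size < 2:
            break
        sub = link[np.ix_(ids, ids)]
        tm_diff = np.abs(mean_tm[ids, None] - mean_tm[None, ids])
        iu = np.triu_indices(ids.size, k=1)
        qualifies = (sub[iu] <= theta) & (tm_diff[iu] <= params.tm_threshold)
        if not qualifies.any():
            break
        candidates = np.where(qualifies, sub[iu], np.inf)
        # argmin scans the upper triangle row-major, so exact-distance ties
        # resolve to the smallest (cluster id a, cluster id b) pair
        k = int(np.argmin(candidates))
        a, b = int(ids[iu[0][k]]), int(ids[iu[1][k]])
        na, nb = len(members[a]), len(members[b])
        members[a].extend(members[b])
        mean_tm[a] = (na * mean_tm[a] + nb * mean_tm[b]) / (na + nb)
        link[a, :] = np.maximum(link[a, :], link[b, :])
        link[:, a] = link[a, :]
        live[b] = False
        del members[b]

    # order clusters: primaries first, by descending size then first well id
    groups = sorted(
        members.values(),
        key=lambda g: (len(g) < params.min_cluster_size, -len(g), wells[min(g)]),
    )
    labels: dict[str, int] = {}
    outlier_flags: dict[str, bool] = {}
    summaries: dict[int, ClusterSummary] = {}
    for cluster_id, group in enumerate(groups, start=1):
        is_outlier = len(group) < params.min_cluster_size
        # medoid: member minimizing summed within-cluster shape distance
        sub = dist[np.ix_(group, group)]
        totals = sub.sum(axis=1)
        order = sorted(range(len(group)), key=lambda k: (totals[k], wells[group[k]]))
        medoid = wells[group[order[0]]]
        for idx in group:
            labels[wells[idx]] = cluster_id
            outlier_flags[wells[idx]] = is_outlier
        summaries[cluster_id] = ClusterSummary(
            cluster_id=cluster_id,
            size=len(group),
            mean_tm=float(np.mean(tms[group])),
            medoid_well_id=medoid,
            is_outlier=is_outlier,
        )
    return ClusterResult(
        labels=labels, outlier_flags=outlier_flags, summaries=summaries, params=params
    )


@dataclass(frozen=True)
class ClusterDiagnostics:
    """Signature summary of one cluster, used to tell sex clusters apart."""

    cluster_id: int
    size: int
    mean_n_peaks: float
    has_secondary_transition: bool  # medoid shows >= 2 derivative peaks
    primary_tm: float
    min_difference_value: float | None  # largest negative excursion
    min_difference_tm: float | None  # temperature of that excursion


def cluster_diagnostics(
    result: ClusterResult,
    difference_curves: Mapping[str, DifferenceCurve] | None,
    peaks: Mapping[str, MeltPeaks],
) -> dict[int, ClusterDiagnostics]:
    """Per-cluster melt-signature summaries.

    For each cluster: mean derivative-peak count, whether the medoid shows a
    secondary transition (≥ 2 peaks — the XIST + ACTB duplex signature), the
    cluster mean primary Tm, and the temperature/depth of the largest
    negative excursion of the cluster-mean difference curve (for a female
    cluster against a male reference this sits near the XIST Tm).
    """
    out: dict[int, ClusterDiagnostics] = {}
    for cluster_id, summary in result.summaries.items():
        wells = result.wells_in(cluster_id)
        n_peaks = [peaks[w].n_peaks for w in wells if w in peaks]
        medoid_peaks = peaks.get(summary.medoid_well_id)
        min_val = min_tm = None
        if difference_curves:
            traces = [difference_curves[w] for w in wells if w in difference_curves]
            if traces:
                mean_vals = np.mean([t.values for t in traces], axis=0)
                idx = int(np.argmin(mean_vals))
                min_val = float(mean_vals[idx])
                min_tm = float(traces[0].temperatures[idx])
        out[cluster_id] = ClusterDiagnostics(
            cluster_id=cluster_id,
            size=summary.size,
            mean_n_peaks=float(np.mean(n_peaks)) if n_peaks else 0.0,
            has_secondary_transition=bool(medoid_peaks and medoid_peaks.n_peaks >= 2),
            primary_tm=summary.mean_tm,
            min_difference_value=min_val,
            min_difference_tm=min_tm,
        )
    return out
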