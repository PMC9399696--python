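"""Well QC, cluster→sex mapping and per-sample majority-rule sex calls.

Wells that did not amplify any product (flat trace, absent/late Cq, or a
degenerate normalization baseline) are excluded, as are wells sorted into
outlying clusters (primer dimers, non-specific products). Primary clusters
are mapped to sexes using known-female anchor samples (e.g. individuals
seen with a calf); a signature fallback — the cluster whose medoid shows a
secondary melt transition is the female one — covers anchor-free runs.
A sample is called female or male only when at least two-thirds of its
evaluable wells sit in one sex-mapped cluster; samples failing the
majority are inconclusive, and samples with no evaluable wells are
insufficient. Low RNA yield attaches an advisory flag but never changes a
call — the remedy for a low-yield sample is to repeat the extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import hrm_core as hrm_core_defaults
from .hrm_core import DegenerateBaselineError, MeltPeaks, melt_amplitude
from .melt_cluster import ClusterResult
from .plate_io import MeltCurve

__all__ = [
    "WellQC",
    "SexMapping",
    "MAJORITY_FRACTION",
    "qc_wells",
    "map_clusters_to_sex",
    "call_sample_sex",
    "yield_gate",
]

#: a sample is assigned a sex only if ≥ 2/3 of its evaluable wells agree
MAJORITY_FRACTION = Fraction(2, 3)

#: minimum relative melt amplitude for a well to count as amplified
DEFAULT_AMPLITUDE_FLOOR = 0.1

QC_REASONS = ("none", "non_amplified", "degenerate_baseline", "outlier_cluster")


@dataclass(frozen=True)
class WellQC:
    """Pass/fail status of one well with its single primary failure reason."""

    well_id: str
    passed: bool
    reason: str = "none"

    def __post_init__(self) -> None:
        if self.reason not in QC_REASONS:
            raise ValueError(f"unknown QC reason {self.reason!r}")
        if self.passed != (self.reason == "none"):
            raise ValueError("a failed well needs exactly one failure reason")


def qc_wells(
    curves: Iterable[MeltCurve],
    cq: Mapping[str, float | None] | None = None,
    cluster_result: ClusterResult | None = None,
    pre_window: tuple[float, float] = hrm_core_defaults.DEFAULT_PRE_WINDOW,
    post_window: tuple[float, float] = hrm_core_defaults.DEFAULT_POST_WINDOW,
    amplitude_floor: float = DEFAULT_AMPLITUDE_FLOOR,
    max_cycles: int = 45,
) -> dict[str, WellQC]:
    """Flag wells that must be excluded from further analysis.

    A well fails as ``non_amplified`` when its amplification flag is false,
    its Cq is absent or ≥ ``max_cycles``, or its relative melt amplitude is
    below ``amplitude_floor``; as ``degenerate_baseline`` when the pre/post
    baselines cross inside the analysis window; and as ``outlier_cluster``
    when clustering (if already available) sorted it into an outlying
    cluster.
    """
    out: dict[str, WellQC] = {}
    for curve in curves:
        reason = "none"
        if curve.amplified is False:
            reason = "non_amplified"
        elif cq is not None and curve.well_id in cq:
            value = cq[curve.well_id]
            if value is None or (np.isfinite(value) and value >= max_cycles):
                reason = "non_amplified"
        if reason == "none":
            try:
                if melt_amplitude(curve, pre_window, post_window) < amplitude_floor:
                    reason = "non_amplified"
            except DegenerateBaselineError:
                reason = "degenerate_baseline"
        if (
            reason == "none"
            and cluster_result is not None
            and cluster_result.outlier_flags.get(curve.well_id, False)
        ):
            reason = "outlier_cluster"
        out[curve.well_id] = WellQC(curve.well_id, passed=reason == "none", reason=reason)
    return out


@dataclass(frozen=True)
class SexMapping:
    """Cluster → sex assignment with the evidence behind it."""

    mapping: dict[int, str]  # cluster id -> female | male | unassigned
    anchor_counts: dict[int, int]  # anchor wells per primary cluster
    signature_female: int | None  # cluster the signature rule would call female
    warnings: tuple[str, ...] = ()

    def sex_of(self, cluster_id: int) -> str:
        return self.mapping.get(cluster_id, "unassigned")


def _anchor_counts(
    result: ClusterResult, layout: pd.DataFrame, metadata: pd.DataFrame
) -> dict[int, int]:
    anchors = set(
        metadata.loc[metadata["known_female_anchor"].astype(bool), "sample_id"]
    )
    well_sample = dict(zip(layout["well"], layout["sample_id"]))
    counts: dict[int, int] = {c: 0 for c in result.primary_clusters}
    for well, cluster in result.labels.items():
        if cluster in counts and well_sample.get(well) in anchors:
            counts[cluster] += 1
    return counts


def map_clusters_to_sex(
    result: ClusterResult,
    layout: pd.DataFrame,
    metadata: pd.DataFrame,
    peaks: Mapping[str, MeltPeaks],
) -> SexMapping:
    """Assign each primary cluster a sex.

    Anchor rule first: the primary cluster holding the majority of
    known-female-anchor wells is female and the remaining primary clusters
    are male. Fallback signature rule: the cluster whose medoid shows ≥ 2
    derivative peaks (XIST + ACTB secondary transition) is female. When both
    rules apply and disagree, all clusters are left unassigned with a
    warning rather than guessing. Outlier clusters are never assigned.
    """
    primaries = result.primary_clusters
    notes: list[str] = []
    mapping: dict[int, str] = {c: "unassigned" for c in result.summaries}

    counts = _anchor_counts(result, layout, metadata)
    total_anchor_wells = sum(counts.values())

    # signature rule: medoid with a secondary transition marks the female cluster
    sig_female: int | None = None
    with_secondary = [
        c
        for c in primaries
        if (p := peaks.get(result.summaries[c].medoid_well_id)) and p.n_peaks >= 2
    ]
    if len(with_secondary) == 1:
        sig_female = with_secondary[0]

    anchor_female: int | None = None
    if total_anchor_wells > 0:
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            notes.append(
                "anchor wells split evenly between clusters "
                f"{ranked[0][0]} and {ranked[1][0]}; sex mapping aborted"
            )
        else:
            anchor_female = ranked[0][0]

    female: int | None = None
    if anchor_female is not None:
        if sig_female is not None and sig_female != anchor_female:
            notes.append(
                f"anchor rule (cluster {anchor_female}) conflicts with melt "
                f"signature rule (cluster {sig_female}); sex mapping aborted"
            )
        else:
            female = anchor_female
    elif total_anchor_wells == 0 and sig_female is not None:
        female = sig_female

    if female is not None:
        for c in primaries:
            mapping[c] = "female" if c == female else "male"
    elif not notes:
        notes.append(
            "no anchor samples and no unambiguous melt-signature separation; "
            "clusters left unassigned (calls will be inconclusive)"
        )
    for note in notes:
        warnings.warn(note, stacklevel=2)
    return SexMapping(
        mapping=mapping,
        anchor_counts=counts,
        signature_female=sig_female,
        warnings=tuple(notes),
    )


def yield_gate(metadata: pd.DataFrame, cutoff: float = 9.0) -> pd.DataFrame:
    """Advisory low-yield flags: samples with RNA yield strictly below
    ``cutoff`` ng µl⁻¹ should have their extraction repeated.

    Flags annotate calls but never change them.
    """
    if cutoff <= 0:
        raise ValueError("yield cutoff must be > 0")
    flagged = metadata["rna_yield"].notna() & (metadata["rna_yield"] < cutoff)
    return pd.DataFrame(
        {
            "sample_id": metadata["sample_id"],
            "low_yield": flagged.to_numpy(),
            "advisory": np.where(flagged, "repeat extraction", ""),
        }
    )


def call_sample_sex(
    layout: pd.DataFrame,
    qc: Mapping[str, WellQC],
    result: ClusterResult,
    sex_mapping: SexMapping,
    metadata: pd.DataFrame | None = None,
    yield_cutoff: float = 9.0,
) -> pd.DataFrame:
    """Per-sample sex calls under the ≥ 2/3 majority rule.

    The denominator is the sample's QC-passing wells in primary clusters
    (outlier and non-amplified wells are excluded from both numerator and
    denominator). The modal cluster is the one holding most of those wells;
    the sample receives that cluster's sex when the modal fraction is at
    least two-thirds, ``inconclusive`` otherwise, and ``insufficient`` when
    no well survives QC.
    """
    low_yield: dict[str, bool] = {}
    if metadata is not None:
        gate = yield_gate(metadata, yield_cutoff)
        low_yield = dict(zip(gate["sample_id"], gate["low_yield"]))

    primary = set(result.primary_clusters)
    rows = []
    for sample_id, group in layout.groupby("sample_id", sort=True):
        wells = list(group["well"])
        evaluable = [
            w
            for w in wells
            if qc.get(w) is not None
            and qc[w].passed
            and result.labels.get(w) in primary
        ]
        n_pass = len(evaluable)
        flags = ["low_yield"] if low_yield.get(sample_id, False) else []
        if n_pass == 0:
            rows.append(
                {
                    "sample_id": sample_id,
                    "call": "insufficient",
                    "n_wells_pass": 0,
                    "n_modal": 0,
                    "fraction_modal": 0.0,
                    "cluster_label": "",
                    "flags": ";".join(flags),
                }
            )
            continue
        counts: dict[int, int] = {}
        for w in evaluable:
            counts[result.labels[w]] = counts.get(result.labels[w], 0) + 1
        modal_cluster, n_modal = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        tie = sum(1 for v in counts.values() if v == n_modal) > 1
        fraction = Fraction(n_modal, n_pass)
        sex = sex_mapping.sex_of(modal_cluster)
        if tie or fraction < MAJORITY_FRACTION or sex == "unassigned":
            call = "inconclusive"
        else:
            call = sex
        rows.append(
            {
                "sample_id": sample_id,
                "call": call,
                "n_wells_pass": n_pass,
                "n_modal": n_modal,
                "fraction_modal": float(fraction),
                "cluster_label": str(modal_cluster),
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)
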