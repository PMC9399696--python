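"""End-to-end plate analysis: QC → normalize → peaks → cluster → call.

Thin orchestration over the module functions, in the order the HRM
workflow prescribes:

1. first-pass well QC (amplification flag, optional Cq, baseline sanity);
2. normalization of passing wells onto the analysis window;
3. −dF/dT peak calling with a run-wide prominence floor (10% of the
   global derivative maximum);
4. shape/Tm clustering; wells in outlying clusters fail QC;
5. medoid reference selection and difference curves;
6. cluster→sex mapping (anchors, then melt-signature fallback) and
   majority-rule sample calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import hrm_core, melt_cluster, sex_caller
from .hrm_core import DifferenceCurve, MeltPeaks, NormalizedCurve
from .melt_cluster import ClusterParams, ClusterResult
from .plate_io import MeltCurve
from .sex_caller import SexMapping, WellQC

__all__ = ["RunResult", "analyze_plate"]

DEFAULT_PROMINENCE_FRACTION = 0.10


@dataclass
class RunResult:
    """All intermediate and final artifacts of one plate analysis."""

    qc: dict[str, WellQC]
    normalized: dict[str, NormalizedCurve]
    peaks: dict[str, MeltPeaks]
    cluster_result: ClusterResult
    sex_mapping: SexMapping
    reference_well_id: str
    difference_curves: dict[str, DifferenceCurve]
    diagnostics: dict[int, melt_cluster.ClusterDiagnostics]
    calls: pd.DataFrame
    params: dict

    def clusters_frame(self, layout: pd.DataFrame) -> pd.DataFrame:
        """Per-well cluster table (``well,sample_id,cluster,outlier,primary_tm``)."""
        well_sample = dict(zip(layout["well"], layout["sample_id"]))
        rows = []
        for well in sorted(self.cluster_result.labels):
            peak = self.peaks.get(well)
            rows.append(
                {
                    "well": well,
                    "sample_id": well_sample.get(well, ""),
                    "cluster": self.cluster_result.labels[well],
                    "outlier": self.cluster_result.outlier_flags[well],
                    "primary_tm": (
                        round(peak.primary_tm, 3)
                        if peak and peak.primary_tm is not None
                        else None
                    ),
                }
            )
        return pd.DataFrame(rows)


def analyze_plate(
    curves: list[MeltCurve],
    layout: pd.DataFrame,
    metadata: pd.DataFrame,
    *,
    cluster_params: ClusterParams | None = None,
    pre_window: tuple[float, float] = hrm_core.DEFAULT_PRE_WINDOW,
    post_window: tuple[float, float] = hrm_core.DEFAULT_POST_WINDOW,
    amplitude_floor: float = sex_caller.DEFAULT_AMPLITUDE_FLOOR,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
    min_separation: float = 1.0,
    yield_cutoff: float = 9.0,
    cq: Mapping[str, float | None] | None = None,
) -> RunResult:
    """Run the full melt-curve sex-determination analysis on one run's wells."""
    cluster_params = cluster_params or ClusterParams()

    qc = sex_caller.qc_wells(
        curves,
        cq=cq,
        pre_window=pre_window,
        post_window=post_window,
        amplitude_floor=amplitude_floor,
    )
    by_id = {c.well_id: c for c in curves}
    passing = [w for w in sorted(by_id) if qc[w].passed]

    normalized: dict[str, NormalizedCurve] = {}
    derivatives: dict[str, np.ndarray] = {}
    for well in passing:
        normalized[well] = hrm_core.normalize_curve(by_id[well], pre_window, post_window)
        derivatives[well] = hrm_core.negative_derivative(by_id[well])

    if not passing:
        raise ValueError("no wells passed QC; nothing to analyze")

    global_max = max(float(np.max(d)) for d in derivatives.values())
    floor = prominence_fraction * global_max
    peaks: dict[str, MeltPeaks] = {}
    for well in list(passing):
        p = hrm_core.estimate_tms(
            by_id[well].temperatures,
            derivatives[well],
            min_prominence=floor,
            min_separation=min_separation,
            well_id=well,
        )
        if p.n_peaks == 0:  # no transition above the run-wide floor
            qc[well] = WellQC(well, passed=False, reason="non_amplified")
            passing.remove(well)
            normalized.pop(well)
        else:
            peaks[well] = p

    result = melt_cluster.cluster_wells(
        {w: normalized[w] for w in passing}, peaks, cluster_params
    )
    # wells in outlying clusters are excluded from further analysis
    for well in passing:
        if result.outlier_flags.get(well, False):
            qc[well] = WellQC(well, passed=False, reason="outlier_cluster")

    primary_wells = [w for w in passing if not result.outlier_flags.get(w, False)]
    reference_pool = primary_wells or passing
    reference = hrm_core.select_reference([normalized[w] for w in reference_pool])
    difference = {
        w: hrm_core.difference_curve(normalized[w], normalized[reference])
        for w in passing
    }
    diagnostics = melt_cluster.cluster_diagnostics(result, difference, peaks)
    mapping = sex_caller.map_clusters_to_sex(result, layout, metadata, peaks)
    calls = sex_caller.call_sample_sex(
        layout, qc, result, mapping, metadata=metadata, yield_cutoff=yield_cutoff
    )
    params = {
        "shape_sensitivity": cluster_params.shape_sensitivity,
        "tm_threshold": cluster_params.tm_threshold,
        "min_cluster_size": cluster_params.min_cluster_size,
        "theta_max": cluster_params.theta_max,
        "pre_window": list(pre_window),
        "post_window": list(post_window),
        "amplitude_floor": amplitude_floor,
        "prominence_fraction": prominence_fraction,
        "min_separation": min_separation,
        "yield_cutoff": yield_cutoff,
    }
    return RunResult(
        qc=qc,
        normalized=normalized,
        peaks=peaks,
        cluster_result=result,
        sex_mapping=mapping,
        reference_well_id=reference,
        difference_curves=difference,
        diagnostics=diagnostics,
        calls=calls,
        params=params,
    )
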