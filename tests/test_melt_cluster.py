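"""Shape/Tm clustering: partitions, outliers, determinism, oracle parity."""

import numpy as np
import pytest

from xistmelt import hrm_core, meltsim
from xistmelt.hrm_core import normalize_curve
from xistmelt.melt_cluster import (
    ClusterParams,
    cluster_diagnostics,
    cluster_wells,
    shape_distance,
)
from xistmelt.meltsim import ProductSpec


def _partition(result):
    groups = {}
    for well, cid in result.labels.items():
        groups.setdefault(cid, set()).add(well)
    return {frozenset(g) for g in groups.values()}


def _normalized_and_peaks(curves, fraction=0.10):
    derivs = {c.well_id: hrm_core.negative_derivative(c) for c in curves}
    floor = fraction * max(float(d.max()) for d in derivs.values())
    normalized, peaks = {}, {}
    for c in curves:
        normalized[c.well_id] = normalize_curve(c)
        peaks[c.well_id] = hrm_core.estimate_tms(
            c.temperatures, derivs[c.well_id], floor, 1.0, c.well_id
        )
    return normalized, peaks


@pytest.fixture(scope="module")
def mixed_plate(make_well, actb_product, xist_product):
    """4 female + 4 male noisy wells with default products."""
    curves = []
    for i in range(4):
        curves.append(make_well([actb_product, xist_product],
                                well_id=f"F{i}", seed=100 + i))
    for i in range(4):
        curves.append(make_well([actb_product], well_id=f"M{i}", seed=200 + i))
    return curves


class TestClusterParams:
    def test_sensitivity_maps_linearly_to_shape_threshold(self):
        assert ClusterParams(shape_sensitivity=1).shape_threshold == pytest.approx(0.10)
        assert ClusterParams(shape_sensitivity=100).shape_threshold == pytest.approx(0.0)
        assert ClusterParams(shape_sensitivity=50.5).shape_threshold == pytest.approx(0.05)

    def test_validation(self):
        with pytest.raises(ValueError):
            ClusterParams(shape_sensitivity=0)
        with pytest.raises(ValueError):
            ClusterParams(tm_threshold=0.0)
        with pytest.raises(ValueError):
            ClusterParams(tm_threshold=3.0)


class TestShapeDistance:
    def test_identical_curves_distance_zero(self, female_curve):
        n = normalize_curve(female_curve)
        assert shape_distance(n, n) == 0.0

    def test_mirrored_curve_reaches_closed_form_maximum(self, male_curve):
        n = normalize_curve(male_curve)
        mirrored = hrm_core.NormalizedCurve(
            "Mirror", n.temperatures, 1.0 - n.values, n.pre_window, n.post_window
        )
        expected = float(np.max(np.abs(1.0 - 2.0 * n.values)))
        assert shape_distance(n, mirrored) == pytest.approx(expected)

    def test_female_vs_male_exceeds_merge_ceiling(self, female_curve, male_curve):
        d = shape_distance(normalize_curve(female_curve), normalize_curve(male_curve))
        assert d > 0.10


class TestClusterWells:
    def test_identical_plate_collapses_to_one_cluster(self, male_curve):
        n = normalize_curve(male_curve)
        curves = {
            w: hrm_core.NormalizedCurve(w, n.temperatures, n.values,
                                        n.pre_window, n.post_window)
            for w in ("A1", "A2", "A3", "A4")
        }
        peaks = {
            w: hrm_core.MeltPeaks(w, ((85.5, 900.0),)) for w in curves
        }
        result = cluster_wells(curves, peaks, ClusterParams())
        assert len(result.summaries) == 1
        assert not any(result.outlier_flags.values())

    def test_mixed_plate_partitions_by_sex(self, mixed_plate):
        normalized, peaks = _normalized_and_peaks(mixed_plate)
        result = cluster_wells(normalized, peaks, ClusterParams())
        assert len(result.primary_clusters) == 2
        partition = _partition(result)
        assert frozenset({"F0", "F1", "F2", "F3"}) in partition
        assert frozenset({"M0", "M1", "M2", "M3"}) in partition

    def test_primer_dimer_wells_form_flagged_outlier_cluster(
        self, mixed_plate, make_well, config
    ):
        dimers = [
            make_well(
                [
                    ProductSpec("primer_dimer", config.dimer_tm, config.dimer_width,
                                config.dimer_abundance),
                    ProductSpec("ACTB_weak", config.actb_tm, config.product_width,
                                config.dimer_actb_abundance),
                ],
                well_id=f"D{i}",
                seed=300 + i,
            )
            for i in range(2)
        ]
        normalized, peaks = _normalized_and_peaks(mixed_plate + dimers)
        result = cluster_wells(normalized, peaks, ClusterParams())
        assert len(result.primary_clusters) == 2
        outliers = {w for w, flag in result.outlier_flags.items() if flag}
        assert outliers == {"D0", "D1"}
        outlier_ids = {result.labels[w] for w in outliers}
        assert len(outlier_ids) == 1
        assert result.summaries[outlier_ids.pop()].size == 2

    def test_deterministic_and_permutation_invariant(self, mixed_plate):
        normalized, peaks = _normalized_and_peaks(mixed_plate)
        base = cluster_wells(normalized, peaks, ClusterParams())
        again = cluster_wells(normalized, peaks, ClusterParams())
        assert base.labels == again.labels
        reversed_order = dict(reversed(list(normalized.items())))
        shuffled = cluster_wells(reversed_order, peaks, ClusterParams())
        assert _partition(base) == _partition(shuffled)

    def test_increasing_sensitivity_only_refines_partitions(self, mixed_plate):
        normalized, peaks = _normalized_and_peaks(mixed_plate)
        previous = None
        for s in (1, 25, 50, 75, 100):
            part = _partition(
                cluster_wells(normalized, peaks, ClusterParams(shape_sensitivity=s))
            )
            if previous is not None:
                assert all(
                    any(group <= coarse for coarse in previous) for group in part
                )
            previous = part

    def test_greedy_matches_naive_reexecution_oracle(self, mixed_plate):
        """Independent naive re-run of the merge predicate (fresh pairwise
        complete-linkage scan each step) reproduces the partition."""
        normalized, peaks = _normalized_and_peaks(mixed_plate)
        params = ClusterParams()
        result = cluster_wells(normalized, peaks, params)
        assert _partition(result) == _naive_partition(normalized, peaks, params)

    def test_well_without_peaks_rejected(self, mixed_plate):
        normalized, peaks = _normalized_and_peaks(mixed_plate)
        peaks["F0"] = hrm_core.MeltPeaks("F0", ())
        with pytest.raises(ValueError, match="no melt peak"):
            cluster_wells(normalized, peaks, ClusterParams())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_wells({}, {}, ClusterParams())


def _naive_partition(normalized, peaks, params):
    clusters = [[w] for w in sorted(normalized)]
    theta = params.shape_threshold
    while True:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(
                    shape_distance(normalized[a], normalized[b])
                    for a in clusters[i]
                    for b in clusters[j]
                )
                tm_i = np.mean([peaks[w].primary_tm for w in clusters[i]])
                tm_j = np.mean([peaks[w].primary_tm for w in clusters[j]])
                if d <= theta and abs(tm_i - tm_j) <= params.tm_threshold:
                    key = (d, min(clusters[i]), min(clusters[j]))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return {frozenset(c) for c in clusters}


class TestClusterDiagnostics:
    def test_sex_and_dimer_signatures(self, mixed_plate, make_well, config):
        dimers = [
            make_well(
                [
                    ProductSpec("primer_dimer", config.dimer_tm, config.dimer_width,
                                config.dimer_abundance),
                    ProductSpec("ACTB_weak", config.actb_tm, config.product_width,
                                config.dimer_actb_abundance),
                ],
                well_id=f"D{i}",
                seed=300 + i,
            )
            for i in range(2)
        ]
        all_curves = mixed_plate + dimers
        normalized, peaks = _normalized_and_peaks(all_curves)
        result = cluster_wells(normalized, peaks, ClusterParams())
        reference = normalized[hrm_core.select_reference(
            [normalized[w] for w, f in result.outlier_flags.items() if not f]
        )]
        diffs = {
            w: hrm_core.difference_curve(normalized[w], reference) for w in normalized
        }
        diag = cluster_diagnostics(result, diffs, peaks)

        by_label = {result.labels[w]: w for w in ("F0", "M0", "D0")}
        female = diag[result.labels["F0"]]
        male = diag[result.labels["M0"]]
        dimer = diag[result.labels["D0"]]

        assert female.has_secondary_transition
        assert abs(female.min_difference_tm - config.xist_tm) <= 1.0
        assert female.min_difference_value < -0.15

        assert not male.has_secondary_transition
        assert male.mean_n_peaks == pytest.approx(1.0)
        assert abs(male.min_difference_value) < 0.05

        assert dimer.primary_tm < min(female.primary_tm, male.primary_tm) - 2.0
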