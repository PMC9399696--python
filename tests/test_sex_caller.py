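"""Well QC, anchor/signature sex mapping and the ≥2/3 majority rule."""

import numpy as np
import pandas as pd
import pytest

from xistmelt import hrm_core, meltsim, pipeline, validation
from xistmelt.melt_cluster import ClusterParams, ClusterResult, ClusterSummary
from xistmelt.meltsim import SimConfig
from xistmelt.sex_caller import (
    SexMapping,
    WellQC,
    call_sample_sex,
    map_clusters_to_sex,
    qc_wells,
    yield_gate,
)

from .conftest import build_plate, sample


class TestQcWells:
    def test_flat_and_flagged_wells_fail(self, grid, make_well, actb_product):
        from xistmelt.plate_io import MeltCurve

        rng = np.random.default_rng(1)
        flat = MeltCurve("Flat", grid, 110.0 - 0.3 * grid + rng.normal(0, 0.2, grid.size))
        unamplified = make_well([actb_product], well_id="Off", amplified=False)
        good = make_well([actb_product], well_id="Good", seed=4)
        qc = qc_wells([flat, unamplified, good])
        assert not qc["Flat"].passed and qc["Flat"].reason in (
            "non_amplified", "degenerate_baseline"
        )
        assert not qc["Off"].passed and qc["Off"].reason == "non_amplified"
        assert qc["Good"].passed

    def test_late_cq_fails(self, make_well, actb_product):
        good = make_well([actb_product], well_id="W1", seed=4)
        qc = qc_wells([good], cq={"W1": 46.0}, max_cycles=45)
        assert qc["W1"].reason == "non_amplified"
        qc = qc_wells([good], cq={"W1": None})
        assert not qc["W1"].passed

    def test_wellqc_reason_consistency_enforced(self):
        with pytest.raises(ValueError):
            WellQC("W", passed=True, reason="non_amplified")
        with pytest.raises(ValueError):
            WellQC("W", passed=False, reason="nonsense")


def _two_cluster_result(wells_by_cluster, tms=(85.5, 85.5), outliers=()):
    labels, flags, summaries = {}, {}, {}
    for cid, wells in wells_by_cluster.items():
        if not wells:
            continue
        is_outlier = cid in outliers
        for w in wells:
            labels[w] = cid
            flags[w] = is_outlier
        summaries[cid] = ClusterSummary(
            cluster_id=cid,
            size=len(wells),
            mean_tm=tms[cid - 1] if cid - 1 < len(tms) else 85.5,
            medoid_well_id=sorted(wells)[0],
            is_outlier=is_outlier,
        )
    return ClusterResult(labels, flags, summaries, ClusterParams())


def _peaks(well_peaks):
    return {
        w: hrm_core.MeltPeaks(w, tuple((tm, 100.0) for tm in tms))
        for w, tms in well_peaks.items()
    }


def _frame(rows, cols):
    return pd.DataFrame(rows, columns=cols)


META_COLS = ["sample_id", "rna_yield", "dna_sex", "known_female_anchor", "cohort"]


class TestMapClustersToSex:
    def _layout(self):
        return _frame(
            [("a1", "A", 1), ("a2", "A", 2), ("b1", "B", 1), ("b2", "B", 2)],
            ["well", "sample_id", "replicate"],
        )

    def test_anchor_cluster_is_female_other_male(self):
        result = _two_cluster_result({1: ["a1", "a2"], 2: ["b1", "b2"]})
        metadata = _frame(
            [("A", 50.0, "female", True, "c"), ("B", 50.0, "male", False, "c")],
            META_COLS,
        )
        peaks = _peaks({"a1": [84.0, 85.5], "a2": [84.0, 85.5], "b1": [85.5], "b2": [85.5]})
        mapping = map_clusters_to_sex(result, self._layout(), metadata, peaks)
        assert mapping.mapping == {1: "female", 2: "male"}
        assert mapping.anchor_counts == {1: 2, 2: 0}

    def test_signature_fallback_without_anchors(self):
        result = _two_cluster_result({1: ["a1", "a2"], 2: ["b1", "b2"]})
        metadata = _frame(
            [("A", 50.0, "unknown", False, "c"), ("B", 50.0, "unknown", False, "c")],
            META_COLS,
        )
        peaks = _peaks({"a1": [85.5], "a2": [85.5], "b1": [84.0, 85.5], "b2": [84.0, 85.5]})
        mapping = map_clusters_to_sex(result, self._layout(), metadata, peaks)
        assert mapping.mapping == {1: "male", 2: "female"}
        assert mapping.signature_female == 2

    def test_split_anchors_abort_mapping(self):
        result = _two_cluster_result({1: ["a1", "b1"], 2: ["a2", "b2"]})
        metadata = _frame(
            [("A", 50.0, "female", True, "c"), ("B", 50.0, "female", True, "c")],
            META_COLS,
        )
        peaks = _peaks({w: [85.5] for w in ("a1", "a2", "b1", "b2")})
        with pytest.warns(UserWarning, match="split evenly"):
            mapping = map_clusters_to_sex(result, self._layout(), metadata, peaks)
        assert set(mapping.mapping.values()) == {"unassigned"}

    def test_anchor_signature_conflict_aborts(self):
        result = _two_cluster_result({1: ["a1", "a2"], 2: ["b1", "b2"]})
        metadata = _frame(
            [("A", 50.0, "female", True, "c"), ("B", 50.0, "male", False, "c")],
            META_COLS,
        )
        # anchors say cluster 1, duplex signature says cluster 2
        peaks = _peaks({"a1": [85.5], "a2": [85.5], "b1": [84.0, 85.5], "b2": [84.0, 85.5]})
        with pytest.warns(UserWarning, match="conflicts"):
            mapping = map_clusters_to_sex(result, self._layout(), metadata, peaks)
        assert set(mapping.mapping.values()) == {"unassigned"}


class TestCallSampleSex:
    def _inputs(self, cluster_of):
        wells = sorted(cluster_of)
        layout = _frame(
            [(w, "S1", i + 1) for i, w in enumerate(wells)],
            ["well", "sample_id", "replicate"],
        )
        result = _two_cluster_result(
            {
                1: [w for w in wells if cluster_of[w] == 1],
                2: [w for w in wells if cluster_of[w] == 2],
            }
        )
        qc = {w: WellQC(w, passed=True) for w in wells}
        mapping = SexMapping({cid: ("female", "male")[cid - 1] for cid in result.summaries},
                             {cid: 0 for cid in result.summaries}, None)
        return layout, qc, result, mapping

    @pytest.mark.parametrize(
        "cluster_of, call, fraction",
        [
            ({"w1": 1, "w2": 1, "w3": 1}, "female", 1.0),
            ({"w1": 1, "w2": 1, "w3": 2}, "female", 2 / 3),
            ({"w1": 1, "w2": 2}, "inconclusive", 1 / 2),
        ],
    )
    def test_majority_rule(self, cluster_of, call, fraction):
        layout, qc, result, mapping = self._inputs(cluster_of)
        calls = call_sample_sex(layout, qc, result, mapping)
        row = calls.iloc[0]
        assert row["call"] == call
        assert row["fraction_modal"] == pytest.approx(fraction)

    def test_no_passing_wells_is_insufficient(self):
        layout, qc, result, mapping = self._inputs({"w1": 1, "w2": 1, "w3": 1})
        qc = {w: WellQC(w, passed=False, reason="non_amplified") for w in qc}
        calls = call_sample_sex(layout, qc, result, mapping)
        assert calls.iloc[0]["call"] == "insufficient"
        assert calls.iloc[0]["n_wells_pass"] == 0

    def test_unassigned_cluster_gives_inconclusive(self):
        layout, qc, result, _ = self._inputs({"w1": 1, "w2": 1, "w3": 1})
        mapping = SexMapping({1: "unassigned"}, {}, None)
        calls = call_sample_sex(layout, qc, result, mapping)
        assert calls.iloc[0]["call"] == "inconclusive"

    def test_calls_invariant_to_well_order(self):
        layout, qc, result, mapping = self._inputs({"w1": 1, "w2": 1, "w3": 2})
        reordered = layout.iloc[::-1].reset_index(drop=True)
        a = call_sample_sex(layout, qc, result, mapping)
        b = call_sample_sex(reordered, qc, result, mapping)
        pd.testing.assert_frame_equal(a, b)


class TestYieldGate:
    @pytest.mark.parametrize(
        "rna_yield, flagged",
        [(3.1, True), (8.99, True), (9.0, False), (71.4, False)],
    )
    def test_strict_cutoff(self, rna_yield, flagged):
        metadata = _frame([("A", rna_yield, "female", False, "c")], META_COLS)
        gate = yield_gate(metadata, cutoff=9.0)
        assert bool(gate.iloc[0]["low_yield"]) is flagged
        assert (gate.iloc[0]["advisory"] == "repeat extraction") is flagged

    def test_rejects_non_positive_cutoff(self):
        metadata = _frame([("A", 5.0, "female", False, "c")], META_COLS)
        with pytest.raises(ValueError):
            yield_gate(metadata, cutoff=0.0)


class TestFailureModesEndToEnd:
    def test_total_xist_dropout_female_called_male(self):
        """A low-yield female whose every well lost XIST is indistinguishable
        from a male and is miscalled — the documented failure mode."""
        forced = SimConfig(dropout_prob=1.0, dimer_prob=0.0, nonamp_prob=0.0)
        samples = [
            sample("F1", "female", rna_yield=60.0, anchor=True),
            sample("F2", "female", rna_yield=60.0),
            sample("M1", "male", rna_yield=60.0),
            sample("M2", "male", rna_yield=60.0),
            sample("FX", "female", rna_yield=4.0),  # below dropout threshold
        ]
        curves, layout, metadata = build_plate(samples, forced, seed=17)
        result = pipeline.analyze_plate(curves, layout, metadata)
        calls = result.calls.set_index("sample_id")
        assert calls.loc["FX", "call"] == "male"
        assert "low_yield" in calls.loc["FX", "flags"]
        assert calls.loc["F1", "call"] == "female"
        assert calls.loc["M1", "call"] == "male"
        report = validation.concordance(result.calls, metadata)
        reasons = {d["sample_id"]: d["reason"] for d in report.discordant}
        assert reasons == {"FX": "xist_dropout_suspected"}

    def test_xxy_individual_called_female_against_male_dna(self):
        samples = [
            sample("F1", "female", anchor=True),
            sample("F2", "female"),
            sample("M1", "male"),
            sample("M2", "male"),
            sample("K1", "male", karyotype="XXY"),
        ]
        curves, layout, metadata = build_plate(samples, SimConfig(), seed=23)
        result = pipeline.analyze_plate(curves, layout, metadata)
        calls = result.calls.set_index("sample_id")
        assert calls.loc["K1", "call"] == "female"
        report = validation.concordance(result.calls, metadata)
        reasons = {d["sample_id"]: d["reason"] for d in report.discordant}
        assert reasons == {"K1": "xxy_candidate"}
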