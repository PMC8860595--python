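"""Sensitivity statistic, target classification and stratified summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from threeprime import (
    Contrast,
    TargetClass,
    ValidationError,
    classify_targets,
    composition,
    intron_length_class,
    sa_overlap_fraction,
    sensitivity,
    sensitivity_matrix,
    union_pa_modes,
)
from threeprime.clusters import Cluster
from threeprime.genomic import GenomicInterval
from tests.conftest import truth_overlapping_calls


class TestSensitivity:
    @pytest.mark.parametrize(
        "treated,ctrl,expected",
        [
            (37, 0, 1.0),  # signal exclusive to the depletion sample
            (250, 0, 1.0),
            (58, 58, 0.0),  # equal signal
            (0.3, 0.3, 0.0),
            (0, 12, -1.0),  # signal exclusive to the reference
            (3, 1, 2 / 3),
            (0.4, 0, 0.4),  # unit floor binds below 1
        ],
    )
    def test_reference_values(self, treated, ctrl, expected):
        assert sensitivity(treated, ctrl) == pytest.approx(expected, abs=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            sensitivity(-1, 0)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_bounded(self, a, b):
        assert abs(sensitivity(a, b)) <= 1.0

    def test_antisymmetric_above_unit_floor(self):
        rng = np.random.default_rng(0)
        for a, b in rng.uniform(1, 1e3, size=(200, 2)):
            assert sensitivity(a, b) == pytest.approx(-sensitivity(b, a))

    def test_scale_invariant_above_unit_floor(self):
        for a in np.geomspace(1, 1e3, 7):
            for b in np.geomspace(1, 1e3, 7):
                for c in np.geomspace(1, 1e2, 5):
                    assert sensitivity(c * a, c * b) == pytest.approx(
                        sensitivity(a, b), abs=1e-12
                    )


class TestSensitivityMatrix:
    def test_identical_groups_give_zero(self):
        norm = pd.DataFrame({"a": [5.0, 0.0], "b": [5.0, 0.0]}, index=["c1", "c2"])
        out = sensitivity_matrix(norm, [Contrast("x", ["a"], ["b"])])
        assert (out["x"] == 0).all()

    def test_replicates_averaged_before_ratio(self):
        norm = pd.DataFrame(
            {"t1": [8.0], "t2": [0.0], "r1": [2.0], "r2": [2.0]}, index=["c"]
        )
        out = sensitivity_matrix(norm, [Contrast("x", ["t1", "t2"], ["r1", "r2"])])
        assert out.loc["c", "x"] == pytest.approx((4 - 2) / 4)

    def test_empty_group_rejected(self):
        norm = pd.DataFrame({"a": [1.0]})
        with pytest.raises(ValidationError):
            sensitivity_matrix(norm, [Contrast("x", [], ["a"])])

    def test_bounded_on_random_input(self):
        rng = np.random.default_rng(1)
        norm = pd.DataFrame(rng.uniform(0, 1e4, size=(100, 4)), columns=list("abcd"))
        out = sensitivity_matrix(norm, [Contrast("x", ["a", "b"], ["c", "d"])])
        assert (out["x"].abs() <= 1).all()

    def test_planted_four_fold_effect(self, sim_bundle):
        # a NEXT cluster up 4x under ZCCHC8 6 h: sensitivity -> (4-1)/4
        truth, norm = sim_bundle["truth"], sim_bundle["norm"]
        clusters = sim_bundle["clusters"]
        metas = sim_bundle["metas"]
        trts = [m.library_id for m in metas
                if m.target == "ZCCHC8" and m.method == "AID"
                and m.timepoint_h == 6 and m.pA_mode == "pA+/-"]
        refs = [m.library_id for m in metas
                if m.target == "ZCCHC8" and m.method == "AID"
                and m.timepoint_h == 0 and m.pA_mode == "pA+/-"]
        sens = sensitivity_matrix(norm, [Contrast("z8", trts, refs)])
        vals = []
        for t in truth[(truth.pathway == "NEXT") & (truth.base_mean > 100)].itertuples():
            for cid in truth_overlapping_calls(t, clusters):
                if cid in sens.index:
                    vals.append(sens.loc[cid, "z8"])
        assert np.mean(vals) == pytest.approx(0.75, abs=0.1)


class TestClassifyTargets:
    def test_disjoint_candidates_pass_through(self):
        nxt, paxt = classify_targets({"a"}, {"a"}, {"b"}, {"b"})
        assert nxt.members == {"a"} and paxt.members == {"b"}

    def test_shared_cluster_excluded_from_both(self):
        nxt, paxt = classify_targets({"a", "x"}, {"a", "x"}, {"b", "x"}, {"b", "x"})
        assert "x" not in nxt.members and "x" not in paxt.members

    def test_rnai_mode_ignores_aid_sets(self):
        nxt, paxt = classify_targets({"a"}, set(), {"b"}, set(), mode="RNAi")
        assert nxt.members == {"a"} and paxt.members == {"b"}

    def test_rnai_aid_class_subset_of_rnai_class(self):
        rn_z8, aid_z8 = {"a", "b", "c"}, {"b", "c", "d"}
        rn_z1, aid_z1 = {"c", "e"}, {"c", "e", "f"}
        strict_n, strict_p = classify_targets(rn_z8, aid_z8, rn_z1, aid_z1)
        loose_n, loose_p = classify_targets(rn_z8, aid_z8, rn_z1, aid_z1, mode="RNAi")
        assert strict_n.members <= loose_n.members | {"c"}
        assert strict_n.members <= rn_z8 and strict_p.members <= rn_z1

    @settings(max_examples=100, deadline=None)
    @given(
        st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)),
        st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)),
        st.sampled_from(["RNAi", "RNAi+AID"]),
    )
    def test_classes_always_disjoint(self, a, b, c, d, mode):
        nxt, paxt = classify_targets(a, b, c, d, mode=mode)
        assert nxt.members.isdisjoint(paxt.members)

    def test_union_pa_modes(self):
        assert union_pa_modes({"pA+": {"a"}, "pA+/-": {"b"}}) == {"a", "b"}


class TestComposition:
    def test_percentages(self):
        annot = pd.DataFrame(
            {"biotype": ["PROMPT", "PROMPT", "eRNA"], "feature": [None] * 3},
            index=["a", "b", "c"],
        )
        cls = TargetClass("NEXT", "RNAi", {"a", "b", "c", "d"})
        comp = composition(cls, annot)
        assert comp["PROMPT"] == 50 and comp["eRNA"] == 25
        assert comp["not_annotated"] == 25
        assert comp.sum() == pytest.approx(100)

    def test_single_member(self):
        annot = pd.DataFrame({"biotype": ["lncRNA"], "feature": [None]}, index=["a"])
        comp = composition(TargetClass("PAXT", "RNAi", {"a"}), annot)
        assert comp.to_dict() == {"lncRNA": 100.0}

    def test_empty_class_warns(self):
        annot = pd.DataFrame({"biotype": [], "feature": []})
        with pytest.warns(UserWarning):
            comp = composition(TargetClass("NEXT", "RNAi", set()), annot)
        assert comp.empty


class TestIntronLengthClass:
    @pytest.mark.parametrize(
        "length,expected",
        [(1, "short"), (699, "short"), (700, "medium"), (4000, "medium"), (4001, "long")],
    )
    def test_boundaries(self, length, expected):
        assert intron_length_class(length) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            intron_length_class(0)


class TestSAOverlapFraction:
    def _anchors(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "pos": [1000, 2000, 3000],
                "strand": ["+"] * 3,
                "length_class": ["short", "medium", "long"],
            }
        )

    def _clusters(self):
        return {
            f"c{i}": Cluster(
                f"c{i}", GenomicInterval("chr1", pos - 10, pos, "+"), pos - 1
            )
            for i, pos in enumerate([1000, 2000, 3000])
        }

    def test_no_upregulated_gives_zero(self):
        tab = sa_overlap_fraction(self._anchors(), {"x": set()}, self._clusters())
        assert (tab["x"] == 0).all()

    def test_full_coverage_gives_hundred(self):
        tab = sa_overlap_fraction(
            self._anchors(), {"x": {"c0", "c1", "c2"}}, self._clusters()
        )
        assert (tab["x"] == 100).all()

    def test_expressed_denominator_drops_empty_anchors(self):
        anchors = self._anchors()
        clusters = {"c0": self._clusters()["c0"]}  # only the short anchor has a cluster
        tab = sa_overlap_fraction(anchors, {"x": {"c0"}}, clusters,
                                  denominator="expressed")
        assert tab.loc["short", "x"] == 100
        assert np.isnan(tab.loc["medium", "x"])
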