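import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stagescreen import (HitCallingConfig, call_killing_hits, call_primary_hits,
                         call_secondary_hits, select_killing_library)
from stagescreen.hit_calling import SecondaryResult, verify_hit_table

from _oracles import naive_consensus


def primary_frame(genes):
    """genes: {gene: {channel: (rep1, rep2)}} -> tidy score frame."""
    rows = []
    for gene, channels in genes.items():
        for ch, reps in channels.items():
            for r, score in enumerate(reps, start=1):
                if score is not None:
                    rows.append(dict(gene=gene, sirna_id=f"{gene}-pool", replicate=r,
                                     channel=ch, score=score))
    return pd.DataFrame(rows)


def tensor_frame(gene_tensors, channel="IL6"):
    """{gene: 2-D array (siRNA x replicate)} -> tidy score frame."""
    rows = []
    for gene, mat in gene_tensors.items():
        mat = np.asarray(mat, dtype=float)
        for i in range(mat.shape[0]):
            for j in range(mat.shape[1]):
                if not np.isnan(mat[i, j]):
                    rows.append(dict(gene=gene, sirna_id=f"{gene}-s{i + 1}",
                                     replicate=j + 1, channel=channel,
                                     score=mat[i, j]))
    return pd.DataFrame(rows)


class TestPrimary:
    def test_channel_specific_calls_and_disjoint_sets(self):
        res = call_primary_hits(primary_frame({
            "A": {"IL6": (5.0, 4.3), "IL8": (1.0, 1.0)},     # IL6 only
            "B": {"IL6": (1.0, 1.0), "IL8": (3.2, 4.0)},     # IL8 only
            "C": {"IL6": (6.0, 5.0), "IL8": (3.1, 3.6)},     # both
            "D": {"IL6": (9.0, 4.0), "IL8": (0.0, 0.0)},     # one replicate fails
        }))
        assert res.il6_only == {"A"}
        assert res.il8_only == {"B"}
        assert res.both == {"C"}
        assert res.per_channel_hits["IL6"] == {"A", "C"}

    def test_threshold_boundary_is_inclusive(self):
        res = call_primary_hits(primary_frame({"A": {"IL6": (4.20, 4.20)}}))
        assert res.per_channel_hits["IL6"] == {"A"}

    def test_missing_replicate_is_not_a_hit(self):
        res = call_primary_hits(primary_frame({"A": {"IL6": (9.0, None)}}))
        assert res.per_channel_hits["IL6"] == set()

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="CCL2"):
            call_primary_hits(primary_frame({"A": {"CCL2": (5.0, 5.0)}}))

    def test_hit_tables_self_consistent(self):
        res = call_primary_hits(primary_frame({
            "A": {"IL6": (5.0, 4.3)}, "B": {"IL6": (9.0, 4.0)}}))
        assert all(verify_hit_table(t) for t in res.hit_tables)


class TestSecondary:
    def test_two_sirnas_each_passing_two_of_three(self):
        res = call_secondary_hits(tensor_frame({
            "A": [[1.2, 1.1, 0.0], [1.0, 0.9, 1.3], [0, 0, 0], [0, 0, 0]]}))
        assert res.channel_hits["IL6"] == {"A"}
        assert res.validated == {"A"}

    def test_single_strong_sirna_is_not_enough(self):
        res = call_secondary_hits(tensor_frame({
            "A": [[5, 5, 5], [0, 0, 0], [0, 0, 0], [0, 0, 0]]}))
        assert res.validated == set()

    def test_all_zero_scores_hit_nothing(self):
        res = call_secondary_hits(tensor_frame({"A": np.zeros((4, 3))}))
        assert res.validated == set()

    def test_ccl2_uses_stricter_threshold(self):
        mat = [[1.5, 1.5, 1.5], [1.5, 1.5, 1.5], [0, 0, 0], [0, 0, 0]]
        assert call_secondary_hits(tensor_frame(mat and {"A": mat}, channel="IL6")
                                   ).channel_hits["IL6"] == {"A"}
        assert call_secondary_hits(tensor_frame({"A": mat}, channel="CCL2")
                                   ).channel_hits["CCL2"] == set()

    def test_more_than_four_sirnas_rejected(self):
        with pytest.raises(ValueError, match="at most 4"):
            call_secondary_hits(tensor_frame({"A": np.ones((5, 3))}))

    def test_joint_consensus_mode_is_stricter(self):
        # each siRNA passes in 2 of 3 reps, but never the same two reps together
        mat = [[1.5, 1.5, 0.0], [0.0, 1.5, 1.5], [0, 0, 0], [0, 0, 0]]
        per_sirna = call_secondary_hits(tensor_frame({"A": mat}))
        joint = call_secondary_hits(tensor_frame({"A": mat}),
                                    HitCallingConfig(secondary_consensus="joint"))
        assert per_sirna.channel_hits["IL6"] == {"A"}
        assert joint.channel_hits["IL6"] == set()


class TestKilling:
    def test_two_qualifying_sirnas_make_a_hit(self):
        mat = np.zeros((4, 6))
        mat[0, [0, 1, 2]] = 1.0   # passes reps 1-3
        mat[1, [1, 3, 5]] = 1.0   # passes reps 2,4,6
        res = call_killing_hits(tensor_frame({"A": mat}, channel="KILLING"))
        assert res.hits == {"A"}

    def test_two_sirnas_with_only_two_passes_each_fail(self):
        mat = np.zeros((4, 6))
        mat[0, [0, 1]] = 1.0
        mat[1, [2, 3]] = 1.0
        res = call_killing_hits(tensor_frame({"A": mat}, channel="KILLING"))
        assert res.hits == set()

    def test_all_below_cutoff_hits_nothing(self):
        res = call_killing_hits(tensor_frame(
            {"A": np.full((4, 6), 0.69)}, channel="KILLING"))
        assert res.hits == set()

    def test_boundary_case_exactly_at_rule_minima(self):
        # NPA exactly 0.7 in exactly 3 of 6 replicates for exactly 2 siRNAs
        mat = np.zeros((4, 6))
        mat[0, :3] = 0.7
        mat[1, 3:] = 0.7
        res = call_killing_hits(tensor_frame({"A": mat}, channel="KILLING"))
        assert res.hits == {"A"}

    def test_brute_force_equivalence_on_random_tensors(self):
        """1000 random 4x6 score tensors agree with the exhaustive rule evaluator."""
        rng = np.random.default_rng(31)
        cfg = HitCallingConfig()
        for _ in range(1000):
            mat = rng.normal(0.6, 0.3, size=(4, 6))
            mat[rng.random((4, 6)) < 0.05] = np.nan
            res = call_killing_hits(tensor_frame({"G": mat}, channel="KILLING"), cfg)
            expected = naive_consensus(mat.tolist(), cfg.killing_npa_threshold,
                                       cfg.killing_min_sirnas, cfg.killing_min_reps)
            assert (len(res.hits) == 1) == expected


class TestLibrarySelection:
    @staticmethod
    def secondary_result(channel_hits):
        return SecondaryResult(channel_hits=channel_hits,
                               validated=set().union(*channel_hits.values()),
                               hit_tables=[], thresholds={})

    def test_multi_channel_hits_always_included(self):
        res = self.secondary_result({"IL6": {"A"}, "IL8": set(), "CCL2": {"A"},
                                     "IL1B": set()})
        assert select_killing_library(res) == ["A"]

    def test_single_non_ccl2_channel_excluded(self):
        res = self.secondary_result({"IL6": set(), "IL8": {"B"}, "CCL2": set(),
                                     "IL1B": set()})
        assert select_killing_library(res) == []

    def test_ccl2_only_capped_by_best_npa_with_name_tiebreak(self):
        genes = [f"G{i}" for i in range(10)]
        res = self.secondary_result({"IL6": set(), "IL8": set(),
                                     "CCL2": set(genes), "IL1B": set()})
        scores = pd.DataFrame([
            dict(gene=g, sirna_id=f"{g}-s1", replicate=1, channel="CCL2",
                 score=float(i // 2))  # pairs tie: (G0,G1)=0 ... (G8,G9)=4
            for i, g in enumerate(genes)])
        picked = select_killing_library(res, scores, cap_ccl2_only=8)
        # highest best-NPA pairs first, alphabetical inside ties; G0/G1 dropped
        assert picked == ["G8", "G9", "G6", "G7", "G4", "G5", "G2", "G3"]


class TestMonotonicity:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.0))
    def test_raising_killing_threshold_never_adds_hits(self, seed, bump):
        rng = np.random.default_rng(seed)
        frame = tensor_frame({f"G{k}": rng.normal(0.7, 0.3, size=(4, 6))
                              for k in range(5)}, channel="KILLING")
        low = call_killing_hits(frame, HitCallingConfig(killing_npa_threshold=0.7))
        high = call_killing_hits(frame, HitCallingConfig(killing_npa_threshold=0.7 + bump))
        assert high.hits <= low.hits

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_stricter_consensus_minima_never_add_hits(self, seed):
        rng = np.random.default_rng(seed)
        frame = tensor_frame({f"G{k}": rng.normal(1.0, 0.8, size=(4, 3))
                              for k in range(5)})
        base = call_secondary_hits(frame, HitCallingConfig())
        stricter_s = call_secondary_hits(frame, HitCallingConfig(secondary_min_sirnas=3))
        stricter_r = call_secondary_hits(frame, HitCallingConfig(secondary_min_reps=3))
        assert stricter_s.channel_hits["IL6"] <= base.channel_hits["IL6"]
        assert stricter_r.channel_hits["IL6"] <= base.channel_hits["IL6"]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 3.0))
    def test_raising_primary_threshold_never_adds_hits(self, seed, bump):
        rng = np.random.default_rng(seed)
        frame = tensor_frame({f"G{k}": rng.normal(4.0, 1.5, size=(1, 2))
                              for k in range(8)})
        low = call_primary_hits(frame, HitCallingConfig())
        cfg = HitCallingConfig(primary_thresholds={"IL6": 4.20 + bump, "IL8": 3.05})
        high = call_primary_hits(frame, cfg)
        assert high.per_channel_hits["IL6"] <= low.per_channel_hits["IL6"]


def test_record_order_does_not_change_calls():
    rng = np.random.default_rng(17)
    frame = tensor_frame({f"G{k}": rng.normal(0.7, 0.3, size=(4, 6))
                          for k in range(6)}, channel="KILLING")
    shuffled = frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
    assert call_killing_hits(frame).hits == call_killing_hits(shuffled).hits
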