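"""Haplotype-block reconstruction: polarization, clustering, validation."""

import numpy as np
import pandas as pd
import pytest

from erpoly import blocks as blk
from erpoly import detect
from erpoly.io import HaplotypePanel

from conftest import tensor_from_freq


class TestPolarize:
    def test_rising_allele_chosen(self):
        freq = np.zeros((1, 3, 2))
        freq[0, :, 0] = 0.5
        freq[0, :, 1] = 0.2  # the labelled allele falls: flip expected
        t = tensor_from_freq(freq, generations=(0, 60))
        pol = blk.polarize_rising(t)
        f = pol.frequency()
        assert (f[0, :, 1] - f[0, :, 0] > 0).all()
        assert pol.snps.loc[0, "rising"] == "A"  # swapped with "other"

    def test_tie_breaks_lexicographic_and_flagged(self):
        freq = np.full((1, 2, 2), 0.5)
        t = tensor_from_freq(freq, generations=(0, 60))
        # rising = "T", other = "A"; tie -> smaller nucleotide "A" rises
        pol = blk.polarize_rising(t)
        assert pol.snps.loc[0, "rising"] == "A"
        assert pol.meta["polarization_ties"] == 1

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        freq = rng.random((20, 3, 4))
        t = tensor_from_freq(freq, generations=(0, 20, 40, 60))
        once = blk.polarize_rising(t)
        twice = blk.polarize_rising(once)
        np.testing.assert_array_equal(once.rising_count, twice.rising_count)
        assert once.snps.equals(twice.snps)


class TestSelectBlockInput:
    def candidates(self, n, cmh_q, fisher_q=None):
        d = {"cmh_q": cmh_q}
        if fisher_q is not None:
            d["fisher_q_R1"] = fisher_q
        d["chrom"] = ["2L"] * n
        return pd.DataFrame(d)

    def test_rise_between_intermediate_timepoints_counts(self):
        # rises 0.25 between generations 20 and 50 in replicates 1 and 2
        freq = np.full((1, 3, 7), 0.3)
        freq[0, :2, 4:] = 0.55
        t = tensor_from_freq(freq)
        cand = self.candidates(1, [0.01])
        assert blk.select_block_input(cand, t).tolist() == [0]

    def test_single_replicate_rise_excluded(self):
        freq = np.full((1, 3, 7), 0.3)
        freq[0, 0, 4:] = 0.55
        t = tensor_from_freq(freq)
        cand = self.candidates(1, [0.01])
        with pytest.warns(UserWarning):
            assert blk.select_block_input(cand, t).size == 0

    def test_fisher_candidate_needs_no_rise(self):
        freq = np.full((1, 3, 7), 0.3)
        freq[0, 0, -1] = 0.35  # tiny rise
        t = tensor_from_freq(freq)
        cand = self.candidates(1, [0.5], fisher_q=[0.01])
        assert blk.select_block_input(cand, t).tolist() == [0]


class TestTrajectoryMatrix:
    def test_rows_standardized(self):
        rng = np.random.default_rng(1)
        freq = rng.random((10, 3, 7))
        t = tensor_from_freq(freq)
        tm = blk.build_trajectory_matrix(t, np.arange(10))
        np.testing.assert_allclose(tm.values.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(tm.values.std(axis=1), 1, atol=1e-12)

    def test_endpoint_transform(self):
        # p = 0 -> arcsin 0, p = 1 -> pi/2; a 0/1 row standardizes to +-1
        freq = np.zeros((1, 1, 4))
        freq[0, 0, 2:] = 1.0
        t = tensor_from_freq(freq, generations=(0, 10, 20, 30))
        tm = blk.build_trajectory_matrix(t, np.arange(1))
        np.testing.assert_allclose(np.unique(tm.values), [-1, 1])

    def test_constant_rows_dropped(self):
        freq = np.concatenate([np.full((1, 2, 7), 0.4),
                               np.sort(np.random.default_rng(0)
                                       .random((1, 2, 7)), axis=2)])
        t = tensor_from_freq(freq)
        tm = blk.build_trajectory_matrix(t, np.arange(2))
        assert tm.n_dropped_constant == 1
        assert tm.values.shape[0] == 1


class TestClusterWindow:
    def test_identical_rows_form_one_cluster(self):
        row = np.sin(np.linspace(0, 3, 30))
        X = np.vstack([row, row])
        X = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        clusters = blk.cluster_window(X, r_min=0.75)
        assert len(clusters) == 1 and len(clusters[0]) == 2

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_cluster_recovered_without_contamination(self, seed):
        # 30 noisy copies of one trajectory + 30 independent-noise rows
        rng = np.random.default_rng(seed)
        base = np.cumsum(rng.random(70)) / 10
        planted = base + rng.normal(0, 0.1, size=(30, 70))
        noise = rng.normal(0, 1, size=(30, 70))
        X = np.vstack([planted, noise])
        X = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        clusters = blk.cluster_window(X, r_min=0.75)
        best = max(clusters, key=len)
        planted_in = (best < 30).sum()
        assert planted_in >= 0.95 * 30
        assert (best >= 30).sum() == 0


class TestMerge:
    def mk(self, members, window):
        return blk.Cluster(members=np.asarray(members), mean_r=np.nan,
                           windows={window})

    def test_share_five_merges(self):
        a = self.mk(range(0, 25), 1)
        b = self.mk(range(19, 45), 2)  # shares 6
        merged = blk.merge_clusters([a, b], min_members=21)
        assert len(merged) == 1 and len(merged[0].members) == 45

    def test_share_four_does_not_merge(self):
        a = self.mk(range(0, 25), 1)
        b = self.mk(range(21, 46), 2)  # shares 4
        merged = blk.merge_clusters([a, b], min_members=21)
        assert len(merged) == 2

    def test_transitive_closure(self):
        a = self.mk(range(0, 25), 1)
        b = self.mk(range(20, 45), 2)  # shares 5 with a
        c = self.mk(range(40, 65), 3)  # shares 5 with b, none with a
        merged = blk.merge_clusters([a, b, c], min_members=21)
        assert len(merged) == 1 and len(merged[0].members) == 65

    def test_small_merged_clusters_discarded(self):
        a = self.mk(range(0, 10), 1)
        merged = blk.merge_clusters([a], min_members=21)
        assert merged == []


class TestValidate:
    def make_block_and_panel(self, states):
        n = len(states)
        snps = pd.DataFrame({
            "chrom": ["2L"] * n, "pos": np.arange(1, n + 1) * 100,
            "ref": ["A"] * n, "rising": ["T"] * n, "other": ["A"] * n,
        })
        block = blk.HaplotypeBlock(
            block_id=0, marker_idx=np.arange(n), snps=snps, chrom="2L",
            start=100, end=n * 100, mean_r=1.0,
            trajectories=np.zeros((1, 2)), generations=np.array([0, 60]))
        panel = HaplotypePanel(
            snps=snps[["chrom", "pos"]].assign(allele="T"),
            alleles=np.array([states], dtype=np.int8))
        return block, panel

    def test_identical_haplotype_matches(self):
        block, panel = self.make_block_and_panel([1] * 20)
        out = blk.validate_blocks([block], panel)
        assert out.loc[0, "n_matching"] == 1

    def test_over_20_percent_mismatch_fails(self):
        states = [1] * 79 + [0] * 21  # 21% mismatched
        block, panel = self.make_block_and_panel(states)
        out = blk.validate_blocks([block], panel)
        assert out.loc[0, "n_matching"] == 0

    def test_missing_plus_mismatch_combine(self):
        states = [1] * 81 + [-1] * 15 + [0] * 4  # 19% <= 20%: match
        block, panel = self.make_block_and_panel(states)
        out = blk.validate_blocks([block], panel)
        assert out.loc[0, "n_matching"] == 1

    def test_absent_markers_flagged_unvalidatable(self):
        block, panel = self.make_block_and_panel([1] * 10)
        panel2 = HaplotypePanel(
            snps=pd.DataFrame({"chrom": ["3R"] * 2, "pos": [5, 10],
                               "allele": ["T", "T"]}),
            alleles=np.zeros((1, 2), dtype=np.int8))
        out = blk.validate_blocks([block], panel2)
        assert out.loc[0, "unvalidatable"].item() is True


@pytest.fixture(scope="module")
def pipeline(planted_experiment):
    """Detection + polarization + input selection on the planted fixture."""
    tensor = planted_experiment["tensor"]
    cand = detect.detect_candidates(tensor, ne=300, iterations=4,
                                    seed=40, fisher=False)
    pol = blk.polarize_rising(tensor)
    idx = blk.select_block_input(cand, pol)
    return pol, idx, planted_experiment["ledger"]


class TestReconstruction:
    def test_planted_blocks_recovered(self, pipeline):
        pol, idx, ledger = pipeline
        found = blk.reconstruct_blocks(pol, idx)
        assert len(found) == len(ledger.blocks)
        truth = ledger.marker_sets()
        for b in found:
            capture = max(len(set(b.marker_idx.tolist()) & ts) / len(ts)
                          for ts in truth)
            assert capture >= 0.9

    def test_invariant_to_input_order(self, pipeline):
        pol, idx, _ = pipeline
        rng = np.random.default_rng(0)
        shuffled = idx.copy()
        rng.shuffle(shuffled)
        a = blk.reconstruct_blocks(pol, idx)
        b = blk.reconstruct_blocks(pol, shuffled)
        assert [x.marker_idx.tolist() for x in a] == \
            [x.marker_idx.tolist() for x in b]

    def test_blocks_validate_against_founder_panel(self, pipeline,
                                                   planted_experiment):
        pol, idx, ledger = pipeline
        found = blk.reconstruct_blocks(pol, idx)
        out = blk.validate_blocks(found, planted_experiment["panel"])
        # every block's carriers exist in the founder panel
        expected_carriers = {len(b.carrier_haplotypes)
                             for b in ledger.blocks}
        assert (out["n_matching"] >= min(expected_carriers)).all()

    def test_final_blocks_meet_correlation_floor(self, pipeline):
        pol, idx, _ = pipeline
        for b in blk.reconstruct_blocks(pol, idx):
            assert b.mean_r >= 0.35
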