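"""Sequence, motif, overlap and score-table featurization."""

import numpy as np
import pandas as pd
import pytest

from mprameta.featurize import (
    PWM,
    Region,
    assemble_matrix,
    composition_features,
    kmer_features,
    locus_features,
    overlap_features,
    reverse_complement,
    scan_motifs,
    score_table_features,
    select_subset,
)


class TestKmerFeatures:
    def test_hand_enumeration(self):
        vec, distinct = kmer_features("ACGTACGTA")
        assert distinct == 4  # ACGTA CGTAC GTACG TACGT; ACGTA repeats
        assert vec.sum() == 4
        assert vec["kmer_ACGTA"] == 1

    def test_homopolymer_single_kmer(self):
        vec, distinct = kmer_features("A" * 20)
        assert distinct == 1
        assert vec["kmer_AAAAA"] == 1

    def test_presence_matches_window_enumeration_oracle(self):
        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(list("ACGT"), size=150))
        vec, _ = kmer_features(seq)
        oracle = {seq[i : i + 5] for i in range(len(seq) - 4)}
        for name, val in vec.items():
            assert val == int(name.removeprefix("kmer_") in oracle)

    def test_non_acgt_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            kmer_features("ACGNACGT")


class TestComposition:
    @pytest.mark.parametrize(
        "seq,gc,pa,pt",
        [("GGCCAT", 4, 1, 1), ("AAATAAAA", 0, 4, 1), ("ACGT", 2, 1, 1)],
    )
    def test_hand_counts(self, seq, gc, pa, pt):
        f = composition_features(seq)
        assert (f["n_GC"], f["polyA"], f["polyT"]) == (gc, pa, pt)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            composition_features("")


class TestScanMotifs:
    def test_planted_consensus_single_forward_hit(self, sharp_pwm):
        rng = np.random.default_rng(3)
        bg = "".join(rng.choice(list("ACGT"), size=100))
        start = 40
        seq = bg[:start] + sharp_pwm.consensus + bg[start + len(sharp_pwm):]
        hits, summ = scan_motifs(seq, [sharp_pwm], p_threshold=1e-4)
        fwd = hits[hits["strand"] == "+"]
        assert start in set(fwd["start"])
        assert summ["n_motifs"] >= 1

    def test_motif_density_hand_case(self):
        starts = np.array([1, 5, 30])
        # windows of width 20: [1..21) covers 1 and 5 -> density 2
        density = max(
            ((starts >= s) & (starts < s + 20)).sum() for s in starts
        )
        assert density == 2

    def test_uniform_pwm_no_hits(self):
        uni = PWM("uniform", np.full((6, 4), 0.25))
        seq = "ACGTACGTACGTACGTACGT"
        hits, summ = scan_motifs(seq, [uni], p_threshold=0.5)
        assert len(hits) == 0
        assert summ["n_motifs"] == 0

    def test_strand_symmetry(self, sharp_pwm):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        seq = seq[:30] + sharp_pwm.consensus + seq[38:]
        h1, _ = scan_motifs(seq, [sharp_pwm])
        h2, _ = scan_motifs(reverse_complement(seq), [sharp_pwm])
        assert len(h1) == len(h2)

    def test_pwm_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            PWM("bad", np.full((4, 4), 0.3))

    def test_zero_background_with_weight_rejected(self):
        mat = np.array([[0.7, 0.1, 0.1, 0.1]])
        with pytest.raises(ValueError, match="background"):
            PWM("bad", mat, background=[0.0, 0.4, 0.3, 0.3])

    def test_score_threshold_is_exact_tail(self, sharp_pwm):
        """The DP threshold matches brute-force enumeration over all words."""
        mat = sharp_pwm.matrix[:4]  # 4-mer: 256 words, enumerable
        pwm = PWM("mini", mat)
        from itertools import product

        words = ["".join(w) for w in product("ACGT", repeat=4)]
        scores = np.array([pwm.scan(w)[0] for w in words])
        for p_thr in (1e-2, 1e-3):
            thr = pwm.score_threshold(p_thr)
            # exact tail probability at the DP threshold is below p_thr ...
            assert (scores >= thr - 1e-9).mean() < p_thr
            # ... and the threshold is the smallest achievable such score
            below = scores[scores < thr - 1e-9]
            if below.size:
                s2 = below.max()
                assert (scores >= s2 - 1e-9).mean() >= p_thr


class TestOverlapFeatures:
    @pytest.fixture
    def region(self):
        return Region("r1", "A" * 150, interval=("chr1", 100, 250), cell_type="K562")

    def _meta(self, rows):
        return pd.DataFrame(rows, columns=["track_id", "factor", "cell_type"])

    def test_half_open_boundary_no_overlap(self, region):
        tracks = {"t1": pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})}
        meta = self._meta([("t1", "TFBS", "K562")])
        feats = overlap_features(region, tracks, meta)
        assert feats["track_t1"] == 0.0

    def test_tfbs_mean_of_binaries(self, region):
        tracks = {
            f"t{i}": pd.DataFrame(
                {"chrom": ["chr1"], "start": [120 if i < 2 else 500],
                 "end": [130 if i < 2 else 600]}
            )
            for i in range(4)
        }
        meta = self._meta([(f"t{i}", "TFBS", "other") for i in range(4)])
        feats = overlap_features(region, tracks, meta)
        assert feats["TFBS_mean"] == pytest.approx(0.5)

    def test_shuffled_mean_degenerate_pool_is_one(self, region):
        # every pool track overlaps -> shuffled mean 1.0 for any seed
        tracks = {
            f"c{i}": pd.DataFrame({"chrom": ["chr1"], "start": [110], "end": [120]})
            for i in range(2)
        }
        tracks.update(
            {
                f"p{i}": pd.DataFrame({"chrom": ["chr1"], "start": [130], "end": [140]})
                for i in range(5)
            }
        )
        meta = self._meta(
            [(f"c{i}", "TFBS", "K562") for i in range(2)]
            + [(f"p{i}", "TFBS", "HepG2") for i in range(5)]
        )
        for seed in (0, 99):
            feats = overlap_features(region, tracks, meta, seed=seed)
            assert feats["TFBS_shuffled_mean"] == pytest.approx(1.0)

    def test_bad_track_interval_rejected(self, region):
        tracks = {"t1": pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [10]})}
        meta = self._meta([("t1", "TFBS", "K562")])
        with pytest.raises(ValueError, match="end <= start"):
            overlap_features(region, tracks, meta)


class TestScoreTableFeatures:
    def test_single_factor_top_decile(self):
        ids = [f"r{i}" for i in range(10)]
        table = pd.DataFrame({"TF1": np.arange(1, 11)}, index=ids)
        out = score_table_features(ids, {"bind": table})
        assert out["n_bind_top"].sum() == 1
        assert out.loc["r9", "n_bind_top"] == 1

    def test_all_equal_scores_no_top(self):
        ids = [f"r{i}" for i in range(10)]
        table = pd.DataFrame({"TF1": np.ones(10)}, index=ids)
        out = score_table_features(ids, {"bind": table})
        assert (out["n_bind_top"] == 0).all()

    def test_strata_counts_bounded_by_top_count(self):
        rng = np.random.default_rng(4)
        ids = [f"r{i}" for i in range(40)]
        factors = [f"TF{i}" for i in range(30)]
        table = pd.DataFrame(rng.random((40, 30)), index=ids, columns=factors)
        tpm = pd.Series(rng.random(30), index=factors)
        out = score_table_features(ids, {"bind": table}, expression=tpm, strata_size=10)
        total = out["n_tf_high"] + out["n_tf_med"] + out["n_tf_low"]
        assert (total <= out["n_bind_top"]).all()
        # brute-force check of the top counts
        cut = np.percentile(table, 90, axis=0)
        brute = (table.to_numpy() > cut).sum(axis=1)
        np.testing.assert_array_equal(out["n_bind_top"].to_numpy(), brute)

    def test_missing_expression_rejected_naming_factor(self):
        ids = ["r0", "r1"]
        table = pd.DataFrame({"TFX": [1.0, 2.0]}, index=ids)
        tpm = pd.Series({"OTHER": 5.0})
        with pytest.raises(ValueError, match="TFX"):
            score_table_features(ids, {"bind": table}, expression=tpm)


class TestLocusFeatures:
    def _region(self):
        return Region("r", "A" * 100, interval=("chr2", 1000, 1100))

    def test_exon_only(self):
        ann = {"exon": pd.DataFrame({"chrom": ["chr2"], "start": [1050], "end": [1060]})}
        f = locus_features(self._region(), ann)
        assert (f["promoter"], f["exon"], f["intron"], f["distal"]) == (0, 1, 0, 0)

    def test_no_overlap_is_distal(self):
        f = locus_features(self._region(), {})
        assert f["distal"] == 1.0

    def test_constant_conservation_mean(self):
        cons = pd.Series(0.8, index=np.arange(1000, 1100))
        f = locus_features(self._region(), {}, conservation=cons)
        assert f["conservation"] == pytest.approx(0.8)

    def test_partial_conservation_flagged_missing(self):
        cons = pd.Series(0.8, index=np.arange(1000, 1050))
        f = locus_features(self._region(), {}, conservation=cons)
        assert np.isnan(f["conservation"])


class TestAssembleMatrix:
    def test_column_bind_in_declared_order(self):
        idx = pd.Index(["r1", "r2"], name="region_id")
        b1 = pd.DataFrame({"a": [1, 2], "b": [3, 4], "c": [5, 6]}, index=idx)
        b2 = pd.DataFrame({f"k{i}": [0, 1] for i in range(4)}, index=idx)
        m, cats = assemble_matrix(
            {"one": b1, "two": b2}, {"one": "experimental", "two": "kmer"}
        )
        assert list(m.columns) == ["a", "b", "c", "k0", "k1", "k2", "k3"]
        assert (cats.loc[["a", "b", "c"]] == "experimental").all()

    def test_full_subset_is_union(self):
        idx = pd.Index(["r1"], name="region_id")
        blocks = {
            "e": pd.DataFrame({"x": [1]}, index=idx),
            "k": pd.DataFrame({"y": [2]}, index=idx),
        }
        m, cats = assemble_matrix(blocks, {"e": "experimental", "k": "kmer"})
        assert list(select_subset(m, cats, "Full").columns) == ["x", "y"]
        assert list(select_subset(m, cats, "kmer").columns) == ["y"]

    def test_duplicate_feature_rejected(self):
        idx = pd.Index(["r1"], name="region_id")
        blocks = {
            "e": pd.DataFrame({"x": [1]}, index=idx),
            "k": pd.DataFrame({"x": [2]}, index=idx),
        }
        with pytest.raises(ValueError, match="duplicate"):
            assemble_matrix(blocks, {"e": "experimental", "k": "kmer"})

    def test_tsv_round_trip_exact(self, tmp_path):
        from mprameta.io import read_feature_matrix, write_feature_matrix

        idx = pd.Index(["r1", "r2"], name="region_id")
        m = pd.DataFrame({"a": [0.125, -3.5], "b": [1.0, 2.0]}, index=idx)
        cats = pd.Series({"a": "kmer", "b": "locus"})
        path = tmp_path / "fm.tsv"
        write_feature_matrix(m, path, cats)
        m2, cats2 = read_feature_matrix(path)
        pd.testing.assert_frame_equal(m, m2)
        pd.testing.assert_series_equal(
            cats.rename("category"), cats2, check_names=False
        )
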