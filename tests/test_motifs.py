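import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitsig import motifs
from traitsig.motifs import (
    HitProfile,
    PromoterSet,
    WeightMatrix,
    builtin_motifs,
    enrichment_heatmap,
    enrichment_table,
    fisher_sequence_test,
    load_pfm,
    profile_set,
    reverse_complement,
    scan,
    zscore_bp_test,
)
from traitsig.simulate import SimConfig, generate_promoter_sets


# -- brute-force scanning oracle -----------------------------------------

def oracle_scan(seq: str, wm: WeightMatrix):
    """Enumerate all windows on both strands independently of the scanner."""
    L = wm.length
    lr = wm.logratio
    hits = []
    for i in range(len(seq) - L + 1):
        w = seq[i : i + L]
        if "N" in w:
            continue
        score = sum(lr["ACGT".index(c), j] for j, c in enumerate(w))
        if score >= wm.threshold:
            hits.append((i, "+", score))
    rc = reverse_complement(seq)
    for i in range(len(rc) - L + 1):
        w = rc[i : i + L]
        if "N" in w:
            continue
        score = sum(lr["ACGT".index(c), j] for j, c in enumerate(w))
        if score >= wm.threshold:
            hits.append((len(seq) - L - i, "-", score))
    return sorted(hits, key=lambda h: (h[0], h[1]))


def random_matrix(rng, max_len=6):
    L = int(rng.integers(1, max_len + 1))
    counts = rng.integers(0, 12, size=(4, L)).astype(float)
    return WeightMatrix(f"R{L}", counts)


def assert_hits_equal(got, expected):
    assert [(h.position, h.strand) for h in got] == [(p, s) for p, s, _ in expected]
    np.testing.assert_allclose(
        [h.score for h in got], [sc for _, _, sc in expected], rtol=1e-9, atol=1e-12
    )


class TestWeightMatrix:
    def test_uniform_column_scores_zero(self, tmp_path):
        p = tmp_path / "u.pfm"
        p.write_text("1\n1\n1\n1\n")
        wm = load_pfm(p)
        assert wm.motif_id == "u"
        np.testing.assert_allclose(wm.logratio, 0.0)
        assert wm.min_score == wm.max_score == wm.threshold == 0.0

    def test_single_dominant_column_hand_values(self, tmp_path):
        p = tmp_path / "a.pfm"
        p.write_text(">a\n4\n0\n0\n0\n")
        wm = load_pfm(p)
        assert wm.logratio[0, 0] == pytest.approx(math.log2(2.5))
        np.testing.assert_allclose(wm.logratio[1:, 0], -1.0)
        assert wm.threshold == pytest.approx(-1 + 0.8 * (math.log2(2.5) + 1))

    def test_jaspar_bracket_dialect(self, tmp_path):
        p = tmp_path / "b.pfm"
        p.write_text(">MOT1 something\nA [ 1 2 ]\nC [ 3 4 ]\nG [ 5 6 ]\nT [ 7 8 ]\n")
        wm = load_pfm(p)
        assert wm.motif_id == "MOT1"
        np.testing.assert_allclose(wm.counts, [[1, 2], [3, 4], [5, 6], [7, 8]])

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "e.pfm"
        p.write_text("")
        with pytest.raises(ValueError, match="4 count rows"):
            load_pfm(p)

    def test_three_rows_rejected(self, tmp_path):
        p = tmp_path / "t.pfm"
        p.write_text("1 2\n3 4\n5 6\n")
        with pytest.raises(ValueError, match="4 count rows"):
            load_pfm(p)

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "r.pfm"
        p.write_text("1 2\n3 4 5\n6 7\n8 9\n")
        with pytest.raises(ValueError, match="ragged"):
            load_pfm(p)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            WeightMatrix("neg", [[-1], [1], [1], [1]])

    def test_threshold_between_min_and_max(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            wm = random_matrix(rng)
            assert wm.min_score <= wm.threshold <= wm.max_score

    def test_builtin_collection_loads(self):
        mats = builtin_motifs()
        assert len(mats) == 10
        assert all(m.length >= 8 for m in mats)
        assert len({m.motif_id for m in mats}) == 10


class TestScan:
    def test_sequence_shorter_than_matrix_no_hits(self):
        wm = WeightMatrix("m", np.ones((4, 5)))
        assert scan("ACG", wm) == []

    def test_invalid_characters_rejected(self):
        wm = WeightMatrix("m", np.ones((4, 2)))
        with pytest.raises(ValueError, match="outside ACGTN"):
            scan("ACXG", wm)

    def test_strand_symmetry_total_hits(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=80))
        wm = random_matrix(rng, max_len=4)
        fwd_hits = scan(seq, wm)
        rc_hits = scan(reverse_complement(seq), wm)
        assert len(fwd_hits) == len(rc_hits)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(60):
            seq = "".join(rng.choice(list("ACGTN"), size=60, p=[0.24] * 4 + [0.04]))
            wm = random_matrix(rng, max_len=3)
            assert_hits_equal(scan(seq, wm), oracle_scan(seq, wm))

    @settings(max_examples=150, deadline=None)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=0, max_size=100),
        seed=st.integers(0, 10_000),
    )
    def test_oracle_equivalence_property(self, seq, seed):
        wm = random_matrix(np.random.default_rng(seed))
        assert_hits_equal(scan(seq, wm), oracle_scan(seq, wm))

    def test_n_windows_skipped(self):
        wm = WeightMatrix("m", np.full((4, 3), 2.0), threshold_fraction=0.0)
        hits = scan("ACGNACG", wm)
        # windows touching the N (starts 1,2,3) are excluded on both strands
        assert {h.position for h in hits} == {0, 4}

    def test_raising_threshold_never_adds_hits(self):
        rng = np.random.default_rng(33)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        counts = rng.integers(0, 10, size=(4, 5)).astype(float)
        lo = WeightMatrix("lo", counts, threshold_fraction=0.6)
        hi = WeightMatrix("hi", counts, threshold_fraction=0.9)
        lo_hits = {(h.position, h.strand) for h in scan(seq, lo)}
        hi_hits = {(h.position, h.strand) for h in scan(seq, hi)}
        assert hi_hits <= lo_hits


class TestProfileSet:
    def test_all_sequences_shorter_than_matrix(self):
        wm = WeightMatrix("m", np.ones((4, 9)))
        ps = PromoterSet({"a": "ACGT", "b": "GG"})
        prof = profile_set(ps, wm)
        assert prof.total_hits == 0
        assert prof.total_scanned_bp == 0
        assert prof.n_sequences == 2

    def test_window_start_count_hand_example(self):
        wm = WeightMatrix("m", np.ones((4, 3)))
        ps = PromoterSet({"a": "ACGTACGTAC"})  # 10 bp, L=3 -> 8 starts x 2 strands
        assert profile_set(ps, wm).total_scanned_bp == 16

    def test_duplication_doubles_tallies(self):
        rng = np.random.default_rng(2)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=50)) for i in range(5)}
        wm = random_matrix(rng, max_len=4)
        single = profile_set(PromoterSet(seqs), wm)
        doubled = profile_set(
            PromoterSet({**seqs, **{f"d{i}": s for i, s in enumerate(seqs.values())}}),
            wm,
        )
        assert doubled.total_hits == 2 * single.total_hits
        assert doubled.total_scanned_bp == 2 * single.total_scanned_bp

    def test_agrees_with_per_sequence_scan(self):
        rng = np.random.default_rng(21)
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACGTN"), size=int(rng.integers(2, 70)),
                                        p=[0.24] * 4 + [0.04]))
            for i in range(12)
        }
        ps = PromoterSet(seqs)
        for _ in range(5):
            wm = random_matrix(rng, max_len=5)
            per_seq = {name: scan(s, wm) for name, s in ps.sequences.items()}
            prof = profile_set(ps, wm)
            assert prof.total_hits == sum(len(h) for h in per_seq.values())
            assert prof.n_sequences_with_hit == sum(bool(h) for h in per_seq.values())
            expected_bp = 0
            for s in ps.sequences.values():
                L = wm.length
                starts = max(0, len(s) - L + 1)
                valid = sum("N" not in s[i : i + L] for i in range(starts))
                expected_bp += 2 * valid
            assert prof.total_scanned_bp == expected_bp


class TestFisher:
    def test_symmetric_table_p_one(self):
        fg = HitProfile("m", 2, 1, 1, 10)
        bg = HitProfile("m", 2, 1, 1, 10)
        p, odds = fisher_sequence_test(fg, bg)
        assert p == pytest.approx(1.0)

    def test_equal_rates_p_one(self):
        fg = HitProfile("m", 10, 5, 5, 100)
        bg = HitProfile("m", 100, 50, 50, 1000)
        p, _ = fisher_sequence_test(fg, bg)
        assert p == pytest.approx(1.0)

    def test_against_hypergeometric_oracle(self):
        from scipy.stats import hypergeom

        fg = HitProfile("m", 10, 8, 8, 100)
        bg = HitProfile("m", 100, 20, 20, 1000)
        p, _ = fisher_sequence_test(fg, bg)
        N, K, n = 110, 28, 10
        ks = np.arange(max(0, K + n - N), min(K, n) + 1)
        pmf = hypergeom.pmf(ks, N, K, n)
        obs = pmf[ks == 8][0]
        oracle = pmf[pmf <= obs * (1 + 1e-12)].sum()
        assert p == pytest.approx(oracle, abs=1e-12)

    def test_haldane_correction_on_zero_cell(self):
        fg = HitProfile("m", 10, 10, 10, 100)
        bg = HitProfile("m", 10, 5, 5, 100)
        _, odds = fisher_sequence_test(fg, bg)
        assert np.isfinite(odds) and odds > 1

    def test_empty_set_rejected(self):
        fg = HitProfile("m", 0, 0, 0, 0)
        bg = HitProfile("m", 10, 5, 5, 100)
        with pytest.raises(ValueError, match="at least one sequence"):
            fisher_sequence_test(fg, bg)

    def test_null_planting_p_super_uniform(self):
        # exchangeable fg/bg: P(p < alpha) <= alpha + 3 MC SE
        mats = builtin_motifs()[:1]
        alpha = 0.1
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = SimConfig(n_samples=4, n_genes=4, n_pos_signature=0,
                            n_neg_signature=0, n_fg_promoters=40,
                            n_bg_promoters=80, promoter_length=400, seed=seed)
            fg, bg = generate_promoter_sets(cfg, mats)
            p, _ = fisher_sequence_test(profile_set(fg, mats[0]), profile_set(bg, mats[0]))
            hits += p < alpha
        assert hits / n_seeds <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_seeds)


class TestZScore:
    def test_equal_rates_zero(self):
        fg = HitProfile("m", 1, 1, 10, 1000)
        bg = HitProfile("m", 1, 1, 100, 10000)
        assert zscore_bp_test(fg, bg) == pytest.approx(0.0)

    def test_hand_example(self):
        fg = HitProfile("m", 1, 1, 30, 1000)
        bg = HitProfile("m", 1, 1, 100, 10000)  # bg rate 0.01
        z = zscore_bp_test(fg, bg)
        assert z == pytest.approx((30 - 10) / math.sqrt(10 * 0.99))

    def test_sqrt_n_scaling(self):
        bg = HitProfile("m", 1, 1, 100, 10000)
        z_full = zscore_bp_test(HitProfile("m", 1, 1, 30, 1000), bg)
        z_half = zscore_bp_test(HitProfile("m", 1, 1, 15, 500), bg)
        assert z_half == pytest.approx(z_full / math.sqrt(2))

    def test_degenerate_background_rate_missing(self, caplog):
        fg = HitProfile("m", 1, 1, 5, 100)
        bg = HitProfile("m", 1, 1, 0, 100)
        with caplog.at_level("WARNING"):
            assert np.isnan(zscore_bp_test(fg, bg))


class TestEnrichmentOutputs:
    def test_direction_matches_z_sign(self):
        fg = {"m": HitProfile("m", 10, 8, 20, 1000)}
        bg = {"m": HitProfile("m", 10, 2, 5, 1000)}
        table = enrichment_table(fg, bg)
        assert table.loc["m", "z_score"] > 0
        assert table.loc["m", "direction"] == "over"

    def test_single_cell_heatmap(self, tmp_path):
        z = pd.DataFrame({"set1": [2.5]}, index=["m"])
        out = enrichment_heatmap(z, tmp_path / "h.tsv")
        assert out.iloc[0, 0] == 2.5
        text = (tmp_path / "h.tsv").read_text()
        assert "2.5" in text

    def test_input_order_invariance(self, tmp_path):
        z = pd.DataFrame(
            {"b_set": [1.0, 2.0], "a_set": [3.0, 4.0]}, index=["m2", "m1"]
        )
        p1, p2 = tmp_path / "1.tsv", tmp_path / "2.tsv"
        enrichment_heatmap(z, p1)
        enrichment_heatmap(z.iloc[::-1, ::-1], p2)
        assert p1.read_text() == p2.read_text()

    def test_mismatched_profiles_rejected(self):
        fg = {"m": HitProfile("m", 1, 1, 1, 10)}
        bg = {"x": HitProfile("x", 1, 1, 1, 10)}
        with pytest.raises(ValueError, match="motif ids differ"):
            enrichment_table(fg, bg)


class TestPromoterSet:
    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            PromoterSet({})

    def test_fasta_round_trip(self, tmp_path):
        ps = PromoterSet({"p1": "ACGTACGT", "p2": "GGGNCCC"})
        path = tmp_path / "x.fasta"
        ps.to_fasta(path)
        back = PromoterSet.from_fasta(path)
        assert back.sequences == ps.sequences

    def test_truncation_keeps_3prime_end(self):
        ps = PromoterSet({"p": "AAAACGT"})
        assert ps.truncated(3).sequences["p"] == "CGT"
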