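"""Per-ORF statistics against hand computations and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ribodrug.scores import (
    KOZAK_MATRIX,
    KOZAK_MAX,
    RegionCounts,
    codon_phase_counts,
    drug_resistance,
    floss_reference,
    floss_score,
    kozak_context,
    kozak_score,
    normalize_length_hist,
    orf_score,
    orf_score_from_profile,
    relative_codon_density,
    rr_score,
    start_codon_accumulation,
    te_score,
    utr3_window,
)
from ribodrug.transcripts import ORFRecord


class TestTe:
    def test_arithmetic(self):
        assert te_score(50, 100) == 0.5
        assert te_score(0, 100) == 0.0

    def test_zero_denominator_undefined(self):
        assert np.isnan(te_score(10, 0))


class TestRr:
    def test_symmetric_counts_give_one(self):
        rc = RegionCounts(7, 7, 7, 7)
        assert rr_score(rc, "as-printed", pseudocount=0) == 1.0
        assert rr_score(rc, "coding-high", pseudocount=0) == 1.0

    def test_hand_computation(self):
        rc = RegionCounts(100, 100, 100, 1)
        assert rr_score(rc, "as-printed", pseudocount=0) == pytest.approx(0.01)
        assert rr_score(rc, "coding-high", pseudocount=0) == pytest.approx(100.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1000), min_size=4, max_size=4))
    def test_orientation_duality(self, counts):
        rc = RegionCounts(*counts)
        p = rr_score(rc, "as-printed")
        c = rr_score(rc, "coding-high")
        assert p * c == pytest.approx(1.0)

    def test_utr3_window_dialects(self):
        seq = "ATGAAATAA" + "CCCC" + "ATG" + "GGGG"
        assert utr3_window(seq, 9, "to-first-AUG") == (9, 13)
        assert utr3_window(seq, 9, "full-3'UTR") == (9, len(seq))
        assert utr3_window("ATGAAATAACCC", 9, "to-first-AUG") == (9, 12)

    def test_full_utr_dialect_shifts_coding_scores_up(self):
        """Footprints confined to the CDS with a short pre-AUG window: the
        full-3'UTR dialect inflates the coding-high RR score."""
        seq = "ATG" + "AAA" * 5 + "TAA" + "CC" + "ATG" + "C" * 50
        stop_end = 21
        wt = np.ones(len(seq))
        ribo = np.zeros(len(seq))
        ribo[:stop_end] = 10.0

        def rc(dialect):
            lo, hi = utr3_window(seq, stop_end, dialect)
            return RegionCounts(
                wt[:stop_end].sum(), wt[lo:hi].sum(),
                ribo[:stop_end].sum(), ribo[lo:hi].sum(),
            )

        short = rr_score(rc("to-first-AUG"), "coding-high")
        full = rr_score(rc("full-3'UTR"), "coding-high")
        assert full > short

    def test_zero_after_pseudocount_fails(self):
        with pytest.raises(ValueError):
            rr_score(RegionCounts(0, 1, 1, 1), pseudocount=0)


class TestOrfScore:
    def test_uniform_phasing_scores_zero(self):
        assert orf_score(np.array([5, 5, 5])) == 0.0

    def test_hand_computation_positive(self):
        expected = np.log2(350 / 15 + 1)
        assert orf_score(np.array([10, 30, 5])) == pytest.approx(expected)
        assert expected == pytest.approx(4.605, abs=5e-4)

    def test_hand_computation_negative_sign(self):
        assert orf_score(np.array([30, 10, 5])) == pytest.approx(-4.605, abs=5e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 500), min_size=3, max_size=3))
    def test_sign_flip_under_swap(self, f):
        f1, f2, f3 = f
        if f1 == f2:
            return
        a = orf_score(np.array([f1, f2, f3], dtype=float))
        b = orf_score(np.array([f2, f1, f3], dtype=float))
        assert abs(a) == pytest.approx(abs(b))
        if f3 <= min(f1, f2):
            assert a == pytest.approx(-b)

    def test_seventy_percent_codon_exclusion(self):
        # one codon with 80% of the footprints is ignored
        v = np.array([0.0, 80.0, 0.0, 5.0, 10.0, 5.0])
        assert np.allclose(codon_phase_counts(v), [5.0, 10.0, 5.0])
        # without the dominant codon the score equals the plain computation
        assert orf_score_from_profile(v) == orf_score(np.array([5.0, 10.0, 5.0]))

    def test_all_zero_flags_zero(self):
        assert orf_score_from_profile(np.zeros(9)) == 0.0


class TestFloss:
    def test_identical_distributions_zero(self):
        f = np.full(9, 1 / 9)
        assert floss_score(f, f) == 0.0

    def test_disjoint_supports_one(self):
        a = np.zeros(9); a[0] = 1.0
        b = np.zeros(9); b[8] = 1.0
        assert floss_score(a, b) == 1.0

    def test_hand_computation(self):
        f = np.array([0.5, 0.5, 0, 0, 0, 0, 0, 0, 0])
        r = np.array([0.25, 0.25, 0.5, 0, 0, 0, 0, 0, 0])
        assert floss_score(f, r) == pytest.approx(0.5)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            floss_score(np.full(9, 0.2), np.full(9, 1 / 9))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 10), min_size=9, max_size=9),
           st.lists(st.floats(0.01, 10), min_size=9, max_size=9))
    def test_bounded_symmetric_metric(self, a, b):
        f = np.array(a) / np.sum(a)
        r = np.array(b) / np.sum(b)
        s = floss_score(f, r)
        assert 0 <= s <= 1
        assert s == pytest.approx(floss_score(r, f))
        assert floss_score(f, f) == 0.0

    def test_reference_sums_to_one(self):
        ref = floss_reference([np.arange(9.0), np.ones(11)])
        assert ref.sum() == pytest.approx(1.0)

    def test_reference_recovers_generator_lengths(self, small_cfg, small_loaded):
        """Aggregated CDS read-length fractions match the configured
        footprint length distribution within multinomial error."""
        tx, profiles, _ = small_loaded
        hists = []
        for tid, t in tx.items():
            if t.is_coding:
                hists.append(profiles.length_hist(tid, "control", t.cds_start, t.cds_stop))
        ref = floss_reference(hists)
        probs = np.asarray(small_cfg.read_length_probs)[:9]
        expected = probs / probs.sum()
        n = np.sum(hists)
        assert np.all(np.abs(ref - expected) < 5 * np.sqrt(expected / n) + 0.005)


class TestKozak:
    def test_favorable_context_hand_sum(self):
        assert kozak_score("CCACCATGGC") == pytest.approx(440.65)

    def test_poor_context_hand_sum(self):
        assert kozak_score("TTTTTATGTT") == pytest.approx(-128.76)

    def test_column_max_bound_value(self):
        assert KOZAK_MAX == pytest.approx(443.79)
        best = "".join(
            max(KOZAK_MATRIX, key=lambda b: KOZAK_MATRIX[b][i])
            for i in range(5)
        ) + "ATG" + "".join(
            max(KOZAK_MATRIX, key=lambda b: KOZAK_MATRIX[b][i]) for i in (5, 6)
        )
        assert kozak_score(best) == pytest.approx(KOZAK_MAX)

    def test_random_contexts_below_bound(self):
        rng = np.random.default_rng(0)
        for _ in range(2000):
            ctx = "".join(rng.choice(list("ACGT"), 5)) + "ATG" + "".join(
                rng.choice(list("ACGT"), 2)
            )
            assert kozak_score(ctx) <= KOZAK_MAX + 1e-9

    def test_truncated_context_padded_with_n(self):
        seq = "ATGGC"  # AUG at the very 5' end: all upstream positions off-transcript
        ctx = kozak_context(seq, 0)
        assert ctx == "NNNNNATGGC"
        assert kozak_score(ctx) == pytest.approx(
            KOZAK_MATRIX["G"][5] + KOZAK_MATRIX["C"][6]
        )

    def test_rejects_off_center_context(self):
        with pytest.raises(ValueError):
            kozak_score("CCACCTTGGC")


class TestDrugResistance:
    def test_arithmetic(self):
        assert drug_resistance(100, 10) == (0.1, 10.0)

    def test_snorna_signature(self):
        assert drug_resistance(50, 50) == (1.0, 1.0)

    def test_zero_drug_censored_at_cap(self):
        frac, fold = drug_resistance(100, 0, fold_cap=1000)
        assert frac == 0.0 and fold == 1000.0

    def test_zero_control_undefined(self):
        frac, fold = drug_resistance(0, 5)
        assert np.isnan(frac) and np.isnan(fold)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.1, 1e4), st.floats(0.0, 1e4), st.floats(0.1, 100))
    def test_invariant_under_common_scaling(self, control, drug, c):
        base = drug_resistance(control, drug)
        scaled = drug_resistance(c * control, c * drug)
        assert scaled[0] == pytest.approx(base[0], rel=1e-9)
        assert scaled[1] == pytest.approx(base[1], rel=1e-9)


class TestStartAccumulation:
    def test_hand_computation(self):
        orf = ORFRecord("t", 10, 40, "ATG", 1, "5UTR")
        v = np.zeros(60)
        v[9:12] = 10.0  # 30 footprints on start +/- 1 (20 inside the ORF)
        v[20] = 40.0  # ORF total 60
        assert start_codon_accumulation(v, orf) == pytest.approx(5.0)

    def test_uniform_profile_is_one(self):
        orf = ORFRecord("t", 10, 40, "ATG", 1, "5UTR")
        v = np.ones(60)
        assert start_codon_accumulation(v, orf) == pytest.approx(1.0)

    def test_zero_counts_undefined(self):
        orf = ORFRecord("t", 10, 40, "ATG", 1, "5UTR")
        assert np.isnan(start_codon_accumulation(np.zeros(60), orf))


class TestRelativeCodonDensity:
    def test_uniform_profile_gives_one_for_any_codon(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 120))
        v = np.ones(120)
        for codon in ("ATG", "CTG", "AAA"):
            d = relative_codon_density(v, seq, codon)
            if not np.isnan(d):
                assert d == pytest.approx(1.0)

    def test_all_mass_on_single_aug_center(self):
        seq = "CCC" + "ATG" + "CCC" * 10
        v = np.zeros(len(seq))
        v[4] = 50.0  # center nucleotide of the single ATG
        n_windows = len(seq) - 2
        d = relative_codon_density(v, seq, "ATG")
        assert d == pytest.approx(50.0 / (50.0 / n_windows))

    def test_absent_codon_undefined(self):
        assert np.isnan(relative_codon_density(np.ones(30), "C" * 30, "ATG"))

    def test_planted_uorfs_raise_aug_density(self, small_cfg, small_loaded):
        """5'UTRs with translated AUG uORFs show above-average AUG density
        while a non-start codon stays near 1."""
        tx, profiles, truth = small_loaded
        uorf_tids = set(
            truth.orfs[(truth.orfs.orf_class == "uorf") & truth.orfs.translated]
            .transcript_id
        )
        aug, ctrl_codon = [], []
        for tid in uorf_tids:
            t = tx[tid]
            v = profiles.vector(tid, "control")[: t.cds_start]
            seq = t.sequence[: t.cds_start]
            if v.sum() < 20:
                continue
            d = relative_codon_density(v, seq, "ATG")
            if not np.isnan(d):
                aug.append(d)
            d2 = relative_codon_density(v, seq, "CCC")
            if not np.isnan(d2):
                ctrl_codon.append(d2)
        assert np.median(aug) > 1.5
        if ctrl_codon:
            assert np.median(ctrl_codon) < np.median(aug)
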