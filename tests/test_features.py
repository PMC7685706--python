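"""TFBS scoring, feature blocks, and the non-TF annotation features."""

import numpy as np
import pandas as pd
import pytest

from promvar.design import VariantRecord, reverse_complement
from promvar.features import (
    CONTEXTS,
    PWM,
    TF_METRICS,
    aggregate_tf_features,
    count_atg,
    count_tata,
    derived_allele,
    nontf_features,
    nucleosome_bound,
    parse_pwm_text,
    score_windows,
    tf_features,
    variant_tf_features,
    zscore_features,
)


def random_pwm(rng, name="tf", length=None, cutoff=None):
    length = length or int(rng.integers(4, 9))
    matrix = rng.normal(0, 1, size=(length, 4))
    if cutoff is None:
        cutoff = float(rng.normal(0, 1))
    return PWM(name=name, matrix=matrix, cutoff=cutoff)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestPwm:
    def test_score_is_sum_of_position_weights(self):
        matrix = np.arange(8, dtype=float).reshape(2, 4)
        pwm = PWM("t", matrix, cutoff=0.0)
        # "AG": A at pos 0 -> 0, G at pos 1 -> 6
        assert pwm.score("AG") == 6.0

    def test_all_zero_matrix_scores_zero(self):
        pwm = PWM("t", np.zeros((5, 4)), cutoff=1.0)
        assert pwm.score("ACGTA") == 0.0

    def test_wrong_window_length_rejected(self):
        pwm = PWM("t", np.zeros((3, 4)), cutoff=0.0)
        with pytest.raises(ValueError, match="length"):
            pwm.score("AC")

    def test_parse_scertf_style_text(self):
        text = "A | 1 2\nC | 3 4\nG | 5 6\nT | 7 8\n"
        pwm = parse_pwm_text(text, "abf1", cutoff=2.5)
        assert len(pwm) == 2
        assert pwm.score("TA") == 7 + 2
        assert pwm.cutoff == 2.5

    def test_parse_missing_row_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            parse_pwm_text("A | 1\nC | 2\nG | 3\n", "x", 0.0)


class TestScoreWindows:
    def test_snv_has_exactly_pwm_length_windows_per_strand(self, rng):
        pwm = random_pwm(rng, length=6)
        seq = random_seq(rng, 40)
        plus = score_windows(seq, (20, 21), pwm, "plus")
        minus = score_windows(seq, (20, 21), pwm, "minus")
        agn = score_windows(seq, (20, 21), pwm, "agnostic")
        assert len(plus) == 6 and len(minus) == 6 and len(agn) == 12

    def test_brute_force_oracle(self, rng):
        """score_windows equals a naive enumerate-and-sum implementation on
        200 random (sequence, span, PWM) triples, to 1e-12."""
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for _ in range(200):
            pwm = random_pwm(rng)
            L = len(pwm)
            seq = random_seq(rng, 60)
            s0 = int(rng.integers(L, 60 - L - 3))
            s1 = s0 + int(rng.integers(1, 4))
            got = score_windows(seq, (s0, s1), pwm, "plus")
            expected = []
            for start in range(len(seq) - L + 1):
                # keep windows overlapping [s0, s1)
                if start + L > s0 and start < s1:
                    window = seq[start : start + L]
                    expected.append(
                        sum(pwm.matrix[i, idx[b]] for i, b in enumerate(window))
                    )
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_minus_equals_plus_on_reverse_complement(self, rng):
        """Scoring the minus strand equals scoring the plus strand of the
        reverse-complemented sequence with a mirrored span."""
        for _ in range(50):
            pwm = random_pwm(rng)
            L = len(pwm)
            seq = random_seq(rng, 50)
            s0 = int(rng.integers(L, 50 - L - 2))
            s1 = s0 + int(rng.integers(1, 3))
            minus = score_windows(seq, (s0, s1), pwm, "minus")
            mirrored = (len(seq) - s1, len(seq) - s0)
            plus_rc = score_windows(reverse_complement(seq), mirrored, pwm, "plus")
            np.testing.assert_allclose(np.sort(minus), np.sort(plus_rc), atol=1e-12)

    def test_zero_length_deletion_span_still_has_windows(self, rng):
        pwm = random_pwm(rng, length=5)
        seq = random_seq(rng, 30)
        assert len(score_windows(seq, (15, 15), pwm, "plus")) > 0

    def test_insufficient_flank_rejected(self, rng):
        pwm = random_pwm(rng, length=8)
        with pytest.raises(ValueError, match="flank"):
            score_windows("ACGTACGT", (2, 3), pwm, "plus")


class TestTfFeatures:
    def test_fifteen_features_per_tf(self, rng):
        pwm = random_pwm(rng, name="abf1")
        seq = random_seq(rng, 40)
        out = tf_features(seq, (18, 19), seq, (18, 19), pwm)
        assert len(out) == 15
        assert set(out) == {
            f"abf1_{c}_{m}" for c in CONTEXTS for m in TF_METRICS
        }

    def test_identical_alleles_all_zero(self, rng):
        pwm = random_pwm(rng)
        seq = random_seq(rng, 40)
        out = tf_features(seq, (18, 19), seq, (18, 19), pwm)
        assert all(v == 0.0 for v in out.values())

    def test_strong_weak_partition(self, rng):
        """Every window is either strong or weak; their counts add to the
        total number of windows."""
        pwm = random_pwm(rng, length=5)
        seq = random_seq(rng, 40)
        scores = score_windows(seq, (18, 19), pwm, "plus")
        n_strong = (scores >= pwm.cutoff).sum()
        n_weak = (scores < pwm.cutoff).sum()
        assert n_strong + n_weak == len(scores)

    def test_empty_strong_side_gives_zero(self, rng):
        """A cutoff above every achievable score leaves the strong metrics
        at 0 and makes the weak metrics equal to unrestricted differences."""
        matrix = np.abs(np.random.default_rng(0).normal(0, 1, size=(5, 4)))
        pwm = PWM("t", matrix, cutoff=1e9)
        by = random_seq(rng, 40)
        rm = by[:20] + ("A" if by[20] != "A" else "C") + by[21:]
        out = tf_features(by, (20, 21), rm, (20, 21), pwm)
        for c in CONTEXTS:
            assert out[f"t_{c}_best_strong"] == 0.0
            assert out[f"t_{c}_mean_strong"] == 0.0
            assert out[f"t_{c}_n_strong"] == 0.0
            by_sc = score_windows(by, (20, 21), pwm, c)
            rm_sc = score_windows(rm, (20, 21), pwm, c)
            assert out[f"t_{c}_best_weak"] == pytest.approx(
                abs(rm_sc.max() - by_sc.max()), abs=1e-12
            )
            assert out[f"t_{c}_mean_weak"] == pytest.approx(
                abs(rm_sc.mean() - by_sc.mean()), abs=1e-12
            )

    def test_feature_counts_scale_with_tf_panel(self, rng):
        """196 PWMs give 196 * 15 = 2940 per-TF features and 27 aggregates."""
        pwms = [random_pwm(rng, name=f"tf{i:03d}") for i in range(196)]
        seq = random_seq(rng, 40)
        rm = seq[:20] + ("A" if seq[20] != "A" else "C") + seq[21:]
        per_tf = variant_tf_features(seq, (20, 21), rm, (20, 21), pwms)
        assert len(per_tf) == 2940
        agg = aggregate_tf_features(per_tf, [p.name for p in pwms])
        assert len(agg) == 27

    def test_single_tf_aggregate_max_equals_avg(self, rng):
        pwm = random_pwm(rng, name="only")
        seq = random_seq(rng, 40)
        rm = seq[:20] + ("A" if seq[20] != "A" else "C") + seq[21:]
        per_tf = variant_tf_features(seq, (20, 21), rm, (20, 21), [pwm])
        agg = aggregate_tf_features(per_tf, ["only"])
        for c in CONTEXTS:
            for strength in ("strong", "weak"):
                for metric in ("best", "mean"):
                    assert (
                        agg[f"agg_{c}_{strength}_{metric}_max"]
                        == agg[f"agg_{c}_{strength}_{metric}_avg"]
                    )

    def test_aggregate_n_strong_changed_sums_over_tfs(self, rng):
        per_tf = {}
        names = ["a", "b"]
        for tf, val in zip(names, (2.0, 3.0)):
            for c in CONTEXTS:
                per_tf[f"{tf}_{c}_n_strong"] = val
                for strength in ("strong", "weak"):
                    for metric in ("best", "mean"):
                        per_tf[f"{tf}_{c}_{metric}_{strength}"] = 0.0
        agg = aggregate_tf_features(per_tf, names)
        assert agg["agg_plus_n_strong_changed"] == 5.0


class TestNonTf:
    def test_tata_consensus_counts(self):
        assert count_tata("TATATAAG") == 1
        assert count_tata("GGGGGGGG") == 0
        # overlapping occurrences are both counted (offsets 0 and 2)
        assert count_tata("TATATATAAA") == 2
        assert count_tata("TATAAATAAG") == 1

    def test_tata_degenerate_positions(self):
        # consensus TATA(A/T)A(A/T)(A/G)
        assert count_tata("TATATATG") == 1
        assert count_tata("TATACAAG") == 0

    def test_atg_overlapping_count(self):
        assert count_atg("ATGATG") == 2
        assert count_atg("ATATG") == 1

    def test_nucleosome_closed_interval(self):
        assert nucleosome_bound(172, [100])  # center + 72: bound
        assert not nucleosome_bound(173, [100])  # center + 73: free
        assert nucleosome_bound(28, [100])
        assert nucleosome_bound(500, [100, 500])

    def test_derived_allele_from_outgroup(self):
        assert derived_allele("A", "G", "A") == "G"
        assert derived_allele("A", "G", "G") == "A"
        assert derived_allele("A", "G", "T") is None
        assert derived_allele("A", "G", None) is None
        assert derived_allele("A", "G", "A/G") is None
        assert derived_allele("A", "G", "A/A") == "G"

    def test_nontf_feature_block(self):
        v = VariantRecord("chrI", 300, "A", "ACG", "G1")
        out = nontf_features(
            v, "TATATAAG" * 3, "GGGG" * 6,
            nucleosome_centers=[280], outgroup_call="A", alt_frequency=0.3,
        )
        assert out["is_snv"] == 0.0
        assert out["indel_length"] == 2.0
        assert out["tata_by"] == 3.0 and out["tata_rm"] == 0.0
        assert out["tata_diff"] == 3.0
        assert out["nucleosome_bound"] == 1.0
        # derived allele is the alt, so frequency is the alt frequency
        assert out["derived_allele_frequency"] == 0.3

    def test_nontf_missing_annotations_are_nan(self):
        v = VariantRecord("chrI", 300, "A", "G", "G1")
        out = nontf_features(v, "ACGT", "GCGT")
        assert np.isnan(out["nucleosome_bound"])
        assert np.isnan(out["derived_allele_frequency"])


class TestZscore:
    def test_population_sd_hand_case(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        z, constant = zscore_features(df)
        # population SD of (1,2,3) is sqrt(2/3): z = +/- 1.2247, 0
        np.testing.assert_allclose(
            z["x"], [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )
        assert constant == []

    def test_constant_column_excluded(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "c": [5.0, 5.0]})
        z, constant = zscore_features(df)
        assert constant == ["c"] and "c" not in z.columns

    def test_idempotent_up_to_tolerance(self, rng):
        df = pd.DataFrame(rng.normal(2, 3, size=(50, 4)), columns=list("abcd"))
        z1, _ = zscore_features(df)
        z2, _ = zscore_features(z1)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)
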