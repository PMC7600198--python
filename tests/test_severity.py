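import numpy as np
import pytest

from sdhseg.severity import (
    MILD,
    SEVERE,
    classify_severity,
    confusion_stats,
    interrater_compare,
    measure_volume,
    overlap_metrics,
    severity_confusion,
    volume_agreement,
)


class TestVolume:
    @pytest.mark.parametrize(
        "n_true, spacing, expected_cc",
        [
            (1000, (1.0, 1.0, 1.0), 1.0),
            (0, (1.0, 1.0, 1.0), 0.0),
            (2000, (0.5, 0.5, 5.0), 2.5),
        ],
    )
    def test_unit_conversion(self, n_true, spacing, expected_cc):
        mask = np.zeros(4000, dtype=bool)
        mask[:n_true] = True
        assert measure_volume(mask.reshape(20, 20, 10), spacing) == pytest.approx(expected_cc)

    def test_additive_over_disjoint_masks(self, rng):
        a = rng.uniform(size=(10, 10, 5)) > 0.7
        b = (rng.uniform(size=(10, 10, 5)) > 0.7) & ~a
        sp = (0.7, 0.7, 5.0)
        assert measure_volume(a | b, sp) == pytest.approx(
            measure_volume(a, sp) + measure_volume(b, sp)
        )

    def test_positive_spacing_required(self):
        with pytest.raises(ValueError, match="spacing"):
            measure_volume(np.ones((2, 2, 2), dtype=bool), (1.0, -1.0, 5.0))


class TestSeverityClass:
    @pytest.mark.parametrize(
        "volume, expected",
        [(24.9, MILD), (25.0, SEVERE), (0.0, MILD), (300.0, SEVERE)],
    )
    def test_threshold_dichotomy(self, volume, expected):
        assert classify_severity(volume).severity == expected

    def test_invariant_severity_iff_above_threshold(self):
        for v in np.linspace(0, 60, 41):
            rep = classify_severity(float(v))
            assert (rep.severity == SEVERE) == (v >= rep.threshold_cc)


class TestOverlap:
    def test_identity_gives_ones(self, rng):
        m = rng.uniform(size=(8, 8, 3)) > 0.5
        u = np.ones_like(m)
        om = overlap_metrics(m, m, u)
        assert om.dice == om.recall == om.precision == 1.0

    def test_disjoint_gives_zero_dice(self):
        a = np.zeros((4, 4, 1), dtype=bool)
        b = np.zeros((4, 4, 1), dtype=bool)
        a[0, 0, 0] = True
        b[1, 1, 0] = True
        assert overlap_metrics(a, b, np.ones_like(a)).dice == 0.0

    def test_direct_counts(self):
        S = np.zeros((4, 4, 1), dtype=bool)
        GT = np.zeros((4, 4, 1), dtype=bool)
        S[0, :4, 0] = True
        GT[0, 2:, 0] = True
        GT[1, :2, 0] = True
        om = overlap_metrics(S, GT, np.ones_like(S))
        assert om.dice == pytest.approx(0.5)
        assert om.recall == pytest.approx(0.5)
        assert om.precision == pytest.approx(0.5)

    def test_empty_reference_metrics_absent(self):
        S = np.ones((3, 3, 1), dtype=bool)
        GT = np.zeros_like(S)
        om = overlap_metrics(S, GT, np.ones_like(S))
        assert om.dice is None and om.recall is None
        assert om.precision == 0.0

    def test_empty_segmentation_precision_absent(self):
        S = np.zeros((3, 3, 1), dtype=bool)
        GT = np.ones_like(S)
        om = overlap_metrics(S, GT, np.ones_like(S))
        assert om.precision is None

    def test_specificity_within_universe_only(self):
        shape = (6, 6, 1)
        universe = np.zeros(shape, dtype=bool)
        universe[:3] = True
        S = np.zeros(shape, dtype=bool)
        S[0] = True  # 6 FP inside the universe
        GT = np.zeros(shape, dtype=bool)
        om = overlap_metrics(S, GT, universe)
        assert om.specificity == pytest.approx(12 / 18)

    def test_geometry_mismatch(self):
        with pytest.raises(ValueError, match="geometry"):
            overlap_metrics(
                np.zeros((2, 2, 1), bool), np.zeros((3, 3, 1), bool), np.zeros((3, 3, 1), bool)
            )

    def test_brute_force_enumeration_oracle(self, rng):
        """Metrics equal explicit set-cardinality arithmetic on random masks."""
        for _ in range(200):
            S = rng.uniform(size=(10, 10, 1)) > rng.uniform(0.2, 0.8)
            GT = rng.uniform(size=(10, 10, 1)) > rng.uniform(0.2, 0.8)
            U = np.ones_like(S)
            om = overlap_metrics(S, GT, U)
            tp = sum(1 for s, g in zip(S.ravel(), GT.ravel()) if s and g)
            fp = sum(1 for s, g in zip(S.ravel(), GT.ravel()) if s and not g)
            fn = sum(1 for s, g in zip(S.ravel(), GT.ravel()) if not s and g)
            tn = S.size - tp - fp - fn
            if tp + fn:
                assert om.dice == pytest.approx(2 * tp / (2 * tp + fp + fn))
                assert om.recall == pytest.approx(tp / (tp + fn))
            if tp + fp:
                assert om.precision == pytest.approx(tp / (tp + fp))
            if tn + fp:
                assert om.specificity == pytest.approx(tn / (tn + fp))


class TestSeverityConfusion:
    def test_reported_cohort_statistics(self):
        """The published 2x2 volume-severity matrix yields recall 98.81%,
        specificity 92.31%, F1 98.22% for the severe class."""
        stats = confusion_stats(np.array([[24, 2], [1, 83]]))
        assert stats["recall_pct"] == 98.81
        assert stats["specificity_pct"] == 92.31
        assert stats["f1_pct"] == 98.22

    def test_perfect_agreement(self):
        stats = confusion_stats(np.array([[10, 0], [0, 30]]))
        assert stats["recall_pct"] == stats["specificity_pct"] == stats["f1_pct"] == 100.0

    def test_symmetric_counts(self):
        stats = confusion_stats(np.array([[1, 1], [1, 1]]))
        assert stats["recall_pct"] == 50.0
        assert stats["specificity_pct"] == 50.0

    def test_counts_from_paired_volumes(self):
        ref = [10, 30, 40, 5]
        com = [12, 20, 50, 2]
        counts, stats = severity_confusion(ref, com)
        np.testing.assert_array_equal(counts, [[2, 0], [1, 1]])
        assert stats["recall_pct"] == 50.0

    def test_transposition_swaps_recall_and_not_specificity_rule(self):
        counts = np.array([[24, 2], [1, 83]])
        swapped = confusion_stats(counts.T)
        original = confusion_stats(counts)
        # swapping reference and computed transposes the matrix: recall of
        # the severe class becomes 83/85, not 83/84
        assert swapped["recall_pct"] == pytest.approx(round(100 * 83 / 85, 2))
        assert original["recall_pct"] == pytest.approx(round(100 * 83 / 84, 2))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            severity_confusion([1, 2], [1])


class TestVolumeAgreement:
    def test_identity(self):
        ref = [10.0, 50.0, 100.0]
        out = volume_agreement(ref, ref)
        assert out["slope"] == pytest.approx(1.0)
        assert out["bias_cc"] == pytest.approx(0.0)
        assert out["loa_low_cc"] == pytest.approx(0.0)
        assert out["loa_high_cc"] == pytest.approx(0.0)

    def test_constant_shift(self):
        ref = np.array([10.0, 50.0, 100.0, 200.0])
        out = volume_agreement(ref, ref + 5.0)
        assert out["slope"] == pytest.approx(1.0)
        assert out["bias_cc"] == pytest.approx(5.0)

    def test_proportional_closed_form(self):
        ref = np.array([10.0, 50.0, 100.0, 200.0])
        out = volume_agreement(ref, 0.9 * ref)
        assert out["slope"] == pytest.approx(0.9)
        assert out["bias_cc"] == pytest.approx(-0.1 * ref.mean())
        assert out["slope_through_origin"] == pytest.approx(0.9)

    def test_zero_variance_reference(self):
        with pytest.raises(ValueError, match="variance"):
            volume_agreement([5.0, 5.0, 5.0], [4.0, 5.0, 6.0])

    def test_minimum_pairs(self):
        with pytest.raises(ValueError, match="3"):
            volume_agreement([1.0, 2.0], [1.0, 2.0])


class TestInterrater:
    def _case(self, overlap_frac, n=100):
        a = np.zeros(n, dtype=bool)
        b = np.zeros(n, dtype=bool)
        a[:50] = True
        b[50 - int(50 * overlap_frac) : 100 - int(50 * overlap_frac)] = True
        return a.reshape(10, 10, 1), b.reshape(10, 10, 1)

    def test_identical_sets_dice_one(self):
        a1, _ = self._case(1.0)
        masks_a = {"c1": a1, "c2": a1}
        u = {k: np.ones_like(a1) for k in masks_a}
        _, means = interrater_compare(masks_a, dict(masks_a), {"c1": 10.0, "c2": 40.0}, u)
        assert means["all"] == pytest.approx(1.0)
        assert means["mild"] == pytest.approx(1.0)
        assert means["severe"] == pytest.approx(1.0)

    def test_mixed_pairs_mean(self):
        a1, b1 = self._case(1.0)
        a2, b2 = self._case(0.0)
        masks_a = {"c1": a1, "c2": a2}
        masks_b = {"c1": b1, "c2": b2}
        u = {k: np.ones_like(a1) for k in masks_a}
        per_case, means = interrater_compare(masks_a, masks_b, {"c1": 30.0, "c2": 30.0}, u)
        assert per_case["c1"] == pytest.approx(1.0)
        assert per_case["c2"] == pytest.approx(0.0)
        assert means["all"] == pytest.approx(0.5)

    def test_stratum_means_hand_computed(self):
        a1, b1 = self._case(0.5)
        a2, b2 = self._case(1.0)
        a3, b3 = self._case(0.0)
        masks_a = {"c1": a1, "c2": a2, "c3": a3}
        masks_b = {"c1": b1, "c2": b2, "c3": b3}
        vols = {"c1": 10.0, "c2": 40.0, "c3": 50.0}
        u = {k: np.ones_like(a1) for k in masks_a}
        _, means = interrater_compare(masks_a, masks_b, vols, u)
        assert means["mild"] == pytest.approx(0.5)
        assert means["severe"] == pytest.approx(0.5)

    def test_unmatched_ids_error(self):
        a, b = self._case(1.0)
        with pytest.raises(ValueError, match="case ids"):
            interrater_compare({"x": a}, {"y": b}, {"x": 1.0}, {"x": np.ones_like(a)})
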