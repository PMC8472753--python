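"""Two-sided FIR scoring, causal equivalence, thresholds and logit algebra."""

import numpy as np
import pytest

from actifilt import (
    EpochSeries,
    ScoringKernel,
    SLEEP,
    WAKE,
    as_causal_fir,
    fold_bias_into_threshold,
    sazonov_alpha,
    sazonov_alpha_inverse,
    score_convolve,
    threshold_labels,
)
from actifilt.fir import causal_filter_scores


def epochs(values):
    return EpochSeries(values=values, epoch_length=60.0)


def kernel(coeffs, nf, npast, **kw):
    kw.setdefault("threshold", 1.0)
    return ScoringKernel(coefficients=coeffs, future_span=nf, past_span=npast, **kw)


class TestScoreConvolve:
    def test_identity_kernel(self):
        out = score_convolve(epochs([2, 7, 0]), kernel([1.0], 0, 0))
        np.testing.assert_allclose(out.values, [2, 7, 0])
        assert out.start_index == 0

    def test_symmetric_three_tap_hand_convolution(self):
        out = score_convolve(epochs([0, 0, 3, 0, 0]), kernel([1, 1, 1], 1, 1))
        np.testing.assert_allclose(out.values, [3, 3, 3])
        assert out.start_index == 1

    def test_asymmetric_alignment_past_vs_future(self):
        # w(lag=-1)=10 (next epoch), w(0)=1, w(+1)=0.1 (previous epoch)
        k = kernel([10.0, 1.0, 0.1], 1, 1)
        x = [1.0, 2.0, 3.0, 4.0]
        out = score_convolve(epochs(x), k)
        # score[n] = 10*x[n+1] + x[n] + 0.1*x[n-1]
        np.testing.assert_allclose(out.values, [10 * 3 + 2 + 0.1 * 1, 10 * 4 + 3 + 0.1 * 2])

    def test_constant_input_yields_bias_plus_dc_gain_times_constant(self):
        k = kernel([0.5, 0.25, 0.25], 1, 1, scale=2.0, bias=3.0)
        out = score_convolve(epochs(np.full(10, 4.0)), k)
        np.testing.assert_allclose(out.values, 3.0 + k.dc_gain * 4.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="insufficient epochs"):
            score_convolve(epochs([1, 2]), kernel([1, 1, 1], 1, 1))

    def test_linearity_of_fir_stage(self, rng, random_kernel_factory):
        k = random_kernel_factory(bias=0.0)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        a, b = 1.7, -0.4
        lhs = score_convolve(epochs(a * x + b * y + 10), k).values
        # inputs must be non-negative-free here: EpochSeries allows any reals
        rhs = (
            a * score_convolve(epochs(x), k).values
            + b * score_convolve(epochs(y), k).values
            + score_convolve(epochs(np.full(50, 10.0)), k).values
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestCausalForm:
    def test_index_relabelling(self):
        b, delay = as_causal_fir(kernel([1.0, 2.0, 3.0], 1, 1))
        np.testing.assert_allclose(b, [1, 2, 3])
        assert delay == 1

    def test_already_causal(self):
        b, delay = as_causal_fir(kernel([1.0, 2.0, 3.0], 0, 2))
        np.testing.assert_allclose(b, [1, 2, 3])
        assert delay == 0

    def test_causal_filter_plus_delay_matches_direct_convolution(
        self, rng, random_kernel_factory
    ):
        for _ in range(100):
            k = random_kernel_factory(bias=float(rng.normal()))
            x = rng.poisson(5.0, size=int(rng.integers(k.order + 1, 200))).astype(float)
            direct = score_convolve(epochs(x), k)
            causal = causal_filter_scores(epochs(x), k)
            assert direct.start_index == causal.start_index
            np.testing.assert_allclose(direct.values, causal.values, atol=1e-10)


class TestThreshold:
    def test_wake_strictly_above_threshold(self):
        from actifilt.types import ScoreSeries

        k = kernel([1.0], 0, 0, threshold=1.0, wake_above=True)
        s = ScoreSeries(values=[0.5, 1.2])
        np.testing.assert_array_equal(threshold_labels(s, k).labels, [SLEEP, WAKE])

    def test_tie_goes_to_sleep(self):
        from actifilt.types import ScoreSeries

        k = kernel([1.0], 0, 0, threshold=1.0)
        s = ScoreSeries(values=[1.0])
        assert threshold_labels(s, k).labels[0] == SLEEP

    def test_all_zero_scores_are_sleep(self):
        from actifilt.types import ScoreSeries

        k = kernel([1.0], 0, 0, threshold=1.0)
        s = ScoreSeries(values=np.zeros(20))
        assert not threshold_labels(s, k).labels.any()

    def test_wake_below_direction(self):
        from actifilt.types import ScoreSeries

        k = kernel([1.0], 0, 0, threshold=0.0, wake_above=False)
        s = ScoreSeries(values=[-0.5, 0.0, 0.5])
        np.testing.assert_array_equal(threshold_labels(s, k).labels, [WAKE, SLEEP, SLEEP])


class TestLogit:
    def test_half_maps_to_zero_and_back(self):
        assert sazonov_alpha(0.5) == pytest.approx(0.0)
        assert sazonov_alpha_inverse(0.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("p", [0.01, 0.3, 0.99])
    def test_roundtrip(self, p):
        assert sazonov_alpha_inverse(sazonov_alpha(p)) == pytest.approx(p, rel=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_boundary_rejected(self, p):
        with pytest.raises(ValueError, match="logit undefined"):
            sazonov_alpha(p)

    def test_probability_and_logit_thresholds_agree(self, rng):
        p = rng.uniform(1e-6, 1 - 1e-6, size=1000)
        np.testing.assert_array_equal(p > 0.5, sazonov_alpha(p) > 0)


class TestFoldBias:
    def test_fold_shifts_threshold_and_preserves_labels(self, rng):
        k = kernel([1.0, -0.5, 0.25], 1, 1, bias=2.0, threshold=0.0)
        folded = fold_bias_into_threshold(k)
        assert folded.bias == 0.0
        assert folded.threshold == -2.0
        x = rng.poisson(4.0, size=100).astype(float)
        a = threshold_labels(score_convolve(epochs(x), k), k)
        b = threshold_labels(score_convolve(epochs(x), folded), folded)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_fold_preserves_labels_wake_below(self, rng):
        k = kernel([-0.3, -0.2], 0, 1, bias=1.727, threshold=0.0, wake_above=False)
        folded = fold_bias_into_threshold(k)
        x = rng.poisson(3.0, size=80).astype(float)
        a = threshold_labels(score_convolve(epochs(x), k), k)
        b = threshold_labels(score_convolve(epochs(x), folded), folded)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_zero_bias_is_fixed_point_and_idempotent(self):
        k = kernel([1.0], 0, 0, bias=0.0)
        assert fold_bias_into_threshold(k) is k
        k2 = kernel([1.0], 0, 0, bias=5.0)
        once = fold_bias_into_threshold(k2)
        assert fold_bias_into_threshold(once) is once


class TestKernelInvariants:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ScoringKernel(coefficients=[1, 2], future_span=1, past_span=1)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="non-zero"):
            ScoringKernel(coefficients=[0.0, 0.0], future_span=0, past_span=1)

    def test_dc_gain_is_scale_times_sum(self):
        k = kernel([1.0, 2.0, 3.0], 1, 1, scale=0.5)
        assert k.dc_gain == pytest.approx(3.0)
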