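"""Transmittance, weakening and -3 dB cutoff analysis."""

import numpy as np
import pytest

from actifilt import (
    ScoringKernel,
    cutoff_minus3db,
    load_preset,
    published_cutoff,
    table1_presets,
    table1_report,
    transmittance,
    weakening,
)


def kernel(coeffs, nf=0, npast=None, scale=1.0, epoch_length=60.0):
    if npast is None:
        npast = len(coeffs) - 1 - nf
    return ScoringKernel(
        coefficients=coeffs,
        future_span=nf,
        past_span=npast,
        scale=scale,
        threshold=1.0,
        epoch_length=epoch_length,
    )


class TestTransmittance:
    def test_single_tap_is_all_pass(self):
        prof = transmittance(kernel([1.0]), 128)
        np.testing.assert_allclose(prof.magnitude, 1.0, atol=1e-12)
        assert cutoff_minus3db(prof) is None

    def test_two_point_average_closed_form(self):
        prof = transmittance(kernel([0.5, 0.5]), 4096)
        w = prof.frequencies_hz * 2 * np.pi * 60.0
        np.testing.assert_allclose(prof.magnitude, np.abs(np.cos(w / 2)), atol=1e-12)

    def test_magnitude_at_dc_equals_coefficient_sum(self):
        for k in table1_presets().values():
            prof = transmittance(k, 256)
            assert prof.magnitude[0] == pytest.approx(abs(k.dc_gain), rel=1e-12)

    def test_scaling_kernel_scales_magnitude_everywhere(self):
        base = kernel([0.2, 0.5, 0.3])
        scaled = kernel([0.2, 0.5, 0.3], scale=3.5)
        a = transmittance(base, 512).magnitude
        b = transmittance(scaled, 512).magnitude
        np.testing.assert_allclose(b, 3.5 * a, rtol=1e-12)

    def test_brute_force_dtft_agreement_at_random_grid_points(self, rng):
        coeffs = rng.normal(size=9)
        k = kernel(coeffs, nf=3)
        prof = transmittance(k, 2048)
        idx = rng.choice(2048, size=10, replace=False)
        w = prof.frequencies_hz[idx] * 2 * np.pi * 60.0
        brute = np.abs(
            np.sum(coeffs[None, :] * np.exp(-1j * np.outer(w, np.arange(9))), axis=1)
        )
        np.testing.assert_allclose(prof.magnitude[idx], brute, atol=1e-10)


class TestCutoff:
    def test_two_point_average_analytic_cutoff(self):
        # |cos(w/2)| = 1/sqrt(2) at w = pi/2  ->  (1/60) / 4 Hz
        cut = cutoff_minus3db(transmittance(kernel([0.5, 0.5]), 8192))
        assert cut == pytest.approx((1 / 60) / 4, rel=1e-4)

    def test_cutoff_invariant_under_kernel_scaling(self):
        a = cutoff_minus3db(transmittance(kernel([0.1, 0.4, 0.1]), 8192))
        b = cutoff_minus3db(transmittance(kernel([0.1, 0.4, 0.1], scale=17.0), 8192))
        assert a == pytest.approx(b, rel=1e-12)

    def test_grid_convergence_below_half_percent(self):
        for k in table1_presets().values():
            c1 = cutoff_minus3db(transmittance(k, 8192))
            c2 = cutoff_minus3db(transmittance(k, 16384))
            assert abs(c2 - c1) / c1 < 0.005

    def test_zero_dc_gain_has_no_passband(self):
        with pytest.raises(ValueError, match="no passband"):
            cutoff_minus3db(transmittance(kernel([1.0, -1.0]), 256))

    def test_moving_average_cutoff_under_both_conventions(self):
        from actifilt import sadeh_linear_kernel

        k = sadeh_linear_kernel("1994")
        assert cutoff_minus3db(transmittance(k, 8192)) == pytest.approx(0.000674, abs=2e-6)
        assert published_cutoff(k) == pytest.approx(0.000651, abs=1e-6)

    def test_published_convention_quantizes_to_512_grid(self):
        for k in table1_presets().values():
            cut = published_cutoff(k)
            steps = cut * 1024 * k.epoch_length
            assert steps == pytest.approx(round(steps), abs=1e-9)


class TestWeakening:
    def test_identity_kernel(self):
        assert weakening(kernel([1.0])) == 1.0

    def test_scaled_moving_average(self):
        assert weakening(kernel([1 / 11.0] * 11, scale=2.0)) == pytest.approx(2.0)

    def test_ucsd_weakening_ratio_equals_scale_ratio(self):
        a, b = load_preset("ucsd-a"), load_preset("ucsd-b")
        assert weakening(a) / weakening(b) == pytest.approx(a.scale / b.scale)


class TestUCSDFamily:
    def test_transmittance_ratio_constant_across_frequency(self):
        a, b = load_preset("ucsd-a"), load_preset("ucsd-b")
        ma = transmittance(a, 4096).magnitude
        mb = transmittance(b, 4096).magnitude
        ok = mb > 1e-12
        ratios = ma[ok] / mb[ok]
        assert np.ptp(ratios) / ratios.mean() < 1e-9
        assert ratios.mean() == pytest.approx(a.scale / b.scale, rel=1e-12)

    def test_cutoff_identical_for_all_weakenings(self):
        a, b = load_preset("ucsd-a"), load_preset("ucsd-b")
        ca = cutoff_minus3db(transmittance(a, 8192))
        cb = cutoff_minus3db(transmittance(b, 8192))
        assert ca == pytest.approx(cb, rel=1e-12)


class TestReport:
    def test_report_has_nine_rows_plus_average(self):
        df = table1_report()
        assert len(df) == 10
        assert df["preset"].iloc[-1] == "average"

    def test_periods_are_reciprocal_cutoffs(self):
        df = table1_report()
        for _, row in df.iterrows():
            m, s = row["period"].replace(" s", "").split(" m ")
            assert int(m) * 60 + int(s) == pytest.approx(1 / row["cutoff_hz"], abs=0.5)

    def test_population_sd_attached(self):
        df = table1_report()
        cuts = df["cutoff_hz"].to_numpy()[:-1]
        assert df.attrs["cutoff_sd_hz"] == pytest.approx(np.std(cuts))
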