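"""Tests for the three measurement corrections and the corrected simulator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from s2wex.corrections import (
    MixingSpec,
    S3CorrectionSpec,
    apply_s3_carryover,
    corrected_simulate,
    s3_generator,
    single_site_instant,
    single_site_linear,
    t_shift,
)
from s2wex.kinetic_core import (
    EnrichmentSpec,
    RateConstants,
    build_generator,
    equilibrium_initial_state,
    propagate,
    yields_from_state,
)


class TestSingleSite:
    def test_instant_limits(self, enrichment):
        assert single_site_instant(0.0, 2.0, enrichment) == enrichment.alpha_in
        assert single_site_instant(1e6, 2.0, enrichment) == pytest.approx(
            enrichment.alpha_f)

    def test_instant_half_life(self, enrichment):
        t = 0.4
        k = np.log(2) / t
        mid = enrichment.alpha_in + (enrichment.alpha_f - enrichment.alpha_in) / 2
        assert single_site_instant(t, k, enrichment) == pytest.approx(mid)

    def test_linear_starts_at_initial_enrichment(self, enrichment):
        assert single_site_linear(0.0, 5.0, enrichment, 0.006) == pytest.approx(
            enrichment.alpha_in)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    def test_linear_continuous_at_ramp_end(self, k):
        e = EnrichmentSpec(0.007, 0.25)
        t_m = 0.006
        below = single_site_linear(t_m, k, e, t_m)
        above = single_site_linear(np.nextafter(t_m, 1.0), k, e, t_m)
        assert abs(below - above) < 1e-12

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(k=st.floats(min_value=1e-3, max_value=1e3),
           t=st.floats(min_value=0.006, max_value=50.0),
           a_in=st.floats(min_value=0.0, max_value=0.05))
    def test_linear_equals_time_shifted_instant(self, k, t, a_in):
        e = EnrichmentSpec(a_in, 0.25)
        t_m = 0.006
        shifted = single_site_instant(t - t_shift(k, t_m), k, e)
        assert abs(single_site_linear(t, k, e, t_m) - shifted) < 1e-12


class TestTimeShift:
    def test_small_rate_limit_is_half_ramp(self):
        assert t_shift(0.0, 0.006) == pytest.approx(0.003)
        assert t_shift(1e-9, 0.006) == pytest.approx(0.003, abs=1e-12)

    def test_published_threshold_values(self):
        # exceeds 3.3 ms only above k ~ 200 s^-1
        assert t_shift(200.0, 0.006) == pytest.approx(3.2965e-3, rel=1e-4)
        assert t_shift(250.0, 0.006) == pytest.approx(3.3682e-3, rel=1e-4)
        assert t_shift(250.0, 0.006) > 3.3e-3

    def test_monotone_increasing_and_bounded(self):
        t_m = 0.006
        ks = np.logspace(-3, 4, 50)
        values = np.array([t_shift(k, t_m) for k in ks])
        assert np.all(np.diff(values) > 0)
        assert np.all(values > t_m / 2)
        assert np.all(values < t_m)

    def test_series_matches_direct_formula_at_crossover(self):
        # the series branch hands over to the exact formula continuously
        t_m = 0.006
        k_lo = (1.0 - 1e-9) * 1e-4 / t_m
        k_hi = (1.0 + 1e-9) * 1e-4 / t_m
        assert t_shift(k_lo, t_m) == pytest.approx(t_shift(k_hi, t_m), rel=1e-9)


class TestS3Carryover:
    def test_disabled_or_zero_duration_is_identity(self, sr_ph83_rates,
                                                   enrichment):
        s = equilibrium_initial_state(sr_ph83_rates, 0.007)
        for spec in (S3CorrectionSpec(enabled=False),
                     S3CorrectionSpec(duration=0.0)):
            out = apply_s3_carryover(s, spec, sr_ph83_rates, enrichment)
            np.testing.assert_array_equal(out.populations, s.populations)

    def test_zero_s3_rates_do_not_exchange(self, sr_ph83_rates, enrichment):
        r = RateConstants(1, 1, 1, 1, 0.0, 0.0)
        s = equilibrium_initial_state(r, 0.007, conformation_split=0.3)
        spec = S3CorrectionSpec(k_f_s3=0.0, k_s_s3=0.0)
        out = apply_s3_carryover(s, spec, r, enrichment)
        assert out.p_both_18() == pytest.approx(s.p_both_18(), abs=1e-12)
        assert out.p_exactly_one_18() == pytest.approx(s.p_exactly_one_18(),
                                                       abs=1e-12)

    def test_carryover_increases_yields(self, sr_ph83_rates, enrichment):
        s0 = equilibrium_initial_state(sr_ph83_rates, enrichment.alpha_in)
        G = build_generator(sr_ph83_rates, enrichment.alpha_f)
        mid = propagate(s0, G, 0.05)
        out = apply_s3_carryover(mid, S3CorrectionSpec(), sr_ph83_rates,
                                 enrichment)
        y_before = yields_from_state(mid, enrichment)
        y_after = yields_from_state(out, enrichment)
        assert y_after[0] > y_before[0]
        assert y_after[1] > y_before[1]

    def test_matches_direct_propagation_oracle(self, sr_ph83_rates, enrichment):
        # the carryover is, by definition, 10 ms of evolution under the
        # S3-rates generator; cross-check against kinetic_core.propagate
        s0 = equilibrium_initial_state(sr_ph83_rates, enrichment.alpha_in)
        G = build_generator(sr_ph83_rates, enrichment.alpha_f)
        mid = propagate(s0, G, 0.2)
        spec = S3CorrectionSpec()
        out = apply_s3_carryover(mid, spec, sr_ph83_rates, enrichment)
        G3 = s3_generator(sr_ph83_rates, spec, enrichment.alpha_f)
        ref = propagate(mid, G3, spec.duration)
        np.testing.assert_allclose(out.populations, ref.populations, atol=1e-12)


class TestCorrectedSimulate:
    times = np.geomspace(0.01, 100.0, 40)

    def test_reduces_to_closed_form_without_corrections(self, enrichment_clean,
                                                        corrections_off):
        k_f, k_s = 60.0, 0.5
        r = RateConstants(k_f, 0, k_s, 0, 0, 0)
        curve = corrected_simulate(r, enrichment_clean, times=self.times,
                                   conformation_split=0.0, **corrections_off)
        ref36 = (1 - np.exp(-k_f * self.times)) * (1 - np.exp(-k_s * self.times))
        np.testing.assert_allclose(curve.y36, ref36, atol=1e-10)

    def test_enrichment_correction_shifts_earlier(self, sr_ph83_rates,
                                                  corrections_off):
        base = corrected_simulate(sr_ph83_rates, EnrichmentSpec(0.0, 0.25),
                                  times=self.times, **corrections_off)
        shifted = corrected_simulate(sr_ph83_rates, EnrichmentSpec(0.007, 0.25),
                                     times=self.times, **corrections_off)
        assert np.all(shifted.y34 >= base.y34 - 1e-12)
        assert np.all(shifted.y36 >= base.y36 - 1e-12)

    def test_mixing_correction_shifts_later(self, sr_ph83_rates):
        e = EnrichmentSpec(0.0, 0.25)
        off = corrected_simulate(sr_ph83_rates, e, MixingSpec(mode="instant"),
                                 S3CorrectionSpec(enabled=False),
                                 times=self.times)
        on = corrected_simulate(sr_ph83_rates, e, MixingSpec(mode="shift"),
                                S3CorrectionSpec(enabled=False),
                                times=self.times)
        assert np.all(on.y34 <= off.y34 + 1e-12)
        assert np.all(on.y36 <= off.y36 + 1e-12)

    def test_s3_correction_shifts_earlier(self, sr_ph83_rates):
        e = EnrichmentSpec(0.0, 0.25)
        off = corrected_simulate(sr_ph83_rates, e, MixingSpec(mode="instant"),
                                 S3CorrectionSpec(enabled=False),
                                 times=self.times)
        on = corrected_simulate(sr_ph83_rates, e, MixingSpec(mode="instant"),
                                S3CorrectionSpec(), times=self.times)
        assert np.all(on.y34 >= off.y34 - 1e-12)
        assert np.all(on.y36 >= off.y36 - 1e-12)

    @pytest.mark.parametrize("preset_name", ["ca_pH8.6_hb", "sr_pH6.0_hb",
                                             "sr_pH8.3_hb"])
    def test_corrections_mostly_cancel(self, preset_name):
        from s2wex.cli_io import preset
        r = preset(preset_name)
        e0, e = EnrichmentSpec(0.0, 0.25), EnrichmentSpec(0.007, 0.25)
        mix_off, mix_on = MixingSpec(mode="instant"), MixingSpec()
        s3_off, s3_on = S3CorrectionSpec(enabled=False), S3CorrectionSpec()

        def max_diff(a, b):
            return max(np.abs(a.y34 - b.y34).max(), np.abs(a.y36 - b.y36).max())

        base = corrected_simulate(r, e0, mix_off, s3_off, times=self.times)
        singles = [
            corrected_simulate(r, e, mix_off, s3_off, times=self.times),
            corrected_simulate(r, e0, mix_on, s3_off, times=self.times),
            corrected_simulate(r, e0, mix_off, s3_on, times=self.times),
        ]
        all_on = corrected_simulate(r, e, mix_on, s3_on, times=self.times)
        assert max_diff(all_on, base) < max(max_diff(s, base) for s in singles)

    def test_times_before_shift_clamp_to_zero(self, sr_ph83_rates, enrichment):
        curve = corrected_simulate(
            sr_ph83_rates, enrichment, MixingSpec(),
            S3CorrectionSpec(enabled=False),
            times=np.array([0.001, 0.002, 0.01]),
        )
        # both pre-shift points see zero exchange time, hence equal yields
        assert curve.y34[0] == pytest.approx(curve.y34[1], abs=1e-12)

    def test_exact_single_site_mode_rejected_for_full_model(self, sr_ph83_rates,
                                                            enrichment):
        with pytest.raises(ValueError, match="single-site"):
            corrected_simulate(sr_ph83_rates, enrichment,
                               MixingSpec(mode="exact-single-site"),
                               times=self.times)

    def test_shift_rate_flag_uses_rate_dependent_shift(self, sr_ph83_rates,
                                                       enrichment):
        fixed = corrected_simulate(sr_ph83_rates, enrichment,
                                   MixingSpec(), S3CorrectionSpec(enabled=False),
                                   times=self.times)
        derived = corrected_simulate(
            sr_ph83_rates, enrichment,
            MixingSpec(shift_rate=250.0), S3CorrectionSpec(enabled=False),
            times=self.times)
        # t_k(250) > 3 ms, so the derived-shift curve lags the fixed-shift one
        assert np.all(derived.y36 <= fixed.y36 + 1e-12)
        assert np.any(derived.y36 < fixed.y36)
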