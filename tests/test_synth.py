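from dataclasses import replace

import numpy as np
import pytest

from corti.clicks import detect_first_peak, first_period, in_phase_time, polarity_flip_check
from corti.latency import latency_from_phase_slope, phase_difference_curve
from corti.report import click_feature_table, tone_latency_table, tone_latency_summary
from corti.spectra import best_frequency, compression_db
from corti.synth import gerbil_params, make_click_pair, make_cohort, make_spectra


def at_bf(spec, bf):
    return int(np.argmin(np.abs(spec.frequency_hz - bf)))


def clone(params, **kw):
    return replace(params, _active_offset_oct=params._active_offset_oct, **kw)


class TestToneDescriptors:
    def test_bf_at_low_level_is_26khz(self, gerbil_nf):
        _, bm, _ = make_spectra(gerbil_nf, "g01", 30.0)
        assert best_frequency(bm) == pytest.approx(26_000.0)

    @pytest.mark.parametrize("level,expected", [(30.0, 10.0), (80.0, 1.5)])
    def test_ratio_endpoints_at_bf(self, gerbil_nf, level, expected):
        rl, bm, _ = make_spectra(gerbil_nf, "g01", level)
        i = at_bf(bm, 26_000.0)
        assert rl.magnitude_nm[i] / bm.magnitude_nm[i] == pytest.approx(expected, rel=0.01)

    def test_phase_law_reaches_half_cycle_at_dc(self, gerbil_nf):
        # at 10 Hz the law sits within 0.1 deg of full opposition
        assert 360 * gerbil_nf.delta_phi_cycles(10.0) == pytest.approx(180.0, abs=0.1)
        assert float(gerbil_nf.delta_phi_cycles(0.0)) == 0.5

    def test_bm_compression_at_bf(self, gerbil_nf):
        _, bm30, _ = make_spectra(gerbil_nf, "g01", 30.0)
        _, bm80, _ = make_spectra(gerbil_nf, "g01", 80.0)
        i = at_bf(bm30, 26_000.0)
        fold = bm80.magnitude_nm[i] / bm30.magnitude_nm[i]
        assert compression_db(30, 80, fold) == pytest.approx(23.0, abs=0.5)

    def test_rl_compression_consistent_with_ratio_endpoints(self, gerbil_nf):
        """BM compression c and ratio endpoints (10 -> 1.5) force RL
        compression of c + 20*log10(10/1.5) ~= 39.5 dB."""
        rl30, bm30, _ = make_spectra(gerbil_nf, "g01", 30.0)
        rl80, _, _ = make_spectra(gerbil_nf, "g01", 80.0)
        i = at_bf(bm30, 26_000.0)
        fold = rl80.magnitude_nm[i] / rl30.magnitude_nm[i]
        expected = 23.0 + 20 * np.log10(10 / 1.5)
        assert compression_db(30, 80, fold) == pytest.approx(expected, abs=1.0)

    def test_low_frequency_opposition(self, gerbil_nf):
        rl, bm, _ = make_spectra(gerbil_nf, "g01", 70.0)
        curve = phase_difference_curve(rl, bm)
        low = curve.frequency_hz < 5000
        assert np.all(curve.phase_diff_cycles[low] > 0.4)

    def test_ratio_largest_far_below_bf_at_high_level(self, gerbil_nf):
        rl, bm, _ = make_spectra(gerbil_nf, "g01", 80.0)
        r = rl.magnitude_nm / bm.magnitude_nm
        i_low = at_bf(bm, 4000.0)
        i_bf = at_bf(bm, 26_000.0)
        assert r[i_low] > r[i_bf]
        assert np.argmax(r) < i_bf


class TestPostmortemDescriptors:
    def test_linear_growth_equal_db_spacing(self, gerbil_nf):
        mags = []
        for level in (50.0, 60.0, 70.0, 80.0):
            _, bm, _ = make_spectra(gerbil_nf, "g01", level, state="postmortem")
            mags.append(bm.magnitude_nm)
        steps = [20 * np.log10(b / a) for a, b in zip(mags, mags[1:])]
        for s in steps:
            assert np.allclose(s, 10.0, atol=1e-9)

    def test_rl_smaller_than_bm(self, gerbil_nf):
        rl, bm, _ = make_spectra(gerbil_nf, "g01", 70.0, state="postmortem")
        assert np.all(rl.magnitude_nm < bm.magnitude_nm)

    def test_phase_difference_is_passive_lag_without_opposition(self, gerbil_nf):
        rl, bm, _ = make_spectra(gerbil_nf, "g01", 70.0, state="postmortem")
        curve = phase_difference_curve(rl, bm)
        expected = -curve.frequency_hz * gerbil_nf.delta_pm_s
        assert np.allclose(curve.phase_diff_cycles, expected, atol=1e-9)

    def test_postmortem_latency_recovers_passive_lag(self, gerbil_nf):
        # RL trails BM by the passive coupling lag delta_pm = 5 us
        table = tone_latency_table(
            [s for s in sum((make_spectra(gerbil_nf, "g01", lv, state="postmortem")
                             for lv in (30.0, 70.0)), ())],
            state="postmortem",
        )
        assert table.delta_tau_us.iloc[0] == pytest.approx(5.0, abs=0.01)

    def test_bf_gain_lost_near_peak_only(self, gerbil_nf):
        _, bm_s, _ = make_spectra(gerbil_nf, "g01", 30.0)
        _, bm_p, _ = make_spectra(gerbil_nf, "g01", 30.0, state="postmortem")
        i = at_bf(bm_s, 26_000.0)
        j = at_bf(bm_s, 4000.0)
        drop_bf = 20 * np.log10(bm_s.magnitude_nm[i] / bm_p.magnitude_nm[i])
        drop_low = 20 * np.log10(bm_s.magnitude_nm[j] / bm_p.magnitude_nm[j])
        assert drop_bf > 25
        assert abs(drop_low) < 3


class TestClickDescriptors:
    def test_opposite_initial_polarities(self, gerbil_nf):
        rl, bm = make_click_pair(gerbil_nf, "g01", 90.0)
        frl, fbm = detect_first_peak(rl), detect_first_peak(bm)
        assert fbm.first_peak_sign == 1   # BM toward scala vestibuli
        assert frl.first_peak_sign == -1  # RL toward scala tympani

    def test_rl_first_peak_near_0p4_ms(self, gerbil_nf):
        rl, _ = make_click_pair(gerbil_nf, "g01", 90.0)
        t_b = detect_first_peak(rl).first_peak_time_s
        assert t_b == pytest.approx(0.40e-3, abs=0.01e-3)

    def test_peak_magnitude_ratio_about_eight(self, gerbil_nf):
        rl, bm = make_click_pair(gerbil_nf, "g01", 90.0)
        frl, fbm = detect_first_peak(rl), detect_first_peak(bm)
        ratio = frl.first_peak_magnitude_nm / fbm.first_peak_magnitude_nm
        assert ratio == pytest.approx(8.0, rel=0.10)

    def test_rl_first_period_exceeds_bm(self, gerbil_nf):
        rl, bm = make_click_pair(gerbil_nf, "g01", 90.0)
        frl, fbm = detect_first_peak(rl), detect_first_peak(bm)
        assert first_period(rl, frl) > first_period(bm, fbm)

    def test_in_phase_time_follows_first_peaks(self, gerbil_nf):
        rl, bm = make_click_pair(gerbil_nf, "g01", 90.0)
        frl, fbm = detect_first_peak(rl), detect_first_peak(bm)
        t_c = in_phase_time(rl, bm, frl, fbm)
        assert t_c > max(frl.first_peak_time_s, fbm.first_peak_time_s)
        assert t_c < 0.6e-3

    def test_postmortem_polarity_flip_and_comparable_magnitude(self, gerbil_nf):
        rl_s, _ = make_click_pair(gerbil_nf, "g01", 90.0)
        rl_p, bm_p = make_click_pair(gerbil_nf, "g01", 90.0, state="postmortem")
        f_s, f_p = detect_first_peak(rl_s), detect_first_peak(rl_p)
        assert polarity_flip_check(f_s, f_p)
        assert f_p.first_peak_sign == 1
        fb = detect_first_peak(bm_p)
        assert 0.3 < f_p.first_peak_magnitude_nm / fb.first_peak_magnitude_nm < 3.0

    def test_pure_delay_degenerate_params_recover_tau(self, gerbil_nf):
        """With the ratio and tilt removed the RL click is an inverted,
        delayed copy of the BM click; first-peak timing must recover the
        injected delay to sub-sample accuracy."""
        p = clone(gerbil_nf, click_ratio=1.0, click_tilt=0.0)
        for tau_us in (10.0, 20.0, 32.6, 50.0):
            p2 = clone(p, delta_tau_click_s=tau_us * 1e-6)
            rl, bm = make_click_pair(p2, "g01", 90.0)
            d = detect_first_peak(rl).first_peak_time_s - detect_first_peak(bm).first_peak_time_s
            assert abs(d - tau_us * 1e-6) < 1e-6

    def test_low_level_initial_peak_undetectable(self, gerbil_default):
        _, bm = make_click_pair(gerbil_default, "g01", 50.0)
        with pytest.raises(ValueError):
            detect_first_peak(bm)


class TestCohort:
    def test_determinism_identical_reruns(self, gerbil_default):
        a = make_cohort(gerbil_default, 2, seed=5, click_levels=(90.0,))
        b = make_cohort(gerbil_default, 2, seed=5, click_levels=(90.0,))
        for sa, sb in zip(a.spectra, b.spectra):
            assert np.array_equal(sa.magnitude_nm, sb.magnitude_nm)
            assert np.array_equal(sa.phase_cycles, sb.phase_cycles)
        for ca, cb in zip(a.clicks, b.clicks):
            assert np.array_equal(ca.displacement_nm, cb.displacement_nm)

    def test_record_count_matches_study_design(self, gerbil_default):
        cohort = make_cohort(gerbil_default, 7, levels=(50, 60, 70, 80), seed=1)
        table = tone_latency_table(cohort.spectra, levels=(50, 60, 70, 80))
        assert len(table) == 28  # 7 animals x 4 levels

    def test_animals_differ(self, gerbil_default):
        cohort = make_cohort(gerbil_default, 2, levels=(70.0,), seed=3)
        a = cohort.spectra_by(animal_id="g01", structure="BM", level_db_spl=70.0)[0]
        b = cohort.spectra_by(animal_id="g02", structure="BM", level_db_spl=70.0)[0]
        assert not np.allclose(a.magnitude_nm, b.magnitude_nm)


class TestParameterRecovery:
    @pytest.mark.parametrize("tau_us", [10.0, 17.9, 25.0])
    def test_tone_latency_recovery(self, tau_us):
        params = gerbil_params(delta_tau_tone_s=tau_us * 1e-6, seed=0)
        cohort = make_cohort(params, 7, levels=(50, 60, 70, 80), seed=11)
        table = tone_latency_table(cohort.spectra, levels=(50, 60, 70, 80))
        g = tone_latency_summary(table)
        assert g.n == 28
        assert abs(g.mean - tau_us) < 2 * max(g.sem, 1e-3)

    def test_click_latency_recovery(self):
        params = gerbil_params(delta_tau_click_s=32.6e-6)
        cohort = make_cohort(params, 10, levels=(), seed=21, click_levels=(90.0,))
        table = click_feature_table(cohort.clicks)
        assert len(table) == 10
        assert abs(table.delta_tau_us.mean() - 32.6) < 2.0
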