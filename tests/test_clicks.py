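import numpy as np
import pytest

from corti.clicks import (
    ClickResponse,
    detect_first_peak,
    first_period,
    in_phase_time,
    latency_difference_click,
    polarity_flip_check,
)

FS = 200_000.0
DT = 1.0 / FS


def response(x, structure="BM", t0=0.0, **kw):
    x = np.asarray(x, float)
    t = t0 + DT * np.arange(x.size)
    defaults = dict(state="sensitive", level_db_p=90.0, animal_id="a1")
    defaults.update(kw)
    return ClickResponse(structure=structure, time_s=t, displacement_nm=x, **defaults)


def triangle(n=400, peak=80, width=12, amp=1.0):
    x = np.zeros(n)
    ramp = np.linspace(0, amp, width + 1)
    x[peak - width:peak + 1] = ramp
    x[peak:peak + width + 1] = ramp[::-1]
    return x


def shifted_copy(x, tau):
    """Exact sub-sample delay via Fourier phase shift (periodic)."""
    n = x.size
    f = np.fft.rfftfreq(n, DT)
    return np.fft.irfft(np.fft.rfft(x) * np.exp(-2j * np.pi * f * tau), n=n)


def ringing(n=1024, f0=26_000.0, t_on=1e-3, decay=3e-4):
    t = DT * np.arange(n)
    env = np.where(t >= t_on, np.exp(-(t - t_on) / decay), 0.0)
    return env * np.sin(2 * np.pi * f0 * (t - t_on))


def smooth_ringing(n=1024, f0=26_000.0, t_on=1e-3, decay=3e-4):
    """Gamma-envelope tone burst: C2-smooth onset, safe to Fourier-shift."""
    t = DT * np.arange(n)
    u = np.maximum(t - t_on, 0.0)
    env = (u / 1e-4) ** 3 * np.exp(-u / decay)
    return env * np.sin(2 * np.pi * f0 * u)


class TestDetectFirstPeak:
    def test_triangle_apex_time_and_sign(self):
        feats = detect_first_peak(response(triangle()))
        assert feats.first_peak_time_s == pytest.approx(80 * DT, abs=1e-12)
        assert feats.first_peak_sign == 1

    def test_negated_waveform_flips_sign_only(self):
        feats = detect_first_peak(response(-triangle()))
        assert feats.first_peak_time_s == pytest.approx(80 * DT, abs=1e-12)
        assert feats.first_peak_sign == -1

    def test_time_shift_equivariance(self):
        x = ringing()
        t1 = detect_first_peak(response(x)).first_peak_time_s
        k = 37
        t2 = detect_first_peak(response(np.roll(x, k))).first_peak_time_s
        assert t2 - t1 == pytest.approx(k * DT, abs=1e-9)

    def test_amplitude_invariance(self):
        x = ringing()
        f1 = detect_first_peak(response(x))
        f2 = detect_first_peak(response(137.0 * x))
        assert f2.first_peak_time_s == pytest.approx(f1.first_peak_time_s, abs=1e-12)
        assert f2.first_peak_sign == f1.first_peak_sign

    def test_subthreshold_record_rejected(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 1.0, 1000)
        with pytest.raises(ValueError):
            detect_first_peak(response(noise), threshold_mult=30.0)


class TestLatencyDifference:
    def test_plain_difference(self):
        rl = detect_first_peak(response(triangle(peak=86), "RL"))
        bm = detect_first_peak(response(triangle(peak=80)))
        assert latency_difference_click(rl, bm) == pytest.approx(30e-6, abs=1e-12)

    def test_identical_waveforms_give_zero(self):
        f1 = detect_first_peak(response(ringing(), "RL"))
        f2 = detect_first_peak(response(ringing()))
        assert latency_difference_click(f1, f2) == 0.0

    @pytest.mark.parametrize("tau_us", [10.0, 20.0, 32.6, 50.0])
    def test_pure_delay_pair_oracle(self, tau_us):
        """BM = w(t), RL = -w(t - tau): first peaks must differ by tau to
        sub-sample accuracy at 200 kHz sampling."""
        tau = tau_us * 1e-6
        w = smooth_ringing()
        bm = response(w)
        rl = response(-shifted_copy(w, tau), "RL")
        d = latency_difference_click(detect_first_peak(rl), detect_first_peak(bm))
        assert abs(d - tau) < 1e-6


class TestFirstPeriod:
    def test_decaying_bf_ringing(self):
        resp = response(ringing(f0=26_000.0))
        period = first_period(resp, detect_first_peak(resp))
        assert period == pytest.approx(1 / 26_000.0, abs=0.5e-6)

    def test_low_frequency_tone(self):
        resp = response(ringing(f0=10_000.0, decay=1e-3))
        period = first_period(resp, detect_first_peak(resp))
        assert period == pytest.approx(100e-6, abs=0.5e-6)

    def test_missing_second_extremum_flagged(self):
        resp = response(triangle())
        with pytest.raises(ValueError):
            first_period(resp, detect_first_peak(resp))


class TestInPhaseTime:
    def test_identical_records_align_immediately(self):
        x = ringing()
        rl, bm = response(x, "RL"), response(x)
        feats = detect_first_peak(bm)
        t_c = in_phase_time(rl, bm, feats, feats)
        assert t_c == pytest.approx(feats.first_peak_time_s, abs=2 * DT)

    def test_constructed_drift_crossing(self):
        """Antiphase 20 kHz tones whose phase offset decays linearly to zero
        at 0.5 ms must be declared in phase at 0.5 ms."""
        n = 1024
        t0 = -0.6e-3  # pre-trigger baseline
        t = t0 + DT * np.arange(n)
        t_align = 0.5e-3
        offset = 0.5 * np.clip(1 - t / t_align, 0, None)  # cycles
        env = np.where(t > 1e-4, 1.0, 0.0) * np.exp(-np.maximum(t, 0) / 2e-3)
        bm = response(env * np.cos(2 * np.pi * 20_000 * t), t0=t0)
        rl = response(env * np.cos(2 * np.pi * (20_000 * t + offset)), "RL", t0=t0)
        t_c = in_phase_time(rl, bm)
        assert t_c == pytest.approx(t_align, abs=5e-6)

    def test_never_aligning_records_flagged(self):
        t0 = -0.6e-3
        t = t0 + DT * np.arange(1024)
        env = np.where(t > 1e-4, 1.0, 0.0) * np.exp(-np.maximum(t, 0) / 2e-3)
        bm = response(env * np.cos(2 * np.pi * 20_000 * t), t0=t0)
        rl = response(-env * np.cos(2 * np.pi * 20_000 * t), "RL", t0=t0)
        with pytest.raises(ValueError):
            in_phase_time(rl, bm)


class TestPolarity:
    def test_flip_detected(self):
        neg = detect_first_peak(response(-triangle(), "RL"))
        pos = detect_first_peak(response(triangle(), "RL", state="postmortem"))
        assert polarity_flip_check(neg, pos)

    def test_same_sign_not_a_flip(self):
        a = detect_first_peak(response(triangle(), "RL"))
        b = detect_first_peak(response(triangle(), "RL", state="postmortem"))
        assert not polarity_flip_check(a, b)


class TestClickResponseValidation:
    def test_nonuniform_sampling_rejected(self):
        t = DT * np.arange(100.0)
        t[50] += 1e-6
        with pytest.raises(ValueError):
            ClickResponse("BM", "sensitive", 90.0, t, np.zeros(100))
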