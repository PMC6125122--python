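"""Synthetic two-component cochlea: calibrated generator of vibrometry data.

This module does not solve cochlear hydrodynamics. It is a *descriptor*
model: a parametric generator whose defaults are calibrated to the measured
summary statistics of basal-turn gerbil (and mouse) vibrometry, so that
every analysis stage in the package can be exercised end-to-end with known
ground truth. The encoded descriptors are:

* a sharply tuned, compressive basilar-membrane (BM) response peaking at the
  best frequency (BF, 26 kHz gerbil preset) at low level, broadening and
  shifting down in frequency as level rises, with ~23 dB compression at BF
  over 30..80 dB SPL and linear growth well below BF;
* a reticular-lamina (RL) response linked to the BM by a magnitude ratio law
  R(f, level) -- 10 at BF/30 dB SPL falling to 1.5 at 80 dB SPL, largest far
  below BF at high level -- and by the phase-difference law
  ``dphi(f) = 0.5 - f*delta_tau`` cycles: half-cycle opposition at low
  frequency decaying with frequency at the fixed latency difference;
* a postmortem mode in which the active terms vanish: the BM loses its
  near-BF gain (linear growth, broad low-shifted peak) and the RL passively
  follows the BM with a fraction beta of its amplitude and a few
  microseconds of passive lag -- no half-cycle opposition;
* click responses synthesized by inverse Fourier transform of the frequency
  response times a 10-us pulse spectrum at 200 kHz sampling, with a bulk
  stimulus-path delay placing the first peaks near 0.4 ms, opposite initial
  polarities and an ~8-fold RL/BM first-peak ratio in the sensitive state.

All functional forms (log-Gaussian filters, linear-in-level gain laws) are
package plumbing; only the calibration constants above carry meaning.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .clicks import ClickResponse
from .spectra import VibrationSpectrum

__all__ = [
    "CochleaModelParams",
    "gerbil_params",
    "mouse_params",
    "make_spectra",
    "make_click_pair",
    "make_cohort",
    "Cohort",
]

_LN10_20 = np.log(10.0) / 20.0


@dataclass
class CochleaModelParams:
    """Full parameterization of the synthetic two-component generator."""

    species: str = "gerbil"
    bf_hz: float = 26000.0

    # tone frequency grid (measurement sweep)
    f_min_hz: float = 1800.0
    f_max_hz: float = 40000.0
    f_step_hz: float = 200.0

    # passive BM filter: quadratic-in-log-frequency magnitude (dB), centered
    # below BF, plus an extra high-side rolloff above BF
    passive_center_rel: float = 0.6
    passive_curv_db_oct2: float = 6.8
    high_rolloff_db_oct2: float = 40.0

    # active near-BF gain: A(level) = gain - c_bm*(level-30)/50 dB, applied
    # through a log-Gaussian weight of width active_width_oct around BF
    active_gain_db: float = 35.0
    c_bm_db: float = 23.0
    # narrow enough that the low-level response occupies ~0.2 mm of place
    active_width_oct: float = 0.12

    # BM traveling-wave phase (cycles): -f*tau0 - disp_cycles*(f/bf)**disp_order
    tau0_s: float = 30e-6
    disp_cycles: float = 0.57
    disp_order: float = 3.0

    # RL/BM magnitude ratio law: log-level interpolation between the BF
    # endpoints, plus a low-frequency term growing with level
    ratio_bf_lo: float = 10.0
    ratio_bf_hi: float = 1.5
    level_lo_db: float = 30.0
    level_hi_db: float = 80.0
    lf_ratio_gain: float = 0.5

    # latency differences (tone and click stimuli differ, as measured)
    delta_tau_tone_s: float = 17.9e-6
    delta_tau_click_s: float = 32.6e-6

    # stapes reference: flat, linear, small fixed delay
    stapes_scale_nm: float = 1e-4
    stapes_tau_s: float = 15e-6

    # absolute scale: BM displacement at (BF, 30 dB SPL), sensitive
    bm_ref_nm: float = 0.3

    # postmortem passive coupling: RL = beta * BM * exp(-i*2*pi*f*delta_pm)
    beta_pm: float = 0.7
    delta_pm_s: float = 5e-6

    # click synthesis
    click_fs_hz: float = 200000.0
    click_dur_s: float = 5e-3
    click_pre_s: float = 5e-4
    pulse_dur_s: float = 10e-6
    t_me_s: float = 371.6e-6  # bulk speaker/middle-ear delay: RL first peak ~0.40 ms
    click_gain: float = 1.7566e-3  # abs scale: BM click max ~6 nm at 90 dB-p
    click_ratio: float = 8.0  # RL/BM first-peak magnitude ratio at 90 dB-p
    click_tilt: float = 0.3  # low-frequency tilt of the RL click spectrum
    click_tilt_ref_hz: float = 13700.0  # tilt pivot: ~the first-peak carrier
    click_noise_nm: float = 0.05

    # measurement noise and biological variability
    sigma_phase_cycles: float = 0.02
    sigma_mag_log10: float = 0.05
    noise_floor_nm: float = 0.005
    bf_jitter_rel: float = 0.03
    # optional per-animal latency spread; off by default so the cohort SEM
    # reflects measurement noise alone and the grouped mean stays unbiased
    tau_jitter_rel: float = 0.0
    seed: int = 0

    _active_offset_oct: Optional[float] = field(default=None, repr=False)

    # ---- derived helpers -------------------------------------------------

    def frequency_grid(self) -> np.ndarray:
        n = int(round((self.f_max_hz - self.f_min_hz) / self.f_step_hz))
        return self.f_min_hz + self.f_step_hz * np.arange(n + 1)

    def noise_free(self) -> "CochleaModelParams":
        """Copy with every stochastic term switched off."""
        return replace(
            self,
            sigma_phase_cycles=0.0,
            sigma_mag_log10=0.0,
            bf_jitter_rel=0.0,
            tau_jitter_rel=0.0,
            click_noise_nm=0.0,
            _active_offset_oct=self._active_offset_oct,
        )

    def active_level_db(self, level_db: float) -> float:
        span = self.level_hi_db - self.level_lo_db
        a = self.active_gain_db - self.c_bm_db * (level_db - self.level_lo_db) / span
        return max(0.0, a)

    def _offset(self) -> float:
        """Center offset (octaves) of the active weight, solved so the total
        magnitude curve is stationary exactly at BF at the low level."""
        if self._active_offset_oct is None:
            g0 = self.active_gain_db
            s2 = self.active_width_oct**2
            xc = np.log2(self.passive_center_rel)
            slope = -2.0 * self.passive_curv_db_oct2 * (0.0 - xc)  # dB/oct at BF

            def grad(delta: float) -> float:
                return slope + g0 * (delta / s2) * np.exp(-(delta**2) / (2 * s2))

            self._active_offset_oct = brentq(grad, 1e-6, self.active_width_oct)
        return self._active_offset_oct

    def _passive_db(self, f_hz: np.ndarray, bf: float) -> np.ndarray:
        x = np.log2(f_hz / bf)
        xc = np.log2(self.passive_center_rel)
        out = -self.passive_curv_db_oct2 * (x - xc) ** 2
        out -= self.high_rolloff_db_oct2 * np.maximum(0.0, x) ** 2
        return out

    def bm_magnitude_nm(
        self, f_hz, level_db: float, bf_hz: Optional[float] = None, active: bool = True
    ) -> np.ndarray:
        """Deterministic BM displacement magnitude model (nm)."""
        bf = self.bf_hz if bf_hz is None else bf_hz
        f = np.asarray(f_hz, dtype=float)
        x = np.log2(f / bf)
        delta = self._offset()
        w = np.exp(-((x - delta) ** 2) / (2 * self.active_width_oct**2))
        a_db = self.active_level_db(level_db) if active else 0.0
        db = (
            20.0 * np.log10(self.bm_ref_nm)
            + (level_db - self.level_lo_db)
            + self._passive_db(f, bf)
            - self._passive_db(np.asarray([bf]), bf)[0]
            + a_db * w
            - self.active_gain_db * np.exp(-(delta**2) / (2 * self.active_width_oct**2))
        )
        return 10.0 ** (db / 20.0)

    def bm_phase_cycles(self, f_hz, bf_hz: Optional[float] = None) -> np.ndarray:
        bf = self.bf_hz if bf_hz is None else bf_hz
        f = np.asarray(f_hz, dtype=float)
        return -f * self.tau0_s - self.disp_cycles * (f / bf) ** self.disp_order

    def ratio(self, f_hz, level_db: float, bf_hz: Optional[float] = None) -> np.ndarray:
        """RL/BM magnitude ratio law R(f, level)."""
        bf = self.bf_hz if bf_hz is None else bf_hz
        f = np.asarray(f_hz, dtype=float)
        u = (level_db - self.level_lo_db) / (self.level_hi_db - self.level_lo_db)
        log_r_bf = (1 - u) * np.log10(self.ratio_bf_lo) + u * np.log10(self.ratio_bf_hi)
        lf = 1.0 + self.lf_ratio_gain * max(0.0, u) * np.maximum(0.0, np.log2(bf / f)) ** 2
        return 10.0**log_r_bf * lf

    def delta_phi_cycles(self, f_hz, delta_tau_s: Optional[float] = None) -> np.ndarray:
        """Sensitive-state RL-BM phase-difference law (cycles)."""
        tau = self.delta_tau_tone_s if delta_tau_s is None else delta_tau_s
        return 0.5 - np.asarray(f_hz, dtype=float) * tau


def gerbil_params(**overrides) -> CochleaModelParams:
    return CochleaModelParams(**overrides)


def mouse_params(**overrides) -> CochleaModelParams:
    """Mouse preset: higher BF, shorter latency difference, wider sweep."""
    defaults = dict(
        species="mouse",
        bf_hz=48000.0,
        f_min_hz=3000.0,
        f_max_hz=63900.0,
        f_step_hz=300.0,
        delta_tau_tone_s=12.1e-6,
        delta_tau_click_s=20e-6,
        beta_pm=0.9,
    )
    defaults.update(overrides)
    return CochleaModelParams(**defaults)


# ---- per-animal and per-measurement randomness ---------------------------


def _aid_hash(animal_id: str) -> int:
    return zlib.crc32(animal_id.encode()) & 0x7FFFFFFF


def _animal_draws(params: CochleaModelParams, animal_id: str):
    """(bf, tau_tone, tau_click) for one animal; deterministic in (seed, id)."""
    rng = np.random.default_rng([params.seed, _aid_hash(animal_id)])
    z = rng.standard_normal(3)
    bf = params.bf_hz * np.exp(params.bf_jitter_rel * z[0])
    tau_tone = params.delta_tau_tone_s * (1.0 + params.tau_jitter_rel * z[1])
    tau_click = params.delta_tau_click_s * (1.0 + params.tau_jitter_rel * z[2])
    return bf, tau_tone, tau_click


def _meas_rng(params, animal_id, level_db, state, kind: int) -> np.random.Generator:
    state_code = 0 if state == "sensitive" else 1
    return np.random.default_rng(
        [params.seed, _aid_hash(animal_id), int(round(level_db * 10)), state_code, kind]
    )


def _noisy(mag, phase, rng, params):
    if params.sigma_mag_log10 > 0:
        mag = mag * 10.0 ** (params.sigma_mag_log10 * rng.standard_normal(mag.size))
    if params.sigma_phase_cycles > 0:
        phase = phase + params.sigma_phase_cycles * rng.standard_normal(phase.size)
    return mag, phase


# ---- tone spectra --------------------------------------------------------


def make_spectra(
    params: CochleaModelParams,
    animal_id: str,
    level_db_spl: float,
    state: str = "sensitive",
    frequency_hz: Optional[np.ndarray] = None,
):
    """Synthesize one (RL, BM, stapes) spectrum triple.

    Deterministic given (params.seed, animal_id, level, state). The sensitive
    RL is the BM response scaled by the ratio law and rotated by the
    half-cycle-minus-delay phase law; postmortem zeroes the active terms.
    """
    if state not in ("sensitive", "postmortem"):
        raise ValueError("state must be 'sensitive' or 'postmortem'")
    f = params.frequency_grid() if frequency_hz is None else np.asarray(frequency_hz, float)
    bf_a, tau_tone_a, _ = _animal_draws(params, animal_id)

    active = state == "sensitive"
    bm_mag = params.bm_magnitude_nm(f, level_db_spl, bf_hz=bf_a, active=active)
    bm_phase = params.bm_phase_cycles(f, bf_hz=bf_a)

    if active:
        rl_mag = bm_mag * params.ratio(f, level_db_spl, bf_hz=bf_a)
        rl_phase = bm_phase + params.delta_phi_cycles(f, tau_tone_a)
    else:
        rl_mag = params.beta_pm * bm_mag
        rl_phase = bm_phase - f * params.delta_pm_s

    st_mag = np.full_like(f, params.stapes_scale_nm * 10.0 ** (level_db_spl / 20.0))
    st_phase = -f * params.stapes_tau_s

    floor = np.full_like(f, params.noise_floor_nm)
    out = []
    for structure, mag, phase, kind in (
        ("RL", rl_mag, rl_phase, 0),
        ("BM", bm_mag, bm_phase, 1),
        ("stapes", st_mag, st_phase, 2),
    ):
        rng = _meas_rng(params, animal_id, level_db_spl, state, kind)
        m, p = _noisy(mag, phase, rng, params)
        out.append(
            VibrationSpectrum(
                animal_id=animal_id,
                species=params.species,
                structure=structure,
                state=state,
                level_db_spl=float(level_db_spl),
                frequency_hz=f.copy(),
                magnitude_nm=m,
                phase_cycles=p,
                noise_floor_nm=floor.copy(),
            )
        )
    return tuple(out)


# ---- click waveforms -----------------------------------------------------


def _click_freq_response(params, f, level_db_p, bf_a, state: str, tau_click):
    """Complex displacement spectra (BM, RL) on the rfft grid."""
    fsafe = np.maximum(f, 1.0)
    active = state == "sensitive"
    mag = params.bm_magnitude_nm(fsafe, level_db_p, bf_hz=bf_a, active=active)
    pulse = np.sinc(f * params.pulse_dur_s)  # 10-us rectangular pulse spectrum
    phase = params.bm_phase_cycles(fsafe, bf_hz=bf_a) - f * params.t_me_s
    # rarefaction polarity: sign fixed so the sensitive BM first peak is
    # positive (toward scala vestibuli)
    h_bm = -params.click_gain * mag * pulse * np.exp(2j * np.pi * phase)
    h_bm[f < 200.0] = 0.0

    if active:
        # low-frequency tilt, pivoted at the first-peak carrier so the
        # first-peak magnitude ratio stays at click_ratio
        tilt = (params.click_tilt_ref_hz / fsafe) ** params.click_tilt
        rot = np.exp(2j * np.pi * (0.5 - f * tau_click))
        h_rl = h_bm * params.click_ratio * tilt * rot
    else:
        h_rl = params.beta_pm * h_bm * np.exp(-2j * np.pi * f * params.delta_pm_s)
    return h_bm, h_rl


def make_click_pair(
    params: CochleaModelParams,
    animal_id: str,
    level_db_p: float,
    state: str = "sensitive",
):
    """Synthesize one (RL, BM) click-evoked waveform pair.

    Records are sampled at ``click_fs_hz`` and include a pre-trigger baseline
    of ``click_pre_s`` before the stimulus at t = 0, as in averaged evoked
    recordings; the pre-trigger segment carries only measurement noise and
    serves as the detection noise window.
    """
    if state not in ("sensitive", "postmortem"):
        raise ValueError("state must be 'sensitive' or 'postmortem'")
    dt = 1.0 / params.click_fs_hz
    n_total = int(round(params.click_dur_s * params.click_fs_hz))
    n_pre = int(round(params.click_pre_s * params.click_fs_hz))
    n_post = n_total - n_pre

    nfft = 1
    while nfft < 2 * n_post:
        nfft *= 2
    f = np.fft.rfftfreq(nfft, dt)

    bf_a, _, tau_click_a = _animal_draws(params, animal_id)
    h_bm, h_rl = _click_freq_response(params, f, level_db_p, bf_a, state, tau_click_a)

    t = (np.arange(n_total) - n_pre) * dt
    rng = _meas_rng(params, animal_id, level_db_p, state, kind=3)
    out = []
    for structure, h, kind in (("RL", h_rl, 0), ("BM", h_bm, 1)):
        y_full = np.fft.irfft(h, n=nfft) * nfft  # spectrum-shape scaling
        y = np.zeros(n_total)
        y[n_pre:] = y_full[:n_post]
        if params.click_noise_nm > 0:
            y = y + params.click_noise_nm * rng.standard_normal(n_total)
        out.append(
            ClickResponse(
                structure=structure,
                state=state,
                level_db_p=float(level_db_p),
                time_s=t.copy(),
                displacement_nm=y,
                n_averages=100,
                animal_id=animal_id,
                species=params.species,
            )
        )
    rl, bm = out
    return rl, bm


# ---- cohorts -------------------------------------------------------------


@dataclass
class Cohort:
    """Full synthetic dataset: tone spectra and click pairs."""

    params: CochleaModelParams
    spectra: list
    clicks: list

    def spectra_by(self, **conds) -> list:
        out = self.spectra
        for key, val in conds.items():
            out = [s for s in out if getattr(s, key) == val]
        return out

    def clicks_by(self, **conds) -> list:
        out = self.clicks
        for key, val in conds.items():
            out = [c for c in out if getattr(c, key) == val]
        return out


def make_cohort(
    params: CochleaModelParams,
    n_animals: int,
    levels: Sequence[float] = (50.0, 60.0, 70.0, 80.0),
    seed: Optional[int] = None,
    states: Sequence[str] = ("sensitive",),
    click_levels: Sequence[float] = (),
    bf_level_db: float = 30.0,
) -> Cohort:
    """Generate a cohort of animals with independent jitter and noise.

    Each animal gets tone spectra at ``bf_level_db`` (for BF determination)
    and at every level in ``levels``, for every requested state, plus click
    pairs at ``click_levels``. Reproducible given the seed.
    """
    if n_animals < 1:
        raise ValueError("need at least one animal")
    if seed is not None:
        params = replace(params, seed=seed, _active_offset_oct=params._active_offset_oct)
    prefix = params.species[0]
    spectra, clicks = [], []
    for i in range(n_animals):
        aid = f"{prefix}{i + 1:02d}"
        for state in states:
            all_levels = list(dict.fromkeys([bf_level_db, *levels]))
            for level in all_levels:
                spectra.extend(make_spectra(params, aid, level, state))
            for level in click_levels:
                clicks.extend(make_click_pair(params, aid, level, state))
    return Cohort(params=params, spectra=spectra, clicks=clicks)
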