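"""Frequency-domain types and operations for cochlear vibrometry.

A tone-evoked measurement of one structure (reticular lamina, basilar
membrane, or stapes) at one sound level is a :class:`VibrationSpectrum`:
displacement magnitude (nm) and unwrapped phase (cycles) on a strictly
increasing frequency grid, optionally with a per-frequency noise floor.

Phase is kept in cycles (1 cycle = 360 deg) throughout the package, so the
phase lag of a pure delay tau is simply ``-f * tau`` and a latency falls out
of a phase-vs-frequency regression as minus the slope, with no 2*pi
bookkeeping. Degree/radian conversion happens only at interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "VibrationSpectrum",
    "TransferRatio",
    "QcResult",
    "unwrap_phase",
    "wrap_phase",
    "transfer_ratio",
    "compression_db",
    "best_frequency",
    "dpoae_qc",
    "DPOAE_SENSITIVE_MAX_DROP_DB",
]

#: Sensitivity criterion: a cochlea whose DPOAE dropped by less than this many
#: dB during the experiment is considered sensitive.
DPOAE_SENSITIVE_MAX_DROP_DB = 5.0

_STRUCTURES = {"RL", "BM", "stapes", "OHC"}
_STATES = {"sensitive", "postmortem"}
_SPECIES = {"gerbil", "mouse"}


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class VibrationSpectrum:
    """One structure's tone-evoked frequency response at one sound level."""

    animal_id: str
    species: str
    structure: str
    state: str
    level_db_spl: float
    frequency_hz: np.ndarray
    magnitude_nm: np.ndarray
    phase_cycles: np.ndarray
    noise_floor_nm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frequency_hz = _as_float_array(self.frequency_hz, "frequency_hz")
        self.magnitude_nm = _as_float_array(self.magnitude_nm, "magnitude_nm")
        self.phase_cycles = _as_float_array(self.phase_cycles, "phase_cycles")
        if self.species not in _SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.structure not in _STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")
        n = self.frequency_hz.size
        if n == 0:
            raise ValueError("spectrum has no frequencies")
        if self.magnitude_nm.size != n or self.phase_cycles.size != n:
            raise ValueError("frequency/magnitude/phase lengths differ")
        if np.any(self.frequency_hz <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(np.diff(self.frequency_hz) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.magnitude_nm < 0):
            raise ValueError("magnitudes must be non-negative")
        if n > 1 and np.any(np.abs(np.diff(self.phase_cycles)) > 0.5 + 1e-12):
            raise ValueError(
                "phase must be stored unwrapped (adjacent jump > 0.5 cycles); "
                "use unwrap_phase() first"
            )
        if self.noise_floor_nm is not None:
            self.noise_floor_nm = _as_float_array(self.noise_floor_nm, "noise_floor_nm")
            if self.noise_floor_nm.size != n:
                raise ValueError("noise_floor_nm length differs from grid")

    @property
    def above_noise(self) -> np.ndarray:
        """Boolean mask of points whose magnitude clears the noise floor.

        All-true when no noise floor was recorded.
        """
        if self.noise_floor_nm is None:
            return np.ones_like(self.magnitude_nm, dtype=bool)
        return self.magnitude_nm > self.noise_floor_nm


@dataclass
class TransferRatio:
    """Per-frequency magnitude ratio and phase difference of two spectra."""

    numerator: str
    denominator: str
    level_db_spl: float
    frequency_hz: np.ndarray
    ratio: np.ndarray
    phase_diff_cycles: np.ndarray
    #: points where the ratio is well defined (non-zero denominator) and both
    #: inputs were above their noise floors
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.frequency_hz = _as_float_array(self.frequency_hz, "frequency_hz")
        self.ratio = _as_float_array(self.ratio, "ratio")
        self.phase_diff_cycles = _as_float_array(self.phase_diff_cycles, "phase_diff_cycles")
        if self.valid is None:
            self.valid = np.isfinite(self.ratio)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.frequency_hz.size
        if not (self.ratio.size == self.phase_diff_cycles.size == self.valid.size == n):
            raise ValueError("parallel arrays must share the frequency grid")


@dataclass(frozen=True)
class QcResult:
    """DPOAE-based cochlear sensitivity verdict."""

    dpoae_pre_db: float
    dpoae_post_db: float
    drop_db: float
    sensitive: bool


def unwrap_phase(wrapped_cycles) -> np.ndarray:
    """Unwrap a phase sequence given in cycles on (-0.5, 0.5].

    The first sample is kept as the anchor; every later sample is shifted by
    an integer number of cycles so that adjacent differences stay within
    (-0.5, 0.5]. The result is congruent to the input modulo 1 elementwise.
    """
    w = _as_float_array(wrapped_cycles, "wrapped_cycles")
    if w.size == 0:
        raise ValueError("cannot unwrap an empty phase sequence")
    return np.unwrap(w, period=1.0)


def wrap_phase(unwrapped_cycles) -> np.ndarray:
    """Wrap phase in cycles onto (-0.5, 0.5] (inverse of measurement wrap)."""
    u = _as_float_array(unwrapped_cycles, "unwrapped_cycles")
    w = u - np.round(u)
    # round() maps x.5 to the even side; force the half-cycle point to +0.5
    w[w == -0.5] = 0.5
    return w


def transfer_ratio(num: VibrationSpectrum, den: VibrationSpectrum) -> TransferRatio:
    """Magnitude ratio |num|/|den| and phase difference of two spectra.

    Both spectra must come from the same animal and sound level and share the
    frequency grid. Points with a zero denominator are flagged invalid
    (ratio = NaN) rather than raising; points below either noise floor are
    flagged invalid but keep their numeric value.
    """
    if not np.array_equal(num.frequency_hz, den.frequency_hz):
        raise ValueError("frequency grids differ between numerator and denominator")
    if num.animal_id != den.animal_id:
        raise ValueError("refusing to form a ratio across animals")
    if num.level_db_spl != den.level_db_spl:
        raise ValueError("refusing to form a ratio across sound levels")
    nonzero = den.magnitude_nm > 0
    ratio = np.full_like(num.magnitude_nm, np.nan)
    np.divide(num.magnitude_nm, den.magnitude_nm, out=ratio, where=nonzero)
    valid = nonzero & num.above_noise & den.above_noise
    return TransferRatio(
        numerator=num.structure,
        denominator=den.structure,
        level_db_spl=num.level_db_spl,
        frequency_hz=num.frequency_hz.copy(),
        ratio=ratio,
        phase_diff_cycles=num.phase_cycles - den.phase_cycles,
        valid=valid,
        animal_id=num.animal_id,
    )


def compression_db(level_lo_db: float, level_hi_db: float, displacement_fold: float) -> float:
    """Compressive gain loss, in dB, of a level-growth measurement.

    A stimulus step from ``level_lo_db`` to ``level_hi_db`` that grows the
    response only ``displacement_fold``-fold has lost
    ``(hi - lo) - 20*log10(fold)`` dB relative to linear growth. Zero means
    perfectly linear growth; (hi - lo) means complete saturation.
    """
    if level_hi_db <= level_lo_db:
        raise ValueError("level_hi_db must exceed level_lo_db")
    if displacement_fold <= 0:
        raise ValueError("displacement_fold must be positive")
    return (level_hi_db - level_lo_db) - 20.0 * np.log10(displacement_fold)


def best_frequency(spec: VibrationSpectrum) -> float:
    """Grid frequency of the global displacement maximum (the BF).

    By convention the BF is read from the basilar-membrane response at a low
    sound level; this function just finds the peak of whatever spectrum it is
    given. Ties break toward the lowest frequency.
    """
    if spec.frequency_hz.size < 3:
        raise ValueError("need at least 3 frequencies to call a peak")
    mags = spec.magnitude_nm
    if np.all(mags == mags[0]):
        raise ValueError("all magnitudes equal: no peak")
    return float(spec.frequency_hz[int(np.argmax(mags))])


def dpoae_qc(pre_db: float, post_db: float) -> QcResult:
    """Apply the DPOAE sensitivity criterion (drop < 5 dB => sensitive)."""
    if not (np.isfinite(pre_db) and np.isfinite(post_db)):
        raise ValueError("DPOAE levels must be finite")
    drop = float(pre_db) - float(post_db)
    return QcResult(
        dpoae_pre_db=float(pre_db),
        dpoae_post_db=float(post_db),
        drop_db=drop,
        sensitive=drop < DPOAE_SENSITIVE_MAX_DROP_DB,
    )
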