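"""Frequency-to-place mapping and longitudinal snapshot reconstruction.

A log-frequency place map assigns each stimulus frequency its characteristic
place along the basilar membrane::

    d% = a - b * log10(f / 1 kHz),     x = L * d% / 100

with ``d%`` the percent distance (high frequencies map near the base) and
``L`` the basilar-membrane length. Because a single location responds best
to its characteristic frequency, a frequency sweep measured at one place can
be re-read as a longitudinal pattern: magnitude and phase vs distance. A
snapshot of the traveling wave at time t is then::

    W(x; t) = magnitude(x) * cos(2*pi*(f*t + phase_cycles(x)))

so that two snapshots dt apart differ by a phase advance of f*dt cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import VibrationSpectrum

__all__ = [
    "PlaceMapParams",
    "PlaceProfile",
    "frequency_to_place",
    "place_to_frequency",
    "spectra_to_place_profile",
    "snapshot_waveform",
    "GERBIL_MUELLER",
]


@dataclass(frozen=True)
class PlaceMapParams:
    """Coefficients of the percent-distance map d% = a - b*log10(f_kHz)."""

    a_percent: float
    b_percent_per_decade: float
    bm_length_mm: float
    orientation: str = "from_base"

    def __post_init__(self) -> None:
        if self.b_percent_per_decade <= 0:
            raise ValueError("b must be positive (map must be monotonic)")
        if self.bm_length_mm <= 0:
            raise ValueError("bm_length_mm must be positive")
        if self.orientation not in ("from_base", "from_apex"):
            raise ValueError("orientation must be 'from_base' or 'from_apex'")


#: Gerbil preset. The slope is the literature-typical ~38.2 %/decade for the
#: gerbil cochlea and the intercept anchors 26 kHz at 2.05 mm from the base
#: (BM length 11.1 mm); see docs/methods.md for how these were fixed.
GERBIL_MUELLER = PlaceMapParams(
    a_percent=72.52,
    b_percent_per_decade=38.2,
    bm_length_mm=11.1,
    orientation="from_base",
)


def _percent(f_hz: np.ndarray, m: PlaceMapParams) -> np.ndarray:
    return m.a_percent - m.b_percent_per_decade * np.log10(np.asarray(f_hz, float) / 1000.0)


def frequency_to_place(f_hz, map_params: PlaceMapParams):
    """Characteristic place (mm) of frequency ``f_hz`` under the map."""
    f = np.asarray(f_hz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    d = _percent(f, map_params)
    if np.any((d < 0) | (d > 100)):
        raise ValueError("frequency outside the valid range of the place map")
    x = map_params.bm_length_mm * d / 100.0
    if map_params.orientation == "from_apex":
        x = map_params.bm_length_mm - x
    return float(x) if np.isscalar(f_hz) else x


def place_to_frequency(x_mm, map_params: PlaceMapParams):
    """Inverse map: frequency (Hz) whose characteristic place is ``x_mm``."""
    x = np.asarray(x_mm, dtype=float)
    if map_params.orientation == "from_apex":
        x = map_params.bm_length_mm - x
    d = 100.0 * x / map_params.bm_length_mm
    f = 1000.0 * 10.0 ** ((map_params.a_percent - d) / map_params.b_percent_per_decade)
    return float(f) if np.isscalar(x_mm) else f


@dataclass
class PlaceProfile:
    """Vibration magnitude and phase as a function of longitudinal place."""

    x_mm: np.ndarray
    magnitude_nm: np.ndarray
    phase_cycles: np.ndarray
    structure: str
    level_db_spl: float

    def __post_init__(self) -> None:
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.magnitude_nm = np.asarray(self.magnitude_nm, dtype=float)
        self.phase_cycles = np.asarray(self.phase_cycles, dtype=float)
        if not (self.x_mm.size == self.magnitude_nm.size == self.phase_cycles.size):
            raise ValueError("parallel arrays must share the place grid")
        if self.x_mm.size > 1 and np.any(np.diff(self.x_mm) <= 0):
            raise ValueError("places must be strictly monotonic")


def spectra_to_place_profile(
    spec: VibrationSpectrum, map_params: PlaceMapParams
) -> PlaceProfile:
    """Re-index a frequency sweep as a longitudinal vibration pattern."""
    x = frequency_to_place(spec.frequency_hz, map_params)
    order = np.argsort(x)
    return PlaceProfile(
        x_mm=x[order],
        magnitude_nm=spec.magnitude_nm[order],
        phase_cycles=spec.phase_cycles[order],
        structure=spec.structure,
        level_db_spl=spec.level_db_spl,
    )


def snapshot_waveform(profile: PlaceProfile, f_hz: float, t_s: float) -> np.ndarray:
    """Instantaneous displacement vs place at time ``t_s`` for frequency ``f_hz``.

    Phase enters with a plus sign inside the cosine, so a larger phase lag
    (more negative phase) shifts the local oscillation later in time.
    """
    if profile.x_mm.size == 0:
        raise ValueError("empty profile")
    return profile.magnitude_nm * np.cos(
        2.0 * np.pi * (f_hz * t_s + profile.phase_cycles)
    )
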