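"""Complex-phasor decomposition of the reticular lamina motion.

At each frequency the measured displacements are phasors. The outer hair
cell-driven component of the reticular lamina motion is isolated by vector
subtraction of the basilar membrane phasor from the measured reticular
lamina phasor::

    D_OHC(f) = D_RL(f) - D_BM(f)

Under postmortem (passive) conditions the active component vanishes and the
RL passively follows the BM, so D_OHC collapses to the residual passive
mismatch. The dominance index |D_OHC|/|D_RL| is ~1 where the active
component carries the RL motion and ~0 where the RL merely rides the BM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .spectra import VibrationSpectrum, unwrap_phase

__all__ = ["PhasorField", "phasor_from_spectrum", "subtract_active", "dominance_index"]


@dataclass
class PhasorField:
    """Complex displacement vs frequency, stored as magnitude and phase."""

    structure: str
    frequency_hz: np.ndarray
    magnitude_nm: np.ndarray
    phase_cycles: np.ndarray
    level_db_spl: Optional[float] = None
    state: Optional[str] = None
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.frequency_hz = np.asarray(self.frequency_hz, dtype=float)
        self.magnitude_nm = np.asarray(self.magnitude_nm, dtype=float)
        self.phase_cycles = np.asarray(self.phase_cycles, dtype=float)
        if not (self.frequency_hz.size == self.magnitude_nm.size == self.phase_cycles.size):
            raise ValueError("parallel arrays must share the frequency grid")
        if np.any(self.magnitude_nm < 0):
            raise ValueError("magnitudes must be non-negative")
        if not np.all(np.isfinite(self.phase_cycles)):
            raise ValueError("phase must be finite")

    @property
    def complex_nm(self) -> np.ndarray:
        return self.magnitude_nm * np.exp(2j * np.pi * self.phase_cycles)

    @classmethod
    def from_complex(
        cls,
        structure: str,
        frequency_hz: np.ndarray,
        z: np.ndarray,
        **meta,
    ) -> "PhasorField":
        """Build from complex values; phase is unwrapped along frequency,
        anchored at the lowest frequency."""
        mag = np.abs(z)
        ph = np.angle(z) / (2 * np.pi)
        if ph.size:
            ph = unwrap_phase(ph)
        return cls(structure, np.asarray(frequency_hz, float), mag, ph, **meta)


def phasor_from_spectrum(spec: VibrationSpectrum) -> PhasorField:
    return PhasorField(
        structure=spec.structure,
        frequency_hz=spec.frequency_hz.copy(),
        magnitude_nm=spec.magnitude_nm.copy(),
        phase_cycles=spec.phase_cycles.copy(),
        level_db_spl=spec.level_db_spl,
        state=spec.state,
        animal_id=spec.animal_id,
    )


def _check_compatible(rl: PhasorField, bm: PhasorField) -> None:
    if not np.array_equal(rl.frequency_hz, bm.frequency_hz):
        raise ValueError("frequency grids differ")
    # phasors only share a reference within one stimulus condition
    if rl.level_db_spl is not None and bm.level_db_spl is not None:
        if rl.level_db_spl != bm.level_db_spl:
            raise ValueError("refusing to combine phasors across sound levels")
    if rl.state is not None and bm.state is not None and rl.state != bm.state:
        raise ValueError("refusing to combine phasors across sensitive/postmortem states")


def subtract_active(rl: PhasorField, bm: PhasorField) -> PhasorField:
    """Outer hair cell-driven component D_OHC = D_RL - D_BM (complex)."""
    _check_compatible(rl, bm)
    z = rl.complex_nm - bm.complex_nm
    return PhasorField.from_complex(
        "OHC",
        rl.frequency_hz,
        z,
        level_db_spl=rl.level_db_spl,
        state=rl.state,
        animal_id=rl.animal_id,
    )


def dominance_index(rl: PhasorField, bm: PhasorField) -> np.ndarray:
    """Per-frequency |D_OHC| / |D_RL|; NaN where |D_RL| is zero."""
    _check_compatible(rl, bm)
    ohc_mag = np.abs(rl.complex_nm - bm.complex_nm)
    out = np.full_like(ohc_mag, np.nan)
    nz = rl.magnitude_nm > 0
    np.divide(ohc_mag, rl.magnitude_nm, out=out, where=nz)
    return out
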