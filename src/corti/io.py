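"""Readers and writers for the package's two TSV dialects, and config I/O.

Spectrum dialect (one row per frequency, tab-separated, UTF-8, '.' decimal,
header required)::

    animal_id  species  state  structure  level_db_spl  frequency_hz
    magnitude_nm  phase_cycles  noise_floor_nm

An optional extra column ``wrapped`` (0/1) marks rows whose phase is still
wrapped to (-0.5, 0.5]; such records are unwrapped on load.

Time-series dialect::

    animal_id  species  state  structure  level_db_p  time_s  displacement_nm

Floats are written with 17 significant digits, so a write/read round trip is
lossless.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
import yaml

from .clicks import ClickResponse
from .spectra import VibrationSpectrum, unwrap_phase
from .synth import CochleaModelParams

__all__ = [
    "SPECTRUM_COLUMNS",
    "TIMESERIES_COLUMNS",
    "read_spectra",
    "write_spectra",
    "read_timeseries",
    "write_timeseries",
    "load_params",
    "save_params",
]

SPECTRUM_COLUMNS = [
    "animal_id",
    "species",
    "state",
    "structure",
    "level_db_spl",
    "frequency_hz",
    "magnitude_nm",
    "phase_cycles",
    "noise_floor_nm",
]

TIMESERIES_COLUMNS = [
    "animal_id",
    "species",
    "state",
    "structure",
    "level_db_p",
    "time_s",
    "displacement_nm",
]

_SPECTRUM_KEY = ["animal_id", "species", "state", "structure", "level_db_spl"]
_TS_KEY = ["animal_id", "species", "state", "structure", "level_db_p"]


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def read_spectra(path) -> List[VibrationSpectrum]:
    """Load a spectrum TSV; rows are grouped by (animal, species, state,
    structure, level) and sorted by frequency within each record."""
    df = _read_table(path, SPECTRUM_COLUMNS)
    df["_row"] = np.arange(len(df)) + 2  # 1-based, after the header line
    out = []
    for key, grp in df.groupby(_SPECTRUM_KEY, sort=True):
        grp = grp.sort_values("frequency_hz")
        dup = grp["frequency_hz"].duplicated()
        if dup.any():
            row = int(grp.loc[dup, "_row"].iloc[0])
            raise ValueError(f"{path}: duplicate frequency for record {key} at row {row}")
        phase = grp["phase_cycles"].to_numpy(float)
        if "wrapped" in grp.columns and grp["wrapped"].astype(bool).any():
            phase = unwrap_phase(phase)
        floor = grp["noise_floor_nm"].to_numpy(float)
        out.append(
            VibrationSpectrum(
                animal_id=str(key[0]),
                species=str(key[1]),
                state=str(key[2]),
                structure=str(key[3]),
                level_db_spl=float(key[4]),
                frequency_hz=grp["frequency_hz"].to_numpy(float),
                magnitude_nm=grp["magnitude_nm"].to_numpy(float),
                phase_cycles=phase,
                noise_floor_nm=None if np.isnan(floor).all() else floor,
            )
        )
    return out


def write_spectra(specs: Sequence[VibrationSpectrum], path) -> None:
    rows = []
    for s in specs:
        floor = (
            s.noise_floor_nm
            if s.noise_floor_nm is not None
            else np.full_like(s.frequency_hz, np.nan)
        )
        for f, m, p, nf in zip(s.frequency_hz, s.magnitude_nm, s.phase_cycles, floor):
            rows.append(
                (s.animal_id, s.species, s.state, s.structure, s.level_db_spl, f, m, p, nf)
            )
    df = pd.DataFrame(rows, columns=SPECTRUM_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_timeseries(path) -> List[ClickResponse]:
    """Load a time-series TSV; enforces uniform sampling per record."""
    df = _read_table(path, TIMESERIES_COLUMNS)
    out = []
    for key, grp in df.groupby(_TS_KEY, sort=True):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy(float)
        if t.size >= 3:
            steps = np.diff(t)
            if np.ptp(steps) > 1e-9 * np.median(steps) + 1e-15:
                raise ValueError(
                    f"{path}: record {key} is not uniformly sampled "
                    "(missing or duplicated samples)"
                )
        out.append(
            ClickResponse(
                structure=str(key[3]),
                state=str(key[2]),
                level_db_p=float(key[4]),
                time_s=t,
                displacement_nm=grp["displacement_nm"].to_numpy(float),
                animal_id=str(key[0]),
                species=str(key[1]),
            )
        )
    return out


def write_timeseries(responses: Sequence[ClickResponse], path) -> None:
    frames = []
    for r in responses:
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": r.animal_id,
                    "species": r.species,
                    "state": r.state,
                    "structure": r.structure,
                    "level_db_p": r.level_db_p,
                    "time_s": r.time_s,
                    "displacement_nm": r.displacement_nm,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)[TIMESERIES_COLUMNS]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_params(path) -> CochleaModelParams:
    """Load generator parameters from a YAML mapping of field overrides."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(CochleaModelParams) if not f.name.startswith("_")}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown parameter(s) in {path}: {sorted(unknown)}")
    return CochleaModelParams(**data)


def save_params(params: CochleaModelParams, path) -> None:
    data = {
        f.name: getattr(params, f.name)
        for f in dataclasses.fields(CochleaModelParams)
        if not f.name.startswith("_")
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
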