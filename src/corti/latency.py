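"""Phase-slope latency estimation and group statistics.

The phase lag of a structure vibrating with latency tau is
``phi = -f * tau`` cycles, so the RL-BM phase difference
``dphi(f) = phi_RL - phi_BM`` falls with frequency at slope ``-dtau``.
An ordinary least-squares line fitted to dphi (cycles) versus f (Hz) over a
chosen band therefore yields the latency difference directly as minus the
slope, in seconds. Positive dtau means the reticular lamina vibrates later
than the basilar membrane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy import stats

from .spectra import TransferRatio, VibrationSpectrum, transfer_ratio

__all__ = [
    "LatencyEstimate",
    "GroupStats",
    "phase_difference_curve",
    "latency_from_phase_slope",
    "group_latency",
    "level_invariance_anova",
    "compare_groups",
]


@dataclass(frozen=True)
class LatencyEstimate:
    """Latency difference from one phase-difference regression."""

    delta_tau_s: float
    slope_cycles_per_hz: float
    intercept_cycles: float
    fit_fmin_hz: float
    fit_fmax_hz: float
    n_points: int
    r_squared: float
    animal_id: str = ""
    level_db_spl: float = np.nan


@dataclass(frozen=True)
class GroupStats:
    mean: float
    sem: float
    n: int
    unit: str = ""


def phase_difference_curve(rl: VibrationSpectrum, bm: VibrationSpectrum) -> TransferRatio:
    """RL-BM phase difference (and magnitude ratio) on the shared grid."""
    if rl.structure != "RL" or bm.structure != "BM":
        raise ValueError("expected an RL numerator and a BM denominator")
    return transfer_ratio(rl, bm)


def latency_from_phase_slope(
    curve: TransferRatio, fmin_hz: float, fmax_hz: float
) -> LatencyEstimate:
    """OLS fit of the phase difference vs frequency over [fmin, fmax].

    Only points flagged valid (above both noise floors) enter the fit.
    Returns the latency difference ``delta_tau_s = -slope`` together with the
    fit diagnostics. Requires at least three usable points with non-zero
    frequency spread.
    """
    if fmax_hz <= fmin_hz:
        raise ValueError("fmax_hz must exceed fmin_hz")
    f = curve.frequency_hz
    mask = curve.valid & (f >= fmin_hz) & (f <= fmax_hz)
    mask &= np.isfinite(curve.phase_diff_cycles)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"only {n} usable points in [{fmin_hz}, {fmax_hz}] Hz; need >= 3")
    fs = f[mask]
    ys = curve.phase_diff_cycles[mask]
    if np.ptp(fs) == 0:
        raise ValueError("zero frequency spread in fit range")
    fit = stats.linregress(fs, ys)
    return LatencyEstimate(
        delta_tau_s=-float(fit.slope),
        slope_cycles_per_hz=float(fit.slope),
        intercept_cycles=float(fit.intercept),
        fit_fmin_hz=float(fs.min()),
        fit_fmax_hz=float(fs.max()),
        n_points=n,
        r_squared=float(fit.rvalue) ** 2,
        animal_id=curve.animal_id,
        level_db_spl=curve.level_db_spl,
    )


def _values(estimates: Sequence) -> np.ndarray:
    out = []
    for e in estimates:
        out.append(e.delta_tau_s if isinstance(e, LatencyEstimate) else float(e))
    return np.asarray(out, dtype=float)


def group_latency(estimates: Sequence, unit: str = "s") -> GroupStats:
    """Mean and SEM (sd/sqrt(n)) over per-record latency estimates.

    Each animal-by-level record counts as one observation; a single value has
    SEM 0 by convention.
    """
    vals = _values(estimates)
    if vals.size == 0:
        raise ValueError("no estimates to group")
    n = vals.size
    sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return GroupStats(mean=float(vals.mean()), sem=sem, n=n, unit=unit)


def level_invariance_anova(groups: Dict[float, Sequence]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of latency across sound levels.

    ``groups`` maps level (dB SPL) to that level's per-record estimates.
    Returns (F, p) with the usual k-1 and N-k degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least two level groups")
    arrays = []
    for level in sorted(groups):
        vals = _values(groups[level])
        if vals.size < 2:
            raise ValueError(f"level {level}: need >= 2 values per group")
        arrays.append(vals)
    f_stat, p = stats.f_oneway(*arrays)
    return float(f_stat), float(p)


def compare_groups(
    a: Sequence, b: Sequence, equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-sample t comparison of per-record latency estimates.

    Student's pooled-variance t by default (df = n_a + n_b - 2); pass
    ``equal_var=False`` for the Welch variant. Returns (t, two-sided p, df).
    """
    va, vb = _values(a), _values(b)
    if va.size < 2 or vb.size < 2:
        raise ValueError("each group needs at least two values")
    res = stats.ttest_ind(va, vb, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue), float(res.df)
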