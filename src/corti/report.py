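"""Cohort-level pipelines: per-record tables and grouped summary statistics.

These functions tie the primitive operations together the way the study's
analysis is organized: per animal-by-level records first (phase-slope
latency from tone spectra, first-peak features from click waveforms), then
grouping across records with mean +/- SEM, a one-way ANOVA for level
invariance, and a two-group species comparison.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .clicks import (
    detect_first_peak,
    first_period,
    in_phase_time,
    latency_difference_click,
)
from .latency import (
    GroupStats,
    LatencyEstimate,
    compare_groups,
    group_latency,
    latency_from_phase_slope,
    level_invariance_anova,
    phase_difference_curve,
)
from .spectra import best_frequency

__all__ = [
    "measured_best_frequencies",
    "tone_latency_table",
    "click_feature_table",
    "tone_latency_summary",
    "report",
    "DEFAULT_FIT_RANGE_REL",
]

#: default phase-difference regression band, as fractions of the measured BF
DEFAULT_FIT_RANGE_REL = (0.1, 1.0)


def _index(spectra):
    by_key = {}
    for s in spectra:
        by_key[(s.animal_id, s.state, s.structure, s.level_db_spl)] = s
    return by_key


def measured_best_frequencies(
    spectra, bf_level_db: float = 30.0, state: str = "sensitive"
) -> Dict[str, float]:
    """Per-animal BF from the BM response at the BF-determination level."""
    bfs = {}
    for s in spectra:
        if s.structure == "BM" and s.state == state and s.level_db_spl == bf_level_db:
            bfs[s.animal_id] = best_frequency(s)
    return bfs


def tone_latency_table(
    spectra,
    fit_range_rel=DEFAULT_FIT_RANGE_REL,
    levels: Optional[Sequence[float]] = None,
    state: str = "sensitive",
    bf_level_db: float = 30.0,
) -> pd.DataFrame:
    """Phase-slope latency estimate for every animal-by-level record.

    The regression band is ``fit_range_rel`` times each animal's measured BF
    (peak of its BM response at ``bf_level_db``), mirroring the per-animal
    frequency normalization of grouped vibrometry data.
    """
    bfs = measured_best_frequencies(spectra, bf_level_db=bf_level_db, state=state)
    by_key = _index(spectra)
    rows = []
    for (animal, st, structure, level), rl in sorted(by_key.items()):
        if structure != "RL" or st != state:
            continue
        if levels is not None and level not in levels:
            continue
        bm = by_key.get((animal, st, "BM", level))
        if bm is None or animal not in bfs:
            continue
        bf = bfs[animal]
        curve = phase_difference_curve(rl, bm)
        est = latency_from_phase_slope(curve, fit_range_rel[0] * bf, fit_range_rel[1] * bf)
        rows.append(
            {
                "animal_id": animal,
                "level_db_spl": level,
                "bf_hz": bf,
                "delta_tau_us": est.delta_tau_s * 1e6,
                "r_squared": est.r_squared,
                "n_points": est.n_points,
            }
        )
    return pd.DataFrame(rows)


def tone_latency_summary(table: pd.DataFrame) -> GroupStats:
    """Grouped latency (mean, SEM, n) over all records of a tone table."""
    ests = [
        LatencyEstimate(
            delta_tau_s=v * 1e-6,
            slope_cycles_per_hz=-v * 1e-6,
            intercept_cycles=0.0,
            fit_fmin_hz=0.0,
            fit_fmax_hz=1.0,
            n_points=3,
            r_squared=1.0,
        )
        for v in table["delta_tau_us"]
    ]
    g = group_latency(ests, unit="s")
    return GroupStats(mean=g.mean * 1e6, sem=g.sem * 1e6, n=g.n, unit="us")


def click_feature_table(clicks, threshold_mult: float = 3.0) -> pd.DataFrame:
    """First-peak features and RL-BM timing for every click record pair."""
    pairs = defaultdict(dict)
    for c in clicks:
        pairs[(c.animal_id, c.state, c.level_db_p)][c.structure] = c
    rows = []
    for (animal, state, level), pair in sorted(pairs.items()):
        if "RL" not in pair or "BM" not in pair:
            continue
        rl, bm = pair["RL"], pair["BM"]
        try:
            frl = detect_first_peak(rl, threshold_mult)
            fbm = detect_first_peak(bm, threshold_mult)
        except ValueError:
            continue  # initial peak too small to be reliably detected
        row = {
            "animal_id": animal,
            "state": state,
            "level_db_p": level,
            "t_a_us": fbm.first_peak_time_s * 1e6,
            "t_b_us": frl.first_peak_time_s * 1e6,
            "delta_tau_us": latency_difference_click(frl, fbm) * 1e6,
            "bm_sign": fbm.first_peak_sign,
            "rl_sign": frl.first_peak_sign,
            "peak_ratio": frl.first_peak_magnitude_nm / fbm.first_peak_magnitude_nm,
        }
        for name, resp, feat in (("t_bm_us", bm, fbm), ("t_rl_us", rl, frl)):
            try:
                row[name] = first_period(resp, feat) * 1e6
            except ValueError:
                row[name] = np.nan
        try:
            row["t_c_us"] = in_phase_time(rl, bm, frl, fbm) * 1e6
        except ValueError:
            row["t_c_us"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def report(
    spectra,
    clicks=(),
    fit_range_rel=DEFAULT_FIT_RANGE_REL,
    levels: Optional[Sequence[float]] = None,
    anova_levels: Sequence[float] = (50.0, 60.0, 70.0, 80.0),
) -> dict:
    """Run the full analysis over a dataset and collect the headline rows.

    Returns a dict with the per-record tables, the grouped tone and click
    latencies, and the level-invariance ANOVA. Analyses whose inputs are
    missing are skipped with a note in ``skipped``.
    """
    out: dict = {"skipped": []}
    tone = tone_latency_table(spectra, fit_range_rel=fit_range_rel, levels=levels)
    out["tone_table"] = tone
    if len(tone):
        out["tone_group"] = tone_latency_summary(tone)
        groups = {
            lvl: (grp["delta_tau_us"] * 1e-6).tolist()
            for lvl, grp in tone.groupby("level_db_spl")
            if lvl in anova_levels and len(grp) >= 2
        }
        if len(groups) >= 2:
            out["anova_f"], out["anova_p"] = level_invariance_anova(groups)
        else:
            out["skipped"].append("anova: fewer than two usable level groups")
    else:
        out["skipped"].append("tone latency: no RL/BM records")
    click_tab = click_feature_table(clicks)
    out["click_table"] = click_tab
    if len(click_tab):
        g = group_latency(list(click_tab["delta_tau_us"] * 1e-6), unit="s")
        out["click_group"] = GroupStats(g.mean * 1e6, g.sem * 1e6, g.n, "us")
    elif clicks:
        out["skipped"].append("click latency: no detectable record pairs")
    return out


def compare_species(table_a: pd.DataFrame, table_b: pd.DataFrame):
    """Pooled and Welch two-sample t for two tone-latency tables (a vs b)."""
    a = (table_a["delta_tau_us"]).to_numpy(float)
    b = (table_b["delta_tau_us"]).to_numpy(float)
    pooled = compare_groups(a, b, equal_var=True)
    welch = compare_groups(a, b, equal_var=False)
    return {"student": pooled, "welch": welch}
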