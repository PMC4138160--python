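"""Reduction of stance waveforms to the 72 discrete kinematic variables."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .gait_events import StanceCycle
from .variables import (
    CHANNEL_NAMES,
    DEMOGRAPHIC_COLUMNS,
    GENDERS,
    TIMEPOINTS,
    VARIABLE_NAMES,
)


def extract_discrete(cycle: StanceCycle) -> dict[str, tuple[float, float, float, float]]:
    """Per-channel quadruple (touchdown, maxpeak, minpeak, toeoff).

    Touchdown is the value at 0% of stance, toe-off at 100%; the peaks are
    the extrema over the full closed 0-100% interval (endpoints included).
    """
    out = {}
    for name, w in cycle.channels.items():
        if not np.all(np.isfinite(w)):
            raise ValueError(f"non-finite values in channel {name}")
        out[name] = (float(w[0]), float(w.max()), float(w.min()), float(w[-1]))
    return out


def assemble_table(
    subjects: list[tuple[str, str, float, dict[str, tuple[float, float, float, float]]]],
) -> pd.DataFrame:
    """Build the n x 72 feature table from per-subject channel quadruples.

    Each entry is ``(subject_id, gender, age, quadruples)`` where quadruples
    maps all 18 channel names to their (touchdown, maxpeak, minpeak, toeoff).
    """
    rows = []
    seen = set()
    for sid, gender, age, quads in subjects:
        if sid in seen:
            raise ValueError(f"duplicate subject_id {sid!r}")
        seen.add(sid)
        missing = set(CHANNEL_NAMES) - set(quads)
        if missing:
            raise ValueError(f"subject {sid!r} missing channels: {sorted(missing)}")
        values = {
            f"{ch}_{tp}": quads[ch][k]
            for ch in CHANNEL_NAMES
            for k, tp in enumerate(TIMEPOINTS)
        }
        rows.append({"subject_id": sid, "gender": gender, "age": age, **values})
    return pd.DataFrame(rows, columns=list(DEMOGRAPHIC_COLUMNS) + list(VARIABLE_NAMES))


def filter_age_band(table: pd.DataFrame, low: float, high: float) -> pd.DataFrame:
    """Rows with ``low <= age <= high`` (closed interval), order preserved."""
    if high < low:
        raise ValueError("invalid age band: high < low")
    out = table.loc[(table["age"] >= low) & (table["age"] <= high)].copy()
    if out.empty:
        warnings.warn(f"age band [{low}, {high}] selected no subjects", stacklevel=2)
    return out


def validate_feature_table(
    table: pd.DataFrame, check_quadruple_order: bool = False
) -> list[str]:
    """Contract checks on a feature table; returns a list of diagnostics.

    Always checks column completeness, gender labels, positive ages and
    finite values. ``check_quadruple_order`` additionally enforces
    minpeak <= touchdown/toeoff <= maxpeak per (side, joint, plane) — valid
    for tables extracted from waveforms, but not for synthetic cohorts drawn
    variable-by-variable.
    """
    diags = []
    missing = set(VARIABLE_NAMES) - set(table.columns)
    if missing:
        diags.append(f"missing feature columns: {sorted(missing)}")
    for col in DEMOGRAPHIC_COLUMNS:
        if col not in table.columns:
            diags.append(f"missing demographic column: {col}")
    if not diags:
        if table["subject_id"].duplicated().any():
            diags.append("duplicate subject_id values")
        bad_gender = set(table["gender"].unique()) - set(GENDERS)
        if bad_gender:
            diags.append(f"unknown gender labels: {sorted(bad_gender)}")
        if (table["age"] <= 0).any():
            diags.append("non-positive ages")
        values = table[list(VARIABLE_NAMES)].to_numpy(float)
        if not np.all(np.isfinite(values)):
            diags.append("non-finite feature values")
        if check_quadruple_order:
            for ch in CHANNEL_NAMES:
                td, mx, mn, to = (table[f"{ch}_{tp}"] for tp in TIMEPOINTS)
                if ((mn > td) | (td > mx) | (mn > to) | (to > mx)).any():
                    diags.append(f"quadruple ordering violated for channel {ch}")
    return diags


def canonicalize_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Reorder any valid feature table into canonical column order."""
    diags = [
        d
        for d in validate_feature_table(table)
        if d.startswith("missing")
    ]
    if diags:
        raise ValueError("; ".join(diags))
    return table[list(DEMOGRAPHIC_COLUMNS) + list(VARIABLE_NAMES)].copy()
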