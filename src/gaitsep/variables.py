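"""Canonical naming of the 72 discrete kinematic variables.

Each stance waveform (2 sides x 3 joints x 3 planes = 18 channels) is reduced
to four scalars: the angle at touchdown, the maximum peak, the minimum peak,
and the angle at toe-off. Variable names are ``{side}_{joint}_{plane}_{timepoint}``,
e.g. ``L_hip_frontal_maxpeak``, and the canonical column order iterates side
(L, R), then joint (hip, knee, ankle), then plane (sagittal, frontal,
transverse), then timepoint (touchdown, maxpeak, minpeak, toeoff).
"""

from __future__ import annotations

SIDES: tuple[str, ...] = ("L", "R")
JOINTS: tuple[str, ...] = ("hip", "knee", "ankle")
PLANES: tuple[str, ...] = ("sagittal", "frontal", "transverse")
TIMEPOINTS: tuple[str, ...] = ("touchdown", "maxpeak", "minpeak", "toeoff")

#: 18 stance-waveform channel names, canonical order.
CHANNEL_NAMES: tuple[str, ...] = tuple(
    f"{s}_{j}_{p}" for s in SIDES for j in JOINTS for p in PLANES
)

#: The 72 discrete variable names, canonical order.
VARIABLE_NAMES: tuple[str, ...] = tuple(
    f"{c}_{t}" for c in CHANNEL_NAMES for t in TIMEPOINTS
)

#: Demographic columns expected alongside the 72 variables.
DEMOGRAPHIC_COLUMNS: tuple[str, ...] = ("subject_id", "gender", "age")

#: Calcaneal-marker vertical-velocity channel names (used for contact detection).
VELOCITY_CHANNELS: dict[str, str] = {s: f"{s}_calc_vz" for s in SIDES}

GENDERS: tuple[str, ...] = ("male", "female")


def channel_of(variable: str) -> str:
    """Return the waveform channel a discrete variable belongs to."""
    channel, _, timepoint = variable.rpartition("_")
    if timepoint not in TIMEPOINTS or channel not in CHANNEL_NAMES:
        raise ValueError(f"not a canonical variable name: {variable!r}")
    return channel


def bilateral_partner(variable: str) -> str:
    """Return the same variable on the contralateral side."""
    side, _, rest = variable.partition("_")
    if side not in SIDES:
        raise ValueError(f"not a canonical variable name: {variable!r}")
    other = "R" if side == "L" else "L"
    return f"{other}_{rest}"
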