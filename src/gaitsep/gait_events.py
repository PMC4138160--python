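"""Gait-event detection and stance-phase time normalization.

Initial contact is the sample where the superior calcaneal marker's vertical
velocity moves from positive to negative; toe-off is the instant of peak knee
extension (minimum knee flexion) within the stance search window. Each stance
phase is resampled to 101 points (0..100% of stance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .synthetic_data import AngleTimeSeries
from .variables import CHANNEL_NAMES, SIDES, VELOCITY_CHANNELS

N_POINTS = 101

#: Default refractory period between accepted contacts, seconds. Shorter than
#: any plausible running stride at 2.2-3.4 m/s, so genuine contacts are never
#: suppressed while noise-induced double crossings are.
DEFAULT_MIN_SEPARATION = 0.2


@dataclass
class StanceCycle:
    """One stance phase, each channel resampled to exactly 101 points."""

    channels: dict[str, np.ndarray]
    contact: int
    toe_off: int

    def __post_init__(self) -> None:
        for name, values in self.channels.items():
            if len(values) != N_POINTS:
                raise ValueError(f"channel {name} has {len(values)} points, not {N_POINTS}")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"channel {name} contains non-finite values")


def detect_initial_contacts(
    vertical_velocity: np.ndarray,
    sampling_rate: float,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> list[int]:
    """Indices where the velocity crosses from positive to non-positive.

    The returned index is the first sample at or below zero. Crossings closer
    than ``min_separation`` seconds to the previously accepted one are
    suppressed.
    """
    v = np.asarray(vertical_velocity, dtype=float)
    if v.size < 2:
        raise ValueError("signal must have at least 2 samples")
    if min_separation < 0:
        raise ValueError("min_separation must be non-negative")
    crossings = np.nonzero((v[:-1] > 0) & (v[1:] <= 0))[0] + 1
    gap = min_separation * sampling_rate
    accepted: list[int] = []
    for idx in crossings:
        if not accepted or idx - accepted[-1] >= gap:
            accepted.append(int(idx))
    return accepted


def detect_toe_off(knee_sagittal: np.ndarray, window: tuple[int, int]) -> int:
    """Sample index of minimum knee flexion (peak extension) in [start, stop).

    First occurrence wins on exact ties. A warning is emitted when the
    minimum sits on the window boundary (the true extremum may lie outside).
    """
    start, stop = window
    y = np.asarray(knee_sagittal, dtype=float)
    if not (0 <= start < stop <= y.size):
        raise ValueError(f"window {window} out of bounds for signal of length {y.size}")
    if stop - start < 2:
        raise ValueError("search window must contain at least 2 samples")
    idx = start + int(np.argmin(y[start:stop]))
    if idx in (start, stop - 1):
        warnings.warn(
            f"knee-flexion minimum at window boundary (index {idx}); "
            "toe-off may lie outside the search window",
            stacklevel=2,
        )
    return idx


def normalize_stance(
    series: AngleTimeSeries,
    contact: int,
    toe_off: int,
    method: str = "linear",
    channels: list[str] | None = None,
) -> StanceCycle:
    """Resample each angle channel onto 101 equally spaced stance points.

    Endpoints are the raw samples at ``contact`` and ``toe_off`` exactly.
    ``method`` is ``"linear"`` (default; monotone, overshoot-free) or
    ``"cubic"`` (natural cubic spline). ``channels`` restricts which angle
    channels enter the cycle (left and right stance phases occur at
    different times, so each side is normalized over its own window).
    """
    if toe_off <= contact:
        raise ValueError("toe_off must come after contact")
    n = series.n_samples
    if not (0 <= contact and toe_off < n):
        raise ValueError("contact/toe_off out of bounds")
    if toe_off - contact < 1:
        raise ValueError("stance must span at least 2 raw samples")
    raw_x = np.arange(contact, toe_off + 1)
    grid = np.linspace(contact, toe_off, N_POINTS)
    wanted = set(CHANNEL_NAMES if channels is None else channels)
    out = {}
    for name, values in series.channels.items():
        if name not in wanted:
            continue  # velocity channels are not part of the stance cycle
        seg = np.asarray(values[contact : toe_off + 1], dtype=float)
        if method == "linear":
            out[name] = np.interp(grid, raw_x, seg)
        elif method == "cubic":
            out[name] = CubicSpline(raw_x, seg)(grid)
        else:
            raise ValueError(f"unknown interpolation method {method!r}")
        out[name][0] = seg[0]
        out[name][-1] = seg[-1]
    return StanceCycle(out, contact=contact, toe_off=toe_off)


def extract_stance_cycles(
    series: AngleTimeSeries,
    side: str,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    method: str = "linear",
) -> list[StanceCycle]:
    """Detect events on one side and return all valid normalized stance cycles.

    For each detected contact, toe-off is searched from that contact to the
    next contact (or the end of the signal); a cycle is produced whenever the
    toe-off falls strictly after the contact.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    vz = series.channels[VELOCITY_CHANNELS[side]]
    knee = series.channels[f"{side}_knee_sagittal"]
    side_channels = [c for c in CHANNEL_NAMES if c.startswith(side + "_")]
    contacts = detect_initial_contacts(vz, series.sampling_rate, min_separation)
    cycles = []
    for j, c in enumerate(contacts):
        stop = contacts[j + 1] if j + 1 < len(contacts) else series.n_samples
        if stop - c < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t_off = detect_toe_off(knee, (c, stop))
        if t_off > c:
            cycles.append(
                normalize_stance(series, c, t_off, method=method, channels=side_channels)
            )
    return cycles


def ensemble_average(cycles: list[StanceCycle]) -> StanceCycle:
    """Pointwise mean across stance cycles, channel by channel."""
    if not cycles:
        raise ValueError("need at least one cycle")
    names = set(cycles[0].channels)
    for c in cycles[1:]:
        if set(c.channels) != names:
            raise ValueError("cycles have mismatched channel sets")
    mean = {
        name: np.mean([c.channels[name] for c in cycles], axis=0) for name in names
    }
    return StanceCycle(mean, contact=cycles[0].contact, toe_off=cycles[0].toe_off)
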