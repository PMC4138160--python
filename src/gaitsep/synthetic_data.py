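"""Synthetic running cohorts and stride-level time series.

Two generators make the whole pipeline testable without any recorded data:

* :func:`generate_feature_cohort` draws per-subject 72-variable discrete
  feature tables from per-group multivariate normals whose means and SDs are
  calibrated to published group statistics (packaged fixtures ``general``,
  ``young``, ``older``).
* :func:`generate_stride_series` synthesizes continuous multi-stride joint
  angle channels plus calcaneal vertical-velocity channels with *planted*
  gait events, so event detection and discrete-feature extraction can be
  checked against exact ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .variables import (
    CHANNEL_NAMES,
    DEMOGRAPHIC_COLUMNS,
    SIDES,
    VARIABLE_NAMES,
    VELOCITY_CHANNELS,
    bilateral_partner,
)

FIXTURE_NAMES = ("general", "young", "older")

# --------------------------------------------------------------------------
# Cohort specification
# --------------------------------------------------------------------------


@dataclass
class GroupSpec:
    """One labelled group: subject count and age strata (count, low, high)."""

    n: int
    age_strata: list[tuple[int, float, float]]

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("group must have count >= 1")
        if sum(c for c, _, _ in self.age_strata) != self.n:
            raise ValueError("age strata counts must sum to the group size")
        for count, low, high in self.age_strata:
            if count < 0 or low <= 0 or high < low:
                raise ValueError(f"invalid age stratum ({count}, {low}, {high})")


@dataclass
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort.

    ``variables`` maps each of the 72 canonical names to
    ``{group_label: (mean_deg, sd_deg)}``. The correlation model is one of
    ``"independent"``, ``"bilateral"`` (each left/right pair correlated at
    ``rho``, pairs mutually independent), or a user-supplied 72x72 matrix.
    """

    name: str
    groups: dict[str, GroupSpec]
    variables: dict[str, dict[str, tuple[float, float]]]
    correlation: str | np.ndarray = "bilateral"
    rho: float = 0.6
    seed: int | None = None
    sources: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        for g in self.groups.values():
            g.validate()
        missing = set(VARIABLE_NAMES) - set(self.variables)
        if missing:
            raise ValueError(f"missing variables: {sorted(missing)[:5]}...")
        for name, per_group in self.variables.items():
            for label in self.groups:
                if label not in per_group:
                    raise ValueError(f"variable {name} missing group {label}")
                _, sd = per_group[label]
                if sd < 0:
                    raise ValueError(f"negative SD for {name}/{label}")
        if isinstance(self.correlation, np.ndarray):
            _check_correlation_matrix(self.correlation)
        elif self.correlation not in ("independent", "bilateral"):
            raise ValueError(f"unknown correlation model {self.correlation!r}")

    def correlation_matrix(self) -> np.ndarray:
        if isinstance(self.correlation, np.ndarray):
            return self.correlation
        p = len(VARIABLE_NAMES)
        corr = np.eye(p)
        if self.correlation == "bilateral":
            index = {v: i for i, v in enumerate(VARIABLE_NAMES)}
            for v in VARIABLE_NAMES:
                if v.startswith("L_"):
                    i, j = index[v], index[bilateral_partner(v)]
                    corr[i, j] = corr[j, i] = self.rho
        return corr


def _check_correlation_matrix(corr: np.ndarray) -> None:
    p = len(VARIABLE_NAMES)
    if corr.shape != (p, p):
        raise ValueError(f"correlation matrix must be {p}x{p}")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.linalg.eigvalsh((corr + corr.T) / 2).min() < -1e-8:
        raise ValueError("correlation matrix must be positive semi-definite")


def load_cohort_fixture(name: str) -> SyntheticCohortSpec:
    """Load a packaged cohort fixture (``general``, ``young`` or ``older``)."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    text = (resources.files("gaitsep") / "fixtures" / f"{name}.json").read_text()
    raw = json.loads(text)
    groups = {
        label: GroupSpec(g["n"], [tuple(s) for s in g["age_strata"]])
        for label, g in raw["groups"].items()
    }
    variables = {
        v: {lab: tuple(cell[lab]) for lab in groups} for v, cell in raw["variables"].items()
    }
    sources = {v: cell["source"] for v, cell in raw["variables"].items()}
    spec = SyntheticCohortSpec(
        name=raw["name"], groups=groups, variables=variables, sources=sources
    )
    spec.validate()
    return spec


def generate_feature_cohort(
    spec: SyntheticCohortSpec, seed: int | None = None
) -> pd.DataFrame:
    """Draw a labelled feature cohort from the spec's per-group normals.

    Returns a DataFrame with columns ``subject_id, gender, age`` followed by
    the 72 canonical variables, one row per subject, groups in spec order.
    Deterministic for a fixed spec and seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    corr = spec.correlation_matrix()
    rows = []
    sid = 0
    for label, group in spec.groups.items():
        means = np.array([spec.variables[v][label][0] for v in VARIABLE_NAMES])
        sds = np.array([spec.variables[v][label][1] for v in VARIABLE_NAMES])
        cov = corr * np.outer(sds, sds)
        values = rng.multivariate_normal(means, cov, size=group.n, method="svd")
        ages = np.concatenate(
            [rng.uniform(low, high, size=count) for count, low, high in group.age_strata]
        )
        for i in range(group.n):
            rows.append((f"S{sid:04d}", label, ages[i], *values[i]))
            sid += 1
    return pd.DataFrame(
        rows, columns=list(DEMOGRAPHIC_COLUMNS) + list(VARIABLE_NAMES)
    )


# --------------------------------------------------------------------------
# Stride-level time series
# --------------------------------------------------------------------------


@dataclass
class ChannelShape:
    """Stance-waveform control values for one channel, in degrees.

    ``max_time``/``min_time`` are fractions of stance in (0, 1); a
    ``min_time`` of ``None`` places the minimum at toe-off (the toe-off value
    is then the stance minimum, as knee flexion behaves by definition of the
    toe-off event).
    """

    touchdown: float
    max_value: float
    max_time: float
    min_value: float
    min_time: float | None
    toeoff: float

    def knots(self) -> tuple[np.ndarray, np.ndarray]:
        pts = [(0.0, self.touchdown), (self.max_time, self.max_value)]
        if self.min_time is None:
            pts.append((1.0, self.min_value))
        else:
            pts.append((self.min_time, self.min_value))
            pts.append((1.0, self.toeoff))
        pts.sort(key=lambda q: q[0])
        t, v = zip(*pts)
        if len(set(t)) != len(t):
            raise ValueError("control times must be distinct")
        return np.array(t), np.array(v)

    def targets(self) -> tuple[float, float, float, float]:
        """Discrete quadruple implied by the shape (touchdown, max, min, toeoff)."""
        _, v = self.knots()
        return (self.touchdown, float(v.max()), float(v.min()), float(v[-1]))


def default_channel_shapes() -> dict[str, ChannelShape]:
    """Plausible stance shapes for all 18 channels, near the general-cohort means."""
    base = {
        ("hip", "sagittal"): ChannelShape(32.0, 34.0, 0.08, -8.0, None, -8.0),
        ("hip", "frontal"): ChannelShape(6.0, 10.5, 0.45, 0.5, 0.9, 4.5),
        ("hip", "transverse"): ChannelShape(10.9, 12.3, 0.3, -2.5, 0.92, -2.0),
        ("knee", "sagittal"): ChannelShape(16.0, 45.0, 0.4, 14.0, None, 14.0),
        ("knee", "frontal"): ChannelShape(-6.8, -3.7, 0.9, -9.7, 0.35, -6.5),
        ("knee", "transverse"): ChannelShape(-2.0, 8.0, 0.45, -6.0, 0.95, 0.0),
        ("ankle", "sagittal"): ChannelShape(-5.0, 13.5, 0.92, -23.0, 0.55, 12.0),
        ("ankle", "frontal"): ChannelShape(2.0, 5.0, 0.9, -6.4, 0.4, 3.0),
        ("ankle", "transverse"): ChannelShape(-2.0, 4.0, 0.5, -8.0, 0.9, -1.0),
    }
    return {
        f"{s}_{j}_{p}": base[(j, p)]
        for s in SIDES
        for (j, p) in base
    }


@dataclass
class StrideSimParams:
    """Parameters of the multi-stride simulator.

    Defaults emulate treadmill running at a self-selected pace: ~35
    consecutive strides of 0.6 s sampled at 200 Hz with a 38% stance
    fraction. ``noise_sd`` is additive Gaussian noise on the angle channels.
    """

    n_strides: int = 35
    stride_duration: float = 0.6
    stance_fraction: float = 0.38
    sampling_rate: float = 200.0
    shapes: dict[str, ChannelShape] = field(default_factory=default_channel_shapes)
    noise_sd: float = 0.0
    velocity_noise_sd: float = 0.0
    swing_bump: float = 30.0
    seed: int | None = None

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance fraction must lie in (0, 1)")
        if self.n_strides < 1:
            raise ValueError("need at least one stride")
        missing = set(CHANNEL_NAMES) - set(self.shapes)
        if missing:
            raise ValueError(f"missing channel shapes: {sorted(missing)}")


@dataclass
class AngleTimeSeries:
    """Multi-channel recording: 18 angle channels + per-side calcaneal vz."""

    sampling_rate: float
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")
        if lengths and min(lengths) < 2:
            raise ValueError("channels must have at least 2 samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_samples) / self.sampling_rate
        return pd.DataFrame({"time": t, **self.channels})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sampling_rate: float) -> "AngleTimeSeries":
        channels = {c: df[c].to_numpy(float) for c in df.columns if c != "time"}
        return cls(sampling_rate=sampling_rate, channels=channels)


def _stance_waveform(shape: ChannelShape, n: int) -> np.ndarray:
    """Evaluate the stance shape on n samples via monotone (pchip) interpolation.

    Pchip never overshoots between knots, so the stance extrema are exactly
    the knot extrema and the planted discrete targets are recoverable.
    """
    t, v = shape.knots()
    return PchipInterpolator(t, v)(np.linspace(0.0, 1.0, n))


def generate_stride_series(
    params: StrideSimParams, seed: int | None = None
) -> tuple[AngleTimeSeries, dict[str, dict[str, list[int]]]]:
    """Simulate consecutive strides with planted, exactly recoverable events.

    Returns the series plus ground truth ``{"L": {"contacts": [...],
    "toe_offs": [...]}, "R": ...}`` in sample indices. On the noiseless
    signal the calcaneal vz channel crosses positive-to-negative exactly at
    each planted contact and the knee sagittal channel attains its
    within-stance minimum exactly at each planted toe-off.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    S = int(round(params.stride_duration * params.sampling_rate))
    if S < 8:
        raise ValueError("stride too short for the sampling rate")
    stance = int(round(params.stance_fraction * S))
    stance = min(max(stance, 2), S - 2)
    lead = S // 4
    total = lead + params.n_strides * S + S // 4

    events: dict[str, dict[str, list[int]]] = {}
    channels: dict[str, np.ndarray] = {}
    offsets = {"L": 0, "R": S // 2}
    i = np.arange(total)
    for side in SIDES:
        first = lead + offsets[side]
        contacts = [first + k * S for k in range(params.n_strides)]
        toe_offs = [c + stance for c in contacts]
        events[side] = {"contacts": contacts, "toe_offs": toe_offs}

        # Calcaneal vertical velocity: periodic, one +/- crossing per stride,
        # planted exactly at each contact sample. Integer phase arithmetic
        # keeps the sign at phase 0 and pi deterministic.
        phase = (i - first) % S
        v = -np.sin(2 * np.pi * (phase / S))
        v[i >= contacts[-1] + S] = 1.0  # tail stays positive: no extra crossing
        if params.velocity_noise_sd > 0:
            v = v + rng.normal(0, params.velocity_noise_sd, total)
        channels[VELOCITY_CHANNELS[side]] = v

        for name, shape in params.shapes.items():
            if not name.startswith(side + "_"):
                continue
            y = np.full(total, shape.touchdown, dtype=float)
            stance_wave = _stance_waveform(shape, stance + 1)
            for c, t_off in zip(contacts, toe_offs):
                y[c : t_off + 1] = stance_wave
                # swing: rise from toe-off value over a mid-swing bump back to
                # the next touchdown value, monotone between knots (no dip
                # below the stance minimum for the toe-off detection window)
                swing_n = S - stance
                if swing_n >= 2:
                    bump = params.swing_bump if "knee_sagittal" in name else 0.0
                    tt = np.array([0.0, 0.5, 1.0])
                    vv = np.array(
                        [stance_wave[-1], (stance_wave[-1] + shape.touchdown) / 2 + bump,
                         shape.touchdown]
                    )
                    sw = PchipInterpolator(tt, vv)(np.linspace(0, 1, swing_n + 1))
                    end = min(t_off + swing_n + 1, total)
                    y[t_off : end] = sw[: end - t_off]
            if params.noise_sd > 0:
                y = y + rng.normal(0, params.noise_sd, total)
            channels[name] = y

    return AngleTimeSeries(params.sampling_rate, channels), events


def write_stride_series(
    series: AngleTimeSeries,
    events: dict[str, dict[str, list[int]]],
    csv_path,
    events_path=None,
) -> None:
    """Write the series as wide CSV plus a JSON sidecar of ground-truth events."""
    series.to_frame().to_csv(csv_path, index=False)
    if events_path is not None:
        with open(events_path, "w") as fh:
            json.dump(
                {"sampling_rate": series.sampling_rate, "events": events}, fh, indent=1
            )


def check_calibration(
    spec: SyntheticCohortSpec, table: pd.DataFrame, n_se: float = 3.0
) -> pd.DataFrame:
    """Compare sample means/SDs of a generated table with the spec, in SE units.

    Returns one row per (variable, group) with z-scores of the mean deviation;
    used by tests of distributional calibration.
    """
    recs = []
    for label, group in spec.groups.items():
        sub = table.loc[table["gender"] == label, list(VARIABLE_NAMES)]
        n = len(sub)
        for v in VARIABLE_NAMES:
            mean, sd = spec.variables[v][label]
            se = sd / np.sqrt(n) if sd > 0 else np.nan
            z = (sub[v].mean() - mean) / se if sd > 0 else 0.0
            recs.append((v, label, sub[v].mean(), mean, sd, z, abs(z) <= n_se if sd > 0 else True))
    return pd.DataFrame(
        recs, columns=["variable", "group", "sample_mean", "spec_mean", "spec_sd", "z", "ok"]
    )
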