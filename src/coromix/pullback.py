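"""Semi-quantitative pullback analysis of thermodilution temperature traces.

During a pullback the pressure/temperature sensor is retracted manually
from 6 cm distal of the catheter tip back to the tip in 15-30 s while the
temperature is recorded.  With proper mixing the trace is flat; an
unmixed cold core shows up as a cold near-tip segment.  The pipeline
follows the clinical recipe in a fixed order enforced by the types:

1. :func:`rolling_mean` — 2 s centred moving average on the raw trace;
2. :func:`resample_to_n` — normalize to N = 1000 points over the recorded
   span so traces of different pullback speed are comparable
   (returns a :class:`NormalizedTrace`);
3. :func:`relative_deviation_profile` — per-point percentage deviation
   from the pullback-mean temperature (computed on the degC reading as
   recorded, which is the scale on which the clinical percentages are
   defined);
4. :func:`exceedance_fraction` — percentage of points deviating more than
   a threshold (15% and 20% by convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import TraceError

N_NORMALIZED = 1000

__all__ = [
    "PullbackTrace",
    "NormalizedTrace",
    "DeviationProfile",
    "read_trace_csv",
    "rolling_mean",
    "resample_to_n",
    "relative_deviation_profile",
    "exceedance_fraction",
    "analyze_pullback",
]


@dataclass(frozen=True)
class PullbackTrace:
    """Time-stamped sensor temperature during one pullback.

    ``position_cm`` is the sensor position distal to the catheter tip
    (decreasing from ~6 to 0 over the recording).
    """

    time: np.ndarray
    position_cm: np.ndarray
    temperature: np.ndarray
    sample_rate_hz: float
    metadata: dict = field(default_factory=dict)
    #: plausibility window for the pullback duration, s (None disables)
    duration_bounds: tuple[float, float] | None = (10.0, 60.0)

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.position_cm, dtype=float)
        temp = np.asarray(self.temperature, dtype=float)
        if not (t.shape == p.shape == temp.shape) or t.ndim != 1:
            raise TraceError("time, position and temperature must be equal-length 1D")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise TraceError("time stamps must be strictly increasing")
        if np.any(np.diff(p) > 1e-9):
            raise TraceError("sensor position must be monotone non-increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "position_cm", p)
        object.__setattr__(self, "temperature", temp)
        if self.duration_bounds is not None and t.size >= 2:
            lo, hi = self.duration_bounds
            if not (lo <= self.duration <= hi):
                raise TraceError(
                    f"pullback duration {self.duration:.1f} s outside the "
                    f"plausibility window [{lo}, {hi}] s"
                )

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass(frozen=True)
class NormalizedTrace:
    """A pullback trace resampled onto N uniformly spaced positions."""

    position_cm: np.ndarray
    temperature: np.ndarray
    n_points: int
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DeviationProfile:
    """Relative temperature deviation along a normalized pullback.

    ``relative_deviation`` is the per-point percentage deviation from the
    pullback-mean temperature; its mean is zero by construction.
    """

    position_cm: np.ndarray
    relative_deviation: np.ndarray  # percent
    mean_temperature: float  # degC
    exceedance_15: float  # percent of points
    exceedance_20: float

    @property
    def n_points(self) -> int:
        return self.relative_deviation.size


def read_trace_csv(
    path,
    sample_rate_hz: float | None = None,
    span_cm: float = 6.0,
    duration_bounds: tuple[float, float] | None = (10.0, 60.0),
) -> PullbackTrace:
    """Load a recorded pullback from CSV.

    Expects columns ``time_s`` and ``temperature_C``; an optional
    ``position_cm`` column overrides the default assumption of a constant
    pullback speed over ``span_cm``.
    """
    df = pd.read_csv(path, comment="#")
    for col in ("time_s", "temperature_C"):
        if col not in df.columns:
            raise TraceError(f"column {col!r} missing from {path}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise TraceError("trace must contain at least 2 samples")
    if "position_cm" in df.columns:
        pos = df["position_cm"].to_numpy(dtype=float)
    else:
        pos = span_cm * (1.0 - (t - t[0]) / (t[-1] - t[0]))
    if sample_rate_hz is None:
        sample_rate_hz = (t.size - 1) / (t[-1] - t[0])
    return PullbackTrace(
        time=t,
        position_cm=pos,
        temperature=df["temperature_C"].to_numpy(dtype=float),
        sample_rate_hz=float(sample_rate_hz),
        metadata={"source": str(path)},
        duration_bounds=duration_bounds,
    )


def rolling_mean(trace: PullbackTrace, window_s: float = 2.0) -> PullbackTrace:
    """Centred moving average over ``window_s`` seconds of the raw trace.

    The window shrinks symmetrically at the edges; positions are left
    untouched.  Matches the smoothing applied to clinical recordings.
    """
    if not isinstance(trace, PullbackTrace):
        raise TraceError("rolling_mean smooths the raw recording, before resampling")
    if window_s <= 0:
        raise TraceError("window must be positive")
    if window_s >= trace.duration:
        raise TraceError(
            f"window {window_s} s must be shorter than the trace ({trace.duration:.1f} s)"
        )
    n_win = int(round(window_s * trace.sample_rate_hz))
    n_win = max(n_win | 1, 1)  # odd so the window is centred
    smoothed = (
        pd.Series(trace.temperature)
        .rolling(n_win, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return replace(trace, temperature=smoothed)


def resample_to_n(trace: PullbackTrace, n: int = N_NORMALIZED) -> NormalizedTrace:
    """Linear interpolation onto ``n`` uniformly spaced positions.

    Normalizing every recording to the same number of points over its
    recorded span makes traces with different pullback times directly
    comparable; the endpoints are preserved exactly.
    """
    if not isinstance(trace, PullbackTrace):
        raise TraceError("resampling applies to a raw (optionally smoothed) trace")
    if trace.time.size < 2:
        raise TraceError("cannot resample a trace with fewer than 2 points")
    if n < 2:
        raise TraceError("n must be at least 2")
    # positions run high -> low; np.interp needs ascending abscissae
    p = trace.position_cm[::-1]
    temp = trace.temperature[::-1]
    targets = np.linspace(trace.position_cm[0], trace.position_cm[-1], n)
    resampled = np.interp(targets[::-1], p, temp)[::-1]
    return NormalizedTrace(
        position_cm=targets,
        temperature=resampled,
        n_points=n,
        metadata=dict(trace.metadata),
    )


def relative_deviation_profile(trace: NormalizedTrace) -> DeviationProfile:
    """Per-point percentage deviation from the pullback-mean temperature.

    ``dT_rel,i = (T_i - T_mean) / T_mean * 100%`` with ``T_mean`` the
    arithmetic mean of the normalized points, evaluated on the recorded
    degC scale.  The profile's own mean is zero by construction.
    """
    if not isinstance(trace, NormalizedTrace):
        raise TraceError(
            "relative deviations are defined on the N-point normalized "
            "trace; resample first"
        )
    temp = np.asarray(trace.temperature, dtype=float)
    mean = float(temp.mean())
    if mean == 0.0:
        raise TraceError("mean temperature is zero; relative deviation undefined")
    dev = (temp - mean) / mean * 100.0
    return DeviationProfile(
        position_cm=trace.position_cm,
        relative_deviation=dev,
        mean_temperature=mean,
        exceedance_15=exceedance_fraction(dev, 15.0),
        exceedance_20=exceedance_fraction(dev, 20.0),
    )


def exceedance_fraction(profile, threshold: float) -> float:
    """Percentage of points with ``|dT_rel| > threshold`` (both in %)."""
    if threshold <= 0:
        raise TraceError("threshold must be positive")
    dev = (
        profile.relative_deviation
        if isinstance(profile, DeviationProfile)
        else np.asarray(profile, dtype=float)
    )
    return float(100.0 * np.count_nonzero(np.abs(dev) > threshold) / dev.size)


def analyze_pullback(
    trace: PullbackTrace,
    window_s: float = 2.0,
    n: int = N_NORMALIZED,
) -> DeviationProfile:
    """Full pipeline in the clinical order: smooth, normalize, deviations."""
    return relative_deviation_profile(resample_to_n(rolling_mean(trace, window_s), n))
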