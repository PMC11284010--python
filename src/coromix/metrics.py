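"""Cross-section mixing statistics: SD_t, dilution probability, entropy ratio.

Two scalar measures quantify how homogeneously the infusate has mixed into
the blood at a cross-section distal to the injection site:

* ``SD_t`` — the standard deviation of the time-averaged temperature over
  sample points spread uniformly by area across the lumen; 0 means the
  temperature is uniform over the cross-section.
* the entropy ratio ``E`` — a Shannon-entropy homogeneity index on the
  dilution probability ``P = (Tb - T) / (Tb - Ti)`` (the fractional
  thermal contribution of infusate at a point):

  ``E = mean_k(-P_k ln P_k) / (-P* ln P*)``

  normalized by the entropy of the perfect-mixing fraction
  ``P* = Qi / (Qb + Qi)`` so that a perfectly mixed section gives exactly
  E = 1 (values slightly above 1 are possible because the point entropy
  peaks at P = 1/e, not at P*).  When no infusate has reached any sample
  point (all ``P_k = 0``) the numerator vanishes and E is not calculable.

Sample points at the pressure/temperature wire are excluded from both
measures.  Time averages run over the stored snapshots of the final
simulated cardiac cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import VesselCatheterGeometry, WirePlacement, perfect_mix_fraction
from .errors import InvalidProtocolError, RangeError, SamplingError

logger = logging.getLogger(__name__)

__all__ = [
    "CrossSectionSample",
    "MixingMeasures",
    "sample_grid",
    "time_averaged_temperatures",
    "cross_section_sd",
    "dilution_probability",
    "entropy_ratio",
    "station_measures",
    "longitudinal_profile",
    "measures_table",
]


@dataclass(frozen=True)
class CrossSectionSample:
    """Polar sample lattice at one axial station.

    ``wire_mask`` flags points whose representative area patch touches the
    wire footprint; they are excluded from every statistic.
    """

    station_cm: float
    r: np.ndarray
    theta: np.ndarray
    wire_mask: np.ndarray
    temperatures: np.ndarray | None = None  # (n_times, n_points)

    @property
    def n_points(self) -> int:
        return self.r.size

    @property
    def n_used(self) -> int:
        return int(np.count_nonzero(~self.wire_mask))


@dataclass(frozen=True)
class MixingMeasures:
    """SD_t and entropy ratio at one station."""

    station_cm: float
    sd_t: float
    entropy_ratio: float  # NaN when not calculable
    n_used: int
    calculable: bool


def sample_grid(
    geometry: VesselCatheterGeometry,
    station_cm: float,
    n_radial: int = 8,
    n_angular: int = 16,
) -> CrossSectionSample:
    """Deterministic polar lattice covering the lumen uniformly by area.

    Radii sit at the equal-area ring midpoints ``R sqrt((i + 1/2) / n_r)``
    so every point represents the same lumen area.  Points whose area
    patch (the annular sector between adjacent equal-area rings and angle
    bounds) intersects the wire footprint at this station are masked.
    """
    if n_radial < 1 or n_angular < 2:
        raise SamplingError("need n_radial >= 1 and n_angular >= 2")
    radius = geometry.vessel_radius
    ring_edges = radius * np.sqrt(np.arange(n_radial + 1) / n_radial)
    r = radius * np.sqrt((np.arange(n_radial) + 0.5) / n_radial)
    theta = (np.arange(n_angular) + 0.5) * 2.0 * np.pi / n_angular
    rr, tt = np.meshgrid(r, theta, indexing="ij")
    r_in = np.repeat(ring_edges[:-1], n_angular)
    r_out = np.repeat(ring_edges[1:], n_angular)
    th_lo = np.tile(theta - np.pi / n_angular, n_radial)
    th_hi = np.tile(theta + np.pi / n_angular, n_radial)

    if geometry.wire_placement is WirePlacement.INSIDE:
        wire_r, wire_th = 0.0, 0.0
    else:
        wire_r = geometry.catheter_radius + geometry.wire_radius
        wire_th = 0.0
    # minimum distance from the wire axis to each annular-sector patch
    dist = _point_to_sector_distance(wire_r, wire_th, r_in, r_out, th_lo, th_hi)
    mask = dist < geometry.wire_radius
    return CrossSectionSample(
        station_cm=station_cm,
        r=rr.ravel(),
        theta=tt.ravel(),
        wire_mask=mask,
    )


def _point_to_sector_distance(pr, pth, r_in, r_out, th_lo, th_hi):
    """Distance from a point (polar) to annular sectors (vectorized)."""
    # wrap the point angle into each sector's frame
    rel = np.mod(pth - th_lo, 2.0 * np.pi)
    width = th_hi - th_lo
    inside_angle = rel <= width
    r_cl = np.clip(pr, r_in, r_out)
    # if angularly inside: distance is purely radial
    d_inside = np.abs(pr - r_cl)
    # else: nearest point is on a bounding radial edge
    ang = np.where(rel - width < 2.0 * np.pi - rel, th_hi, th_lo)
    px, py = pr * np.cos(pth), pr * np.sin(pth)
    ex = np.cos(ang)
    ey = np.sin(ang)
    proj = np.clip(px * ex + py * ey, r_in, r_out)
    d_edge = np.hypot(px - proj * ex, py - proj * ey)
    return np.where(inside_angle, d_inside, d_edge)


def time_averaged_temperatures(field, sample: CrossSectionSample):
    """Per-point mean temperature over the final cardiac cycle.

    Returns ``(T_mk, T_bar)``: the per-point time averages and their mean
    over unmasked points.  Uses periodic-trapezoid weights over the stored
    snapshots and bilinear interpolation in the cross-section plane.
    """
    from scipy.interpolate import RegularGridInterpolator

    z = field.station_z(sample.station_cm)
    times, planes = field.plane_timeseries(z, fill=True)
    if times.size < 2:
        raise SamplingError("need at least 2 stored snapshots for time averaging")
    g = field.grid
    idx = field.last_cycle_indices()
    weights = field.cycle_weights(idx)
    theta_ext = np.concatenate(
        [[g.theta_centers[0] - g.dtheta], g.theta_centers, [g.theta_centers[-1] + g.dtheta]]
    )
    r_q = np.clip(sample.r, g.r_centers[0], g.r_centers[-1])
    pts = np.column_stack([r_q, sample.theta])
    t_mk = np.zeros(sample.n_points)
    for w, plane in zip(weights, planes):
        padded = np.concatenate([plane[:, -1:], plane, plane[:, :1]], axis=1)
        interp = RegularGridInterpolator(
            (g.r_centers, theta_ext), padded, method="linear",
            bounds_error=False, fill_value=None,
        )
        t_mk += w * interp(pts)
    used = ~sample.wire_mask
    if np.count_nonzero(used) < 2:
        raise SamplingError("fewer than 2 unmasked sample points")
    return t_mk, float(t_mk[used].mean())


def cross_section_sd(
    values, mean: float | None = None, *, method: str = "rms"
) -> float:
    """Spread of the time-averaged temperatures over a cross-section, degC.

    ``method="rms"`` (default) is the root-mean-square deviation
    ``sqrt(sum (T_mk - Tbar)^2 / n)``; ``method="mad"`` is the mean
    absolute deviation ``sum |T_mk - Tbar| / n`` — both renderings of the
    same uniformity measure (0 iff the section is uniform).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise SamplingError("SD_t needs at least 2 unmasked values")
    m = float(v.mean()) if mean is None else mean
    dev = v - m
    if method == "rms":
        return float(np.sqrt(np.mean(dev**2)))
    if method == "mad":
        return float(np.mean(np.abs(dev)))
    raise ValueError(f"unknown method {method!r}")


def dilution_probability(temperature, tb: float, ti: float):
    """Fractional infusate contribution ``P = (Tb - T) / (Tb - Ti)``.

    1 means pure infusate, 0 pure blood.  Values outside [0, 1] (numerical
    overshoot) are clamped with a logged warning.
    """
    if tb <= ti:
        raise InvalidProtocolError("blood temperature must exceed infusate temperature")
    t = np.asarray(temperature, dtype=float)
    p = (tb - t) / (tb - ti)
    if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
        logger.warning(
            "dilution probability outside [0, 1] (range %.4f..%.4f); clamping",
            float(p.min()),
            float(p.max()),
        )
    p = np.clip(p, 0.0, 1.0)
    return p if p.ndim else float(p)


def entropy_ratio(p_values, p_star: float, *, base: float | None = None) -> float:
    """Entropy-based homogeneity index of a cross-section.

    ``E = mean_k(-P_k log P_k) / (-P* log P*)`` with ``0 log 0 := 0``.
    E = 1 when every point sits at the perfect-mixing fraction ``P*``.
    Returns NaN (not calculable) when every ``P_k`` is 0, i.e. no infusate
    reached the station.  The ratio is independent of the logarithm base;
    ``base`` is exposed for verification.
    """
    if not (0.0 < p_star < 1.0):
        raise InvalidProtocolError("perfect-mixing fraction must lie in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    if p.size < 2:
        raise SamplingError("entropy ratio needs at least 2 unmasked values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    log = np.log if base is None else (lambda x: np.log(x) / np.log(base))
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, -p * log(np.where(p > 0, p, 1.0)), 0.0)
    if not np.any(p > 0):
        return float("nan")
    return float(plogp.mean() / (-p_star * log(p_star)))


def raw_mean_entropy(p_values, *, base: float | None = None) -> float:
    """Un-normalized mean point entropy ``mean_k(-P_k log P_k)`` (audit)."""
    p = np.asarray(p_values, dtype=float)
    log = np.log if base is None else (lambda x: np.log(x) / np.log(base))
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, -p * log(np.where(p > 0, p, 1.0)), 0.0)
    return float(plogp.mean())


def station_measures(
    field,
    station_cm: float,
    n_radial: int = 8,
    n_angular: int = 16,
    sd_method: str = "rms",
) -> MixingMeasures:
    """SD_t and entropy ratio at one station of a simulated field."""
    sample = sample_grid(field.geometry, station_cm, n_radial, n_angular)
    t_mk, t_bar = time_averaged_temperatures(field, sample)
    used = ~sample.wire_mask
    sd = cross_section_sd(t_mk[used], t_bar, method=sd_method)
    prot = field.protocol
    p = dilution_probability(
        t_mk[used], prot.blood_temperature, prot.infusate_exit_temperature
    )
    p_star = perfect_mix_fraction(prot.coronary_flow_mean, prot.infusion_rate)
    e = entropy_ratio(p, p_star)
    return MixingMeasures(
        station_cm=station_cm,
        sd_t=sd,
        entropy_ratio=e,
        n_used=int(np.count_nonzero(used)),
        calculable=bool(np.isfinite(e)),
    )


def longitudinal_profile(
    field,
    stations_cm=None,
    n_radial: int = 8,
    n_angular: int = 16,
    sd_threshold: float = 0.1,
) -> tuple[list[MixingMeasures], float]:
    """Measures along the vessel plus the station where SD_t first settles.

    Default stations run from the injection site to 4.8 cm distal.
    Returns ``(measures, settling_station_cm)`` where the settling station
    is the first station with ``SD_t < sd_threshold`` (NaN if none).
    """
    if stations_cm is None:
        stations_cm = np.arange(0.0, 4.81, 0.2)
    stations_cm = np.asarray(stations_cm, dtype=float)
    max_cm = (field.geometry.vessel_length - field.z_injection) / 10.0
    if stations_cm.min() < 0 or stations_cm.max() > max_cm + 1e-9:
        raise RangeError(
            f"stations must lie within 0 to {max_cm:.1f} cm distal of the injection site"
        )
    measures = [
        station_measures(field, s, n_radial, n_angular) for s in stations_cm
    ]
    settling = float("nan")
    for m in measures:
        if m.sd_t < sd_threshold:
            settling = m.station_cm
            break
    return measures, settling


def measures_table(fields, stations_cm=(1.2, 4.4), **kwargs) -> pd.DataFrame:
    """Tabulate SD_t / E for several simulated fields — one row per
    (catheter, combination, station), the machine-readable analogue of a
    results table."""
    rows = []
    for f in fields:
        for s in stations_cm:
            m = station_measures(f, s, **kwargs)
            rows.append(
                {
                    "catheter": f.protocol.catheter.value,
                    "coronary_flow": f.protocol.coronary_flow_mean,
                    "infusion_rate": f.protocol.infusion_rate,
                    "station_cm": s,
                    "sd_t": m.sd_t,
                    "entropy_ratio": m.entropy_ratio,
                    "n_used": m.n_used,
                    "calculable": m.calculable,
                }
            )
    return pd.DataFrame(rows)
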