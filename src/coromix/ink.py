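"""Projectional pass/fail mixing assessment and pass-rate tabulation.

The bench experiment films an ink-saline cloud from one side and calls the
mixing a 'pass' when the colour is uniform over the projected diameter
within 1-3 cm of the catheter tip.  Here that visual judgement is
operationalized: the simulated temperature field is converted to dilution
probability, averaged along the viewing line of sight and over one cardiac
cycle, and a station passes when the coefficient of variation (CV) of the
projected intensity across the diameter stays below a threshold.  The
threshold is an explicit, configurable operationalization of a judgement
that was human and binary in the laboratory — not a claim of equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoromixError, RangeError
from .metrics import dilution_probability

#: Default CV-across-diameter threshold separating pass from fail.
#: Calibrated on the simulated MED/15 pair: side-hole projections sit far
#: below it, the end-hole cold-core streak far above.
DEFAULT_CV_THRESHOLD = 0.35

__all__ = [
    "ProjectedImage",
    "MixingVerdict",
    "project_field",
    "classify_mixing",
    "tabulate_pass_fail",
    "DEFAULT_CV_THRESHOLD",
]


@dataclass(frozen=True)
class ProjectedImage:
    """Line-of-sight mean dilution probability, as a camera would see it.

    ``intensity[i, j]`` is the mean dilution probability along the viewing
    axis at axial position ``axial_cm[i]`` (from the catheter tip) and
    transverse position ``transverse_mm[j]`` across the projected
    diameter.  NaN marks transverse bins with no lumen on the chord.
    """

    axial_cm: np.ndarray
    transverse_mm: np.ndarray
    intensity: np.ndarray
    view_axis: str


@dataclass(frozen=True)
class MixingVerdict:
    verdict: str  # "PASS" | "FAIL"
    worst_station_cm: float
    uniformity_scores: dict = field(default_factory=dict)  # station -> CV
    cv_threshold: float = DEFAULT_CV_THRESHOLD

    @property
    def passed(self) -> bool:
        return self.verdict == "PASS"


def project_field(field_, view_axis: str = "x", n_transverse: int | None = None) -> ProjectedImage:
    """Project the cycle-averaged dilution field along one viewing axis.

    Converts temperature to dilution probability, time-averages the final
    cycle, then volume-weight-averages the lumen cells along the chosen
    line of sight (``"x"`` views along x so the transverse coordinate is
    y, and vice versa).
    """
    if view_axis not in ("x", "y"):
        raise ValueError("view_axis must be 'x' or 'y'")
    g = field_.grid
    prot = field_.protocol
    idx = field_.last_cycle_indices()
    wts = field_.cycle_weights(idx)
    with np.errstate(invalid="ignore"):
        mean_t = np.tensordot(wts, field_.temperature[idx], axes=(0, 0))
    lumen = ~np.isnan(mean_t)
    p = np.zeros_like(mean_t)
    p[lumen] = dilution_probability(
        mean_t[lumen], prot.blood_temperature, prot.infusate_exit_temperature
    )

    if n_transverse is None:
        n_transverse = 2 * g.nr
    rr = g.r_centers[:, None] * np.ones((1, g.ntheta))
    tt = np.ones((g.nr, 1)) * g.theta_centers[None, :]
    transverse = rr * (np.sin(tt) if view_axis == "x" else np.cos(tt))
    edges = np.linspace(-g.geometry.vessel_radius, g.geometry.vessel_radius, n_transverse + 1)
    bins = np.clip(np.digitize(transverse.ravel(), edges) - 1, 0, n_transverse - 1)
    vol = np.broadcast_to(g.cell_volume[:, None], (g.nr, g.ntheta)).ravel()

    intensity = np.full((g.nz, n_transverse), np.nan)
    for i in range(g.nz):
        w = vol * lumen[i].ravel()
        num = np.bincount(bins, weights=w * p[i].ravel(), minlength=n_transverse)
        den = np.bincount(bins, weights=w, minlength=n_transverse)
        with np.errstate(invalid="ignore"):
            intensity[i] = np.where(den > 0, num / den, np.nan)

    axial_cm = (g.z_centers - field_.z_injection) / 10.0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ProjectedImage(
        axial_cm=axial_cm,
        transverse_mm=centers,
        intensity=intensity,
        view_axis=view_axis,
    )


def classify_mixing(
    image: ProjectedImage,
    window_cm: tuple[float, float] = (1.0, 3.0),
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
) -> MixingVerdict:
    """PASS iff the projected intensity is uniform across the diameter at
    every station inside the assessment window.

    Uniformity per station is the coefficient of variation of the valid
    transverse bins; a uniform (even all-zero) profile scores 0.  Raising
    the threshold can only turn FAIL into PASS.
    """
    lo, hi = window_cm
    if lo >= hi:
        raise ValueError("window must be (low, high) with low < high")
    in_window = (image.axial_cm >= lo) & (image.axial_cm <= hi)
    if not in_window.any():
        raise RangeError(
            f"assessment window [{lo}, {hi}] cm lies outside the image "
            f"({image.axial_cm.min():.2f} to {image.axial_cm.max():.2f} cm)"
        )
    scores = {}
    for i in np.flatnonzero(in_window):
        row = image.intensity[i]
        valid = row[np.isfinite(row)]
        if valid.size < 2:
            raise CoromixError("projected image has fewer than 2 valid bins")
        mean = float(valid.mean())
        sd = float(valid.std())
        scores[float(image.axial_cm[i])] = 0.0 if sd == 0.0 else sd / max(mean, 1e-12)
    worst = max(scores, key=scores.get)
    verdict = "PASS" if all(cv <= cv_threshold for cv in scores.values()) else "FAIL"
    return MixingVerdict(
        verdict=verdict,
        worst_station_cm=worst,
        uniformity_scores=scores,
        cv_threshold=cv_threshold,
    )


def tabulate_pass_fail(results) -> tuple[pd.DataFrame, dict]:
    """Contingency table and pass rates from per-replicate verdicts.

    ``results`` is either a mapping ``(catheter, category, replicate) ->
    verdict`` (bool, "PASS"/"FAIL", or :class:`MixingVerdict`) or a
    DataFrame with columns ``catheter, category, passed``.  Returns the
    stratified fail/pass counts and per-catheter pass percentages (both
    exact and rounded to the nearest integer, the convention used when
    reporting such rates).
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        if not results:
            raise CoromixError("empty verdict table")
        rows = []
        for key, v in results.items():
            cath, category = key[0], key[1]
            if isinstance(v, MixingVerdict):
                passed = v.passed
            elif isinstance(v, str):
                passed = v.upper() == "PASS"
            else:
                passed = bool(v)
            rows.append({"catheter": str(cath), "category": str(category), "passed": passed})
        df = pd.DataFrame(rows)
    if df.empty:
        raise CoromixError("empty verdict table")

    table = (
        df.groupby(["catheter", "category"])["passed"]
        .agg(fail=lambda s: int((~s).sum()), **{"pass": lambda s: int(s.sum())})
        .reset_index()
    )
    rates = {}
    for cath, sub in df.groupby("catheter"):
        n_pass = int(sub["passed"].sum())
        n = len(sub)
        exact = 100.0 * n_pass / n
        rates[cath] = {
            "pass": n_pass,
            "fail": n - n_pass,
            "total": n,
            "rate_percent": int(round(exact)),
            "rate_exact": exact,
        }
    return table, rates
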