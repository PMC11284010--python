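"""Run configuration: YAML-backed parameters for the whole pipeline.

The bundled ``data/default_config.yaml`` spells out the study design (flow
categories, the nine clinical flow/infusion cells, the simulated subset)
and the vessel/catheter geometry; a user YAML overrides any subset of it.
Every output embeds the configuration hash, seed and software version so
runs are reproducible and traceable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

from .design import (
    CatheterType,
    FlowCategory,
    FlowProtocol,
    VesselCatheterGeometry,
)
from .errors import CoromixError, RangeError
from .grid import SolverResolution
from .transport import MixingModel

__all__ = ["RunConfig", "load_default_config", "config_hash"]

_CATHETER_ALIASES = {
    "sidehole": CatheterType.SIDE_HOLE,
    "side_hole": CatheterType.SIDE_HOLE,
    "rayflow": CatheterType.SIDE_HOLE,
    "endhole": CatheterType.END_HOLE,
    "end_hole": CatheterType.END_HOLE,
    "finecross": CatheterType.END_HOLE,
}


def parse_catheter(name) -> CatheterType:
    if isinstance(name, CatheterType):
        return name
    try:
        return _CATHETER_ALIASES[str(name).lower()]
    except KeyError:
        raise CoromixError(f"unknown catheter {name!r}") from None


def parse_combo(text: str) -> tuple[str, float]:
    """Parse a ``CATEGORY:rate`` string like ``LOW:8``."""
    try:
        cat, rate = str(text).split(":")
        return FlowCategory(cat.strip().upper()).value, float(rate)
    except (ValueError, KeyError) as exc:
        raise CoromixError(f"cannot parse combination {text!r} (want e.g. LOW:8)") from exc


def load_default_config() -> dict:
    """The bundled default configuration as a plain dict."""
    text = resources.files("coromix").joinpath("data/default_config.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass(frozen=True)
class RunConfig:
    """Validated, resolved configuration for one pipeline run."""

    raw: dict
    catheters: tuple[CatheterType, ...]
    combos: tuple[tuple[str, float], ...]
    geometry_overrides: dict
    resolution: SolverResolution
    mixing: MixingModel
    stations_cm: tuple[float, ...]
    profile_stations_cm: tuple[float, ...]
    pullback: dict
    cv_threshold: float
    pulsatility: float
    seed: int
    outdir: Path
    write_fields: bool

    @classmethod
    def load(
        cls,
        path: str | Path | None = None,
        overrides: dict | None = None,
    ) -> "RunConfig":
        cfg = load_default_config()
        if path is not None:
            with open(path) as fh:
                cfg = _deep_merge(cfg, yaml.safe_load(fh) or {})
        cfg = _deep_merge(cfg, overrides or {})
        run = cfg.get("run", {})

        catheters = tuple(parse_catheter(c) for c in run.get("catheters", []))
        combos = run.get("combos")
        if combos:
            combos = tuple(parse_combo(c) for c in combos)
        else:
            combos = tuple(
                (cat, float(rate)) for cat, rate in cfg["simulated_combinations"]
            )
        prof = run.get("profile_stations_cm", {})
        import numpy as np

        profile = tuple(
            float(s)
            for s in np.arange(
                prof.get("start", 0.0),
                prof.get("stop", 4.8) + 1e-9,
                prof.get("step", 0.4),
            )
        )
        res = run.get("resolution", {})
        resolution = SolverResolution(
            n_axial=int(res.get("n_axial", 63)),
            n_radial=int(res.get("n_radial", 10)),
            n_angular=int(res.get("n_angular", 16)),
            cfl=float(res.get("cfl", 0.7)),
            snapshots_per_cycle=int(res.get("snapshots_per_cycle", 32)),
            n_cycles=int(res.get("n_cycles", 2)),
        )
        mix = run.get("mixing", {})
        mixing = MixingModel(
            molecular_diffusivity=float(mix.get("molecular_diffusivity", 0.143)),
            side_jet_coefficient=float(mix.get("side_jet_coefficient", 0.02)),
            end_jet_coefficient=float(mix.get("end_jet_coefficient", 0.002)),
            decay_length_mm=float(mix.get("decay_length_mm", 15.0)),
        )
        stations = tuple(float(s) for s in run.get("stations_cm", (1.2, 4.4)))
        geometry = dict(cfg.get("geometry", {}))
        geo_probe = VesselCatheterGeometry(
            **{k: v for k, v in geometry.items() if k != "wire_placement"}
        )
        max_cm = (geo_probe.vessel_length - geo_probe.outlet_axial_position) / 10.0
        for s in stations + profile:
            if not (0.0 <= s <= max_cm + 1e-9):
                raise RangeError(f"station {s} cm outside the vessel extent")
        return cls(
            raw=cfg,
            catheters=catheters or tuple(CatheterType),
            combos=combos,
            geometry_overrides=geometry,
            resolution=resolution,
            mixing=mixing,
            stations_cm=stations,
            profile_stations_cm=profile,
            pullback=dict(run.get("pullback", {})),
            cv_threshold=float(run.get("cv_threshold", 0.35)),
            pulsatility=float(run.get("pulsatility", 0.9)),
            seed=int(run.get("seed", 0)),
            outdir=Path(run.get("outdir", "coromix_out")),
            write_fields=bool(run.get("write_fields", False)),
        )

    def geometry_for(self, catheter: CatheterType) -> VesselCatheterGeometry:
        kwargs = {k: v for k, v in self.geometry_overrides.items() if k != "wire_placement"}
        return VesselCatheterGeometry.for_catheter(catheter, **kwargs)

    def protocol_for(self, catheter: CatheterType, category: str, rate: float) -> FlowProtocol:
        cat = FlowCategory(category)
        return FlowProtocol(
            coronary_category=cat,
            coronary_flow_mean=cat.mean_flow_ml_min,
            infusion_rate=rate,
            catheter=catheter,
            blood_temperature=float(self.raw.get("blood_temperature_C", 37.0)),
            infusate_exit_temperature=float(
                self.raw.get("infusate_exit_temperature_C", 29.0)
            ),
            cardiac_period=float(self.raw.get("cardiac_period_s", 1.0)),
        )

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=int(seed))

    @property
    def hash(self) -> str:
        return config_hash(self.raw)


def config_hash(cfg: dict) -> str:
    """Short stable hash of a configuration dict."""
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha1(canon.encode()).hexdigest()[:12]
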