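"""One-command pipeline: tables or simulation -> both estimators -> report."""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .ctds import CtdsConfig, bootstrap_ctds
from .observations import (
    CameraDeployment,
    ObservationSet,
    read_observations,
    write_observations,
)
from .rem import RemConfig, rem_estimate
from .synthetic import (
    GPSTrack,
    HalfNormalDetection,
    ConstantDetection,
    SimulationTruth,
    UniformActivity,
    VonMisesActivity,
    simulate_detections,
    simulate_gps_track,
    simulate_movement,
)

__all__ = ["SurveyReport", "make_fixture", "run_pipeline"]


@dataclass
class SurveyReport:
    ctds: dict
    rem: dict | None
    parameters: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2, default=_jsonable)

    def to_markdown(self) -> str:
        lines = ["# Survey report", "", "| parameter | value |", "|---|---|"]
        for k, v in sorted(self.parameters.items()):
            lines.append(f"| {k} | {v} |")
        lines.append("")
        for name, block in (("CTDS", self.ctds), ("REM", self.rem)):
            if block is None:
                continue
            lines.append(
                f"**{name}**: {block['density']:.3g}/km^2 "
                f"[{block['ci_low']:.3g}-{block['ci_high']:.3g}], CV {block['cv']:.3g}"
            )
        return "\n".join(lines)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(type(x))


def _activity_from_spec(spec: dict):
    kind = spec.get("kind", "uniform")
    if kind == "uniform":
        return UniformActivity(level=float(spec.get("level", 1.0)))
    if kind == "vonmises":
        return VonMisesActivity(
            mus=tuple(spec.get("mus", [math.pi])),
            kappas=tuple(spec.get("kappas", [1.0])),
            weights=tuple(spec.get("weights", [1.0])),
        )
    raise ValueError(f"unknown activity kind {kind!r}")


def _detection_from_spec(spec: dict):
    kind = spec.get("kind", "constant")
    if kind == "constant":
        return ConstantDetection(p=float(spec.get("p", 1.0)))
    if kind == "halfnormal":
        return HalfNormalDetection(sigma=float(spec["sigma"]))
    raise ValueError(f"unknown detection kind {kind!r}")


def _grid_deployments(sim: dict, arena_km: float, duration: int) -> list[CameraDeployment]:
    n = int(sim.get("n_cameras", 9))
    side = math.ceil(math.sqrt(n))
    L = arena_km * 1000.0
    deps = []
    mech = sim.get("camera", {})
    for i in range(n):
        gx, gy = i % side, i // side
        deps.append(
            CameraDeployment(
                camera_id=f"cam{i:03d}",
                x=(gx + 0.5) * L / side,
                y=(gy + 0.5) * L / side,
                start=0.0,
                end=float(duration),
                nominal_half_angle=float(mech.get("half_angle", 0.37)),
                max_tag_distance=float(mech.get("max_tag_distance", 25.0)),
                recovery_time=float(mech.get("recovery_s", 10.35)),
                burst_size=int(mech.get("burst_size", 6)),
                intra_burst_interval=float(mech.get("burst_interval_s", 0.49)),
                bearing=float(mech.get("bearing", 0.0)),
            )
        )
    return deps


def _simulate(sim: dict, seed: int) -> tuple[ObservationSet, GPSTrack, dict]:
    duration = int(sim.get("duration_days", 1) * 86400)
    truth = SimulationTruth(
        true_density=float(sim.get("density", 2.0)),
        n_groups=int(sim.get("n_groups", 1)),
        group_sizes=sim.get("group_sizes"),
        speed_active=float(sim.get("speed_active", 1.0)),
        activity=_activity_from_spec(sim.get("activity", {})),
        group_spread=float(sim.get("group_spread", 0.0)),
        arena_km=float(sim.get("arena_km", 2.0)),
        turning_sd=float(sim.get("turning_sd", 0.1)),
        seed=seed,
    )
    tracks = simulate_movement(truth, duration_s=duration)
    deps = _grid_deployments(sim, truth.arena_km, duration)
    obs = simulate_detections(
        tracks,
        deps,
        detection=_detection_from_spec(sim.get("detection", {})),
        seed=seed + 1,
        arena_km=truth.arena_km,
    )
    if tracks:
        gps = simulate_gps_track(tracks[0], fix_interval=float(sim.get("fix_interval", 3600)))
    else:  # empty arena (density -> 0 limit)
        gps = GPSTrack(fixes=np.empty((0, 3)), fix_interval=float(sim.get("fix_interval", 3600)))
    truth_dict = {
        "true_density": truth.true_density,
        "group_sizes": truth.group_sizes,
        "speed_active": truth.speed_active,
        "activity_level": truth.activity.true_level,
        "arena_km": truth.arena_km,
        "seed": seed,
    }
    return obs, gps, truth_dict


def run_pipeline(config: str | dict) -> SurveyReport:
    """Execute filter -> detection -> activity -> CTDS -> REM -> report."""
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        cfg = yaml.safe_load(text)
    else:
        cfg = config
        text = yaml.safe_dump(cfg, sort_keys=True)
    seed = int(cfg.get("seed", 0))
    truth_dict = None

    if "simulate" in cfg:
        obs, gps, truth_dict = _simulate(cfg["simulate"], seed)
    elif "data" in cfg:
        data = cfg["data"]
        obs = read_observations(data["photos"], data["deployments"])
        gps = None
        if "gps" in data:
            import pandas as pd

            df = pd.read_csv(data["gps"])
            t = (pd.to_datetime(df["timestamp"]) - obs.epoch).dt.total_seconds()
            fixes = np.column_stack([t.to_numpy(), df["x"].to_numpy(), df["y"].to_numpy()])
            dt = np.diff(fixes[:, 0])
            interval = float(np.median(dt)) if len(dt) else 3600.0
            gps = GPSTrack(fixes=fixes, fix_interval=interval)
    else:
        raise ValueError("config must contain a 'simulate' or 'data' section")

    ctds_cfg = CtdsConfig(seed=seed, **cfg.get("ctds", {}))
    try:
        ctds_est = bootstrap_ctds(obs, ctds_cfg)
    except Exception as exc:  # noqa: BLE001 - stage name propagated
        raise RuntimeError(f"CTDS stage failed: {exc}") from exc

    rem_block = None
    if cfg.get("rem", {}).get("enabled", True):
        if gps is None:
            raise ValueError("REM requested but no gps table provided")
        rem_cfg = RemConfig(
            seed=seed, **{k: v for k, v in cfg.get("rem", {}).items() if k != "enabled"}
        )
        try:
            rem_est = rem_estimate(obs, gps, rem_cfg)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"REM stage failed: {exc}") from exc
        rem_block = {
            "density": rem_est.density,
            "ci_low": rem_est.ci_low,
            "ci_high": rem_est.ci_high,
            "cv": rem_est.cv,
            "components": rem_est.components,
            **rem_est.details,
        }

    parameters = {
        "n_cameras": len(obs.deployments),
        "n_photos": len(obs.photos),
        "n_tags": len(obs.all_tags()),
        "activity_level": ctds_est.details.get("activity"),
        "effective_angle": ctds_est.details.get("theta"),
        "encounter_rate": ctds_est.details.get("encounter_rate"),
        "p_hat": ctds_est.details.get("p_hat"),
        "truncation": [ctds_est.details.get("w_left"), ctds_est.details.get("w")],
    }
    if truth_dict:
        parameters["truth"] = truth_dict

    report = SurveyReport(
        ctds={
            "density": ctds_est.density,
            "ci_low": ctds_est.ci_low,
            "ci_high": ctds_est.ci_high,
            "cv": ctds_est.cv,
            "components": ctds_est.components,
            **{k: v for k, v in ctds_est.details.items() if not isinstance(v, (list, dict))},
        },
        rem=rem_block,
        parameters=parameters,
        provenance={
            "seed": seed,
            "config_sha256": hashlib.sha256(text.encode()).hexdigest(),
            "version": __version__,
        },
    )
    return report


def make_fixture(truth_spec: dict, seed: int, out_dir: str) -> dict:
    """Write photos.csv, deployments.csv, gps.csv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    obs, gps, truth_dict = _simulate(truth_spec, seed)
    write_observations(obs, str(out / "photos.csv"), str(out / "deployments.csv"))

    from datetime import timedelta

    import pandas as pd

    rows = [
        {
            "timestamp": (obs.epoch + timedelta(seconds=float(t))).isoformat(),
            "x": float(x),
            "y": float(y),
        }
        for t, x, y in gps.fixes
    ]
    pd.DataFrame(rows, columns=["timestamp", "x", "y"]).to_csv(out / "gps.csv", index=False)
    (out / "truth.json").write_text(json.dumps(truth_dict, sort_keys=True, indent=2))
    return {
        "photos": str(out / "photos.csv"),
        "deployments": str(out / "deployments.csv"),
        "gps": str(out / "gps.csv"),
        "truth": str(out / "truth.json"),
    }
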