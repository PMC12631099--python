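"""Camera-trap distance-sampling (CTDS) density estimation.

Continuous monitoring is discretised into snapshot moments at spacing t.
Effort per camera is e_k = theta * T_k / (2 pi t) snapshot moments, with
T_k the operating time after removing trigger recovery dead-time.  The
point density is

    D = sum(n_k) / (pi (w^2 - w_left^2) * sum(e_k) * P) / activity

reported per km^2, where n_k counts in-window individual tags per frame
and P is the mean detection probability from the fitted detection
function.  Variance comes from a nonparametric bootstrap that resamples
camera locations with replacement, refitting the detection function
(selected family held fixed) and the activity kernel per resample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import activity as activity_mod
from . import detection as det
from .observations import (
    CameraDeployment,
    ObservationSet,
    PhotoRecord,
    filter_reactions,
    segment_group_contacts,
)

__all__ = [
    "CtdsConfig",
    "DensityEstimate",
    "EffortRecord",
    "bootstrap_ctds",
    "count_snapshot_observations",
    "ctds_density",
    "ctds_point_estimate",
    "snapshot_effort",
    "trigger_adjusted_effort",
]

M2_PER_KM2 = 1e6


@dataclass
class EffortRecord:
    camera_id: str
    T_k: float  # trigger-adjusted operating seconds
    n_triggers: int
    e_k: float = 0.0  # snapshot moments


@dataclass
class DensityEstimate:
    """A density point estimate with bootstrap/delta uncertainty."""

    method: str
    density: float  # individuals per km^2
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    cv: float = float("nan")
    components: dict = field(default_factory=dict)
    details: dict = field(default_factory=dict)


def trigger_adjusted_effort(
    deployment: CameraDeployment, photos: list[PhotoRecord]
) -> EffortRecord:
    """Operating time minus recovery dead-time accumulated per trigger."""
    span = deployment.span
    if span < 0:
        raise ValueError("negative deployment span")
    n_triggers = len({p.trigger_id for p in photos})
    T_k = span - n_triggers * deployment.recovery_time
    if T_k < 0:
        warnings.warn(
            f"camera {deployment.camera_id}: recovery time exceeds span; effort floored at 0"
        )
        T_k = 0.0
    return EffortRecord(camera_id=deployment.camera_id, T_k=T_k, n_triggers=n_triggers)


def snapshot_effort(T_k: float, theta: float, t: float) -> float:
    """Number of snapshot moments: e_k = theta * T_k / (2 pi t)."""
    if t <= 0:
        raise ValueError("snapshot interval t must be positive")
    if not (0 <= theta <= 2 * math.pi):
        raise ValueError("theta outside [0, 2 pi]")
    return theta * T_k / (2 * math.pi * t)


def count_snapshot_observations(
    photos: list[PhotoRecord], w_left: float, w: float
) -> int:
    """Total individual tags with band midpoint inside (w_left, w]."""
    n = 0
    for p in photos:
        for tag in p.animals:
            if w_left < tag.distance <= w:
                n += 1
    return n


def ctds_density(
    n_k: list[float] | np.ndarray,
    e_k: list[float] | np.ndarray,
    p_hat: float,
    w_left: float,
    w: float,
    activity_level: float,
) -> float:
    """CTDS point density per km^2 with availability correction."""
    if not (0 < p_hat <= 1):
        raise ValueError("p_hat must be in (0, 1]")
    if not (0 < activity_level <= 1):
        raise ValueError("activity_level must be in (0, 1]")
    total_e = float(np.sum(e_k))
    if total_e <= 0:
        raise ValueError("zero survey effort")
    total_n = float(np.sum(n_k))
    area = math.pi * (w**2 - w_left**2)
    return total_n / (area * total_e * p_hat) / activity_level * M2_PER_KM2


@dataclass
class CtdsConfig:
    """Knobs for the end-to-end CTDS estimate."""

    t: float = 0.5
    w_left: float = 0.0
    right_rule: float | str = "detection-prob-0.15"
    B: int = 1000
    seed: int = 0
    bandwidth_adjust: float = 1.5
    refit_detection: bool = True  # refit detection per bootstrap resample
    reselect_model: bool = False  # re-run model selection per resample
    fixed_p_hat: float | None = None  # bypass detection fitting (known curve)
    fixed_theta: float | None = None  # bypass angle fitting
    fixed_activity: float | None = None  # bypass activity fitting
    detection_models: list | None = None  # candidate set override


def _gather(obs: ObservationSet):
    """Per-camera photo streams, efforts and tags after reaction filtering."""
    obs = filter_reactions(obs)
    cams = obs.camera_ids
    streams = {c: obs.photos_for(c) for c in cams}
    efforts = {c: trigger_adjusted_effort(obs.deployment(c), streams[c]) for c in cams}
    return obs, cams, streams, efforts


def _estimate_once(
    obs: ObservationSet,
    cams: list[str],
    streams: dict,
    efforts: dict,
    config: CtdsConfig,
    fit_template: det.DetectionFit | None = None,
):
    """One full CTDS computation over the given cameras (with multiplicity)."""
    tags = [t for c in cams for p in streams[c] for t in p.animals]

    # effective angle
    if config.fixed_theta is not None:
        theta = config.fixed_theta
        theta_se = 0.0
    else:
        half = obs.deployments[0].nominal_half_angle
        angles = np.array([t.angle(half) for t in tags])
        afit = det.fit_effective_angle(angles, half)
        theta, theta_se = afit.effective_angle, afit.se

    # detection function
    if config.fixed_p_hat is not None:
        p_hat = config.fixed_p_hat
        w_left = config.w_left
        w = config.right_rule if isinstance(config.right_rule, (int, float)) else max(
            hi for _, hi in (t.distance_band for t in tags)
        )
        fit = None
        c_hat = 1.0
    else:
        bands = [t.distance_band for t in tags]
        if fit_template is None:
            kept, w_left, w = det.truncate_distances(
                bands, left=config.w_left, right_rule=config.right_rule
            )
            fit, _, c_hat = det.fit_all_candidates(
                kept, w_left, w, models=config.detection_models
            )
        else:
            w_left, w = fit_template.w_left, fit_template.w_right
            kept = [b for b in bands if b[0] >= w_left - 1e-9 and b[1] <= w + 1e-9]
            if config.reselect_model:
                fit, _, c_hat = det.fit_all_candidates(
                    kept, w_left, w, models=config.detection_models
                )
            else:
                fit = det.fit_detection_function(
                    kept,
                    det.DetectionModel(fit_template.model.family, fit_template.model.n_adjust),
                    w_left,
                    w,
                )
                c_hat = 1.0
        p_hat = fit.p_hat

    # activity from group-contact times
    if config.fixed_activity is not None:
        act_level = config.fixed_activity
    else:
        contact_times: list[float] = []
        for c in cams:
            contact_times.extend(segment_group_contacts(streams[c]))
        rad = activity_mod.times_to_radians(np.array(contact_times))
        act_level = activity_mod.fit_activity(
            rad, bandwidth_adjust=config.bandwidth_adjust
        ).level

    n_k = [count_snapshot_observations(streams[c], w_left, w) for c in cams]
    e_k = [snapshot_effort(efforts[c].T_k, theta, config.t) for c in cams]
    total_e = float(np.sum(e_k))
    enc_rate = float(np.sum(n_k)) / total_e if total_e > 0 else float("nan")
    if float(np.sum(n_k)) == 0:
        density = 0.0
    else:
        density = ctds_density(n_k, e_k, p_hat, w_left, w, act_level)
    return {
        "density": density,
        "encounter_rate": enc_rate,
        "p_hat": p_hat,
        "theta": theta,
        "theta_se": theta_se if config.fixed_theta is None else 0.0,
        "activity": act_level,
        "w_left": w_left,
        "w": w,
        "n_obs": int(np.sum(n_k)),
        "fit": fit,
        "c_hat": c_hat,
        "n_k": n_k,
        "e_k": e_k,
    }


def ctds_point_estimate(obs: ObservationSet, config: CtdsConfig | None = None) -> dict:
    """Full-data CTDS estimate (no bootstrap); returns the detail dict."""
    config = config or CtdsConfig()
    obs, cams, streams, efforts = _gather(obs)
    return _estimate_once(obs, cams, streams, efforts, config)


def bootstrap_ctds(obs: ObservationSet, config: CtdsConfig | None = None) -> DensityEstimate:
    """CTDS density with percentile bootstrap CI over camera locations."""
    config = config or CtdsConfig()
    obs, cams, streams, efforts = _gather(obs)
    if len(cams) < 2:
        raise ValueError("bootstrap needs at least 2 cameras")
    full = _estimate_once(obs, cams, streams, efforts, config)

    rng = np.random.default_rng(config.seed)
    template = full["fit"] if (config.refit_detection and full["fit"] is not None) else None
    boot_cfg = config
    if not config.refit_detection and config.fixed_p_hat is None and full["fit"] is not None:
        # hold the full-data detection fit fixed across resamples
        boot_cfg = CtdsConfig(**{**config.__dict__, "fixed_p_hat": full["p_hat"]})
        boot_cfg.right_rule = full["w"]
        boot_cfg.w_left = full["w_left"]
    dens = np.empty(config.B)
    rates = np.empty(config.B)
    phats = np.empty(config.B)
    acts = np.empty(config.B)
    for b in range(config.B):
        pick = list(rng.choice(cams, size=len(cams), replace=True))
        try:
            res = _estimate_once(obs, pick, streams, efforts, boot_cfg, fit_template=template)
            dens[b] = res["density"]
            rates[b] = res["encounter_rate"]
            phats[b] = res["p_hat"]
            acts[b] = res["activity"]
        except (det.FitError, ValueError):
            dens[b] = 0.0  # zero-observation resample recorded, not dropped
            rates[b] = 0.0
            phats[b] = np.nan
            acts[b] = np.nan

    mean = float(np.mean(dens))
    cv = float(np.std(dens, ddof=1) / mean) if mean > 0 else float("nan")
    lo, hi = np.percentile(dens, [2.5, 97.5])

    def _cv(arr):
        arr = arr[np.isfinite(arr)]
        m = float(np.mean(arr)) if len(arr) else float("nan")
        return float(np.std(arr, ddof=1) / m) if len(arr) > 1 and m > 0 else float("nan")

    return DensityEstimate(
        method="CTDS",
        density=full["density"],
        ci_low=float(min(lo, full["density"])),
        ci_high=float(max(hi, full["density"])),
        cv=cv,
        components={
            "encounter_rate": _cv(rates),
            "detection": _cv(phats),
            "activity": _cv(acts),
        },
        details={k: v for k, v in full.items() if k not in ("fit", "n_k", "e_k")},
    )
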