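"""Random encounter model (REM) density estimation.

Density follows from the contact rate between moving animals and static
cameras under ideal-gas assumptions:

    D = (y/t) * pi / (v * r * (2 + theta))

with the trapping rate y/t in contacts per camera-day, day range v in
km/day, effective detection radius r in km and effective angle theta in
radians.  Contacts are identified from per-frame individual counts (first
qualifying appearance within the gating distance; re-entry after leaving
the field of view counts anew).  Speed comes from GPS fix tables, with
fix-interval rarefaction to probe daily-path-length sensitivity.  Overall
variance combines independent component CVs by the delta method, with a
lognormal confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ctds import DensityEstimate, trigger_adjusted_effort
from .observations import ObservationSet, PhotoRecord, filter_reactions

__all__ = [
    "RemConfig",
    "RemParameters",
    "SpeedEstimate",
    "day_range",
    "dpl_percent_change",
    "identify_contacts",
    "linear_speed",
    "rarefy_track",
    "rem_density",
    "rem_estimate",
    "rem_variance",
    "speed_sensitivity",
    "trapping_rate",
]

SECONDS_PER_DAY = 86400.0


@dataclass
class SpeedEstimate:
    speed_active: float  # m/s over active segments
    se: float
    n_segments: int
    fix_interval: float
    dpl: float  # mean daily path length, meters


@dataclass
class RemParameters:
    """Inputs to the REM formula plus their uncertainty components."""

    trapping_rate: float  # contacts per camera-day
    day_range_km: float  # km/day
    r_km: float  # effective detection radius, km
    theta: float  # effective detection angle, radians (full)
    activity: float = 1.0
    cv_rate: float = 0.0
    cv_speed: float = 0.0
    cv_r: float = 0.0
    se_theta: float = 0.0
    cv_activity: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.theta <= 2 * math.pi):
            raise ValueError("theta outside (0, 2 pi]")


# ---------------------------------------------------------------------------
# contacts and trapping rate
# ---------------------------------------------------------------------------


def identify_contacts(
    photos: list[PhotoRecord],
    gate: float = 25.0,
    reset_gap: float | None = None,
) -> tuple[int, list]:
    """Count first contacts for one camera's time-sorted frame stream.

    Identities are unknown, so bookkeeping runs on per-frame counts: a
    frame-over-frame increase in the number of in-view individuals adds
    that many contacts, credited only once each individual is within the
    ``gate`` distance; a blank frame (or, optionally, a gap longer than
    ``reset_gap`` seconds between frames) resets the in-view set.

    Returns (contact count, list of (timestamp, tag) for credited tags).
    """
    times = [p.timestamp for p in photos]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("photo stream is not time-sorted")
    y = 0
    contacts: list = []
    in_view = 0
    credited = 0
    last_time: float | None = None
    for p in photos:
        if (
            reset_gap is not None
            and last_time is not None
            and p.timestamp - last_time > reset_gap
        ):
            in_view = 0
            credited = 0
        last_time = p.timestamp
        n = len(p.animals)
        if n == 0:
            in_view = 0
            credited = 0
            continue
        gated = [t for t in p.animals if t.distance <= gate]
        credited = min(credited, n)
        new = max(0, len(gated) - credited)
        if new:
            for t in gated[:new]:
                contacts.append((p.timestamp, t))
            y += new
            credited += new
        in_view = n
    return y, contacts


def trapping_rate(
    y_per_camera: list[int] | np.ndarray,
    T_days_per_camera: list[float] | np.ndarray,
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Contacts per camera-day plus bootstrap CV over camera locations.

    Returns (rate, cv, bootstrap rates).  CV is NaN (flagged) when no
    contacts were observed.
    """
    y = np.asarray(y_per_camera, dtype=float)
    T = np.asarray(T_days_per_camera, dtype=float)
    if T.sum() <= 0:
        raise ValueError("zero total effort")
    rate = float(y.sum() / T.sum())
    rng = np.random.default_rng(seed)
    k = len(y)
    idx = rng.integers(0, k, size=(B, k))
    ys = y[idx].sum(axis=1)
    Ts = T[idx].sum(axis=1)
    boots = np.divide(ys, Ts, out=np.zeros(B), where=Ts > 0)
    mean = boots.mean()
    cv = float(boots.std(ddof=1) / mean) if mean > 0 else float("nan")
    return rate, cv, boots


# ---------------------------------------------------------------------------
# GPS speed, day range, rarefaction
# ---------------------------------------------------------------------------


def linear_speed(gps, active_threshold: float = 0.05) -> SpeedEstimate:
    """Straight-line speeds between consecutive GPS fixes.

    Segments faster than ``active_threshold`` (m/s) are classed active;
    speed-while-active is their mean and its SE is SD/sqrt(n).  The daily
    path length is the summed displacement divided by the number of
    distinct days with fixes.
    """
    fixes = np.asarray(gps.fixes, dtype=float)
    if len(fixes) < 2:
        raise ValueError("need at least 2 fixes")
    t, x, y = fixes[:, 0], fixes[:, 1], fixes[:, 2]
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("duplicate or unsorted fix timestamps")
    disp = np.hypot(np.diff(x), np.diff(y))
    speeds = disp / dt
    active = speeds > active_threshold
    n_act = int(active.sum())
    if n_act == 0:
        speed_active, se = 0.0, float("nan")
    else:
        speed_active = float(speeds[active].mean())
        se = (
            float(speeds[active].std(ddof=1) / math.sqrt(n_act))
            if n_act > 1
            else float("nan")
        )
    n_days = max(1, len(np.unique(np.floor(t[:-1] / SECONDS_PER_DAY))))
    dpl = float(disp.sum() / n_days)
    return SpeedEstimate(
        speed_active=speed_active,
        se=se,
        n_segments=n_act,
        fix_interval=float(np.median(dt)),
        dpl=dpl,
    )


def rarefy_track(gps, new_interval: float):
    """Keep every (new/native)-th fix from the first; intervals must nest."""
    native = gps.fix_interval
    ratio = new_interval / native
    k = round(ratio)
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"new interval {new_interval} is not a multiple of native {native}"
        )
    from .synthetic import GPSTrack  # local import to avoid a cycle at import time

    fixes = np.asarray(gps.fixes, dtype=float)[::k]
    return GPSTrack(fixes=fixes, fix_interval=float(new_interval))


def dpl_percent_change(dpl: float, dpl_reference: float) -> float:
    """Percentage change in daily path length relative to a reference."""
    if dpl_reference <= 0:
        raise ValueError("reference DPL must be positive")
    return 100.0 * (dpl - dpl_reference) / dpl_reference


def day_range(
    speed_active: float, moving_proportion: float, active_seconds_per_day: float
) -> float:
    """Day range in km/day from speed while active (m/s)."""
    if speed_active < 0 or moving_proportion < 0 or active_seconds_per_day < 0:
        raise ValueError("inputs must be non-negative")
    return speed_active * moving_proportion * active_seconds_per_day / 1000.0


# ---------------------------------------------------------------------------
# the REM formula and its variance
# ---------------------------------------------------------------------------


def rem_density(params: RemParameters) -> float:
    """REM point density per km^2."""
    if params.day_range_km <= 0 or params.r_km <= 0:
        raise ValueError("day range and detection radius must be positive")
    return (
        params.trapping_rate
        * math.pi
        / (params.day_range_km * params.r_km * (2.0 + params.theta))
    )


def rem_variance(params: RemParameters) -> DensityEstimate:
    """Delta-method CV and lognormal CI around the REM point estimate.

    CV(D)^2 = CV(y/t)^2 + CV(v)^2 + CV(r)^2 + [SE(theta)/(2+theta)]^2
              + CV(activity)^2 (activity enters through the day range).
    """
    d = rem_density(params)
    theta_term = params.se_theta / (2.0 + params.theta)
    cv2 = (
        params.cv_rate**2
        + params.cv_speed**2
        + params.cv_r**2
        + theta_term**2
        + params.cv_activity**2
    )
    cv = math.sqrt(cv2)
    if d > 0 and cv > 0:
        c = math.exp(1.959963984540054 * math.sqrt(math.log(1.0 + cv2)))
        lo, hi = d / c, d * c
    else:
        lo = hi = d
    return DensityEstimate(
        method="REM",
        density=d,
        ci_low=lo,
        ci_high=hi,
        cv=cv,
        components={
            "trapping_rate": params.cv_rate,
            "speed": params.cv_speed,
            "detection_radius": params.cv_r,
            "angle": theta_term,
            "activity": params.cv_activity,
        },
    )


def speed_sensitivity(
    baseline_density: float, baseline_speed: float, speeds: list[float]
) -> list[dict]:
    """Rescale a baseline REM density by inverse speed for each regime."""
    if baseline_speed <= 0:
        raise ValueError("baseline speed must be positive")
    return [
        {"speed": s, "density": baseline_density * baseline_speed / s} for s in speeds
    ]


# ---------------------------------------------------------------------------
# end-to-end REM estimate
# ---------------------------------------------------------------------------


@dataclass
class RemConfig:
    gate: float = 25.0
    reset_gap: float | None = None
    fix_interval: float | None = None  # rarefy GPS to this interval if set
    moving_proportion: float = 1.0
    active_seconds_per_day: float | None = None  # default: activity * 86400
    speed_threshold: float = 0.05
    w_left: float = 0.0
    right_rule: float | str = "detection-prob-0.15"
    B: int = 1000
    seed: int = 0
    bandwidth_adjust: float = 1.5
    fixed_r_km: float | None = None
    fixed_theta: float | None = None
    fixed_activity: float | None = None


def rem_estimate(obs: ObservationSet, gps, config: RemConfig | None = None) -> DensityEstimate:
    """Contacts -> trapping rate -> detection zone -> speed -> REM density."""
    from . import activity as activity_mod
    from . import detection as det

    config = config or RemConfig()
    obs = filter_reactions(obs)
    cams = obs.camera_ids

    y_k: list[int] = []
    T_days: list[float] = []
    contact_tags = []
    contact_times: list[float] = []
    for c in cams:
        photos = obs.photos_for(c)
        eff = trigger_adjusted_effort(obs.deployment(c), photos)
        y, contacts = identify_contacts(photos, gate=config.gate, reset_gap=config.reset_gap)
        y_k.append(y)
        T_days.append(eff.T_k / SECONDS_PER_DAY)
        contact_tags.extend(t for _, t in contacts)
        contact_times.extend(ts for ts, _ in contacts)

    rate, cv_rate, _ = trapping_rate(y_k, T_days, B=config.B, seed=config.seed)

    # detection zone from the contact-position distance-sampling fit
    if config.fixed_r_km is not None:
        r_km, cv_r = config.fixed_r_km, 0.0
        fit = None
    else:
        bands = [t.distance_band for t in contact_tags]
        kept, w_left, w = det.truncate_distances(
            bands, left=config.w_left, right_rule=config.right_rule
        )
        fit, _, _ = det.fit_all_candidates(kept, w_left, w)
        r_km = fit.edr / 1000.0
        cv_r = fit.se_edr / fit.edr if np.isfinite(fit.se_edr) else 0.0

    if config.fixed_theta is not None:
        theta, se_theta = config.fixed_theta, 0.0
    else:
        half = obs.deployments[0].nominal_half_angle
        angles = np.array([t.angle(half) for t in contact_tags])
        afit = det.fit_effective_angle(angles, half)
        theta, se_theta = afit.effective_angle, afit.se

    # activity (shared definition with CTDS: group-contact event times)
    if config.fixed_activity is not None:
        act_level, act_cv = config.fixed_activity, 0.0
    else:
        rad = activity_mod.times_to_radians(np.array(contact_times))
        act = activity_mod.bootstrap_activity(
            rad, B=min(config.B, 500), seed=config.seed, bandwidth_adjust=config.bandwidth_adjust
        )
        act_level, act_cv = act.level, (act.se / act.level if act.level > 0 else 0.0)

    # speed and day range
    track = gps
    if config.fix_interval is not None:
        track = rarefy_track(track, config.fix_interval)
    sp = linear_speed(track, active_threshold=config.speed_threshold)
    active_s = (
        config.active_seconds_per_day
        if config.active_seconds_per_day is not None
        else act_level * SECONDS_PER_DAY
    )
    v = day_range(sp.speed_active, config.moving_proportion, active_s)
    cv_speed = sp.se / sp.speed_active if sp.speed_active > 0 and np.isfinite(sp.se) else 0.0

    params = RemParameters(
        trapping_rate=rate,
        day_range_km=v,
        r_km=r_km,
        theta=theta,
        activity=act_level,
        cv_rate=cv_rate if np.isfinite(cv_rate) else 0.0,
        cv_speed=cv_speed,
        cv_r=cv_r,
        se_theta=se_theta if np.isfinite(se_theta) else 0.0,
        cv_activity=act_cv if config.active_seconds_per_day is None else 0.0,
    )
    est = rem_variance(params)
    est.details = {
        "trapping_rate": rate,
        "day_range_km": v,
        "speed_active_ms": sp.speed_active,
        "dpl_m": sp.dpl,
        "r_km": r_km,
        "theta": theta,
        "activity": act_level,
        "n_contacts": int(sum(y_k)),
    }
    return est
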