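"""Synthetic group movement, camera trigger mechanics and GPS collars.

Everything runs at 1 s resolution on a torus arena so ideal-gas
assumptions hold exactly and estimator error can be isolated.  Group
centroids perform correlated random walks gated by a daily activity
curve; members scatter around the centroid with bivariate-normal spread.
Cameras monitor a sector viewshed with burst/recovery trigger mechanics
and emit banded tags through a distance detection curve.  All stochastic
operations are deterministic under an explicit integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from .observations import (
    AnimalTag,
    CameraDeployment,
    ObservationSet,
    PhotoRecord,
    angle_band_for_fraction,
    band_for_distance,
)

__all__ = [
    "ConstantDetection",
    "GPSTrack",
    "HalfNormalDetection",
    "SimulationTruth",
    "Track",
    "UniformActivity",
    "VonMisesActivity",
    "expected_trapping_rate",
    "simulate_detections",
    "simulate_gps_track",
    "simulate_movement",
]

SECONDS_PER_DAY = 86400


# ---------------------------------------------------------------------------
# activity curves
# ---------------------------------------------------------------------------


@dataclass
class UniformActivity:
    """Constant probability of being active at every second of the day."""

    level: float = 1.0

    def p_active(self, tod_seconds: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(tod_seconds, dtype=float), self.level)

    @property
    def true_level(self) -> float:
        return self.level


@dataclass
class VonMisesActivity:
    """Activity probability proportional to a von Mises mixture, peak scaled to 1.

    With the peak at 1, the time-averaged activity equals the level a
    circular-kernel activity estimator targets (1 / (2 pi max density)).
    """

    mus: tuple[float, ...] = (math.pi,)
    kappas: tuple[float, ...] = (1.0,)
    weights: tuple[float, ...] = (1.0,)

    def _mixture(self, radians: np.ndarray) -> np.ndarray:
        from scipy.special import i0

        radians = np.asarray(radians, dtype=float)
        out = np.zeros_like(radians)
        wsum = sum(self.weights)
        for mu, k, w in zip(self.mus, self.kappas, self.weights):
            out += (w / wsum) * np.exp(k * np.cos(radians - mu)) / (2 * np.pi * i0(k))
        return out

    def _peak(self) -> float:
        grid = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        return float(self._mixture(grid).max())

    def p_active(self, tod_seconds: np.ndarray) -> np.ndarray:
        rad = 2 * np.pi * (np.asarray(tod_seconds, dtype=float) % SECONDS_PER_DAY) / SECONDS_PER_DAY
        return self._mixture(rad) / self._peak()

    @property
    def true_level(self) -> float:
        grid = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        return float(self._mixture(grid).mean() / self._peak())


# ---------------------------------------------------------------------------
# detection curves (distance -> per-frame detection probability)
# ---------------------------------------------------------------------------


@dataclass
class ConstantDetection:
    p: float = 1.0

    def prob(self, r: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(r, dtype=float), self.p)


@dataclass
class HalfNormalDetection:
    sigma: float

    def prob(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return np.exp(-0.5 * (r / self.sigma) ** 2)


# ---------------------------------------------------------------------------
# truth and tracks
# ---------------------------------------------------------------------------


@dataclass
class SimulationTruth:
    """Generator parameters against which estimator recovery is judged."""

    true_density: float  # individuals per km^2
    n_groups: int = 1
    group_sizes: list[int] | None = None  # default: equal split of D * area
    speed_active: float = 1.0  # m/s while active
    activity: UniformActivity | VonMisesActivity = field(default_factory=UniformActivity)
    group_spread: float = 0.0  # SD (m) of member scatter about the centroid
    arena_km: float = 2.0  # torus side length
    turning_sd: float = 0.0  # heading noise SD (radians per second)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_density <= 0:
            raise ValueError("true_density must be positive")
        if self.speed_active <= 0:
            raise ValueError("speed must be positive")
        area = self.arena_km**2
        if self.group_sizes is None:
            total = round(self.true_density * area)
            if total == 0:  # density -> 0 limit: an empty arena
                self.group_sizes = [0] * self.n_groups
            else:
                total = max(self.n_groups, total)
                base, extra = divmod(total, self.n_groups)
                self.group_sizes = [
                    base + (1 if i < extra else 0) for i in range(self.n_groups)
                ]
        total = sum(self.group_sizes)
        if abs(total - self.true_density * area) > max(1.0, 0.05 * total):
            raise ValueError(
                f"group sizes ({total}) inconsistent with true_density * area "
                f"({self.true_density * area:.1f})"
            )

    @property
    def arena_m(self) -> float:
        return self.arena_km * 1000.0


@dataclass
class Track:
    """Per-second positions of one individual (unwrapped planar meters)."""

    individual_id: str
    positions: np.ndarray  # (T+1, 2), float32
    moving: np.ndarray  # (T,) bool
    group_id: str = "g0"


@dataclass
class GPSTrack:
    fixes: np.ndarray  # (n, 3): timestamp, x, y
    fix_interval: float

    def __post_init__(self) -> None:
        t = np.asarray(self.fixes, dtype=float)[:, 0]
        if np.any(np.diff(t) <= 0):
            raise ValueError("fixes must be strictly time-sorted")


def simulate_movement(
    truth: SimulationTruth, duration_s: int = SECONDS_PER_DAY, start_tod: int = 0
) -> list[Track]:
    """Correlated-random-walk group movement gated by the activity curve.

    Group centroids move at ``speed_active`` whenever the (per-second
    Bernoulli) activity draw marks the group active; members scatter
    around the centroid with SD ``group_spread`` refreshed each step.
    Positions are unwrapped; detection geometry applies the torus wrap.
    """
    rng = np.random.default_rng(truth.seed)
    T = int(duration_s)
    tod = (start_tod + np.arange(T)) % SECONDS_PER_DAY
    p_act = truth.activity.p_active(tod)
    L = truth.arena_m
    tracks: list[Track] = []
    for gi, size in enumerate(truth.group_sizes):
        active = rng.random(T) < p_act
        heading0 = rng.uniform(0, 2 * np.pi)
        turns = (
            rng.normal(0.0, truth.turning_sd, size=T)
            if truth.turning_sd > 0
            else np.zeros(T)
        )
        turns[~active] = 0.0  # heading frozen while resting
        heading = heading0 + np.cumsum(turns)
        step = truth.speed_active * active
        dx = np.cumsum(step * np.cos(heading), dtype=np.float64)
        dy = np.cumsum(step * np.sin(heading), dtype=np.float64)
        start = rng.uniform(0, L, size=2)
        cx = np.concatenate([[start[0]], start[0] + dx]).astype(np.float32)
        cy = np.concatenate([[start[1]], start[1] + dy]).astype(np.float32)
        for mi in range(size):
            if truth.group_spread > 0:
                sx = cx + rng.normal(0, truth.group_spread, size=T + 1).astype(np.float32)
                sy = cy + rng.normal(0, truth.group_spread, size=T + 1).astype(np.float32)
            else:
                sx, sy = cx, cy
            tracks.append(
                Track(
                    individual_id=f"g{gi}_i{mi}",
                    positions=np.stack([sx, sy], axis=1),
                    moving=active.copy(),
                    group_id=f"g{gi}",
                )
            )
    return tracks


# ---------------------------------------------------------------------------
# camera detection mechanics
# ---------------------------------------------------------------------------


def _wrap(delta: np.ndarray, L: float) -> np.ndarray:
    """Minimal-image displacement on the torus."""
    return (delta + L / 2.0) % L - L / 2.0


def simulate_detections(
    tracks: list[Track],
    deployments: list[CameraDeployment],
    detection: ConstantDetection | HalfNormalDetection | None = None,
    seed: int = 0,
    arena_km: float | None = None,
    epoch: datetime = datetime(2019, 6, 1),
) -> ObservationSet:
    """Run burst/recovery trigger mechanics over the tracks.

    At each ready second a camera triggers when at least one individual
    inside the sector viewshed passes a Bernoulli draw from the detection
    curve; a trigger emits ``burst_size`` frames at the intra-burst
    spacing (positions sampled at whole seconds) followed by the recovery
    dead-time.  Frames where every in-view animal fails its draw are
    emitted blank.
    """
    detection = detection or ConstantDetection(1.0)
    if arena_km is None:
        raise ValueError("arena_km is required to apply the torus wrap")
    L = arena_km * 1000.0
    rng = np.random.default_rng(seed)
    photos: list[PhotoRecord] = []

    n_ind = len(tracks)
    if n_ind == 0:
        return ObservationSet(deployments=list(deployments), photos=[], epoch=epoch)
    T = min(t.positions.shape[0] for t in tracks)
    pos = np.stack([t.positions[:T] for t in tracks])  # (n_ind, T, 2)
    group_ids = [t.group_id for t in tracks]
    ind_ids = [t.individual_id for t in tracks]

    for dep in deployments:
        if not (0 <= dep.x <= L and 0 <= dep.y <= L):
            raise ValueError(f"camera {dep.camera_id} outside the arena")
        t0 = max(0, int(dep.start))
        t1 = min(T - 1, int(dep.end))
        if t1 <= t0:
            continue
        dx = _wrap(pos[:, t0 : t1 + 1, 0] - dep.x, L)
        dy = _wrap(pos[:, t0 : t1 + 1, 1] - dep.y, L)
        dist2 = dx * dx + dy * dy
        in_sector = dist2 <= dep.max_tag_distance**2
        ii, jj = np.nonzero(in_sector)  # sparse: refine by viewshed angle
        rel_s = np.arctan2(dy[ii, jj], dx[ii, jj]) - dep.bearing
        rel_s = (rel_s + np.pi) % (2 * np.pi) - np.pi
        ok = np.abs(rel_s) <= dep.nominal_half_angle
        in_sector[ii[~ok], jj[~ok]] = False

        def _geom(idx: np.ndarray, sec: int) -> tuple[np.ndarray, np.ndarray]:
            """Distances and |relative angles| for animals ``idx`` at column ``sec``."""
            r = np.sqrt(dist2[idx, sec])
            rel = np.arctan2(dy[idx, sec], dx[idx, sec]) - dep.bearing
            rel = (rel + np.pi) % (2 * np.pi) - np.pi
            return r, np.abs(rel)

        any_in = in_sector.any(axis=0)
        candidates = np.nonzero(any_in)[0]
        if len(candidates) == 0:
            continue

        burst_span = (dep.burst_size - 1) * dep.intra_burst_interval
        trigger_id = 0
        ready_time = float(t0)
        ci = 0
        n_cand = len(candidates)
        while ci < n_cand:
            s_rel = int(candidates[ci])
            s_abs = t0 + s_rel
            if s_abs < ready_time:
                ci += 1
                continue
            who = np.nonzero(in_sector[:, s_rel])[0]
            r_who, _ = _geom(who, s_rel)
            detected = who[rng.random(len(who)) < detection.prob(r_who)]
            if len(detected) == 0:
                ci += 1
                continue
            # trigger: emit the burst
            trigger_id += 1
            for j in range(dep.burst_size):
                ft = s_abs + j * dep.intra_burst_interval
                fsec = min(int(ft), t1) - t0
                if j == 0:
                    frame_detected = detected
                else:
                    fwho = np.nonzero(in_sector[:, fsec])[0]
                    fr, _ = _geom(fwho, fsec)
                    frame_detected = fwho[rng.random(len(fwho)) < detection.prob(fr)]
                tags = []
                if len(frame_detected):
                    rr, aa = _geom(frame_detected, fsec)
                for n_i, idx in enumerate(frame_detected):
                    r = max(float(rr[n_i]), 1e-6)
                    frac = min(1.0, float(aa[n_i]) / dep.nominal_half_angle)
                    tags.append(
                        AnimalTag(
                            distance_band=band_for_distance(r, dep.max_tag_distance),
                            angle_band=angle_band_for_fraction(frac),
                            group_id=group_ids[idx],
                            animal_id=ind_ids[idx],
                        )
                    )
                photos.append(
                    PhotoRecord(
                        camera_id=dep.camera_id,
                        timestamp=float(ft),
                        trigger_id=trigger_id,
                        animals=tags,
                    )
                )
            # at 1 s resolution a camera triggers at most once per second
            ready_time = max(s_abs + burst_span + dep.recovery_time, s_abs + 1.0)
            # skip candidates inside the dead window
            while ci < n_cand and t0 + candidates[ci] < ready_time:
                ci += 1

    photos.sort(key=lambda p: (p.camera_id, p.timestamp))
    return ObservationSet(deployments=list(deployments), photos=photos, epoch=epoch)


# ---------------------------------------------------------------------------
# GPS collars
# ---------------------------------------------------------------------------


def simulate_gps_track(
    track: Track,
    fix_interval: float,
    window: tuple[float, float] | None = None,
    start_tod: int = 0,
) -> GPSTrack:
    """Sample a track at a fixed interval, optionally inside a daily window.

    ``window`` is (start, end) in seconds-into-day; the collar takes no
    fixes outside it.  There are no fix failures.
    """
    if fix_interval < 1:
        raise ValueError("fix interval below the 1 s track resolution")
    T = track.positions.shape[0] - 1
    times = np.arange(0, T + 1, int(fix_interval))
    if window is not None:
        tod = (start_tod + times) % SECONDS_PER_DAY
        times = times[(tod >= window[0]) & (tod <= window[1])]
    fixes = np.column_stack(
        [times.astype(float), track.positions[times, 0], track.positions[times, 1]]
    )
    return GPSTrack(fixes=fixes, fix_interval=float(fix_interval))


def expected_trapping_rate(
    density: float, day_range: float, r: float, theta: float
) -> float:
    """Ideal-gas expected contacts per camera-day: D v r (2 + theta) / pi.

    ``density`` per km^2, ``day_range`` km/day, ``r`` km, ``theta`` radians.
    """
    return density * day_range * r * (2.0 + theta) / math.pi
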