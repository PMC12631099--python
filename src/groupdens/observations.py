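"""Domain types and table IO for camera-trap observation data.

Observations are per-photo, per-individual tags carrying a binned distance,
a binned angle (as a fraction of the camera half field-of-view) and flags.
Blank frames (photos with no tagged animals) are legal and load-bearing:
they delimit group contacts.

The distance-band scheme is 0.5 m wide bands on (0, 10] and 1 m wide bands
above 10 m.  Angle bands split the half field-of-view into five equal
fractions (0 = viewshed centre, 1 = edge).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "ANGLE_BANDS",
    "AnimalTag",
    "CameraDeployment",
    "ObservationSet",
    "PhotoRecord",
    "SchemaError",
    "ValidationError",
    "angle_band_to_radians",
    "band_midpoint",
    "band_for_distance",
    "distance_bands",
    "angle_band_for_fraction",
    "filter_reactions",
    "read_observations",
    "segment_group_contacts",
    "write_observations",
]

#: Angle bands as fractions of the half field-of-view.
ANGLE_BANDS: tuple[tuple[float, float], ...] = (
    (0.0, 0.2),
    (0.2, 0.4),
    (0.4, 0.6),
    (0.6, 0.8),
    (0.8, 1.0),
)

_FINE_LIMIT = 10.0  # bands are 0.5 m wide up to here, 1 m wide beyond


class SchemaError(ValueError):
    """An input table does not match the documented column schema."""


class ValidationError(ValueError):
    """An input table violates a cross-record invariant."""


# ---------------------------------------------------------------------------
# band arithmetic
# ---------------------------------------------------------------------------


def distance_bands(max_distance: float = 25.0) -> list[tuple[float, float]]:
    """Full distance-band partition of (0, max_distance].

    0.5 m wide bands on (0, 10], 1 m wide bands on (10, max_distance].
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    bands: list[tuple[float, float]] = []
    lo = 0.0
    while lo < min(_FINE_LIMIT, max_distance) - 1e-9:
        hi = min(lo + 0.5, max_distance)
        bands.append((lo, hi))
        lo = hi
    while lo < max_distance - 1e-9:
        hi = min(lo + 1.0, max_distance)
        bands.append((lo, hi))
        lo = hi
    return bands


def _validate_band(band: tuple[float, float]) -> None:
    lo, hi = band
    if not (0 <= lo < hi):
        raise ValueError(f"illegal distance band {band!r}")
    if hi <= _FINE_LIMIT + 1e-9:
        ok = abs(hi - lo - 0.5) < 1e-9 and abs(lo * 2 - round(lo * 2)) < 1e-9
    elif lo >= _FINE_LIMIT - 1e-9:
        ok = abs(hi - lo - 1.0) < 1e-9 and abs(lo - round(lo)) < 1e-9
    else:
        ok = False
    if not ok:
        raise ValueError(f"distance band {band!r} not in the tagging scheme")


def band_midpoint(band: tuple[float, float]) -> float:
    """Arithmetic midpoint of a legal distance band, in meters."""
    _validate_band(band)
    return 0.5 * (band[0] + band[1])


def band_for_distance(distance: float, max_distance: float = 25.0) -> tuple[float, float]:
    """The scheme band (lo, hi] containing ``distance``."""
    if not (0 < distance <= max_distance):
        raise ValueError(f"distance {distance} outside (0, {max_distance}]")
    if distance <= _FINE_LIMIT:
        hi = math.ceil(distance / 0.5 - 1e-12) * 0.5
        return (round(hi - 0.5, 6), round(hi, 6))
    hi = math.ceil(distance - 1e-12)
    return (float(hi - 1), float(hi))


def angle_band_for_fraction(fraction: float) -> tuple[float, float]:
    """The angle band (as a fraction interval) containing ``fraction``."""
    if not (0 <= fraction <= 1):
        raise ValueError(f"angle fraction {fraction} outside [0, 1]")
    for lo, hi in ANGLE_BANDS:
        if fraction <= hi:
            return (lo, hi)
    raise AssertionError("unreachable")


def angle_band_to_radians(angle_band: tuple[float, float], half_angle: float) -> float:
    """Absolute angle (radians from viewshed centre) at the band midpoint."""
    if half_angle <= 0:
        raise ValueError("half_angle must be positive")
    if tuple(np.round(angle_band, 6)) not in ANGLE_BANDS:
        raise ValueError(f"unknown angle band {angle_band!r}")
    return 0.5 * (angle_band[0] + angle_band[1]) * half_angle


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnimalTag:
    """A single tagged individual in a single photo."""

    distance_band: tuple[float, float]
    angle_band: tuple[float, float]
    reaction: bool = False
    rem_contact: bool = False
    group_id: str | None = None
    animal_id: str | None = None

    def __post_init__(self) -> None:
        _validate_band(self.distance_band)
        if tuple(np.round(self.angle_band, 6)) not in ANGLE_BANDS:
            raise ValueError(f"unknown angle band {self.angle_band!r}")

    @property
    def distance(self) -> float:
        return band_midpoint(self.distance_band)

    def angle(self, half_angle: float) -> float:
        return angle_band_to_radians(self.angle_band, half_angle)


@dataclass
class PhotoRecord:
    """One photo frame; ``animals`` may be empty (a blank frame)."""

    camera_id: str
    timestamp: float  # seconds since the survey epoch
    trigger_id: int
    animals: list[AnimalTag] = field(default_factory=list)

    @property
    def is_blank(self) -> bool:
        return len(self.animals) == 0


@dataclass
class CameraDeployment:
    """Viewshed geometry, operating window and trigger mechanics of one camera.

    ``start``/``end`` are seconds since the survey epoch. ``bearing`` is the
    direction of the viewshed axis (radians, arbitrary planar frame).
    """

    camera_id: str
    x: float
    y: float
    start: float
    end: float
    nominal_half_angle: float = 0.37
    max_tag_distance: float = 25.0
    recovery_time: float = 10.35
    burst_size: int = 6
    intra_burst_interval: float = 0.49
    bearing: float = 0.0

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"camera {self.camera_id}: end must be after start")
        if not (0 < self.nominal_half_angle <= math.pi):
            raise ValueError(f"camera {self.camera_id}: half angle outside (0, pi]")
        if self.recovery_time < 0:
            raise ValueError(f"camera {self.camera_id}: negative recovery time")
        if self.burst_size < 1:
            raise ValueError(f"camera {self.camera_id}: burst_size must be >= 1")
        if self.max_tag_distance <= 0:
            raise ValueError(f"camera {self.camera_id}: max_tag_distance must be > 0")

    @property
    def span(self) -> float:
        """Operating window length in seconds."""
        return self.end - self.start


@dataclass
class ObservationSet:
    """Deployments plus the photo stream they produced."""

    deployments: list[CameraDeployment]
    photos: list[PhotoRecord]
    epoch: datetime = datetime(2000, 1, 1)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_id = {d.camera_id: d for d in self.deployments}
        if len(by_id) != len(self.deployments):
            raise ValidationError("duplicate camera_id in deployments")
        bad: list[int] = []
        for i, p in enumerate(self.photos):
            d = by_id.get(p.camera_id)
            if d is None:
                raise ValidationError(
                    f"photo row {i}: camera_id {p.camera_id!r} not in deployments"
                )
            # bursts may overrun the nominal end by one burst span
            slack = d.burst_size * d.intra_burst_interval + 1.0
            if not (d.start - 1e-6 <= p.timestamp <= d.end + slack):
                bad.append(i)
        if bad:
            raise ValidationError(
                f"photo timestamps outside deployment window at rows {bad[:20]}"
            )

    @property
    def camera_ids(self) -> list[str]:
        return [d.camera_id for d in self.deployments]

    def deployment(self, camera_id: str) -> CameraDeployment:
        for d in self.deployments:
            if d.camera_id == camera_id:
                return d
        raise KeyError(camera_id)

    def photos_for(self, camera_id: str) -> list[PhotoRecord]:
        return sorted(
            (p for p in self.photos if p.camera_id == camera_id),
            key=lambda p: p.timestamp,
        )

    def all_tags(self) -> list[AnimalTag]:
        return [t for p in self.photos for t in p.animals]


# ---------------------------------------------------------------------------
# filtering and contact segmentation
# ---------------------------------------------------------------------------


def filter_reactions(obs: ObservationSet) -> ObservationSet:
    """Drop tags of individuals that reacted to the camera.

    Frames whose only tags are reactions are retained as blank frames so
    that they keep delimiting group contacts.  Idempotent.
    """
    photos = [
        replace(p, animals=[t for t in p.animals if not t.reaction])
        for p in obs.photos
    ]
    return ObservationSet(deployments=obs.deployments, photos=photos, epoch=obs.epoch)


def segment_group_contacts(photos: list[PhotoRecord]) -> list[float]:
    """Group-contact timestamps for one camera's time-sorted frame stream.

    A new contact starts at the first non-blank frame of every maximal run
    of non-blank frames separated by at least one blank frame.
    """
    times = [p.timestamp for p in photos]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("photo stream is not time-sorted")
    contacts: list[float] = []
    in_run = False
    for p in photos:
        if p.is_blank:
            in_run = False
        elif not in_run:
            contacts.append(p.timestamp)
            in_run = True
    return contacts


# ---------------------------------------------------------------------------
# table IO
# ---------------------------------------------------------------------------

PHOTO_COLUMNS = [
    "camera_id",
    "timestamp",
    "trigger_id",
    "animal_id",
    "distance_lo",
    "distance_hi",
    "angle_band",
    "reaction",
    "rem_contact",
    "group_id",
]
DEPLOYMENT_COLUMNS = [
    "camera_id",
    "x",
    "y",
    "start",
    "end",
    "half_angle",
    "recovery_s",
    "burst_size",
    "burst_interval_s",
]


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {', '.join(missing)}")


def _parse_angle_band(text: str) -> tuple[float, float]:
    lo, hi = str(text).split("-")
    return (float(lo), float(hi))


def read_observations(
    photo_table_path: str, deployment_table_path: str
) -> ObservationSet:
    """Read photos.csv + deployments.csv (ISO 8601 site-local timestamps).

    The survey epoch is midnight of the earliest deployment start, so that
    internal second offsets are also clock-time offsets.
    """
    dep_df = pd.read_csv(deployment_table_path)
    _require_columns(dep_df, DEPLOYMENT_COLUMNS, "deployments table")
    photo_df = pd.read_csv(photo_table_path)
    _require_columns(photo_df, PHOTO_COLUMNS, "photos table")

    starts = pd.to_datetime(dep_df["start"])
    epoch = starts.min().normalize().to_pydatetime()

    def _secs(value) -> float:
        return (pd.to_datetime(value) - epoch).total_seconds()

    deployments = [
        CameraDeployment(
            camera_id=str(row.camera_id),
            x=float(row.x),
            y=float(row.y),
            start=_secs(row.start),
            end=_secs(row.end),
            nominal_half_angle=float(row.half_angle),
            recovery_time=float(row.recovery_s),
            burst_size=int(row.burst_size),
            intra_burst_interval=float(row.burst_interval_s),
            bearing=float(getattr(row, "bearing", 0.0) or 0.0),
            max_tag_distance=float(getattr(row, "max_tag_distance", 25.0) or 25.0),
        )
        for row in dep_df.itertuples()
    ]

    photos: list[PhotoRecord] = []
    key_to_index: dict[tuple[str, float, int], int] = {}
    for row in photo_df.itertuples():
        cam = str(row.camera_id)
        ts = _secs(row.timestamp)
        trig = int(row.trigger_id)
        key = (cam, round(ts, 3), trig)
        if key not in key_to_index:
            key_to_index[key] = len(photos)
            photos.append(PhotoRecord(camera_id=cam, timestamp=ts, trigger_id=trig))
        rec = photos[key_to_index[key]]
        if pd.isna(row.animal_id) or str(row.animal_id) == "":
            continue  # blank frame row
        rec.animals.append(
            AnimalTag(
                distance_band=(float(row.distance_lo), float(row.distance_hi)),
                angle_band=_parse_angle_band(row.angle_band),
                reaction=bool(row.reaction),
                rem_contact=bool(row.rem_contact),
                group_id=None if pd.isna(row.group_id) else str(row.group_id),
                animal_id=str(row.animal_id),
            )
        )
    return ObservationSet(deployments=deployments, photos=photos, epoch=epoch)


def write_observations(
    obs: ObservationSet, photo_table_path: str, deployment_table_path: str
) -> None:
    """Write the CSV pair read back by :func:`read_observations`."""
    epoch = obs.epoch

    def _iso(seconds: float) -> str:
        return (epoch + timedelta(seconds=float(seconds))).isoformat()

    dep_rows = [
        {
            "camera_id": d.camera_id,
            "x": d.x,
            "y": d.y,
            "start": _iso(d.start),
            "end": _iso(d.end),
            "half_angle": d.nominal_half_angle,
            "recovery_s": d.recovery_time,
            "burst_size": d.burst_size,
            "burst_interval_s": d.intra_burst_interval,
            "bearing": d.bearing,
            "max_tag_distance": d.max_tag_distance,
        }
        for d in obs.deployments
    ]
    pd.DataFrame(dep_rows, columns=DEPLOYMENT_COLUMNS + ["bearing", "max_tag_distance"]).to_csv(
        deployment_table_path, index=False
    )

    photo_rows = []
    for p in obs.photos:
        base = {
            "camera_id": p.camera_id,
            "timestamp": _iso(p.timestamp),
            "trigger_id": p.trigger_id,
        }
        if p.is_blank:
            photo_rows.append(
                {**base, "animal_id": "", "distance_lo": "", "distance_hi": "",
                 "angle_band": "", "reaction": "", "rem_contact": "", "group_id": ""}
            )
        else:
            for t in p.animals:
                photo_rows.append(
                    {
                        **base,
                        "animal_id": t.animal_id or "",
                        "distance_lo": t.distance_band[0],
                        "distance_hi": t.distance_band[1],
                        "angle_band": f"{t.angle_band[0]:g}-{t.angle_band[1]:g}",
                        "reaction": t.reaction,
                        "rem_contact": t.rem_contact,
                        "group_id": t.group_id or "",
                    }
                )
    pd.DataFrame(photo_rows, columns=PHOTO_COLUMNS).to_csv(photo_table_path, index=False)
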