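"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from groupdens.observations import (
    AnimalTag,
    CameraDeployment,
    ObservationSet,
    PhotoRecord,
    angle_band_for_fraction,
    band_for_distance,
)


def make_tag(
    distance: float,
    frac: float = 0.1,
    reaction: bool = False,
    rem_contact: bool = False,
    group_id: str | None = None,
    animal_id: str | None = None,
    max_distance: float = 25.0,
) -> AnimalTag:
    """Tag builder: exact distance/angle-fraction -> scheme bands."""
    return AnimalTag(
        distance_band=band_for_distance(distance, max_distance),
        angle_band=angle_band_for_fraction(frac),
        reaction=reaction,
        rem_contact=rem_contact,
        group_id=group_id,
        animal_id=animal_id,
    )


def make_deployment(
    camera_id: str = "cam0",
    span: float = 3600.0,
    recovery: float = 10.35,
    half_angle: float = 0.37,
    **kw,
) -> CameraDeployment:
    return CameraDeployment(
        camera_id=camera_id,
        x=kw.pop("x", 100.0),
        y=kw.pop("y", 100.0),
        start=0.0,
        end=span,
        nominal_half_angle=half_angle,
        recovery_time=recovery,
        **kw,
    )


def frames(camera_id: str, counts: list[int], distance: float = 5.0, dt: float = 1.0):
    """Photo stream with the given per-frame tag counts, dt seconds apart."""
    return [
        PhotoRecord(
            camera_id=camera_id,
            timestamp=i * dt,
            trigger_id=i,
            animals=[make_tag(distance) for _ in range(c)],
        )
        for i, c in enumerate(counts)
    ]


@pytest.fixture
def toy_obs() -> ObservationSet:
    dep = make_deployment("cam0", span=600.0)
    photos = [
        PhotoRecord("cam0", 10.0, 1, [make_tag(3.2), make_tag(7.9, frac=0.5)]),
        PhotoRecord("cam0", 11.0, 1, []),
        PhotoRecord("cam0", 40.0, 2, [make_tag(12.4, reaction=True)]),
    ]
    return ObservationSet(deployments=[dep], photos=photos)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def sample_point_transect_halfnormal(
    sigma: float, w: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Distances from a point-transect half-normal: density ~ r * g(r) on (0, w]."""
    out: list[float] = []
    while len(out) < n:
        r = np.sqrt(rng.random(4 * n)) * w
        keep = rng.random(len(r)) < np.exp(-0.5 * (r / sigma) ** 2)
        out.extend(r[keep][: n - len(out)])
    return np.array(out)


def sample_point_transect_hazard(
    sigma: float, b: float, w: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    out: list[float] = []
    while len(out) < n:
        r = np.sqrt(rng.random(4 * n)) * w
        keep = rng.random(len(r)) < 1.0 - np.exp(-((r / sigma) ** (-b)))
        out.extend(r[keep][: n - len(out)])
    return np.array(out)
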