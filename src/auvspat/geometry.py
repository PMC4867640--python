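"""Georeferencing of seafloor photographs from vehicle pose.

Each photograph is located by rotating the camera's four corner view rays
from the vehicle body frame into the world frame (east-north-up, metres)
with a yaw-pitch-roll rotation matrix, and intersecting them with a
horizontal seafloor plane at the measured altitude below the vehicle.  The
resulting quadrilateral is the image *footprint*; its shoelace area is the
survey effort contributed by that image.

Conventions
-----------
* World frame: x = easting, y = northing, z = up (metres).
* Body frame: x = forward, y = starboard, z = down.
* Heading is degrees clockwise from north; pitch positive nose-up; roll
  positive starboard-down.  Composition is intrinsic Z-Y-X (yaw, then
  pitch, then roll).
* The seafloor under a single image is treated as a horizontal plane at
  the measured altitude; bathymetric slope within one footprint (a few
  metres across) is ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy.optimize import brentq
from shapely.strtree import STRtree

__all__ = [
    "PoseRecord",
    "CameraModel",
    "ImageFootprint",
    "FootprintSet",
    "FootprintIndex",
    "rotation_matrix",
    "rotation_matrices",
    "project_footprint",
    "project_footprints",
    "calibrate_fov",
    "select_images",
    "locate_observation",
]

#: Sensor size in pixels as (rows, cols); rows run along-track for the
#: vertical camera, cols across-track.
PIXEL_DIMS = (2048, 2448)


@dataclass(frozen=True)
class PoseRecord:
    """One navigation fix of the vehicle."""

    timestamp: float
    easting: float
    northing: float
    depth: float
    altitude: float
    pitch: float
    roll: float
    heading: float

    def __post_init__(self) -> None:
        if not self.altitude > 0:
            raise ValueError(f"altitude must be > 0, got {self.altitude}")
        if abs(self.pitch) >= 90 or abs(self.roll) >= 90:
            raise ValueError("pitch/roll must satisfy |angle| < 90 degrees")
        if not (0 <= self.heading < 360):
            object.__setattr__(self, "heading", self.heading % 360.0)


@dataclass(frozen=True)
class CameraModel:
    """Pinhole view-cone model of one survey camera.

    ``mount_angle`` is the boresight depression below horizontal: 90 for
    the vertical camera, 35 (default) for the forward oblique camera.
    ``half_fov_along``/``half_fov_across`` are the half-angles of the view
    cone in the image row/column directions, degrees.
    """

    mount: str
    half_fov_along: float
    half_fov_across: float
    mount_angle: float = 35.0
    pixel_dims: tuple[int, int] = PIXEL_DIMS

    def __post_init__(self) -> None:
        if self.mount not in ("vertical", "oblique"):
            raise ValueError(f"unknown mount {self.mount!r}")
        for a in (self.half_fov_along, self.half_fov_across):
            if not 0 < a < 90:
                raise ValueError(f"half-FOV must be in (0, 90), got {a}")

    @property
    def depression(self) -> float:
        """Boresight angle below horizontal, degrees."""
        return 90.0 if self.mount == "vertical" else float(self.mount_angle)

    def corner_rays_body(self) -> np.ndarray:
        """Unit-z view rays of the four image corners in the body frame.

        Returned in ring order (--, -+, ++, +-) over (along, across)
        signs, which projects to a simple quadrilateral.
        """
        ta = math.tan(math.radians(self.half_fov_along))
        tc = math.tan(math.radians(self.half_fov_across))
        corners = np.array(
            [[-ta, -tc, 1.0], [-ta, tc, 1.0], [ta, tc, 1.0], [ta, -tc, 1.0]]
        )
        return corners @ self._mount_rotation().T

    def pixel_ray_body(self, pixel: tuple[float, float]) -> np.ndarray:
        """Body-frame view ray through ``pixel`` = (row, col)."""
        rows, cols = self.pixel_dims
        r, c = pixel
        if not (0 <= r <= rows - 1 and 0 <= c <= cols - 1):
            raise ValueError(f"pixel {pixel} outside sensor {self.pixel_dims}")
        ya = (2.0 * r - (rows - 1)) / (rows - 1)
        xa = (2.0 * c - (cols - 1)) / (cols - 1)
        d = np.array(
            [
                ya * math.tan(math.radians(self.half_fov_along)),
                xa * math.tan(math.radians(self.half_fov_across)),
                1.0,
            ]
        )
        return self._mount_rotation() @ d

    def _mount_rotation(self) -> np.ndarray:
        # Pitch the nadir-pointing bundle forward by (90 - depression).
        a = math.radians(90.0 - self.depression)
        ca, sa = math.cos(a), math.sin(a)
        return np.array([[ca, 0.0, sa], [0.0, 1.0, 0.0], [-sa, 0.0, ca]])


@dataclass(frozen=True)
class ImageFootprint:
    """Georeferenced seafloor footprint of one photograph."""

    image_id: int
    camera: str
    corners: np.ndarray  # (4, 2) easting/northing, metres
    centre: tuple[float, float]
    area: float  # m^2
    altitude: float
    timestamp: float = 0.0
    valid: bool = True

    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.corners)


def rotation_matrix(heading: float, pitch: float, roll: float) -> np.ndarray:
    """Body-to-world rotation for one attitude triple (degrees).

    Returns the proper orthonormal 3x3 matrix mapping body-frame vectors
    (forward, starboard, down) to world east-north-up.  At zero attitude
    body-forward maps to north; at heading 90 it maps to east.
    """
    return rotation_matrices([heading], [pitch], [roll])[0]


def rotation_matrices(
    heading: Sequence[float], pitch: Sequence[float], roll: Sequence[float]
) -> np.ndarray:
    """Vectorised :func:`rotation_matrix`; returns (n, 3, 3)."""
    psi = np.radians(np.asarray(heading, dtype=float))
    th = np.radians(np.asarray(pitch, dtype=float))
    ph = np.radians(np.asarray(roll, dtype=float))
    cps, sps = np.cos(psi), np.sin(psi)
    ct, st = np.cos(th), np.sin(th)
    cph, sph = np.cos(ph), np.sin(ph)
    n = psi.shape[0]
    # Rz(psi) @ Ry(theta) @ Rx(phi) in the north-east-down frame.
    r = np.empty((n, 3, 3))
    r[:, 0, 0] = cps * ct
    r[:, 0, 1] = cps * st * sph - sps * cph
    r[:, 0, 2] = cps * st * cph + sps * sph
    r[:, 1, 0] = sps * ct
    r[:, 1, 1] = sps * st * sph + cps * cph
    r[:, 1, 2] = sps * st * cph - cps * sph
    r[:, 2, 0] = -st
    r[:, 2, 1] = ct * sph
    r[:, 2, 2] = ct * cph
    # NED world axes -> ENU world axes (swap N/E, flip D).
    perm = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, -1.0]])
    return perm @ r


def shoelace_area(corners: np.ndarray) -> np.ndarray:
    """Absolute polygon area(s) by the shoelace formula.

    ``corners`` has shape (..., k, 2).
    """
    x = corners[..., 0]
    y = corners[..., 1]
    xn = np.roll(x, -1, axis=-1)
    yn = np.roll(y, -1, axis=-1)
    return 0.5 * np.abs(np.sum(x * yn - xn * y, axis=-1))


@dataclass
class FootprintSet:
    """Column-wise container of georeferenced image footprints."""

    camera: str
    image_id: np.ndarray
    timestamp: np.ndarray
    corners: np.ndarray  # (n, 4, 2)
    centre: np.ndarray  # (n, 2)
    area: np.ndarray
    altitude: np.ndarray
    capture_xy: np.ndarray  # vehicle easting/northing at capture, (n, 2)
    valid: np.ndarray
    line_id: np.ndarray | None = None
    survey_id: str = ""

    def __len__(self) -> int:
        return int(self.image_id.shape[0])

    def __getitem__(self, i: int) -> ImageFootprint:
        return ImageFootprint(
            image_id=int(self.image_id[i]),
            camera=self.camera,
            corners=self.corners[i],
            centre=(float(self.centre[i, 0]), float(self.centre[i, 1])),
            area=float(self.area[i]),
            altitude=float(self.altitude[i]),
            timestamp=float(self.timestamp[i]),
            valid=bool(self.valid[i]),
        )

    def subset(self, mask: np.ndarray) -> "FootprintSet":
        mask = np.asarray(mask)
        return FootprintSet(
            camera=self.camera,
            image_id=self.image_id[mask],
            timestamp=self.timestamp[mask],
            corners=self.corners[mask],
            centre=self.centre[mask],
            area=self.area[mask],
            altitude=self.altitude[mask],
            capture_xy=self.capture_xy[mask],
            valid=self.valid[mask],
            line_id=None if self.line_id is None else self.line_id[mask],
            survey_id=self.survey_id,
        )

    def effort_area_km2(self) -> float:
        """Survey effort as the sum of footprint areas, km^2."""
        return float(self.area[self.valid].sum() / 1e6)

    def polygons(self) -> np.ndarray:
        rings = np.concatenate([self.corners, self.corners[:, :1, :]], axis=1)
        return shapely.polygons(rings)

    @staticmethod
    def concatenate(sets: Iterable["FootprintSet"]) -> "FootprintSet":
        sets = list(sets)
        if not sets:
            raise ValueError("no footprint sets to concatenate")
        cam = sets[0].camera
        if any(s.camera != cam for s in sets):
            raise ValueError("cannot concatenate footprints of different cameras")
        return FootprintSet(
            camera=cam,
            image_id=np.concatenate([s.image_id for s in sets]),
            timestamp=np.concatenate([s.timestamp for s in sets]),
            corners=np.concatenate([s.corners for s in sets]),
            centre=np.concatenate([s.centre for s in sets]),
            area=np.concatenate([s.area for s in sets]),
            altitude=np.concatenate([s.altitude for s in sets]),
            capture_xy=np.concatenate([s.capture_xy for s in sets]),
            valid=np.concatenate([s.valid for s in sets]),
            line_id=(
                None
                if any(s.line_id is None for s in sets)
                else np.concatenate([s.line_id for s in sets])
            ),
            survey_id="+".join(dict.fromkeys(s.survey_id for s in sets)),
        )


class FootprintIndex:
    """Spatial index over a footprint set for fast point-in-footprint queries."""

    def __init__(self, footprints: FootprintSet):
        self.footprints = footprints
        self._polys = footprints.polygons()
        self._tree = STRtree(self._polys)

    def query_points(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Indices of (point, footprint) containment pairs (boundary counts)."""
        pts = shapely.points(np.asarray(xy, dtype=float))
        pt_idx, fp_idx = self._tree.query(pts, predicate="intersects")
        return pt_idx, fp_idx


def project_footprints(
    easting: np.ndarray,
    northing: np.ndarray,
    altitude: np.ndarray,
    heading: np.ndarray,
    pitch: np.ndarray,
    roll: np.ndarray,
    cam: CameraModel,
    *,
    timestamp: np.ndarray | None = None,
    image_id: np.ndarray | None = None,
    line_id: np.ndarray | None = None,
    survey_id: str = "",
) -> FootprintSet:
    """Project many poses into a :class:`FootprintSet` (vectorised).

    Rays that do not descend toward the seafloor (extreme oblique attitude)
    flag the image invalid; such images carry zero area and are excluded
    from survey effort.
    """
    easting = np.asarray(easting, dtype=float)
    n = easting.shape[0]
    rot = rotation_matrices(heading, pitch, roll)
    rays = cam.corner_rays_body()  # (4, 3)
    world = np.einsum("nij,kj->nki", rot, rays)  # (n, 4, 3) ENU
    dz = world[..., 2]
    valid = np.all(dz < -1e-9, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(dz < -1e-9, -np.asarray(altitude, dtype=float)[:, None] / dz, np.nan)
    corners = np.stack([easting, np.asarray(northing, dtype=float)], axis=-1)[
        :, None, :
    ] + t[..., None] * world[..., :2]
    corners = np.where(valid[:, None, None], corners, 0.0)
    area = np.where(valid, shoelace_area(corners), 0.0)
    centre = corners.mean(axis=1)
    return FootprintSet(
        camera=cam.mount,
        image_id=np.arange(n) if image_id is None else np.asarray(image_id),
        timestamp=np.zeros(n) if timestamp is None else np.asarray(timestamp, float),
        corners=corners,
        centre=centre,
        area=area,
        altitude=np.asarray(altitude, dtype=float),
        capture_xy=np.stack([easting, np.asarray(northing, float)], axis=-1),
        valid=valid,
        line_id=None if line_id is None else np.asarray(line_id),
        survey_id=survey_id,
    )


def project_footprint(pose: PoseRecord, cam: CameraModel) -> ImageFootprint:
    """Georeference a single photograph from its pose."""
    fps = project_footprints(
        np.array([pose.easting]),
        np.array([pose.northing]),
        np.array([pose.altitude]),
        np.array([pose.heading]),
        np.array([pose.pitch]),
        np.array([pose.roll]),
        cam,
        timestamp=np.array([pose.timestamp]),
    )
    fp = fps[0]
    if not fp.valid:
        raise ValueError(
            "footprint invalid: a corner ray does not intersect the seafloor"
        )
    return fp


def _level_area(cam: CameraModel, altitude: float) -> float:
    pose = PoseRecord(0.0, 0.0, 0.0, 0.0, altitude, 0.0, 0.0, 0.0)
    return project_footprint(pose, cam).area


def calibrate_fov(
    cam_mount: str,
    target_area: float,
    altitude: float = 3.2,
    aspect: float = PIXEL_DIMS[1] / PIXEL_DIMS[0],
    mount_angle: float = 35.0,
) -> CameraModel:
    """Recover camera half-FOV angles from a known footprint area.

    The lens field of view is not part of the survey metadata, but the
    level-pose footprint areas at the target altitude are; this inverts
    the projection so that re-projecting a level pose at ``altitude``
    reproduces ``target_area`` within 1%.  The across/along ratio of the
    FOV tangents is fixed by the sensor pixel aspect.
    """
    if target_area <= 0:
        raise ValueError("target_area must be positive")
    if cam_mount == "vertical":
        # area = 4 alt^2 tan(ha) tan(hc), tan(hc) = aspect * tan(ha)
        ta = math.sqrt(target_area / (4.0 * altitude**2 * aspect))
        return CameraModel(
            mount="vertical",
            half_fov_along=math.degrees(math.atan(ta)),
            half_fov_across=math.degrees(math.atan(aspect * ta)),
            mount_angle=90.0,
        )

    def make(scale: float) -> CameraModel:
        return CameraModel(
            mount="oblique",
            half_fov_along=math.degrees(math.atan(scale)),
            half_fov_across=math.degrees(math.atan(aspect * scale)),
            mount_angle=mount_angle,
        )

    def resid(scale: float) -> float:
        return _level_area(make(scale), altitude) - target_area

    # Far-edge ray must still descend: tan(half_along) < tan(depression).
    hi = 0.999 * math.tan(math.radians(mount_angle))
    hi = min(hi, math.tan(math.radians(89.0)) / aspect)
    lo = 1e-6
    if resid(hi) < 0:
        raise ValueError(
            f"no oblique FOV below 89 deg reproduces area {target_area} m^2"
        )
    scale = brentq(resid, lo, hi, xtol=1e-12)
    return make(scale)


def select_images(
    footprints: FootprintSet,
    min_alt: float = 1.9,
    max_alt: float = 4.1,
    oblique_stride: int = 2,
) -> FootprintSet:
    """Apply the image-retention rules.

    Photographs outside the altitude window [min_alt, max_alt] (metres
    above seafloor) are discarded for both cameras; oblique images, which
    overlap heavily along track, are additionally decimated to every
    ``oblique_stride``-th image.  Vertical images are never decimated.
    """
    mask = (
        footprints.valid
        & (footprints.altitude >= min_alt)
        & (footprints.altitude <= max_alt)
    )
    kept = footprints.subset(mask)
    if footprints.camera == "oblique" and oblique_stride > 1:
        kept = kept.subset(np.arange(len(kept)) % oblique_stride == 0)
    return kept


def locate_observation(
    pose: PoseRecord, cam: CameraModel, pixel_coord: tuple[float, float]
) -> tuple[float, float]:
    """Seafloor position (easting, northing) of a pixel in one image."""
    d = cam.pixel_ray_body(pixel_coord)
    w = rotation_matrix(pose.heading, pose.pitch, pose.roll) @ d
    if not w[2] < -1e-9:
        raise ValueError("pixel ray does not intersect the seafloor")
    t = -pose.altitude / w[2]
    return (pose.easting + t * w[0], pose.northing + t * w[1])
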