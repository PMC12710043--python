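"""Turntable camera geometry and calibrated projection operators.

A plant on a rotating stage imaged by a fixed side camera is geometrically
equivalent to a fixed plant imaged from a ring of azimuths around it, plus an
optional top-down view.  Each view is represented by a
:class:`CalibratedView` that maps world coordinates in millimetres to
fractional pixel coordinates ``(row, col)``.  The default projection model is
orthographic (turntable-at-infinity approximation); a pinhole model with a
finite camera distance is available for completeness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

Array = np.ndarray

__all__ = ["CalibratedView", "CameraRig"]


def _unit(v: Array) -> Array:
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


@dataclass(frozen=True)
class CalibratedView:
    """Projection operator from world millimetres to pixel ``(row, col)``.

    ``origin`` is the look-at point for orthographic views and the camera
    position for pinhole views.  ``px_size`` is the millimetre extent of one
    pixel at the reference (look-at) plane.
    """

    label: str
    image_shape: tuple[int, int]
    right: Array
    up: Array
    forward: Array
    origin: Array
    px_size: float
    kind: str = "orthographic"
    focal_px: float | None = None
    azimuth: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("orthographic", "pinhole"):
            raise ValueError(f"unknown projection kind {self.kind!r}")
        if self.kind == "pinhole" and self.focal_px is None:
            raise ValueError("pinhole view requires focal_px")

    def project(self, points: Array) -> tuple[Array, Array]:
        """Project ``(n, 3)`` world points; returns float ``(rows, cols)``."""
        p = np.atleast_2d(np.asarray(points, dtype=np.float64)) - np.asarray(self.origin)
        x = p @ np.asarray(self.right)
        y = p @ np.asarray(self.up)
        h, w = self.image_shape
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        if self.kind == "orthographic":
            rows = cy - y / self.px_size
            cols = cx + x / self.px_size
        else:
            z = p @ np.asarray(self.forward)
            with np.errstate(divide="ignore", invalid="ignore"):
                rows = cy - self.focal_px * y / z
                cols = cx + self.focal_px * x / z
        return rows, cols

    def scale_at(self, points: Array | None = None) -> float:
        """Pixels per millimetre at the given depth (reference plane if None)."""
        if self.kind == "orthographic" or points is None:
            if self.kind == "pinhole":
                # scale at unit forward distance equal to the mean depth of origin-centred content
                return self.focal_px / max(self.px_size, 1e-9) / (self.focal_px or 1.0)
            return 1.0 / self.px_size
        p = np.atleast_2d(points) - np.asarray(self.origin)
        z = float(np.mean(p @ np.asarray(self.forward)))
        return self.focal_px / z

    def footprint_halfwidth_px(self, cube_mm: float) -> tuple[float, float]:
        """Half extent, in pixels, of the projection of an axis-aligned cube."""
        s = self.scale_at() if self.kind == "orthographic" else self.focal_px / np.linalg.norm(self.origin)
        hr = 0.5 * cube_mm * float(np.abs(self.up).sum()) * s
        hc = 0.5 * cube_mm * float(np.abs(self.right).sum()) * s
        return hr, hc


@dataclass(frozen=True)
class CameraRig:
    """Imaging geometry: side views at fixed turntable azimuths plus a top view.

    The default matches a five-view turntable at equidistant azimuths
    (0, 72, 144, 216, 288 degrees) with one top-down view.  ``world_extent``
    is the side length of the cubic volume (mm) that must project inside every
    image; the pixel pitch is chosen so the full cube diagonal fits.
    """

    side_azimuths: tuple[float, ...] = (0.0, 72.0, 144.0, 216.0, 288.0)
    has_top_view: bool = True
    image_size: tuple[int, int] = (512, 512)
    projection: str = "orthographic"
    world_extent: float = 1000.0
    camera_distance: float = 4000.0

    def __post_init__(self) -> None:
        az = tuple(float(a) for a in self.side_azimuths)
        if len(set(az)) != len(az):
            raise ValueError("side azimuths must be distinct")
        if any(a < 0 or a >= 360 for a in az):
            raise ValueError("side azimuths must lie in [0, 360)")
        if self.projection not in ("orthographic", "pinhole"):
            raise ValueError(f"unknown projection {self.projection!r}")
        if self.world_extent <= 0:
            raise ValueError("world_extent must be positive")

    @property
    def px_size(self) -> float:
        """mm per pixel; sized so the cube diagonal fits inside the image."""
        return float(np.sqrt(2.0) * self.world_extent / min(self.image_size))

    @property
    def center(self) -> Array:
        return np.array([0.0, 0.0, self.world_extent / 2.0])

    @property
    def n_views(self) -> int:
        return len(self.side_azimuths) + int(self.has_top_view)

    def views(self) -> list[CalibratedView]:
        out = []
        for az in self.side_azimuths:
            a = np.deg2rad(az)
            forward = np.array([-np.cos(a), -np.sin(a), 0.0])  # camera looks inward
            up = np.array([0.0, 0.0, 1.0])
            right = np.cross(up, forward)
            out.append(self._make_view(f"side_{az:g}", right, up, forward, az))
        if self.has_top_view:
            forward = np.array([0.0, 0.0, -1.0])
            up = np.array([0.0, 1.0, 0.0])
            right = np.cross(up, forward)
            out.append(self._make_view("top", right, up, forward, None))
        return out

    def _make_view(self, label: str, right: Array, up: Array, forward: Array,
                   azimuth: float | None) -> CalibratedView:
        if self.projection == "orthographic":
            return CalibratedView(
                label=label, image_shape=self.image_size, right=right, up=up,
                forward=forward, origin=self.center, px_size=self.px_size,
                kind="orthographic", azimuth=azimuth)
        cam = self.center - forward * self.camera_distance
        # focal length chosen so the nearest face of the world cube still fits
        d_min = self.camera_distance - np.sqrt(2.0) * self.world_extent / 2.0
        if d_min <= 0:
            raise ValueError("camera_distance too small for world_extent")
        focal_px = d_min * min(self.image_size) / (np.sqrt(2.0) * self.world_extent)
        return CalibratedView(
            label=label, image_shape=self.image_size, right=right, up=up,
            forward=forward, origin=cam, px_size=self.px_size,
            kind="pinhole", focal_px=focal_px, azimuth=azimuth)

    # -- JSON round trip ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "side_azimuths": list(self.side_azimuths),
            "has_top_view": self.has_top_view,
            "image_size": list(self.image_size),
            "projection": self.projection,
            "world_extent": self.world_extent,
            "camera_distance": self.camera_distance,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CameraRig":
        d = json.loads(text)
        return cls(side_azimuths=tuple(d["side_azimuths"]),
                   has_top_view=bool(d["has_top_view"]),
                   image_size=tuple(d["image_size"]),
                   projection=d.get("projection", "orthographic"),
                   world_extent=float(d["world_extent"]),
                   camera_distance=float(d.get("camera_distance", 4000.0)))

    def voxel_matched(self, resolution: int) -> "CameraRig":
        """Return a rig whose pixel pitch equals the voxel pitch at ``resolution``.

        Reprojection scores are only meaningful when the image raster and the
        voxel raster sample at commensurate scales; this helper sizes the
        images so one pixel covers one voxel.
        """
        n = int(np.ceil(resolution * np.sqrt(2.0)))
        return CameraRig(side_azimuths=self.side_azimuths,
                         has_top_view=self.has_top_view,
                         image_size=(n, n),
                         projection=self.projection,
                         world_extent=self.world_extent,
                         camera_distance=self.camera_distance)
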