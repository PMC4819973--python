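"""Freehand 3D ultrasound reconstruction.

A tracked 2D ultrasound stream is compounded into a 3D volume in three
steps:

1. **Sector clipping** — pixels outside the probe's imaging sector
   (lateral/angular width, depth range) carry no echo data and are masked
   away (:func:`sector_mask`).
2. **Pose assignment** — each frame's timestamp, shifted by the probe's
   temporal calibration offset, is looked up in the tracker pose stream by
   slerp interpolation (:func:`assign_frame_poses`).  Frames whose shifted
   timestamp falls outside the recorded stream are dropped, never
   extrapolated.
3. **Compounding** — every unmasked pixel is mapped through the spatial
   calibration and the frame pose into the reference frame and binned into
   its nearest voxel (pixel-nearest-neighbour forward mapping); multiple
   contributions to one voxel are averaged, then small holes are filled
   with the mean of filled neighbours (:func:`reconstruct_pnn`).

Image-plane frame convention: x = lateral (columns), y = depth (rows),
z = x cross y = elevation (plane normal).  ``ProbeModel.origin_px`` is the
(row, col) pixel coordinate of the beam origin (depth 0); it may lie
outside the raster (e.g. the virtual apex of a clipped sector).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import EmptyInputError, ExtrapolationError
from .geometry import PoseStream, RigidTransform

__all__ = [
    "ProbeModel",
    "USFrame",
    "Volume",
    "sector_mask",
    "pixel_to_reference",
    "assign_frame_poses",
    "reconstruct_pnn",
]

log = logging.getLogger(__name__)


@dataclass
class ProbeModel:
    """Geometry and calibration of a 2D ultrasound probe.

    Parameters
    ----------
    geometry_kind : {"linear", "sector"}
        Linear probes image a rectangle of given lateral ``width`` (mm);
        sector probes a wedge of given angular ``width`` (degrees) centred
        on the depth axis.
    depth_start, depth_end : float
        Imaging depth range in mm (radial for sector probes).
    pixel_spacing : (float, float)
        (row, col) spacing in mm/pixel.
    image_size : (int, int)
        (rows, cols) of the raster.
    origin_px : (float, float)
        (row, col) of the beam origin (depth 0).
    calibration : RigidTransform
        Spatial calibration, image-plane frame -> sensor frame.
    temporal_offset : float
        ms added to frame timestamps to align them with the tracker clock.
    """

    geometry_kind: str
    width: float
    depth_start: float
    depth_end: float
    pixel_spacing: tuple[float, float]
    image_size: tuple[int, int]
    origin_px: tuple[float, float]
    calibration: RigidTransform = field(
        default_factory=lambda: RigidTransform.identity("image", "sensor")
    )
    temporal_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.geometry_kind not in ("linear", "sector"):
            raise ValueError(f"unknown geometry_kind {self.geometry_kind!r}")
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel_spacing must be positive")
        if not (self.depth_end > self.depth_start >= 0):
            raise ValueError("need depth_end > depth_start >= 0")
        if min(self.image_size) <= 0:
            raise ValueError("image_size must be positive")

    def pixel_to_image_mm(self, pixels: np.ndarray) -> np.ndarray:
        """Map (row, col) pixel coordinates to image-plane mm (N, 3)."""
        px = np.atleast_2d(np.asarray(pixels, dtype=float))
        x = (px[:, 1] - self.origin_px[1]) * self.pixel_spacing[1]
        y = (px[:, 0] - self.origin_px[0]) * self.pixel_spacing[0]
        return np.column_stack([x, y, np.zeros(len(px))])


@dataclass
class USFrame:
    """One 2D echo raster (0-255) with its acquisition timestamp (ms)."""

    pixels: np.ndarray
    timestamp: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("frame pixels must be 2D")
        if not np.all(np.isfinite(px)):
            raise ValueError("frame contains non-finite intensities")
        self.pixels = px


@dataclass
class Volume:
    """A 3D scalar grid in a reference frame.

    ``voxels`` is indexed (ix, iy, iz); ``origin`` is the reference-frame
    position (mm) of the *center* of voxel (0, 0, 0).  ``orientation``
    maps the (axis-aligned) volume frame into the reference frame and is
    identity for volumes produced by this package.  ``fill_mask`` marks
    voxels that received data before hole filling.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: RigidTransform = field(default_factory=RigidTransform.identity)
    fill_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3D")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if self.fill_mask is not None:
            self.fill_mask = np.asarray(self.fill_mask, dtype=bool)
            if self.fill_mask.shape != self.voxels.shape:
                raise ValueError("fill_mask shape must match voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def indices_to_reference(self, idx: np.ndarray) -> np.ndarray:
        """Voxel indices (N, 3) -> reference-frame mm (voxel centers)."""
        pts = np.asarray(idx, dtype=float) * self.spacing + self.origin
        return self.orientation.apply(pts)

    @property
    def voxel_diagonal(self) -> float:
        """Length of one voxel's space diagonal (mm)."""
        return float(np.linalg.norm(self.spacing))


def sector_mask(probe: ProbeModel) -> np.ndarray:
    """Boolean raster of pixels inside the imaging sector.

    Linear probes keep pixels within the lateral half-width and the depth
    range; sector probes keep pixels within the angular half-width (about
    the depth axis through ``origin_px``) and the radial depth range.
    """
    rows, cols = probe.image_size
    r, c = np.mgrid[0:rows, 0:cols]
    pts = probe.pixel_to_image_mm(np.column_stack([r.ravel(), c.ravel()]))
    x, y = pts[:, 0], pts[:, 1]
    if probe.geometry_kind == "linear":
        keep = (np.abs(x) <= probe.width / 2.0) & (y >= probe.depth_start) & (
            y <= probe.depth_end
        )
    else:
        radius = np.hypot(x, y)
        angle = np.degrees(np.arctan2(x, y))  # from the depth axis
        keep = (
            (np.abs(angle) <= probe.width / 2.0)
            & (radius >= probe.depth_start)
            & (radius <= probe.depth_end)
        )
    return keep.reshape(rows, cols)


def pixel_to_reference(
    probe: ProbeModel, sensor_pose: RigidTransform, pixel: Sequence[float]
) -> np.ndarray:
    """Map one (row, col) pixel to reference-frame mm.

    Chain: pixel -> mm scaling -> spatial calibration (image->sensor) ->
    sensor pose (sensor->reference).  Every link is rigid.
    """
    row, col = pixel
    rows, cols = probe.image_size
    if not (0 <= row < rows and 0 <= col < cols):
        raise ValueError(f"pixel {pixel} outside image of size {probe.image_size}")
    p_img = probe.pixel_to_image_mm(np.array([[row, col]]))
    return sensor_pose.compose(probe.calibration).apply(p_img)[0]


def assign_frame_poses(
    frames: Sequence[USFrame], stream: PoseStream, probe: ProbeModel
) -> list[RigidTransform | None]:
    """Interpolated sensor pose per frame at its temporally calibrated time.

    Each frame's timestamp is shifted by ``probe.temporal_offset`` and the
    pose stream is interpolated there.  Frames whose shifted timestamp is
    outside the stream are assigned ``None`` and counted in the log —
    dropped, never extrapolated.
    """
    poses: list[RigidTransform | None] = []
    dropped = 0
    for fr in frames:
        t = fr.timestamp + probe.temporal_offset
        try:
            poses.append(stream.interpolate(t))
        except ExtrapolationError:
            poses.append(None)
            dropped += 1
    if dropped:
        log.info("assign_frame_poses: dropped %d/%d frames outside stream range",
                 dropped, len(frames))
    return poses


def reconstruct_pnn(
    frames: Sequence[USFrame],
    poses: Sequence[RigidTransform | None],
    probe: ProbeModel,
    spacing: float | Sequence[float] | None = None,
    hole_fill_radius: int = 1,
) -> Volume:
    """Pixel-nearest-neighbour compounding of tracked frames into a volume.

    Every unmasked pixel of every frame with a valid pose is transformed
    to the reference frame and binned to its nearest voxel.  Voxels
    receiving several pixels store their mean, which makes the result
    independent of frame order.  Unfilled voxels with at least one filled
    neighbour within ``hole_fill_radius`` voxels (spherical neighbourhood,
    single pass) are then filled with the mean of those neighbours.
    ``fill_mask`` records pre-fill coverage.  The volume's bounding box is
    the tight bounds of the mapped pixels padded by one voxel; axes are
    aligned with the reference frame.

    ``spacing`` defaults to the probe's maximum in-plane pixel spacing
    (isotropic), which avoids aliasing holes in-plane.
    """
    if len(frames) != len(poses):
        raise ValueError("frames and poses must have equal length")
    if spacing is None:
        spacing = max(probe.pixel_spacing)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")

    mask = sector_mask(probe)
    rows, cols = probe.image_size
    r, c = np.mgrid[0:rows, 0:cols]
    pix_rc = np.column_stack([r[mask], c[mask]])
    p_img = probe.pixel_to_image_mm(pix_rc)

    all_pts = []
    all_vals = []
    used = 0
    for fr, pose in zip(frames, poses):
        if pose is None:
            continue
        if fr.pixels.shape != (rows, cols):
            raise ValueError("frame size does not match probe.image_size")
        chain = pose.compose(probe.calibration)
        all_pts.append(chain.apply(p_img))
        all_vals.append(fr.pixels[mask].astype(np.float64))
        used += 1
    if not all_pts or sum(len(v) for v in all_vals) == 0:
        raise EmptyInputError("no unmasked pixels with valid poses to reconstruct")
    pts = np.concatenate(all_pts)
    vals = np.concatenate(all_vals)

    lo = pts.min(axis=0) - spacing  # one-voxel pad
    hi = pts.max(axis=0) + spacing
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)
    idx = np.rint((pts - lo) / spacing).astype(int)
    np.clip(idx, 0, dims - 1, out=idx)

    flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), dims)
    sums = np.bincount(flat, weights=vals, minlength=int(np.prod(dims)))
    cnts = np.bincount(flat, minlength=int(np.prod(dims)))
    sums = sums.reshape(dims)
    cnts = cnts.reshape(dims)
    filled = cnts > 0
    voxels = np.zeros(tuple(dims), dtype=np.float32)
    voxels[filled] = (sums[filled] / cnts[filled]).astype(np.float32)

    n_holes = 0
    if hole_fill_radius > 0:
        kernel = _ball_kernel(hole_fill_radius)
        nb_sum = ndimage.convolve(voxels * filled, kernel, mode="constant")
        nb_cnt = ndimage.convolve(filled.astype(np.float32), kernel, mode="constant")
        holes = ~filled & (nb_cnt > 0.5)
        voxels[holes] = nb_sum[holes] / nb_cnt[holes]
        n_holes = int(holes.sum())

    log.info(
        "reconstruct_pnn: %d frames, %d pixels -> %s volume at %s mm, "
        "%d voxels filled, %d holes filled",
        used, len(vals), "x".join(map(str, dims)),
        "/".join(f"{s:g}" for s in spacing), int(filled.sum()), n_holes,
    )
    return Volume(voxels, spacing, lo, RigidTransform.identity(), filled)


def _ball_kernel(radius: int) -> np.ndarray:
    """Spherical boolean kernel of the given voxel radius (float32)."""
    r = int(radius)
    g = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return ((g**2).sum(axis=0) <= r**2).astype(np.float32)
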