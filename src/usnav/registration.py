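"""Rigid registration methods for image-to-image and image-to-patient
alignment.

Four methods are provided:

``register_landmarks``
    Paired-point least squares: given the same named point set defined in
    the moving and fixed spaces, find the rigid transform minimizing the
    sum of squared distances (SVD solution with a reflection guard).

``register_fast``
    A rough initial estimate from a single landmark pair plus the tool
    orientation: the minimal rotation carrying the moving reference axis
    onto the tool axis, with the translation pinning the landmark exactly.
    Fast but approximate — intended to seed a refined method.

``icp_register_centerlines``
    Iterative closest point between two curved paths.  Correspondence is
    point-to-segment (orthogonal projection onto the fixed polyline), so
    residuals do not depend on how densely the fixed path is sampled.

``register_trajectory_to_airway``
    Image-to-patient registration matching a tracked endoscope-tip
    trajectory to an airway centerline.  A modified ICP: candidate
    correspondences are rejected when the tip's pointing axis disagrees
    with the local running direction of the centerline by more than a
    configurable angle, which disambiguates geometrically similar
    branches.

Registration quality is quantified by ``evaluate_registration_displacement``:
the movement a transform imposes on landmarks defined in the moving space.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateGeometryError,
    InsufficientLandmarksError,
    NoCorrespondenceError,
    UsnavError,
)
from .geometry import PoseStream, RigidTransform

__all__ = [
    "LandmarkSet",
    "Centerline",
    "RegistrationResult",
    "IcpParams",
    "fit_rigid",
    "register_landmarks",
    "register_fast",
    "icp_register_centerlines",
    "register_trajectory_to_airway",
    "evaluate_registration_displacement",
    "run_external_i2i",
]

log = logging.getLogger(__name__)


@dataclass
class LandmarkSet:
    """Named 3D points in a single coordinate frame (mm)."""

    landmarks: dict[str, np.ndarray]
    frame: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, p in self.landmarks.items():
            p = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name!r} is not finite")
            clean[name] = p
        self.landmarks = clean

    def __len__(self) -> int:
        return len(self.landmarks)

    def names(self) -> list[str]:
        return list(self.landmarks)

    def points(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = self.names() if names is None else list(names)
        return np.array([self.landmarks[n] for n in names])


@dataclass
class Centerline:
    """An ordered 3D polyline (mm) with optional unit tangents.

    Tangents, when absent but required, are computed by normalized central
    differences.
    """

    points: np.ndarray
    tangents: np.ndarray | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise ValueError("centerline needs an (N>=2, 3) point array")
        if np.any(np.linalg.norm(np.diff(pts, axis=0), axis=1) == 0):
            raise ValueError("consecutive centerline points must be distinct")
        self.points = pts
        if self.tangents is not None:
            tg = np.asarray(self.tangents, dtype=float)
            if tg.shape != pts.shape:
                raise ValueError("tangents must match points in shape")
            norms = np.linalg.norm(tg, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-9):
                raise ValueError("tangents must be unit-norm")
            self.tangents = tg

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def with_tangents(self) -> "Centerline":
        """Return a copy with tangents (central differences) if missing."""
        if self.tangents is not None:
            return self
        pts = self.points
        tg = np.empty_like(pts)
        tg[1:-1] = pts[2:] - pts[:-2]
        tg[0] = pts[1] - pts[0]
        tg[-1] = pts[-1] - pts[-2]
        tg /= np.linalg.norm(tg, axis=1, keepdims=True)
        return Centerline(pts.copy(), tg)

    def resample(self, step: float) -> "Centerline":
        """Resample at (approximately) uniform arc-length ``step`` mm."""
        if step <= 0:
            raise ValueError("step must be positive")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        n = max(2, int(np.ceil(s[-1] / step)) + 1)
        si = np.linspace(0.0, s[-1], n)
        pts = np.column_stack([np.interp(si, s, self.points[:, k]) for k in range(3)])
        return Centerline(pts)


@dataclass
class RegistrationResult:
    """Outcome of a rigid registration (moving -> fixed)."""

    transform: RigidTransform
    rms_residual: float
    per_iteration_residuals: list[float] = field(default_factory=list)
    n_correspondences: int = 0


@dataclass
class IcpParams:
    """Settings for the ICP family.

    max_iter : iteration cap.
    tol_mm : stop when the rms residual changes by less than this.
    trim_fraction : fraction of worst correspondences discarded each
        iteration (0 disables trimming).
    initial : initial guess for the moving->fixed transform.
    max_angle_deg : orientation gate for trajectory-to-centerline
        registration; correspondences whose pointing-axis/running-direction
        angle exceeds this are rejected.
    min_samples : minimum number of trajectory poses required.
    """

    max_iter: int = 100
    tol_mm: float = 1e-6
    trim_fraction: float = 0.0
    initial: RigidTransform | None = None
    max_angle_deg: float = 60.0
    min_samples: int = 10


# -- core least-squares fit ----------------------------------------------


def fit_rigid(moving: np.ndarray, fixed: np.ndarray,
              weights: np.ndarray | None = None) -> RigidTransform:
    """Least-squares rigid transform taking paired ``moving`` onto ``fixed``.

    SVD of the cross-covariance with a determinant sign guard, so the
    result is always a proper rotation (never a reflection), even when a
    reflection would fit the pairs better.
    """
    m = np.asarray(moving, dtype=float)
    f = np.asarray(fixed, dtype=float)
    if m.shape != f.shape or m.ndim != 2 or m.shape[1] != 3:
        raise ValueError("point sets must be matching (N, 3) arrays")
    if weights is None:
        weights = np.ones(len(m))
    w = weights / weights.sum()
    mc = (w[:, None] * m).sum(axis=0)
    fc = (w[:, None] * f).sum(axis=0)
    h = (w[:, None] * (m - mc)).T @ (f - fc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    tr = fc - rot @ mc
    return RigidTransform(rot, tr)


def register_landmarks(moving: LandmarkSet, fixed: LandmarkSet) -> RegistrationResult:
    """Paired-point least-squares registration on common landmark names.

    Requires at least three common, non-collinear landmarks.  Usable for
    both image-to-image and image-to-patient registration (the fixed set
    being physical-space points acquired with a tracked pointer in the
    latter case).
    """
    common = [n for n in moving.names() if n in fixed.landmarks]
    if len(common) < 3:
        raise InsufficientLandmarksError(
            f"need >=3 common landmark names, found {len(common)}: {common}"
        )
    m = moving.points(common)
    f = fixed.points(common)
    # collinearity check on the moving set: rank of centered points < 2
    sv = np.linalg.svd(m - m.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("landmarks are collinear")
    t = fit_rigid(m, f)
    t = t.relabel(moving.frame, fixed.frame)
    res = np.linalg.norm(t.apply(m) - f, axis=1)
    rms = float(np.sqrt(np.mean(res**2)))
    return RegistrationResult(t, rms, [rms], len(common))


def register_fast(
    landmark_moving: np.ndarray,
    landmark_fixed: np.ndarray,
    tool_axis_fixed: np.ndarray,
    reference_axis_moving: np.ndarray,
) -> RegistrationResult:
    """Rough registration from one landmark pair plus the tool orientation.

    The rotation is the minimal-angle rotation carrying the moving-space
    reference axis onto the fixed-space tool axis; the translation then
    maps the moving landmark exactly onto the fixed landmark.  This is not
    an accurate method — it is a fast initial estimate for refinement.

    Anti-parallel axes are handled deterministically by rotating 180 deg
    about the coordinate axis most perpendicular to the reference axis.
    """
    pm = np.asarray(landmark_moving, dtype=float).reshape(3)
    pf = np.asarray(landmark_fixed, dtype=float).reshape(3)
    a = np.asarray(reference_axis_moving, dtype=float).reshape(3)
    b = np.asarray(tool_axis_fixed, dtype=float).reshape(3)
    for v, name in ((a, "reference_axis_moving"), (b, "tool_axis_fixed")):
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ValueError(f"{name} must be unit-norm")
    c = float(a @ b)
    if c < -1.0 + 1e-12:
        # anti-parallel: 180 deg about the coordinate axis with the smallest
        # |component| along a, orthogonalized against a
        k = int(np.argmin(np.abs(a)))
        e = np.zeros(3)
        e[k] = 1.0
        axis = e - (e @ a) * a
        axis /= np.linalg.norm(axis)
        rot = 2.0 * np.outer(axis, axis) - np.eye(3)
    else:
        v = np.cross(a, b)
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)  # Rodrigues, minimal angle
    tr = pf - rot @ pm
    t = RigidTransform(rot, tr)
    res = float(np.linalg.norm(t.apply(pm) - pf))
    return RegistrationResult(t, res, [res], 1)


# -- point-to-polyline machinery -----------------------------------------


def _polyline_segments(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Segment starts and direction vectors of a polyline."""
    return points[:-1], np.diff(points, axis=0)


def closest_points_on_segments(
    query: np.ndarray, seg_start: np.ndarray, seg_vec: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """For each query point, the closest point over a set of segments.

    Returns (closest points, distances, segment indices).  Vectorized over
    all query x segment pairs; fine for the polyline sizes used here.
    """
    q = np.atleast_2d(query)
    len2 = np.einsum("ij,ij->i", seg_vec, seg_vec)
    # parameter of orthogonal projection, clamped to the segment
    diff = q[:, None, :] - seg_start[None, :, :]          # (Q, S, 3)
    tpar = np.einsum("qsj,sj->qs", diff, seg_vec) / len2  # (Q, S)
    np.clip(tpar, 0.0, 1.0, out=tpar)
    proj = seg_start[None] + tpar[..., None] * seg_vec[None]
    d2 = np.einsum("qsj,qsj->qs", q[:, None] - proj, q[:, None] - proj)
    idx = np.argmin(d2, axis=1)
    rows = np.arange(len(q))
    return proj[rows, idx], np.sqrt(d2[rows, idx]), idx


def _run_icp(
    moving_pts: np.ndarray,
    seg_start: np.ndarray,
    seg_vec: np.ndarray,
    params: IcpParams,
    seg_dirs_unit: np.ndarray | None = None,
    moving_axes: np.ndarray | None = None,
) -> RegistrationResult:
    """Shared ICP loop.

    When ``seg_dirs_unit`` and ``moving_axes`` are given, a correspondence
    is kept only if the angle between the (rotated) moving axis and the
    local segment running direction is within ``params.max_angle_deg``.
    The recorded residual sequence is non-increasing by construction: the
    loop terminates (keeping the previous estimate) rather than record an
    increase.
    """
    t = params.initial if params.initial is not None else RigidTransform.identity()
    cos_gate = np.cos(np.deg2rad(params.max_angle_deg))
    residuals: list[float] = []
    n_used = 0
    for _ in range(params.max_iter):
        pts = t.apply(moving_pts)
        closest, dist, idx = closest_points_on_segments(pts, seg_start, seg_vec)
        keep = np.ones(len(pts), dtype=bool)
        if seg_dirs_unit is not None and moving_axes is not None:
            axes = t.apply_vectors(moving_axes)
            cosang = np.einsum("ij,ij->i", axes, seg_dirs_unit[idx])
            keep &= cosang >= cos_gate
        if params.trim_fraction > 0 and keep.sum() > 3:
            kept_d = np.where(keep, dist, np.inf)
            n_keep = max(3, int(np.ceil(keep.sum() * (1.0 - params.trim_fraction))))
            order = np.argsort(kept_d)
            trimmed = np.zeros(len(pts), dtype=bool)
            trimmed[order[:n_keep]] = True
            keep &= trimmed
        if keep.sum() == 0:
            raise NoCorrespondenceError(
                "no usable correspondences (empty overlap or all rejected "
                "by the orientation gate)"
            )
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        if residuals and rms > residuals[-1]:
            break  # keep previous estimate; sequence stays non-increasing
        residuals.append(rms)
        n_used = int(keep.sum())
        t_new = fit_rigid(moving_pts[keep], closest[keep]).relabel(
            t.from_frame, t.to_frame
        )
        if residuals[-1] < params.tol_mm or (
            len(residuals) > 1 and residuals[-2] - residuals[-1] < params.tol_mm
        ):
            t = t_new
            break
        t = t_new
    return RegistrationResult(t, residuals[-1], residuals, n_used)


def icp_register_centerlines(
    moving: Centerline, fixed: Centerline, params: IcpParams | None = None
) -> RegistrationResult:
    """Rigid ICP minimizing the distance between two curved paths.

    Correspondences are orthogonal projections of the moving points onto
    the fixed polyline's segments (continuous, resolution-independent),
    alternated with a least-squares rigid fit until the rms residual
    converges.  ``params.trim_fraction`` discards the worst fraction of
    correspondences each iteration, which makes the method robust to
    partial overlap.
    """
    params = params or IcpParams()
    seg_start, seg_vec = _polyline_segments(fixed.points)
    res = _run_icp(moving.points, seg_start, seg_vec, params)
    log.info("centerline ICP: %d iterations, rms %.4f mm, %d correspondences",
             len(res.per_iteration_residuals), res.rms_residual, res.n_correspondences)
    return res


def register_trajectory_to_airway(
    trajectory: PoseStream,
    airway: Centerline,
    params: IcpParams | None = None,
    tip_axis_local: Sequence[float] = (0.0, 0.0, 1.0),
) -> RegistrationResult:
    """Match an endoscope-tip trajectory to an airway centerline.

    The tip positions are registered to the centerline with ICP, but a
    candidate correspondence is rejected when the angle between the tip's
    pointing axis (``tip_axis_local`` expressed through each pose) and the
    local running direction of the centerline exceeds
    ``params.max_angle_deg``.  The gate uses the signed direction: a scope
    cannot travel against the running direction of the branch it is in, so
    anti-parallel matches are spurious.
    """
    params = params or IcpParams()
    if len(trajectory) < params.min_samples:
        raise UsnavError(
            f"trajectory has {len(trajectory)} poses; need >= {params.min_samples}"
        )
    airway = airway.with_tangents()
    pts = trajectory.positions()
    axes = np.array(
        [s.pose.apply_vectors(np.asarray(tip_axis_local, float)) for s in trajectory]
    )
    seg_start, seg_vec = _polyline_segments(airway.points)
    # running direction per segment: mean of endpoint tangents, normalized
    seg_dir = airway.tangents[:-1] + airway.tangents[1:]
    seg_dir /= np.linalg.norm(seg_dir, axis=1, keepdims=True)
    res = _run_icp(pts, seg_start, seg_vec, params,
                   seg_dirs_unit=seg_dir, moving_axes=axes)
    log.info("trajectory ICP: %d iterations, rms %.4f mm, %d/%d poses used",
             len(res.per_iteration_residuals), res.rms_residual,
             res.n_correspondences, len(pts))
    return res


def evaluate_registration_displacement(
    landmarks: LandmarkSet, t: RigidTransform
) -> tuple[dict[str, float], Mapping[str, float]]:
    """Movement a registration imposes on landmarks in the moving space.

    Returns per-landmark displacement magnitudes |T p - p| (mm) plus a
    summary with mean and max.
    """
    if landmarks.frame and t.from_frame and landmarks.frame != t.from_frame:
        raise UsnavError(
            f"landmarks are in frame {landmarks.frame!r}, "
            f"transform expects {t.from_frame!r}"
        )
    p = landmarks.points()
    d = np.linalg.norm(t.apply(p) - p, axis=1)
    per = dict(zip(landmarks.names(), map(float, d)))
    return per, {"mean": float(d.mean()), "max": float(d.max())}


def run_external_i2i(
    command_template: str,
    moving_path: str | Path,
    fixed_path: str | Path,
    output_transform_path: str | Path,
    timeout_s: float = 600.0,
) -> RigidTransform:
    """Hook for image-to-image registration via an external command-line tool.

    Subprocess contract: ``command_template`` is formatted with ``{moving}``,
    ``{fixed}`` and ``{output}``; the tool must exit 0 and write the
    resulting moving->fixed transform to ``{output}`` as four lines of four
    whitespace-separated floats (row-major homogeneous matrix).  No
    external tool is bundled.
    """
    out = Path(output_transform_path)
    cmd = command_template.format(
        moving=str(moving_path), fixed=str(fixed_path), output=str(out)
    )
    log.info("running external I2I registration: %s", cmd)
    proc = subprocess.run(shlex.split(cmd), capture_output=True, timeout=timeout_s)
    if proc.returncode != 0:
        raise UsnavError(
            f"external I2I tool failed (exit {proc.returncode}): "
            f"{proc.stderr.decode(errors='replace')[:500]}"
        )
    if not out.exists():
        raise UsnavError(f"external I2I tool did not write {out}")
    from .io import read_transform  # local import to avoid cycle

    return read_transform(out)
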