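"""Rigid-body transforms, coordinate-frame chains, and pose-stream
interpolation.

Conventions used throughout the toolkit:

* lengths in millimetres, times in milliseconds, right-handed frames;
* a :class:`RigidTransform` maps points expressed in ``from_frame`` into
  ``to_frame`` (``p_to = R @ p_from + t``);
* tracker pose convention: a pose maps sensor-local coordinates into
  tracker coordinates (``from_frame = sensor``, ``to_frame = tracker``);
* frame labels are checked strings — composing transforms whose labels do
  not chain raises :class:`~usnav.errors.FrameMismatchError` rather than
  warning, so calibration-chain mistakes fail loudly.

Rotations are interpolated on the shortest arc with unit quaternions
(slerp); translations linearly.  Orthonormality is maintained by a polar
decomposition applied when numerical drift accumulates (long composition
chains).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import polar
from scipy.spatial.transform import Rotation

from .errors import ExtrapolationError, FrameMismatchError

__all__ = [
    "RigidTransform",
    "TimedPose",
    "PoseStream",
    "compose",
    "invert",
    "transform_points",
    "interpolate_pose",
]

_ORTHO_ATOL = 1e-6          # construction-time validation tolerance
_DRIFT_TOL = 1e-12          # re-orthonormalize when drift exceeds this
_REORTHO_CHAIN_LEN = 10     # ... or after composition chains this long


def _reorthonormalize(rotation: np.ndarray) -> np.ndarray:
    """Project a near-rotation matrix onto SO(3) via polar decomposition."""
    u, _ = polar(rotation)
    if np.linalg.det(u) < 0:  # pragma: no cover - cannot happen for det>0 input
        u = -u
    return u


@dataclass(frozen=True)
class RigidTransform:
    """A rigid (rotation + translation) mapping between two named frames.

    Parameters
    ----------
    rotation : (3, 3) ndarray
        Orthonormal with determinant +1.
    translation : (3,) ndarray
        Millimetres.
    from_frame, to_frame : str
        Labels of the source and destination coordinate frames.
    """

    rotation: np.ndarray
    translation: np.ndarray
    from_frame: str = ""
    to_frame: str = ""
    _chain: int = field(default=0, compare=False, repr=False)

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float).reshape(3)
        if rot.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {rot.shape}")
        if not np.all(np.isfinite(rot)) or not np.all(np.isfinite(tr)):
            raise ValueError("non-finite rigid transform")
        drift = np.abs(rot.T @ rot - np.eye(3)).max()
        if drift > _ORTHO_ATOL:
            raise ValueError(f"rotation not orthonormal (drift {drift:.2e})")
        if np.linalg.det(rot) < 0:
            raise ValueError("rotation has determinant -1 (reflection)")
        if drift > _DRIFT_TOL:
            rot = _reorthonormalize(rot)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    # -- constructors -----------------------------------------------------

    @classmethod
    def identity(cls, from_frame: str = "", to_frame: str = "") -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), from_frame, to_frame)

    @classmethod
    def from_matrix(
        cls, matrix: np.ndarray, from_frame: str = "", to_frame: str = ""
    ) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (row-major)."""
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected 4x4 homogeneous matrix, got {m.shape}")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-9):
            raise ValueError("bottom row of homogeneous matrix must be 0 0 0 1")
        return cls(m[:3, :3], m[:3, 3], from_frame, to_frame)

    @classmethod
    def from_quaternion(
        cls,
        qwxyz: Sequence[float],
        translation: Sequence[float],
        from_frame: str = "",
        to_frame: str = "",
    ) -> "RigidTransform":
        """Build from a unit quaternion given scalar-first (qw, qx, qy, qz)."""
        qw, qx, qy, qz = qwxyz
        rot = Rotation.from_quat([qx, qy, qz, qw]).as_matrix()
        return cls(rot, np.asarray(translation, dtype=float), from_frame, to_frame)

    @classmethod
    def from_axis_angle(
        cls,
        axis: Sequence[float],
        angle_deg: float,
        translation: Sequence[float] = (0.0, 0.0, 0.0),
        from_frame: str = "",
        to_frame: str = "",
    ) -> "RigidTransform":
        ax = np.asarray(axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * ax).as_matrix()
        return cls(rot, np.asarray(translation, dtype=float), from_frame, to_frame)

    # -- views ------------------------------------------------------------

    @property
    def matrix(self) -> np.ndarray:
        """The 4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def quaternion_wxyz(self) -> np.ndarray:
        """Unit quaternion, scalar first, with qw >= 0."""
        q = Rotation.from_matrix(self.rotation).as_quat()  # x y z w
        q = np.array([q[3], q[0], q[1], q[2]])
        return -q if q[0] < 0 else q

    # -- algebra ----------------------------------------------------------

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply *other* first, then *self*.

        Frame labels must chain: ``self.from_frame == other.to_frame``.
        Empty labels act as wildcards (useful for ad-hoc math).
        """
        if self.from_frame and other.to_frame and self.from_frame != other.to_frame:
            raise FrameMismatchError(
                f"cannot compose: {other.from_frame!r}->{other.to_frame!r} "
                f"then {self.from_frame!r}->{self.to_frame!r}"
            )
        rot = self.rotation @ other.rotation
        tr = self.rotation @ other.translation + self.translation
        chain = self._chain + other._chain + 1
        if chain > _REORTHO_CHAIN_LEN:
            rot = _reorthonormalize(rot)
            chain = 0
        return RigidTransform(
            rot, tr, other.from_frame, self.to_frame, _chain=chain
        )

    def invert(self) -> "RigidTransform":
        """Inverse transform; frame labels swapped."""
        rot = self.rotation.T
        return RigidTransform(
            rot, -rot @ self.translation, self.to_frame, self.from_frame
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array (or a single 3-vector) of points."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        if pts.shape[1] != 3:
            raise ValueError("points must be (N, 3)")
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        v = np.asarray(vectors, dtype=float)
        single = v.ndim == 1
        out = np.atleast_2d(v) @ self.rotation.T
        return out[0] if single else out

    def relabel(self, from_frame: str, to_frame: str) -> "RigidTransform":
        return replace(self, from_frame=from_frame, to_frame=to_frame)

    def is_close(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )


@dataclass(frozen=True)
class TimedPose:
    """A tracker sample: timestamp (ms) plus the sensor->tracker pose."""

    timestamp: float
    pose: RigidTransform

    def __post_init__(self) -> None:
        if not np.isfinite(self.timestamp):
            raise ValueError("timestamp must be finite")


class PoseStream:
    """Ordered, strictly increasing sequence of timed tracker poses.

    All samples share the same frame labels.  Used to look up (by slerp
    interpolation) the probe pose at an ultrasound frame's timestamp.
    """

    def __init__(self, samples: Iterable[TimedPose]):
        samples = list(samples)
        if not samples:
            raise ValueError("PoseStream requires at least one sample")
        ts = np.array([s.timestamp for s in samples], dtype=float)
        if np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        f0, t0 = samples[0].pose.from_frame, samples[0].pose.to_frame
        for s in samples:
            if (s.pose.from_frame, s.pose.to_frame) != (f0, t0):
                raise FrameMismatchError("all samples must share frame labels")
        self._samples = samples
        self._timestamps = ts

    def __len__(self) -> int:
        return len(self._samples)

    def __iter__(self):
        return iter(self._samples)

    def __getitem__(self, i: int) -> TimedPose:
        return self._samples[i]

    @property
    def timestamps(self) -> np.ndarray:
        return self._timestamps.copy()

    @property
    def from_frame(self) -> str:
        return self._samples[0].pose.from_frame

    @property
    def to_frame(self) -> str:
        return self._samples[0].pose.to_frame

    @property
    def t_first(self) -> float:
        return float(self._timestamps[0])

    @property
    def t_last(self) -> float:
        return float(self._timestamps[-1])

    def positions(self) -> np.ndarray:
        """(N, 3) translations — e.g. the tool-tip trajectory."""
        return np.array([s.pose.translation for s in self._samples])

    def interpolate(self, t: float) -> RigidTransform:
        """Pose at time ``t`` (ms).

        Translation is linearly interpolated, rotation by shortest-arc
        slerp on unit quaternions.  A ``t`` matching a sample timestamp
        returns that sample's pose exactly; a ``t`` outside the recorded
        range raises :class:`~usnav.errors.ExtrapolationError` — poses are
        never silently clamped.
        """
        ts = self._timestamps
        if t < ts[0] or t > ts[-1]:
            raise ExtrapolationError(
                f"t={t} ms outside stream range [{ts[0]}, {ts[-1]}] ms"
            )
        i = int(np.searchsorted(ts, t))
        if ts[i] == t:
            return self._samples[i].pose
        a, b = self._samples[i - 1], self._samples[i]
        w = (t - a.timestamp) / (b.timestamp - a.timestamp)
        return _slerp_pose(a.pose, b.pose, w)


def _slerp_pose(a: RigidTransform, b: RigidTransform, w: float) -> RigidTransform:
    """Shortest-arc quaternion slerp between two poses, weight w in [0, 1]."""
    qa = a.quaternion_wxyz()
    qb = b.quaternion_wxyz()
    dot = float(qa @ qb)
    if dot < 0.0:  # take the short way round
        qb = -qb
        dot = -dot
    if dot > 1.0 - 1e-12:
        q = (1.0 - w) * qa + w * qb  # nearly parallel: lerp, renormalize
    else:
        theta = np.arccos(np.clip(dot, -1.0, 1.0))
        q = (np.sin((1.0 - w) * theta) * qa + np.sin(w * theta) * qb) / np.sin(theta)
    q = q / np.linalg.norm(q)
    tr = (1.0 - w) * a.translation + w * b.translation
    return RigidTransform.from_quaternion(q, tr, a.from_frame, a.to_frame)


# -- module-level functional API -----------------------------------------


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Chain two transforms: result maps ``b.from_frame -> a.to_frame``."""
    return a.compose(b)


def invert(t: RigidTransform) -> RigidTransform:
    return t.invert()


def transform_points(t: RigidTransform, points: np.ndarray) -> np.ndarray:
    return t.apply(points)


def interpolate_pose(stream: PoseStream, t: float) -> RigidTransform:
    return stream.interpolate(t)
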