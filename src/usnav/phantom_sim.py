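"""Synthetic wire-cross phantom and tracked-sweep simulator.

This module generates the inputs of a navigation-accuracy experiment:
a wire cross suspended in a water tank, a tracked ultrasound probe swept
over it, and the resulting 2D frame stream plus tracker pose stream.
It exists to exercise the reconstruction and accuracy-evaluation pipeline
with *known* ground truth and *controlled* error injection:

* ``calibration_offset`` — the probe calibration handed to the consumer is
  the true calibration composed with this perturbation, while frames are
  rendered with the true one.  This reproduces the dominant real-world
  error source (miscalibration) and its effect on navigation accuracy.
* ``tracking_jitter`` — independent per-sample white perturbations of the
  reported poses (translation in mm, rotation in degrees), matching the
  character of optical-tracking noise.
* ``sound_speed_scale`` — scales apparent echo depth, emulating a scanner
  whose assumed speed of sound differs from the medium's.
* ``latency_ms`` — the reported pose stream lags the true motion.

The echo model is deliberately synthetic: wires appear with a Gaussian
radial intensity profile (sigma = wire radius) over a water background
with additive seeded noise.  That is adequate for testing the geometric
pipeline; it does not emulate speckle statistics, shadowing or
reverberation.

Reference-frame convention used by the simulator: z up, probe above the
tank imaging downwards (image depth axis = -z), probe translating along
+/-y (image plane normal = elevation = y), image lateral axis = x.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import PoseStream, RigidTransform, TimedPose
from .reconstruction import ProbeModel, USFrame, sector_mask

__all__ = [
    "WireCrossModel",
    "SweepSpec",
    "ErrorInjection",
    "SimulatedAcquisition",
    "make_wire_cross",
    "default_probe",
    "simulate_sweep",
    "batch_acquisitions",
    "DIRECTION_LABELS",
]

log = logging.getLogger(__name__)

#: The four acquisition conditions of a standard accuracy session:
#: probe motion along vs. diagonal to the wire cross, crossed with sweep
#: direction front-to-back vs. back-to-front.
DIRECTION_LABELS = [
    ("along", "front_to_back"),
    ("along", "back_to_front"),
    ("diagonal", "front_to_back"),
    ("diagonal", "back_to_front"),
]


@dataclass
class WireCrossModel:
    """Two straight wires crossing at a point — the accuracy gold standard.

    Each wire is (center, unit direction, half_length).  The two infinite
    lines must intersect; the nominal wire diameter is 1.0 mm.
    """

    wires: tuple[tuple[np.ndarray, np.ndarray, float], ...]
    wire_diameter: float = 1.0
    frame: str = "reference"

    def __post_init__(self) -> None:
        if len(self.wires) != 2:
            raise ValueError("a wire cross has exactly two wires")
        wires = []
        for center, direction, half_length in self.wires:
            c = np.asarray(center, dtype=float).reshape(3)
            d = np.asarray(direction, dtype=float).reshape(3)
            if abs(np.linalg.norm(d) - 1.0) > 1e-9:
                raise ValueError("wire directions must be unit-norm")
            if half_length <= 0:
                raise ValueError("half_length must be positive")
            wires.append((c, d, float(half_length)))
        self.wires = tuple(wires)
        if np.linalg.norm(self.cross_point() - self._nearest_points()[1]) > 1e-6:
            raise ValueError("the two wire lines do not intersect")

    def _nearest_points(self) -> tuple[np.ndarray, np.ndarray]:
        (c1, d1, _), (c2, d2, _) = self.wires
        # closest points of two lines: solve for parameters s, t
        w = c1 - c2
        a, b, c = d1 @ d1, d1 @ d2, d2 @ d2
        d, e = d1 @ w, d2 @ w
        denom = a * c - b * b
        if abs(denom) < 1e-12:
            raise ValueError("wire directions are parallel")
        s = (b * e - c * d) / denom
        t = (a * e - b * d) / denom
        return c1 + s * d1, c2 + t * d2

    def cross_point(self) -> np.ndarray:
        """Intersection of the two wire lines (mm)."""
        p1, p2 = self._nearest_points()
        return (p1 + p2) / 2.0

    def crossing_angle_deg(self) -> float:
        (_, d1, _), (_, d2, _) = self.wires
        return float(np.degrees(np.arccos(np.clip(abs(d1 @ d2), -1.0, 1.0))))

    def endpoints(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(c - h * d, c + h * d) for c, d, h in self.wires]


@dataclass
class SweepSpec:
    """One probe sweep: linear translation between two positions.

    ``direction_label`` encodes the acquisition condition (probe motion
    along vs. diagonal to the cross, front-to-back vs. back-to-front).
    """

    start_mm: np.ndarray
    end_mm: np.ndarray
    n_frames: int = 80
    frame_rate: float = 20.0
    direction_label: tuple[str, str] = ("along", "front_to_back")
    seed: int = 0

    def __post_init__(self) -> None:
        self.start_mm = np.asarray(self.start_mm, dtype=float).reshape(3)
        self.end_mm = np.asarray(self.end_mm, dtype=float).reshape(3)
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


@dataclass
class ErrorInjection:
    """Controlled error sources applied to a simulated acquisition."""

    calibration_offset: RigidTransform = field(
        default_factory=lambda: RigidTransform.identity("image", "image")
    )
    tracking_jitter_mm: float = 0.0
    tracking_jitter_deg: float = 0.0
    sound_speed_scale: float = 1.0
    latency_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.tracking_jitter_mm < 0 or self.tracking_jitter_deg < 0:
            raise ValueError("jitter SDs must be >= 0")
        if self.sound_speed_scale <= 0:
            raise ValueError("sound_speed_scale must be positive")


@dataclass
class SimulatedAcquisition:
    """Everything a consumer needs, plus the hidden truth for evaluation."""

    frames: list[USFrame]
    poses: PoseStream
    probe: ProbeModel           # carries the (possibly perturbed) calibration
    truth_model: WireCrossModel
    truth_injection: ErrorInjection
    seed: int
    direction_label: tuple[str, str] = ("along", "front_to_back")
    mid_sweep_pose: RigidTransform | None = None  # true image->reference at mid-sweep


def make_wire_cross(
    arm_length: float = 40.0,
    crossing_angle_deg: float = 90.0,
    center: Sequence[float] = (0.0, 0.0, -40.0),
    plane_axes: tuple[Sequence[float], Sequence[float]] | None = None,
) -> WireCrossModel:
    """Build a symmetric wire cross.

    The two wires lie in the plane spanned by ``plane_axes`` (default: the
    horizontal x-y plane), symmetric about the first axis, crossing at
    ``center`` with the given angle.
    """
    if not 0.0 < crossing_angle_deg < 180.0:
        raise ValueError("crossing angle must be in (0, 180) degrees")
    if arm_length <= 0:
        raise ValueError("arm_length must be positive")
    if plane_axes is None:
        u, v = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
    else:
        u = np.asarray(plane_axes[0], dtype=float)
        v = np.asarray(plane_axes[1], dtype=float)
        u = u / np.linalg.norm(u)
        v = v - (v @ u) * u
        v = v / np.linalg.norm(v)
    c = np.asarray(center, dtype=float)
    half = np.deg2rad(crossing_angle_deg) / 2.0
    d1 = np.cos(half) * u + np.sin(half) * v
    d2 = np.cos(half) * u - np.sin(half) * v
    return WireCrossModel(((c, d1, arm_length), (c, d2, arm_length)))


def default_probe(
    image_size: tuple[int, int] = (96, 96),
    pixel_spacing_mm: float = 0.2,
    depth_start: float = 30.0,
) -> ProbeModel:
    """A linear probe whose raster covers the region around the wire cross.

    96x96 pixels at 0.2 mm/px images a 19.2 mm lateral window from 30 mm
    depth — enough to keep reconstructed phantom volumes near 100^3 voxels
    at 0.2 mm spacing.
    """
    rows, cols = image_size
    depth_end = depth_start + rows * pixel_spacing_mm
    return ProbeModel(
        geometry_kind="linear",
        width=cols * pixel_spacing_mm,
        depth_start=depth_start,
        depth_end=depth_end,
        pixel_spacing=(pixel_spacing_mm, pixel_spacing_mm),
        image_size=image_size,
        origin_px=(-depth_start / pixel_spacing_mm, (cols - 1) / 2.0),
        calibration=RigidTransform.identity("image", "sensor"),
        temporal_offset=0.0,
    )


def _probe_pose_at(position: np.ndarray) -> RigidTransform:
    """True sensor->reference pose of the probe at a given beam origin.

    Image axes in the reference frame: lateral x -> +X, depth y -> -Z
    (imaging downwards), elevation z = x cross y -> +Y.
    """
    rot = np.column_stack([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
    return RigidTransform(rot, position, "sensor", "reference")


def _wire_intensity(points: np.ndarray, model: WireCrossModel,
                    plane_normal: np.ndarray, echo: float,
                    elevation_sigma: float) -> np.ndarray:
    """Echo amplitude at 3D query points from both wires.

    Gaussian radial profile: sigma = wire radius within the scan plane,
    ``elevation_sigma`` across it (the elevation beam width makes wires
    look blurrier out of plane than in plane).
    """
    out = np.zeros(len(points))
    sigma_r = model.wire_diameter / 2.0
    for c, d, h in model.wires:
        rel = points - c
        along = rel @ d
        radial = rel - along[:, None] * d[None, :]
        d2 = np.einsum("ij,ij->i", radial, radial)
        d_elev = radial @ plane_normal
        d_in2 = np.maximum(d2 - d_elev**2, 0.0)
        amp = echo * np.exp(
            -(d_in2 / (2.0 * sigma_r**2) + d_elev**2 / (2.0 * elevation_sigma**2))
        )
        amp[np.abs(along) > h] = 0.0
        np.maximum(out, amp, out=out)
    return out


def simulate_sweep(
    model: WireCrossModel,
    spec: SweepSpec,
    probe: ProbeModel | None = None,
    inject: ErrorInjection | None = None,
    background: float = 5.0,
    wire_echo: float = 200.0,
    noise_sd: float = 2.0,
    elevation_beam_width: float = 1.0,
    pose_rate_hz: float = 40.0,
) -> SimulatedAcquisition:
    """Render a tracked sweep over the wire cross.

    For each frame time the true probe pose follows the linear trajectory;
    the *reported* pose is the true pose perturbed by tracking jitter and
    timestamped with the injected latency.  Frames are rendered by
    sampling the wire echo model at each in-sector pixel's true 3D
    position, with apparent depth scaled by ``sound_speed_scale``.  The
    probe model handed back carries ``true calibration ∘
    calibration_offset`` — the discrepancy that creates navigation error
    downstream.
    """
    probe = probe or default_probe()
    inject = inject or ErrorInjection()
    rng = np.random.default_rng(spec.seed)

    duration = (spec.n_frames - 1) / spec.frame_rate * 1000.0
    frame_ts = np.arange(spec.n_frames) / spec.frame_rate * 1000.0

    mask = sector_mask(probe)
    rows, cols = probe.image_size
    rr, cc = np.mgrid[0:rows, 0:cols]
    pix = np.column_stack([rr[mask], cc[mask]])
    p_img = probe.pixel_to_image_mm(pix)
    # sound-speed: a pixel drawn at apparent depth y displays echoes from
    # true depth y / scale, so echoes land at scale x their true row
    p_query = p_img.copy()
    p_query[:, 1] /= inject.sound_speed_scale
    elev_sigma = max(elevation_beam_width / 2.355, 1e-6)  # FWHM -> sigma

    frames: list[USFrame] = []
    mid_pose = None
    hit_any = False
    for i, t in enumerate(frame_ts):
        alpha = t / duration if duration > 0 else 0.0
        position = (1.0 - alpha) * spec.start_mm + alpha * spec.end_mm
        true_pose = _probe_pose_at(position)
        if i == spec.n_frames // 2:
            mid_pose = true_pose.compose(probe.calibration)
        chain = true_pose.compose(probe.calibration)
        pts_ref = chain.apply(p_query)
        normal = chain.apply_vectors(np.array([0.0, 0.0, 1.0]))
        echo = _wire_intensity(pts_ref, model, normal, wire_echo, elev_sigma)
        hit_any = hit_any or bool(np.any(echo > wire_echo * 0.1))
        img = np.full((rows, cols), 0.0)
        vals = background + echo + rng.normal(0.0, noise_sd, size=len(echo))
        img[mask] = np.clip(vals, 0.0, 255.0)
        frames.append(USFrame(img, float(t)))
    if not hit_any:
        log.warning("simulate_sweep: trajectory never intersected the wires; "
                    "frames contain no echo")

    # tracker pose stream at its own rate, padded past both ends so frame
    # timestamps stay interpolable under latency and temporal offsets
    pad = 100.0
    pose_ts = np.arange(-pad, duration + pad + 1e-9, 1000.0 / pose_rate_hz)
    samples = []
    for t in pose_ts:
        alpha = np.clip(t / duration if duration > 0 else 0.0, 0.0, 1.0)
        position = (1.0 - alpha) * spec.start_mm + alpha * spec.end_mm
        pose = _probe_pose_at(position)
        if inject.tracking_jitter_mm > 0 or inject.tracking_jitter_deg > 0:
            dt = rng.normal(0.0, inject.tracking_jitter_mm, size=3)
            rotvec = rng.normal(
                0.0, np.deg2rad(inject.tracking_jitter_deg), size=3
            )
            jitter = RigidTransform(
                Rotation.from_rotvec(rotvec).as_matrix(), dt, "sensor", "sensor"
            )
            pose = pose.compose(jitter)
        samples.append(TimedPose(float(t + inject.latency_ms), pose))
    stream = PoseStream(samples)

    consumer_probe = replace(
        probe,
        calibration=probe.calibration.compose(
            inject.calibration_offset.relabel("image", "image")
        ),
    )
    return SimulatedAcquisition(
        frames, stream, consumer_probe, model, inject, spec.seed,
        spec.direction_label, mid_pose,
    )


def sweep_spec_for_condition(
    motion: str,
    direction: str,
    model: WireCrossModel,
    half_travel: float = 8.0,
    n_frames: int = 80,
    seed: int = 0,
) -> SweepSpec:
    """Sweep endpoints for one acquisition condition.

    The simulator's probe always translates along the reference y axis
    (its elevation direction).  ``motion`` instead reorients nothing: the
    *cross* is built with its bisector along y for "along" sweeps and
    rotated 45 deg for "diagonal" ones by the caller; here only the travel
    direction sign differs between front_to_back (+y) and back_to_front.
    """
    c = model.cross_point()
    a = np.array([c[0], c[1] - half_travel, 0.0])
    b = np.array([c[0], c[1] + half_travel, 0.0])
    if direction == "back_to_front":
        a, b = b, a
    elif direction != "front_to_back":
        raise ValueError(f"unknown sweep direction {direction!r}")
    return SweepSpec(a, b, n_frames=n_frames,
                     direction_label=(motion, direction), seed=seed)


def cross_for_motion(motion: str, center: Sequence[float] = (0.0, 0.0, -40.0),
                     arm_length: float = 40.0) -> WireCrossModel:
    """Wire cross oriented for the requested motion condition.

    "along": the sweep direction (y) bisects the 90-degree cross, so the
    probe travels along the cross.  "diagonal": the cross is rotated 45
    degrees so the wires run along/perpendicular to the sweep.
    """
    if motion == "along":
        axes = (np.array([0.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0]))
    elif motion == "diagonal":
        s = np.sqrt(0.5)
        axes = (np.array([s, s, 0.0]), np.array([-s, s, 0.0]))
    else:
        raise ValueError(f"unknown motion condition {motion!r}")
    return make_wire_cross(arm_length, 90.0, center, plane_axes=axes)


def batch_acquisitions(
    specs_or_repeats: Sequence[SweepSpec] | int,
    probe: ProbeModel | None = None,
    inject: ErrorInjection | None = None,
    base_seed: int = 0,
    n_frames: int = 80,
) -> list[SimulatedAcquisition]:
    """Run a batch of independent seeded acquisitions.

    Passing an integer ``n`` reproduces the standard accuracy-session
    design — ``n`` repeats of each of the four conditions in
    :data:`DIRECTION_LABELS` (n=3 gives the classic 12-acquisition
    session) — with distinct seeds derived from ``base_seed``.  Passing an
    explicit list of :class:`SweepSpec` runs exactly those sweeps over an
    "along"-oriented cross.
    """
    acqs: list[SimulatedAcquisition] = []
    if isinstance(specs_or_repeats, int):
        k = 0
        for motion, direction in DIRECTION_LABELS:
            model = cross_for_motion(motion)
            for _ in range(specs_or_repeats):
                spec = sweep_spec_for_condition(
                    motion, direction, model, n_frames=n_frames,
                    seed=(base_seed * 131 + k) % (2**31 - 1),
                )
                acqs.append(simulate_sweep(model, spec, probe, inject))
                k += 1
    else:
        model = cross_for_motion("along")
        for spec in specs_or_repeats:
            acqs.append(simulate_sweep(model, spec, probe, inject))
    return acqs
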