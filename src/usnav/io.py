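"""Readers and writers for the toolkit's on-disk formats.

Formats (all plain text except the MetaImage raw payload and the frame
rasters):

* Volumes: MetaImage ``.mhd`` header + little-endian uncompressed ``.raw``
  (``MET_UCHAR`` or ``MET_FLOAT``).
* Pose streams: CSV ``timestamp_ms,qw,qx,qy,qz,tx_mm,ty_mm,tz_mm,status``
  with status OK or MISSING; MISSING rows carry no pose and are skipped
  (counted in the log).  Quaternions are scalar-first and are normalized
  on read; a norm further than 1e-3 from 1 is an error naming the row.
* Landmarks: CSV ``name,x_mm,y_mm,z_mm``.
* Centerlines: CSV ``x_mm,y_mm,z_mm`` with optional ``tx,ty,tz`` tangent
  columns.
* Transforms: 4 lines of 4 whitespace-separated floats (row-major
  homogeneous matrix).
* Tool configuration: minimal XML with a tool name, tracking-system label
  and a 16-number sensor->tip calibration matrix.
* Frame stacks: a directory of PNG/PGM rasters plus ``frames.csv``
  (``filename,timestamp_ms``).
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .errors import FormatError
from .geometry import PoseStream, RigidTransform, TimedPose
from .phantom_sim import ErrorInjection, SimulatedAcquisition, WireCrossModel
from .reconstruction import ProbeModel, USFrame, Volume
from .registration import Centerline, LandmarkSet

__all__ = [
    "ToolConfig",
    "read_metaimage",
    "write_metaimage",
    "read_pose_csv",
    "write_pose_csv",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_centerline_csv",
    "write_centerline_csv",
    "read_transform",
    "write_transform",
    "read_tool_config_xml",
    "write_tool_config_xml",
    "read_probe_xml",
    "write_probe_xml",
    "read_frames",
    "write_frames",
    "read_truth_json",
    "write_truth_json",
]

log = logging.getLogger(__name__)


@dataclass
class ToolConfig:
    """A tracked tool: its name, tracking system, and sensor->tip calibration."""

    name: str
    tracking_system: str
    calibration: RigidTransform
    probe_reference: str | None = None


# -- MetaImage ------------------------------------------------------------

_MHD_DTYPES = {"MET_UCHAR": np.uint8, "MET_FLOAT": np.float32}


def write_metaimage(vol: Volume, path: str | Path) -> None:
    """Write a volume as an uncompressed little-endian MetaImage pair.

    ``.mhd`` text header plus a sibling ``.raw`` payload; element order is
    x fastest.  uint8 volumes map to MET_UCHAR, everything else to
    MET_FLOAT (float32).
    """
    path = Path(path)
    if path.suffix != ".mhd":
        raise ValueError("MetaImage path must end in .mhd")
    raw_path = path.with_suffix(".raw")
    if vol.voxels.dtype == np.uint8 or vol.voxels.dtype == bool:
        data = vol.voxels.astype(np.uint8)
        elem = "MET_UCHAR"
    else:
        data = vol.voxels.astype("<f4")
        elem = "MET_FLOAT"
    dims = vol.shape
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        "CompressedData = False\n"
        f"DimSize = {dims[0]} {dims[1]} {dims[2]}\n"
        f"ElementSpacing = {vol.spacing[0]:.17g} {vol.spacing[1]:.17g} "
        f"{vol.spacing[2]:.17g}\n"
        f"Offset = {vol.origin[0]:.17g} {vol.origin[1]:.17g} {vol.origin[2]:.17g}\n"
        f"ElementType = {elem}\n"
        f"ElementDataFile = {raw_path.name}\n"
    )
    path.write_text(header)
    # shape is (nx, ny, nz); Fortran order writes x fastest, per MetaImage
    raw_path.write_bytes(data.flatten(order="F").tobytes())


def read_metaimage(path: str | Path) -> Volume:
    """Read an uncompressed MetaImage volume (MET_UCHAR or MET_FLOAT)."""
    path = Path(path)
    keys: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if "=" in line:
            k, _, v = line.partition("=")
            keys[k.strip()] = v.strip()
    for required in ("DimSize", "ElementSpacing", "ElementType", "ElementDataFile"):
        if required not in keys:
            raise FormatError(f"{path}: missing MetaImage key {required}")
    if keys.get("NDims", "3") != "3":
        raise FormatError(f"{path}: only NDims = 3 supported")
    if keys.get("CompressedData", "False").lower() == "true":
        raise FormatError(
            f"{path}: compressed MetaImage payloads are not supported; "
            "write uncompressed raw data"
        )
    if keys.get("BinaryDataByteOrderMSB", "False").lower() == "true":
        raise FormatError(f"{path}: big-endian payloads are not supported")
    elem = keys["ElementType"]
    if elem not in _MHD_DTYPES:
        raise FormatError(f"{path}: unsupported ElementType {elem}")
    dims = tuple(int(x) for x in keys["DimSize"].split())
    spacing = np.array([float(x) for x in keys["ElementSpacing"].split()])
    origin = np.array(
        [float(x) for x in keys.get("Offset", "0 0 0").split()]
    )
    raw_path = path.parent / keys["ElementDataFile"]
    raw = raw_path.read_bytes()
    dtype = np.dtype(_MHD_DTYPES[elem]).newbyteorder("<")
    expected = int(np.prod(dims)) * dtype.itemsize
    if len(raw) != expected:
        raise FormatError(
            f"{raw_path}: raw payload is {len(raw)} bytes, header implies {expected}"
        )
    data = np.frombuffer(raw, dtype=dtype).reshape(dims, order="F")
    return Volume(data.copy(), spacing, origin)


# -- pose CSV -------------------------------------------------------------

_POSE_HEADER = "timestamp_ms,qw,qx,qy,qz,tx_mm,ty_mm,tz_mm,status"


def write_pose_csv(stream: PoseStream, path: str | Path) -> None:
    lines = [_POSE_HEADER]
    for s in stream:
        q = s.pose.quaternion_wxyz()
        t = s.pose.translation
        lines.append(
            f"{s.timestamp:.17g},{q[0]:.17g},{q[1]:.17g},{q[2]:.17g},{q[3]:.17g},"
            f"{t[0]:.17g},{t[1]:.17g},{t[2]:.17g},OK"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_pose_csv(
    path: str | Path, from_frame: str = "sensor", to_frame: str = "tracker"
) -> PoseStream:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != _POSE_HEADER:
        raise FormatError(f"{path}: expected header {_POSE_HEADER!r}")
    samples = []
    missing = 0
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 9:
            raise FormatError(f"{path}:{ln}: expected 9 fields, got {len(parts)}")
        status = parts[8].upper()
        if status == "MISSING":
            missing += 1
            continue
        if status != "OK":
            raise FormatError(f"{path}:{ln}: unknown status {parts[8]!r}")
        try:
            nums = [float(p) for p in parts[:8]]
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: {exc}") from None
        q = np.array(nums[1:5])
        norm = np.linalg.norm(q)
        if abs(norm - 1.0) > 1e-3:
            raise FormatError(
                f"{path}:{ln}: quaternion norm {norm:.6f} differs from 1 by "
                "more than 1e-3"
            )
        pose = RigidTransform.from_quaternion(
            q / norm, nums[5:8], from_frame, to_frame
        )
        samples.append(TimedPose(nums[0], pose))
    if missing:
        log.info("read_pose_csv: skipped %d MISSING rows in %s", missing, path)
    return PoseStream(samples)


# -- landmarks / centerlines ---------------------------------------------


def write_landmarks_csv(landmarks: LandmarkSet, path: str | Path) -> None:
    lines = ["name,x_mm,y_mm,z_mm"]
    for name, p in landmarks.landmarks.items():
        lines.append(f"{name},{p[0]:.17g},{p[1]:.17g},{p[2]:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_landmarks_csv(path: str | Path, frame: str = "") -> LandmarkSet:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "name,x_mm,y_mm,z_mm":
        raise FormatError(f"{path}: expected header 'name,x_mm,y_mm,z_mm'")
    marks: dict[str, np.ndarray] = {}
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 4:
            raise FormatError(f"{path}:{ln}: expected 4 fields")
        name = parts[0]
        if name in marks:
            raise FormatError(f"{path}:{ln}: duplicate landmark name {name!r}")
        try:
            marks[name] = np.array([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: {exc}") from None
    return LandmarkSet(marks, frame)


def write_centerline_csv(centerline: Centerline, path: str | Path) -> None:
    has_t = centerline.tangents is not None
    lines = ["x_mm,y_mm,z_mm" + (",tx,ty,tz" if has_t else "")]
    for i, p in enumerate(centerline.points):
        row = f"{p[0]:.17g},{p[1]:.17g},{p[2]:.17g}"
        if has_t:
            t = centerline.tangents[i]
            row += f",{t[0]:.17g},{t[1]:.17g},{t[2]:.17g}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def read_centerline_csv(path: str | Path) -> Centerline:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("x_mm,y_mm,z_mm"):
        raise FormatError(f"{path}: expected header starting 'x_mm,y_mm,z_mm'")
    has_t = "tx" in lines[0]
    pts, tgs = [], []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            nums = [float(x) for x in line.split(",")]
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: {exc}") from None
        if len(nums) != (6 if has_t else 3):
            raise FormatError(f"{path}:{ln}: wrong field count")
        pts.append(nums[:3])
        if has_t:
            tgs.append(nums[3:])
    return Centerline(np.array(pts), np.array(tgs) if has_t else None)


# -- transforms -----------------------------------------------------------


def write_transform(t: RigidTransform, path: str | Path) -> None:
    """Write a 4x4 row-major homogeneous matrix, 4 floats per line."""
    m = t.matrix
    Path(path).write_text(
        "\n".join(" ".join(f"{v:.17g}" for v in row) for row in m) + "\n"
    )


def read_transform(
    path: str | Path, from_frame: str = "", to_frame: str = ""
) -> RigidTransform:
    path = Path(path)
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            rows.append([float(x) for x in line.split()])
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: {exc}") from None
    m = np.array(rows)
    if m.shape != (4, 4):
        raise FormatError(f"{path}: expected 4x4 matrix, got shape {m.shape}")
    try:
        return RigidTransform.from_matrix(m, from_frame, to_frame)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


# -- tool / probe XML -----------------------------------------------------


def write_tool_config_xml(tool: ToolConfig, path: str | Path) -> None:
    root = ET.Element("tool", name=tool.name)
    ET.SubElement(root, "tracking", system=tool.tracking_system)
    cal = ET.SubElement(root, "calibration")
    cal.text = " ".join(f"{v:.17g}" for v in tool.calibration.matrix.ravel())
    if tool.probe_reference:
        ET.SubElement(root, "probe", reference=tool.probe_reference)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def read_tool_config_xml(path: str | Path) -> ToolConfig:
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"{path}: malformed XML: {exc}") from None
    if root.tag != "tool" or "name" not in root.attrib:
        raise FormatError(f"{path}: root must be <tool name=...>")
    tracking = root.find("tracking")
    system = tracking.get("system", "") if tracking is not None else ""
    cal = root.find("calibration")
    if cal is None or not (cal.text or "").strip():
        raise FormatError(f"{path}: missing <calibration> matrix")
    nums = [float(x) for x in cal.text.split()]
    if len(nums) != 16:
        raise FormatError(
            f"{path}: calibration must have 16 numbers, got {len(nums)}"
        )
    try:
        t = RigidTransform.from_matrix(
            np.array(nums).reshape(4, 4), "sensor", "tip"
        )
    except ValueError as exc:
        raise FormatError(f"{path}: non-rigid calibration matrix: {exc}") from None
    probe = root.find("probe")
    ref = probe.get("reference") if probe is not None else None
    return ToolConfig(root.get("name"), system, t, ref)


def write_probe_xml(probe: ProbeModel, path: str | Path) -> None:
    root = ET.Element("probe", kind=probe.geometry_kind)
    ET.SubElement(
        root, "geometry",
        width=f"{probe.width:.17g}",
        depth_start=f"{probe.depth_start:.17g}",
        depth_end=f"{probe.depth_end:.17g}",
    )
    ET.SubElement(
        root, "raster",
        rows=str(probe.image_size[0]), cols=str(probe.image_size[1]),
        row_spacing=f"{probe.pixel_spacing[0]:.17g}",
        col_spacing=f"{probe.pixel_spacing[1]:.17g}",
        origin_row=f"{probe.origin_px[0]:.17g}",
        origin_col=f"{probe.origin_px[1]:.17g}",
    )
    cal = ET.SubElement(root, "calibration")
    cal.text = " ".join(f"{v:.17g}" for v in probe.calibration.matrix.ravel())
    ET.SubElement(root, "temporal", offset_ms=f"{probe.temporal_offset:.17g}")
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def read_probe_xml(path: str | Path) -> ProbeModel:
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"{path}: malformed XML: {exc}") from None
    if root.tag != "probe":
        raise FormatError(f"{path}: root must be <probe>")
    geo = root.find("geometry")
    ras = root.find("raster")
    cal = root.find("calibration")
    tmp = root.find("temporal")
    if geo is None or ras is None or cal is None:
        raise FormatError(f"{path}: probe XML needs geometry, raster, calibration")
    nums = [float(x) for x in (cal.text or "").split()]
    if len(nums) != 16:
        raise FormatError(f"{path}: calibration must have 16 numbers")
    try:
        calibration = RigidTransform.from_matrix(
            np.array(nums).reshape(4, 4), "image", "sensor"
        )
    except ValueError as exc:
        raise FormatError(f"{path}: non-rigid calibration: {exc}") from None
    return ProbeModel(
        geometry_kind=root.get("kind", "linear"),
        width=float(geo.get("width")),
        depth_start=float(geo.get("depth_start")),
        depth_end=float(geo.get("depth_end")),
        pixel_spacing=(float(ras.get("row_spacing")), float(ras.get("col_spacing"))),
        image_size=(int(ras.get("rows")), int(ras.get("cols"))),
        origin_px=(float(ras.get("origin_row")), float(ras.get("origin_col"))),
        calibration=calibration,
        temporal_offset=float(tmp.get("offset_ms")) if tmp is not None else 0.0,
    )


# -- frame stacks ---------------------------------------------------------


def write_frames(frames: Sequence[USFrame], directory: str | Path) -> None:
    """Write frames as PNG rasters plus frames.csv (filename, timestamp)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ["filename,timestamp_ms"]
    for i, fr in enumerate(frames):
        name = f"frame_{i:05d}.png"
        iio.imwrite(directory / name,
                    np.clip(fr.pixels, 0, 255).astype(np.uint8))
        lines.append(f"{name},{fr.timestamp:.17g}")
    (directory / "frames.csv").write_text("\n".join(lines) + "\n")


def read_frames(directory: str | Path) -> list[USFrame]:
    directory = Path(directory)
    index = directory / "frames.csv"
    lines = index.read_text().splitlines()
    if not lines or lines[0].strip() != "filename,timestamp_ms":
        raise FormatError(f"{index}: expected header 'filename,timestamp_ms'")
    frames = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        name, _, ts = line.partition(",")
        try:
            frames.append(
                USFrame(iio.imread(directory / name.strip()).astype(float),
                        float(ts))
            )
        except (ValueError, OSError) as exc:
            raise FormatError(f"{index}:{ln}: {exc}") from None
    return frames


# -- truth JSON (simulator output) ----------------------------------------


def write_truth_json(acq: SimulatedAcquisition, path: str | Path) -> None:
    """Persist a simulated acquisition's ground truth for evaluation."""
    model = acq.truth_model
    inj = acq.truth_injection
    doc = {
        "seed": acq.seed,
        "direction_label": list(acq.direction_label),
        "wire_cross": {
            "wire_diameter_mm": model.wire_diameter,
            "wires": [
                {"center_mm": list(map(float, c)),
                 "direction": list(map(float, d)),
                 "half_length_mm": h}
                for c, d, h in model.wires
            ],
        },
        "injection": {
            "calibration_offset_matrix": acq.truth_injection
            .calibration_offset.matrix.tolist(),
            "tracking_jitter_mm": inj.tracking_jitter_mm,
            "tracking_jitter_deg": inj.tracking_jitter_deg,
            "sound_speed_scale": inj.sound_speed_scale,
            "latency_ms": inj.latency_ms,
        },
        "mid_sweep_pose_matrix": (
            acq.mid_sweep_pose.matrix.tolist()
            if acq.mid_sweep_pose is not None else None
        ),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_truth_json(path: str | Path) -> dict:
    """Load simulator truth; reconstructs the wire-cross model and poses."""
    doc = json.loads(Path(path).read_text())
    wires = tuple(
        (np.array(w["center_mm"]), np.array(w["direction"]), w["half_length_mm"])
        for w in doc["wire_cross"]["wires"]
    )
    doc["wire_cross_model"] = WireCrossModel(
        wires, doc["wire_cross"]["wire_diameter_mm"]
    )
    doc["injection_obj"] = ErrorInjection(
        calibration_offset=RigidTransform.from_matrix(
            np.array(doc["injection"]["calibration_offset_matrix"]),
            "image", "image",
        ),
        tracking_jitter_mm=doc["injection"]["tracking_jitter_mm"],
        tracking_jitter_deg=doc["injection"]["tracking_jitter_deg"],
        sound_speed_scale=doc["injection"]["sound_speed_scale"],
        latency_ms=doc["injection"]["latency_ms"],
    )
    if doc.get("mid_sweep_pose_matrix"):
        doc["mid_sweep_pose"] = RigidTransform.from_matrix(
            np.array(doc["mid_sweep_pose_matrix"]), "image", "reference"
        )
    return doc
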