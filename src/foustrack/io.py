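"""File formats: HDF5 FOUS records, YAML configs, CSV tables, PNG images.

The HDF5 layout mirrors the acquisition structure: one group per frame
under ``/frames/<k>`` holding the ``lines`` dataset (scanline x sample),
with triggers as frame attributes and probe/medium/pose/seed metadata as
root attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .fiber import FiberSpec, FiberType, ITFModel
from .probe import MediumSpec, ProbeKind, ProbeModel, SensorPose
from .synth import FOUSRecord, Frame, NoiseSpec, PulseSpec

__all__ = [
    "save_record",
    "load_record",
    "load_config",
    "build_probe",
    "build_medium",
    "build_sensor",
    "build_fiber",
    "build_pulse",
    "build_noise",
    "save_image_png",
]


def save_record(path: str | Path, record: FOUSRecord) -> None:
    """Write a :class:`FOUSRecord` to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = record.sample_rate
        f.attrs["probe"] = json.dumps({
            "kind": record.probe.kind.value,
            "n_elements": record.probe.n_elements,
            "pitch_m": record.probe.pitch,
            "f0_hz": record.probe.center_frequency,
            "fractional_bandwidth": record.probe.fractional_bandwidth,
            "fov_deg": record.probe.fov_angle,
            "focus_m": record.probe.focus_depth,
            "n_lines": record.probe.n_scanlines,
            "tx_aperture": record.probe.tx_aperture,
        })
        f.attrs["medium"] = json.dumps({
            "speed_of_sound": record.medium.speed_of_sound,
            "attenuation_db_cm_mhz": record.medium.attenuation_coeff,
        })
        f.attrs["pose"] = json.dumps({
            "x_m": record.sensor.position[0],
            "z_m": record.sensor.position[1],
            "orientation_deg": record.sensor.orientation,
        })
        f.attrs["metadata"] = json.dumps(record.metadata, default=str)
        grp = f.create_group("frames")
        for k, frame in enumerate(record.frames):
            g = grp.create_group(str(k))
            g.create_dataset("lines", data=frame.data)
            g.attrs["frame_trigger_index"] = frame.frame_trigger_index
            g.attrs["line_trigger_indices"] = frame.line_trigger_indices


def load_record(path: str | Path) -> FOUSRecord:
    """Read a :class:`FOUSRecord` back from HDF5."""
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["fs"])
        probe = build_probe(json.loads(f.attrs["probe"]))
        medium = build_medium(json.loads(f.attrs["medium"]))
        sensor = build_sensor(json.loads(f.attrs["pose"]))
        metadata = json.loads(f.attrs["metadata"])
        frames = []
        for k in sorted(f["frames"], key=int):
            g = f["frames"][k]
            frames.append(Frame(
                data=g["lines"][()],
                sample_rate=fs,
                frame_trigger_index=int(g.attrs["frame_trigger_index"]),
                line_trigger_indices=np.asarray(g.attrs["line_trigger_indices"]),
            ))
    return FOUSRecord(frames=frames, probe=probe, medium=medium, sensor=sensor, metadata=metadata)


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def build_probe(cfg: dict) -> ProbeModel:
    """Probe from config keys kind, n_elements, pitch_m, f0_hz, fov_deg, focus_m, n_lines."""
    return ProbeModel(
        kind=ProbeKind(cfg["kind"]),
        n_elements=int(cfg["n_elements"]),
        pitch=float(cfg["pitch_m"]),
        center_frequency=float(cfg["f0_hz"]),
        fractional_bandwidth=float(cfg.get("fractional_bandwidth", 0.6)),
        fov_angle=None if cfg.get("fov_deg") is None else float(cfg["fov_deg"]),
        focus_depth=float(cfg.get("focus_m", 0.055)),
        n_scanlines=None if cfg.get("n_lines") is None else int(cfg["n_lines"]),
        tx_aperture=None if cfg.get("tx_aperture") is None else int(cfg["tx_aperture"]),
    )


def build_medium(cfg: dict) -> MediumSpec:
    return MediumSpec(
        speed_of_sound=float(cfg.get("speed_of_sound", 1500.0)),
        attenuation_coeff=float(cfg.get("attenuation_db_cm_mhz", 0.0)),
    )


def build_sensor(cfg: dict) -> SensorPose:
    return SensorPose(
        position=(float(cfg["x_m"]), float(cfg["z_m"])),
        orientation=float(cfg.get("orientation_deg", 0.0)),
    )


def build_fiber(cfg: dict | None) -> FiberSpec | None:
    if cfg is None:
        return None
    bends = tuple((float(b["radius_m"]), float(b["turns"])) for b in cfg.get("bends", []))
    return FiberSpec(FiberType(cfg.get("type", "bend_insensitive")), bends)


def build_pulse(cfg: dict | None) -> PulseSpec | None:
    if cfg is None:
        return None
    return PulseSpec(
        center_frequency=float(cfg.get("f0_hz", 3.5e6)),
        fractional_bandwidth=float(cfg.get("fractional_bandwidth", 0.6)),
        amplitude=float(cfg.get("amplitude", 1.0)),
    )


def build_noise(cfg: dict | None) -> NoiseSpec:
    if cfg is None:
        return NoiseSpec()
    return NoiseSpec(noise_std=float(cfg.get("std", 0.0)), seed=cfg.get("seed"))


def save_image_png(path: str | Path, pixels: np.ndarray, pixel_size: tuple[float, float],
                   origin: tuple[float, float] = (0.0, 0.0)) -> None:
    """8-bit PNG of a non-negative image plus a JSON sidecar with geometry.

    ``pixel_size`` is (row spacing, column spacing) in meters (column
    spacing may be a beam index step for pre-scan-conversion images);
    ``origin`` is the physical position of pixel (0, 0).
    """
    from PIL import Image

    path = Path(path)
    arr = np.asarray(pixels, float)
    top = arr.max()
    scaled = np.zeros_like(arr, dtype=np.uint8) if top <= 0 else np.clip(arr / top * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(scaled, mode="L").save(path)
    sidecar = {
        "pixel_size": list(pixel_size),
        "origin": list(origin),
        "shape": list(arr.shape),
        "intensity_max": float(top),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
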