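"""Imaging-probe geometry, transmit events, and one-way propagation.

The tracking modality is *receive-mode*: the imaging array transmits its
ordinary focused scanlines and a point-like fiber sensor in the field
receives them.  Time-of-flight from the line trigger to reception maps to
a one-way distance (no pulse-echo factor of two).

Coordinate frame: origin at the aperture center on the probe face,
x lateral, z depth (increasing away from the face); beam angles measured
from +z.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ProbeKind",
    "ProbeModel",
    "TransmitEvent",
    "MediumSpec",
    "SensorPose",
    "GridSpec",
    "CartesianImage",
    "make_probe",
    "element_positions",
    "enumerate_events",
    "beam_table",
    "arrival_times",
    "tof_to_depth",
    "depth_to_tof",
    "scan_convert_sector",
    "WATER",
]


class ProbeKind(str, enum.Enum):
    LINEAR = "linear"
    PHASED_SECTOR = "phased_sector"


@dataclass(frozen=True)
class MediumSpec:
    """Acoustic propagation medium."""

    speed_of_sound: float = 1500.0  # m/s; deionized-water phantom
    attenuation_coeff: float = 0.0  # dB/(cm*MHz)

    def __post_init__(self) -> None:
        if self.speed_of_sound <= 0:
            raise ValueError("speed_of_sound must be positive")
        if self.attenuation_coeff < 0:
            raise ValueError("attenuation_coeff must be non-negative")


WATER = MediumSpec()


@dataclass(frozen=True)
class ProbeModel:
    """Transducer array geometry and scan parameters.

    ``tx_aperture`` is the number of elements driven per scanline: the whole
    array for a phased sector probe, a sliding sub-aperture for a linear
    probe (keeping the focal-delay geometry bias at depth small compared
    with one axial sample).
    """

    kind: ProbeKind
    n_elements: int
    pitch: float
    center_frequency: float
    fractional_bandwidth: float = 0.6
    fov_angle: float | None = None
    focus_depth: float = 0.055
    n_scanlines: int | None = None
    tx_aperture: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ProbeKind(self.kind))
        if self.n_elements < 1:
            raise ValueError(f"n_elements must be >= 1, got {self.n_elements}")
        if self.pitch <= 0:
            raise ValueError(f"pitch must be positive, got {self.pitch}")
        if self.center_frequency <= 0:
            raise ValueError(f"center_frequency must be positive, got {self.center_frequency}")
        if self.focus_depth <= 0:
            raise ValueError(f"focus_depth must be positive, got {self.focus_depth}")
        if self.kind is ProbeKind.PHASED_SECTOR:
            if self.fov_angle is None:
                raise ValueError("fov_angle is required for a phased_sector probe")
            if not 0.0 < self.fov_angle <= 180.0:
                raise ValueError(f"fov_angle must lie in (0, 180], got {self.fov_angle}")
        if self.n_scanlines is None:
            if self.kind is ProbeKind.LINEAR:
                object.__setattr__(self, "n_scanlines", self.n_elements)
            else:
                object.__setattr__(self, "n_scanlines", int(round(self.fov_angle)) + 1)
        if self.n_scanlines < 1:
            raise ValueError(f"n_scanlines must be >= 1, got {self.n_scanlines}")
        if self.tx_aperture is None:
            default = self.n_elements if self.kind is ProbeKind.PHASED_SECTOR else min(16, self.n_elements)
            object.__setattr__(self, "tx_aperture", default)
        if not 1 <= self.tx_aperture <= self.n_elements:
            raise ValueError("tx_aperture must lie in [1, n_elements]")

    @property
    def aperture_width(self) -> float:
        """Span of element centers, (n_elements - 1) * pitch, meters."""
        return (self.n_elements - 1) * self.pitch


def make_probe(
    kind: str | ProbeKind,
    n_elements: int,
    pitch: float,
    center_frequency: float,
    fov_angle: float | None = None,
    focus_depth: float = 0.055,
    n_scanlines: int | None = None,
    fractional_bandwidth: float = 0.6,
    tx_aperture: int | None = None,
) -> ProbeModel:
    """Build a validated :class:`ProbeModel`.

    Element centers span ``(n_elements - 1) * pitch`` symmetric about x=0
    on the probe face (z=0).
    """
    return ProbeModel(
        kind=ProbeKind(kind),
        n_elements=n_elements,
        pitch=pitch,
        center_frequency=center_frequency,
        fov_angle=fov_angle,
        focus_depth=focus_depth,
        n_scanlines=n_scanlines,
        fractional_bandwidth=fractional_bandwidth,
        tx_aperture=tx_aperture,
    )


def element_positions(probe: ProbeModel) -> np.ndarray:
    """(n_elements, 2) array of element (x, z) centers, symmetric about x=0."""
    x = (np.arange(probe.n_elements) - (probe.n_elements - 1) / 2.0) * probe.pitch
    return np.column_stack([x, np.zeros_like(x)])


@dataclass(frozen=True)
class SensorPose:
    """Position of the fiber sensor in the probe frame.

    ``orientation`` is the angle (degrees) of the fiber axis with respect
    to the +z axis in the imaging plane; it sets the incidence angle of
    arriving wavefronts on the sensor.
    """

    position: tuple[float, float]
    orientation: float = 0.0
    in_plane: bool = True

    def __post_init__(self) -> None:
        if self.position[1] < 0:
            raise ValueError("sensor depth z must be >= 0 (z increases away from the probe face)")


@dataclass(frozen=True)
class TransmitEvent:
    """One focused transmit (one scanline / A-line).

    ``element_delays`` implement transmit focusing at the probe's focus
    depth along the beam direction; the minimum delay is zero, so t=0 (the
    line trigger) is the instant the earliest element fires.
    """

    line_index: int
    origin: tuple[float, float]
    direction: tuple[float, float]
    element_positions: np.ndarray
    element_delays: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        if not math.isclose(float(np.hypot(*d)), 1.0, rel_tol=1e-9):
            raise ValueError("direction must be a unit vector")
        if np.any(self.element_delays < -1e-15) or abs(float(self.element_delays.min())) > 1e-15:
            raise ValueError("delays must be >= 0 with minimum delay 0")


def _focus_delays(elements: np.ndarray, focus_point: np.ndarray, c: float) -> np.ndarray:
    """Delays aligning all element wavefronts at the focus; min delay 0."""
    d = np.hypot(elements[:, 0] - focus_point[0], elements[:, 1] - focus_point[1])
    return (d.max() - d) / c


def enumerate_events(probe: ProbeModel, medium: MediumSpec = WATER) -> list[TransmitEvent]:
    """Enumerate the probe's scanlines as focused transmit events.

    Sector probe: all beams pivot at the aperture center, at angles evenly
    spaced over ``fov_angle`` (a single scanline fires at boresight).
    Linear probe: beams parallel to +z, origins at per-line sub-aperture
    centers stepping across the array; each line drives the ``tx_aperture``
    elements nearest its origin (clipped at the array edges).

    The medium's speed of sound enters only through the focusing delays;
    the default matches the 1500 m/s phantom medium.
    """
    elems = element_positions(probe)
    c = medium.speed_of_sound
    events: list[TransmitEvent] = []
    if probe.kind is ProbeKind.PHASED_SECTOR:
        half = probe.fov_angle / 2.0
        if probe.n_scanlines == 1:
            angles = np.array([0.0])
        else:
            angles = np.linspace(-half, half, probe.n_scanlines)
        for j, ang in enumerate(angles):
            th = math.radians(ang)
            direction = (math.sin(th), math.cos(th))
            focus = np.array(direction) * probe.focus_depth
            events.append(
                TransmitEvent(j, (0.0, 0.0), direction, elems, _focus_delays(elems, focus, c))
            )
    else:
        # Line origins sweep the element span; with one line per element the
        # origins coincide with the element centers.
        if probe.n_scanlines == 1:
            origins_x = np.array([0.0])
        else:
            half_span = probe.aperture_width / 2.0
            origins_x = np.linspace(-half_span, half_span, probe.n_scanlines)
        half_ap = probe.tx_aperture * probe.pitch / 2.0
        for j, x0 in enumerate(origins_x):
            mask = np.abs(elems[:, 0] - x0) <= half_ap + 1e-12
            sub = elems[mask]
            focus = np.array([x0, probe.focus_depth])
            events.append(
                TransmitEvent(j, (float(x0), 0.0), (0.0, 1.0), sub, _focus_delays(sub, focus, c))
            )
    return events


def beam_table(probe: ProbeModel) -> np.ndarray:
    """Per-scanline beam parameter: angle (deg) for sector, lateral origin x (m) for linear."""
    if probe.kind is ProbeKind.PHASED_SECTOR:
        half = probe.fov_angle / 2.0
        if probe.n_scanlines == 1:
            return np.array([0.0])
        return np.linspace(-half, half, probe.n_scanlines)
    if probe.n_scanlines == 1:
        return np.array([0.0])
    half_span = probe.aperture_width / 2.0
    return np.linspace(-half_span, half_span, probe.n_scanlines)


def arrival_times(event: TransmitEvent, sensor: SensorPose, medium: MediumSpec) -> np.ndarray:
    """Per-element one-way arrival times at the sensor, seconds.

    t_i = delay_i + |element_i - sensor| / c, measured from the line
    trigger.  The minimum over elements is the first arrival; for a sensor
    on the beam axis at the focus all t_i coincide (focusing coherence).
    """
    if medium.speed_of_sound <= 0:
        raise ValueError("speed_of_sound must be positive")
    px, pz = sensor.position
    d = np.hypot(event.element_positions[:, 0] - px, event.element_positions[:, 1] - pz)
    return event.element_delays + d / medium.speed_of_sound


def tof_to_depth(t: np.ndarray | float, medium: MediumSpec) -> np.ndarray | float:
    """One-way time-of-flight to distance, d = c*t.

    The sensor is a receiver, not a reflector, so the path is one-way and
    the pulse-echo factor of one half does not apply.
    """
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("time of flight must be non-negative")
    out = medium.speed_of_sound * t
    return float(out) if out.ndim == 0 else out


def depth_to_tof(d: np.ndarray | float, medium: MediumSpec) -> np.ndarray | float:
    """Inverse of :func:`tof_to_depth`: t = d/c."""
    d = np.asarray(d, float)
    if np.any(d < 0):
        raise ValueError("depth must be non-negative")
    out = d / medium.speed_of_sound
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GridSpec:
    """Cartesian output grid for scan conversion: extent (m) and pixel size (m)."""

    x_min: float
    x_max: float
    z_min: float
    z_max: float
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.x_max <= self.x_min or self.z_max <= self.z_min:
            raise ValueError("grid extent must be non-empty")

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.x_min, self.x_max, self.pixel_size)

    @property
    def z(self) -> np.ndarray:
        return np.arange(self.z_min, self.z_max, self.pixel_size)


@dataclass(frozen=True)
class CartesianImage:
    """Scan-converted image with its physical grid and in-sector mask."""

    pixels: np.ndarray  # (n_z, n_x)
    grid: GridSpec
    mask: np.ndarray  # True where the pixel lies inside the sector


def scan_convert_sector(
    polar_image: np.ndarray,
    probe: ProbeModel,
    grid_spec: GridSpec,
    axial_spacing: float,
    method: str = "bilinear",
) -> CartesianImage:
    """Map a (range sample x beam) sector image onto a cartesian grid.

    Each output pixel (x, z) samples the polar image at r = hypot(x, z),
    theta = atan2(x, z) with bilinear interpolation (nearest-neighbour via
    ``method="nearest"``); pixels outside the imaged sector are zero and
    flagged False in the mask.
    """
    if probe.kind is not ProbeKind.PHASED_SECTOR or probe.fov_angle is None:
        raise ValueError("scan conversion requires a phased_sector probe with fov_angle")
    if polar_image.ndim != 2:
        raise ValueError("polar_image must be 2D (range sample, beam index)")
    if axial_spacing <= 0:
        raise ValueError("axial_spacing must be positive")
    n_r, n_beams = polar_image.shape
    angles = beam_table(probe)
    if n_beams != angles.size:
        raise ValueError(
            f"polar_image has {n_beams} beams but the probe defines {angles.size} scanlines"
        )
    x, z = np.meshgrid(grid_spec.x, grid_spec.z)
    r = np.hypot(x, z)
    theta = np.degrees(np.arctan2(x, z))
    half = probe.fov_angle / 2.0
    mask = (theta >= angles[0]) & (theta <= angles[-1]) & (r <= (n_r - 1) * axial_spacing)
    mask &= np.abs(theta) <= half
    r_idx = r / axial_spacing
    dth = angles[1] - angles[0] if n_beams > 1 else 1.0
    th_idx = (theta - angles[0]) / dth
    order = {"bilinear": 1, "nearest": 0}[method]
    out = ndimage.map_coordinates(
        polar_image.astype(float), [r_idx, th_idx], order=order, mode="constant", cval=0.0
    )
    out[~mask] = 0.0
    return CartesianImage(pixels=out, grid=grid_spec, mask=mask)
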