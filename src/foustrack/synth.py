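"""Synthetic FOUS data: tracking frames, bench pulse traces, ITF scans.

The generator emulates the study conditions end to end: a phased-sector or
linear imaging array fires focused scanlines into a 1500 m/s water medium;
a point fiber sensor at depth receives each transmit as a superposition of
per-element Gaussian-enveloped pulses delayed by one-way time of flight,
scaled by Fabry-Pérot sensitivity after macrobend loss, sensor directivity
and 1/r spreading; i.i.d. Gaussian detector noise is added on top.  All
randomness flows from a single master seed through deterministic
substreams, so any record is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fiber import (
    BendLossModel,
    DirectivityModel,
    FiberSpec,
    ITFModel,
    directivity_gain,
    roundtrip_transmission,
    sensor_sensitivity,
)
from .probe import (
    MediumSpec,
    ProbeModel,
    SensorPose,
    TransmitEvent,
    WATER,
    arrival_times,
    enumerate_events,
)

__all__ = [
    "PulseSpec",
    "NoiseSpec",
    "Frame",
    "FOUSRecord",
    "pulse_waveform",
    "generate_frame",
    "generate_sequence",
    "generate_static_bend_experiment",
    "generate_itf_scan",
    "ITF_SCAN_RADII_MM",
]

#: Bend radii of the wavelength-scan protocol, mm (12.5 mm down to 2.5 mm).
ITF_SCAN_RADII_MM = (12.5, 10.0, 7.5, 5.0, 2.5)


@dataclass(frozen=True)
class PulseSpec:
    """Transmitted acoustic pulse: Gaussian-enveloped sinusoid.

    ``fractional_bandwidth`` is the -6 dB (FWHM) bandwidth divided by the
    center frequency.
    """

    center_frequency: float = 3.5e6
    fractional_bandwidth: float = 0.6
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not 0.0 < self.fractional_bandwidth < 2.0:
            raise ValueError("fractional_bandwidth must lie in (0, 2)")
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be positive")

    @property
    def envelope_sigma(self) -> float:
        """Temporal std of the Gaussian envelope, seconds."""
        sigma_f = self.fractional_bandwidth * self.center_frequency / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        return 1.0 / (2.0 * math.pi * sigma_f)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive zero-mean Gaussian detector noise."""

    noise_std: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")


def pulse_waveform(t: np.ndarray, pulse: PulseSpec) -> np.ndarray:
    """Pulse amplitude at times ``t`` (seconds, centered at 0)."""
    sig = pulse.envelope_sigma
    return pulse.amplitude * np.exp(-0.5 * (t / sig) ** 2) * np.cos(2.0 * np.pi * pulse.center_frequency * t)


@dataclass
class Frame:
    """One imaging frame of sensor data: one time series per scanline.

    Each series starts at its line trigger; trigger indices are positions
    in the concatenated per-frame sample stream and are strictly
    increasing.
    """

    data: np.ndarray  # (n_scanlines, n_samples)
    sample_rate: float
    frame_trigger_index: int
    line_trigger_indices: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("frame data must be 2D (scanline, sample)")
        if np.any(np.diff(self.line_trigger_indices) <= 0):
            raise ValueError("line trigger indices must be strictly increasing")


@dataclass
class FOUSRecord:
    """Multi-frame sensor recording with trigger bookkeeping and provenance."""

    frames: list[Frame]
    probe: ProbeModel
    medium: MediumSpec
    sensor: SensorPose
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def sample_rate(self) -> float:
        return self.frames[0].sample_rate


def _sensor_gain(
    sensor: SensorPose,
    fiber: FiberSpec | None,
    itf: ITFModel | None,
    loss_model: BendLossModel | None,
    directivity: DirectivityModel | None,
) -> float:
    """Relative sensor amplitude: bend transmission x directivity at the pose."""
    transmission = 1.0
    if fiber is not None:
        model = loss_model if loss_model is not None else BendLossModel.calibrated()
        transmission = roundtrip_transmission(model, fiber)
    gain = sensor_sensitivity(itf, transmission) if itf is not None else transmission
    if directivity is not None:
        arrival_deg = math.degrees(math.atan2(sensor.position[0], sensor.position[1]))
        incidence = ((arrival_deg - sensor.orientation) + 180.0) % 360.0 - 180.0
        gain *= directivity_gain(directivity, incidence)
    return gain


def _clean_line(
    event: TransmitEvent,
    sensor: SensorPose,
    medium: MediumSpec,
    pulse: PulseSpec,
    t_grid: np.ndarray,
    gain: float,
) -> np.ndarray:
    t_arr = arrival_times(event, sensor, medium)
    px, pz = sensor.position
    dist = np.hypot(event.element_positions[:, 0] - px, event.element_positions[:, 1] - pz)
    dist = np.maximum(dist, 1e-6)  # guard a sensor exactly on an element
    amp = gain / dist
    if medium.attenuation_coeff > 0:
        att_db = medium.attenuation_coeff * (dist * 100.0) * (pulse.center_frequency / 1e6)
        amp = amp * 10.0 ** (-att_db / 20.0)
    # (n_elements, n_samples) pulse superposition
    return np.einsum("e,es->s", amp, pulse_waveform(t_grid[None, :] - t_arr[:, None], pulse))


def clean_frame(
    probe: ProbeModel,
    sensor: SensorPose,
    medium: MediumSpec = WATER,
    pulse: PulseSpec | None = None,
    *,
    fiber: FiberSpec | None = None,
    itf: ITFModel | None = None,
    loss_model: BendLossModel | None = None,
    directivity: DirectivityModel | None = None,
    sample_rate: float = 40e6,
    max_depth: float = 0.075,
) -> np.ndarray:
    """Noiseless (n_scanlines, n_samples) sensor data for one frame.

    The record length covers 1.3x the maximum imaged depth so late arrivals
    from steered beams are not clipped.
    """
    if sensor.position[1] < 0:
        raise ValueError("sensor must be in front of the probe face (z >= 0)")
    if pulse is None:
        pulse = PulseSpec(center_frequency=probe.center_frequency,
                          fractional_bandwidth=probe.fractional_bandwidth)
    n_samples = int(math.ceil(1.3 * max_depth / medium.speed_of_sound * sample_rate))
    t_grid = np.arange(n_samples) / sample_rate
    gain = _sensor_gain(sensor, fiber, itf, loss_model, directivity)
    events = enumerate_events(probe, medium)
    data = np.empty((len(events), n_samples))
    for ev in events:
        data[ev.line_index] = _clean_line(ev, sensor, medium, pulse, t_grid, gain)
    return data


def _frame_from_data(data: np.ndarray, sample_rate: float, frame_index: int) -> Frame:
    n_lines, n_samples = data.shape
    offset = frame_index * n_lines * n_samples
    return Frame(
        data=data,
        sample_rate=sample_rate,
        frame_trigger_index=offset,
        line_trigger_indices=offset + np.arange(n_lines) * n_samples,
    )


def generate_frame(
    probe: ProbeModel,
    sensor: SensorPose,
    medium: MediumSpec = WATER,
    pulse: PulseSpec | None = None,
    noise: NoiseSpec | None = None,
    *,
    fiber: FiberSpec | None = None,
    itf: ITFModel | None = None,
    loss_model: BendLossModel | None = None,
    directivity: DirectivityModel | None = None,
    sample_rate: float = 40e6,
    max_depth: float = 0.075,
    seed: int | None = None,
) -> FOUSRecord:
    """Simulate a single imaging frame of FOUS data.

    Per scanline, the sensor series is the superposition over transmitting
    elements of the pulse delayed by the one-way arrival time, scaled by
    sensor sensitivity (Fabry-Pérot slope x bend transmission), directivity
    and 1/r spreading, plus seeded Gaussian noise.
    """
    rec = generate_sequence(
        1, probe, sensor, medium, pulse, noise,
        fiber=fiber, itf=itf, loss_model=loss_model, directivity=directivity,
        sample_rate=sample_rate, max_depth=max_depth, seed=seed,
    )
    return rec


def generate_sequence(
    n_frames: int,
    probe: ProbeModel,
    sensor: SensorPose,
    medium: MediumSpec = WATER,
    pulse: PulseSpec | None = None,
    noise: NoiseSpec | None = None,
    *,
    fiber: FiberSpec | None = None,
    itf: ITFModel | None = None,
    loss_model: BendLossModel | None = None,
    directivity: DirectivityModel | None = None,
    sample_rate: float = 40e6,
    max_depth: float = 0.075,
    pose_jitter_std: float = 0.0,
    seed: int | None = None,
) -> FOUSRecord:
    """Simulate ``n_frames`` frames with fixed geometry and fresh noise.

    Per-frame noise (and optional isotropic Gaussian pose jitter,
    ``pose_jitter_std`` meters) comes from substreams derived
    deterministically from the master ``seed``.  Without jitter the clean
    field is computed once and reused, so long high-SNR sequences are cheap.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if noise is None:
        noise = NoiseSpec()
    master = seed if seed is not None else noise.seed
    ss = np.random.SeedSequence(master)
    children = ss.spawn(2 * n_frames)
    common = dict(
        medium=medium, pulse=pulse, fiber=fiber, itf=itf, loss_model=loss_model,
        directivity=directivity, sample_rate=sample_rate, max_depth=max_depth,
    )
    base = None
    if pose_jitter_std == 0.0:
        base = clean_frame(probe, sensor, **common)
    frames: list[Frame] = []
    for k in range(n_frames):
        if base is None:
            jit = np.random.default_rng(children[2 * k]).normal(0.0, pose_jitter_std, 2)
            pose_k = SensorPose(
                (sensor.position[0] + jit[0], max(0.0, sensor.position[1] + jit[1])),
                sensor.orientation, sensor.in_plane,
            )
            data = clean_frame(probe, pose_k, **common)
        else:
            data = base.copy()
        if noise.noise_std > 0:
            rng = np.random.default_rng(children[2 * k + 1])
            data = data + rng.normal(0.0, noise.noise_std, data.shape)
        frames.append(_frame_from_data(data, sample_rate, k))
    return FOUSRecord(
        frames=frames, probe=probe, medium=medium, sensor=sensor,
        metadata={
            "seed": master, "noise_std": noise.noise_std,
            "pose_jitter_std": pose_jitter_std,
            "fiber": None if fiber is None else {
                "type": fiber.fiber_type.value, "bends": list(fiber.bend_profile)},
        },
    )


def generate_static_bend_experiment(
    fiber: FiberSpec,
    itf: ITFModel | None = None,
    pulse: PulseSpec | None = None,
    distance: float = 0.022,
    noise: NoiseSpec | None = None,
    n_repeats: int = 100,
    seed: int | None = None,
    *,
    medium: MediumSpec = WATER,
    loss_model: BendLossModel | None = None,
    sample_rate: float = 40e6,
) -> np.ndarray:
    """Water-tank bench traces: a planar transducer insonifies the bare sensor.

    Returns an (n_repeats, n_samples) array of single-arrival traces.  The
    pulse arrives at t = distance/c (14.67 us for the 2.2 cm stand-off)
    with amplitude proportional to the sensor sensitivity after bend loss;
    each repeat carries fresh seeded noise, so averaging repeats shrinks
    the noise floor of the mean trace by ~sqrt(N).
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    if pulse is None:
        pulse = PulseSpec()  # 3.5 MHz bench transducer
    if noise is None:
        noise = NoiseSpec()
    model = loss_model if loss_model is not None else BendLossModel.calibrated()
    gain = sensor_sensitivity(itf, roundtrip_transmission(model, fiber)) if itf is not None \
        else roundtrip_transmission(model, fiber)
    t_arrival = distance / medium.speed_of_sound
    n_samples = int(math.ceil(1.3 * t_arrival * sample_rate)) + int(20 * pulse.envelope_sigma * sample_rate)
    t_grid = np.arange(n_samples) / sample_rate
    trace = gain * pulse_waveform(t_grid - t_arrival, pulse)
    out = np.tile(trace, (n_repeats, 1))
    if noise.noise_std > 0:
        master = seed if seed is not None else noise.seed
        rng = np.random.default_rng(np.random.SeedSequence(master))
        out = out + rng.normal(0.0, noise.noise_std, out.shape)
    return out


def generate_itf_scan(
    fiber_type,
    itf: ITFModel | None = None,
    wavelength_grid: np.ndarray | None = None,
    radii_mm=ITF_SCAN_RADII_MM,
    turns: float = 0.5,
    *,
    loss_model: BendLossModel | None = None,
) -> pd.DataFrame:
    """Wavelength-scan ITF curves at a ladder of bend radii.

    Emulates winding the fiber once through a 180 degree bend at each
    radius (12.5 mm down to 2.5 mm by default) and re-scanning the ITF:
    each curve is the straight-fiber reflected-power curve scaled by the
    round-trip bend transmission.  Returns a CSV-ready DataFrame with
    columns ``wavelength_nm``, ``phase_rad``, ``straight`` and one column
    per radius (``r_<mm>mm``).
    """
    from .fiber import FiberType, itf_reflectance

    if itf is None:
        itf = ITFModel()
    if wavelength_grid is None:
        wavelength_grid = np.linspace(1500e-9, 1620e-9, 1201)
    phase = itf.phase(wavelength_grid)
    if np.ptp(phase) < 2.0 * np.pi:
        raise ValueError("wavelength grid must span at least one full fringe (2*pi of phase)")
    model = loss_model if loss_model is not None else BendLossModel.calibrated()
    straight = itf.input_power * itf_reflectance(itf, phase)
    out = {"wavelength_nm": wavelength_grid * 1e9, "phase_rad": phase, "straight": straight}
    ftype = FiberType(fiber_type)
    for r_mm in radii_mm:
        fiber = FiberSpec(ftype, ((r_mm * 1e-3, turns),))
        out[f"r_{r_mm:g}mm"] = straight * roundtrip_transmission(model, fiber)
    return pd.DataFrame(out)
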