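"""Fabry-Pérot fiber-optic ultrasound sensor (FOUS) optics.

A FOUS is a thin Fabry-Pérot (F-P) cavity on the tip of a single-mode
fiber.  Incident ultrasound modulates the cavity's optical thickness and
hence the reflected optical power; the acoustic sensitivity is set by the
slope of the interference transfer function (ITF, reflected power vs.
round-trip phase) at the interrogation bias point, and scales linearly
with the optical power reaching the cavity.

When the fiber is bent tightly (macrobending), light leaks from the core.
Interrogation light crosses each bend twice (in and back), so the detected
signal scales with the *round-trip* bend transmission.  Standard SMF loses
power catastrophically below ~10 mm bend radius, while trench-assisted
bend-insensitive (BI, ITU-T G.657.B3 class) fiber stays within a few
percent of the straight-fiber response down to 2.5 mm.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FiberType",
    "ITFModel",
    "FiberSpec",
    "BendLossModel",
    "DirectivityModel",
    "itf_reflectance",
    "itf_slope",
    "bias_phase",
    "bend_loss_db",
    "roundtrip_transmission",
    "sensor_sensitivity",
    "directivity_gain",
]


class FiberType(str, enum.Enum):
    """Fiber classes distinguished by macrobend behaviour."""

    STANDARD_SMF = "standard_smf"
    BEND_INSENSITIVE = "bend_insensitive"


@dataclass(frozen=True)
class ITFModel:
    """Two-mirror lossless Fabry-Pérot cavity.

    Parameters
    ----------
    cavity_optical_thickness : float
        Optical thickness (refractive index x geometric thickness) of the
        cavity, meters.  Sets the fringe spacing in wavelength.
    mirror_reflectivity_1, mirror_reflectivity_2 : float
        Amplitude reflection coefficients of the two mirrors, in (0, 1).
    input_power : float
        Interrogation optical power incident on the fiber, arbitrary units.
    bias_wavelength : float
        Nominal interrogation wavelength, meters.
    """

    cavity_optical_thickness: float = 20e-6
    mirror_reflectivity_1: float = 0.8
    mirror_reflectivity_2: float = 0.8
    input_power: float = 1.0
    bias_wavelength: float = 1550e-9

    def __post_init__(self) -> None:
        for name in ("mirror_reflectivity_1", "mirror_reflectivity_2"):
            r = getattr(self, name)
            if not 0.0 < r < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {r}")
        if self.cavity_optical_thickness <= 0:
            raise ValueError("cavity_optical_thickness must be positive")
        if self.input_power < 0:
            raise ValueError("input_power must be non-negative")

    def phase(self, wavelength: np.ndarray | float) -> np.ndarray | float:
        """Round-trip phase 4*pi*L_opt/lambda for a wavelength (m)."""
        return 4.0 * np.pi * self.cavity_optical_thickness / np.asarray(wavelength, float)


@dataclass(frozen=True)
class FiberSpec:
    """A fiber and its bend configuration.

    ``bend_profile`` is a list of ``(radius_m, turns)`` segments; ``turns``
    counts full turns (0.5 = a 180 degree bend).  An empty profile is a
    straight fiber.
    """

    fiber_type: FiberType = FiberType.BEND_INSENSITIVE
    bend_profile: tuple[tuple[float, float], ...] = ()
    outer_diameter: float = 155e-6

    def __post_init__(self) -> None:
        object.__setattr__(self, "fiber_type", FiberType(self.fiber_type))
        object.__setattr__(self, "bend_profile", tuple((float(r), float(t)) for r, t in self.bend_profile))
        for radius, turns in self.bend_profile:
            if radius <= 0:
                raise ValueError(f"bend radius must be positive, got {radius}")
            if turns < 0:
                raise ValueError(f"turns must be non-negative, got {turns}")


def _fit_exponential(r1_m: float, loss1: float, r2_m: float, loss2: float) -> tuple[float, float]:
    """Solve loss_per_turn(r) = a*exp(-b*r) through two (radius, dB/turn) anchors."""
    b = math.log(loss1 / loss2) / (r2_m - r1_m)
    a = loss1 * math.exp(b * r1_m)
    return a, b


@dataclass(frozen=True)
class BendLossModel:
    """Macrobend loss per fiber type: one-way loss_per_turn(r) = a*exp(-b*r) dB.

    ``coefficients`` maps a :class:`FiberType` to ``(a, b)`` with ``a`` in
    dB/turn and ``b`` in 1/m.  :meth:`calibrated` builds the default model
    from measured optical anchors:

    * standard SMF — round-trip reflectivity relative to straight fiber of
      50% at 10 mm radius and 2% at 5 mm radius, for a 180 degree bend;
    * BI fiber — 0.2 dB/turn one-way at 5 mm (G.657.B3 specification) and
      95% round-trip reflectivity at 2.5 mm for a 180 degree bend.
    """

    coefficients: dict[FiberType, tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def calibrated(cls) -> "BendLossModel":
        # Round-trip transmission of a half-turn bend: T = 10^(-2*0.5*L/10)
        # = 10^(-L/10), so per-turn one-way loss L(r) = -10*log10(T_halfturn).
        smf = _fit_exponential(
            10e-3, -10.0 * math.log10(0.50),
            5e-3, -10.0 * math.log10(0.02),
        )
        bi = _fit_exponential(
            5e-3, 0.2,
            2.5e-3, -10.0 * math.log10(0.95),
        )
        return cls({FiberType.STANDARD_SMF: smf, FiberType.BEND_INSENSITIVE: bi})

    def loss_per_turn_db(self, fiber_type: FiberType, radius: float) -> float:
        """One-way bend loss of one full turn at the given radius (dB)."""
        if radius <= 0:
            raise ValueError(f"bend radius must be positive, got {radius}")
        a, b = self.coefficients[FiberType(fiber_type)]
        return a * math.exp(-b * radius)


def itf_reflectance(itf: ITFModel, phase: np.ndarray | float) -> np.ndarray | float:
    """Reflected power fraction of the F-P cavity at a round-trip phase.

    Airy reflectance of a lossless two-mirror cavity with amplitude
    coefficients r1, r2:

        R(phi) = (r1^2 + r2^2 - 2 r1 r2 cos phi) / (1 + r1^2 r2^2 - 2 r1 r2 cos phi)

    R is smooth, 2*pi-periodic, bounded in [0, 1), and vanishes at
    resonance (phi = 0 mod 2*pi) for matched mirrors.
    """
    r1 = itf.mirror_reflectivity_1
    r2 = itf.mirror_reflectivity_2
    c = np.cos(np.asarray(phase, dtype=float))
    num = r1 * r1 + r2 * r2 - 2.0 * r1 * r2 * c
    den = 1.0 + (r1 * r2) ** 2 - 2.0 * r1 * r2 * c
    out = num / den
    return float(out) if np.isscalar(phase) else out


def itf_slope(itf: ITFModel, phase: np.ndarray | float) -> np.ndarray | float:
    """Analytic derivative dR/dphi of the Airy reflectance."""
    r1 = itf.mirror_reflectivity_1
    r2 = itf.mirror_reflectivity_2
    b = 2.0 * r1 * r2
    phase = np.asarray(phase, dtype=float)
    den = 1.0 + (r1 * r2) ** 2 - b * np.cos(phase)
    out = b * np.sin(phase) * (1.0 - r1 * r1) * (1.0 - r2 * r2) / den**2
    return float(out) if out.ndim == 0 else out


def bias_phase(itf: ITFModel, n_grid: int = 200_001) -> float:
    """Operating phase with maximum |dR/dphi| (standard F-P interrogation).

    Found numerically on a dense grid over one period; the ITF slope is
    smooth so grid resolution ~3e-5 rad is far below any quantity of
    interest here.
    """
    phi = np.linspace(0.0, 2.0 * np.pi, n_grid)
    return float(phi[np.argmax(np.abs(itf_slope(itf, phi)))])


def bend_loss_db(model: BendLossModel, fiber: FiberSpec) -> float:
    """Total one-way macrobend loss of a fiber's bend profile (dB).

    Each ``(radius, turns)`` segment contributes turns x loss_per_turn(radius);
    partial turns scale linearly in dB.  A straight fiber has zero loss.
    """
    return sum(
        turns * model.loss_per_turn_db(fiber.fiber_type, radius)
        for radius, turns in fiber.bend_profile
    )


def roundtrip_transmission(model: BendLossModel, fiber: FiberSpec) -> float:
    """Round-trip optical transmission through the bend profile, in [0, 1].

    Interrogation light traverses each bend twice (towards the cavity and
    back to the detector), so the detected-power fraction relative to a
    straight fiber is 10^(-2*loss_one_way_dB/10).
    """
    return 10.0 ** (-2.0 * bend_loss_db(model, fiber) / 10.0)


def sensor_sensitivity(
    itf: ITFModel,
    transmission: float,
    *,
    relative: bool = True,
) -> float:
    """Acoustic sensitivity of the sensor for a given optical transmission.

    Sensitivity is (max |dR/dphi| at the bias point) x input optical power x
    bend transmission.  With ``relative=True`` (default) the value is
    normalized to the straight fiber (transmission 1) so that it equals the
    transmission itself; ``relative=False`` returns the un-normalized value,
    which is linear in ``input_power``.
    """
    if not 0.0 <= transmission <= 1.0:
        raise ValueError(f"transmission must lie in [0, 1], got {transmission}")
    slope = abs(itf_slope(itf, bias_phase(itf)))
    absolute = slope * itf.input_power * transmission
    if relative:
        straight = slope * itf.input_power
        return absolute / straight if straight > 0 else 0.0
    return absolute


@dataclass(frozen=True)
class DirectivityModel:
    """Angular sensitivity envelope of the sensor.

    The sensor is close to omnidirectional: unit gain out to
    ``flat_half_angle`` degrees from the fiber axis, then a raised-cosine
    roll-off to zero at 180 degrees.  ``min_inband_gain`` is the floor the
    in-band response must respect (a validation constraint, not a shape
    parameter of the default flat response).
    """

    flat_half_angle: float = 165.0
    min_inband_gain: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.flat_half_angle <= 180.0:
            raise ValueError("flat_half_angle must lie in (0, 180]")
        if not 0.0 <= self.min_inband_gain <= 1.0:
            raise ValueError("min_inband_gain must lie in [0, 1]")


def directivity_gain(model: DirectivityModel, angle_deg: np.ndarray | float) -> np.ndarray | float:
    """Gain in [0, 1] at an incidence angle (degrees, in [-180, 180]).

    Symmetric about 0 with g(0) = 1; above ``flat_half_angle`` the gain
    rolls off as a raised cosine reaching 0 at 180 degrees.
    """
    a = np.abs(np.asarray(angle_deg, dtype=float))
    if np.any(a > 180.0):
        raise ValueError("angle must lie in [-180, 180] degrees")
    width = 180.0 - model.flat_half_angle
    with np.errstate(invalid="ignore"):
        roll = 0.5 * (1.0 + np.cos(np.pi * (a - model.flat_half_angle) / width)) if width > 0 else np.zeros_like(a)
    out = np.where(a <= model.flat_half_angle, 1.0, roll)
    return float(out) if out.ndim == 0 else out
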