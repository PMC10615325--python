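"""Receive-mode tracking: from raw sensor series to per-frame tip positions.

One imaging frame gives one time series per scanline.  Envelope-detected
series are concatenated column-wise into a 2D tracking image (axial sample
x scanline) in which the sensor appears as a bright focal spot.  The tip is
localized as the intensity-weighted centre of mass (CoM) of a thresholded
region of interest around the image maximum, then mapped to cartesian
display coordinates through the probe geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import hilbert

from .probe import MediumSpec, ProbeKind, ProbeModel, beam_table
from .synth import FOUSRecord, Frame

__all__ = [
    "NoSignalError",
    "TrackerConfig",
    "TrackingImage",
    "TipEstimate",
    "envelope",
    "build_tracking_image",
    "background_subtract",
    "localize_tip",
    "map_to_display",
    "track_sequence",
]


class NoSignalError(RuntimeError):
    """Raised when an image contains no localizable signal."""


@dataclass(frozen=True)
class TrackerConfig:
    """Localization parameters.

    ``roi_size`` is the (rows, cols) window around the image maximum
    (clipped, not padded, at borders); pixels below ``threshold_fraction``
    of the ROI maximum are zeroed before the CoM.  ``detection_factor``
    scales the Rayleigh extreme-value gate used by :func:`track_sequence`
    to flag frames with no apparent signal.
    """

    roi_size: tuple[int, int] = (100, 100)
    threshold_fraction: float = 0.70
    background_method: str = "median"  # or "reference"
    envelope_method: str = "hilbert"
    detection_factor: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must lie in (0, 1)")
        if self.roi_size[0] < 1 or self.roi_size[1] < 1:
            raise ValueError("roi_size must be at least 1x1")


@dataclass
class TrackingImage:
    """Envelope-detected frame data as a 2D image.

    Rows are axial samples (row r maps to one-way depth r * axial_spacing
    with axial_spacing = c / fs); columns are scanlines with the beam
    geometry carried by ``probe``.
    """

    pixels: np.ndarray  # (n_axial, n_scanlines), non-negative
    axial_spacing: float
    probe: ProbeModel | None = None
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.axial_spacing <= 0:
            raise ValueError("axial_spacing must be positive")


@dataclass
class TipEstimate:
    """Per-frame tip localization result.

    ``row``/``col`` are fractional image coordinates (0-based, row-major);
    ``x``/``z`` are cartesian display coordinates in meters when the probe
    geometry is known.  ``flag`` is None for a valid estimate, otherwise a
    short reason string ("no_signal").
    """

    frame_index: int
    row: float
    col: float
    x: float | None
    z: float | None
    roi_bounds: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open
    flag: str | None = None


def envelope(series: np.ndarray, axis: int = -1) -> np.ndarray:
    """Magnitude of the analytic signal (Hilbert envelope).

    Non-negative and, away from edge effects, bounding |series| from above.
    """
    series = np.asarray(series, float)
    if not np.all(np.isfinite(series)):
        raise ValueError("series must be finite")
    if series.size == 0 or np.ptp(series) == 0 and series.ravel()[0] == 0:
        return np.abs(series)
    return np.abs(hilbert(series, axis=axis))


def build_tracking_image(frame: Frame, medium: MediumSpec, probe: ProbeModel | None = None,
                         frame_index: int | None = None) -> TrackingImage:
    """Concatenate envelope-detected scanlines into a tracking image.

    Column j is the envelope of scanline j's series; row r corresponds to
    one-way depth r*c/fs.
    """
    data = frame.data
    if data.shape[0] < 1:
        raise ValueError("frame must contain at least one scanline")
    env = envelope(data, axis=1)
    return TrackingImage(
        pixels=env.T.copy(),
        axial_spacing=medium.speed_of_sound / frame.sample_rate,
        probe=probe,
        frame_index=frame.frame_trigger_index if frame_index is None else frame_index,
    )


def background_subtract(
    image: TrackingImage | np.ndarray,
    config: TrackerConfig = TrackerConfig(),
    reference: np.ndarray | None = None,
) -> TrackingImage | np.ndarray:
    """Remove the image background, clamping at zero.

    Default subtracts the per-image median (offset-invariant for a spot on
    a flat background); with ``config.background_method == "reference"`` a
    recorded signal-free frame is subtracted instead.
    """
    pixels = image.pixels if isinstance(image, TrackingImage) else np.asarray(image, float)
    if config.background_method == "reference" or reference is not None:
        if reference is None:
            raise ValueError("background_method='reference' requires a reference frame")
        if reference.shape != pixels.shape:
            raise ValueError(
                f"reference shape {reference.shape} does not match image shape {pixels.shape}"
            )
        out = np.clip(pixels - reference, 0.0, None)
    else:
        out = np.clip(pixels - np.median(pixels), 0.0, None)
    if isinstance(image, TrackingImage):
        return replace(image, pixels=out)
    return out


def _as_pixels(image) -> tuple[np.ndarray, TrackingImage | None]:
    if isinstance(image, TrackingImage):
        return image.pixels, image
    return np.asarray(image, float), None


def localize_tip(image: TrackingImage | np.ndarray, config: TrackerConfig = TrackerConfig()) -> TipEstimate:
    """Centre-of-mass tip localization around the image maximum.

    Steps: (1) global maximum pixel (ties broken to the smallest row, then
    column); (2) ROI of ``config.roi_size`` centered there, clipped at the
    borders; (3) zero ROI pixels below ``threshold_fraction`` x ROI max;
    (4) CoM = intensity-weighted mean (row, col) over surviving pixels.
    Physical coordinates are attached when the image carries its probe
    geometry.
    """
    pixels, timg = _as_pixels(image)
    if pixels.ndim != 2:
        raise ValueError("image must be 2D")
    peak = float(pixels.max(initial=-np.inf))
    if not peak > 0:
        raise NoSignalError("image has no strictly positive maximum; nothing to localize")
    r0c0 = np.unravel_index(int(np.argmax(pixels)), pixels.shape)  # row-major first occurrence
    n_rows, n_cols = pixels.shape
    h, w = config.roi_size
    row0 = max(0, r0c0[0] - h // 2)
    row1 = min(n_rows, row0 + h)
    row0 = max(0, row1 - h)
    col0 = max(0, r0c0[1] - w // 2)
    col1 = min(n_cols, col0 + w)
    col0 = max(0, col1 - w)
    roi = pixels[row0:row1, col0:col1].copy()
    roi[roi < config.threshold_fraction * roi.max()] = 0.0
    total = roi.sum()
    rr, cc = np.mgrid[row0:row1, col0:col1]
    row = float((rr * roi).sum() / total)
    col = float((cc * roi).sum() / total)
    est = TipEstimate(
        frame_index=timg.frame_index if timg is not None else 0,
        row=row, col=col, x=None, z=None,
        roi_bounds=(row0, row1, col0, col1),
    )
    if timg is not None and timg.probe is not None:
        est.x, est.z = map_to_display(est, timg.probe, timg.axial_spacing)
    return est


def map_to_display(
    tip: TipEstimate | tuple[float, float],
    probe: ProbeModel,
    axial_spacing: float,
) -> tuple[float, float]:
    """Image (row, col) to cartesian display coordinates (x, z), meters.

    Linear probe: x is the beam's lateral origin, z the one-way depth.
    Sector probe: the column's beam angle theta gives (x, z) =
    (r sin theta, r cos theta) with r the one-way depth.  Fractional
    columns interpolate linearly in the beam table.
    """
    row, col = (tip.row, tip.col) if isinstance(tip, TipEstimate) else tip
    table = beam_table(probe)
    if not -0.5 <= col <= table.size - 0.5:
        raise ValueError(f"column {col} lies outside the beam table (0..{table.size - 1})")
    depth = row * axial_spacing
    param = float(np.interp(col, np.arange(table.size), table))
    if probe.kind is ProbeKind.PHASED_SECTOR:
        th = math.radians(param)
        return depth * math.sin(th), depth * math.cos(th)
    return param, depth


def _noise_sigma_rayleigh(env_pixels: np.ndarray) -> float:
    """Noise scale from the envelope-image median (Rayleigh median = sigma*1.1774)."""
    return float(np.median(env_pixels)) / math.sqrt(math.log(4.0))


def track_sequence(record: FOUSRecord, config: TrackerConfig = TrackerConfig()) -> list[TipEstimate]:
    """Run the full pipeline on every frame of a record.

    Frames whose envelope peak is indistinguishable from the Rayleigh
    noise-extreme level (peak <= detection_factor * sqrt(2 ln N) * sigma)
    are flagged ``"no_signal"`` with NaN coordinates rather than dropped.
    """
    if record.n_frames == 0:
        raise ValueError("record contains no frames")
    estimates: list[TipEstimate] = []
    for k, frame in enumerate(record.frames):
        image = build_tracking_image(frame, record.medium, record.probe, frame_index=k)
        sigma = _noise_sigma_rayleigh(image.pixels)
        n_pix = image.pixels.size
        gate = config.detection_factor * math.sqrt(2.0 * math.log(n_pix)) * sigma
        peak = float(image.pixels.max())
        if peak <= gate or peak <= 0.0:
            estimates.append(TipEstimate(k, math.nan, math.nan, None, None, (0, 0, 0, 0), flag="no_signal"))
            continue
        image = background_subtract(image, config)
        try:
            estimates.append(localize_tip(image, config))
        except NoSignalError:
            estimates.append(TipEstimate(k, math.nan, math.nan, None, None, (0, 0, 0, 0), flag="no_signal"))
    return estimates
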