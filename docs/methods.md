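# Methods

## Physical picture and coordinate conventions

A point-like Fabry-Pérot (F-P) ultrasound sensor on a fiber tip sits in
the field of a clinical imaging array and *receives* the array's ordinary
focused transmits. All geometry lives in the imaging plane: origin at the
aperture center on the probe face, x lateral, z depth, beam angles from
+z. Time zero of every scanline is the line trigger, taken as the instant
the earliest element fires (transmit focusing delays are non-negative with
minimum zero). Because the sensor is a receiver and not a reflector, time
of flight maps to distance one-way, `d = c·t`, with `c = 1500 m/s` for the
deionized-water phantom medium; there is no pulse-echo factor of ½.

Two probe models are built in: a 16-element, 6 MHz phased array scanning a
90° sector (91 beams at 1° spacing, all pivoting at the aperture center),
and a 128-element linear array (0.3 mm pitch, 6.5 MHz taken as the middle
of its 4–9 MHz band, one beam per element). Both focus at 5.5 cm, the
depth of the tracked tip in the phantom geometry. The element pitch of the
phased probe is not published; we assume half a wavelength at 6 MHz
(0.125 mm). For the linear probe each line drives a 16-element
sub-aperture centered on the line. This choice is geometric: the residual
between the coherent-sum arrival time and `z/c` for an on-axis sensor
grows with the square of the aperture half-width, and 16 elements
(±2.4 mm) keeps that bias below about two axial samples across 3–7 cm
depths, comfortably inside the localization tolerance, while preserving a
realistic focused beam.

## Fiber-sensor model

**ITF.** The cavity is modelled as a lossless two-mirror F-P with
amplitude reflection coefficients r₁ = r₂ = 0.8 (configurable); the
reflected-power fraction is the Airy form
`R(φ) = (r₁² + r₂² − 2r₁r₂cos φ)/(1 + r₁²r₂² − 2r₁r₂cos φ)`, 2π-periodic
and zero at resonance for matched mirrors. The interrogation bias point is
the phase of maximum |dR/dφ| (found on a dense grid; the derivative is
analytic). Acoustic sensitivity is `max|dR/dφ| × input power ×
bend transmission`, reported relative to the straight fiber, where it
reduces to the bend transmission itself. Wavelength scans use a 20 µm
optical-thickness cavity around 1550 nm so a 1500–1620 nm sweep covers
more than one fringe.

**Macrobend loss.** One-way loss per full turn follows the standard
macrobend phenomenology `L(r) = a·e^{−b·r}` dB/turn; partial turns scale
linearly in dB, segments add, and detected power scales with the
*round-trip* transmission `10^(−2·ΣturnsᵢL(rᵢ)/10)` because interrogation
light crosses each bend twice. The two coefficients per fiber type are
solved exactly at run time from measured optical anchors rather than
hard-coded: standard SMF from round-trip reflectivities 0.50 at 10 mm and
0.02 at 5 mm (180° bends), giving a ≈ 95.9 dB/turn, b ≈ 0.346 mm⁻¹;
bend-insensitive fiber from the G.657.B3 figure 0.2 dB/turn at 5 mm plus
round-trip reflectivity 0.95 at 2.5 mm (180° bend), giving
a ≈ 0.248 dB/turn, b ≈ 0.0431 mm⁻¹. The model then predicts ~40 dB
round-trip loss for standard SMF bent 180° at 2.5 mm — i.e. no detectable
signal, consistent with the qualitative bench observation. A separate
bench SNR pair (47.7 straight vs. 36.8 bent at 3 mm) implies a somewhat
larger loss (~1.1 dB round trip) than these optical anchors predict
(~0.44 dB); the two measurements involve different bend geometries, so the
model is calibrated to the optical anchors only and the SNR pair is left
as an out-of-sample observation.

**Directivity.** The sensor is nearly omnidirectional; the default model
is unit gain within ±165° of the fiber axis with a raised-cosine roll-off
to zero at 180°. This is a qualitative envelope — no numeric fidelity is
claimed beyond symmetry, g(0)=1, and the roll-off location.

## Synthetic data generator

Per scanline, the sensor series is the superposition over transmitting
elements of a Gaussian-enveloped sinusoid (fractional −6 dB bandwidth 0.6;
the true transmit waveform is not published) delayed by
`delay_i + dist_i/c`, scaled by sensitivity × directivity × 1/dist
spherical spreading, with optional frequency-linear medium attenuation
(default 0 dB/cm/MHz for water). Records default to 40 MHz sampling
(≥ Nyquist for both probes) and a length covering 1.3× the maximum imaged
depth (7.5 cm default). Detector noise is i.i.d. zero-mean Gaussian; all
substreams (per frame, per repeat) derive from one master seed via
`SeedSequence.spawn`, so records are bit-reproducible. When the pose is
fixed the clean field is computed once and only the noise is redrawn per
frame.

The bench ("static bend") generator emulates a 3.5 MHz planar transducer
2.2 cm from the bare sensor in a water tank: a single arrival at
`t = d/c ≈ 14.7 µs`, amplitude proportional to sensitivity after bend
loss, with fresh noise per repeat; 100-repeat averaging shrinks the mean
trace's noise floor by ~√100. The default bench noise level
(≈ 0.21 per unit pulse amplitude) places the straight fiber at an
averaged-trace SNR near 48, the scale of the bench measurements.

What the generator does **not** emulate: tissue speckle and clutter,
reverberation, element directivity and apodization of the imaging array,
near-field diffraction, cardiac/vessel motion, and out-of-plane physics.
Passing tests therefore demonstrate the correctness of the pipeline and
the internal consistency of the physics models under clean conditions, not
performance on in-vivo data.

## Tracking pipeline

Envelope detection is the magnitude of the analytic signal (Hilbert).
Tracking images are (axial sample × scanline); localization happens in
this space and coordinates are scan-converted afterwards, since the
pixel grid of the original console display is not published. Background
subtraction defaults to per-image median with clamping at zero (a recorded
signal-free reference frame is also supported). Localization: global
maximum (ties broken row-major to the first occurrence), 100×100-pixel ROI
clipped (not padded) at borders, pixels below 0.70 of the *ROI* maximum
zeroed — the ROI-local reference is chosen because thresholding follows
ROI extraction in the processing order; the 0.70 is configurable since the
source protocol gives it only approximately — then the intensity-weighted
mean pixel coordinate. Fractional scanline indices are mapped to display
coordinates by linear interpolation in the beam table.

Sequence tracking flags, rather than drops, frames with no apparent
signal. The gate is derived from Rayleigh extreme-value statistics of an
envelope-detected noise image: noise σ is estimated from the envelope
median (Rayleigh median = σ√(ln 4)), and a frame is flagged when its peak
does not exceed `1.5·σ·sqrt(2 ln N)` (N image pixels), i.e. 1.5× the
expected maximum of pure noise. Noiseless and high-SNR frames pass this
gate by orders of magnitude.

## SNR estimation

SNR = envelope peak / noise-floor standard deviation (linear scale). For
traces the noise std is measured on the raw series outside the peak gate
(default gate ±1 µs around the predicted arrival); for tracking images it
is the pixel std of a signal-free rectangle of the envelope image,
matching how a manual region of a displayed tracking image would be used.
The automatic noise region takes the deepest 20% of rows over the quarter
of columns farthest from the peak column; a single far column would leave
only a few hundred samples, making the noise estimate itself the dominant
variance term in per-frame SNR, so the block form is used (a manual
rectangle, which must be disjoint from the 100×100 peak region, takes
precedence). The estimator carries two small positive biases, both
quantified by the calibration test: the expectation of 1/s for a
sample std s (≈ 3/(4n), negligible for the ROI sizes used), and the max
over a noisy window when the peak is weak (visible at true SNR ≈ 5,
immaterial at the SNR ≈ 200 regime of the tracking experiments).

## Study-condition experiments and problem sizes

`frame_variation_experiment` reproduces the 100-frame fixed-pose stability
protocol: linear 128-element probe, sensor at 5.5 cm on a central beam,
noise set so the clean envelope peak is 200× the noise std, per-frame SNR
via the automatic noise region, reporting the mean and the maximum
relative deviation. Simulated runs land at 2–3% maximum deviation, within
the 10% bound reported for the physical phantom.

Test problem sizes are chosen to exercise every code path at interactive
runtimes: reduced scanline counts (31-beam sector) for unit tests, the
full 91-beam/128-line probes for the end-to-end acceptance checks (50
random poses per probe for noiseless recovery, 1000 images for the CoM
oracle, 1000 seeds per level for estimator calibration).

## Numerical choices and degenerate inputs

Bilinear interpolation for scan conversion (nearest-neighbour by flag);
out-of-sector pixels are zeroed and masked. A sensor exactly on an element
is kept finite by a 1 µm distance floor. All-zero images raise a
`NoSignalError` rather than returning a coordinate; empty records, ragged
shapes, negative radii/times and out-of-range reflectivities raise
`ValueError` naming the offending quantity. SI units internally; CLI and
file boundaries accept the units stated in their schemas (meters, Hz).

## Known limitations

Single-frequency bend-loss and directivity models; no elevational physics
or receive beamforming of the imaging array's own B-mode; the bench SNR
pair noted above is not reproduced by the optical calibration; absolute
pressure/NEP calibration is out of scope (all amplitudes are relative).
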