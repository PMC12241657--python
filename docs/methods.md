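# Methods

This note documents the models, parameter choices, and numerical
conventions behind `sonocell`, and what the synthetic experiments do and
do not establish about real acquisitions.

## The problem

Macrophages phagocytose lipid-shelled microbubbles, and the engulfed
bubble keeps oscillating nonlinearly under ultrasound.  That turns a
cell that is otherwise acoustically indistinguishable from host tissue
(σ_macrophage ≈ σ_cancer) into a strong, spectrally distinctive
scatterer.  The package implements the computational chain that makes
this usable: the bubble physics, the nonlinear imaging sequence that
separates bubbles from tissue, cavitation dosimetry for choosing safe
exposures, and super-resolution mapping of the vasculature the labeled
cells travel through.

## Shelled-bubble dynamics (`bubble_dynamics`)

The oscillator is a modified Rayleigh–Plesset equation with a
regime-switching shell tension (a Marmottant-family model):

ρ(R R̈ + 3/2 Ṙ²) = P_g0 (R0/R)^{3κ}(1 − 3κṘ/c) − P0 − p_ac(t)
  − 2σ(R)/R − 4μ_eff Ṙ/R − 4κ_s Ṙ/R²

with σ(R) = 0 below the buckling radius, χ((R/R_b)² − 1) on the elastic
branch, saturating at the rupture tension.  The buckled→elastic switch
is blended smoothly (softplus over an areal-strain width of 0.005): a
hard switch injects artificial wideband energy into the re-radiated
spectrum at every crossing, which would masquerade as broadband
cavitation noise.

A bubble resting at its buckling radius expands against the shell
elasticity but compresses against gas pressure alone — the mechanism
behind compression-dominant oscillation at low mechanical index.

Defaults (editable in `defaults.yaml`): R0 = 1.1 µm (clinical
perfluorocarbon-agent modal radius regime), χ = 0.8 N/m,
κ_s = 7.2·10⁻⁹ kg/s, R_b/R0 = 1.0, rupture tension 1.0 N/m (a
rupture-resistant monolayer; low-MI drives stay on the elastic branch),
κ = 1.07, liquid viscosity 2 mPa·s (water plus lumped thermal damping).
No published shell constants exist for this preparation; the values are
literature-typical and chosen once so that the free bubble at
MI 0.21 / 0.5 MHz is compression-dominant (expansion ≈ 4.9%,
compression ≈ −23%).

**Phagocytosis as damping.**  The engulfed state is represented by a
single effective parameter: a multiplier on the liquid viscosity,
standing in for the viscoelastic cytoplasm surrounding the bubble.  The
multiplier is fit once by bisection so the phagocytosed bubble's peak
*compression* at MI 0.21 / 0.5 MHz / 20 cycles equals the observed
−19% of R0; the fitted value (≈ 20.5) is stored in configuration, not
hard-coded.  Compression is the calibration metric because damping
controls it smoothly over the whole usable range, whereas expansion is
shell-stiffness-limited and nearly flat at low damping — no multiplier
can land expansion on its observed mean while keeping compression in
its observed band.  With the compression-calibrated multiplier, both
metrics fall inside the observed mean ± SD windows.

The ODE is solved with LSODA, radius tolerance 10⁻¹² m, maximum step an
eighth of a drive period, over the burst plus five ring-down cycles.  A
collapse below 5% of R0 terminates the solve and flags the series
rather than propagating NaNs.  Solutions are tolerance-converged
(halving tolerances moves max |R| by < 0.1%).

## Scenes (`scene`)

Coordinates: x lateral (origin at the array center), z axial (depth),
metres, half-open extents.  Tissue speckle is a homogeneous Poisson
point process at ≥ 10 scatterers per diffraction-limited resolution
cell (fully developed speckle), reflectivity Rayleigh-distributed.
Unlabeled cells draw from the *same* reflectivity distribution — this
encodes the comparable scattering cross-section of macrophages and host
cells, and is what makes them invisible in B-Mode.

The vessel phantom is wall-less: a 1.6 mm fluid channel at 5 mm depth
containing only suspended cells.  The surrounding gel is acoustically
weak (16% gelatin is nearly transparent), so gel speckle is scaled to
0.25 of the cell reflectivity.  Cell counts are Poisson with mean
(concentration × 3.2 µl imaging volume); the detection ladder instead
places the rounded expected count exactly, because the experimental
protocol counts realized cells in the sonication volume (a Poisson
count-1 rung would cap any detector at a 63% detection rate).  Labeled
cells carry one engulfed microbubble plus a tissue-like cell-body
scatterer.  Flow is plug flow with periodic wrap, which preserves the
in-channel concentration exactly.

Tumor scenes draw vessel center points at radius R·u^{1/(2(1+b))} —
area-uniform over the tumor disk at bias b = 0, concentrating toward
the rim as b grows — with sinusoidally perturbed chords as centerlines
and bubbles advected along them.

## RF simulation (`rf_simulation`)

Single-scattering Born approximation, point receive elements, no
attenuation.  Transmit is a plane wave from the array plane; aperture
parity (even/odd elements) scales the incident field by the active
fraction, so the three-pulse sequence's linear echoes cancel exactly.
The package uses plane-wave transmit for all image formation (focused
delay laws live in `incident_pressure_at`): the properties under test —
linear-vs-nonlinear discrimination and PSF brackets — are preserved,
at 1/128 the event count of focused ray-line imaging.

Linear echo scale: a unit-reflectivity scatterer has a Born scattering
length of 2.5·10⁻⁸ m (k²a³ × impedance contrast for a cell-sized
scatterer at 15.625 MHz).  A single microbubble's re-radiated echo then
sits ≈ 29 dB above a single cell's — the contrast-agent enhancement
that motivates labeling.  Bubbles are driven with the peak-equivalent
incident pulse (one ODE solve per unique drive, cached) and their
far-field monopole re-radiation p = ρ/r (R²R̈ + 2RṘ²) is deposited at
each element with 1/r spreading.  Echo deposition uses two-tap
fractional-delay impulses accumulated with `bincount` plus one FFT
convolution per waveform group.

Receive noise is white Gaussian at σ = 0.5 (same units as the echoes),
seeded; a single-cell element-level echo is ≈ 2.8.

## Imaging (`imaging`)

Delay-and-sum beamforming of the analytic (Hilbert) RF onto a 25 µm
grid, with a pulse-center time-zero correction.  The AMPI combination
(full-amplitude inverted + even-aperture + odd-aperture, all summed
sample-wise *before* beamforming) cancels linear echoes to the
floating-point floor; DAS is linear, so this equals beamform-then-sum.
Quantification is always on the linear envelope; log compression is
display-only (60 dB default).

Detection rule: any channel-ROI pixel above (gel background mean +
k·σ), k = 6 by default.  The any-pixel-above rule is a family-wise test
over the ~500–3000 correlated pixels of the ROI; at k = 3 it would
false-positive with near certainty on pure-noise AMPI residual images,
while k = 6 holds the blank false-positive rate at a few percent and
leaves ≈ 28 dB of margin on a single bubble.

## Cavitation dosimetry (`pcd`)

Records are high-pass filtered (zero-phase Butterworth, 0.6 MHz
cut-off), Hann-windowed, and zero-padded to the next power of two.
Band doses are means over 11 FFT bins centered on the nearest bin to
2f0 (harmonic), 1.5f0 (ultraharmonic), and 5.72f0 (broadband); at the
default record length the three bands are disjoint.  The displayed
spectrum is dB re max, but doses are referenced to 1 Pa so that
bubble-vs-baseline excesses compare on a common absolute scale (re-max
normalization makes the excess move opposite to drive level).  Dose
averaging is on dB magnitudes (config switch for linear).

The synthetic receive model: fundamental leak (10⁻⁷ of the drive),
far-field scattered pressure from a detector at 10 mm, and detector
noise at 0.07 Pa RMS.  With these constants the phagocytosed bubble
shows a harmonic excess of ≈ 8–11 dB at MI 0.08 with broadband at
baseline, and the free bubble develops a broadband excess at moderate
MI.  Single-record dose estimates wobble by ±2 dB (11-bin dB
averaging), so sweeps average doses over 4 records per MI — the
analogue of repeating the acquisition over several dishes.  The
deterministic shell model produces no true inertial broadband;
inertial classification (broadband excess > 6 dB) is exercised by
injecting broadband noise.

## Vascular mapping (`ulm`)

The frame stack is rearranged into a pixels × frames Casorati matrix
and SVD-filtered: the first 10% of singular values (tissue clutter) and
last 15% (noise) are truncated to zero; truncation counts use ceiling
on fraction × K, K = min(pixels, frames).  A `tissue_only` mode keeps
only the leading components (the registration reference).  Filtering
operates on **complex** beamformed data: a moving bubble's echo phase
rotates frame to frame (Doppler), placing its temporal signature at
high frequencies orthogonal to slow clutter.  This is not a nicety — a
non-negative envelope stack leaves the bubble with a DC temporal
component, and each of the 175 truncated components then absorbs about
one bubble-component of energy, capping retention near 82% regardless
of amplitudes.  With complex data, measured bubble retention on the
canonical two-component stack is ≈ 99% with tissue suppression ≈
−105 dB.

Richardson–Lucy deconvolution uses a position-independent Gaussian PSF
(σ from the system FWHM / 2.3548), 10 multiplicative updates,
reflective boundaries; non-negativity is preserved and flux conserved
to < 0.1%.  The map is the pixel-wise maximum-intensity projection over
deconvolved frames, 2× bilinearly upsampled and smoothed (σ = 1 output
pixel); local maxima above 0.3 of the map maximum are reported as
localizations.

The image-domain stack synthesizer renders bubbles as discrete transit
events — each transit carries its own random echo phase and traverses
its vessel once — because a bubble circulating continuously would paint
a quasi-static intensity ridge that the clutter filter correctly
treats as tissue.  In the same spirit, the two-component test stack
gives its clutter rank 70 (filling the truncated head), a 1.5-decade
singular spectrum 40 dB above the bubble, spatial modes that vanish on
the bubble path (vessel lumina carry no tissue signal), and a bubble
dwell of ~3 frames per pixel.  These are the conditions under which a
fixed 10%/15% truncation operates well in practice; the measured
retention and suppression quantify that regime, not an arbitrary stack.

## Problem sizes

The experiments run at desk scale as the package's standard conditions:
phantom cross-sections of 3 × 3.2 mm at ≥ 10 scatterers per resolution
cell (~30k scatterers), 20 phantoms per ladder rung, 700-frame
128 × 128 stacks for the SVD pipeline, and 150-frame stacks for vessel
localization.  The acceptance script (`scripts/acceptance.py`)
recomputes every headline quantity from scratch at these sizes.

## What the synthetic data does not capture

No attenuation, phase aberration, elevational beam structure, or
multiple scattering; point elements without directivity; plug rather
than parabolic flow; one bubble per labeled cell; no bubble
destruction, translation, or bubble–bubble interaction; deterministic
(non-inertial) bubble emissions; and image-domain (not RF-level)
synthesis for the long vascular stacks.  Passing tests therefore show
that the *processing chain* behaves as designed under its stated
physics, not that a particular in vivo contrast value would be
reproduced.
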