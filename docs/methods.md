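# Methods

## Imaging model

An unfocused light-field microscope samples the 4D phase space of the
emitted light: a microlens of pitch p at an image plane maps pupil angle
(u, v) to sensor pixel (u, v) inside the macro-pixel behind it. The
package represents the optics as a *phase-space PSF*: a bank of 2D
kernels, one per angle and depth, so that angular view (u, v) of a volume
is

    view(u, v) = Σ_z  volume[z] ∗ kernel[u, v, z].

The kernels are an approximation, not a wave-optics derivation:

* `geometric` — angle (u, v) sits on a uniform grid over the pupil disk
  (indices outside the NA circle carry zero kernels). A point at depth z
  appears shifted by z·tanθ_uv (θ from sinθ = ρ·NA/n, n the immersion
  index, default 1.518) and blurred by a Gaussian whose σ grows linearly
  with |z| at the sub-aperture rate NA/a (a = angular side). The focal σ
  floor is half a view pixel so kernels stay renderable on the grid.
* `quasi_wave` — the same with the diffraction floor σ₀ = 0.61λ/NA.

Kernels are normalised so each depth carries unit total energy across all
angles; forward projection therefore conserves flux for
interior-supported objects, and the backprojector is the exact adjoint
(correlation with the same kernels; boundary handling is zero-padded
convolution). A rigorous externally computed PSF can be loaded from file
in the same layout.

Scan rendering adds one physical detail the realignment arithmetic alone
does not fix: every view sample integrates over the full microlens
aperture. On the 3× fine grid this is a 3×3 box filter applied before
sub-phase sampling. Without it the nine galvo frames of a sub-pixel-sharp
scene carry wildly unequal energies; with it each frame integrates all
emitted light and the frame-energy identity (nine frames = 9× the middle
frame) holds exactly.

Conventions fixed here (both configurable upstream): row-major 0-based
indexing, angle (0, 0) at the top-left pupil corner with the chief-ray
view at the centre index; the frame with galvo offset (−1/3, −1/3) pitch
fills fine-grid sub-phase (0, 0).

## Virtual scanning network

The network maps scale-1 views to scale-3 views with a global bicubic
residual: the learned path only adds the high-frequency detail that
cross-angle aliasing makes recoverable. Three linear branches decouple
the input — per-angle spatial features (shared 3×3 convolution), a
light-field branch on the macro-pixel-interleaved (h·a, w·a) grid with
dilation-a convolutions (so taps align across angles), and a 1×1 learned
mix over all angles that suppresses independent per-angle noise.
K interaction blocks fuse the three in the light-field domain with local
residual connections; the K block outputs concatenated with the two
companion features give (K+2)·C channels, squeezed back to C by a 1×1
convolution and leaky ReLU (slope 0.1), then a per-angle convolution to
scale² channels and a pixel shuffle produce the ×3 output.

Training: L1 loss (fluorescent scenes are sparse; L1 favours sharp
zeros), Adam with β₁ = 0.9, β₂ = 0.999, learning rate 2×10⁻⁴ halved
every 10 epochs, ~40 epochs, patch pairs of 25 → 75 pixels, intensities
normalised by the mean of per-stack maxima (one divisor shared by both
members of a pair, recorded for inversion). One global seed drives
weight initialisation, patch cropping and shuffling. Whole-field
inference tiles the 153-pixel field into nine 69-pixel patches with
stride 42, predicts 207-pixel outputs, and blends them with per-axis
sigmoid ramps w(d) = 1/(1 + exp(−(d − o/2)/(o/8))) over the overlap o,
renormalised to sum to exactly 1 at every output pixel.

Implementation notes: the layer stack is pure numpy (im2col convolutions
with explicit backward passes, hand-rolled Adam) in float32; gradients
are verified against finite differences in the test suite. The
upsampling head is zero-initialised, so an untrained network *is* the
bicubic baseline and optimisation can only improve on it. Extractor
convolutions carry biases ("linear" is read as "no nonlinearity", not
"no affine term"). Desk-scale studies in the tests and the acceptance
script use a reduced configuration — 5×5 angles, C = 16, K = 2,
8-pixel patches, 150–200 patch pairs, 12–20 epochs, learning rate
2×10⁻³ — sized so a full study runs in about a minute on one CPU; the
higher rate compensates for the ~25× smaller number of optimisation
steps relative to the full-scale schedule. Exact per-layer kernel
sizes of the original design are not reproduced; the defaults above
match all its printed tensor shapes.

## Tomography and digital adaptive optics

Reconstruction is multiplicative Richardson–Lucy jointly over all angular
views — the Poisson maximum-likelihood iteration, with an ε = 10⁻⁹
division guard, uniform initialisation carrying the measured energy, and
a default of 5–8 iterations (phase-space RL converges in few iterations;
quantitative experiments here use 6–16 as noted). Non-negativity and
flux conservation follow from the multiplicative form; equivalence with
an explicit sparse system-matrix RL oracle is asserted to 10⁻⁵ relative
in the tests.

DAO estimates one lateral shift per angular view by subpixel
cross-correlation (upsampled matrix-multiplication correlation,
1/50 px quantisation by default, 1/100 in the recovery experiments)
between each measured view and its re-projection
from the current volume estimate. The shift grid samples the pupil
gradient of the wavefront; a global tilt only translates the volume, so
the mean shift over in-pupil angles is removed (gauge fixing).
Re-estimates inside the reconstruction loop are *incremental*: the
re-projection is rendered with the current correction applied and the
measured residual is added to it, which converges where a from-scratch
re-estimate against a partially corrected volume stalls. Shifts are
applied in the view domain with an explicit bilinear gather whose adjoint
is exactly the negated shift — scipy's interpolation shift breaks
adjointness at boundaries, which the RL update relies on. Optional
Zernike-gradient smoothing (least squares over modes 4..N, tilt
excluded) is off by default.

Identifiability caveat: a per-angle shift field proportional to tanθ_uv
is indistinguishable from an axial displacement of the object, and
jointly free bead positions can absorb part of a dense random shift
field. Shift recovery is therefore quantified in the regime the method
is used in — a sparse set of aberrated angles against a consensus of
clean ones, or a smooth low-order wavefront — where recovery is within
0.1 px for shifts up to 2 px.

## Metrics

All formulas follow the definitions stated in the module docstrings:
SNR in dB from the energy ratio; SSIM with Gaussian 11×11 (σ = 1.5)
valid-mode windows and constants (0.01L)², (0.03L)² on data normalised to
L = 1, the 3D variant reshaping (u, v, y, x) views to a (y, x, angle)
stack with 11³ windows; Pearson correlation; decorrelation analysis as
the single masked cross-correlation d(r) with k_c the radius of its
highest peak (ties resolve to the largest radius; the high-pass filter
refinement bank of the original decorrelation method is deliberately
omitted); FRC with 1-pixel rings, no curve smoothing, linear
interpolation at the 1/7 crossing (the degenerate DC ring is set to 1);
FWHM from a four-parameter least-squares Gaussian fit, 2√(2 ln 2)·σ.
The SSIM implementation is cross-checked against
`skimage.metrics.structural_similarity` in the tests but does not call
it.

## Voltage analysis

ΔF/F₀ uses the mean of the entire series as F₀ (appropriate for sparse
spiking; a drifting baseline would bias it — the median subtraction in
detection absorbs slow drift). Spikes are strict local maxima (plateaus
resolve to their first sample) of the 40 ms-median-subtracted trace above
an absolute threshold, 2% by default at 500 Hz sampling. Spike widths
come from Gaussian fits to peak-aligned windows; edge spikes are excluded
and counted. Firing rates use centred 1 s sliding windows. Peak-time
maps apply a spatial Gaussian (σ = 9 voxels at full scale; tests use
smaller σ on small grids), per-voxel wavelet denoising (symlet-4,
soft universal threshold — the specific wavelet is this package's
choice), a quadratic spline on a 10× upsampled time grid, and report the
rising-edge crossing at 50% of the voxel's amplitude; voxels that never
cross are NaN-masked. The spike-recovery study models an ROI-integrated
photon budget of 5×10⁴ photons/frame (a few thousand voxels at the
dim-baseline end of the camera model), where 3% spikes at a 2% threshold
are detected with precision and recall ≥ 0.9.

## Synthetic data: what it does and does not emulate

The generators emulate geometry and statistics, not biology: beads are
unit-flux Gaussians (sub-voxel beads represented by their flux),
tubulins are persistent random-walk tubes with Gaussian cross-section
FWHM equal to their diameter, noise is pixel-independent mixed
Poisson–Gaussian with unit camera gain by default (30 photons at peak →
30 counts, where read-noise variance 5 is severe), and aberrations are
low-order Zernike phase maps acting as per-angle shifts. Real data add
scattering background, sample motion, structured noise, lattice
rotation/distortion of the microlens grid and model mismatch of the true
wave-optics PSF; passing tests therefore validate the computational
pipeline, not instrument-level performance. Desk-scale studies use 5×5
angles and 24–32-lens fields; the measured virtual-scanning gains
(≈ +0.4–2 dB view-domain SNR, ≈ +0.002–0.01 3D-SSIM, ≈ +0.3–0.8 dB after
reconstruction, seed-dependent) are accordingly far below full-scale
instrument figures, while the qualitative orderings (network > bicubic;
scanned reconstruction out-resolves snapshot reconstruction by ~1.4× in
bead FWHM) are stable across seeds.

## Known limitations

* The PSF ignores diffraction ringing, spherical aberration with depth,
  and vignetting; angles outside the pupil are simply zero.
* No motion compensation across the nine scan frames; scenes are assumed
  static within a scan (the virtual-scanning path exists precisely to
  avoid this assumption at acquisition time).
* DAO corrects lateral view shifts only — higher-order intra-aperture
  blur is not modelled — and inherits the axial gauge ambiguity above.
* The Gaussian read-noise variance is interpreted in digital units at
  the stated bit depth; absolute camera gain is arbitrary, so
  reconstruction SNRs against ground truth fit a global scale factor.
* Square microlens lattices only; no rectification of rotated or
  distorted grids.
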