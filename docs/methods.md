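# Methods

This note documents the models, conventions and numerical choices behind
tomopipe, and what its synthetic-data experiments do and do not demonstrate.

## Coordinate and angle conventions

Volumes are indexed `[x, y, z]`; the tilt axis is always the volume **y** axis
and the beam direction at zero tilt is **z**. Orientations are intrinsic,
active **ZXZ** Euler triplets `(tdrot, tilt, narot)` in degrees: a particle
with pose R looks like `rotate(reference, R)` in its box. STAR export maps the
triplet to the ZYZ `(rot, tilt, psi)` convention through the rotation matrix;
the identity maps to all-zero angles, and the mapping is round-trip tested.
Particle tables store 1-based integer voxel positions plus sub-voxel shifts;
everything in memory is 0-based, converted only at the I/O boundary.

Defocus is in micrometers, positive = underfocus, everywhere. Negative input
values (the acquisition-software convention) are normalized on construction.
The z-height defocus handedness is an explicit ±1 parameter, never guessed,
because it is dataset-dependent in practice.

## Forward model (simulator)

The generator emulates a dose-symmetric single-axis acquisition: a specimen
volume containing rotated copies of a density phantom (torus "bagel", sphere,
or a sum of displaced Gaussians) plus optional gold beads (default 5 nm
diameter at 10x phantom density, matching typical colloidal-gold fiducials).
Projections are parallel-beam line integrals computed by rotating the specimen
about y (linear interpolation) and summing along z — chosen over Fourier
slicing for simplicity and testability; the interpolation error is inside the
tolerance of every downstream check. Each projection is optionally
CTF-modulated at its per-image defocus and degraded with additive white
Gaussian noise; `degrade_to_snr` fixes the signal-variance/noise-variance
ratio within 2%.

Default acquisition: −45° to +45° in 3° increments (31 images), dose-symmetric
ordering in Hagen-style groups of 2 starting on the positive branch
(0, +3 | −3, −6 | +6, +9 | ...). The group size is a parameter because the
scheme family, not the group size, is what published acquisitions specify.
A `zero_tilt_dose` override reproduces hybrid schemes that spend extra dose
(e.g. 15 e⁻/Å²) on the untilted image; the STAR export writes the resulting
non-uniform pre-exposure values.

What the simulator does **not** model: beam-induced local motion, detector
MTF and Poisson counting, thick-specimen multiple scattering, tilt-dependent
thickness attenuation, and misalignment of the tilt series (stacks are emitted
aligned). Passing tests therefore show algorithmic correctness under an
idealized image-formation model, not robustness to the full error budget of
real acquisitions.

## CTF

`ctf_value` implements the standard weak-phase model
`CTF(f) = −sqrt(1−A²)·sin χ − A·cos χ` with
`χ = π λ Δz f² − (π/2) Cs λ³ f⁴ + φ`. Phase flipping inverts the sign of
Fourier components where the CTF is negative; when the CTF has a constant sign
over the whole band (first zero beyond Nyquist) there is no contrast inversion
to correct and the image is returned unchanged. Tilted images can be corrected
in overlapping strips (256 px, 50% cosine-blended overlap) with the defocus
gradient `Δz(x) = Δz0 + h·x·tan θ` perpendicular to the tilt axis; strip
blending loses a small amount of power at seams where adjacent sign maps
differ, which is inherent to the approach.

The internal defocus estimator is a deliberately simple 1D grid search: the
rotationally averaged log power spectrum is background-subtracted with a cubic
polynomial and correlated against the model CTF² over 5–90% of Nyquist.
No astigmatism. A normalized fit score below 0.4 flags the estimate
unreliable; pure-noise spectra score well below this, CTF-bearing spectra
well above. Recovery on simulated micrographs is exact to within one grid
step (0.05 µm) across 1.5–5 µm.

## Reconstruction

Weighted back-projection: each image is 1D-filtered along x (ramp |k| by
default multiplied with a Hamming window; plain ramp and no filter are
options — the apodization choice is ours, configurable). Images are
zero-padded to twice their width before filtering so the ramp kernel does not
wrap, and the zero-DC property of the ramp is enforced exactly per filtered
line. Back-projection is voxel-driven gathering with linear interpolation;
because tilt is about y this reduces to a 1D gather per (x, z) plane.
The slab's x, y axes coincide with the image axes at 0°, z is thickness,
rotation center at the volume center.

Per-particle reconstruction cuts a padded window (one box of context on each
side) around the particle's projected position at every tilt, optionally
phase-flips it at the particle's height-dependent defocus, ramp-filters, and
back-projects into the box. It matches a crop from the full reconstruction to
correlation > 0.99 (noise-free), which is the storage-saving contract that
makes reconstructing large unbinned tomograms unnecessary. Per-particle CTF
correction defaults on below binning 4 and off above, where the first CTF zero
leaves the band.

Binning is centered Fourier cropping; the volume mean is preserved exactly and
binning factors compose (`bin4 ∘ bin2 = bin8`). Denoising is the scalar
Perona–Malik edge-stopping diffusion (`g = 1/(1+(|∇I|/κ)²)`), conservative
flux differencing (voxel sum preserved to 1e-4), explicit steps bounded at
dt ≤ 0.15 for 3D stability — not the full tensor-driven anisotropic scheme of
larger packages, and named accordingly.

## Missing wedge

A `WedgeSpec` carries the tilt list; the Fourier mask treats the interval
between the extreme tilts as continuously covered (the standard missing-wedge
model) with central-section thickness of one Fourier voxel, so a single tilt
yields one central plane and ±45° yields 50% coverage. An optional cosine
soft edge (in Fourier voxels) widens support; soft-edged masks are what the
averaging tests use, because the hard boundary otherwise discards a thin
shell of genuinely sampled frequencies.

## Template matching

The engine computes, for every orientation of the search grid, the masked
locally normalized cross-correlation

    cc(v) = Σᵢ wᵢ (Tᵢ − T̄_w) D(v+i) /
            sqrt(Σᵢ wᵢ(Tᵢ−T̄_w)²) / sqrt(Σᵢ wᵢ D(v+i)² − (Σᵢ wᵢ D(v+i))²/W)

with all running sums through FFTs, bounded in [−1, 1] by Cauchy–Schwarz.
The rotated template is wedge-filtered **after** rotation because the wedge is
fixed in the tomogram frame. Normalization uses the rotated mask; since the
default mask is spherical (rotation-invariant within 1e-3), the local moments
are computed once and reused — detected, not assumed. The ε-guard on the local
variance is 1e-6 of the global variance; constant regions get cc = 0, never
NaN. Equal-CC ties resolve to the lowest linear voxel index and the lowest
orientation index (deterministic).

Chunked execution tiles the volume with an overlap of one template box and is
exact: chunked and unchunked maps agree to < 1e-5 (in double precision they
agree to rounding). FFTs run in float64 by default; a `precision="single"`
option exists for large exhaustive searches where the ~1e-4 score noise of
float32 is irrelevant. Padded FFT sizes are rounded up to 5-smooth integers.

Cone axes come from a deterministic golden-angle spiral over the spherical
cap of half-angle `cone_range/2` (cone_range is the **full** opening angle),
oversampled 1.4× relative to the bare `Ω/s²` count so the covering radius
stays well inside the nominal sampling step; grids need no seed. Symmetry
reduction removes members whose geodesic distance to a kept member, minimized
over the group orbit, is below half the smaller sampling step; the identity is
always kept.

Orientation-grid searches report the best grid member per voxel; peak
extraction computes map statistics once (over the valid region) before
selection, then greedily selects descending-CC peaks with spherical
non-maximum suppression, stopping at `mean + kσ` and/or a particle cap.
CC-map post-processing removes connected suprathreshold components (threshold
mean + 2σ) larger than a size bound — the "large island" bound is a tuning
knob, defaulting to 4× the template's suprathreshold volume. Gold-bead
erasing is polarity-agnostic matched filtering with a disc; grid-edge erasing
targets the largest low-intensity component touching the image border.

## Classification and averaging

Constrained alignment rotates the reference to each candidate (the local grid
composed onto the particle's current pose), imposes the particle's wedge on it
so both volumes live in the same sampled subspace, and maximizes masked
cross-correlation over shifts within a limit (≤ box/4), with parabolic
sub-voxel interpolation of the peak.

Noise-trap multi-reference alignment uses one (or more) structural references
plus traps: Gaussian noise low-passed at the reference band, scaled to the
reference's in-mask standard deviation. Traps stay fixed across iterations
(regeneration is an option): stable sinks are reproducible sinks. Traps work
because rotating a noise volume produces nearly independent candidates while
rotating a smooth reference does not, so the maximum over the search is
statistically larger for noise against a trap; the effect strengthens with a
dense, wide-band search, which is why the classification benchmark uses
10° local sampling over ±30° and a 2.5 Å band at 1 Å/voxel. An emptied class
keeps its previous reference with a warning.

Averaging is wedge-compensated in Fourier space:
`avg = IFFT[ Σᵢ FFT(Rᵢ⁻¹ Pᵢ) / max(Σᵢ Rᵢ⁻¹ Wᵢ, ε) ]` with ε = 1% of the
denominator maximum, preventing missing-wedge noise amplification. Optional
point-group symmetrization (C-groups, O) is applied last. Half sets split
even-odd by table row (deterministic; seeded random is an option) after final
class selection. FSC uses 1-voxel shells, an optional 5-voxel-soft spherical
mask, and reads resolution at the first 0.143 crossing with linear shell
interpolation; a curve that never crosses reports the Nyquist bound flagged
"not crossed". No phase-randomized mask correction is applied.

## Workflow engine

One module-named folder per configured step, one zero-padded item folder per
tilt-series/tomogram. SUCCESS markers are written atomically
(write-then-rename). A module is skipped when its global marker and all item
markers exist; a missing item marker re-runs exactly that item; deleting the
global marker while item markers remain is read as a deliberate request to
re-execute the whole module. Items are independent by contract — a failure is
recorded and siblings continue; the run report carries per-item status,
timing and failure reasons, and the process exits with a partial-success
status. Configuration is validated in full (unknown modules, unknown keys,
type mismatches) before any computation starts, because unattended runs are
long. Live mode watches a directory, closes a series at the expected image
count or after a per-series inactivity timeout (a per-file variant of the
threshold would be stricter; the per-series reading is the implemented one),
and reconstructs through the simplified path (bin by Fourier crop, WBP; no
motion/CTF steps). Cleanup removes only declared-temporary categories;
SUCCESS markers, tables and final maps are never candidates.

## Benchmark experiment sizes

The standard verification conditions (in `tomopipe.benchmarks`) are sized for
a single CPU: pose recovery uses 20 torus particles in 200×200×100 voxels,
±45°/3° wedge, SNR 0.5, a global 20° search (~2600 orientations);
classification uses 30 true + 30 noise boxes of 24³; the chunking check uses
128×128×64; FSC and CTF checks use 32³ volumes and 256² micrographs. The
recovery criterion counts a particle as found within 2 voxels and 20° of the
torus axis (the axis modulo sign is the only orientation observable of an
axially symmetric particle), and a false positive as a pick with no particle
within 2 voxels.

## Known limitations

No astigmatism or phase-plate fitting; no dose weighting (dose is metadata
only); no SIRT; no icosahedral/helical symmetry; no dual-axis geometry; no
GPU path (the chunking contract is kept, device parallelism is not); tilt
series are assumed aligned (no fiducial tracking). The defocus estimator is a
teaching-grade 1D fit, not a replacement for dedicated CTF packages.
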