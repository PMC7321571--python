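# Methods

This note records the models, algorithms, parameter choices and known
limitations of `dvcstrain`, in the spirit of a methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinate and sign conventions

Volumes are arrays indexed `(x, y, z)`, 0-based; `z` is the third axis
and the compression axis. The image center is the voxel-center centroid
`(n − 1)/2` per axis. Strain is dimensionless internally and reported in
microstrain (µε, ×10⁶); compression is negative. The von Mises
equivalent strain ε_eq is nonnegative by construction.

## Synthetic phantom

The generator emulates a micro-CT field of view across the osteochondral
interface, as a stand-in for real scans:

* two tissue regions split by a rough interface at a height fraction
  (default 0.5). The roughness is a Gaussian-filtered random surface
  (σ = 6 voxels laterally) scaled to a height SD of 8 µm — enough to make
  the interface non-planar at the sub-volume scale without destroying
  the slab geometry;
* dark ellipsoidal lacunae with uniformly random orientation and
  semi-axes drawn from 2.5–7.5 µm, at 1.5·10⁴ /mm³ in cartilage
  (chondrocyte lacunae) and 3·10⁴ /mm³ in mineralized tissue
  (osteocyte / hypertrophic-chondrocyte lacunae). These orders of
  magnitude follow published cell/lacuna densities for bovine articular
  cartilage and bone; no imaging study of this tissue quantifies the
  *visible* lacuna contrast, so the defaults are assumptions, not
  calibrations. Counts are Poisson in the region volume; lacunae are
  clipped to their host region;
* gray levels 20/90/170/40 (background, cartilage, mineralized, lacuna)
  on an arbitrary 8-bit-like scale, additive white Gaussian noise
  (default SD 3), and an optional edge-enhancement fringe mimicking
  propagation-based phase contrast, modeled as the z-derivative of the
  Gaussian-blurred label image scaled to a chosen amplitude (a bright/dark
  bipolar band at gray-level boundaries). No Fresnel-propagation physics
  is simulated;
* identical spec + seed gives bit-identical volumes.

What passing tests on phantoms do **not** show: performance on real
tomograms with reconstruction artifacts, beam hardening, ring artifacts,
spatially correlated noise, depth-dependent lacuna density, or marrow
space. The phantom's texture is idealized and its noise is white.

## Virtual deformation

`make_synthetic_pair` applies `diag(1, 1, 1 − s)` about the image center
(default s = 0.01, i.e. 10,000 µε axial compression) by inverse mapping
through voxel centers with Lanczos interpolation. The Lanczos kernel
order is a = 3 (the common default; the interpolant family is standard
but the order is our choice), with per-sample weight renormalization so
constants are reproduced; source positions that are exactly integral
bypass the kernel (floating-point `sinc` at integers is not exactly
zero). Voxels mapped from outside the domain are zeroed and flagged so
the correlation stage can exclude windows that touch them. Axis-aligned
maps use a fast separable path; full matrices use a general gather.
Ground truth is analytic: `u(x) = (M − I)(x − c)`, strain = sym(M − I).

The error protocols follow the physical workflow: deform the full
volume, then crop the volume of interest from the middle, so resampling
boundary effects stay outside the analyzed region.

## Rigid registration

NMI = (H(A) + H(B)) / H(A,B) on a 64-bin joint histogram with linear
(Parzen) soft binning, which removes most of the integer-lattice
artifacts of hard binning. Optimization: an integer translation seed
from FFT phase correlation, Powell refinement of the 6 rigid parameters
on a 2× mean-pooled pyramid level and then at full resolution
(histograms stride-subsampled 3× for speed), with rotations bounded to
±10°. Because soft binning slightly biases the continuous optimum off
the voxel lattice (~0.01 NMI), a final tie-break prefers the rounded
translation / zero rotation whenever its metric lies within 0.02 of the
optimum — a genuine half-voxel misalignment costs ~0.1 NMI on smooth
content, so the tie-break cannot mask real sub-voxel shifts.
Registration fails loudly on constant images.

## Denoising and labeling

Perona-Malik anisotropic diffusion with exponential conductance
exp(−(∇I/κ)²), 6-neighbor fluxes and zero-flux boundaries (mean exactly
conserved); default κ = 30 gray units, step λ = 1/6 (the 3D stability
limit), 10 iterations. Parameters are exposed because no single setting
suits all noise levels.

Region labeling is a gradient-magnitude watershed seeded by multi-Otsu
classes eroded away from boundaries (2 classes for tissue-only volumes,
3 when a background/marrow phase is present); explicit markers
(−1 = unmarked, else the desired label) override the automatic seeds and
are guaranteed to keep their label. Marrow/background voxels are zeroed
before correlation.

## DVC engine

Local approach: cubic sub-volumes on a regular grid symmetric about the
image center; node spacing = size × (1 − overlap), default final overlap
0 (node spacing equals the sub-volume size — the protocol default here;
overlap is config-exposed). Per node:

1. integer displacement from the peak of the FFT-computed zero-normalized
   cross-correlation (skimage's `match_template`) inside a search window
   centered on the trilinearly interpolated previous-pass displacement
   (±4 voxels on predictor passes). The coarsest multipass pass is seeded
   by one full-volume FFT phase correlation — the global integer shift —
   and searches ±size/8 around it; a lone `correlate_pass` without any
   predictor falls back to ±half sub-volume. The global seed costs two
   large FFTs once instead of a half-window search per node, which
   dominates runtime on a single CPU while preserving robustness to bulk
   motion. Small search windows (≤ ~11³ offsets) use an exact
   spatial-domain ZNCC with integral-image normalization instead of the
   FFT — identical values, far cheaper when only a few voxels of range
   are needed;
2. sub-voxel seed by separable 3-point Gaussian fits of the correlation
   peak (log-parabola; plain parabola when a neighbor is non-positive);
3. gray-level refinement: translation-only Lucas-Kanade iteration against
   the cubic-spline-interpolated deformed volume, with per-iteration
   photometric gain/offset normalization, the constant template gradient
   as Jacobian, and divergence fallback to the seed. The 3-point fit
   alone shows the classic pull-to-integer bias (several hundredths of a
   voxel); the gray-level stage reduces sub-voxel error to ~0.01 voxel
   on textured volumes, which the shift-recovery tests check directly.

Validity rules: flat (zero-variance) templates, correlation below the
threshold (default cc ≥ 0.1), windows whose search range touches
out-of-domain voxels (a blocked true peak silently biases the match),
and peaks on the *searchable* window border are invalid. Exact
correlation ties — translation-degenerate texture such as a perfectly
flat interface with no lacunae in the window — are resolved toward the
smallest displacement magnitude, then lexicographically — a peak
pressed against the physical image boundary is kept (no further search
is possible) but gets no sub-voxel stencil on that side. A perfect match
(cc = 1 to machine precision) short-circuits all sub-voxel machinery to
an exact zero offset: the logarithm of floating-point noise ratios
carries no information, and this makes the zero-strain identity test
exactly zero rather than ~10⁻⁷ µε. Invalid nodes are excluded from every
statistic, never interpolated silently.

The multipass cascade (default 80-72-64-56 → 48 voxels) seeds each pass
with the previous field, preventing peak loss at the final size. The
uncertainty size sweep runs single passes per size with a ±6-voxel
search window: registered or zero-strain pairs carry displacements far
below a sub-volume, and the tighter window is substantially faster than
the no-predictor default.

## Strain and equivalent strain

ε_ij = ½(∂u_i/∂x_j + ∂u_j/∂x_i) by central differences on the node grid,
one-sided at grid borders and next to invalid nodes; a node keeps its
strain only if all nine displacement gradients exist. Linear fields are
differentiated exactly, so an affine deformation is recovered without
discretization error. The gradient scheme is our choice — commercial
local-DVC packages do not document theirs.

ε_eq = (2/3)·√(3(e_xx² + e_yy² + e_zz²)/2 + 3(γ_xy² + γ_xz² + γ_yz²)/4)
from deviatoric normal components and engineering shears γ_ij = 2ε_ij.
It is invariant under hydrostatic offsets and absolutely homogeneous of
degree one — both asserted numerically in the suite.

## Error protocols

MAER/SDER follow the convention of the uncertainty literature for DVC in
bone: per node the average of the absolute values of the six strain
components (minus the analytic truth, for the synthetic protocol); mean
and SD (population SD, ddof = 0) over nodes. Statistics are reported per
region over nodes whose entire sub-volume lies inside that region
(strict inclusion); strain itself is differentiated on the full grid so
near-interface nodes retain neighbors. Region × size combinations with
no valid node are flagged absent, never reported as zero. Histograms of
ε_eq use 100 µε bins by default (binning unstated in the literature);
frequencies are normalized to sum to 1 and the peak is the modal bin
center.

## Indentation

Phases of a load-controlled record are segmented by the load plateau
(within 1% of max; a plateau shorter than 2 samples counts as a
triangle-wave apex, giving an empty hold). S = dP/dh is the least-squares
slope over the top 20% of the unloading load range by default — "initial
unloading stage" quantified by a config-exposed fraction. Hardness is
max load over the nominal flat-punch base area (2,500 µm² for a
50 µm × 50 µm tip) unless a calibrated effective area is supplied: with
the nominal area, 45 mN gives 18 MPa by definition, so published
cartilage hardness values of order 1-2 MPa imply an effective contact
area an order of magnitude larger than the tip base — the area
definition is deliberately left to the user. Compression stress uses the
nominal plug cross-section, strain the nominal cartilage thickness, and
the relaxation drop is the stress difference between the start and end
of the displacement hold.

## Problem sizes

The acceptance computation uses a 256³ phantom cropped to 240³, the full
80-72-64-56-48 cascade and zero final overlap (125 final nodes, 27
interior); the test suite exercises the same chain at 96³–192³ with
scaled-down cascades where the property under test does not require
protocol scale. These sizes are the package's own defaults for
desk-scale verification.

## Known limitations

* Translation-only sub-voxel refinement: no affine window shape
  functions, so very large strains (≫1%) bias the match slightly; the
  multipass predictor mitigates but does not remove this.
* No finite-strain (Green-Lagrange) formulation and no stress.
* No deformable registration, beam-hardening or ring-artifact handling.
* The rigid-registration optimizer is local; initial misalignments far
  beyond ±10° or half the image are out of scope.
* Interface-straddling windows show larger displacement error than
  intra-region windows (mixed texture and edge ringing); the
  strict-inclusion mask keeps them out of per-region statistics, and
  windows whose edge plane abuts the interface can be buffered out with
  the mask's ``margin`` option.
* Sub-voxel error has a phase-dependent bias component of a few
  hundredths of a voxel (the deformed image is itself an interpolated
  object); divided by the node spacing this bounds strain accuracy, so
  fine node spacings trade accuracy for spatial resolution.
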