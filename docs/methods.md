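# Methods

This note documents the models, algorithms and numerical choices behind the
package, in the spirit of a methods appendix: what is computed, under which
assumptions, with which defaults, and what the synthetic validation does and
does not demonstrate.

## Geometry conventions

Volumes are cubic grids with axes `(a0, a1, a2)`.  The electron beam runs
along `a2` at zero tilt; the goniometer tilt axis is `a1` (the second axis
of every image); tilting rotates the volume right-handedly in the
`(a0, a2)` plane about the box centre `n/2`.  Voxel `(0, 0, 0)` is the grid
corner; phantom and model coordinates place the particle origin at the box
centre.  All interpolation is bilinear/trilinear.  Protein is positive
density everywhere (stain exclusion is not modelled), so simulated images,
maps and rasterized models share one sign convention.

The projector is materialized as a sparse bilinear-interpolation matrix per
tilt angle, so back-projection is the *exact* linear adjoint of projection
(verified to float precision in the tests).  Exact adjointness keeps the
iterative refinement's energy bookkeeping consistent; it also means
integrated density is conserved to well under 1% for particles supported
inside the inscribed sphere (content in the box corners is clipped by
rotation, as with any fixed-grid rotation).

## Phantoms

Antibody-like phantoms are unions of soft-edged solids: Fab arms are
dumbbells ~85 A long and ~45 A wide, half-Fc (CH2+CH3) units are prolate
rods ~80 x 30 A, and the intact Fc of a Y-phantom is an ellipsoid.  Class
layouts: Y (2 Fab + Fc), X (2 Fab + 2 separated half-Fc), i (1 Fab + 1
half-Fc), bowtie (2 Fab).  Default overall extents are ~190 A (X), ~192 A
(Y) and ~110 A (i).

Conformational parameters are the CH3–CH3 mass-centre distance, the
CH2–CH2 (rod-axis) angle, and the Fab–Fab distance and angle; default
values are 90 A / 100° / 85 A / 130°.  For the X class the half-Fc rods
are placed so the density centroid of the *outer half* of each rod — which
sits `3L/16` from the rod centre for a prolate ellipsoid — realizes the
requested CH3–CH3 distance exactly; phantom construction is therefore its
own ground truth.  Ensemble sampling draws these parameters from
user-specified Gaussians (or two-component mixtures); conformations whose
domains would leave the imaging window are redrawn, which truncates the
sampled distribution exactly the way a finite window truncates real data —
recovery comparisons therefore use the realized sample truth, not the
nominal distribution.

## Image formation

Each tilt image is the parallel-beam line integral of the phantom at the
goniometer angle, multiplied in Fourier space by the phase-contrast CTF

    ctf(f) = -( sqrt(1 - A^2) sin(chi) + A cos(chi) ),
    chi(f) = pi lambda dz f^2 - (pi/2) Cs lambda^3 f^4,

with defocus `dz` (underfocus positive, default 0.75 um within the
0.6–0.9 um acquisition range), 120 kV, spherical aberration 2.0 mm and
amplitude contrast 0.1 (typical values for this instrument class; both
configurable).  CTF correction is by phase flipping (sign correction)
only; amplitude restoration is out of scope.

Per-tilt translational jitter is uniform in ±`jitter_max` px per axis.
Detector noise is white Gaussian with standard deviation
`noise_sigma x (clean-image RMS contrast)`, injected **at the acquisition
sampling, before binning** — as on a real detector — so the bin-by-2
working images (default: 256 px at 1.48 A binned to 128 px at 2.96 A) carry
four times the per-pixel variance SNR of the acquired frames.  Electron
dose is not modelled explicitly; `noise_sigma` subsumes it.

## Reconstruction and refinement

The ab initio map is the direct back-projection of the tilt images at their
goniometer angles.  `refine` builds its per-iteration maps with
ramp-weighted (Ram-Lak, capped at `n_tilt/2`) back-projection: the plain
smearing accumulation has a 1/r point-spread halo that caps the
map-to-phantom correlation near 0.5, while the weighted form with wedge
filling exceeds 0.9.  Plain accumulation remains available
(`back_project(..., weighted=False)`) and is the defined adjoint.

Each refinement iteration: (1) back-project at current shifts, (2) fill the
missing wedge, (3) reproject at every angle, (4) low-pass both reprojection
and raw image with the scheduled Gaussian cutoff, (5) update each image's
shift by normalized cross-correlation with parabolic sub-pixel
interpolation (ties break toward the smallest shift).  The automatic
schedule runs cutoffs geometrically from 16x to 4x the pixel size (never
finer than Nyquist); the first half of the iterations masks with a soft
circular disc (particle radius + 20%), later iterations with a soft
particle-shaped mask obtained by thresholding the 20 A-filtered map at
background + 2 sd, dilating 2 px and smoothing with a 3 px Gaussian edge.

Two empirically load-bearing choices deserve emphasis:

* **Masks act on the reference side only.**  Multiplying the raw image (or
  re-masking the reference in 2D) with the current-estimate particle mask
  makes the correlation peak self-confirming: alignment errors freeze at
  the ~1 px level and can drift.  Masking the map in 3D before
  reprojection, and the reference with the static circular disc early on,
  recovers noise-free jitter to <0.3 px.
* **Convergence is declared at a max shift change of 0.05 px** (or 15
  iterations).  A looser 0.5 px criterion stops while the filter schedule
  is still coarse and leaves ~0.5 px alignment errors on the table.

The divergence guard aborts when more than half the images pin at the shift
search limit.  Wedge filling runs every iteration (5 POCS cycles) and once
more at the end (>= 20 cycles); the final map is stored raw and display-
filtered at 20 A.

A per-particle note on gauges: a 3D translation of the particle produces a
perfectly consistent pattern of image shifts (`cos(theta) t0 + sin(theta)
t2` in-plane, constant `t1` along the tilt axis), so alignment can only
determine shifts up to this three-parameter family; in practice the data
anchor it to well under a pixel.

## Missing wedge

The ±45° tilt range leaves a wedge of Fourier space unmeasured, elongating
reconstructions along the beam axis.  `fill_missing_wedge` iterates
projection onto constraint sets: real-space positivity and a loose
spherical support, alternated with exact restoration of the measured
Fourier coefficients (50 cycles by default).  Measured data are preserved
to float precision by construction.  The support is the one genuinely
sensitive ingredient: it is estimated from the 20 A-smoothed map,
thresholded a quarter of the way from background to peak, using only the
in-plane extent (the beam-axis extent is inflated by the artifact being
corrected), with a 30% margin.  Inside `refine` the circular-mask radius is
used instead — a per-iteration estimate from a blurry early map can clip
real density and destabilize alignment.  On a sphere phantom the
axial/lateral FWHM elongation drops from ~2.1 to ~1.2.

## Resolution

FSC between odd- and even-index half-map reconstructions, shells one
Fourier voxel wide, resolution read at the first downward crossing of 0.5
(conservative) and 0.143 (gold standard) with linear interpolation between
shells; a curve that never crosses returns the Nyquist wavelength with a
warning.  Model-to-map FSC rasterizes the placed model at a chosen
resolution (Gaussian atoms, FWHM = nominal resolution, mass-weighted
amplitudes) and reports the same crossings.  Because the odd/even halves
share the alignment, these half-map numbers are consistency estimates, not
fully independent gold-standard ones — same as the underlying experimental
protocol.

## Rigid-body docking

Each rigid body is docked by an exhaustive z-y-z Euler grid (default 15°,
optionally restricted to rotations near the current pose) with the best
translation per rotation found by FFT cross-correlation on a coarsened
grid, followed by Nelder–Mead refinement of the Euler angles at full
resolution (2° tolerance) with sub-voxel parabolic translation
interpolation.  Scores are normalized by the local map energy under a
spherical window of the body's radius (floored at 25% of its maximum), so
bodies match shape rather than chase the brightest region.  The CH2 and
CH3 halves of one heavy chain dock as a single rod.  For multi-domain maps
with twin domains (two Fabs, two half-Fc rods), the pipeline fits greedily
in decreasing-mass order and subtracts each fitted body's amplitude-scaled
density before the next fit; purely independent fits remain the function's
default.  Connectivity between linked bodies is *checked*, not enforced:
the closest approach between fitted bodies must not exceed the fully
extended loop length at 3.8 A per residue (default 16 hinge residues).
Domains are never deformed.  Docking targets the 20 A display-filtered map
with a 15 A model rasterization; fitting the raw weighted back-projection
instead biases rod placements a few Angstrom outward.

## Conformational statistics

Domain positions are mass centres; orientations are far-end vectors — the
unit vector between the centroids of the backbone atoms within 10 A of the
two extremes of the domain's principal axis, signed to point away from the
particle centre.  Distances use the closed interval convention for range
fractions; angles are folded to [0, 180]°.  Ensembles are superposed on
their CH2-domain backbones by least-squares (Kabsch); all reported
geometry is rigid-motion invariant, so this alignment affects display only.
Histograms default to 12 bins over the data range; fits are least squares
on bin counts (1- or 2-term Gaussian with moment-based initialization and
a fixed restart ladder, or a sixth-degree polynomial); non-convergence is
flagged on the result, never raised.

## Validation scales

The test-suite and acceptance computations run at documented reduced sizes
chosen to keep a desk-scale run in minutes: alignment recovery at the full
instrument geometry (256 px at 1.48 A, binned by 2; 61 tilts), resolution
and wedge properties on 64-voxel boxes, and the 50-particle ensemble loop
at a 96 px acquisition box binned to a 48-voxel working grid (4.5 A/px).
The simulator emulates projection geometry, CTF, jitter and white detector
noise; it does not emulate stain-layer physics, substrate adhesion,
beam-induced motion, dose damage, or particle overlap.  Passing tests
demonstrate the internal consistency and parameter recovery of the
algorithms under this noise model — not performance on real micrographs,
where structured background and contamination make tracking and masking
harder.

## Known limitations

* Translational alignment only: per-image rotational and defocus
  refinement are out of scope, as are dual-axis schemes and fiducial
  tracking.
* The alignment reference contains each image's own noise; at detector
  SNR well below 0.5 (without binning gains) this self-correlation locks
  residual shift errors around a pixel.
* Gaussian-atom rasterization ignores element-specific scattering factors
  beyond mass weighting.
* The reference IgG model is synthetic (built to the canonical crystal
  arrangement); accession-backed numbers require supplying the real
  structure file.
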