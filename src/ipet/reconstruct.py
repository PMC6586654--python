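"""Per-particle 3D reconstruction from a single-axis tilt series.

The reconstruction follows the individual-particle electron tomography
scheme: an ab initio map is obtained by direct back-projection of the tilt
images at their goniometer angles, then each image is iteratively re-aligned
(translation only) against projections of the current map under a
coarse-to-fine schedule of Gaussian low-pass filters and soft masks.  The
unmeasured "missing wedge" of Fourier space left by the limited tilt range
is filled by a projection-onto-constraint-sets (POCS) iteration alternating
real-space positivity/support with Fourier-space data consistency.
Resolution is estimated by Fourier shell correlation between maps
back-projected from the odd- and even-index halves of the aligned series
(0.5 and 0.143 crossings).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .io import TiltSeries, Volume3D
from ._projector import back_project_single, project

__all__ = [
    "FilterSchedule",
    "WedgeSpec",
    "FSCCurve",
    "ReconstructionResult",
    "back_project",
    "auto_filter_schedule",
    "align_translation",
    "refine",
    "fill_missing_wedge",
    "split_half_maps",
    "fsc",
    "resolution_at_threshold",
    "bandpass_filter",
    "gaussian_lowpass",
]


# ---------------------------------------------------------------------------
# schedules and specs
# ---------------------------------------------------------------------------

@dataclass
class FilterSchedule:
    """Per-iteration filter/mask parameters for iterative refinement.

    ``cutoffs_A`` are Gaussian low-pass cutoffs (A), non-increasing across
    iterations (coarse to fine).  The first half of the iterations use a
    circular soft mask of ``circ_radius_px``; later iterations switch to a
    particle-shaped mask derived by thresholding the current map at
    background mean + ``particle_thresh_sd`` standard deviations, dilating
    ``dilate_px`` and smoothing with a Gaussian soft edge.
    """

    cutoffs_A: np.ndarray
    mask_kinds: list                      # 'circular' | 'particle'
    circ_radius_px: float
    circ_soft_px: float = 3.0
    particle_thresh_sd: float = 2.0
    dilate_px: int = 2
    particle_soft_px: float = 3.0

    def __post_init__(self) -> None:
        self.cutoffs_A = np.asarray(self.cutoffs_A, dtype=float)
        if np.any(np.diff(self.cutoffs_A) > 1e-9):
            raise ValueError("low-pass cutoffs must be non-increasing")
        if self.circ_soft_px < 1 or self.particle_soft_px < 1:
            raise ValueError("soft edge widths must be >= 1 px")
        if len(self.mask_kinds) != len(self.cutoffs_A):
            raise ValueError("one mask kind per iteration required")

    def __len__(self) -> int:
        return len(self.cutoffs_A)


@dataclass
class WedgeSpec:
    """Measured tilt range defining the missing wedge complement."""

    tilt_min: float = -45.0
    tilt_max: float = 45.0

    def __post_init__(self) -> None:
        if self.tilt_min >= self.tilt_max:
            raise ValueError("tilt_min must be below tilt_max")

    def measured_mask(self, n: int) -> np.ndarray:
        """Boolean mask of measured Fourier voxels for an n^3 volume.

        A frequency (f0, f2) direction is measured iff some tilt in the
        acquired range places a central section through it; sections rotate
        about the f1 axis, so the criterion is on the in-plane angle of
        (f0, f2) folded to (-90, 90] deg.  The f1 axis itself (f0=f2=0) is
        always measured.
        """
        f = np.fft.fftfreq(n)
        f0 = f[:, None, None]
        f2 = f[None, None, :]
        ang = np.degrees(np.arctan2(f2, f0))
        ang = np.where(ang > 90.0, ang - 180.0, ang)
        ang = np.where(ang <= -90.0, ang + 180.0, ang)
        mask = (ang >= self.tilt_min) & (ang <= self.tilt_max)
        mask = mask | ((np.abs(f0) < 1e-12) & (np.abs(f2) < 1e-12))
        return np.broadcast_to(mask, (n, n, n)).copy()


@dataclass
class FSCCurve:
    """Fourier shell correlation per spatial-frequency shell."""

    shell_freq: np.ndarray   # cycles/A
    correlation: np.ndarray

    def __post_init__(self) -> None:
        self.shell_freq = np.asarray(self.shell_freq, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.shell_freq.shape != self.correlation.shape:
            raise ValueError("shell_freq and correlation must match in length")


@dataclass
class ReconstructionResult:
    map: Volume3D                      # raw reconstructed map
    map_filtered: Volume3D             # 20 A display-filtered map
    shifts_px: np.ndarray              # final per-image alignment shifts
    fsc_halves: FSCCurve
    resolution_05: float               # A at the FSC=0.5 crossing
    resolution_0143: float             # A at the FSC=0.143 crossing
    iteration_log: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _radial_freq(shape, pixel_size: float) -> np.ndarray:
    axes = [np.fft.fftfreq(s, d=pixel_size) for s in shape]
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    return np.sqrt(sum(g ** 2 for g in grids))


def gaussian_lowpass(data: np.ndarray, cutoff_A: float,
                     pixel_size: float) -> np.ndarray:
    """Gaussian low-pass: amplitude falls to exp(-1/2) at 1/cutoff_A."""
    if cutoff_A <= 0:
        raise ValueError("cutoff must be positive")
    freq = _radial_freq(data.shape, pixel_size)
    h = np.exp(-0.5 * (freq * cutoff_A) ** 2)
    return np.fft.ifftn(np.fft.fftn(data) * h).real


def bandpass_filter(image: np.ndarray, low_cut_A: float, high_cut_A: float,
                    pixel_size: float, soft_frac: float = 0.2) -> np.ndarray:
    """Band-pass with Gaussian rolloff outside [1/low_cut_A, 1/high_cut_A].

    ``low_cut_A`` is the long spatial-wavelength (low-frequency) edge and
    ``high_cut_A`` the short-wavelength edge, so ``low_cut_A > high_cut_A``
    in Angstrom.  The pass band is flat; the DC component is removed
    whenever the low edge excludes it.
    """
    if low_cut_A <= high_cut_A:
        raise ValueError("band inverted: need low_cut_A > high_cut_A (in A)")
    f_lo = 1.0 / low_cut_A
    f_hi = 1.0 / high_cut_A
    freq = _radial_freq(image.shape, pixel_size)
    h = np.ones_like(freq)
    w_lo = max(soft_frac * f_lo, 1e-12)
    w_hi = max(soft_frac * f_hi, 1e-12)
    below = freq < f_lo
    above = freq > f_hi
    h[below] = np.exp(-0.5 * ((freq[below] - f_lo) / w_lo) ** 2)
    h[above] = np.exp(-0.5 * ((freq[above] - f_hi) / w_hi) ** 2)
    if f_lo > 0:
        h.flat[0] = 0.0
    return np.fft.ifftn(np.fft.fftn(image) * h).real


def _circular_mask(shape, radius_px: float, soft_px: float) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) - s / 2.0 for s in shape],
                        indexing="ij", sparse=True)
    r = np.sqrt(sum(g ** 2 for g in grids))
    hard = (r <= radius_px).astype(float)
    return ndimage.gaussian_filter(hard, soft_px)


def _particle_mask(data: np.ndarray, thresh_sd: float, dilate_px: int,
                   soft_px: float) -> np.ndarray:
    """Soft particle-shaped mask by thresholding above background."""
    background = data[data <= np.percentile(data, 60)]
    thr = background.mean() + thresh_sd * background.std()
    hard = data > thr
    if not hard.any():
        return np.ones_like(data)
    if dilate_px > 0:
        hard = ndimage.binary_dilation(hard, iterations=dilate_px)
    return ndimage.gaussian_filter(hard.astype(float), soft_px)


def auto_filter_schedule(n_iterations: int, pixel_size: float,
                         box_size: int,
                         particle_radius_px: Optional[float] = None
                         ) -> FilterSchedule:
    """Generate the coarse-to-fine filter/mask schedule for refinement.

    Low-pass cutoffs follow a geometric progression from 16x to 4x the pixel
    size (never finer than the 2x-pixel Nyquist wavelength); the first half
    of the iterations use a circular soft mask whose radius defaults to the
    expected particle radius plus 20%, later iterations a particle-shaped
    mask derived from the current map.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    coarse = 16.0 * pixel_size
    fine = max(4.0 * pixel_size, 2.0 * pixel_size)
    if n_iterations == 1:
        cutoffs = np.array([coarse])
    else:
        cutoffs = np.geomspace(coarse, fine, n_iterations)
    cutoffs = np.maximum(cutoffs, 2.0 * pixel_size)
    if particle_radius_px is None:
        particle_radius_px = box_size / 3.0
    kinds = ["circular" if i < n_iterations / 2 else "particle"
             for i in range(n_iterations)]
    return FilterSchedule(cutoffs, kinds, circ_radius_px=1.2 * particle_radius_px)


# ---------------------------------------------------------------------------
# back-projection and alignment
# ---------------------------------------------------------------------------

def _aligned_image(image: np.ndarray, shift) -> np.ndarray:
    if np.any(np.asarray(shift) != 0):
        return ndimage.shift(image, shift, order=1, mode="constant")
    return image


def _ramp_weight(image: np.ndarray, n_angles: int) -> np.ndarray:
    """Ram-Lak-style radial weight along the in-plane axis perpendicular to
    the tilt axis, capped at n_angles/2 (standard weighted back-projection:
    compensates the 1/|f| point-spread of plain smearing)."""
    n = image.shape[0]
    f0 = np.fft.fftfreq(n)[:, None]
    w = np.minimum(np.abs(f0) * n, n_angles / 2.0)
    w[0, 0] = 0.5  # keep a fraction of DC so density stays positive overall
    return np.fft.ifft(np.fft.fft(image, axis=0) * w, axis=0).real


def back_project(series: TiltSeries, weighted: bool = False) -> Volume3D:
    """Ab initio map: accumulate each aligned image smeared along its beam.

    Linear in the series: scaling all images scales the map.  The per-image
    operation is the exact adjoint of the forward projection.  With
    ``weighted=True`` each image is first ramp-filtered perpendicular to the
    tilt axis (weighted back-projection), deconvolving the 1/r smearing
    halo of the plain accumulation.
    """
    if len(series) == 0:
        raise ValueError("cannot back-project an empty series")
    n = series.images.shape[1]
    acc = np.zeros((n, n, n))
    for img, angle, shift in zip(series.images, series.angles_deg,
                                 series.shifts_px):
        img = _aligned_image(img, shift)
        if weighted:
            img = _ramp_weight(img, len(series))
        acc += back_project_single(img, angle)
    acc /= len(series)
    origin = np.full(3, -(n / 2.0) * series.pixel_size)
    return Volume3D(acc, series.pixel_size, origin)


def align_translation(image: np.ndarray, reference: np.ndarray,
                      max_shift_px: float) -> np.ndarray:
    """Shift that best aligns ``image`` onto ``reference``.

    Maximizes the (mean-subtracted) cross-correlation over circular shifts
    within ``|shift| <= max_shift_px`` per axis, then refines the integer
    peak by parabolic interpolation.  Ties are broken towards the smallest
    |shift|.  Applying the returned shift to ``image`` aligns it onto the
    reference.
    """
    if image.shape != reference.shape:
        raise ValueError("image and reference must have the same shape")
    if image.std() == 0 or reference.std() == 0:
        raise ValueError("cannot align a flat (zero-variance) image")
    if max_shift_px >= min(image.shape) / 4:
        raise ValueError("max_shift must be below a quarter of the box")
    a = image - image.mean()
    b = reference - reference.mean()
    corr = np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))).real
    h, w = corr.shape
    m = int(np.floor(max_shift_px))
    # window of allowed integer shifts, centred on zero shift
    wins = np.fft.fftshift(corr)
    cy, cx = h // 2, w // 2
    window = wins[cy - m:cy + m + 1, cx - m:cx + m + 1]
    # deterministic tie-break: smallest |shift| wins on equal correlation
    dy, dx = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1),
                         indexing="ij")
    order = np.lexsort((dy.ravel() ** 2 + dx.ravel() ** 2, -window.ravel()))
    best = order[0]
    sy, sx = int(dy.ravel()[best]), int(dx.ravel()[best])

    def parabolic(c_m, c_0, c_p):
        denom = c_m - 2 * c_0 + c_p
        if abs(denom) < 1e-12:
            return 0.0
        delta = 0.5 * (c_m - c_p) / denom
        return float(np.clip(delta, -0.5, 0.5))

    iy, ix = sy + cy, sx + cx
    frac_y = parabolic(wins[iy - 1, ix], wins[iy, ix], wins[iy + 1, ix]) \
        if 0 < iy < h - 1 else 0.0
    frac_x = parabolic(wins[iy, ix - 1], wins[iy, ix], wins[iy, ix + 1]) \
        if 0 < ix < w - 1 else 0.0
    shift = np.array([sy + frac_y, sx + frac_x])
    norm = np.linalg.norm(shift)
    if norm > max_shift_px:
        shift *= max_shift_px / norm
    return shift


def split_half_maps(series: TiltSeries):
    """Back-project the odd- and even-index halves of an aligned series."""
    if len(series) < 4:
        raise ValueError("need at least 4 images to split into halves")
    idx = np.arange(len(series))
    halves = []
    for parity in (0, 1):
        sel = idx[idx % 2 == parity]
        sub = TiltSeries(series.images[sel], series.angles_deg[sel],
                         series.pixel_size, series.shifts_px[sel], series.ctf)
        halves.append(back_project(sub))
    return halves[0], halves[1]


# ---------------------------------------------------------------------------
# missing wedge
# ---------------------------------------------------------------------------

def _estimate_support_radius(values: np.ndarray, pixel_size: float) -> float:
    """Loose spherical support radius estimated from the map itself.

    The map is first smoothed to 20 A to suppress noise, then thresholded a
    quarter of the way from the background level to the peak (the faint
    smearing/wedge halo of a back-projection must not inflate the support).
    Only the in-plane (tilt-axis plane) extent is used — the beam-axis
    extent is inflated by the very wedge artifact the support is meant to
    suppress — and a 30% margin is added.
    """
    n = values.shape[0]
    smooth = gaussian_lowpass(values, 20.0, pixel_size)
    background = smooth[smooth <= np.percentile(smooth, 60)]
    thr = background.mean() + 0.25 * (smooth.max() - background.mean())
    above = np.argwhere(smooth > thr)
    if len(above) == 0:
        return n / 2.0 - 2.0
    r = np.linalg.norm(above[:, :2] - n / 2.0, axis=1).max()
    return float(min(1.3 * r + 3.0, n / 2.0 - 2.0))


def fill_missing_wedge(volume: Volume3D, wedge: WedgeSpec, n_iter: int = 50,
                       support_radius_px: Optional[float] = None) -> Volume3D:
    """Estimate the unmeasured wedge of Fourier space by POCS iteration.

    Alternates (i) real-space constraints — positivity and a loose spherical
    support — with (ii) Fourier-space data consistency, restoring the
    measured coefficients exactly on every cycle.  The measured region of
    the output therefore matches the input to float precision, while the
    wedge region is extrapolated; on a limited-tilt sphere reconstruction
    this strictly reduces the axial-over-lateral elongation artifact.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n = volume.values.shape[0]
    measured = wedge.measured_mask(n)
    f_data = np.fft.fftn(volume.values)
    if support_radius_px is None:
        support_radius_px = _estimate_support_radius(volume.values,
                                                     volume.pixel_size)
    support = _circular_mask(volume.values.shape, support_radius_px, 2.0)

    f = f_data.copy()
    for _ in range(n_iter):
        v = np.fft.ifftn(f).real
        v = np.clip(v, 0.0, None) * support
        f = np.fft.fftn(v)
        f[measured] = f_data[measured]
    return volume.with_values(np.fft.ifftn(f).real)


# ---------------------------------------------------------------------------
# FSC and resolution
# ---------------------------------------------------------------------------

def fsc(map_a: Volume3D, map_b: Volume3D) -> FSCCurve:
    """Fourier shell correlation between two maps (shell width 1 voxel)."""
    if map_a.values.shape != map_b.values.shape:
        raise ValueError("FSC requires equally shaped maps")
    if abs(map_a.pixel_size - map_b.pixel_size) > 1e-6:
        raise ValueError("FSC requires equal pixel sizes")
    n = map_a.values.shape[0]
    fa = np.fft.fftn(map_a.values)
    fb = np.fft.fftn(map_b.values)
    f = np.fft.fftfreq(n)
    radius = np.sqrt(f[:, None, None] ** 2 + f[None, :, None] ** 2
                     + f[None, None, :] ** 2) * n
    shell = np.minimum(np.round(radius).astype(int), n // 2)
    cross = np.bincount(shell.ravel(), (fa * np.conj(fb)).real.ravel(),
                        minlength=n // 2 + 1)
    pa = np.bincount(shell.ravel(), np.abs(fa).ravel() ** 2,
                     minlength=n // 2 + 1)
    pb = np.bincount(shell.ravel(), np.abs(fb).ravel() ** 2,
                     minlength=n // 2 + 1)
    denom = np.sqrt(pa * pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cross / denom, 0.0)
    freqs = np.arange(n // 2 + 1) / (n * map_a.pixel_size)
    return FSCCurve(freqs, corr)


def resolution_at_threshold(curve: FSCCurve, threshold: float,
                            pixel_size: Optional[float] = None) -> float:
    """Resolution (A) at the first downward threshold crossing of an FSC.

    Linearly interpolates between shells.  If the curve never falls below
    the threshold the Nyquist wavelength is returned with a warning.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    freq = curve.shell_freq
    corr = curve.correlation
    start = 1 if freq[0] == 0 else 0
    if corr[start] < threshold:
        raise ValueError("FSC starts below the threshold")
    for i in range(start, len(corr) - 1):
        if corr[i] >= threshold > corr[i + 1]:
            t = (corr[i] - threshold) / (corr[i] - corr[i + 1])
            f_cross = freq[i] + t * (freq[i + 1] - freq[i])
            return float(1.0 / f_cross)
    nyquist_wavelength = 2.0 * pixel_size if pixel_size is not None \
        else float(1.0 / freq[-1])
    warnings.warn("FSC never fell below the threshold; returning Nyquist")
    return nyquist_wavelength


# ---------------------------------------------------------------------------
# iterative refinement
# ---------------------------------------------------------------------------

def refine(series: TiltSeries, schedule: Optional[FilterSchedule] = None,
           n_iterations: int = 15, max_shift_px: Optional[float] = None,
           wedge_fill_iters: int = 5, convergence_px: float = 0.05,
           display_filter_A: float = 20.0,
           weighted: bool = True) -> ReconstructionResult:
    """Iteratively align a tilt series to its global centre and reconstruct.

    Per iteration: back-project at the current shifts, fill the missing
    wedge, re-project at every tilt angle, low-pass/mask both projection and
    raw image per the schedule, and update each image's alignment shift.
    Terminates early once the largest per-image shift change drops below
    ``convergence_px``.  Aborts with a diagnostic if more than half the
    images pin at the shift search limit (divergence guard).

    The input series is not mutated; the result carries the final shifts,
    the raw and 20 A display-filtered maps, the odd/even half-map FSC and
    the 0.5 / 0.143 resolution estimates.
    """
    work = series.copy()
    n = work.images.shape[1]
    if schedule is None:
        schedule = auto_filter_schedule(n_iterations, work.pixel_size, n)
    n_iterations = len(schedule)
    if max_shift_px is None:
        max_shift_px = n / 8.0
    wedge = WedgeSpec(float(work.angles_deg.min()),
                      float(work.angles_deg.max()))

    log = []
    current = None
    for it in range(n_iterations):
        current = back_project(work, weighted=weighted)
        if wedge_fill_iters > 0:
            # the circular-mask radius is a safe loose support: per-iteration
            # auto-estimates from blurry early maps can clip real density
            current = fill_missing_wedge(
                current, wedge, wedge_fill_iters,
                support_radius_px=schedule.circ_radius_px)
        cutoff = schedule.cutoffs_A[it]
        if schedule.mask_kinds[it] == "circular":
            mask = _circular_mask((n, n), schedule.circ_radius_px,
                                  schedule.circ_soft_px)
            mask3 = None
        else:
            ref_map = gaussian_lowpass(current.values, display_filter_A,
                                       work.pixel_size)
            mask3 = _particle_mask(ref_map, schedule.particle_thresh_sd,
                                   schedule.dilate_px,
                                   schedule.particle_soft_px)
            mask = None

        map_vals = current.values if mask3 is None else \
            current.values * mask3
        max_change = 0.0
        pinned = 0
        new_shifts = work.shifts_px.copy()
        for i, angle in enumerate(work.angles_deg):
            ref = project(map_vals, angle)
            ref_f = gaussian_lowpass(ref, cutoff, work.pixel_size)
            img_f = gaussian_lowpass(work.images[i], cutoff, work.pixel_size)
            # Masks are applied on the reference side only: masking the raw
            # image with the current-estimate mask self-confirms the current
            # shifts.  In the particle-mask phase the reference is already
            # the projection of the 3D-masked map.
            if mask is not None:
                ref_f = ref_f * mask
            try:
                shift = align_translation(img_f, ref_f, max_shift_px)
            except ValueError:
                shift = work.shifts_px[i]
            if np.linalg.norm(shift) >= max_shift_px - 1e-6:
                pinned += 1
            max_change = max(max_change,
                             float(np.linalg.norm(shift - work.shifts_px[i])))
            new_shifts[i] = shift
        if pinned > 0.5 * len(work):
            raise RuntimeError(
                f"refinement diverged at iteration {it}: {pinned}/{len(work)} "
                f"images pinned at the +/-{max_shift_px:.1f} px search limit"
            )
        work.shifts_px = new_shifts
        log.append({"iteration": it, "cutoff_A": float(cutoff),
                    "mask": schedule.mask_kinds[it],
                    "max_shift_change_px": max_change,
                    "mean_abs_shift_px":
                        float(np.mean(np.linalg.norm(new_shifts, axis=1)))})
        if max_change < convergence_px:
            break

    final = back_project(work, weighted=weighted)
    if wedge_fill_iters > 0:
        final = fill_missing_wedge(final, wedge, max(wedge_fill_iters, 20),
                                   support_radius_px=schedule.circ_radius_px)
    filtered = final.with_values(
        gaussian_lowpass(final.values, display_filter_A, work.pixel_size))
    half_a, half_b = split_half_maps(work)
    curve = fsc(half_a, half_b)
    res_05 = resolution_at_threshold(curve, 0.5, work.pixel_size)
    res_0143 = resolution_at_threshold(curve, 0.143, work.pixel_size)
    return ReconstructionResult(final, filtered, work.shifts_px, curve,
                                res_05, res_0143, log)
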