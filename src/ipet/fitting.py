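"""Rigid-body docking of atomic domain models into density maps.

Domain-level conformations are obtained by docking each rigid domain of a
multi-domain model into a reconstructed map independently: an exhaustive
coarse search over rotations (translations scored by FFT cross-correlation
at every rotation) followed by local refinement.  Chain connectivity between
linked domains is checked against the fully extended length of the
connecting loop (3.8 A per residue) rather than enforced — the domains
themselves are never deformed.

A map-resolution-matched density can be rasterized from any model (Gaussian
atoms, mass-weighted) both for docking scores and for model-to-map FSC
resolution estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .io import AtomicModel, DomainPartition, Volume3D
from .reconstruct import FSCCurve, fsc, resolution_at_threshold

__all__ = [
    "RigidTransform",
    "FitResult",
    "LinkageRule",
    "rasterize_model",
    "rigid_fit",
    "fit_multibody",
    "model_map_fsc",
    "default_igg_linkage",
]

#: fully extended backbone length per residue (A), used to convert loop
#: residue counts into maximum terminus-terminus distances
EXTENDED_RESIDUE_LENGTH = 3.8


@dataclass
class RigidTransform:
    """Rotation (z-y-z Euler, degrees) about a pivot plus a translation (A)."""

    euler_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.euler_deg = np.asarray(self.euler_deg, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("zyz", self.euler_deg,
                                   degrees=True).as_matrix()

    def apply(self, coords: np.ndarray, pivot: np.ndarray) -> np.ndarray:
        pivot = np.asarray(pivot, float)
        return (np.asarray(coords) - pivot) @ self.matrix.T + pivot \
            + self.translation

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation (deg)."""
        return float(np.degrees(np.linalg.norm(
            Rotation.from_matrix(self.matrix).as_rotvec())))


@dataclass
class LinkageRule:
    """Connectivity constraint between two fitted bodies.

    ``max_distance`` is the allowed closest-approach distance (A) between the
    two bodies, typically ``loop_residues * 3.8``.
    """

    label_a: str
    label_b: str
    max_distance: float


@dataclass
class FitResult:
    transforms: dict                  # label -> RigidTransform
    correlations: dict                # label -> real-space correlation
    connectivity_ok: dict             # (label_a, label_b) -> bool
    fitted_model: AtomicModel

    def __post_init__(self) -> None:
        for label, c in self.correlations.items():
            if not -1.0 <= c <= 1.0 + 1e-9:
                raise ValueError(f"correlation for {label!r} outside [-1, 1]")


def default_igg_linkage(loop_residues: int = 16) -> list:
    """Fab-to-CH2 connectivity rules for an IgG via the hinge loop."""
    limit = loop_residues * EXTENDED_RESIDUE_LENGTH
    return [LinkageRule("Fab1", "HalfFcA_CH2", limit),
            LinkageRule("Fab2", "HalfFcB_CH2", limit)]


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _scatter_trilinear(coords_px: np.ndarray, weights: np.ndarray,
                       n: int) -> np.ndarray:
    grid = np.zeros((n, n, n))
    base = np.floor(coords_px).astype(int)
    frac = coords_px - base
    for corner in range(8):
        offs = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        idx = base + offs
        w = weights * np.prod(np.where(offs, frac, 1.0 - frac), axis=1)
        ok = np.all((idx >= 0) & (idx < n), axis=1)
        np.add.at(grid, tuple(idx[ok].T), w[ok])
    return grid


def rasterize_model(model: AtomicModel, pixel_size: float,
                    resolution_A: float, box_size: Optional[int] = None,
                    origin: Optional[np.ndarray] = None) -> Volume3D:
    """Rasterize an atomic model to a density map.

    Each atom contributes a 3D Gaussian whose full width at half maximum
    equals ``resolution_A`` and whose integral is proportional to the atomic
    mass, so the map integral is proportional to the total mass.  By default
    the box is sized to hold the model with a 1.2x resolution margin and the
    model's bounding centre sits at the box centre; pass ``box_size`` and
    ``origin`` to rasterize onto an existing map's grid.
    """
    if len(model) == 0:
        raise ValueError("cannot rasterize an empty model")
    if resolution_A < 2.0 * pixel_size:
        raise ValueError(
            f"resolution {resolution_A} A is finer than twice the pixel size"
        )
    coords = model.coords
    if box_size is None:
        span = coords.max(axis=0) - coords.min(axis=0)
        box_size = int(np.ceil((span.max() + 2.4 * resolution_A) / pixel_size))
        box_size += box_size % 2  # even box
    if origin is None:
        mid = 0.5 * (coords.max(axis=0) + coords.min(axis=0))
        origin = mid - (box_size / 2.0) * pixel_size
    origin = np.asarray(origin, float)
    coords_px = (coords - origin) / pixel_size
    grid = _scatter_trilinear(coords_px, model.masses, box_size)
    sigma_px = (resolution_A / 2.3548) / pixel_size
    grid = ndimage.gaussian_filter(grid, sigma_px)
    return Volume3D(grid, pixel_size, origin)


# ---------------------------------------------------------------------------
# rigid-body docking
# ---------------------------------------------------------------------------

def _bin_volume(values: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return values
    n = values.shape[0]
    m = n // factor
    trimmed = values[:m * factor, :m * factor, :m * factor]
    return trimmed.reshape(m, factor, m, factor, m, factor).mean(axis=(1, 3, 5))


def _shift_mask(n: int, pixel_size: float, search_A: float) -> np.ndarray:
    s = np.fft.fftfreq(n) * n * pixel_size  # shift in A per FFT index
    r = np.sqrt(s[:, None, None] ** 2 + s[None, :, None] ** 2
                + s[None, None, :] ** 2)
    return r <= search_A + 1e-9


def _local_energy(values: np.ndarray, radius_px: float) -> np.ndarray:
    """Map energy under a spherical window at every translation (for NCC).

    The window approximates the body's footprint; using a sphere makes the
    normalization rotation-independent so it is computed once per fit.
    """
    n = values.shape[0]
    g = np.arange(n)
    g = np.minimum(g, n - g)  # circular distance
    r = np.sqrt(g[:, None, None] ** 2 + g[None, :, None] ** 2
                + g[None, None, :] ** 2)
    window = (r <= radius_px).astype(float)
    energy = np.fft.ifftn(np.fft.fftn(values ** 2)
                          * np.conj(np.fft.fftn(window))).real
    energy = np.clip(energy, 0.0, None)
    # floor the normalization: a window hanging off the particle edge must
    # not turn a sliver of overlap into a spuriously high score
    return np.sqrt(np.maximum(energy, 0.25 * energy.max()))


def _best_translation(raster: np.ndarray, f_target: np.ndarray,
                      mask: np.ndarray, pixel_size: float,
                      denom: Optional[np.ndarray] = None):
    """(shift_A, score) maximizing the (optionally locally normalized)
    cross-correlation within the mask.

    ``corr[d] = sum_x target[x] raster[x - d]``: the peak index is the
    translation to apply to the raster (and the body it came from).
    """
    corr = np.fft.ifftn(f_target * np.conj(np.fft.fftn(raster))).real
    if denom is not None:
        corr = corr / denom
    corr_masked = np.where(mask, corr, -np.inf)
    flat = int(np.argmax(corr_masked))
    idx = np.array(np.unravel_index(flat, corr.shape))
    n = corr.shape[0]
    # parabolic sub-voxel refinement per axis (circular neighbours)
    frac = np.zeros(3)
    for ax in range(3):
        lo = list(idx); hi = list(idx)
        lo[ax] = (idx[ax] - 1) % n
        hi[ax] = (idx[ax] + 1) % n
        c_m, c_0, c_p = corr[tuple(lo)], corr[tuple(idx)], corr[tuple(hi)]
        denom = c_m - 2 * c_0 + c_p
        if abs(denom) > 1e-12:
            frac[ax] = float(np.clip(0.5 * (c_m - c_p) / denom, -0.5, 0.5))
    shift_vox = np.where(idx > n // 2, idx - n, idx) + frac
    return shift_vox * pixel_size, float(corr[tuple(idx)])


def _euler_grid(step_deg: float) -> np.ndarray:
    phis = np.arange(0.0, 360.0, step_deg)
    thetas = np.arange(0.0, 180.0 + 1e-9, step_deg)
    psis = np.arange(0.0, 360.0, step_deg)
    grid = []
    for th in thetas:
        # at the poles phi and psi are degenerate; keep one of them
        local_phis = phis if 0 < th < 180 else np.array([0.0])
        for ph in local_phis:
            for ps in psis:
                grid.append((ph, th, ps))
    return np.array(grid)


def _normalized_correlation(a: np.ndarray, b: np.ndarray) -> float:
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.sum(a * b) / (na * nb))


def rigid_fit(domain_model: AtomicModel, target_map: Volume3D,
              angular_step_deg: float = 15.0,
              translation_search_A: float = 20.0,
              resolution_A: Optional[float] = None,
              max_rotation_deg: float = 180.0,
              refine_tol_deg: float = 2.0):
    """Dock a rigid domain into a density map.

    Exhaustively scans rotations on a z-y-z Euler grid of ``angular_step_deg``
    (optionally restricted to rotations of magnitude ``max_rotation_deg``
    about the domain's current pose), scoring every translation within
    ``translation_search_A`` of the current position by FFT cross-correlation
    on a coarsened grid, then refines the best rotation locally
    (Nelder-Mead on the Euler offsets) at full resolution.  Deterministic.

    Returns ``(RigidTransform, correlation)`` where the transform pivots
    about the domain's mass centre and the correlation is the normalized
    real-space overlap at the optimum.
    """
    if angular_step_deg > 30.0:
        raise ValueError("angular_step_deg must be <= 30 deg")
    if target_map.values.max() <= 0 or not np.any(target_map.values):
        raise ValueError("cannot fit into an empty map")
    n = target_map.values.shape[0]
    px = target_map.pixel_size
    if resolution_A is None:
        resolution_A = max(15.0, 2.0 * px)
    pivot = domain_model.mass_center()

    ds = 1
    while n // (ds * 2) >= 24 and (n % (ds * 2) == 0):
        ds *= 2
    coarse_vals = _bin_volume(target_map.values, ds)
    nc = coarse_vals.shape[0]
    f_coarse = np.fft.fftn(coarse_vals)
    mask_coarse = _shift_mask(nc, px * ds, translation_search_A)
    f_full = np.fft.fftn(target_map.values)
    mask_full = _shift_mask(n, px, translation_search_A)
    # Local-energy normalization keeps the body from chasing the brightest
    # density region regardless of shape agreement.  The window must track
    # the body: roll the energy map so index d is the energy around the
    # body's pivot displaced by d.
    body_radius_A = float(np.linalg.norm(domain_model.coords - pivot,
                                         axis=1).max()) + resolution_A / 2.0
    p0_full = np.round((pivot - target_map.origin) / px).astype(int)
    denom_full = np.roll(_local_energy(target_map.values, body_radius_A / px),
                         -p0_full, axis=(0, 1, 2))
    p0_coarse = np.round(p0_full / ds).astype(int)
    denom_coarse = np.roll(_local_energy(coarse_vals, body_radius_A / (px * ds)),
                           -p0_coarse, axis=(0, 1, 2))

    def raster_values(rot_matrix, grid_n, grid_px, origin):
        coords = (domain_model.coords - pivot) @ rot_matrix.T + pivot
        moved = AtomicModel(
            coords, domain_model.masses, domain_model.elements,
            domain_model.chain_ids, domain_model.res_ids,
            domain_model.res_names, domain_model.atom_names,
            domain_model.backbone,
        )
        return rasterize_model(moved, grid_px,
                               max(resolution_A, 2.0 * grid_px),
                               box_size=grid_n, origin=origin).values

    grid = _euler_grid(angular_step_deg)
    if max_rotation_deg < 180.0:
        keep = [np.degrees(np.linalg.norm(
            Rotation.from_euler("zyz", e, degrees=True).as_rotvec()))
            <= max_rotation_deg + 1e-6 for e in grid]
        grid = grid[np.asarray(keep)]
        if len(grid) == 0:
            grid = np.zeros((1, 3))

    best = None
    for euler in grid:
        rot = Rotation.from_euler("zyz", euler, degrees=True).as_matrix()
        vals = raster_values(rot, nc, px * ds, target_map.origin)
        _, score = _best_translation(vals, f_coarse, mask_coarse, px * ds,
                                     denom_coarse)
        if best is None or score > best[1]:
            best = (euler, score)

    def full_score(euler):
        rot = Rotation.from_euler("zyz", euler, degrees=True).as_matrix()
        vals = raster_values(rot, n, px, target_map.origin)
        shift, score = _best_translation(vals, f_full, mask_full, px,
                                         denom_full)
        return shift, score, vals

    # local refinement of the Euler angles at full resolution
    def objective(euler):
        _, score, _ = full_score(euler)
        return -score

    res = minimize(objective, np.asarray(best[0], float),
                   method="Nelder-Mead",
                   options={"xatol": refine_tol_deg, "fatol": 1e-12,
                            "maxiter": 60, "initial_simplex":
                                _initial_simplex(best[0], angular_step_deg)})
    euler_opt = res.x
    shift, _, vals = full_score(euler_opt)
    shifted = ndimage.shift(vals, shift / px, order=1, mode="constant")
    correlation = _normalized_correlation(shifted, target_map.values)
    return RigidTransform(euler_opt, shift), correlation


def _initial_simplex(center, step):
    center = np.asarray(center, float)
    simplex = [center]
    for ax in range(3):
        v = center.copy()
        v[ax] += 0.5 * step
        simplex.append(v)
    return np.array(simplex)


def _min_distance(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial import cKDTree
    return float(cKDTree(a).query(b, k=1)[0].min())


def fit_multibody(model: AtomicModel, partition: DomainPartition,
                  target_map: Volume3D, linkage_rules: Sequence[LinkageRule],
                  angular_step_deg: float = 15.0,
                  translation_search_A: float = 25.0,
                  max_rotation_deg: float = 180.0,
                  resolution_A: Optional[float] = None,
                  labels: Optional[Sequence[str]] = None,
                  subtract_fitted: bool = False) -> FitResult:
    """Dock every rigid domain of a partitioned model independently.

    Each labelled body keeps its internal geometry exactly (rigid motion
    only) and is fit with :func:`rigid_fit` starting from its current pose;
    ``max_rotation_deg`` and ``translation_search_A`` bound the search
    around that pose.  Afterwards each linkage rule is checked: the
    closest-approach distance between the two fitted bodies must not exceed
    the extended loop length.  Hinge and unassigned atoms ride along
    unmoved.

    With ``subtract_fitted=True`` the bodies are fit greedily in order of
    decreasing mass and each fitted body's density is subtracted from the
    target before the next fit, which keeps similar-sized domains from
    claiming the same density region.
    """
    if labels is None:
        # one rigid body per domain, with CH2/CH3 halves of the same chain
        # riding together (a half-Fc docks as a single rod)
        groups: dict = {}
        for l in partition.domain_labels():
            if l == "hinge":
                continue
            key = l.split("_CH")[0] if "_CH" in l else l
            groups.setdefault(key, []).append(l)
        bodies = [(key, tuple(ls)) for key, ls in groups.items()]
    else:
        bodies = [(l, (l,)) if isinstance(l, str) else ("+".join(l), tuple(l))
                  for l in labels]

    def body_mask(parts):
        m = np.zeros(len(model), dtype=bool)
        for l in parts:
            m |= partition.mask(l)
        return m

    seen = np.zeros(len(model), dtype=bool)
    for _, parts in bodies:
        m = body_mask(parts)
        if np.any(seen & m):
            raise ValueError("overlapping body assignments")
        seen |= m

    if subtract_fitted:
        bodies = sorted(bodies, key=lambda b: -model.masses[
            body_mask(b[1])].sum())
    work_map = target_map.copy() if subtract_fitted else target_map
    transforms: dict = {}
    correlations: dict = {}
    fitted_coords = model.coords.copy()
    for name, parts in bodies:
        mask = body_mask(parts)
        body = model.subset(mask)
        transform, corr = rigid_fit(
            body, work_map, angular_step_deg, translation_search_A,
            resolution_A, max_rotation_deg,
        )
        transforms[name] = transform
        correlations[name] = corr
        moved = transform.apply(body.coords, body.mass_center())
        fitted_coords[mask] = moved
        if subtract_fitted:
            from dataclasses import replace as _replace
            placed = _replace(body, coords=moved)
            claimed = rasterize_model(
                placed, work_map.pixel_size,
                max(resolution_A or 15.0, 2.0 * work_map.pixel_size),
                box_size=work_map.values.shape[0], origin=work_map.origin)
            # scale the subtraction to the map's local amplitude
            num = float(np.sum(claimed.values * work_map.values))
            den = float(np.sum(claimed.values ** 2))
            scale = max(num / den, 0.0) if den > 0 else 0.0
            work_map.values = work_map.values - scale * claimed.values

    from dataclasses import replace
    fitted = replace(model, coords=fitted_coords)

    connectivity: dict = {}
    for rule in linkage_rules:
        a = fitted.coords[partition.mask(rule.label_a)]
        b = fitted.coords[partition.mask(rule.label_b)]
        connectivity[(rule.label_a, rule.label_b)] = bool(
            _min_distance(a, b) <= rule.max_distance)
    return FitResult(transforms, correlations, connectivity, fitted)


def model_map_fsc(model: AtomicModel, target_map: Volume3D,
                  resolution_for_raster: float = 15.0):
    """FSC between a placed model's rasterization and a map.

    Returns ``(FSCCurve, resolution_05, resolution_0143)``; resolutions are
    NaN when the curve starts below the corresponding threshold.
    """
    raster = rasterize_model(
        model, target_map.pixel_size, resolution_for_raster,
        box_size=target_map.values.shape[0], origin=target_map.origin,
    )
    curve = fsc(raster, target_map)
    out = []
    for thr in (0.5, 0.143):
        try:
            out.append(resolution_at_threshold(curve, thr,
                                               target_map.pixel_size))
        except ValueError:
            out.append(float("nan"))
    return curve, out[0], out[1]
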