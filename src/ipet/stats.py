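"""Conformational-ensemble statistics for multi-domain particles.

Implements the domain-geometry measurements used to quantify antibody
flexibility: mass centres, inter-domain distances, far-end orientation
vectors and inter-domain angles, CH2-based least-squares superposition of an
ensemble, histogram fitting (1/2-term Gaussian, sixth-degree polynomial) and
range fractions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GeometryRecord",
    "HistogramFit",
    "mass_center",
    "pair_distance",
    "domain_axis",
    "pair_angle",
    "align_ensemble",
    "fit_histogram",
    "fraction_in_range",
    "measure_igg_geometry",
]


@dataclass
class GeometryRecord:
    """Per-particle conformational geometry (distances in A, angles in deg)."""

    fab_fab_distance: float
    fab_fab_angle: float
    ch3_ch3_distance: float
    ch2_ch2_angle: float
    class_label: str = ""

    def __post_init__(self) -> None:
        for name in ("fab_fab_distance", "ch3_ch3_distance"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("fab_fab_angle", "ch2_ch2_angle"):
            v = getattr(self, name)
            if np.isfinite(v) and not 0.0 <= v <= 180.0:
                raise ValueError(f"{name} must lie in [0, 180] deg")

    def as_dict(self) -> dict:
        return {
            "fab_fab_distance": self.fab_fab_distance,
            "fab_fab_angle": self.fab_fab_angle,
            "ch3_ch3_distance": self.ch3_ch3_distance,
            "ch2_ch2_angle": self.ch2_ch2_angle,
            "class_label": self.class_label,
        }


@dataclass
class HistogramFit:
    """Result of fitting a parametric curve to a histogram."""

    model_kind: str                 # gauss1 | gauss2 | poly6
    parameters: dict
    bin_edges: np.ndarray
    counts: np.ndarray
    residual_ss: float
    converged: bool = True

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        p = self.parameters
        if self.model_kind == "gauss1":
            return _gauss1(x, p["amplitude"], p["mean"], p["sd"])
        if self.model_kind == "gauss2":
            return (_gauss1(x, p["amplitude1"], p["mean1"], p["sd1"])
                    + _gauss1(x, p["amplitude2"], p["mean2"], p["sd2"]))
        if self.model_kind == "poly6":
            return np.polyval(p["coefficients"], x)
        raise ValueError(self.model_kind)


def mass_center(model, partition, label: str) -> np.ndarray:
    """Mass-weighted centre (A) of the atoms carrying ``label``."""
    mask = partition.mask(label)
    if not np.any(mask):
        raise ValueError(f"domain {label!r} selects no atoms")
    return np.average(model.coords[mask], axis=0, weights=model.masses[mask])


def pair_distance(center_a, center_b) -> float:
    """Euclidean distance (A) between two points."""
    a = np.asarray(center_a, float)
    b = np.asarray(center_b, float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("pair_distance requires finite inputs")
    return float(np.linalg.norm(a - b))


def domain_axis(model, partition, label: str, cap_radius: float = 10.0,
                particle_center: Optional[np.ndarray] = None) -> np.ndarray:
    """Unit orientation vector of a domain from its backbone far ends.

    The domain's backbone atoms are projected onto their principal axis; the
    centroids of the atoms within ``cap_radius`` (A) of the two extremes
    define the vector, which is then signed to point away from the particle
    centre (the whole model's mass centre by default).
    """
    mask = partition.mask(label) & model.backbone
    pts = model.coords[mask]
    if len(pts) < 3:
        raise ValueError(f"domain {label!r} has fewer than 3 backbone atoms")
    centered = pts - pts.mean(axis=0)
    # principal axis = leading right singular vector
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9:
        raise ValueError(f"domain {label!r} is degenerate (zero extent)")
    axis0 = vt[0]
    t = centered @ axis0
    lo_cap = pts[t <= t.min() + cap_radius]
    hi_cap = pts[t >= t.max() - cap_radius]
    vec = hi_cap.mean(axis=0) - lo_cap.mean(axis=0)
    norm = np.linalg.norm(vec)
    if norm < 1e-9:
        raise ValueError(f"domain {label!r} far-end vector is degenerate")
    vec = vec / norm
    ref = model.mass_center() if particle_center is None else \
        np.asarray(particle_center, float)
    outward = pts.mean(axis=0) - ref
    if np.dot(vec, outward) < 0:
        vec = -vec
    return vec


def pair_angle(v1, v2) -> float:
    """Angle (deg, in [0, 180]) between two vectors."""
    a = np.asarray(v1, float)
    b = np.asarray(v2, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("pair_angle requires non-zero vectors")
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _kabsch(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition: returns (R, t) with R@x+t ~ target."""
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    h = (mobile - mu_m).T @ (target - mu_t)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_t - rot @ mu_m
    return rot, trans


def align_ensemble(models: Sequence, partition,
                   reference_labels=("HalfFcA_CH2", "HalfFcB_CH2")):
    """Superpose every model onto the first using reference-domain backbones.

    All models must share the partition's atom indexing (equal atom counts).
    Returns a list of ``(rotation_matrix, translation, rmsd)`` triples; the
    first entry is the identity.  Inter-domain distances and angles are
    invariant under this alignment (it is rigid).
    """
    if len(models) < 2:
        raise ValueError("align_ensemble needs at least 2 models")
    mask = np.zeros(len(models[0]), dtype=bool)
    for label in reference_labels:
        mask |= partition.mask(label)
    mask &= models[0].backbone
    if not mask.any():
        raise ValueError("reference selection is empty")
    ref_pts = models[0].coords[mask]
    out = []
    for m in models:
        if len(m) != len(models[0]):
            raise ValueError("ensemble models must have matching atom counts")
        rot, trans = _kabsch(m.coords[mask], ref_pts)
        moved = m.coords[mask] @ rot.T + trans
        rmsd = float(np.sqrt(np.mean(np.sum((moved - ref_pts) ** 2, axis=1))))
        out.append((rot, trans, rmsd))
    return out


def _gauss1(x, amplitude, mean, sd):
    return amplitude * np.exp(-0.5 * ((x - mean) / sd) ** 2)


# fixed restart offsets (fractions of the data range) for bounded retries
_RESTART_OFFSETS = (0.0, -0.15, 0.15, -0.3, 0.3)


def fit_histogram(values, model_kind: str, n_bins: int = 12) -> HistogramFit:
    """Least-squares fit of a parametric curve to a histogram of ``values``.

    Models: ``gauss1`` (single Gaussian), ``gauss2`` (two-term Gaussian;
    reported weights are the normalized component areas) and ``poly6``
    (sixth-degree polynomial).  Fitting is deterministic: initial guesses
    come from data moments, with a fixed list of restart offsets if the
    optimizer fails.  A fit that cannot converge is returned with
    ``converged=False`` rather than raising.
    """
    values = np.asarray(values, float)
    minimum = {"gauss1": 10, "gauss2": 30, "poly6": 30}
    if model_kind not in minimum:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    if len(values) < minimum[model_kind]:
        raise ValueError(
            f"{model_kind} fit needs >= {minimum[model_kind]} values, "
            f"got {len(values)}"
        )
    counts, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    spread = float(values.std())
    span = float(values.max() - values.min())

    if span == 0 or spread == 0:
        # degenerate data: no meaningful histogram shape to fit
        return HistogramFit(model_kind, {}, edges, counts,
                            residual_ss=float("nan"), converged=False)

    if model_kind == "poly6":
        coeffs = np.polyfit(centers, counts, deg=6)
        resid = counts - np.polyval(coeffs, centers)
        return HistogramFit("poly6", {"coefficients": coeffs}, edges, counts,
                            float(np.sum(resid ** 2)))

    if model_kind == "gauss1":
        model_fn = _gauss1
        base_p0 = [counts.max(), float(values.mean()), spread]
        lower = [0.0, values.min() - span, 1e-3 * spread]
        upper = [np.inf, values.max() + span, 10 * spread]
    else:  # gauss2: moment-style init splitting the sample at its median
        med = float(np.median(values))
        lo_half = values[values <= med]
        hi_half = values[values > med]
        model_fn = lambda x, a1, m1, s1, a2, m2, s2: (
            _gauss1(x, a1, m1, s1) + _gauss1(x, a2, m2, s2))
        base_p0 = [counts.max(), float(lo_half.mean()),
                   max(float(lo_half.std()), 0.1 * spread),
                   counts.max(), float(hi_half.mean()),
                   max(float(hi_half.std()), 0.1 * spread)]
        lower = [0.0, values.min() - span, 1e-3 * spread] * 2
        upper = [np.inf, values.max() + span, 10 * spread] * 2

    for offset in _RESTART_OFFSETS:
        p0 = list(base_p0)
        for i in range(1, len(p0), 3):
            p0[i] = np.clip(p0[i] + offset * span, lower[i], upper[i])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(model_fn, centers, counts, p0=p0,
                                    bounds=(lower, upper), maxfev=20000)
            break
        except (RuntimeError, ValueError):
            popt = None
    if popt is None:
        return HistogramFit(model_kind, {}, edges, counts,
                            residual_ss=float("nan"), converged=False)

    resid = counts - model_fn(centers, *popt)
    rss = float(np.sum(resid ** 2))
    if model_kind == "gauss1":
        params = {"amplitude": popt[0], "mean": popt[1], "sd": abs(popt[2])}
    else:
        a1, m1, s1, a2, m2, s2 = popt
        area1 = a1 * abs(s1)
        area2 = a2 * abs(s2)
        total = area1 + area2
        # report components ordered by mean, weights as normalized areas
        comps = sorted([(m1, abs(s1), a1, area1 / total),
                        (m2, abs(s2), a2, area2 / total)])
        params = {
            "mean1": comps[0][0], "sd1": comps[0][1],
            "amplitude1": comps[0][2], "weight1": comps[0][3],
            "mean2": comps[1][0], "sd2": comps[1][1],
            "amplitude2": comps[1][2], "weight2": comps[1][3],
        }
    return HistogramFit(model_kind, params, edges, counts, rss)


def fraction_in_range(values, lo: float, hi: float) -> float:
    """Fraction of values inside the closed interval ``[lo, hi]``."""
    values = np.asarray(values, float)
    if len(values) == 0:
        raise ValueError("fraction_in_range requires at least one value")
    if lo >= hi:
        raise ValueError("lo must be below hi")
    return float(np.mean((values >= lo) & (values <= hi)))


def measure_igg_geometry(model, partition, class_label: str = "") -> GeometryRecord:
    """Full geometry record of one fitted IgG-like model.

    Fab-Fab and CH3-CH3 distances are mass-centre distances; the Fab-Fab
    angle uses far-end vectors of the Fab domains and the CH2-CH2 angle the
    far-end vectors of the CH2 domains.  Domains absent from the partition
    yield NaN entries.
    """
    nan = float("nan")

    def maybe(fn, *args):
        try:
            return fn(*args)
        except (KeyError, ValueError):
            return None

    fab1 = maybe(mass_center, model, partition, "Fab1")
    fab2 = maybe(mass_center, model, partition, "Fab2")
    d_fab = pair_distance(fab1, fab2) if fab1 is not None and fab2 is not None \
        else nan
    ax1 = maybe(domain_axis, model, partition, "Fab1")
    ax2 = maybe(domain_axis, model, partition, "Fab2")
    a_fab = pair_angle(ax1, ax2) if ax1 is not None and ax2 is not None else nan

    ch3a = maybe(mass_center, model, partition, "HalfFcA_CH3")
    ch3b = maybe(mass_center, model, partition, "HalfFcB_CH3")
    d_ch3 = pair_distance(ch3a, ch3b) if ch3a is not None and ch3b is not None \
        else nan
    cx1 = maybe(domain_axis, model, partition, "HalfFcA_CH2")
    cx2 = maybe(domain_axis, model, partition, "HalfFcB_CH2")
    a_ch2 = pair_angle(cx1, cx2) if cx1 is not None and cx2 is not None else nan
    return GeometryRecord(d_fab, a_fab, d_ch3, a_ch2, class_label)
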