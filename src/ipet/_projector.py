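"""Parallel-beam projection geometry shared by the simulator and reconstructor.

Conventions (fixed across the package):

* volume axes are ``(a0, a1, a2)``; the electron beam travels along ``a2`` at
  zero tilt; the goniometer tilt axis is ``a1`` (the image's second axis);
* a projection image has axes ``(a0, a1)``;
* tilting by ``theta`` rotates the volume right-handedly in the ``(a0, a2)``
  plane about the box centre ``n/2``;
* interpolation is bilinear.

The rotation of each ``(a0, a2)`` plane is materialised as a sparse matrix so
that back-projection is the *exact* linear adjoint of projection — the pair
satisfies ``<P v, i> == <v, P^T i>`` to floating-point precision, which keeps
iterative refinement well behaved.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import sparse

__all__ = ["rotation_operator", "project", "back_project_single", "rotate_plane"]


@lru_cache(maxsize=512)
def rotation_operator(n: int, angle_deg: float) -> sparse.csr_matrix:
    """Sparse bilinear-interpolation operator rotating an (n, n) plane.

    Maps a flattened ``(a0, a2)`` plane (row-major) to the plane seen in the
    tilted frame: output pixel ``(i0, i2)`` samples the input at the inversely
    rotated position about the centre ``n/2``.  Samples falling outside the
    grid contribute zero (zero-padding boundary).
    """
    theta = np.deg2rad(angle_deg)
    c = n / 2.0
    i0, i2 = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    d0 = i0.ravel() - c
    d2 = i2.ravel() - c
    # inverse rotation of the output coordinates into the source frame
    y = c + np.cos(theta) * d0 - np.sin(theta) * d2
    x = c + np.sin(theta) * d0 + np.cos(theta) * d2

    y0 = np.floor(y).astype(np.int64)
    x0 = np.floor(x).astype(np.int64)
    fy = y - y0
    fx = x - x0

    rows, cols, vals = [], [], []
    out_idx = np.arange(n * n, dtype=np.int64)
    for dy, wy in ((0, 1.0 - fy), (1, fy)):
        for dx, wx in ((0, 1.0 - fx), (1, fx)):
            yy = y0 + dy
            xx = x0 + dx
            w = wy * wx
            ok = (yy >= 0) & (yy < n) & (xx >= 0) & (xx < n) & (w > 0)
            rows.append(out_idx[ok])
            cols.append((yy * n + xx)[ok])
            vals.append(w[ok])
    mat = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n * n, n * n),
    )
    return mat


def _as_planes(volume: np.ndarray) -> np.ndarray:
    """(a0, a1, a2) volume -> (a0*a2, a1) plane matrix."""
    n = volume.shape[0]
    return np.ascontiguousarray(volume.transpose(0, 2, 1)).reshape(n * n, n)


def _from_planes(planes: np.ndarray, n: int) -> np.ndarray:
    return planes.reshape(n, n, n).transpose(0, 2, 1)


def project(volume: np.ndarray, angle_deg: float) -> np.ndarray:
    """Line-integral projection of a cubic volume at one tilt angle.

    Returns an image with axes ``(a0, a1)``; the tilt axis is the image's
    second axis.
    """
    n = volume.shape[0]
    if volume.shape != (n, n, n):
        raise ValueError("projection requires a cubic volume")
    if not -90.0 < angle_deg < 90.0:
        raise ValueError("tilt angle must lie strictly inside (-90, 90) deg")
    op = rotation_operator(n, round(float(angle_deg), 6))
    rotated = op @ _as_planes(np.asarray(volume, dtype=np.float64))
    # rows are (i0, i2); integrate out the beam coordinate i2
    return rotated.reshape(n, n, n).sum(axis=1)


def back_project_single(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """Adjoint of :func:`project` for one image: smear along the beam.

    The image is replicated along the beam axis of the tilted frame and
    carried back to the volume frame by the transpose of the rotation
    operator, making this the exact adjoint of :func:`project`.
    """
    n = image.shape[0]
    if image.shape != (n, n):
        raise ValueError("back-projection requires a square image")
    op = rotation_operator(n, round(float(angle_deg), 6))
    # smear: rotated-frame planes S[(i0, i2), i1] = image[i0, i1] for all i2
    smear = np.repeat(np.asarray(image, dtype=np.float64), n, axis=0)
    planes = op.T @ smear
    return _from_planes(planes, n)


def rotate_plane(volume: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a cubic volume about the tilt axis (for tests and phantoms)."""
    n = volume.shape[0]
    op = rotation_operator(n, round(float(angle_deg), 6))
    return _from_planes(op @ _as_planes(np.asarray(volume, float)), n)
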