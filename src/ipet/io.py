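"""File I/O and in-memory containers for maps, tilt series and atomic models.

Density maps and image stacks are exchanged as MRC2014 files (written and
parsed through :mod:`gemmi`); tilt angles are plain one-angle-per-line text
files; atomic models are PDB files read with :mod:`biotite`; domain partition
rules are small key-value text files mapping chain/residue ranges to domain
labels.

Grid convention: voxel ``(0, 0, 0)`` sits at the grid corner, the geometric
centre of a box of ``n`` voxels is at ``n/2`` voxel units along each axis, and
all rotations are taken about that centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "Volume3D",
    "TiltSeries",
    "AtomicModel",
    "DomainPartition",
    "read_mrc",
    "write_mrc",
    "read_tilt_angles",
    "write_tilt_angles",
    "read_model",
    "read_partition_rules",
    "DOMAIN_LABELS",
]

#: canonical domain labels for an IgG-like particle
DOMAIN_LABELS = (
    "Fab1",
    "Fab2",
    "HalfFcA_CH2",
    "HalfFcA_CH3",
    "HalfFcB_CH2",
    "HalfFcB_CH3",
    "hinge",
    "unassigned",
)

# Monoisotopic-ish average atomic masses (Da) for the elements that occur in
# protein models; anything else falls back to carbon with a warning.
_ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "CA": 40.078, "MN": 54.938, "CU": 63.546, "NA": 22.990, "K": 39.098,
    "CL": 35.45,
}

# Average residue masses (Da) used when a model is reduced to one marker atom
# per residue (e.g. C-alpha traces): the marker then carries the whole residue.
_RESIDUE_MASS = {
    "GLY": 57.05, "ALA": 71.08, "SER": 87.08, "PRO": 97.12, "VAL": 99.13,
    "THR": 101.10, "CYS": 103.14, "LEU": 113.16, "ILE": 113.16, "ASN": 114.10,
    "ASP": 115.09, "GLN": 128.13, "LYS": 128.17, "GLU": 129.12, "MET": 131.19,
    "HIS": 137.14, "PHE": 147.18, "ARG": 156.19, "TYR": 163.18, "TRP": 186.21,
}
_MEAN_RESIDUE_MASS = 110.0


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected format."""


@dataclass
class Volume3D:
    """A 3D density grid with physical metadata.

    Parameters
    ----------
    values
        Density grid, axes ``(a0, a1, a2)``.  Reconstruction volumes are
        cubic; the beam axis of the tomographic geometry is ``a2`` and the
        tilt axis is ``a1``.
    pixel_size
        Voxel edge length in Angstrom.
    origin
        Physical position (Angstrom) of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    pixel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("Volume3D requires a 3D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def is_cubic(self) -> bool:
        n = self.values.shape[0]
        return self.values.shape == (n, n, n)

    def copy(self) -> "Volume3D":
        return Volume3D(self.values.copy(), self.pixel_size, self.origin.copy())

    def with_values(self, values: np.ndarray) -> "Volume3D":
        return Volume3D(np.asarray(values), self.pixel_size, self.origin.copy())


@dataclass
class TiltSeries:
    """An ordered single-axis tilt series of 2D images.

    ``shifts_px`` holds the current translational alignment state: the shift
    (in pixels, image axes) that moves each raw image onto the common particle
    centre.  It is mutated by iterative refinement.
    """

    images: np.ndarray  # (n_tilt, h, w)
    angles_deg: np.ndarray
    pixel_size: float
    shifts_px: Optional[np.ndarray] = None
    ctf: Optional[object] = None  # CTFParams, kept loose to avoid a cycle

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n, h, w) stack")
        if len(self.images) != len(self.angles_deg):
            raise ValueError(
                f"{len(self.images)} images but {len(self.angles_deg)} tilt angles"
            )
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("tilt angles must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.shifts_px is None:
            self.shifts_px = np.zeros((len(self.images), 2))
        else:
            self.shifts_px = np.asarray(self.shifts_px, dtype=float)
            if self.shifts_px.shape != (len(self.images), 2):
                raise ValueError("shifts_px must be (n_tilt, 2)")

    def __len__(self) -> int:
        return len(self.images)

    def copy(self) -> "TiltSeries":
        return TiltSeries(
            self.images.copy(), self.angles_deg.copy(), self.pixel_size,
            self.shifts_px.copy(), self.ctf,
        )


@dataclass
class AtomicModel:
    """Atom records of a (possibly coarse-grained) molecular model."""

    coords: np.ndarray        # (n, 3) Angstrom
    masses: np.ndarray        # (n,) Dalton
    elements: np.ndarray      # (n,) str
    chain_ids: np.ndarray     # (n,) str
    res_ids: np.ndarray       # (n,) int
    res_names: np.ndarray     # (n,) str
    atom_names: np.ndarray    # (n,) str
    backbone: np.ndarray      # (n,) bool

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("model coordinates must be finite")
        if np.any(self.masses <= 0):
            raise ValueError("atomic masses must be positive")

    def __len__(self) -> int:
        return len(self.coords)

    def subset(self, mask: np.ndarray) -> "AtomicModel":
        mask = np.asarray(mask)
        return AtomicModel(
            self.coords[mask], self.masses[mask], self.elements[mask],
            self.chain_ids[mask], self.res_ids[mask], self.res_names[mask],
            self.atom_names[mask], self.backbone[mask],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    pivot: Optional[np.ndarray] = None) -> "AtomicModel":
        """Return a rigidly moved copy: ``R @ (x - pivot) + pivot + t``."""
        pivot = np.zeros(3) if pivot is None else np.asarray(pivot, float)
        coords = (self.coords - pivot) @ np.asarray(rotation).T + pivot
        coords = coords + np.asarray(translation, float)
        return replace(self, coords=coords)

    def mass_center(self) -> np.ndarray:
        return np.average(self.coords, axis=0, weights=self.masses)


@dataclass
class DomainPartition:
    """A labelling of a model's atoms into rigid domains.

    ``labels`` maps a domain label to a boolean mask over the model's atoms.
    Masks are disjoint; atoms not covered by any rule are 'unassigned'.
    """

    labels: dict

    def __post_init__(self) -> None:
        masks = [np.asarray(m) for m in self.labels.values()]
        if masks:
            stacked = np.stack(masks)
            if np.any(stacked.sum(axis=0) > 1):
                raise ValueError("partition labels must be disjoint")

    def mask(self, label: str) -> np.ndarray:
        if label not in self.labels:
            raise KeyError(f"no domain label {label!r} in partition")
        return self.labels[label]

    def domain_labels(self) -> list:
        return [k for k in self.labels if k != "unassigned"]


# ---------------------------------------------------------------------------
# MRC I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def write_mrc(obj, path) -> None:
    """Write a :class:`Volume3D` or :class:`TiltSeries` as an MRC2014 file.

    Tilt-series stacks are stored as a 3D grid with the image index on the
    first axis; the companion ``.tlt`` angle file carries the angles.
    """
    import gemmi

    if isinstance(obj, Volume3D):
        values, pixel_size, origin = obj.values, obj.pixel_size, obj.origin
    elif isinstance(obj, TiltSeries):
        values, pixel_size, origin = obj.images, obj.pixel_size, np.zeros(3)
    else:
        raise TypeError("write_mrc accepts Volume3D or TiltSeries")

    arr = np.ascontiguousarray(values, dtype=np.float32)
    grid = gemmi.FloatGrid(arr)
    grid.unit_cell = gemmi.UnitCell(
        arr.shape[0] * pixel_size, arr.shape[1] * pixel_size,
        arr.shape[2] * pixel_size, 90.0, 90.0, 90.0,
    )
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    # MRC2014 ORIGIN field, words 50-52
    for w, val in zip((50, 51, 52), np.asarray(origin, float)):
        m.set_header_float(w, float(val))
    m.write_ccp4_map(str(path))


def read_mrc(path) -> Volume3D:
    """Read an MRC2014 map (or stack) into a :class:`Volume3D`.

    Raises
    ------
    FormatError
        If the file is truncated, has a corrupt header, or an unsupported
        data mode.
    """
    import gemmi

    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read {path} as MRC: {exc}") from exc
    values = np.array(m.grid, copy=True)
    spacings = np.array(m.grid.spacing)
    if not np.all(spacings > 0):
        raise FormatError(f"{path}: non-positive voxel spacing in header")
    if not np.allclose(spacings, spacings[0], rtol=1e-3):
        warnings.warn(f"{path}: anisotropic voxel size, using mean")
    origin = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=float)
    return Volume3D(values, float(np.mean(spacings)), origin)


def read_mrc_stack(path, angles_path=None, pixel_size=None) -> TiltSeries:
    """Read an MRC image stack (+ optional angle file) as a tilt series."""
    vol = read_mrc(path)
    n = vol.values.shape[0]
    if angles_path is not None:
        angles = read_tilt_angles(angles_path)
        if len(angles) != n:
            raise FormatError(
                f"stack {path} has {n} images but {angles_path} lists "
                f"{len(angles)} angles"
            )
    else:
        angles = np.arange(n, dtype=float)
    px = pixel_size if pixel_size is not None else vol.pixel_size
    return TiltSeries(vol.values, np.asarray(angles), px)


# ---------------------------------------------------------------------------
# tilt-angle files
# ---------------------------------------------------------------------------

def read_tilt_angles(path) -> np.ndarray:
    """Read a plain-text tilt-angle file (one angle in degrees per line)."""
    angles = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip().replace("−", "-")  # tolerate unicode minus
            if not text:
                continue
            try:
                angles.append(float(text))
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: not a number: {text!r}"
                ) from exc
    if not angles:
        raise FormatError(f"{path}: no tilt angles found")
    return np.asarray(angles, dtype=float)


def write_tilt_angles(angles_deg: Sequence[float], path) -> None:
    with open(path, "w") as fh:
        for a in angles_deg:
            fh.write(f"{float(a):.3f}\n")


# ---------------------------------------------------------------------------
# atomic models and partitions
# ---------------------------------------------------------------------------

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


def _element_mass(element: str, res_name: str, atom_name: str,
                  per_residue: bool) -> float:
    if per_residue:
        return _RESIDUE_MASS.get(res_name.upper(), _MEAN_RESIDUE_MASS)
    key = element.upper()
    if key not in _ELEMENT_MASS:
        warnings.warn(f"unknown element {element!r} for atom {atom_name}; "
                      "assigning carbon mass")
        return _ELEMENT_MASS["C"]
    return _ELEMENT_MASS[key]


def read_model(path, partition_rules=None):
    """Read a PDB file and (optionally) partition its atoms into domains.

    Highest-occupancy alternate conformers are kept.  If the model is a
    C-alpha-only trace, each marker atom is weighted with its full residue
    mass so that mass centres remain meaningful.

    Parameters
    ----------
    path
        PDB file.
    partition_rules
        Either a path to a partition rules file (see
        :func:`read_partition_rules`) or an already-parsed rules list.

    Returns
    -------
    (AtomicModel, DomainPartition)
        The partition maps every atom to a label or to ``'unassigned'``.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises several parse error types
        raise FormatError(f"cannot parse {path} as PDB: {exc}") from exc
    atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise FormatError(f"{path}: no polymer atoms")

    names = np.asarray(atoms.atom_name, dtype=object)
    ca_only = bool(np.all(names == "CA"))
    masses = np.array([
        _element_mass(e, r, a, per_residue=ca_only)
        for e, r, a in zip(atoms.element, atoms.res_name, names)
    ])
    model = AtomicModel(
        coords=np.asarray(atoms.coord, dtype=float),
        masses=masses,
        elements=np.asarray(atoms.element, dtype=object),
        chain_ids=np.asarray(atoms.chain_id, dtype=object),
        res_ids=np.asarray(atoms.res_id, dtype=int),
        res_names=np.asarray(atoms.res_name, dtype=object),
        atom_names=names,
        backbone=np.isin(names, list(_BACKBONE_NAMES)),
    )
    partition = apply_partition_rules(model, partition_rules)
    return model, partition


def write_model(model: AtomicModel, path) -> None:
    """Write an :class:`AtomicModel` back out as a PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = len(model)
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(model.coords, dtype=np.float32)
    atoms.chain_id = model.chain_ids.astype("U4")
    atoms.res_id = model.res_ids
    atoms.res_name = model.res_names.astype("U5")
    atoms.atom_name = model.atom_names.astype("U6")
    atoms.element = model.elements.astype("U2")
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(atoms)
    pdb_file.write(str(path))


def read_partition_rules(path) -> list:
    """Parse a domain partition rules file.

    Format: one rule per line, ``LABEL CHAIN START-END`` (inclusive residue
    range) or ``LABEL CHAIN *`` for a whole chain.  ``#`` starts a comment.
    A label may appear on several lines (union of ranges).
    """
    rules = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 'LABEL CHAIN RANGE', got {text!r}"
                )
            label, chain, rng = parts
            if rng == "*":
                lo, hi = None, None
            else:
                try:
                    lo_s, hi_s = rng.split("-", 1)
                    lo, hi = int(lo_s), int(hi_s)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: bad residue range {rng!r}"
                    ) from exc
            rules.append((label, chain, lo, hi))
    if not rules:
        raise FormatError(f"{path}: no partition rules found")
    return rules


def apply_partition_rules(model: AtomicModel, rules) -> DomainPartition:
    """Label a model's atoms according to partition rules.

    Atoms matching no rule become ``'unassigned'``.  Raises if a required
    (non-hinge) domain label ends up empty.
    """
    if rules is None:
        labels = {"unassigned": np.ones(len(model), dtype=bool)}
        return DomainPartition(labels)
    if isinstance(rules, (str, Path)):
        rules = read_partition_rules(rules)

    assigned = np.zeros(len(model), dtype=bool)
    labels: dict = {}
    for label, chain, lo, hi in rules:
        mask = model.chain_ids == chain
        if lo is not None:
            mask &= (model.res_ids >= lo) & (model.res_ids <= hi)
        mask &= ~assigned
        labels[label] = labels.get(label, np.zeros(len(model), bool)) | mask
        assigned |= mask
    labels["unassigned"] = ~assigned
    for label, mask in labels.items():
        if label not in ("unassigned", "hinge") and not mask.any():
            raise ValueError(f"partition rule for {label!r} matched no atoms")
    return DomainPartition(labels)
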