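"""Fragment geometry and unit-cell construction.

A training example starts from a short peptide fragment in Cartesian
coordinates.  The fragment is reoriented so the cell axes come out in the
conventional order (first axis longest, second shortest), boxed into an
orthogonal P1 cell grown until the closest intermolecular contact between
periodic images reaches a minimum distance, and finally converted to the
monoclinic space group P2₁ (with β = 90°), which places a second,
screw-related copy of the fragment in the cell.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Fragment",
    "UnitCellModel",
    "ATOMIC_MASS",
    "ATOMIC_NUMBER",
    "reorient",
    "reorientation_matrix",
    "determine_cell",
    "min_contact",
    "to_p21",
    "place_in_cell",
    "solvent_fraction",
]

# H and SE occur only transiently, between parsing and cleanup (hydrogens
# are stripped, selenomethionine is converted to methionine)
SUPPORTED_ELEMENTS = ("C", "N", "O", "S", "H", "SE")

ATOMIC_MASS = {"C": 12.0, "N": 14.0, "O": 16.0, "S": 32.0, "H": 1.0, "SE": 79.0}
ATOMIC_NUMBER = {"C": 6, "N": 7, "O": 8, "S": 16, "H": 1, "SE": 34}

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


@dataclass
class Atom:
    """A single heavy atom: element, PDB atom name, Cartesian xyz (A),
    isotropic B factor (A^2), unit occupancy."""

    element: str
    name: str
    xyz: np.ndarray
    b: float
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if self.element not in SUPPORTED_ELEMENTS:
            raise ValueError(f"unsupported element {self.element!r}")
        if self.b < 0:
            raise ValueError("B factor must be non-negative")
        if self.occupancy != 1.0:
            raise ValueError("occupancies are fixed at 1.0")
        self.xyz = np.asarray(self.xyz, dtype=float)


@dataclass
class Residue:
    name: str
    seq: int
    atoms: list[Atom] = field(default_factory=list)


@dataclass
class Fragment:
    """An ordered run of residues with a free-text provenance tag."""

    residues: list[Residue]
    source_id: str = ""

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def b_factors(self) -> np.ndarray:
        return np.array([a.b for a in self.atoms], dtype=float)

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASS[e] for e in self.elements()])

    def center_of_mass(self) -> np.ndarray:
        m = self.masses()
        return (self.coords() * m[:, None]).sum(axis=0) / m.sum()

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        if len(xyz) != self.n_atoms:
            raise ValueError("coordinate count mismatch")
        for atom, row in zip(self.atoms, xyz):
            atom.xyz = row.copy()

    def transformed(self, rot: np.ndarray | None = None, shift: np.ndarray | None = None) -> "Fragment":
        out = copy.deepcopy(self)
        xyz = out.coords()
        if rot is not None:
            xyz = xyz @ np.asarray(rot, dtype=float).T
        if shift is not None:
            xyz = xyz + np.asarray(shift, dtype=float)
        out.set_coords(xyz)
        return out


@dataclass
class UnitCellModel:
    """An orthogonal-axis cell (alpha=beta=gamma=90 deg) holding one (P1) or
    two screw-related (P2₁) copies of a fragment in Cartesian coordinates."""

    cell_lengths: tuple[float, float, float]
    space_group: str  # "P1" | "P21"
    fragments_in_cell: list[Fragment]
    cell_angles: tuple[float, float, float] = (90.0, 90.0, 90.0)
    screw_multiplier: float | None = None
    origin_shift: np.ndarray | None = None  # Cartesian shift applied at centering

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.cell_lengths):
            raise ValueError("cell lengths must be positive")
        if self.space_group not in ("P1", "P21"):
            raise ValueError(f"unsupported space group {self.space_group!r}")
        if self.space_group == "P21" and len(self.fragments_in_cell) != 2:
            raise ValueError("a P21 cell contains exactly two symmetry copies")

    @property
    def volume(self) -> float:
        a, b, c = self.cell_lengths
        return a * b * c

    def all_coords(self) -> np.ndarray:
        return np.vstack([f.coords() for f in self.fragments_in_cell])

    def all_elements(self) -> list[str]:
        return [e for f in self.fragments_in_cell for e in f.elements()]

    def all_b_factors(self) -> np.ndarray:
        return np.concatenate([f.b_factors() for f in self.fragments_in_cell])

    def fractional_coords(self) -> np.ndarray:
        return self.all_coords() / np.asarray(self.cell_lengths)


# ---------------------------------------------------------------------------
# reorientation

def reorientation_matrix(fragment: Fragment) -> np.ndarray:
    """Proper (det = +1) axis permutation putting the coordinate extents in
    the order extent1 >= extent3 >= extent2.

    The middle axis ends up second-shortest because the second cell axis is
    the P2₁ screw axis and is kept shortest by convention, while the first
    axis is the longest.
    """
    xyz = fragment.coords()
    if len(xyz) == 0:
        raise ValueError("empty fragment")
    extents = xyz.max(axis=0) - xyz.min(axis=0)
    if np.allclose(extents, 0) or np.count_nonzero(extents > 1e-9) < 2:
        raise ValueError("degenerate fragment: atoms coincident or collinear with an axis")
    order = np.argsort(extents)  # ascending: shortest ... longest
    # new axis 1 = longest, new axis 2 = shortest, new axis 3 = middle
    perm = (order[2], order[0], order[1])
    mat = np.zeros((3, 3))
    for new_axis, old_axis in enumerate(perm):
        mat[new_axis, old_axis] = 1.0
    if np.linalg.det(mat) < 0:  # keep the transform proper: proteins are chiral
        mat[2, :] *= -1.0
    return mat


def reorient(fragment: Fragment) -> Fragment:
    """Rotate the fragment so its axis extents satisfy e1 >= e3 >= e2."""
    return fragment.transformed(rot=reorientation_matrix(fragment))


# ---------------------------------------------------------------------------
# contacts and P1 cell determination

def _copy_pairs_min(xyz_a: np.ndarray, xyz_b: np.ndarray) -> float:
    d = xyz_a[:, None, :] - xyz_b[None, :, :]
    return float(np.sqrt((d * d).sum(axis=2)).min())


def min_contact(cell: UnitCellModel, return_vector: bool = False):
    """Minimum atom-atom distance between distinct symmetry/lattice copies.

    Scans all neighbour-cell translations in {-1,0,1}^3 for every ordered
    pair of fragment copies (including a copy against its own lattice
    translates, but never against itself in the home cell).
    """
    frags = cell.fragments_in_cell
    if not frags or all(f.n_atoms == 0 for f in frags):
        raise ValueError("empty cell")
    lengths = np.asarray(cell.cell_lengths)
    best = np.inf
    best_t = None
    coords = [f.coords() for f in frags]
    shifts = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    for ia, xa in enumerate(coords):
        for ib, xb in enumerate(coords):
            for t in shifts:
                if ia == ib and t == (0, 0, 0):
                    continue
                d = _copy_pairs_min(xa, xb + np.asarray(t, dtype=float) * lengths)
                if d < best:
                    best = d
                    best_t = t
    if return_vector:
        return best, best_t
    return best


def determine_cell(fragment: Fragment, min_contact_dist: float = 3.5, step: float = 0.5) -> UnitCellModel:
    """Box a reoriented fragment into a P1 cell grown until the closest
    periodic-image contact is at least ``min_contact_dist`` angstroms.

    Cell lengths start from the raw max-min coordinate extents and the axes
    implicated in the current worst contact (those with a non-zero lattice
    translation component) are grown by ``step`` until the contact clears.
    The fragment's (mass-weighted) centre of mass sits at the cell centre.
    """
    if min_contact_dist <= 0:
        raise ValueError("min_contact must be positive")
    xyz = fragment.coords()
    if len(xyz) == 0:
        raise ValueError("empty fragment")
    lengths = np.maximum(xyz.max(axis=0) - xyz.min(axis=0), 1e-6)
    while True:
        frag = fragment.transformed(shift=lengths / 2 - fragment.center_of_mass())
        cell = UnitCellModel(tuple(lengths), "P1", [frag])
        d, t = min_contact(cell, return_vector=True)
        if d >= min_contact_dist:
            cell.origin_shift = lengths / 2 - fragment.center_of_mass()
            return cell
        grow = np.array([step if ti != 0 else 0.0 for ti in t])
        if not grow.any():  # defensive; t=(0,0,0) is excluded from the scan
            grow[:] = step
        lengths = lengths + grow


# ---------------------------------------------------------------------------
# P21 conversion

def _screw_mate(fragment: Fragment, lengths: np.ndarray) -> Fragment:
    """Apply the P2₁ operator (x,y,z) -> (-x, y+1/2, -z) in fractional
    coordinates, then shift the mate by a whole lattice vector so its centre
    of mass lies inside the home cell."""
    frac = fragment.coords() / lengths
    mate = frac * np.array([-1.0, 1.0, -1.0]) + np.array([0.0, 0.5, 0.0])
    out = copy.deepcopy(fragment)
    out.set_coords(mate * lengths)
    com_frac = out.center_of_mass() / lengths
    out = out.transformed(shift=-np.floor(com_frac) * lengths)
    return out


def to_p21(cell: UnitCellModel, rng: np.random.Generator) -> UnitCellModel:
    """Convert a single-fragment P1 cell to P2₁.

    Each axis gains 1 A; the second (screw) axis is additionally stretched
    by a multiplier drawn from U(1.7, 1.95).  The fragment's centre of mass
    is re-centred to the new cell centre, and the second symmetry copy is
    generated by the screw operator.  No contact re-check is performed:
    cells whose images fall closer than the P1 threshold are kept, which is
    what produces the spread of solvent contents across examples.
    """
    if cell.space_group != "P1":
        raise ValueError("input cell must be P1")
    if len(cell.fragments_in_cell) != 1:
        raise ValueError("input cell must contain exactly one fragment")
    u = float(rng.uniform(1.7, 1.95))
    a, b, c = cell.cell_lengths
    lengths = np.array([a + 1.0, (b + 1.0) * u, c + 1.0])
    frag = cell.fragments_in_cell[0]
    shift = lengths / 2 - frag.center_of_mass()
    frag = frag.transformed(shift=shift)
    mate = _screw_mate(frag, lengths)
    out = UnitCellModel(tuple(lengths), "P21", [frag, mate], screw_multiplier=u)
    # total shift from the frame the P1 cell was built from (so templates in
    # that frame can be dropped into this cell with the same translation)
    out.origin_shift = shift + (cell.origin_shift if cell.origin_shift is not None else 0.0)
    return out


def place_in_cell(cell: UnitCellModel, fragment: Fragment) -> UnitCellModel:
    """Place ``fragment`` (already in the ground-truth Cartesian frame,
    before centering) into an existing P2₁ cell, applying the same origin
    shift the cell's own fragment received and generating the screw mate.

    Used for partial-structure templates, which must share the ground
    truth's cell and origin exactly.
    """
    if cell.space_group != "P21":
        raise ValueError("template placement requires a P21 cell")
    if cell.origin_shift is None:
        raise ValueError("cell does not record its centering shift")
    lengths = np.asarray(cell.cell_lengths)
    frag = fragment.transformed(shift=cell.origin_shift)
    mate = _screw_mate(frag, lengths)
    out = UnitCellModel(tuple(cell.cell_lengths), "P21", [frag, mate],
                        screw_multiplier=cell.screw_multiplier)
    out.origin_shift = np.asarray(cell.origin_shift).copy()
    return out


# ---------------------------------------------------------------------------
# solvent content

def solvent_fraction(cell: UnitCellModel, grid_shape: tuple[int, int, int],
                     mask_radius: float = 2.2) -> float:
    """Fraction of grid voxels farther than ``mask_radius`` (periodic
    distance) from every atom in the cell: the model-free volume fraction.
    """
    lengths = np.asarray(cell.cell_lengths)
    n = np.asarray(grid_shape, dtype=int)
    xyz = cell.all_coords()
    if len(xyz) == 0:
        return 1.0
    spacing = lengths / n
    mask = np.zeros(tuple(n), dtype=bool)
    # number of voxels the radius spans per axis
    reach = np.ceil(mask_radius / spacing).astype(int)
    offs = [np.arange(-r, r + 1) for r in reach]
    off_grid = np.stack(np.meshgrid(*offs, indexing="ij"), axis=-1).reshape(-1, 3)
    for pos in xyz:
        center_idx = pos / spacing  # fractional voxel index of the atom
        idx = np.floor(center_idx).astype(int) + off_grid
        voxel_pos = idx * spacing
        d = np.linalg.norm(voxel_pos - pos, axis=1)
        hit = idx[d <= mask_radius]
        if len(hit):
            mask[hit[:, 0] % n[0], hit[:, 1] % n[1], hit[:, 2] % n[2]] = True
    return float(1.0 - mask.mean())
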