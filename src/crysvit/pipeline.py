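"""Dataset generation: fragment extraction and cleanup, terminal-residue
omission, resolution binning, map generation, normalization, and
shape-batching.

Each example is a 15-residue fragment boxed into a P2₁ cell; the training
record holds the Patterson map of the cell, the ground-truth electron
density, and up to J template densities computed from a noise-perturbed
"predicted" fragment with 3-7 residues omitted from one or both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import crystal, scatter
from .crystal import Fragment, STANDARD_RESIDUES, UnitCellModel

__all__ = [
    "OmissionRecord",
    "ResolutionBin",
    "DatasetExample",
    "NormalizationStats",
    "HEAVY_ATOM_TEMPLATE",
    "extract_fragments",
    "clean_fragment",
    "FragmentRejected",
    "make_partials",
    "assign_bin",
    "grid_shape_for",
    "build_example",
    "normalize_dataset",
    "denormalize",
    "batch_by_shape",
    "split_by_source",
]

N_BINS = 20
D_MIN_RANGE = (1.75, 2.3)
SAMPLING_RANGE = (2.29, 2.7)

# Heavy atoms expected per standard residue (PDB naming, no OXT).
HEAVY_ATOM_TEMPLATE = {
    "ALA": ["N", "CA", "C", "O", "CB"],
    "ARG": ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"],
    "ASP": ["N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"],
    "CYS": ["N", "CA", "C", "O", "CB", "SG"],
    "GLN": ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"],
    "GLY": ["N", "CA", "C", "O"],
    "HIS": ["N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"],
    "LEU": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"],
    "LYS": ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"],
    "MET": ["N", "CA", "C", "O", "CB", "CG", "SD", "CE"],
    "PHE": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["N", "CA", "C", "O", "CB", "CG", "CD"],
    "SER": ["N", "CA", "C", "O", "CB", "OG"],
    "THR": ["N", "CA", "C", "O", "CB", "OG1", "CG2"],
    "TRP": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "VAL": ["N", "CA", "C", "O", "CB", "CG1", "CG2"],
}


@dataclass
class OmissionRecord:
    """Which terminal residues were removed from a template."""

    end_choice: str  # "start" | "end" | "both"
    n_omitted: int
    split: tuple[int, int] | None = None  # (n_start, n_end) when both

    def __post_init__(self) -> None:
        if self.end_choice not in ("start", "end", "both"):
            raise ValueError(f"bad end_choice {self.end_choice!r}")
        if self.n_omitted < 1:
            raise ValueError("n_omitted must be positive")
        if self.end_choice == "both":
            if self.split is None or sum(self.split) != self.n_omitted:
                raise ValueError("split must sum to n_omitted")
            if abs(self.split[0] - self.split[1]) > 1:
                raise ValueError("split halves must differ by at most 1")

    def omitted_indices(self, n_residues: int) -> frozenset[int]:
        if self.end_choice == "start":
            return frozenset(range(self.n_omitted))
        if self.end_choice == "end":
            return frozenset(range(n_residues - self.n_omitted, n_residues))
        ns, ne = self.split
        return frozenset(range(ns)) | frozenset(range(n_residues - ne, n_residues))


@dataclass
class ResolutionBin:
    index: int
    d_min: float
    sampling_factor: float


@dataclass
class DatasetExample:
    patterson: scatter.MapGrid
    ground_truth: scatter.MapGrid
    partials: list[tuple[scatter.MapGrid, OmissionRecord]]
    bin: ResolutionBin
    fragment_id: str = ""
    seed: int | None = None
    cell: UnitCellModel | None = None
    refl: scatter.ReflectionSet | None = None

    def __post_init__(self) -> None:
        shapes = {self.patterson.shape, self.ground_truth.shape}
        shapes |= {m.shape for m, _ in self.partials}
        if len(shapes) != 1:
            raise ValueError("all maps of an example must share one shape")
        if not (1 <= len(self.partials)):
            raise ValueError("an example carries at least one partial template")


@dataclass
class NormalizationStats:
    patterson: tuple[float, float]  # (min, max)
    density: tuple[float, float]


class FragmentRejected(Exception):
    """Signals that a fragment fails the cleanup screen (nonstandard
    residue, numbering gap, or missing heavy atom)."""


# ---------------------------------------------------------------------------
# fragment extraction and cleanup

def extract_fragments(chain: Fragment, frag_len: int = 15, max_overlap: int = 5) -> list[Fragment]:
    """All fragment windows of ``frag_len`` residues at stride
    frag_len - max_overlap; trailing residues that cannot form a window
    without exceeding the overlap cap are dropped."""
    stride = frag_len - max_overlap
    out = []
    n = len(chain.residues)
    start = 0
    while start + frag_len <= n:
        import copy as _copy
        residues = _copy.deepcopy(chain.residues[start:start + frag_len])
        out.append(Fragment(residues, source_id=chain.source_id))
        start += stride
    return out


def clean_fragment(fragment: Fragment) -> Fragment:
    """Standardise a fragment or reject it.

    Hydrogens are removed; selenomethionine (MSE) is renamed to MET with
    Se -> S at the SD position; the fragment is rejected if any residue is
    non-standard, the numbering has a gap, or an expected heavy atom is
    missing.  B factors are kept as-is.
    """
    out = fragment.transformed()  # deep copy
    for res in out.residues:
        if res.name == "MSE":
            res.name = "MET"
            for atom in res.atoms:
                if atom.name in ("SE", "SD") or atom.element == "SE":
                    atom.name = "SD"
                    atom.element = "S"
        res.atoms = [a for a in res.atoms if a.element != "H" and not a.name.startswith("H")]
    seqs = [r.seq for r in out.residues]
    if any(b - a != 1 for a, b in zip(seqs, seqs[1:])):
        raise FragmentRejected("residue numbering gap")
    for res in out.residues:
        if res.name not in STANDARD_RESIDUES:
            raise FragmentRejected(f"nonstandard residue {res.name}")
        have = {a.name for a in res.atoms}
        missing = set(HEAVY_ATOM_TEMPLATE[res.name]) - have
        if missing:
            raise FragmentRejected(f"{res.name}{res.seq} missing {sorted(missing)}")
    return out


# ---------------------------------------------------------------------------
# omission

def make_partials(fragment: Fragment, rng: np.random.Generator, J: int = 3,
                  frag_len: int = 15,
                  omit_range: tuple[int, int] = (3, 7)) -> list[tuple[Fragment, OmissionRecord]]:
    """Up to J terminally truncated copies of ``fragment``.

    Per draw: end choice uniform over {start, end, both}; omitted count
    uniform over ``omit_range`` (inclusive; 3..7 of 15 by default); "both"
    splits floor/ceil with a fair coin deciding which end takes the extra
    residue for odd counts.  A draw that repeats an earlier omitted-residue
    set is discarded rather than retried, so fewer than J templates may
    result.
    """
    if len(fragment.residues) != frag_len:
        raise ValueError(f"fragment must have {frag_len} residues")
    if omit_range[1] >= frag_len:
        raise ValueError("omission range must leave at least one residue")
    seen: set[frozenset[int]] = set()
    out = []
    for _ in range(J):
        end_choice = ("start", "end", "both")[rng.integers(3)]
        n_omit = int(rng.integers(omit_range[0], omit_range[1] + 1))
        split = None
        if end_choice == "both":
            lo, hi = n_omit // 2, n_omit - n_omit // 2
            split = (hi, lo) if (n_omit % 2 == 1 and rng.integers(2) == 0) else (lo, hi)
        rec = OmissionRecord(end_choice, n_omit, split)
        idx = rec.omitted_indices(frag_len)
        if idx in seen:
            continue
        seen.add(idx)
        residues = [r for i, r in enumerate(fragment.residues) if i not in idx]
        partial = Fragment(residues, source_id=fragment.source_id).transformed()
        out.append((partial, rec))
    return out


# ---------------------------------------------------------------------------
# resolution bins and grids

def assign_bin(example_index: int, n_total: int | None = None) -> ResolutionBin:
    """Even modular assignment of examples to the 20 resolution bins."""
    i = example_index % N_BINS
    d_min = D_MIN_RANGE[0] + i * (D_MIN_RANGE[1] - D_MIN_RANGE[0]) / (N_BINS - 1)
    fac = SAMPLING_RANGE[0] + i * (SAMPLING_RANGE[1] - SAMPLING_RANGE[0]) / (N_BINS - 1)
    return ResolutionBin(i, d_min, fac)


def _next_smooth(n: int) -> int:
    while True:
        m = n
        for p in (2, 3, 5):
            while m % p == 0:
                m //= p
        if m == 1:
            return n
        n += 1


def grid_shape_for(cell_lengths, bin: ResolutionBin) -> tuple[int, int, int]:
    """Map dimensions: cell_length * sampling_factor / d_min per axis,
    rounded up to the next {2,3,5}-smooth integer (FFT-friendly)."""
    out = []
    for l in cell_lengths:
        raw = l * bin.sampling_factor / bin.d_min
        out.append(_next_smooth(int(np.ceil(raw - 1e-9))))
    return tuple(out)


# ---------------------------------------------------------------------------
# example construction

def build_example(fragment: Fragment, predicted_fragment: Fragment,
                  bin: ResolutionBin, rng: np.random.Generator, J: int = 3,
                  min_contact_dist: float = 3.5, mode: str = "cromer-mann",
                  omit_range: tuple[int, int] = (3, 7),
                  keep_cell: bool = False) -> DatasetExample:
    """One full training record.

    The ground-truth fragment is reoriented, boxed (P1, min-contact rule),
    and converted to P2₁; Patterson and density maps are synthesised at the
    bin's resolution.  The predicted fragment — already aligned to the
    truth's Cartesian frame — receives the identical reorientation and
    centering, has terminal residues omitted (up to J patterns), gets a
    constant B of 20 A^2, and is rendered into template maps in the same
    cell at the same resolution and grid shape.
    """
    rot = crystal.reorientation_matrix(fragment)
    truth = fragment.transformed(rot=rot)
    pred = predicted_fragment.transformed(rot=rot)
    p1 = crystal.determine_cell(truth, min_contact_dist)
    cell = crystal.to_p21(p1, rng)
    shape = grid_shape_for(cell.cell_lengths, bin)
    refl = scatter.calc_structure_factors(cell, bin.d_min, mode=mode)
    patterson = scatter.patterson_map(refl, shape)
    truth_map = scatter.density_map(refl, shape)
    patterson.sampling_factor = truth_map.sampling_factor = bin.sampling_factor

    partials = []
    for partial_frag, rec in make_partials(pred, rng, J=J,
                                           frag_len=len(fragment.residues),
                                           omit_range=omit_range):
        for atom in partial_frag.atoms:
            atom.b = 20.0
        tcell = crystal.place_in_cell(cell, partial_frag)
        trefl = scatter.calc_structure_factors(tcell, bin.d_min, mode=mode)
        tmap = scatter.density_map(trefl, shape)
        tmap.flavor = "template"
        tmap.sampling_factor = bin.sampling_factor
        partials.append((tmap, rec))
    return DatasetExample(patterson, truth_map, partials, bin,
                          fragment_id=fragment.source_id,
                          cell=cell if keep_cell else None,
                          refl=refl if keep_cell else None)


# ---------------------------------------------------------------------------
# normalization and batching

def normalize_dataset(examples: list[DatasetExample]) -> NormalizationStats:
    """Scale every map into [-1, 1] by the global per-flavor extremes.

    Patterson maps use the Patterson extremes; ground-truth densities use
    the density extremes; template maps reuse the DENSITY extremes so that
    templates and truths live on one scale.  Maps are modified in place and
    the stats are returned for inversion.
    """
    if not examples:
        raise ValueError("empty dataset")
    pvals = [ex.patterson.values for ex in examples]
    dvals = [ex.ground_truth.values for ex in examples]
    pmin = min(v.min() for v in pvals)
    pmax = max(v.max() for v in pvals)
    dmin = min(v.min() for v in dvals)
    dmax = max(v.max() for v in dvals)
    if pmax == pmin:
        raise ValueError("degenerate Patterson value range (max == min)")
    if dmax == dmin:
        raise ValueError("degenerate density value range (max == min)")
    for ex in examples:
        ex.patterson.values = 2 * (ex.patterson.values - pmin) / (pmax - pmin) - 1
        ex.ground_truth.values = 2 * (ex.ground_truth.values - dmin) / (dmax - dmin) - 1
        for m, _ in ex.partials:
            m.values = 2 * (m.values - dmin) / (dmax - dmin) - 1
    return NormalizationStats(patterson=(float(pmin), float(pmax)),
                              density=(float(dmin), float(dmax)))


def denormalize(values: np.ndarray, stats: NormalizationStats, flavor: str) -> np.ndarray:
    lo, hi = stats.patterson if flavor == "patterson" else stats.density
    return (values + 1) / 2 * (hi - lo) + lo


def batch_by_shape(examples: list, min_size: int = 6, max_size: int = 11,
                   shape_of=lambda ex: ex.patterson.shape) -> list[list]:
    """Group by identical map shape, drop groups below ``min_size``, chunk
    greedily into batches of at most ``max_size``, and rebalance the last
    two chunks so no batch falls below ``min_size``."""
    groups: dict[tuple, list] = {}
    for ex in examples:
        groups.setdefault(tuple(shape_of(ex)), []).append(ex)
    batches = []
    for shape in sorted(groups):
        members = groups[shape]
        if len(members) < min_size:
            continue
        chunks = [members[i:i + max_size] for i in range(0, len(members), max_size)]
        if len(chunks) > 1 and len(chunks[-1]) < min_size:
            need = min_size - len(chunks[-1])
            moved = chunks[-2][-need:]
            chunks[-2] = chunks[-2][:-need]
            chunks[-1] = moved + chunks[-1]
        batches.extend(chunks)
    return batches


def split_by_source(fragments: list[Fragment], test_fraction: float,
                    rng: np.random.Generator) -> tuple[list[Fragment], list[Fragment]]:
    """Provenance-grouped train/test split: every fragment sharing a
    source_id lands in the same side, so a model cannot be scored on
    regions it memorised from the training set."""
    sources = sorted({f.source_id for f in fragments})
    perm = rng.permutation(len(sources))
    n_test = int(round(test_fraction * len(sources)))
    test_ids = {sources[i] for i in perm[:n_test]}
    train = [f for f in fragments if f.source_id not in test_ids]
    test = [f for f in fragments if f.source_id in test_ids]
    return train, test
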