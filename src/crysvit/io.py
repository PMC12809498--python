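"""Readers and writers: PDB v3.3 subset, CCP4/MRC mode-2 maps, a plain-text
reflection format, tensor export with a JSON sidecar, and JSON-lines
manifests.  All heavy lifting is delegated to gemmi; the functions here
convert between gemmi objects and the package's own containers.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np

from .crystal import Atom, Fragment, Residue, UnitCellModel
from .scatter import MapGrid, ReflectionSet

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_map",
    "write_map",
    "read_reflections",
    "write_reflections",
    "save_tensor",
    "load_tensor",
]

_SG_NAME = {"P1": "P 1", "P21": "P 1 21 1"}
_SG_FROM_NAME = {"P 1": "P1", "P 1 21 1": "P21", "P 21": "P21"}
_SG_NUMBER = {"P1": 1, "P21": 4}


# ---------------------------------------------------------------------------
# PDB

def read_pdb(path) -> tuple[list[Fragment], UnitCellModel | None]:
    """Parse ATOM/HETATM/CRYST1 records into one Fragment per chain.

    Elements come from PDB columns 77-78 with a fall-back inference from
    the atom name (both handled by gemmi).  Returns the fragments and, when
    a CRYST1 record with a supported space group is present, a
    UnitCellModel wrapping them.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    fragments = []
    for chain in st[0]:
        residues = []
        for res in chain:
            atoms = [Atom(a.element.name, a.name.strip(),
                          np.array([a.pos.x, a.pos.y, a.pos.z]), a.b_iso, a.occ)
                     for a in res]
            residues.append(Residue(res.name, res.seqid.num, atoms))
        if residues:
            fragments.append(Fragment(residues, source_id=f"{Path(path).stem}:{chain.name}"))
    cell = None
    sg = _SG_FROM_NAME.get((st.spacegroup_hm or "").strip())
    if sg and st.cell.a > 1.0 and fragments:
        if sg == "P21" and len(fragments) != 2:
            sg = None  # symmetry copies not present as separate chains
    if sg:
        cell = UnitCellModel((st.cell.a, st.cell.b, st.cell.c), sg, fragments)
    return fragments, cell


def write_pdb(path, fragments: list[Fragment],
              cell_lengths=None, space_group: str = "P1") -> None:
    """Write fragments (one chain each) with a CRYST1 record."""
    st = gemmi.Structure()
    if cell_lengths is not None:
        a, b, c = cell_lengths
        st.cell = gemmi.UnitCell(a, b, c, 90.0, 90.0, 90.0)
    st.spacegroup_hm = _SG_NAME[space_group]
    model = gemmi.Model("1")
    chain_ids = "ABCDEFGHIJ"
    for i, frag in enumerate(fragments):
        chain = gemmi.Chain(chain_ids[i % len(chain_ids)])
        for res in frag.residues:
            r = gemmi.Residue()
            r.name = res.name
            r.seqid = gemmi.SeqId(res.seq, " ")
            r.het_flag = "A"
            for atom in res.atoms:
                a = gemmi.Atom()
                a.name = atom.name
                a.element = gemmi.Element(atom.element)
                a.pos = gemmi.Position(*atom.xyz)
                a.b_iso = atom.b
                a.occ = atom.occupancy
                r.add_atom(a)
            chain.add_residue(r)
        model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


def write_cell_pdb(path, cell: UnitCellModel) -> None:
    write_pdb(path, cell.fragments_in_cell, cell.cell_lengths, cell.space_group)


# ---------------------------------------------------------------------------
# CCP4/MRC maps

def write_map(path, grid: MapGrid, space_group: str = "P1") -> None:
    """Mode-2 (float32) CCP4 map; axis order X,Y,Z; header carries cell and
    space-group number (1 or 4)."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    a, b, c = grid.cell_lengths
    m.grid.unit_cell = gemmi.UnitCell(a, b, c, 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup(_SG_NAME[space_group])
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_map(path, flavor: str = "density", d_min: float = 0.0) -> MapGrid:
    """Read a mode-2 CCP4/MRC map back into a MapGrid."""
    m = gemmi.read_ccp4_map(str(path))
    if m.header_i32(4) != 2:
        raise ValueError(f"{path}: only mode-2 (float32) maps are supported")
    cell = m.grid.unit_cell
    values = np.array(m.grid, copy=True)
    return MapGrid(values, (cell.a, cell.b, cell.c), flavor, d_min)


# ---------------------------------------------------------------------------
# reflection text format

def write_reflections(path, refl: ReflectionSet) -> None:
    """Whitespace-separated ``h k l amp phase_deg d`` with a 2-line header."""
    a, b, c = refl.cell_lengths
    with open(path, "w") as fh:
        fh.write(f"# cell {a:.6f} {b:.6f} {c:.6f}\n")
        fh.write(f"# d_min {refl.d_min:.6f}\n")
        amps = refl.amplitudes
        phases = refl.phases_deg
        for (h, k, l), amp, ph, d in zip(refl.hkl, amps, phases, refl.d):
            fh.write(f"{h:5d} {k:5d} {l:5d} {amp:15.6f} {ph:10.4f} {d:10.5f}\n")


def read_reflections(path) -> ReflectionSet:
    with open(path) as fh:
        header1 = fh.readline().split()
        header2 = fh.readline().split()
        if header1[:2] != ["#", "cell"] or header2[:2] != ["#", "d_min"]:
            raise ValueError(f"{path}: malformed reflection header")
        cell = tuple(float(x) for x in header1[2:5])
        d_min = float(header2[2])
        rows = np.loadtxt(fh, ndmin=2)
    hkl = rows[:, :3].astype(int)
    F = rows[:, 3] * np.exp(1j * np.radians(rows[:, 4]))
    return ReflectionSet(hkl, F, rows[:, 5], d_min, cell)


# ---------------------------------------------------------------------------
# tensor container

def save_tensor(path, values: np.ndarray, meta: dict | None = None) -> None:
    """Little-endian float32 .npy plus a JSON sidecar describing it."""
    path = Path(path)
    np.save(path, np.asarray(values, dtype="<f4"))
    sidecar = {"dtype": "<f4", "shape": list(np.asarray(values).shape),
               "order": "C", **(meta or {})}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_tensor(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return values, meta
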