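"""Synthetic peptide fixtures.

Stands in for fragments extracted from experimentally solved structures and
for their independently predicted counterparts: a coiled backbone is built
from ideal bond geometry (torsions drawn from broad allowed ranges), and a
"predicted" copy is produced by adding a Gaussian displacement field scaled
to a target C-alpha r.m.s.d., with B factors reset to a constant 20 A^2 as
is done for predicted models in the dataset-generation procedure.

Side chains are truncated at C-beta, so the default residue composition is
restricted to ALA/GLY — the two residue types whose full heavy-atom
complement survives that truncation, which lets fixtures pass the
missing-atom screen of the pipeline unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystal import Atom, Fragment, Residue

__all__ = ["FixtureSpec", "make_fragment", "make_prediction"]

# ideal backbone internal coordinates (lengths in A, angles in degrees)
BOND_N_CA = 1.46
BOND_CA_C = 1.52
BOND_C_N = 1.33
BOND_C_O = 1.23
BOND_CA_CB = 1.53
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.5
ANGLE_C_N_CA = 121.5
ANGLE_CA_C_O = 120.5
ANGLE_N_CA_CB = 110.5
OMEGA = 180.0

# broad coil-like torsion windows (degrees)
PHI_RANGE = (-150.0, -60.0)
PSI_RANGE = (-50.0, 160.0)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic truth/prediction pair."""

    n_residues: int = 15
    composition: dict[str, float] = field(default_factory=lambda: {"ALA": 0.75, "GLY": 0.25})
    b_range: tuple[float, float] = (10.0, 40.0)
    target_rmsd: float = 0.5
    terminal_noise_scale: float = 1.0  # extra multiplier on the two end residues
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("need at least one residue")
        if self.target_rmsd < 0:
            raise ValueError("target_rmsd must be non-negative")


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension placement: position atom D given chain A-B-C and
    the internal coordinates bond(C-D), angle(B-C-D), torsion(A-B-C-D)."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(ang),
                        bond * np.sin(ang) * np.cos(tor),
                        bond * np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_fragment(spec: FixtureSpec) -> Fragment:
    """Build an extended/coiled peptide from ideal geometry.

    Backbone N/CA/C placed by torsion chaining (phi/psi random per residue,
    omega trans); carbonyl O and, for non-GLY, a C-beta are branched off.
    B factors are drawn uniformly from ``spec.b_range``.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.composition)
    weights = np.array([spec.composition[n] for n in names], dtype=float)
    weights /= weights.sum()

    # seed coordinates for residue 1: N at origin, CA on +x, C in the xy-plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    backbone = [(n0, ca0, c0)]
    for _ in range(1, spec.n_residues):
        n_prev, ca_prev, c_prev = backbone[-1]
        psi = rng.uniform(*PSI_RANGE)
        phi = rng.uniform(*PHI_RANGE)
        n_i = _place(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi)
        ca_i = _place(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = _place(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        backbone.append((n_i, ca_i, c_i))

    residues = []
    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        resname = names[rng.choice(len(names), p=weights)]
        b = lambda: float(rng.uniform(*spec.b_range))
        atoms = [
            Atom("N", "N", n_i, b()),
            Atom("C", "CA", ca_i, b()),
            Atom("C", "C", c_i, b()),
        ]
        # carbonyl O: trans to the next N (or to an ideal psi=0 direction at the C terminus)
        if i + 1 < len(backbone):
            psi_eff = _dihedral(n_i, ca_i, c_i, backbone[i + 1][0])
        else:
            psi_eff = 140.0
        atoms.append(Atom("O", "O", _place(n_i, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O, psi_eff + 180.0), b()))
        if resname != "GLY":
            # L-configuration branch off the N-CA bond
            atoms.append(Atom("C", "CB", _place(c_i, n_i, ca_i, BOND_CA_CB, ANGLE_N_CA_CB, 122.5), b()))
        residues.append(Residue(resname, i + 1, atoms))
    return Fragment(residues, source_id=f"fixture-{spec.seed}")


def _dihedral(a, b, c, d) -> float:
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(m @ n2, n1 @ n2)))


def make_prediction(fragment: Fragment, spec: FixtureSpec) -> Fragment:
    """Noise-perturbed counterpart emulating a predicted model.

    A raw Gaussian displacement field (optionally inflated on the two
    terminal residues) is rescaled so the realized C-alpha r.m.s.d. to the
    input equals ``spec.target_rmsd`` exactly; every B factor is set to
    20.0 A^2.
    """
    if spec.target_rmsd < 0:
        raise ValueError("target_rmsd must be non-negative")
    rng = np.random.default_rng(spec.seed + 1_000_003)
    out = fragment.transformed()
    xyz = out.coords()
    if spec.target_rmsd > 0:
        disp = rng.normal(0.0, 1.0, xyz.shape)
        scale_per_atom = np.ones(len(xyz))
        res_index = np.repeat(np.arange(len(out.residues)),
                              [len(r.atoms) for r in out.residues])
        ends = (res_index == 0) | (res_index == len(out.residues) - 1)
        scale_per_atom[ends] = spec.terminal_noise_scale
        disp *= scale_per_atom[:, None]
        ca_idx = [i for i, a in enumerate(out.atoms) if a.name == "CA"]
        raw_rmsd = float(np.sqrt((disp[ca_idx] ** 2).sum(axis=1).mean()))
        disp *= spec.target_rmsd / raw_rmsd
        out.set_coords(xyz + disp)
    for atom in out.atoms:
        atom.b = 20.0
    return out
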