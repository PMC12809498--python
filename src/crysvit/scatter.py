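"""Reciprocal-space computation for orthogonal-axis cells.

Structure factors are computed by direct summation over all atoms of all
symmetry copies (the cell is always expanded to P1 content first):

    F(hkl) = sum_j f_j(s) exp(-B_j s^2 / 4) exp(2 pi i (h x_j + k y_j + l z_j))

with s = 1/d and the orthogonal-cell resolution formula
1/d^2 = h^2/a^2 + k^2/b^2 + l^2/c^2.  Electron density and the Patterson
function are synthesised from these coefficients by FFT; the Patterson is
additionally available through the autocorrelation identity
p = Re(IFFT(FFT(e) * FFT(e_inv))), which the test-suite uses as the central
cross-check between the two formulations.

F(000) is omitted from every synthesis (CCP4 FFT convention), so maps are
mean-zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReflectionSet",
    "MapGrid",
    "CROMER_MANN",
    "scattering_factor",
    "calc_structure_factors",
    "density_map",
    "patterson_map",
    "patterson_via_autocorrelation",
    "map_to_structure_factors",
    "unique_hkl",
]

# 4-Gaussian Cromer-Mann coefficients (a1..a4, b1..b4, c), International
# Tables for Crystallography Vol. C, neutral atoms.
CROMER_MANN = {
    "C": ([2.31000, 1.02000, 1.58860, 0.865000],
          [20.8439, 10.2075, 0.568700, 51.6512], 0.215600),
    "N": ([12.2126, 3.13220, 2.01250, 1.16630],
          [0.005700, 9.89330, 28.9975, 0.582600], -11.529),
    "O": ([3.04850, 2.28680, 1.54630, 0.867000],
          [13.2771, 5.70110, 0.323900, 32.9089], 0.250800),
    "S": ([6.90530, 5.20340, 1.43790, 1.58630],
          [1.46790, 22.2151, 0.253600, 56.1720], 0.866900),
}

_ATOMIC_NUMBER = {"C": 6.0, "N": 7.0, "O": 8.0, "S": 16.0}


def scattering_factor(element: str, s, mode: str = "cromer-mann"):
    """X-ray atomic scattering factor f(s), s = 1/d in 1/A.

    mode "cromer-mann" evaluates the tabulated 4-Gaussian fit; mode
    "constant-Z" returns the atomic number (a point-atom oracle used in
    tests, where phases become exact rationals).
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("s must be non-negative")
    if element not in CROMER_MANN:
        raise ValueError(f"unknown element {element!r}")
    if mode == "constant-Z":
        return np.broadcast_to(_ATOMIC_NUMBER[element], s.shape).copy() if s.shape else _ATOMIC_NUMBER[element]
    if mode != "cromer-mann":
        raise ValueError(f"unknown mode {mode!r}")
    a, b, c = CROMER_MANN[element]
    # (sin theta / lambda)^2 = s^2 / 4
    stol2 = s * s / 4.0
    f = c + sum(ai * np.exp(-bi * stol2) for ai, bi in zip(a, b))
    return float(f) if np.isscalar(f) or f.shape == () else f


@dataclass
class ReflectionSet:
    """Unique (Friedel-reduced) reflections with complex structure factors.

    hkl: (N, 3) int array; F: (N,) complex; d: (N,) resolution in A.
    (0,0,0) is excluded.  The mate (-h,-k,-l) is implied as conj(F).
    """

    hkl: np.ndarray
    F: np.ndarray
    d: np.ndarray
    d_min: float
    cell_lengths: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.F = np.asarray(self.F, dtype=complex).reshape(-1)
        self.d = np.asarray(self.d, dtype=float).reshape(-1)
        if np.any(np.all(self.hkl == 0, axis=1)):
            raise ValueError("(0,0,0) may not be stored")
        if np.any(self.d < self.d_min - 1e-9):
            raise ValueError("reflection beyond the stated resolution limit")

    @property
    def amplitudes(self) -> np.ndarray:
        return np.abs(self.F)

    @property
    def phases_deg(self) -> np.ndarray:
        return np.degrees(np.angle(self.F))

    def with_F(self, F: np.ndarray) -> "ReflectionSet":
        return ReflectionSet(self.hkl.copy(), np.asarray(F, dtype=complex),
                             self.d.copy(), self.d_min, self.cell_lengths)


@dataclass
class MapGrid:
    """Real scalar field sampled on a cell-spanning fractional grid."""

    values: np.ndarray
    cell_lengths: tuple[float, float, float]
    flavor: str  # "density" | "patterson" | "template"
    d_min: float
    sampling_factor: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("map values must be a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values")
        if self.flavor not in ("density", "patterson", "template"):
            raise ValueError(f"unknown map flavor {self.flavor!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def _check_shannon(grid_shape, cell_lengths, d_min) -> None:
    for n, l in zip(grid_shape, cell_lengths):
        if n < 2.0 * l / d_min - 1e-9:
            raise ValueError(
                f"grid axis {n} too coarse for d_min={d_min} over {l} A (Shannon)")


def unique_hkl(cell_lengths, d_min):
    """Friedel-unique Miller indices with d >= d_min, (000) excluded.

    Enumerates the full index box, applies the resolution cutoff, then keeps
    the half-sphere h>0, or (h=0, k>0), or (h=0, k=0, l>0).
    """
    a, b, c = cell_lengths
    hmax = int(np.floor(a / d_min))
    kmax = int(np.floor(b / d_min))
    lmax = int(np.floor(c / d_min))
    h, k, l = np.meshgrid(np.arange(-hmax, hmax + 1),
                          np.arange(-kmax, kmax + 1),
                          np.arange(-lmax, lmax + 1), indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    inv_d2 = (hkl[:, 0] / a) ** 2 + (hkl[:, 1] / b) ** 2 + (hkl[:, 2] / c) ** 2
    keep = (inv_d2 > 0) & (inv_d2 <= 1.0 / d_min**2 + 1e-12)
    hkl = hkl[keep]
    inv_d2 = inv_d2[keep]
    half = (hkl[:, 0] > 0) | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0)) | \
           ((hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0))
    return hkl[half], 1.0 / np.sqrt(inv_d2[half])


def calc_structure_factors(cell, d_min: float, mode: str = "cromer-mann") -> ReflectionSet:
    """Direct-summation structure factors over all atoms of all symmetry
    copies of ``cell`` (P1 expansion), to resolution ``d_min``."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    frac = cell.fractional_coords()
    if len(frac) == 0:
        raise ValueError("empty cell")
    elements = cell.all_elements()
    b = cell.all_b_factors()
    hkl, d = unique_hkl(cell.cell_lengths, d_min)
    s = 1.0 / d
    stol2 = s * s / 4.0  # sin^2(theta)/lambda^2
    F = np.zeros(len(hkl), dtype=complex)
    # group atoms by element so f_j(s) is evaluated once per element
    elements_arr = np.array(elements)
    for elem in np.unique(elements_arr):
        sel = elements_arr == elem
        f = np.asarray(scattering_factor(elem, s, mode))
        dw = np.exp(-np.outer(b[sel], stol2))  # (n_atoms_e, n_refl)
        phase = np.exp(2j * np.pi * (frac[sel] @ hkl.T))
        F += (f * (dw * phase)).sum(axis=0)
    return ReflectionSet(hkl, F, d, d_min, tuple(cell.cell_lengths))


def _coeff_grid(refl: ReflectionSet, grid_shape, coeffs: np.ndarray) -> np.ndarray:
    """Scatter Friedel pairs of per-reflection complex coefficients into an
    FFT array (accumulating where h = n/2 aliases onto its own mate)."""
    n1, n2, n3 = grid_shape
    A = np.zeros(grid_shape, dtype=complex)
    h, k, l = refl.hkl.T
    np.add.at(A, (h % n1, k % n2, l % n3), coeffs)
    np.add.at(A, (-h % n1, -k % n2, -l % n3), np.conj(coeffs))
    return A


def density_map(refl: ReflectionSet, grid_shape) -> MapGrid:
    """Electron-density synthesis rho(x) = (1/V) sum F exp(-2 pi i h.x) on a
    fractional grid, via FFT.  F(000) is omitted, so mean(rho) = 0."""
    _check_shannon(grid_shape, refl.cell_lengths, refl.d_min)
    V = float(np.prod(refl.cell_lengths))
    A = _coeff_grid(refl, tuple(grid_shape), refl.F)
    # numpy fftn applies exp(-2 pi i h.x/n): exactly the Eq-2 sign convention
    rho = np.fft.fftn(A).real / V
    return MapGrid(rho, refl.cell_lengths, "density", refl.d_min)


def patterson_map(refl: ReflectionSet, grid_shape) -> MapGrid:
    """Patterson synthesis: amplitudes squared, phases ignored.
    P(u) = (1/V) sum |F|^2 cos(2 pi h.u); |F(000)|^2 omitted."""
    _check_shannon(grid_shape, refl.cell_lengths, refl.d_min)
    V = float(np.prod(refl.cell_lengths))
    A = _coeff_grid(refl, tuple(grid_shape), (refl.amplitudes ** 2).astype(complex))
    p = np.fft.fftn(A).real / V
    return MapGrid(p, refl.cell_lengths, "patterson", refl.d_min)


def map_to_structure_factors(m: MapGrid, template: ReflectionSet) -> ReflectionSet:
    """Structure factors of a real map at the template's Miller indices
    (the exact inverse of :func:`density_map` on the same grid)."""
    V = float(np.prod(m.cell_lengths))
    N = m.values.size
    n1, n2, n3 = m.values.shape
    h, k, l = template.hkl.T
    F = np.conj(np.fft.fftn(m.values))[h % n1, k % n2, l % n3] * V / N
    return template.with_F(F)


def patterson_via_autocorrelation(e: MapGrid) -> MapGrid:
    """Patterson from a density map through the autocorrelation identity
    p = Re(IFFT(FFT(e) * FFT(e_inv))), where e_inv[i] = e[-i mod n].

    Scaled by V/N so the result matches the direct |F|^2 synthesis of
    :func:`patterson_map` on the same grid.
    """
    vals = e.values
    e_inv = vals[tuple(np.ix_(*[(-np.arange(n)) % n for n in vals.shape]))]
    N = vals.size
    V = float(np.prod(e.cell_lengths))
    p = np.fft.ifftn(np.fft.fftn(vals) * np.fft.fftn(e_inv)).real * (V / N)
    return MapGrid(p, e.cell_lengths, "patterson", e.d_min, e.sampling_factor)
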