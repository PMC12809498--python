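"""Evaluation of predicted maps against ground truth.

Covers the map-space and reciprocal-space quality measures used to judge a
completion: Pearson correlation over the full cell or the in-model region,
unweighted and figure-of-merit-weighted phase errors, normalised amplitudes
(E values), a per-shell sigma-A moment estimator, and the classic
(2m|Fo| - D|Fc|) exp(i phi_calc) weighted synthesis.

The sigma-A estimator here is a deterministic moment estimator
(corr(E_o^2, E_c^2)^(1/4) per shell) rather than the Rice-likelihood
maximisation of the full treatment; it preserves the limits that matter
for weighting (1 for a perfect model, 0 for an uninformative one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0e, i1e

from .scatter import MapGrid, ReflectionSet, density_map

__all__ = [
    "PhaseComparison",
    "SigmaAEstimate",
    "pearson_cc",
    "model_region_mask",
    "phase_error",
    "normalized_amplitudes",
    "resolution_shells",
    "estimate_sigma_a",
    "fom",
    "sigmaa_weighted_map",
]


@dataclass
class PhaseComparison:
    delta_phi: np.ndarray  # per reflection, degrees in [0, 180]
    fom: np.ndarray | None
    centric: np.ndarray
    mean_unweighted: float
    mean_weighted: float | None
    cos_unweighted: float
    cos_weighted: float | None


@dataclass
class SigmaAEstimate:
    sigma_a: np.ndarray  # per shell, in [0, 1)
    D: np.ndarray  # per shell scale
    shell_of: np.ndarray  # per reflection shell index
    shell_edges: np.ndarray  # d-spacing edges, descending


# ---------------------------------------------------------------------------
# map correlation

def pearson_cc(a: MapGrid | np.ndarray, b: MapGrid | np.ndarray,
               mask: np.ndarray | None = None) -> float:
    """Pearson correlation over all voxels or a boolean-masked subset."""
    av = a.values if isinstance(a, MapGrid) else np.asarray(a)
    bv = b.values if isinstance(b, MapGrid) else np.asarray(b)
    if av.shape != bv.shape:
        raise ValueError("map shapes differ")
    if mask is not None:
        if mask.shape != av.shape:
            raise ValueError("mask shape differs from maps")
        if mask.sum() < 2:
            raise ValueError("mask must select at least two voxels")
        av, bv = av[mask], bv[mask]
    av = av.ravel() - av.mean()
    bv = bv.ravel() - bv.mean()
    denom = np.sqrt((av @ av) * (bv @ bv))
    if denom == 0:
        raise ValueError("zero variance: correlation undefined")
    return float((av @ bv) / denom)


def model_region_mask(cell, grid_shape, radius: float = 2.0) -> np.ndarray:
    """Boolean grid of voxels within ``radius`` (periodic) of any atom of
    the cell: the in-model region over which completions are scored."""
    lengths = np.asarray(cell.cell_lengths)
    n = np.asarray(grid_shape, dtype=int)
    spacing = lengths / n
    mask = np.zeros(tuple(n), dtype=bool)
    reach = np.ceil(radius / spacing).astype(int)
    offs = [np.arange(-r, r + 1) for r in reach]
    off_grid = np.stack(np.meshgrid(*offs, indexing="ij"), axis=-1).reshape(-1, 3)
    for pos in cell.all_coords():
        idx = np.floor(pos / spacing).astype(int) + off_grid
        d = np.linalg.norm(idx * spacing - pos, axis=1)
        hit = idx[d <= radius]
        if len(hit):
            mask[hit[:, 0] % n[0], hit[:, 1] % n[1], hit[:, 2] % n[2]] = True
    return mask


# ---------------------------------------------------------------------------
# phase error

def _match(pred: ReflectionSet, truth: ReflectionSet) -> None:
    if pred.hkl.shape != truth.hkl.shape or not np.array_equal(pred.hkl, truth.hkl):
        raise ValueError("reflection index sets differ")
    if abs(pred.d_min - truth.d_min) > 1e-9:
        raise ValueError("resolution limits differ")


def centric_zone(hkl: np.ndarray) -> np.ndarray:
    """P2₁ centric reflections: the h0l zone (k = 0)."""
    return hkl[:, 1] == 0


def phase_error(pred: ReflectionSet, truth: ReflectionSet,
                foms: np.ndarray | None = None) -> PhaseComparison:
    """Per-reflection absolute phase difference (wrapped to [0, 180] deg)
    with unweighted and FOM-weighted means and cosine aggregates.  No
    origin-shift search is performed: generator and predictions share one
    origin by construction."""
    _match(pred, truth)
    dphi = np.abs((pred.phases_deg - truth.phases_deg + 180.0) % 360.0 - 180.0)
    cent = centric_zone(pred.hkl)
    mean_u = float(dphi.mean())
    cos_u = float(np.cos(np.radians(dphi)).mean())
    mean_w = cos_w = None
    if foms is not None:
        foms = np.asarray(foms, dtype=float)
        if foms.shape != dphi.shape:
            raise ValueError("FOM array shape mismatch")
        wsum = foms.sum()
        mean_w = float((foms * dphi).sum() / wsum)
        cos_w = float((foms * np.cos(np.radians(dphi))).sum() / wsum)
    return PhaseComparison(dphi, foms, cent, mean_u, mean_w, cos_u, cos_w)


# ---------------------------------------------------------------------------
# normalised amplitudes and sigma-A

def resolution_shells(d: np.ndarray, n_shells: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Equal-population resolution shells; returns (shell index per
    reflection, d-spacing edges).  Shell 0 is the lowest resolution."""
    order = np.argsort(-d)  # descending d
    shell_of = np.empty(len(d), dtype=int)
    bounds = np.linspace(0, len(d), n_shells + 1).astype(int)
    edges = [d[order[0]]] if len(d) else []
    for i in range(n_shells):
        shell_of[order[bounds[i]:bounds[i + 1]]] = i
        if bounds[i + 1] > 0:
            edges.append(d[order[bounds[i + 1] - 1]])
    return shell_of, np.asarray(edges)


def normalized_amplitudes(refl: ReflectionSet, n_shells: int = 10) -> np.ndarray:
    """E values: |F| / <|F|^2>_shell^(1/2), so <E^2> = 1 per shell.
    Shells with no reflections are merged into their neighbour by the
    equal-population construction."""
    amps = refl.amplitudes
    n_shells = min(n_shells, max(1, len(amps) // 3))
    shell_of, _ = resolution_shells(refl.d, n_shells)
    E = np.empty_like(amps)
    for i in range(n_shells):
        sel = shell_of == i
        E[sel] = amps[sel] / np.sqrt((amps[sel] ** 2).mean())
    return E


def estimate_sigma_a(E_obs: np.ndarray, E_calc: np.ndarray, shell_of: np.ndarray,
                     d: np.ndarray | None = None,
                     F_obs: np.ndarray | None = None,
                     F_calc: np.ndarray | None = None) -> SigmaAEstimate:
    """Moment estimator of sigma-A per shell.

    For the acentric Rice model corr(E_o^2, E_c^2) = sigma_A^4, so the
    per-shell estimate is clamp(corr, 0, 1)^(1/4), kept strictly below 1.
    The amplitude scale D is sigma_A * (<|Fo|^2>/<|Fc|^2>)^(1/2) when raw
    amplitudes are supplied, else sigma_A itself.
    """
    E_obs = np.asarray(E_obs, dtype=float)
    E_calc = np.asarray(E_calc, dtype=float)
    n_shells = int(shell_of.max()) + 1
    sig = np.empty(n_shells)
    D = np.empty(n_shells)
    for i in range(n_shells):
        sel = shell_of == i
        if sel.sum() < 3:
            raise ValueError(f"shell {i} has fewer than 3 reflections")
        eo2 = E_obs[sel] ** 2
        ec2 = E_calc[sel] ** 2
        if eo2.std() == 0 or ec2.std() == 0:
            corr = 1.0  # degenerate shell: identical normalised intensities
        else:
            corr = float(np.corrcoef(eo2, ec2)[0, 1])
        # soft-threshold at twice the null sampling noise of a correlation
        # (~1/sqrt(n)); the fourth root would otherwise turn pure noise in
        # an uninformative shell into a sizeable sigma-A
        corr = max(corr - 2.0 / np.sqrt(sel.sum()), 0.0)
        sig[i] = min(np.clip(corr, 0.0, 1.0) ** 0.25, 1.0 - 1e-6)
        if F_obs is not None and F_calc is not None:
            scale = np.sqrt((np.abs(F_obs[sel]) ** 2).mean() /
                            (np.abs(F_calc[sel]) ** 2).mean())
        else:
            scale = 1.0
        D[i] = sig[i] * scale
    edges = np.array([])
    if d is not None:
        _, edges = resolution_shells(np.asarray(d), n_shells)
    return SigmaAEstimate(sig, D, shell_of.copy(), edges)


def fom(E_obs: np.ndarray, E_calc: np.ndarray, sigma_a: SigmaAEstimate,
        centric_flags: np.ndarray) -> np.ndarray:
    """Per-reflection figure of merit m in [0, 1].

    X = 2 sigma_A E_o E_c / (1 - sigma_A^2); acentric m = I1(X)/I0(X),
    centric m = tanh(X/2).
    """
    sa = np.minimum(sigma_a.sigma_a[sigma_a.shell_of], 1.0 - 1e-6)
    X = 2.0 * sa * np.asarray(E_obs) * np.asarray(E_calc) / (1.0 - sa**2)
    m = np.where(centric_flags, np.tanh(X / 2.0), i1e(X) / i0e(X))
    return np.clip(m, 0.0, 1.0)


def sigmaa_weighted_map(obs_amps: np.ndarray, partial_refl: ReflectionSet,
                        sigma_a: SigmaAEstimate, foms: np.ndarray,
                        grid_shape) -> MapGrid:
    """Weighted synthesis from (2m|Fo| - D|Fc|) exp(i phi_calc) coefficients
    (m|Fo| exp(i phi_calc) for centric reflections)."""
    obs_amps = np.asarray(obs_amps, dtype=float)
    if len(obs_amps) != len(partial_refl.F):
        raise ValueError("amplitude/reflection count mismatch")
    phase = np.exp(1j * np.angle(partial_refl.F))
    D = sigma_a.D[sigma_a.shell_of]
    cent = centric_zone(partial_refl.hkl)
    coeff = np.where(cent,
                     foms * obs_amps,
                     2.0 * foms * obs_amps - D * partial_refl.amplitudes)
    out = density_map(partial_refl.with_F(coeff * phase), grid_shape)
    return out
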