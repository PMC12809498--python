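import numpy as np
import pytest

from crysvit import crystal, fixtures, pipeline, scatter


@pytest.fixture(scope="session")
def small_fragment():
    """A 4-residue fixture fragment (fast cells and structure factors)."""
    return fixtures.make_fragment(fixtures.FixtureSpec(n_residues=4, seed=11))


@pytest.fixture(scope="session")
def full_fragment():
    """A standard 15-residue fixture fragment."""
    return fixtures.make_fragment(fixtures.FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def p21_cell(small_fragment):
    p1 = crystal.determine_cell(crystal.reorient(small_fragment))
    return crystal.to_p21(p1, np.random.default_rng(42))


@pytest.fixture(scope="session")
def p21_refl(p21_cell):
    return scatter.calc_structure_factors(p21_cell, 2.0)


def brute_force_min_contact(cell):
    """Independent exhaustive double loop over atom pairs and the 27
    neighbour translations (the oracle for min_contact)."""
    coords = [f.coords() for f in cell.fragments_in_cell]
    lengths = np.asarray(cell.cell_lengths)
    best = np.inf
    for ia, xa in enumerate(coords):
        for ib, xb in enumerate(coords):
            for ti in (-1, 0, 1):
                for tj in (-1, 0, 1):
                    for tk in (-1, 0, 1):
                        if ia == ib and (ti, tj, tk) == (0, 0, 0):
                            continue
                        shift = np.array([ti, tj, tk]) * lengths
                        for p in xa:
                            d = np.linalg.norm(xb + shift - p, axis=1).min()
                            best = min(best, d)
    return best


def direct_density_sum(refl, grid_shape):
    """Triple-sum density synthesis (the FFT oracle): evaluates
    rho(x) = (1/V) sum_hkl F exp(-2 pi i h.x) over both Friedel mates."""
    n1, n2, n3 = grid_shape
    V = float(np.prod(refl.cell_lengths))
    x = np.arange(n1) / n1
    y = np.arange(n2) / n2
    z = np.arange(n3) / n3
    rho = np.zeros(grid_shape, dtype=complex)
    for (h, k, l), F in zip(refl.hkl, refl.F):
        phase = np.exp(-2j * np.pi * (h * x[:, None, None] + k * y[None, :, None]
                                      + l * z[None, None, :]))
        rho += F * phase + np.conj(F) * np.conj(phase)
    return rho.real / V


def make_example(seed, n_residues=4, bin_index=10, target_rmsd=0.5, J=3,
                 omit_range=None, keep_cell=True):
    """One full dataset example from a seeded fixture pair.  Small fragments
    get a proportionally smaller terminal-omission range."""
    spec = fixtures.FixtureSpec(n_residues=n_residues, target_rmsd=target_rmsd,
                                seed=seed)
    truth = fixtures.make_fragment(spec)
    pred = fixtures.make_prediction(truth, spec)
    bin = pipeline.assign_bin(bin_index)
    if omit_range is None:
        omit_range = (3, 7) if n_residues >= 9 else (1, max(1, n_residues - 3))
    return pipeline.build_example(truth, pred, bin, np.random.default_rng(seed),
                                  J=J, omit_range=omit_range, keep_cell=keep_cell)
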