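import gemmi
import numpy as np
import pytest

from crysvit import crystal, io, scatter
from crysvit.crystal import Atom, Fragment, Residue, UnitCellModel
from crysvit.scatter import MapGrid, ReflectionSet

from conftest import direct_density_sum


def _one_atom_cell(frac_pos, lengths=(10.0, 10.0, 10.0), b=0.0, element="C"):
    xyz = np.asarray(frac_pos) * np.asarray(lengths)
    frag = Fragment([Residue("ALA", 1, [Atom(element, "CA", xyz, b)])])
    return UnitCellModel(tuple(lengths), "P1", [frag])


def _random_refl(rng, n=40, lengths=(9.0, 11.0, 13.0), d_min=2.0):
    hkl, d = scatter.unique_hkl(lengths, d_min)
    idx = rng.choice(len(hkl), size=min(n, len(hkl)), replace=False)
    F = rng.normal(size=len(idx)) + 1j * rng.normal(size=len(idx))
    return ReflectionSet(hkl[idx], F, d[idx], d_min, lengths)


class TestScatteringFactor:
    def test_constant_z_oracle(self):
        assert scatter.scattering_factor("C", 0.37, mode="constant-Z") == 6.0

    def test_sulfur_at_zero_near_atomic_number(self):
        assert scatter.scattering_factor("S", 0.0) == pytest.approx(16.0, abs=0.5)

    def test_strictly_decreasing(self):
        s = np.linspace(0, 1.2, 200)
        for elem in ("C", "N", "O", "S"):
            f = scatter.scattering_factor(elem, s)
            assert np.all(np.diff(f) < 0)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            scatter.scattering_factor("Xx", 0.1)


class TestStructureFactors:
    def test_atom_at_origin_constant_z(self):
        refl = scatter.calc_structure_factors(_one_atom_cell((0, 0, 0)), 2.5,
                                              mode="constant-Z")
        assert np.allclose(refl.F, 6.0 + 0j)

    def test_atom_at_half_x_gives_minus_six(self):
        refl = scatter.calc_structure_factors(_one_atom_cell((0.5, 0, 0)), 2.5,
                                              mode="constant-Z")
        i = np.flatnonzero((refl.hkl == [1, 0, 0]).all(axis=1))[0]
        assert refl.F[i] == pytest.approx(-6.0 + 0j, abs=1e-9)

    def test_friedel_symmetry_by_direct_sum(self, p21_cell):
        """F(-h,-k,-l) = conj F(h,k,l): recompute mates by direct sum."""
        refl = scatter.calc_structure_factors(p21_cell, 2.5)
        frac = p21_cell.fractional_coords()
        b = p21_cell.all_b_factors()
        elements = np.array(p21_cell.all_elements())
        rng = np.random.default_rng(0)
        for i in rng.choice(len(refl.F), 20, replace=False):
            h = -refl.hkl[i]
            s = 1.0 / refl.d[i]
            F = 0j
            for e, bj, x in zip(elements, b, frac):
                F += (scatter.scattering_factor(e, s) * np.exp(-bj * s * s / 4)
                      * np.exp(2j * np.pi * (x @ h)))
            assert F == pytest.approx(np.conj(refl.F[i]), abs=1e-8 * abs(F) + 1e-10)

    def test_p21_systematic_absences(self, p21_refl):
        axis = (p21_refl.hkl[:, 0] == 0) & (p21_refl.hkl[:, 2] == 0)
        odd = axis & (p21_refl.hkl[:, 1] % 2 == 1)
        assert odd.any()
        assert np.abs(p21_refl.F[odd]).max() < 1e-8

    def test_cross_check_against_external_calculator(self, p21_cell, tmp_path):
        """Independent oracle: gemmi's direct summation on the same model."""
        refl = scatter.calc_structure_factors(p21_cell, 2.5)
        pdb = tmp_path / "cell.pdb"
        io.write_pdb(pdb, p21_cell.fragments_in_cell, p21_cell.cell_lengths, "P1")
        st = gemmi.read_structure(str(pdb))
        st.setup_entities()
        calc = gemmi.StructureFactorCalculatorX(st.cell)
        rng = np.random.default_rng(1)
        for i in rng.choice(len(refl.F), 40, replace=False):
            h, k, l = (int(v) for v in refl.hkl[i])
            Fg = complex(calc.calculate_sf_from_model(st[0], [h, k, l]))
            assert refl.F[i] == pytest.approx(Fg, rel=5e-3, abs=1e-3)


class TestDensityMap:
    def test_fft_equals_direct_triple_sum(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            refl = _random_refl(rng, n=25, lengths=(6.0, 7.0, 8.0))
            rho = scatter.density_map(refl, (8, 8, 8)).values
            oracle = direct_density_sum(refl, (8, 8, 8))
            assert np.abs(rho - oracle).max() < 1e-8 * max(1.0, np.abs(oracle).max())

    def test_mean_zero(self, p21_refl):
        m = scatter.density_map(p21_refl, (24, 30, 16))
        assert abs(m.values.mean()) < 1e-10

    def test_peak_at_atom(self):
        cell = _one_atom_cell((0.3, 0.6, 0.2), b=20.0)
        refl = scatter.calc_structure_factors(cell, 2.0)
        m = scatter.density_map(refl, (12, 12, 12))
        peak = np.unravel_index(np.argmax(m.values), m.shape)
        assert peak == (round(0.3 * 12) % 12, round(0.6 * 12) % 12, round(0.2 * 12) % 12)

    def test_linearity_in_F(self):
        rng = np.random.default_rng(3)
        r1 = _random_refl(rng)
        r2 = r1.with_F(rng.normal(size=len(r1.F)) + 1j * rng.normal(size=len(r1.F)))
        shape = (10, 12, 15)
        m12 = scatter.density_map(r1.with_F(r1.F + 2.0 * r2.F), shape).values
        m1 = scatter.density_map(r1, shape).values
        m2 = scatter.density_map(r2, shape).values
        assert np.allclose(m12, m1 + 2.0 * m2, atol=1e-12)

    def test_coarse_grid_rejected(self, p21_refl):
        with pytest.raises(ValueError):
            scatter.density_map(p21_refl, (4, 4, 4))

    def test_roundtrip_to_structure_factors(self, p21_refl):
        m = scatter.density_map(p21_refl, (24, 30, 16))
        back = scatter.map_to_structure_factors(m, p21_refl)
        assert np.abs(back.F - p21_refl.F).max() < 1e-8 * np.abs(p21_refl.F).max()


class TestPatterson:
    def test_centrosymmetry(self, p21_refl):
        p = scatter.patterson_map(p21_refl, (24, 30, 16)).values
        inv = p[tuple(np.ix_(*[(-np.arange(n)) % n for n in p.shape]))]
        assert np.abs(p - inv).max() < 1e-10 * np.abs(p).max()

    def test_origin_is_global_maximum(self):
        rng = np.random.default_rng(4)
        for seed in range(20):
            cell = _one_atom_cell(rng.uniform(0, 1, 3), b=15.0)
            cell.fragments_in_cell[0].residues.append(
                Residue("ALA", 2, [Atom("O", "O", rng.uniform(0, 8, 3), 10.0)]))
            refl = scatter.calc_structure_factors(cell, 2.0)
            p = scatter.patterson_map(refl, (12, 12, 12)).values
            assert p[0, 0, 0] == p.max()

    def test_two_atom_vector_peaks(self):
        # equal atoms separated by t: off-origin peaks at +/-t, height ~ half origin
        lengths = (12.0, 12.0, 12.0)
        t_frac = np.array([0.25, 0.5, 0.25])
        frag = Fragment([
            Residue("ALA", 1, [Atom("C", "CA", np.zeros(3), 0.0)]),
            Residue("ALA", 2, [Atom("C", "CA", t_frac * lengths, 0.0)]),
        ])
        cell = UnitCellModel(lengths, "P1", [frag])
        refl = scatter.calc_structure_factors(cell, 2.0, mode="constant-Z")
        p = scatter.patterson_map(refl, (12, 12, 12)).values
        peak_idx = (np.asarray(t_frac * 12)).astype(int)
        assert p[tuple(peak_idx)] == pytest.approx(p[0, 0, 0] / 2, rel=0.05)
        assert p[tuple(-peak_idx)] == pytest.approx(p[0, 0, 0] / 2, rel=0.05)

    def test_phase_invariance(self):
        rng = np.random.default_rng(5)
        refl = _random_refl(rng)
        scrambled = refl.with_F(refl.F * np.exp(1j * rng.uniform(0, 2 * np.pi, len(refl.F))))
        shape = (10, 12, 15)
        p1 = scatter.patterson_map(refl, shape).values
        p2 = scatter.patterson_map(scrambled, shape).values
        assert np.abs(p1 - p2).max() < 1e-9 * np.abs(p1).max()

    def test_translation_invariance(self, small_fragment):
        cellA = crystal.determine_cell(crystal.reorient(small_fragment))
        fragB = cellA.fragments_in_cell[0].transformed(
            shift=np.asarray(cellA.cell_lengths) * np.array([0.25, 0.5, 0.125]))
        cellB = UnitCellModel(cellA.cell_lengths, "P1", [fragB])
        shape = (18, 12, 12)
        pA = scatter.patterson_map(scatter.calc_structure_factors(cellA, 2.5), shape).values
        pB = scatter.patterson_map(scatter.calc_structure_factors(cellB, 2.5), shape).values
        assert np.abs(pA - pB).max() < 1e-8 * np.abs(pA).max()


class TestAutocorrelationIdentity:
    def test_matches_direct_synthesis(self, p21_refl):
        shape = (24, 30, 16)
        direct = scatter.patterson_map(p21_refl, shape).values
        auto = scatter.patterson_via_autocorrelation(
            scatter.density_map(p21_refl, shape)).values
        assert np.abs(direct - auto).max() < 1e-6 * np.abs(direct).max()

    def test_zero_map(self):
        e = MapGrid(np.zeros((6, 6, 6)), (10, 10, 10), "density", 2.0)
        assert np.all(scatter.patterson_via_autocorrelation(e).values == 0)

    def test_delta_at_origin(self):
        vals = np.zeros((6, 6, 6))
        vals[0, 0, 0] = 3.0
        e = MapGrid(vals, (10, 10, 10), "density", 2.0)
        p = scatter.patterson_via_autocorrelation(e).values
        assert p[0, 0, 0] > 0
        assert np.abs(p - np.where(vals > 0, p[0, 0, 0], 0.0)).max() < 1e-12
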