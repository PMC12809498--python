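import numpy as np
import pytest

from crysvit import metrics, scatter
from crysvit.scatter import MapGrid, ReflectionSet


def _refl_with_phases(phases_deg, d=None, lengths=(20.0, 20.0, 20.0), d_min=2.0):
    n = len(phases_deg)
    hkl, dd = scatter.unique_hkl(lengths, d_min)
    hkl, dd = hkl[:n], dd[:n]
    F = np.exp(1j * np.radians(phases_deg))
    return ReflectionSet(hkl, F, dd if d is None else d, d_min, lengths)


def _grid(values, lengths=(10, 10, 10)):
    return MapGrid(np.asarray(values, float), lengths, "density", 2.0)


class TestPearsonCC:
    def test_identity_and_negation(self):
        rng = np.random.default_rng(0)
        e = _grid(rng.normal(size=(6, 6, 6)))
        assert metrics.pearson_cc(e, e) == pytest.approx(1.0)
        assert metrics.pearson_cc(e, _grid(-e.values)) == pytest.approx(-1.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        e = _grid(rng.normal(size=(5, 5, 5)))
        assert metrics.pearson_cc(e, _grid(e.values + 3.7)) == pytest.approx(1.0)

    def test_masked_subset(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(6, 6, 6))
        b = a.copy()
        b[3:] = rng.normal(size=(3, 6, 6))  # corrupt the unmasked half
        mask = np.zeros_like(a, dtype=bool)
        mask[:3] = True
        assert metrics.pearson_cc(_grid(a), _grid(b), mask) == pytest.approx(1.0)

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError):
            metrics.pearson_cc(_grid(np.ones((4, 4, 4))), _grid(np.ones((4, 4, 4))))


class TestPhaseError:
    def test_self_comparison_is_zero(self, p21_refl):
        cmp = metrics.phase_error(p21_refl, p21_refl)
        assert cmp.mean_unweighted == 0.0
        assert cmp.cos_unweighted == pytest.approx(1.0)

    def test_constant_30_degree_shift(self):
        rng = np.random.default_rng(3)
        phases = rng.uniform(0, 360, 500)
        truth = _refl_with_phases(phases)
        pred = truth.with_F(truth.F * np.exp(1j * np.radians(30.0)))
        cmp = metrics.phase_error(pred, truth)
        assert cmp.mean_unweighted == pytest.approx(30.0, abs=1e-9)
        assert cmp.cos_unweighted == pytest.approx(np.cos(np.radians(30.0)), abs=1e-9)

    def test_random_phases_average_90(self):
        rng = np.random.default_rng(4)
        truth = _refl_with_phases(rng.uniform(0, 360, 10_000))
        pred = truth.with_F(np.exp(1j * rng.uniform(0, 2 * np.pi, 10_000)))
        cmp = metrics.phase_error(pred, truth)
        assert cmp.mean_unweighted == pytest.approx(90.0, abs=2.0)

    def test_weighted_mean_uses_fom_normalisation(self):
        truth = _refl_with_phases(np.zeros(4))
        pred = truth.with_F(np.exp(1j * np.radians([0.0, 0.0, 90.0, 90.0])))
        foms = np.array([1.0, 1.0, 0.25, 0.25])
        cmp = metrics.phase_error(pred, truth, foms)
        assert cmp.mean_unweighted == pytest.approx(45.0)
        assert cmp.mean_weighted == pytest.approx(90.0 * 0.5 / 2.5)

    def test_mismatched_indices_rejected(self, p21_refl):
        other = ReflectionSet(p21_refl.hkl[:-1], p21_refl.F[:-1],
                              p21_refl.d[:-1], p21_refl.d_min, p21_refl.cell_lengths)
        with pytest.raises(ValueError):
            metrics.phase_error(other, p21_refl)


class TestNormalizedAmplitudes:
    def test_unit_second_moment_per_shell(self, p21_refl):
        E = metrics.normalized_amplitudes(p21_refl, n_shells=8)
        shell_of, _ = metrics.resolution_shells(p21_refl.d, 8)
        for i in range(8):
            assert (E[shell_of == i] ** 2).mean() == pytest.approx(1.0, abs=1e-10)

    def test_equal_amplitudes_give_unit_E(self):
        refl = _refl_with_phases(np.zeros(200))
        E = metrics.normalized_amplitudes(refl, n_shells=4)
        assert np.allclose(E, 1.0)

    def test_scale_invariance(self, p21_refl):
        E1 = metrics.normalized_amplitudes(p21_refl)
        E2 = metrics.normalized_amplitudes(p21_refl.with_F(10.0 * p21_refl.F))
        assert np.allclose(E1, E2)


class TestSigmaA:
    def test_perfect_model(self):
        rng = np.random.default_rng(5)
        E = np.abs(rng.normal(size=2000)) + 0.05
        shell_of = np.repeat(np.arange(10), 200)
        est = metrics.estimate_sigma_a(E, E, shell_of)
        assert np.all(est.sigma_a >= 0.95)
        assert np.all(est.sigma_a < 1.0)

    def test_uninformative_model(self):
        rng = np.random.default_rng(6)
        shell_of = np.repeat(np.arange(10), 1000)
        E_o = np.abs(rng.normal(size=10_000)) + 0.05
        E_c = np.abs(rng.normal(size=10_000)) + 0.05
        est = metrics.estimate_sigma_a(E_o, E_c, shell_of)
        assert np.all(est.sigma_a < 0.2)

    def test_tiny_shell_rejected(self):
        with pytest.raises(ValueError):
            metrics.estimate_sigma_a(np.ones(4), np.ones(4), np.array([0, 0, 1, 1]))


class TestFom:
    def _sa(self, value, n=1):
        return metrics.SigmaAEstimate(np.full(n, value), np.full(n, value),
                                      np.zeros(1, dtype=int), np.array([]))

    def test_zero_X_gives_zero_acentric(self):
        m = metrics.fom(np.zeros(1), np.ones(1), self._sa(0.5), np.array([False]))
        assert m[0] == 0.0

    def test_monotone_and_saturating(self):
        sa = metrics.SigmaAEstimate(np.array([0.5]), np.array([0.5]),
                                    np.zeros(50, dtype=int), np.array([]))
        E = np.linspace(0, 4, 50)
        for cent in (False, True):
            m = metrics.fom(E, np.ones(50), sa, np.full(50, cent))
            assert np.all(np.diff(m) > 0), "m must increase with X below saturation"
        big = metrics.fom(np.array([50.0]), np.ones(1), sa, np.array([False]))
        assert big[0] > 0.97


class TestSigmaAWeightedMap:
    def test_perfect_partial_model(self, p21_cell, p21_refl):
        shape = (24, 30, 16)
        truth_map = scatter.density_map(p21_refl, shape)
        shell_of, _ = metrics.resolution_shells(p21_refl.d)
        E = metrics.normalized_amplitudes(p21_refl)
        sa = metrics.estimate_sigma_a(E, E, shell_of, F_obs=p21_refl.F, F_calc=p21_refl.F)
        m = metrics.fom(E, E, sa, metrics.centric_zone(p21_refl.hkl))
        wmap = metrics.sigmaa_weighted_map(p21_refl.amplitudes, p21_refl, sa, m, shape)
        assert metrics.pearson_cc(wmap, truth_map) >= 0.99

    def test_zero_fom_gives_zero_map(self, p21_refl):
        sa = metrics.SigmaAEstimate(np.zeros(1), np.zeros(1),
                                    np.zeros(len(p21_refl.F), dtype=int), np.array([]))
        m = np.zeros(len(p21_refl.F))
        wmap = metrics.sigmaa_weighted_map(p21_refl.amplitudes, p21_refl, sa, m, (24, 30, 16))
        assert np.abs(wmap.values).max() == 0.0
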