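"""Eigenmode extraction, periodicity and localisation diagnostics."""

import numpy as np
import pytest

import connfield as cf
from connfield.dynamics import DegenerateInputError
from connfield.modes import NotOscillatoryError

from conftest import random_symmetric


class TestAnatomicalModes:
    def test_scaled_identity_reconstructs_exactly(self):
        w = 3.0 * np.eye(5)
        ms = cf.anatomical_modes(w)
        assert np.allclose(ms.eigenvalues, 3.0)
        recon = (ms.modes * ms.eigenvalues) @ ms.modes.conj().T
        assert np.allclose(recon.real, w, atol=1e-10)

    def test_symmetric_reconstruction_and_realness(self, footprint66):
        ms = cf.anatomical_modes(footprint66)
        assert np.max(np.abs(ms.eigenvalues.imag)) <= 1e-10
        assert np.max(np.abs(ms.modes.imag)) <= 1e-10
        recon = (ms.modes.real * ms.eigenvalues.real) @ ms.modes.real.T
        norm = np.linalg.norm(footprint66.weights)
        assert np.linalg.norm(recon - footprint66.weights) <= 1e-8 * norm

    def test_columns_unit_norm_sorted_descending(self, footprint66):
        ms = cf.anatomical_modes(footprint66)
        assert np.allclose(np.linalg.norm(ms.modes, axis=0), 1.0)
        assert np.all(np.diff(ms.eigenvalues.real) <= 1e-12)

    def test_antisymmetric_pair_eigenvalues(self):
        ms = cf.anatomical_modes(np.array([[0.0, 1.0], [-1.0, 0.0]]))
        assert np.allclose(sorted(ms.eigenvalues, key=lambda z: z.imag), [-1j, 1j])

    def test_conjugate_pairs_adjacent(self):
        ei = cf.make_ei_clique_fixture()
        ms = cf.anatomical_modes(ei)
        lam = ms.eigenvalues
        assert lam[0].imag > 0
        assert lam[1] == pytest.approx(np.conj(lam[0]))

    def test_circulant_modes_concentrate_on_single_wavenumber(self, circulant64):
        """Closed-form circulant eigenvectors are +-m sinusoid pairs."""
        ms = cf.anatomical_modes(circulant64)
        for l in range(64):
            v = ms.modes[:, l].real
            try:
                _, conc = cf.dominant_wavenumber(v)
            except DegenerateInputError:
                continue  # uniform m=0 mode
            assert conc >= 0.99

    def test_phase_convention_largest_entry_positive_real(self):
        ei = cf.make_ei_clique_fixture()
        ms = cf.anatomical_modes(ei)
        for l in range(ms.n_modes):
            v = ms.modes[:, l]
            piv = np.argmax(np.abs(v))
            assert v[piv].real > 0
            assert abs(v[piv].imag) <= 1e-10


class TestTimeConstants:
    @pytest.mark.parametrize(
        "lam,expected", [(-0.5, 2.0), (-1.0, 1.0), (-0.1 + 2j, 10.0)]
    )
    def test_reciprocal_of_decay_rate(self, lam, expected):
        ms = cf.ModeSet(
            eigenvalues=np.array([lam]), modes=np.ones((1, 1), complex),
            source="jacobian",
        )
        assert cf.time_constants(ms)[0] == pytest.approx(expected)

    def test_non_decaying_flagged_infinite(self):
        ms = cf.ModeSet(
            eigenvalues=np.array([0.2 + 0j, -1.0 + 0j]),
            modes=np.eye(2, dtype=complex), source="jacobian",
        )
        taus = cf.time_constants(ms)
        assert np.isinf(taus[0]) and taus[1] == 1.0

    def test_oscillation_frequency_reported(self):
        from connfield.modes import oscillation_frequencies

        ms = cf.ModeSet(
            eigenvalues=np.array([-0.1 + 2j]), modes=np.ones((1, 1), complex),
            source="jacobian",
        )
        assert oscillation_frequencies(ms)[0] == pytest.approx(2.0)


class TestRayleigh:
    def test_negative_identity_zero_residual(self):
        j = -np.eye(4)
        ms = cf.anatomical_modes(j, source="jacobian")
        assert np.allclose(cf.rayleigh_check(ms, j), 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_symmetric_jacobian_residuals_small(self, seed):
        r = np.random.default_rng(seed)
        a = r.standard_normal((12, 12))
        j = (a + a.T) / 2
        ms = cf.anatomical_modes(j, source="jacobian")
        assert np.max(cf.rayleigh_check(ms, j)) <= 1e-8

    def test_perturbed_eigenvector_detected(self):
        r = np.random.default_rng(3)
        a = r.standard_normal((6, 6))
        j = (a + a.T) / 2
        ms = cf.anatomical_modes(j, source="jacobian")
        bad = ms.modes.copy()
        v = bad[:, 0] + 0.2 * bad[:, 1]
        bad[:, 0] = v / np.linalg.norm(v)
        ms_bad = cf.ModeSet(eigenvalues=ms.eigenvalues, modes=bad, source="jacobian")
        assert cf.rayleigh_check(ms_bad, j)[0] > 1e-3

    def test_non_symmetric_skipped_with_notice(self):
        j = np.array([[0.0, 1.0], [-1.0, 0.0]])
        ms = cf.anatomical_modes(j, source="jacobian")
        with pytest.warns(UserWarning, match="symmetric"):
            res = cf.rayleigh_check(ms, j)
        assert np.all(np.isnan(res))


class TestModeSimilarity:
    def test_self_and_sign_flip(self, rng):
        v = rng.standard_normal(10)
        assert cf.mode_similarity(v, v) == pytest.approx(1.0)
        assert cf.mode_similarity(v, -v) == pytest.approx(1.0)

    def test_orthogonal_pair(self):
        assert cf.mode_similarity([1, 0, 0], [0, 1, 0]) == pytest.approx(0.0)

    def test_global_phase_invariance(self, rng):
        v = rng.standard_normal(6) + 1j * rng.standard_normal(6)
        assert cf.mode_similarity(v, v * np.exp(0.7j)) == pytest.approx(1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            cf.mode_similarity(np.zeros(3), np.ones(3))


class TestLocalizationIndex:
    def test_uniform_vector(self):
        assert cf.localization_index(np.ones(10)) == pytest.approx(0.1)

    def test_one_hot(self):
        v = np.zeros(10)
        v[3] = 2.0
        assert cf.localization_index(v) == pytest.approx(1.0)

    def test_full_period_sinusoid_exact(self):
        n = 60
        for m in (1, 3, 7):
            v = np.cos(2 * np.pi * m * np.arange(n) / n)
            # direct summation: sum cos^4 = 3n/8, (sum cos^2)^2 = (n/2)^2
            assert cf.localization_index(v) == pytest.approx(3 / (2 * n))


class TestDominantWavenumber:
    def test_pure_cosine_three_periods(self):
        n = 60
        v = np.cos(2 * np.pi * 3 * np.arange(n) / n)
        k, conc = cf.dominant_wavenumber(v, spacing=1.0)
        assert k == pytest.approx(2 * np.pi * 3 / 60)
        assert conc == pytest.approx(1.0)

    def test_one_hot_flat_spectrum(self):
        n = 64
        v = np.zeros(n)
        v[5] = 1.0
        _, conc = cf.dominant_wavenumber(v)
        assert conc == pytest.approx(2 / (n - 1), rel=0.05)

    def test_second_incommensurate_sinusoid_halves_concentration(self):
        n = 64
        t = np.arange(n)
        one = np.cos(2 * np.pi * 3 * t / n)
        two = one + np.sin(2 * np.pi * 11 * t / n)
        _, c1 = cf.dominant_wavenumber(one)
        _, c2 = cf.dominant_wavenumber(two)
        assert c2 == pytest.approx(c1 / 2, rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            cf.dominant_wavenumber(np.full(8, 2.5))


class TestPhaseLags:
    @staticmethod
    def _modeset(entries, lam=1j):
        v = np.asarray(entries, dtype=complex)
        v = v / np.linalg.norm(v)
        return cf.ModeSet(
            eigenvalues=np.array([lam]), modes=v[:, None], source="jacobian"
        )

    def test_quadrature_pair(self):
        lags = cf.phase_lags(self._modeset([1.0, 1j]), 0)
        assert lags[1] == pytest.approx(np.pi / 2)

    def test_antiphase_pair(self):
        lags = cf.phase_lags(self._modeset([1.0, -1.0]), 0)
        assert abs(lags[1]) == pytest.approx(np.pi)

    def test_conjugate_mode_negates_lags(self):
        lags = cf.phase_lags(self._modeset([1.0, 0.5 + 0.5j]), 0)
        conj = cf.phase_lags(self._modeset([1.0, 0.5 - 0.5j], lam=-1j), 0)
        assert np.allclose(conj, -lags)

    def test_real_mode_rejected(self):
        with pytest.raises(NotOscillatoryError):
            cf.phase_lags(self._modeset([1.0, 0.5], lam=-1.0 + 0j), 0)


class TestStructureSignatures:
    """The homogeneity/heterogeneity/asymmetry signatures of connectivity."""

    def test_clustering_tracks_principal_mode_on_clique_fixture(self):
        # footprint plus a dense local clique: both the principal eigenvector
        # and the clustering profile peak on the clique
        base = cf.make_exponential_footprint(66, cf.KernelSpec(sigma=5.0))
        conns = [
            cf.TwoPointConnection(i, j, 0.8, reciprocal=True)
            for i in range(28, 36) for j in range(28, 36) if i < j
        ]
        m = cf.add_two_point_connections(base, conns)
        v1 = cf.anatomical_modes(m).modes[:, 0].real
        gamma = cf.clustering_coefficients(m)
        r = np.corrcoef(np.abs(v1), gamma)[0, 1]
        assert r >= 0.7

    def test_two_point_perturbation_localises_dominant_mode(self, footprint66):
        pert = cf.add_two_point_connections(
            footprint66, [cf.TwoPointConnection(20, 25, 2.0, reciprocal=True)]
        )
        ipr_base = cf.localization_index(
            cf.anatomical_modes(footprint66).modes[:, 0]
        )
        ipr_pert = cf.localization_index(cf.anatomical_modes(pert).modes[:, 0])
        assert ipr_pert > ipr_base

    def test_ei_fixture_complex_leading_pair_symmetric_baseline_real(
        self, footprint66
    ):
        ms_sym = cf.anatomical_modes(footprint66)
        assert np.max(np.abs(ms_sym.eigenvalues.imag)) == 0.0
        ms_ei = cf.anatomical_modes(cf.make_ei_clique_fixture())
        assert abs(ms_ei.eigenvalues[0].imag) > 0.1

    def test_translationally_invariant_asymmetric_keeps_periodicity(self):
        """A circulant but non-symmetric kernel still has sinusoidal modes
        (now complex), with concentrated spatial spectra."""
        n = 64
        idx = np.arange(n)
        d = (idx[None, :] - idx[:, None]) % n  # forward distance
        w = 0.1 * np.exp(-np.minimum(d, n - d) / 5.0) * (1 + 0.5 * ((d < n - d) * 2 - 1))
        np.fill_diagonal(w, 0.0)
        m = cf.ConnectivityMatrix(weights=w, directed=True)
        ms = cf.anatomical_modes(m)
        concs = []
        for l in range(n):
            v = ms.modes[:, l]
            part = v.real if np.linalg.norm(v.real) > 1e-8 else v.imag
            try:
                _, conc = cf.dominant_wavenumber(part)
            except DegenerateInputError:
                continue
            concs.append(conc)
        assert np.min(concs) >= 0.9
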