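"""Kirchhoff construction, eigendecomposition and fluctuation statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gnmunfold.gnm import (
    InvalidModeError,
    build_kirchhoff,
    connected_component_count,
    cross_correlation,
    decompose,
    fit_gamma,
    fluctuation_report,
    mode_subset_msf,
    msfid_matrix,
    residue_msf,
    theoretical_bfactors,
    topology_from_contacts,
)
from gnmunfold.synthetic import make_linear_chain, make_random_globule

from conftest import dense_pseudoinverse, random_connected_topology


def path_eigenvalues(n):
    """Closed-form spectrum of the n-site path-graph Laplacian."""
    return 4.0 * np.sin(np.arange(n) * np.pi / (2 * n)) ** 2


class TestBuildKirchhoff:
    def test_single_contact_pair(self):
        topo = build_kirchhoff(np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        assert topo.matrix.tolist() == [[1.0, -1.0], [-1.0, 1.0]]

    def test_cutoff_boundary_is_inclusive(self):
        topo = build_kirchhoff(np.array([[0.0, 0, 0], [7.3, 0, 0]]), 7.3)
        assert (0, 1) in topo.contacts

    def test_beyond_cutoff_no_contact(self):
        topo = build_kirchhoff(np.array([[0.0, 0, 0], [7.31, 0, 0]]), 7.3)
        assert not topo.contacts

    def test_three_collinear_sites(self):
        topo = build_kirchhoff(np.array([[0.0, 0, 0], [6.0, 0, 0], [12.0, 0, 0]]))
        assert set(topo.contacts) == {(0, 1), (1, 2)}
        assert topo.matrix.tolist() == [
            [1.0, -1.0, 0.0], [-1.0, 2.0, -1.0], [0.0, -1.0, 1.0]]

    def test_fewer_than_two_sites_rejected(self):
        with pytest.raises(ValueError):
            build_kirchhoff(np.array([[0.0, 0, 0]]))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_rows_sum_to_zero_and_matrix_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 25, size=(rng.integers(2, 40), 3))
        m = build_kirchhoff(coords).matrix
        assert np.array_equal(m, m.T)
        assert np.all(m.sum(axis=1) == 0)
        assert np.all(np.diag(m) == -(m.sum(axis=1) - np.diag(m)))

    def test_diagonal_equals_contact_degree(self):
        topo = random_connected_topology(20, np.random.default_rng(0))
        assert np.array_equal(np.diag(topo.matrix), topo.degree())


class TestDecompose:
    @pytest.mark.parametrize("n", range(3, 51))
    def test_path_graph_spectrum_closed_form(self, n):
        chain = make_linear_chain(n, spacing=3.8)
        d = decompose(build_kirchhoff(chain))
        assert np.allclose(d.eigenvalues, path_eigenvalues(n), atol=1e-10)

    def test_two_disjoint_components_two_zero_modes(self):
        topo = topology_from_contacts(4, {(0, 1), (2, 3)})
        assert decompose(topo).zero_mode_count == 2

    def test_zero_modes_equal_component_count_on_random_topologies(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            k = min(int(rng.integers(n - 1, 3 * n)), n * (n - 1) // 2)
            pairs = set()
            while len(pairs) < k:
                i, j = sorted(rng.choice(n, size=2, replace=False))
                pairs.add((int(i), int(j)))
            topo = topology_from_contacts(n, pairs)
            d = decompose(topo)
            assert d.zero_mode_count == connected_component_count(topo)

    def test_eigenvectors_orthonormal_and_reconstruct(self):
        topo = random_connected_topology(25, np.random.default_rng(5))
        d = decompose(topo)
        assert np.allclose(d.eigenvectors.T @ d.eigenvectors,
                           np.eye(25), atol=1e-10)
        recon = d.eigenvectors @ np.diag(d.eigenvalues) @ d.eigenvectors.T
        assert np.allclose(recon, topo.matrix, atol=1e-9)

    def test_sign_convention_deterministic(self):
        topo = random_connected_topology(15, np.random.default_rng(8))
        a, b = decompose(topo), decompose(topo)
        assert np.array_equal(a.eigenvectors, b.eigenvectors)


class TestFluctuationStatistics:
    @pytest.fixture
    def two_site(self):
        return decompose(build_kirchhoff(np.array([[0.0, 0, 0], [5.0, 0, 0]])))

    def test_two_site_msf_quarter(self, two_site):
        assert np.allclose(residue_msf(two_site), [0.25, 0.25])

    def test_two_site_cross_correlation_off_diagonal(self, two_site):
        assert cross_correlation(two_site)[0, 1] == pytest.approx(-0.25)

    def test_two_site_msfid_value(self, two_site):
        # 3·(0.25 + 0.25 + 0.5) with the adopted distance-fluctuation prefactor
        assert msfid_matrix(two_site)[0, 1] == pytest.approx(3.0)

    def test_cross_correlation_diagonal_is_msf(self):
        d = decompose(random_connected_topology(20, np.random.default_rng(1)))
        assert np.allclose(np.diag(cross_correlation(d)), residue_msf(d))

    def test_cauchy_schwarz_bound(self):
        d = decompose(random_connected_topology(25, np.random.default_rng(2)))
        c = cross_correlation(d)
        m = np.diag(c)
        assert np.all(np.abs(c) <= np.sqrt(np.outer(m, m)) + 1e-12)

    def test_msfid_symmetric_zero_diagonal_nonnegative(self):
        d = decompose(random_connected_topology(25, np.random.default_rng(3)))
        m = msfid_matrix(d)
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0)
        assert np.all(m >= -1e-12)

    def test_msf_strictly_positive_on_connected_network(self):
        d = decompose(random_connected_topology(12, np.random.default_rng(4)))
        assert np.all(residue_msf(d) > 0)

    def test_mirror_symmetric_network_has_symmetric_msf(self):
        chain = make_linear_chain(9, spacing=3.8)
        msf = residue_msf(decompose(build_kirchhoff(chain)))
        assert np.allclose(msf, msf[::-1], atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_statistics_match_dense_pseudoinverse_oracle(self, seed):
        rng = np.random.default_rng(seed)
        topo = random_connected_topology(int(rng.integers(5, 31)), rng)
        d = decompose(topo)
        g = dense_pseudoinverse(topo)
        assert np.allclose(residue_msf(d), np.diag(g), atol=1e-8)
        assert np.allclose(cross_correlation(d), g, atol=1e-8)
        dd = np.diag(g)
        expect = 3.0 * (dd[:, None] + dd[None, :] - 2 * g)
        np.fill_diagonal(expect, 0.0)
        assert np.allclose(msfid_matrix(d), expect, atol=1e-8)

    def test_site_relabeling_equivariance(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 18, size=(16, 3))
        perm = rng.permutation(16)
        d0 = decompose(build_kirchhoff(coords))
        d1 = decompose(build_kirchhoff(coords[perm]))
        assert np.allclose(residue_msf(d1), residue_msf(d0)[perm], atol=1e-9)
        assert np.allclose(msfid_matrix(d1),
                           msfid_matrix(d0)[np.ix_(perm, perm)], atol=1e-9)

    def test_msfid_rank_order_invariant_to_gamma(self):
        d = decompose(random_connected_topology(15, np.random.default_rng(6)))
        a = msfid_matrix(d, gamma=1.0)
        b = msfid_matrix(d, gamma=0.37)
        iu = np.triu_indices(15, k=1)
        assert np.array_equal(np.argsort(a[iu]), np.argsort(b[iu]))


class TestModeSubsets:
    @pytest.fixture
    def decomp(self):
        return decompose(random_connected_topology(20, np.random.default_rng(9)))

    def test_all_nonzero_modes_equals_full_msf(self, decomp):
        full = residue_msf(decomp)
        k_all = decomp.nonzero_modes.size
        assert np.allclose(mode_subset_msf(decomp, k_slowest=k_all), full)

    def test_subset_msf_bounded_by_full(self, decomp):
        assert np.all(mode_subset_msf(decomp, k_slowest=6)
                      <= residue_msf(decomp) + 1e-12)

    def test_zero_mode_in_subset_rejected(self, decomp):
        with pytest.raises(InvalidModeError):
            residue_msf(decomp, mode_subset=[0, 5])

    def test_too_many_slow_modes_rejected(self, decomp):
        with pytest.raises(InvalidModeError):
            mode_subset_msf(decomp, k_slowest=25)


class TestBfactorsAndGammaFit:
    def test_bfactor_prefactor_and_linearity(self):
        assert theoretical_bfactors(np.array([0.0]))[0] == 0.0
        assert theoretical_bfactors(np.array([3 / (8 * np.pi**2)]))[0] == pytest.approx(1.0)
        msf = np.array([0.1, 0.4, 0.9])
        assert np.allclose(theoretical_bfactors(3 * msf),
                           3 * theoretical_bfactors(msf))

    def test_exact_recovery_of_known_gamma(self):
        th = np.array([2.0, 4.0, 6.0])
        fit = fit_gamma(th, th / 0.5)
        assert fit.gamma == pytest.approx(0.5)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_doubling_experiment_halves_gamma(self):
        rng = np.random.default_rng(0)
        th = rng.uniform(1, 10, 50)
        ex = rng.uniform(1, 10, 50)
        assert fit_gamma(th, 2 * ex).gamma == pytest.approx(
            fit_gamma(th, ex).gamma / 2)

    def test_lsq_method_also_recovers_exact_scale(self):
        th = np.array([2.0, 4.0, 6.0])
        assert fit_gamma(th, th / 0.75, method="lsq").gamma == pytest.approx(0.75)

    def test_nonpositive_experimental_mean_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma(np.array([1.0, 2.0]), np.array([-3.0, 1.0]))

    def test_report_bundles_consistent_statistics(self):
        d = decompose(random_connected_topology(18, np.random.default_rng(13)))
        rep = fluctuation_report(d, gamma=0.751)
        assert np.allclose(np.diag(rep.cross_correlation), rep.msf)
        assert np.allclose(rep.bfactors, theoretical_bfactors(rep.msf))
        assert np.allclose(rep.msfid, msfid_matrix(d, gamma=0.751))
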