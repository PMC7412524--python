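"""Entity pedigree, sparse relationship inverse, MME solver, variance
re-estimation."""

import numpy as np
import pytest

from hivesim import (
    DenseEntityPedigree,
    MixedModelEquations,
    expected_relationship,
    reestimate_variance,
    sample_architecture,
    solve_mme,
    sparse_a_inverse,
)
from hivesim.blup import nearest_psd


def random_entity_pedigree(rng, n_extra=50) -> DenseEntityPedigree:
    """Random station-structured entity pedigree with ~n_extra entities."""
    ep = DenseEntityPedigree()
    queens = [ep.add_base_queen() for _ in range(6)]
    pools = [ep.add_base_pool() for _ in range(3)]
    matings = {q: pools[rng.integers(len(pools))] for q in queens}
    for _ in range(n_extra):
        r = rng.random()
        q = queens[rng.integers(len(queens))]
        s = matings[q]
        if r < 0.5:
            new_q = ep.add_queen(q, s)
            matings[new_q] = (
                pools[rng.integers(len(pools))] if pools else s
            )
            queens.append(new_q)
        elif r < 0.8:
            new_p = ep.add_pool(q, s)
            pools.append(new_p)
        else:
            ep.add_worker_group(q, s)
    return ep


class TestEntityRelationships:
    def test_forward_matches_pair_recursive_oracle(self, rng):
        """A = TDT' forward construction equals the independent pair recursion."""
        for _ in range(3):
            ep = random_entity_pedigree(rng)
            oracle = expected_relationship(ep.records)
            assert np.max(np.abs(ep.a - oracle)) < 1e-10

    def test_sparse_inverse_inverts_dense_a(self, rng):
        for _ in range(3):
            ep = random_entity_pedigree(rng)
            ainv = ep.a_inverse().toarray()
            err = np.max(np.abs(ainv @ ep.a - np.eye(len(ep))))
            assert err < 1e-8

    def test_base_entities_have_unit_and_pool_d(self):
        ep = DenseEntityPedigree()
        q = ep.add_base_queen()
        p = ep.add_base_pool()
        assert ep.d[q] == 1.0
        assert ep.d[p] == pytest.approx(1.0 / 12.0)

    def test_pseudo_sire_diagonal_below_two(self, rng):
        ep = random_entity_pedigree(rng)
        for i, kind in enumerate(ep.kinds):
            if kind == "pool":
                assert ep.a[i, i] < 2.0

    def test_inbreeding_appears_for_dam_related_to_pool(self):
        # queen whose dam mated at a station founded by the dam's own dam
        ep = DenseEntityPedigree()
        q0, p0 = ep.add_base_queen(), ep.add_base_pool()
        dam = ep.add_queen(q0, p0)
        pool = ep.add_pool(q0, p0)  # station founded by q0, dam's mother
        child = ep.add_queen(dam, pool)
        assert ep.a[child, child] > 1.0

    def test_dangling_parent_rejected(self):
        ep = DenseEntityPedigree()
        ep.add_base_queen()
        with pytest.raises(ValueError):
            ep.add_queen(0, 7)

    def test_nonpositive_d_rejected(self):
        with pytest.raises(ValueError):
            sparse_a_inverse(np.array([-1]), np.array([-1]), np.array([0.0]))


def _toy_mme(rng, n_rec=10, sigma_e2=1.0):
    """Small colony dataset in 2 apiaries with a 3-generation entity pedigree."""
    ep = DenseEntityPedigree()
    queens = [ep.add_base_queen() for _ in range(4)]
    pools = [ep.add_base_pool() for _ in range(2)]
    for g in range(6):
        queens.append(ep.add_queen(queens[g], pools[g % 2]))
    wgs = []
    q_of_rec, level = [], []
    for r in range(n_rec):
        q = queens[r % len(queens)]
        wgs.append(ep.add_worker_group(q, pools[r % 2]))
        q_of_rec.append(q)
        level.append(r % 2)
    sigma = np.array([[1.0, -0.75], [-0.75, 2.0]])
    y = rng.normal(size=n_rec)
    mme = MixedModelEquations.assemble(
        np.array(level), 2, np.array(q_of_rec), np.array(wgs), y,
        ep.a_inverse(), sigma, sigma_e2,
    )
    return ep, mme, (np.array(level), np.array(q_of_rec), np.array(wgs), y, sigma)


class TestMME:
    def test_matches_dense_gls_oracle(self, rng):
        """MME solutions equal generalized least squares on the dense model."""
        ep, mme, (level, qe, we, y, sigma) = _toy_mme(rng)
        beta, u, _ = solve_mme(mme, tol=1e-12)

        n_rec, n_ent = y.size, len(ep)
        x_mat = np.zeros((n_rec, 2))
        x_mat[np.arange(n_rec), level] = 1.0
        z = np.zeros((n_rec, 2 * n_ent))
        z[np.arange(n_rec), 2 * qe] = 1.0
        z[np.arange(n_rec), 2 * we + 1] = 1.0
        g_big = np.kron(ep.a, sigma)
        v = z @ g_big @ z.T + np.eye(n_rec)
        vi = np.linalg.inv(v)
        beta_gls = np.linalg.solve(x_mat.T @ vi @ x_mat, x_mat.T @ vi @ y)
        u_gls = g_big @ z.T @ vi @ (y - x_mat @ beta_gls)
        np.testing.assert_allclose(beta, beta_gls, atol=1e-6)
        np.testing.assert_allclose(u.ravel(), u_gls, atol=1e-6)

    def test_direct_and_cg_agree(self, rng):
        _, mme, _ = _toy_mme(rng)
        _, u_cg, _ = solve_mme(mme, tol=1e-12, solver="cg")
        _, u_lu, _ = solve_mme(mme, solver="direct")
        np.testing.assert_allclose(u_cg, u_lu, atol=1e-8)

    def test_single_confounded_record_gives_zero_ebv(self, rng):
        ep = DenseEntityPedigree()
        q = ep.add_base_queen()
        p = ep.add_base_pool()
        w = ep.add_worker_group(q, p)
        sigma = np.array([[1.0, -0.75], [-0.75, 2.0]])
        mme = MixedModelEquations.assemble(
            np.array([0]), 1, np.array([q]), np.array([w]),
            np.array([3.7]), ep.a_inverse(), sigma, 1.0,
        )
        beta, u, _ = solve_mme(mme, solver="direct")
        # the record is fully absorbed by its own fixed-effect level
        assert beta[0] == pytest.approx(3.7)
        np.testing.assert_allclose(u, 0.0, atol=1e-10)

    def test_doubling_residual_variance_shrinks_ebvs(self, rng):
        ep, mme1, (level, qe, we, y, sigma) = _toy_mme(rng, sigma_e2=1.0)
        _, u1, _ = solve_mme(mme1, solver="direct")
        mme2 = MixedModelEquations.assemble(
            level, 2, qe, we, y, ep.a_inverse(), sigma, 2.0
        )
        _, u2, _ = solve_mme(mme2, solver="direct")
        assert np.sum(u2**2) < np.sum(u1**2)

    def test_empty_records_rejected(self, rng):
        ep = DenseEntityPedigree()
        ep.add_base_queen()
        sigma = np.eye(2)
        with pytest.raises(ValueError):
            MixedModelEquations.assemble(
                np.array([], dtype=int), 0, np.array([], dtype=int),
                np.array([], dtype=int), np.array([]), ep.a_inverse(), sigma, 1.0,
            )


class TestVarianceReestimation:
    def test_unbiased_on_base_cohort(self, rng):
        """E[Sigma_hat] = Sigma_A for a known non-inbred architecture."""
        arch = sample_architecture(100, (1.0, 2.0, -0.75), 1.0, rng)
        reps = []
        for _ in range(24):
            genos = (rng.random((80, 2, 100)) < arch.allele_freq).astype(np.uint8)
            est = reestimate_variance(genos, np.zeros(80), arch, rng, n_drones=50)
            reps.append(est.sigma_hat)
        reps = np.array(reps)
        se = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
        assert np.all(np.abs(reps.mean(axis=0) - arch.sigma_a) < 3.5 * se)

    def test_negative_covariance_sign_recovered(self, rng):
        arch = sample_architecture(100, (1.0, 2.0, -1.25), 1.0, rng)
        genos = (rng.random((200, 2, 100)) < arch.allele_freq).astype(np.uint8)
        est = reestimate_variance(genos, np.zeros(200), arch, rng, n_drones=100)
        assert est.sigma_hat[0, 1] < 0

    def test_plain_scatter_when_not_inbred(self, rng):
        """With all F=0, the estimator is the unweighted scatter / (nN - 1)."""
        arch = sample_architecture(60, (1.0, 2.0, -0.75), 1.0, rng)
        genos = (rng.random((10, 2, 60)) < arch.allele_freq).astype(np.uint8)
        seed = 99
        est = reestimate_variance(genos, np.zeros(10), arch, np.random.default_rng(seed), n_drones=20)
        est2 = reestimate_variance(genos, np.zeros(10), arch, np.random.default_rng(seed), n_drones=20)
        np.testing.assert_allclose(est.sigma_hat, est2.sigma_hat)
        assert est.sigma_hat.shape == (2, 2)
        assert est.sigma_hat[0, 1] == est.sigma_hat[1, 0]

    def test_fully_inbred_queens_excluded(self, rng):
        arch = sample_architecture(60, (1.0, 2.0, -0.75), 1.0, rng)
        genos = (rng.random((5, 2, 60)) < arch.allele_freq).astype(np.uint8)
        f = np.array([0.0, 0.0, 1.0, 0.2, 1.0 - 1e-9])
        with pytest.warns(UserWarning, match="excluding"):
            est = reestimate_variance(genos, f, arch, rng, n_drones=10)
        assert est.n_queens == 3
        with pytest.raises(ValueError):
            reestimate_variance(genos[:1], np.ones(1), arch, rng)

    def test_nearest_psd_projection(self):
        m = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        p = nearest_psd(m)
        assert np.linalg.eigvalsh(p)[0] >= 0
        np.testing.assert_allclose(p, p.T)
        psd = np.array([[2.0, 0.5], [0.5, 1.0]])
        np.testing.assert_allclose(nearest_psd(psd), psd)
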