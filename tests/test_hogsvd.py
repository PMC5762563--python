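import numpy as np
import pytest
from scipy import linalg
from sklearn.base import clone

from comod import hogsvd
from comod.hogsvd import (
    HOGSVD,
    CoexpressionMatrix,
    NumericalError,
    build_S,
    coexpression_matrix,
    decompose,
    right_basis,
)
from comod.io import ValidationError

from conftest import make_expr


class TestCoexpressionMatrix:
    def test_identity_input(self):
        em = coexpression_matrix(np.eye(2))
        np.testing.assert_allclose(em.E, np.eye(2))
        em_r = coexpression_matrix(np.eye(2), ridge=1e-3)
        np.testing.assert_allclose(em_r.E, (1 + 1e-3) * np.eye(2))
        assert em_r.ridge_epsilon == pytest.approx(1e-3)

    def test_hand_product(self):
        em = coexpression_matrix(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(em.E, [[10, 14], [14, 20]])

    def test_rank_one_ridge_restores_definiteness(self):
        D = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])  # proportional cols
        bare = coexpression_matrix(D)
        assert linalg.eigvalsh(bare.E).min() == pytest.approx(0.0, abs=1e-10)
        ridged = coexpression_matrix(D, ridge=1e-6)
        assert linalg.eigvalsh(ridged.E).min() > 0

    def test_gene_centering(self, rng):
        D = rng.normal(size=(6, 3)) + 5.0
        em = coexpression_matrix(D, center="gene")
        Dc = D - D.mean(axis=0)
        np.testing.assert_allclose(em.E, Dc.T @ Dc, atol=1e-10)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            CoexpressionMatrix("x", np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestBuildS:
    @pytest.mark.parametrize("T", [2, 3, 4, 5, 6])
    def test_identical_inputs_give_identity(self, T, random_spd):
        E = random_spd(5, seed=T)
        S = build_S([CoexpressionMatrix(str(t), E) for t in range(T)])
        assert np.abs(S - np.eye(5)).max() < 1e-10

    def test_hand_diagonal_pair(self):
        S = build_S([CoexpressionMatrix("a", np.diag([2.0, 1.0])),
                     CoexpressionMatrix("b", np.diag([1.0, 2.0]))])
        np.testing.assert_allclose(S, np.diag([1.25, 1.25]))

    @pytest.mark.parametrize("T,p,seed", [(3, 6, 0), (4, 8, 1), (5, 10, 2)])
    def test_matches_naive_pairwise_loop(self, T, p, seed, random_spd):
        ems = [CoexpressionMatrix(str(t), random_spd(p, seed=seed * 10 + t))
               for t in range(T)]
        S = build_S(ems)
        naive = np.zeros((p, p))
        for t in range(T - 1):
            for r in range(t + 1, T):
                Et, Er = ems[t].E, ems[r].E
                naive += Et @ np.linalg.inv(Er) + Er @ np.linalg.inv(Et)
        naive /= T * (T - 1)
        assert np.abs(S - naive).max() < 1e-10 * max(1, np.abs(naive).max())

    def test_singular_input_advises_ridge(self):
        D = np.array([[1.0, 2.0], [2.0, 4.0]])
        em = coexpression_matrix(D)  # rank 1
        good = CoexpressionMatrix("g", np.eye(2))
        with pytest.raises(NumericalError, match="ridge"):
            build_S([em, good])

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError, match="mismatch"):
            build_S([CoexpressionMatrix("a", np.eye(2)),
                     CoexpressionMatrix("b", np.eye(3))])


class TestRightBasis:
    def test_identity_convention(self):
        lam, V = right_basis(np.eye(4))
        np.testing.assert_allclose(lam, np.ones(4))
        np.testing.assert_allclose(V, np.eye(4))

    def test_diagonal_sorted_descending(self):
        lam, V = right_basis(np.diag([1.5, 3.0, 1.0]))
        np.testing.assert_allclose(lam, [3.0, 1.5, 1.0])
        # permutation of coordinate vectors, positive signs
        np.testing.assert_allclose(V[:, 0], [0, 1, 0])
        np.testing.assert_allclose(V[:, 1], [1, 0, 0])

    def test_degenerate_hand_pair(self):
        S = build_S([CoexpressionMatrix("a", np.diag([2.0, 1.0])),
                     CoexpressionMatrix("b", np.diag([1.0, 2.0]))])
        lam, _ = right_basis(S)
        np.testing.assert_allclose(lam, [1.25, 1.25])

    @pytest.mark.parametrize("T,p,seed", [(2, 6, 0), (3, 12, 1), (5, 20, 2)])
    def test_spd_eigenvalues_real_and_at_least_one(self, T, p, seed, random_spd):
        ems = [CoexpressionMatrix(str(t), random_spd(p, seed=seed * 7 + t))
               for t in range(T)]
        lam, V = right_basis(build_S(ems))
        assert lam.min() >= 1 - 1e-8
        assert np.isreal(lam).all()

    def test_sign_convention(self, random_spd):
        lam, V = right_basis(build_S(
            [CoexpressionMatrix("a", random_spd(6, 1)),
             CoexpressionMatrix("b", random_spd(6, 2))]))
        peaks = V[np.abs(V).argmax(axis=0), np.arange(6)]
        assert (peaks > 0).all()
        np.testing.assert_allclose(np.linalg.norm(V, axis=0), 1.0)


class TestDecompose:
    def test_reconstruction_identity(self, rng):
        Ds = [rng.normal(size=(7, 4)), rng.normal(size=(9, 4))]
        res = decompose(Ds, ridge=0.0, center="none")
        for D, U, sig in zip(Ds, res.U, res.sigmas):
            resid = np.linalg.norm(D - (U * sig) @ res.V.T) / np.linalg.norm(D)
            assert resid < 1e-8
        assert res.diagnostics["max_reconstruction_residual"] < 1e-8

    def test_t2_matches_generalized_eigenproblem(self, rng):
        """For T=2, the balance-matrix eigensystem and the pencil
        E1 v = mu E2 v share invariant subspaces, with lambda=(mu+1/mu)/2."""
        for seed in range(3):
            r = np.random.default_rng(seed)
            D1, D2 = r.normal(size=(9, 5)), r.normal(size=(8, 5))
            res = decompose([D1, D2], ridge=0.0, center="none")
            E1, E2 = D1.T @ D1, D2.T @ D2
            mu = linalg.eigvals(np.linalg.solve(E2, E1)).real
            lam_ref = np.sort((mu + 1 / mu) / 2)[::-1]
            np.testing.assert_allclose(res.eigenvalues, lam_ref, rtol=1e-8)
            # invariant-subspace cross-check per degenerate cluster: the
            # returned columns may be rotated within a cluster, but their
            # span must be S-invariant
            for cluster in hogsvd._degenerate_clusters(res.eigenvalues, 0.1):
                Vc = res.V[:, cluster]
                SV = res.S @ Vc
                proj = Vc @ np.linalg.lstsq(Vc, SV, rcond=None)[0]
                assert np.linalg.norm(SV - proj) < 1e-7 * np.linalg.norm(SV)

    def test_zero_gene_column_flagged(self, rng):
        D1 = rng.normal(size=(6, 3))
        D2 = rng.normal(size=(6, 3))
        D1[:, 2] = 0.0
        D2[:, 2] = 0.0
        res = decompose([D1, D2], ridge=1e-6, center="none")
        # the ridge keeps S finite; the zero gene gets ~zero singular values
        assert min(s.min() for s in res.sigmas) < 1e-3

    def test_unaligned_panels_rejected(self, rng):
        m1 = make_expr(rng.normal(size=(4, 2)), gene_ids=["A", "B"])
        m2 = make_expr(rng.normal(size=(4, 2)), gene_ids=["A", "C"],
                       condition="c2")
        with pytest.raises(ValidationError, match="align"):
            decompose([m1, m2])

    def test_permutation_equivariance(self, rng):
        Ds = [rng.normal(size=(10, 5)) for _ in range(3)]
        perm = np.array([3, 0, 4, 1, 2])
        res = decompose(Ds, ridge=0.0, center="none")
        res_p = decompose([D[:, perm] for D in Ds], ridge=0.0, center="none")
        np.testing.assert_allclose(res_p.S, res.S[np.ix_(perm, perm)],
                                   atol=1e-9)
        np.testing.assert_allclose(np.sort(res_p.eigenvalues),
                                   np.sort(res.eigenvalues), rtol=1e-9)

    def test_rank_deficient_skips_factors_with_flag(self, rng):
        # genes far outnumber samples: factors not computable, V still usable
        Ds = [rng.normal(size=(6, 120)) for _ in range(3)]
        res = decompose(Ds, ridge=1e-6, center="none")
        assert res.diagnostics["factors_skipped_ill_conditioned"]
        assert res.U == [] and res.V.shape == (120, 120)
        with pytest.raises(NumericalError, match="ill-conditioned"):
            decompose(Ds, ridge=1e-6, center="none", require_factors=True)


class TestEstimator:
    def test_fit_sets_suffixed_attributes(self, rng):
        Ds = [rng.normal(size=(8, 4)) for _ in range(2)]
        est = HOGSVD(ridge=0.0, center="none").fit(Ds)
        assert est.V_.shape == (4, 4)
        assert est.n_features_in_ == 4
        assert len(est.sigmas_) == 2

    def test_get_set_params_and_clone(self):
        est = HOGSVD(ridge=1e-4, center="gene")
        assert est.get_params() == {"ridge": 1e-4, "center": "gene"}
        c = clone(est).set_params(ridge=0.5)
        assert c.get_params()["ridge"] == 0.5

    def test_transform_projects_onto_right_basis(self, rng):
        Ds = [rng.normal(size=(8, 4)) for _ in range(2)]
        est = HOGSVD(ridge=0.0, center="none").fit(Ds)
        B = est.transform(Ds[0])
        np.testing.assert_allclose(B @ est.V_.T, Ds[0], atol=1e-9)
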