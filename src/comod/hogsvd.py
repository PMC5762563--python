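"""Higher-order generalized SVD of T expression matrices sharing a gene panel.

Each condition's matrix ``D_t`` (samples x genes) is factorized as
``D_t = U_t Sigma_t V^T`` with one right basis ``V`` common to every
condition.  ``V`` is obtained from the eigensystem of

    S = 1 / (T (T - 1)) * sum_{t < r} (E_t E_r^{-1} + E_r E_t^{-1})

where ``E_t = D_t^T D_t`` is condition t's gene-gene co-expression
(cross-product) matrix.  For symmetric positive-definite ``E_t`` the
eigenvalues of S are real and >= 1; eigenvalues near 1 mark directions
equally represented in every condition, large eigenvalues mark directions
whose weight differs strongly between conditions.

With many more genes than samples ``E_t`` is singular and the balance
matrix is undefined; a relative ridge ``E_t + eps * (trace(E_t)/p) * I``
(default eps = 1e-6) restores invertibility while perturbing the spectrum
by a recorded, per-condition amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator

from .io import ExpressionMatrix, ValidationError


class NumericalError(RuntimeError):
    """A linear-algebra step failed (singular E_t, complex leakage, ...)."""


@dataclass
class CoexpressionMatrix:
    condition_name: str
    E: np.ndarray
    ridge_epsilon: float = 0.0  # absolute amount actually added to the diagonal

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.E.ndim != 2 or self.E.shape[0] != self.E.shape[1]:
            raise ValidationError("co-expression matrix must be square")
        asym = np.abs(self.E - self.E.T).max() if self.E.size else 0.0
        if asym > 1e-10 * max(1.0, np.abs(self.E).max()):
            raise ValidationError(f"co-expression matrix not symmetric (dev {asym:g})")


@dataclass
class HogsvdResult:
    """Common right basis and per-condition factors.

    ``V[:, k]`` is the k-th right basis vector (unit norm, largest-magnitude
    entry positive), ``eigenvalues[k]`` its S-eigenvalue (sorted descending),
    ``sigmas[t][k]`` condition t's generalized singular value and
    ``U[t][:, k]`` the matching left basis vector.
    """

    S: np.ndarray
    eigenvalues: np.ndarray
    V: np.ndarray
    U: list[np.ndarray]
    sigmas: list[np.ndarray]
    T: int
    condition_names: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.V.shape[0]


def coexpression_matrix(
    matrix: ExpressionMatrix | np.ndarray,
    ridge: float = 0.0,
    center: str = "none",
    condition_name: str | None = None,
) -> CoexpressionMatrix:
    """E = D^T D, optionally gene-centered first, with optional relative ridge.

    ``ridge`` is relative: the amount added to the diagonal is
    ``ridge * trace(E) / p`` and is recorded on the result.
    """
    if isinstance(matrix, ExpressionMatrix):
        D = matrix.values
        name = condition_name or matrix.condition_name
    else:
        D = np.asarray(matrix, dtype=float)
        name = condition_name or ""
    if D.ndim != 2 or D.shape[1] == 0:
        raise ValidationError("need a 2-D matrix with >= 1 gene column")
    if center == "gene":
        D = D - D.mean(axis=0, keepdims=True)
    elif center != "none":
        raise ValidationError(f"unknown centering {center!r}")
    E = D.T @ D
    E = (E + E.T) / 2.0  # enforce exact symmetry against rounding
    added = 0.0
    if ridge:
        p = E.shape[0]
        scale = np.trace(E) / p
        if scale <= 0:
            scale = 1.0  # all-zero matrix: fall back to an absolute ridge
        added = ridge * scale
        E = E + added * np.eye(p)
    return CoexpressionMatrix(condition_name=name, E=E, ridge_epsilon=added)


def build_S(ematrices: list[CoexpressionMatrix]) -> np.ndarray:
    """Pairwise balance matrix of the co-expression matrices.

    Inverses enter only through Cholesky solves (one factorization per
    condition); a singular ``E_t`` raises with advice to enable the ridge.
    """
    T = len(ematrices)
    if T < 2:
        raise ValidationError("need at least two conditions")
    p = ematrices[0].E.shape[0]
    for em in ematrices:
        if em.E.shape[0] != p:
            raise ValidationError(
                f"dimension mismatch: {em.condition_name!r} has p={em.E.shape[0]}, "
                f"expected {p}"
            )
    factors = []
    for em in ematrices:
        try:
            factors.append(linalg.cho_factor(em.E, lower=True, check_finite=False))
        except linalg.LinAlgError as exc:
            raise NumericalError(
                f"co-expression matrix of {em.condition_name!r} is singular / not "
                "positive definite; rebuild with a ridge (e.g. ridge=1e-6)"
            ) from exc
    S = np.zeros((p, p))
    for t in range(T - 1):
        for r in range(t + 1, T):
            # E_t E_r^{-1} = (E_r^{-1} E_t)^T since both are symmetric
            S += linalg.cho_solve(factors[r], ematrices[t].E, check_finite=False).T
            S += linalg.cho_solve(factors[t], ematrices[r].E, check_finite=False).T
    S /= T * (T - 1)
    return S


def _varimax(A: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Orthogonal varimax rotation of the columns of A (classic SVD algorithm)."""
    p, m = A.shape
    R = np.eye(m)
    d_old = 0.0
    for _ in range(max_iter):
        L = A @ R
        B = A.T @ (L ** 3 - L @ np.diag((L ** 2).sum(axis=0)) / p)
        U, s, Vt = np.linalg.svd(B)
        R = U @ Vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    return A @ R


def _degenerate_clusters(lam: np.ndarray, rel_gap: float) -> list[np.ndarray]:
    """Group consecutive (sorted) eigenvalues whose relative gap is < rel_gap."""
    clusters, start = [], 0
    for i in range(1, len(lam) + 1):
        if i == len(lam) or abs(lam[i - 1] - lam[i]) > rel_gap * max(
            abs(lam[i - 1]), abs(lam[i]), 1e-300
        ):
            clusters.append(np.arange(start, i))
            start = i
    return clusters


def _fix_signs(V: np.ndarray) -> np.ndarray:
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])])
    flip[flip == 0] = 1.0
    return V * flip


def right_basis(
    S: np.ndarray,
    imag_tol: float = 1e-8,
    cluster_rel_gap: float = 0.1,
    rotate_max_size: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decompose S; return (eigenvalues descending, V with unit columns).

    S is not symmetric in general, so a general eigensolver is used.  Theory
    guarantees real eigenvalues for SPD co-expression inputs; a complex
    conjugate eigenpair within numerical degeneracy is replaced by the real
    and imaginary parts of its eigenvector (same invariant subspace), and
    residual imaginary leakage beyond ``imag_tol`` (relative, per
    eigenvalue) is an error flagging genuinely non-SPD inputs.

    Within a numerically degenerate eigenvalue cluster the eigenvectors are
    defined only up to rotation; the returned representative is the varimax
    (sparsity-maximizing) rotation of the cluster basis — deterministic, and
    the natural choice when extreme loadings are what downstream module
    calling consumes.  Clusters larger than ``rotate_max_size`` (bulk noise
    floors) are left as returned by the solver.  Ties keep original order;
    each column is oriented so its largest-magnitude entry is positive.
    A numerically diagonal S short-circuits to coordinate basis vectors.
    """
    lam, V, _ = _eig_real(S, imag_tol=imag_tol, cluster_rel_gap=cluster_rel_gap,
                          rotate_max_size=rotate_max_size)
    return lam, V


def _eig_real(
    S: np.ndarray,
    imag_tol: float = 1e-8,
    cluster_rel_gap: float = 0.1,
    rotate_max_size: int = 50,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Implementation behind `right_basis`; also returns the max imaginary
    leakage of the raw spectrum (0 for the diagonal fast path)."""
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if p == 0:
        raise ValidationError("empty matrix")
    scale = max(1.0, float(np.abs(S).max()))
    offdiag = S - np.diag(np.diag(S))
    if np.abs(offdiag).max() <= 1e-12 * scale:
        lam = np.diag(S).astype(float)
        order = np.argsort(-lam, kind="stable")
        return lam[order], np.eye(p)[:, order], 0.0

    lam_c, V_c = linalg.eig(S, check_finite=False)
    leak = float(np.abs(lam_c.imag).max())
    lam = lam_c.real.copy()
    V = np.empty((p, p))
    j = 0
    while j < p:
        if abs(lam_c[j].imag) <= imag_tol * max(1.0, abs(lam_c[j])):
            V[:, j] = V_c[:, j].real
            j += 1
            continue
        # conjugate pair (adjacent, per LAPACK): real invariant 2-D subspace
        if j + 1 >= p or not np.isclose(lam_c[j].conj(), lam_c[j + 1]):
            raise NumericalError(
                f"complex eigenvalue {lam_c[j]:.6g} without adjacent conjugate; "
                "inputs are likely not positive definite"
            )
        if abs(lam_c[j].imag) > cluster_rel_gap * max(1.0, abs(lam_c[j].real)):
            raise NumericalError(
                f"complex leakage {abs(lam_c[j].imag):g} at eigenvalue "
                f"{lam_c[j].real:.6g} exceeds the degeneracy tolerance; inputs "
                "are likely not positive definite"
            )
        re, im = V_c[:, j].real, V_c[:, j].imag
        q, _ = np.linalg.qr(np.column_stack([re, im]))
        V[:, j], V[:, j + 1] = q[:, 0], q[:, 1]
        lam[j] = lam[j + 1] = lam_c[j].real
        j += 2

    order = np.argsort(-lam, kind="stable")
    lam, V = lam[order], V[:, order]
    V = V / np.linalg.norm(V, axis=0, keepdims=True)
    for cluster in _degenerate_clusters(lam, cluster_rel_gap):
        if 2 <= cluster.size <= rotate_max_size:
            rotated = _varimax(V[:, cluster])
            rotated /= np.linalg.norm(rotated, axis=0, keepdims=True)
            # deterministic order inside the cluster: most concentrated first
            sparsity = (rotated ** 4).sum(axis=0)
            sub = np.argsort(-sparsity, kind="stable")
            V[:, cluster] = rotated[:, sub]
    return lam, _fix_signs(V), leak


def decompose(
    matrices: list[ExpressionMatrix] | list[np.ndarray],
    ridge: float = 1e-6,
    center: str = "gene",
    cond_limit: float = 1e12,
    require_factors: bool = False,
) -> HogsvdResult:
    """Full factorization D_t = U_t Sigma_t V^T for all conditions at once.

    With full-rank inputs (n_t > p) the factorization is exact and the
    relative reconstruction residual is recorded.  With rank-deficient
    inputs (genes outnumbering samples) the eigenbasis of the regularized
    balance matrix is inherently ill-conditioned in its degenerate bulk, so
    inverting V for the per-condition factors is numerically meaningless:
    when cond(V) exceeds ``cond_limit`` the U_t / Sigma_t extraction is
    skipped (empty lists, flagged in diagnostics) unless ``require_factors``
    forces an error.  The right basis and eigenvalues — everything module
    detection consumes — are unaffected.
    """
    if len(matrices) < 2:
        raise ValidationError("need at least two conditions")
    arrays, names = [], []
    for i, m in enumerate(matrices):
        if isinstance(m, ExpressionMatrix):
            arrays.append(m.values)
            names.append(m.condition_name)
        else:
            arrays.append(np.asarray(m, dtype=float))
            names.append(f"condition_{i + 1}")
    p = arrays[0].shape[1]
    gene_panels = [
        tuple(m.gene_ids) for m in matrices if isinstance(m, ExpressionMatrix)
    ]
    if gene_panels and len(set(gene_panels)) > 1:
        raise ValidationError("gene panels differ across conditions; align them first")
    if any(a.shape[1] != p for a in arrays):
        raise ValidationError("all matrices must share the gene dimension p")

    ems = [
        coexpression_matrix(a, ridge=ridge, center=center, condition_name=n)
        for a, n in zip(arrays, names)
    ]
    S = build_S(ems)
    lam, V, leak = _eig_real(S)
    condV = np.linalg.cond(V)
    factors_skipped = bool(condV > cond_limit)
    if factors_skipped and require_factors:
        raise NumericalError(
            f"right basis is ill-conditioned (cond {condV:.3g} > {cond_limit:g}); "
            "per-condition factors are not computable for rank-deficient panels"
        )
    U, sigmas, zero_cols = [], [], []
    max_resid = float("nan")
    if not factors_skipped:
        max_resid = 0.0
        lu, piv = linalg.lu_factor(V, check_finite=False)
        for a, n in zip(arrays, names):
            if center == "gene":
                a = a - a.mean(axis=0, keepdims=True)
            B = linalg.lu_solve((lu, piv), a.T, check_finite=False).T  # B = D V^{-T}
            sig = np.linalg.norm(B, axis=0)
            Ut = np.zeros_like(B)
            nz = sig > 0
            Ut[:, nz] = B[:, nz] / sig[nz]
            if (~nz).any():
                zero_cols.append((n, np.flatnonzero(~nz).tolist()))
            denom = np.linalg.norm(a)
            resid = np.linalg.norm(a - (Ut * sig) @ V.T) / denom if denom > 0 else 0.0
            max_resid = max(max_resid, resid)
            U.append(Ut)
            sigmas.append(sig)
    return HogsvdResult(
        S=S,
        eigenvalues=lam,
        V=V,
        U=U,
        sigmas=sigmas,
        T=len(arrays),
        condition_names=names,
        diagnostics={
            "max_reconstruction_residual": float(max_resid),
            "max_imag_leakage": float(leak),
            "ridge": float(ridge),
            "ridge_added": [float(em.ridge_epsilon) for em in ems],
            "cond_V": float(condV),
            "factors_skipped_ill_conditioned": factors_skipped,
            "zero_sigma_columns": zero_cols,
            "center": center,
        },
    )


class HOGSVD(BaseEstimator):
    """Common right-basis decomposition of several matrices, estimator style.

    Parameters
    ----------
    ridge : float, default 1e-6
        Relative diagonal regularization of each E_t (times trace(E_t)/p).
        Required whenever genes outnumber samples.
    center : {"none", "gene"}, default "none"
        Whether to subtract per-gene means before forming E_t = D^T D.

    Attributes (after ``fit``)
    --------------------------
    S_, eigenvalues_, V_, U_, sigmas_, condition_names_, diagnostics_,
    n_features_in_ : the factorization pieces described on `HogsvdResult`.
    """

    def __init__(self, ridge: float = 1e-6, center: str = "gene"):
        self.ridge = ridge
        self.center = center

    def fit(self, X, y=None):
        """X: list of (n_t, p) arrays or ExpressionMatrix, shared gene panel."""
        res = decompose(list(X), ridge=self.ridge, center=self.center)
        self.result_ = res
        self.S_ = res.S
        self.eigenvalues_ = res.eigenvalues
        self.V_ = res.V
        self.U_ = res.U
        self.sigmas_ = res.sigmas
        self.condition_names_ = res.condition_names
        self.diagnostics_ = res.diagnostics
        self.n_features_in_ = res.p
        return self

    def transform(self, X):
        """Project a (n, p) matrix onto the fitted right basis: B = X V^{-T}."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1]} genes, decomposition used {self.n_features_in_}"
            )
        return linalg.solve(self.V_, X.T, check_finite=False).T

    def fit_transform(self, X, y=None):
        self.fit(X)
        return [self.transform(np.asarray(getattr(m, "values", m), dtype=float))
                for m in X]
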