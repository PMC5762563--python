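"""Co-expression module calling from top right-basis eigenvectors.

A unit-norm eigenvector of the balance matrix spreads most genes in a tight
bulk around zero (typical loading ~ p^-1/2) with a small, coherent set of
genes carrying extreme loadings — the co-expressed module.  Each selected
eigenvector is therefore modeled as a two-component Gaussian mixture on
median/MAD-standardized loadings: the large-weight component is the
empirical null, the small-weight component carries the module.  A
tail-area false discovery rate converts each gene's standardized distance
from the null center into a q-value, and the module is the set of genes
with q at or below the cutoff (default 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .hogsvd import HogsvdResult
from .io import ValidationError

MIN_GENES = 10
_SD_FLOOR = 1e-8


@dataclass
class MixtureFit:
    """Two-component 1-D Gaussian mixture on standardized loadings.

    ``null_index`` points at the larger-weight (empirical null) component.
    ``center``/``scale`` record the median/MAD standardization and
    ``orientation`` the internal sign flip that makes the fit invariant to
    the arbitrary sign of an eigenvector.
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    null_index: int
    loglik: float
    converged: bool
    n_iter: int
    center: float = 0.0
    scale: float = 1.0
    orientation: float = 1.0

    @property
    def null_mean(self) -> float:
        return float(self.means[self.null_index])

    @property
    def null_sd(self) -> float:
        return float(self.sds[self.null_index])

    @property
    def null_weight(self) -> float:
        return float(self.weights[self.null_index])


@dataclass
class GeneModule:
    """Genes called from one eigenvector, with loadings, q-values and the fit."""

    eigenvector_index: int  # 1-based rank by eigenvalue
    gene_ids: list[str]
    loadings: np.ndarray
    qvalues: np.ndarray
    q_cutoff: float
    fit: MixtureFit | None  # None when no usable mixture fit exists
    eigenvalue: float = float("nan")

    def __post_init__(self) -> None:
        if not (len(self.gene_ids) == len(self.loadings) == len(self.qvalues)):
            raise ValidationError("module fields misaligned")
        if len(self.qvalues) and (np.asarray(self.qvalues) > self.q_cutoff).any():
            raise ValidationError("module member with q above the cutoff")

    def __len__(self) -> int:
        return len(self.gene_ids)


def _standardize(loadings: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    """Median/MAD standardization plus a canonical orientation.

    The eigenvector's sign is a solver artifact; flipping the input when the
    standardized skewness is negative makes every downstream quantity
    identical for v and -v.
    """
    x = np.asarray(loadings, dtype=float)
    center = float(np.median(x))
    scale = float(stats.median_abs_deviation(x, scale="normal"))
    if scale < _SD_FLOOR:
        scale = float(np.std(x))
    if scale < _SD_FLOOR:
        raise ValidationError("loadings are (nearly) constant; no mixture structure")
    z = (x - center) / scale
    orientation = -1.0 if stats.skew(z) < 0 else 1.0
    return orientation * z, center, scale, orientation


def _em_two_component(
    z: np.ndarray, mu_init: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized EM for R parallel restarts of a 1-D two-Gaussian mixture.

    ``mu_init`` is (R, 2); returns (w, mu, sd, loglik, converged, n_iter)
    with the leading restart axis.  Convergence criterion: change in mean
    per-observation log-likelihood below ``tol``.  Restarts whose component
    sd collapses to the floor are frozen and flagged non-converged with
    loglik -inf.
    """
    n = z.size
    R = mu_init.shape[0]
    w = np.full((R, 2), 0.5)
    mu = mu_init.astype(float).copy()
    sd = np.full((R, 2), z.std() or 1.0)
    ll_old = np.full(R, -np.inf)
    alive = np.ones(R, dtype=bool)
    converged = np.zeros(R, dtype=bool)
    n_iter = np.zeros(R, dtype=int)
    zb = z[None, None, :]  # (1, 1, n)
    for it in range(1, max_iter + 1):
        active = alive & ~converged
        if not active.any():
            break
        logpdf = (
            -0.5 * ((zb - mu[..., None]) / sd[..., None]) ** 2
            - np.log(sd[..., None])
            - 0.5 * np.log(2 * np.pi)
            + np.log(w[..., None])
        )  # (R, 2, n)
        m = logpdf.max(axis=1, keepdims=True)
        lse = m[:, 0, :] + np.log(np.exp(logpdf - m).sum(axis=1))  # (R, n)
        ll = lse.mean(axis=1)
        resp = np.exp(logpdf - lse[:, None, :])  # (R, 2, n)
        nk = resp.sum(axis=2)  # (R, 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            new_w = nk / n
            new_mu = (resp * zb).sum(axis=2) / nk
            new_var = (resp * (zb - new_mu[..., None]) ** 2).sum(axis=2) / nk
        collapsed = (nk < 1e-10).any(axis=1) | (new_var < _SD_FLOOR**2).any(axis=1)
        alive &= ~collapsed
        upd = alive & ~converged
        w[upd], mu[upd] = new_w[upd], new_mu[upd]
        sd[upd] = np.sqrt(new_var[upd])
        just = upd & (np.abs(ll - ll_old) < tol)
        converged |= just
        n_iter[upd] = it
        ll_old = np.where(upd | just, ll, ll_old)
    loglik = np.where(alive, ll_old * n, -np.inf)
    return w, mu, sd, loglik, converged & alive, n_iter


def fit_bimodal(loadings: np.ndarray, seed: int = 0, n_restarts: int = 10,
                tol: float = 1e-8, max_iter: int = 500) -> MixtureFit:
    """EM fit of the two-component mixture, best of quantile-seeded restarts.

    Restart r initializes the component means at the median and at a
    quantile swept across [0.05, 0.95]; among converged restarts the one
    with the highest log-likelihood wins (falling back to the best
    non-converged restart, honestly flagged).  Restarts collapsing a
    component (sd below floor) are discarded; if every restart collapses
    the loadings carry no mixture structure and an error is raised.
    The fit itself is deterministic; ``seed`` is accepted for interface
    symmetry with stochastic callers.
    """
    x = np.asarray(loadings, dtype=float)
    if x.size < MIN_GENES:
        raise ValidationError(f"need >= {MIN_GENES} loadings, got {x.size}")
    z, center, scale, orientation = _standardize(x)
    qs = np.linspace(0.05, 0.95, n_restarts)
    mu_init = np.column_stack([
        np.full(n_restarts, np.median(z)), np.quantile(z, qs)
    ])
    w, mu, sd, loglik, converged, n_iter = _em_two_component(
        z, mu_init, tol=tol, max_iter=max_iter
    )
    usable = np.isfinite(loglik)
    if not usable.any():
        raise ValidationError("mixture fit degenerate in every restart")
    # a converged restart always beats a non-converged one
    rank = np.where(converged, 1.0, 0.0) * 1e12 + np.where(usable, loglik, -np.inf)
    r = int(np.argmax(rank))
    null_index = int(np.argmax(w[r]))
    return MixtureFit(
        means=mu[r],
        sds=sd[r],
        weights=w[r],
        null_index=null_index,
        loglik=float(loglik[r]),
        converged=bool(converged[r]),
        n_iter=int(n_iter[r]),
        center=center,
        scale=scale,
        orientation=orientation,
    )


def tail_fdr_qvalues(loadings: np.ndarray, fit: MixtureFit) -> np.ndarray:
    """Tail-area FDR per gene from the fitted mixture.

    With standardized loading z and score s = |z - m0| / sd0 (m0, sd0 the
    null component), the raw tail FDR at s is

        Fdr(s) = w0 * 2 * (1 - Phi(s)) / max(empirical fraction {s_j >= s}, 1/p)

    clipped to [0, 1].  The q-value is the minimum raw Fdr over all observed
    scores <= s, which is non-increasing in s by construction.

    The null scale is floored at 1 in standardized units: the loadings are
    median/MAD-standardized, so the majority (null) component cannot be
    genuinely narrower than the robust scale of the bulk — a fitted null sd
    below 1 is the mixture splitting a unimodal distribution in half, and
    scoring against it would inflate the tail scores of ordinary extremes.
    """
    if not fit.converged:
        raise ValidationError("mixture fit did not converge; refusing q-values")
    x = np.asarray(loadings, dtype=float)
    z = fit.orientation * (x - fit.center) / fit.scale
    s = np.abs(z - fit.null_mean) / max(fit.null_sd, 1.0)
    p = s.size
    order = np.argsort(s, kind="stable")
    ranks = np.empty(p, dtype=float)
    # empirical two-sided tail fraction: #(s_j >= s_i) / p, ties counted fully
    sorted_s = s[order]
    first_ge = np.searchsorted(sorted_s, sorted_s, side="left")
    ranks[order] = (p - first_ge) / p
    raw = fit.null_weight * 2.0 * stats.norm.sf(s) / np.maximum(ranks, 1.0 / p)
    raw = np.clip(raw, 0.0, 1.0)
    q = np.empty(p)
    q[order] = np.minimum.accumulate(raw[order])
    return q


def select_top_eigenvectors(
    result: HogsvdResult, k: int = 10
) -> list[tuple[int, np.ndarray]]:
    """The k right-basis columns with largest eigenvalue, as (1-based rank, v)."""
    p = result.p
    if not 1 <= k <= p:
        raise ValidationError(f"k must be in [1, {p}], got {k}")
    return [(i + 1, result.V[:, i]) for i in range(k)]


def extract_module(
    eigenvector_index: int,
    gene_ids: list[str],
    loadings: np.ndarray,
    qvalues: np.ndarray,
    q_cutoff: float,
    fit: MixtureFit,
    eigenvalue: float = float("nan"),
) -> GeneModule:
    """Keep genes with q <= cutoff; an empty module is a valid outcome."""
    keep = np.asarray(qvalues) <= q_cutoff
    return GeneModule(
        eigenvector_index=eigenvector_index,
        gene_ids=[g for g, k in zip(gene_ids, keep) if k],
        loadings=np.asarray(loadings)[keep],
        qvalues=np.asarray(qvalues)[keep],
        q_cutoff=q_cutoff,
        fit=fit,
        eigenvalue=eigenvalue,
    )


class BimodalTailFDR(BaseEstimator):
    """Mixture + tail-FDR gene caller for a single loading vector.

    ``fit(loadings)`` fits the two-component mixture; ``fitted attributes``
    expose the mixture (`mixture_`), per-gene q-values (`qvalues_`) and the
    boolean membership at `q_cutoff` (`members_`).
    """

    def __init__(self, q_cutoff: float = 0.001, seed: int = 0,
                 n_restarts: int = 10, tol: float = 1e-8, max_iter: int = 500):
        self.q_cutoff = q_cutoff
        self.seed = seed
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        self.mixture_ = fit_bimodal(
            x, seed=self.seed, n_restarts=self.n_restarts,
            tol=self.tol, max_iter=self.max_iter,
        )
        self.qvalues_ = tail_fdr_qvalues(x, self.mixture_)
        self.members_ = self.qvalues_ <= self.q_cutoff
        self.n_features_in_ = x.size
        return self

    def transform(self, X):
        """q-values of new loadings under the fitted mixture."""
        return tail_fdr_qvalues(np.asarray(X, dtype=float).ravel(), self.mixture_)


@dataclass
class ModuleCallReport:
    modules: list[GeneModule]
    overlap: np.ndarray  # pairwise shared-gene counts between called modules
    k: int
    q_cutoff: float
    seed: int

    def non_empty(self) -> list[GeneModule]:
        return [m for m in self.modules if len(m)]


def call_all_modules(
    result: HogsvdResult,
    gene_ids: list[str],
    k: int = 10,
    q_cutoff: float = 0.001,
    seed: int = 0,
    rotate: str = "auto",
    min_block_gap: float = 0.2,
) -> ModuleCallReport:
    """One GeneModule per top basis vector, plus pairwise overlap counts.

    Eigenvalues of the balance matrix separate the common co-expression
    directions from the bulk, but within the leading group they fluctuate
    by sampling noise, so individual eigenvectors of the (non-normal)
    balance matrix can mix near-degenerate co-expression directions; the
    leading *subspace* is the stable object.  With ``rotate="auto"``
    (default) the leading block — delimited by the deepest relative
    eigenvalue gap of at least ``min_block_gap`` within the top k — is
    varimax-rotated to its sparsity-maximizing basis before calling; a
    spectrum with no such gap (no direction stands above the bulk) is left
    unrotated, so pure-noise panels are never sharpened into spurious
    modules.  ``rotate="varimax"`` forces rotation of all k vectors,
    ``rotate="none"`` disables rotation.  Rotated vectors are ordered by
    loading concentration (descending sum of 4th powers);
    ``eigenvector_index`` numbers positions in the final order, and each
    module records the same-rank eigenvalue for reference.

    Distinct modules may share a few genes (one gene can load on several
    basis vectors); the overlap matrix makes that visible.
    """
    if len(gene_ids) != result.p:
        raise ValidationError("gene_ids length does not match the decomposition")
    selected = select_top_eigenvectors(result, k)
    if rotate == "auto":
        lam = result.eigenvalues[: k + 1]
        block = 0
        for i in range(1, min(k, len(lam) - 1) + 1):
            prev = abs(lam[i - 1])
            if prev > 0 and (lam[i - 1] - lam[i]) / prev >= min_block_gap:
                block = i
        n_rotate = block if block >= 2 else 0
    elif rotate == "varimax":
        n_rotate = k
    elif rotate == "none":
        n_rotate = 0
    else:
        raise ValidationError(f"unknown rotation {rotate!r}")
    if n_rotate >= 2:
        from .hogsvd import _fix_signs, _varimax

        Vb = np.column_stack([v for _, v in selected[:n_rotate]])
        Vb = _varimax(Vb)
        Vb /= np.linalg.norm(Vb, axis=0, keepdims=True)
        order = np.argsort(-(Vb ** 4).sum(axis=0), kind="stable")
        Vb = _fix_signs(Vb[:, order])
        selected = [(i + 1, Vb[:, i]) for i in range(n_rotate)] + [
            (i + 1, v) for i, (_, v) in enumerate(selected[n_rotate:], start=n_rotate)
        ]
    modules: list[GeneModule] = []
    for rank, v in selected:
        eigenvalue = float(result.eigenvalues[rank - 1])
        caller = BimodalTailFDR(q_cutoff=q_cutoff, seed=seed + rank)
        try:
            caller.fit(v)
        except ValidationError:
            # no usable bimodal structure on this eigenvector: empty module
            modules.append(GeneModule(
                eigenvector_index=rank, gene_ids=[],
                loadings=np.empty(0), qvalues=np.empty(0),
                q_cutoff=q_cutoff, fit=None, eigenvalue=eigenvalue,
            ))
            continue
        modules.append(
            extract_module(
                rank, gene_ids, v, caller.qvalues_, q_cutoff, caller.mixture_,
                eigenvalue=eigenvalue,
            )
        )
    overlap = np.zeros((k, k), dtype=int)
    sets = [set(m.gene_ids) for m in modules]
    for i in range(k):
        for j in range(k):
            overlap[i, j] = len(sets[i] & sets[j])
    return ModuleCallReport(modules=modules, overlap=overlap, k=k,
                            q_cutoff=q_cutoff, seed=seed)


def module_to_dict(m: GeneModule) -> dict:
    return {
        "eigenvector_index": m.eigenvector_index,
        "eigenvalue": m.eigenvalue,
        "q_cutoff": m.q_cutoff,
        "genes": m.gene_ids,
        "loadings": np.asarray(m.loadings).tolist(),
        "qvalues": np.asarray(m.qvalues).tolist(),
        "mixture": None if m.fit is None else {
            "means": m.fit.means.tolist(),
            "sds": m.fit.sds.tolist(),
            "weights": m.fit.weights.tolist(),
            "null_index": m.fit.null_index,
            "loglik": m.fit.loglik,
            "converged": m.fit.converged,
            "n_iter": m.fit.n_iter,
        },
    }
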