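"""Prognostic assessment of modules: NMF patient grouping, log-rank tests,
per-gene Cox proportional-hazards scans.

Tumor samples are grouped by non-negative matrix factorization of the
module-restricted expression matrix (patients assigned to their dominant
metagene); a single-gene module falls back to k-means on that gene.  Group
survival curves are compared with the k-sample log-rank test, and each
gene's univariate prognostic value is the raw (uncorrected) Wald p-value of
its Cox PH coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF

from .io import ExpressionMatrix, SurvivalTable, ValidationError, TUMOR


@dataclass
class PatientGrouping:
    condition_name: str
    patient_ids: list[str]
    labels: np.ndarray  # group label per patient, 1..k
    method: str  # "nmf" or "kmeans"
    k: int
    seed: int
    objective: float  # NMF reconstruction error or k-means inertia

    def group_sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


@dataclass
class PrognosisReport:
    """Per (condition, module) log-rank outcomes plus per-gene Cox scans."""

    logrank: pd.DataFrame  # condition, module, p, neg_log2_p, group sizes, evaluable
    cox: pd.DataFrame | None = None  # condition, module, gene, coef, wald_p, flag
    dropped_patients: dict = field(default_factory=dict)


def _tumor_view(expr: ExpressionMatrix, genes: list[str]) -> ExpressionMatrix:
    if expr.sample_class is not None:
        return expr.subset(genes=genes, sample_mask=expr.class_mask(TUMOR))
    return expr.subset(genes=genes)


def group_patients(
    expr: ExpressionMatrix,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 500,
) -> PatientGrouping:
    """Cluster patients (samples) on the supplied expression matrix.

    Values are shifted by the matrix minimum to enforce non-negativity, then
    factorized with rank-k NMF (multiplicative updates, best objective over
    ``n_restarts`` seeded restarts); patients are clustered by k-means on
    their metagene coefficient rows (scaled by each metagene's profile
    norm).  Coefficient-space k-means subsumes the classic
    dominant-metagene rule: when groups express distinct metagenes it gives
    the same split, and it also separates groups that differ in module
    amplitude rather than profile, where the dominant metagene is the same
    for everyone.  With exactly one gene, k-means on that gene's values is
    used directly.
    """
    X = expr.values
    n, p = X.shape
    if p < 1:
        raise ValidationError("no module genes present in the expression matrix")
    if n < 2 * k:
        raise ValidationError(f"need >= {2 * k} patients for k={k}, got {n}")
    if np.ptp(X) == 0:
        raise ValidationError("all-constant expression; grouping undefined")

    def _kmeans() -> PatientGrouping:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        return PatientGrouping(
            condition_name=expr.condition_name,
            patient_ids=list(expr.sample_ids),
            labels=labels + 1,
            method="kmeans",
            k=k,
            seed=seed,
            objective=float(km.inertia_),
        )

    if p == 1:
        return _kmeans()

    shifted = X - X.min()
    best: tuple[float, np.ndarray] | None = None
    for r in range(n_restarts):
        model = NMF(
            n_components=k,
            solver="mu",
            init="random",
            max_iter=max_iter,
            random_state=seed + r,
            tol=1e-6,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W = model.fit_transform(shifted)
        err = float(model.reconstruction_err_)
        if best is None or err < best[0]:
            best = (err, W * np.linalg.norm(model.components_, axis=1))
    assert best is not None
    err, W = best
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(W) + 1
    return PatientGrouping(
        condition_name=expr.condition_name,
        patient_ids=list(expr.sample_ids),
        labels=labels,
        method="nmf",
        k=k,
        seed=seed,
        objective=err,
    )


def logrank_p(grouping: PatientGrouping, survival: SurvivalTable) -> dict:
    """k-group log-rank test; patients missing from either table are dropped.

    Returns statistic, p, group sizes and the dropped-patient count; errors
    on a single surviving group or zero observed events.
    """
    surv = survival.to_frame().set_index("patient_id")
    keep = [(pid, lab) for pid, lab in zip(grouping.patient_ids, grouping.labels)
            if pid in surv.index]
    dropped = len(grouping.patient_ids) - len(keep)
    if not keep:
        raise ValidationError("no grouped patient appears in the survival table")
    pids, labels = zip(*keep)
    sub = surv.loc[list(pids)]
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("fewer than two groups after matching patients")
    if int(sub["event"].sum()) == 0:
        raise ValidationError("zero observed events; log-rank p undefined")
    res = multivariate_logrank_test(sub["time"].to_numpy(), labels,
                                    sub["event"].to_numpy())
    vals, counts = np.unique(labels, return_counts=True)
    return {
        "statistic": float(res.test_statistic),
        "p": float(res.p_value),
        "group_sizes": {int(v): int(c) for v, c in zip(vals, counts)},
        "n_dropped": dropped,
        "n_events": int(sub["event"].sum()),
    }


def cox_prognostic_scan(
    expr: ExpressionMatrix,
    survival: SurvivalTable,
    alpha: float = 0.05,
    min_events_warn: int = 10,
) -> pd.DataFrame:
    """Univariate Cox PH per gene; raw Wald p, prognostic flag = p < alpha.

    Ties are handled with the Efron approximation.  Genes whose fit does not
    converge (e.g. constant expression) are reported with NaN coefficient and
    p, never dropped silently.
    """
    surv = survival.to_frame().set_index("patient_id")
    common = [s for s in expr.sample_ids if s in surv.index]
    if not common:
        raise ValidationError("no overlap between expression samples and survival")
    idx = [expr.sample_ids.index(s) for s in common]
    sub = surv.loc[common]
    n_events = int(sub["event"].sum())
    if n_events == 0:
        raise ValidationError("zero observed events; Cox model undefined")
    if n_events < min_events_warn:
        warnings.warn(
            f"only {n_events} events for condition {expr.condition_name!r}; "
            "Cox Wald p-values will be unstable", stacklevel=2,
        )
    rows = []
    base = pd.DataFrame({
        "time": sub["time"].to_numpy(),
        "event": sub["event"].to_numpy(),
    })
    for j, gene in enumerate(expr.gene_ids):
        x = expr.values[idx, j]
        df = base.copy()
        df["x"] = x
        coef = wald_p = np.nan
        if np.ptp(x) > 0:
            cph = CoxPHFitter()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(df, duration_col="time", event_col="event")
                coef = float(cph.params_["x"])
                wald_p = float(cph.summary.loc["x", "p"])
            except (ConvergenceError, ValueError, np.linalg.LinAlgError):
                pass
        rows.append({
            "gene": gene,
            "coef": coef,
            "wald_p": wald_p,
            "prognostic": bool(wald_p < alpha) if np.isfinite(wald_p) else None,
        })
    return pd.DataFrame(rows)


def module_prognosis(
    modules: dict[str, list[str]],
    expr_by_condition: dict[str, ExpressionMatrix],
    survival_by_condition: dict[str, SurvivalTable],
    k: int = 2,
    alpha: float = 0.05,
    seed: int = 0,
    run_cox: bool = True,
) -> PrognosisReport:
    """Grouping + log-rank (+ optional Cox scan) for every (condition, module).

    Failures (zero events, too few patients, one surviving group, ...) are
    isolated per pair and reported as not evaluable.
    """
    logrank_rows, cox_frames, dropped = [], [], {}
    for cond, expr in sorted(expr_by_condition.items()):
        survival = survival_by_condition.get(cond)
        for mod_name, genes in sorted(modules.items()):
            row = {"condition": cond, "module": mod_name, "evaluable": False,
                   "p": np.nan, "neg_log2_p": np.nan, "group_sizes": None,
                   "reason": ""}
            try:
                if survival is None:
                    raise ValidationError("no survival table for condition")
                present = [g for g in genes if g in expr.gene_ids]
                if not present:
                    raise ValidationError("no module gene in the expression panel")
                view = _tumor_view(expr, present)
                grouping = group_patients(view, k=k, seed=seed)
                res = logrank_p(grouping, survival)
                row.update(
                    evaluable=True,
                    p=res["p"],
                    neg_log2_p=float(-np.log2(max(res["p"], 1e-300))),
                    group_sizes=res["group_sizes"],
                )
                dropped[(cond, mod_name)] = res["n_dropped"]
                if run_cox:
                    scan = cox_prognostic_scan(view, survival, alpha=alpha)
                    scan.insert(0, "module", mod_name)
                    scan.insert(0, "condition", cond)
                    cox_frames.append(scan)
            except ValidationError as exc:
                row["reason"] = str(exc)
            logrank_rows.append(row)
    cox = pd.concat(cox_frames, ignore_index=True) if cox_frames else None
    return PrognosisReport(
        logrank=pd.DataFrame(logrank_rows),
        cox=cox,
        dropped_patients=dropped,
    )
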