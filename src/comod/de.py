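"""Consensus differential-expression gene selection across conditions.

The selection runs in three steps: (1) per DE method, keep genes significant
(adjusted p < alpha) in at least ``min_conditions`` conditions; (2) intersect
the per-method gene sets; (3) map surviving IDs to canonical gene IDs,
dropping unmapped IDs and collapsing redundant IDs that share one canonical
gene.  Published DE tools (limma, edgeR, DESeq, SAMseq) are consumed through
``import_de_table``; two built-in nonparametric backends make the pipeline
self-contained on raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, ValidationError, TUMOR, NORMAL

BUILTIN_METHODS = ("ranksum", "ttest")


@dataclass
class DEResult:
    """Per-gene adjusted (and optionally raw) p-values for one condition/method."""

    condition_name: str
    method_name: str
    gene_ids: list[str]
    adj_p: np.ndarray
    raw_p: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.adj_p = np.asarray(self.adj_p, dtype=float)
        if len(self.gene_ids) != len(self.adj_p):
            raise ValidationError("gene/p-value length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate genes in DE result")
        if len(self.adj_p) and ((self.adj_p < 0).any() or (self.adj_p > 1).any()):
            raise ValidationError("adjusted p-values outside [0, 1]")

    def significant(self, alpha: float) -> set[str]:
        return {g for g, p in zip(self.gene_ids, self.adj_p) if p < alpha}


@dataclass
class ConsensusConfig:
    alpha: float = 0.05
    min_conditions: int = 4
    methods: tuple[str, ...] = BUILTIN_METHODS

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.min_conditions < 1:
            raise ValidationError("min_conditions must be >= 1")


def _normalized_counts(matrix: ExpressionMatrix) -> np.ndarray:
    """Median-of-ratios size-factor normalization.

    Robust to compositional shift (strongly induced genes inflating a
    sample's library): each sample's size factor is the median, over genes
    expressed in every sample, of its ratio to the gene's geometric mean.
    Falls back to total-count scaling when no gene is always expressed.
    """
    counts = matrix.values
    libsize = counts.sum(axis=1)
    if (libsize == 0).any():
        raise ValidationError("sample with zero library size")
    always = (counts > 0).all(axis=0)
    if always.any():
        log_geo = np.log(counts[:, always]).mean(axis=0)
        factors = np.exp(np.median(np.log(counts[:, always]) - log_geo, axis=1))
    else:
        factors = libsize / np.median(libsize)
    return counts / factors[:, None]


def run_builtin_de(matrix: ExpressionMatrix, method: str = "ranksum") -> DEResult:
    """Two-group test per gene on library-size-normalized counts, BH adjusted.

    ``ranksum`` is a two-sided Wilcoxon rank-sum (the statistic SAMseq is
    built on); ``ttest`` is a Welch t on log2(normalized + 1).  Genes with no
    variation get p = 1.  Deterministic.
    """
    if matrix.value_kind != "raw_count":
        raise ValidationError("built-in DE requires raw counts")
    if method not in BUILTIN_METHODS:
        raise ValidationError(f"unknown built-in method {method!r}")
    tumor = matrix.class_mask(TUMOR)
    normal = matrix.class_mask(NORMAL)
    if tumor.sum() < 2 or normal.sum() < 2:
        raise ValidationError(
            f"condition {matrix.condition_name!r} needs >= 2 tumor and >= 2 "
            f"normal samples (got {tumor.sum()} / {normal.sum()})"
        )
    norm = _normalized_counts(matrix)
    x, y = norm[tumor], norm[normal]
    if method == "ttest":
        x, y = np.log2(x + 1.0), np.log2(y + 1.0)
        res = stats.ttest_ind(x, y, axis=0, equal_var=False)
        raw = np.asarray(res.pvalue, dtype=float)
    else:
        res = stats.mannwhitneyu(x, y, axis=0, alternative="two-sided",
                                 method="asymptotic")
        raw = np.asarray(res.pvalue, dtype=float)
    # zero-variance genes yield nan under either test: no evidence, p = 1
    pooled = np.vstack([x, y])
    constant = np.ptp(pooled, axis=0) == 0
    raw[constant | ~np.isfinite(raw)] = 1.0
    adj = multipletests(raw, method="fdr_bh")[1]
    return DEResult(
        condition_name=matrix.condition_name,
        method_name=method,
        gene_ids=list(matrix.gene_ids),
        adj_p=adj,
        raw_p=raw,
        metadata={"normalization": "library_size_median"},
    )


def import_de_table(
    path,
    condition_name: str,
    method_name: str,
    gene_col: str = "gene",
    adj_p_col: str = "adj_p",
    raw_p_col: str | None = None,
    sep: str = "\t",
    metadata: dict | None = None,
) -> DEResult:
    """Adapter for externally produced DE tables (e.g. an edgeR topTags export
    with ``gene_col='gene', adj_p_col='FDR'``).  Tool-specific settings such as
    SAMseq's permutation counts belong in ``metadata``, they are not re-run."""
    df = pd.read_csv(path, sep=sep)
    needed = [gene_col, adj_p_col] + ([raw_p_col] if raw_p_col else [])
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(
            f"DE table missing columns {missing}; found {list(df.columns)}"
        )
    return DEResult(
        condition_name=condition_name,
        method_name=method_name,
        gene_ids=df[gene_col].astype(str).tolist(),
        adj_p=df[adj_p_col].to_numpy(dtype=float),
        raw_p=df[raw_p_col].to_numpy(dtype=float) if raw_p_col else None,
        metadata=metadata or {},
    )


def per_method_shared_genes(
    results: list[DEResult], config: ConsensusConfig
) -> set[str]:
    """Genes significant (adj p < alpha) in at least ``min_conditions`` of the
    supplied conditions, all analyzed with one method."""
    if not results:
        raise ValidationError("no DE results supplied")
    methods = {r.method_name for r in results}
    if len(methods) > 1:
        raise ValidationError(f"mixed methods in one consensus step: {sorted(methods)}")
    if len(results) < config.min_conditions:
        raise ValidationError(
            f"{len(results)} conditions supplied but min_conditions="
            f"{config.min_conditions}"
        )
    counts: dict[str, int] = {}
    for r in results:
        for g in r.significant(config.alpha):
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= config.min_conditions}


def intersect_methods(method_sets: list[set[str]]) -> set[str]:
    """Candidate set: genes shared by every per-method gene set."""
    if not method_sets:
        raise ValidationError("no method sets to intersect")
    out = set(method_sets[0])
    for s in method_sets[1:]:
        out &= s
    return out


def map_and_dedupe(genes: set[str], id_map: dict[str, str]) -> set[str]:
    """Drop unmapped source IDs; collapse source IDs sharing one canonical gene
    (the lexicographically smallest source is the kept representative); report
    the result in canonical IDs."""
    by_canonical: dict[str, str] = {}
    for g in sorted(genes):
        canon = id_map.get(g)
        if canon is None:
            continue
        by_canonical.setdefault(canon, g)  # smallest source wins (sorted order)
    return set(by_canonical)


def consensus_genes(
    results_by_method: dict[str, list[DEResult]],
    config: ConsensusConfig | None = None,
    id_map: dict[str, str] | None = None,
) -> set[str]:
    """Full three-step consensus over {method: [per-condition DEResult]}."""
    config = config or ConsensusConfig()
    method_sets = [
        per_method_shared_genes(results_by_method[m], config)
        for m in config.methods
        if m in results_by_method
    ]
    if not method_sets:
        raise ValidationError(
            f"none of the configured methods {config.methods} present in results"
        )
    candidate = intersect_methods(method_sets)
    if id_map is not None:
        candidate = map_and_dedupe(candidate, id_map)
    return candidate
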