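"""Synthetic multi-condition panels with known ground truth.

Three coupled generators emulate the statistical structure the pipeline is
built to analyze:

* ``generate_count_panel`` — negative-binomial RNA-seq counts per condition
  with planted differentially expressed gene sets affecting overlapping
  subsets of conditions (tumor means scaled by a configured fold-change).
* ``generate_fpkm_panel`` — log2-FPKM matrices over a shared gene panel with
  planted latent-factor co-expression modules: member gene g of module m
  carries loading a_g (drawn once, shared across conditions) on a per-sample
  factor drawn independently in each condition.  The shared object is the
  gene-loading pattern, not the sample-level factor values — exactly the
  shared-right-basis / distinct-left-basis structure the decomposition
  targets.
* ``generate_survival`` — right-censored exponential survival whose hazard
  is ``baseline * exp(effect * metagene)``, the metagene being the
  standardized mean expression of a planted module across tumor samples.

Everything is reproducible from the config seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .io import EdgeList, ExpressionMatrix, SurvivalTable, ValidationError, TUMOR, NORMAL


@dataclass
class DESpec:
    """A planted differentially expressed gene set."""

    n_genes: int = 20
    log2_fc: float = 2.0
    conditions: tuple[int, ...] | None = None  # None = every condition


@dataclass
class ModuleSpec:
    """A planted latent-factor co-expression module."""

    n_genes: int = 40
    loading_range: tuple[float, float] = (0.6, 1.0)
    factor_sd: float = 1.0


@dataclass
class SurvivalSpec:
    baseline_hazard: float = 0.01  # events per day
    effects: dict[int, float] = field(default_factory=lambda: {0: 1.0})
    censoring_rate: float = 0.2


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic panels.

    Defaults follow the demonstration setup used throughout the tests:
    8 conditions of 20 tumor + 20 normal NB count samples over 200 genes
    for the DE stage; 4 conditions of 80 tumor log2-FPKM samples over 1000
    genes with two planted modules (40 and 30 genes) for the network stage.
    """

    seed: int = 0
    # count panel
    n_conditions_counts: int = 8
    n_tumor: int = 20
    n_normal: int = 20
    p_counts: int = 200
    de_specs: list[DESpec] = field(default_factory=lambda: [
        DESpec(20, 2.0, (0, 1, 2, 3, 4, 5)),
        DESpec(20, 2.0, (2, 3, 4, 5, 6, 7)),
    ])
    nb_dispersion: float = 0.1
    nb_mean_log: float = 4.0
    nb_mean_sdlog: float = 1.0
    # fpkm panel
    n_conditions_fpkm: int = 4
    n_samples_fpkm: int = 80
    p_fpkm: int = 1000
    module_specs: list[ModuleSpec] = field(default_factory=lambda: [
        ModuleSpec(40, (0.6, 1.0), 1.0),
        ModuleSpec(30, (0.6, 1.0), 1.0),
    ])
    noise_sd: float = 0.3
    fpkm_mean_range: tuple[float, float] = (2.0, 8.0)
    # survival
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)

    def validate(self) -> None:
        if min(self.n_tumor, self.n_normal) < 2:
            raise ValidationError("need >= 2 samples per class")
        if sum(s.n_genes for s in self.de_specs) > self.p_counts:
            raise ValidationError("planted DE sets exceed the count panel size")
        if sum(s.n_genes for s in self.module_specs) > self.p_fpkm:
            raise ValidationError("planted modules exceed the gene panel size")
        for s in self.de_specs:
            if s.conditions is not None and any(
                c >= self.n_conditions_counts for c in s.conditions
            ):
                raise ValidationError("DE spec references a nonexistent condition")


@dataclass
class SyntheticTruth:
    seed: int
    de_genes_by_condition: dict[str, list[str]] = field(default_factory=dict)
    shared_de_genes: list[str] = field(default_factory=list)
    module_genes: list[list[str]] = field(default_factory=list)
    module_loadings: list[np.ndarray] = field(default_factory=list)
    survival_effects: dict[int, float] = field(default_factory=dict)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def generate_count_panel(
    config: SimulationConfig,
) -> tuple[list[ExpressionMatrix], SyntheticTruth]:
    """NB count matrices per condition with planted tumor fold-changes."""
    config.validate()
    rng = _rng(config.seed, 1)
    p = config.p_counts
    gene_ids = [f"G{j:05d}" for j in range(p)]
    base_mean = rng.lognormal(config.nb_mean_log, config.nb_mean_sdlog, size=p)
    phi = config.nb_dispersion
    # carve disjoint planted blocks from the front of the panel
    planted: list[tuple[np.ndarray, DESpec]] = []
    cursor = 0
    for spec in config.de_specs:
        planted.append((np.arange(cursor, cursor + spec.n_genes), spec))
        cursor += spec.n_genes

    truth = SyntheticTruth(seed=config.seed)
    matrices = []
    for t in range(config.n_conditions_counts):
        name = f"cancer_{t + 1}"
        mu = np.tile(base_mean, (config.n_tumor + config.n_normal, 1))
        de_here: list[str] = []
        for idx, spec in planted:
            affected = spec.conditions is None or t in spec.conditions
            if affected:
                mu[: config.n_tumor, idx] *= 2.0 ** spec.log2_fc
                de_here.extend(gene_ids[j] for j in idx)
        if phi > 0:
            r = 1.0 / phi
            counts = rng.negative_binomial(r, r / (r + mu))
        else:
            counts = rng.poisson(mu)
        classes = [TUMOR] * config.n_tumor + [NORMAL] * config.n_normal
        # class embedded in the sample ID so written matrices reload labelled
        matrices.append(ExpressionMatrix(
            condition_name=name,
            gene_ids=list(gene_ids),
            sample_ids=[f"{name}_{c}_s{i:03d}" for i, c in enumerate(classes)],
            values=counts.astype(float),
            value_kind="raw_count",
            sample_class=classes,
        ))
        truth.de_genes_by_condition[name] = sorted(de_here)
    truth.shared_de_genes = sorted(
        {gene_ids[j] for idx, _ in planted for j in idx}
    )
    return matrices, truth


def generate_fpkm_panel(
    config: SimulationConfig,
) -> tuple[list[ExpressionMatrix], SyntheticTruth]:
    """log2-FPKM matrices with planted cross-condition latent-factor modules."""
    config.validate()
    rng = _rng(config.seed, 2)
    p = config.p_fpkm
    gene_ids = [f"G{j:05d}" for j in range(p)]
    lo, hi = config.fpkm_mean_range
    gene_mean = rng.uniform(lo, hi, size=p)

    truth = SyntheticTruth(seed=config.seed)
    cursor = 0
    module_idx: list[np.ndarray] = []
    for spec in config.module_specs:
        idx = np.arange(cursor, cursor + spec.n_genes)
        cursor += spec.n_genes
        a_lo, a_hi = spec.loading_range
        loadings = rng.uniform(a_lo, a_hi, size=spec.n_genes)
        module_idx.append(idx)
        truth.module_genes.append([gene_ids[j] for j in idx])
        truth.module_loadings.append(loadings)

    matrices = []
    for t in range(config.n_conditions_fpkm):
        name = f"cancer_{t + 1}"
        n = config.n_samples_fpkm
        values = gene_mean + rng.normal(0.0, config.noise_sd, size=(n, p))
        for idx, loadings, spec in zip(
            module_idx, truth.module_loadings, config.module_specs
        ):
            f = rng.normal(0.0, spec.factor_sd, size=n)  # condition-private factor
            values[:, idx] += np.outer(f, loadings)
        matrices.append(ExpressionMatrix(
            condition_name=name,
            gene_ids=list(gene_ids),
            sample_ids=[f"{name}_tumor_s{i:03d}" for i in range(n)],
            values=values,
            value_kind="log2_fpkm",
            sample_class=[TUMOR] * n,
        ))
    truth.survival_effects = dict(config.survival.effects)
    return matrices, truth


def _censoring_horizon(lam: np.ndarray, rate: float) -> float:
    """Horizon c of U(0, c) censoring achieving the target censoring rate.

    For T ~ Exp(lam) and C ~ U(0, c), P(censored) = (1 - exp(-lam c))/(lam c);
    the mean over patients is decreasing in c, so bisection applies.
    """

    def frac(c: float) -> float:
        x = lam * c
        return float(np.mean(np.where(x > 1e-12, (1 - np.exp(-x)) / np.maximum(x, 1e-12), 1.0)))

    lo, hi = 1e-6 / lam.mean(), 1e6 / lam.mean()
    return float(optimize.brentq(lambda c: frac(c) - rate, lo, hi))


def generate_survival(
    config: SimulationConfig,
    panel: list[ExpressionMatrix],
    truth: SyntheticTruth,
    module_index: int | None = None,
) -> list[SurvivalTable]:
    """Exponential survival driven by a planted module's metagene.

    Per tumor sample, hazard = baseline * exp(effect * metagene) with the
    metagene the per-condition standardized mean expression of the module's
    genes; censoring times are independent U(0, c) with c calibrated to the
    configured censoring rate.
    """
    spec = config.survival
    if module_index is None:
        module_index = next(iter(spec.effects), 0)
    if module_index >= len(truth.module_genes):
        raise ValidationError(f"no planted module with index {module_index}")
    effect = spec.effects.get(module_index, 0.0)
    genes = truth.module_genes[module_index]
    rng = _rng(config.seed, 3)
    tables = []
    for t, matrix in enumerate(panel):
        view = matrix.subset(genes=genes)
        metagene = view.values.mean(axis=1)
        sd = metagene.std()
        metagene = (metagene - metagene.mean()) / (sd if sd > 0 else 1.0)
        lam = spec.baseline_hazard * np.exp(effect * metagene)
        times = rng.exponential(1.0 / lam)
        if spec.censoring_rate >= 1.0:
            obs = rng.uniform(0, times)  # everything censored: zero events
            event = np.zeros_like(times, dtype=int)
        elif spec.censoring_rate <= 0.0:
            obs, event = times, np.ones_like(times, dtype=int)
        else:
            c = _censoring_horizon(lam, spec.censoring_rate)
            cens = rng.uniform(0, c, size=times.shape)
            event = (times <= cens).astype(int)
            obs = np.minimum(times, cens)
        tables.append(SurvivalTable(
            condition_name=matrix.condition_name,
            patient_id=list(matrix.sample_ids),
            time=obs,
            event=event,
        ))
    return tables


def generate_edge_list(
    truth: SyntheticTruth,
    gene_ids: list[str],
    seed: int = 0,
    within_module_prob: float = 0.3,
    background_prob: float = 0.002,
) -> EdgeList:
    """Interaction edges: each planted module wired as a noisy clique plus a
    sparse Erdos-Renyi background over the whole panel."""
    rng = _rng(seed, 4)
    edges: list[tuple[str, str]] = []
    for genes in truth.module_genes:
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if rng.random() < within_module_prob:
                    edges.append((genes[i], genes[j]))
    p = len(gene_ids)
    n_bg = rng.binomial(p * (p - 1) // 2, background_prob)
    for _ in range(n_bg):
        i, j = rng.choice(p, size=2, replace=False)
        edges.append((gene_ids[i], gene_ids[j]))
    return EdgeList(edges=edges, source=f"synthetic(seed={seed})")
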