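"""Readers, writers and container types for expression, survival and network data.

All expression matrices are held samples x genes internally (``D_t`` with
``n_t`` sample rows and ``p`` gene columns), whatever the on-disk
orientation; a flag on the reader declares which way the file is written.
Delimited text (TSV/CSV, optionally gzipped) is the only on-disk format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"

_EVENT_ALIASES = {
    "0": 0, "1": 1,
    "alive": 0, "dead": 1,
    "living": 0, "deceased": 1,
}


class ValidationError(ValueError):
    """Input violates a structural contract (duplicate IDs, negative counts, ...)."""


@dataclass
class ExpressionMatrix:
    """One condition's expression values, samples x genes.

    ``values[i, j]`` is sample ``sample_ids[i]``, gene ``gene_ids[j]``.
    ``value_kind`` is ``"raw_count"`` (non-negative integers) or
    ``"log2_fpkm"`` (finite reals).  ``sample_class`` labels each sample
    ``"tumor"`` or ``"normal"`` and may be None when the class is unused.
    """

    condition_name: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_kind: str
    sample_class: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be 2-D (samples x genes)")
        n, p = self.values.shape
        if n < 2 or p < 1:
            raise ValidationError(f"need >= 2 samples and >= 1 gene, got {n} x {p}")
        if len(self.sample_ids) != n or len(self.gene_ids) != p:
            raise ValidationError("ID lists do not match value dimensions")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"gene {self.gene_ids[bad[1]]!r}; missing values are not supported"
            )
        if self.value_kind == "raw_count":
            if (self.values < 0).any():
                raise ValidationError("raw counts must be non-negative")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValidationError("raw counts must be integers")
        elif self.value_kind != "log2_fpkm":
            raise ValidationError(f"unknown value_kind {self.value_kind!r}")
        if self.sample_class is not None:
            if len(self.sample_class) != n:
                raise ValidationError("sample_class length mismatch")
            bad_cls = set(self.sample_class) - {TUMOR, NORMAL}
            if bad_cls:
                raise ValidationError(f"unknown sample classes: {sorted(bad_cls)}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def class_mask(self, label: str) -> np.ndarray:
        if self.sample_class is None:
            raise ValidationError(
                f"matrix {self.condition_name!r} carries no tumor/normal labels"
            )
        return np.asarray([c == label for c in self.sample_class])

    def subset(
        self,
        genes: Sequence[str] | None = None,
        sample_mask: np.ndarray | None = None,
    ) -> "ExpressionMatrix":
        """Restrict to a gene list (reordering) and/or a boolean sample mask."""
        values = self.values
        gene_ids = list(self.gene_ids)
        sample_ids = list(self.sample_ids)
        classes = list(self.sample_class) if self.sample_class is not None else None
        if genes is not None:
            idx = _gene_indices(self, genes)
            values = values[:, idx]
            gene_ids = list(genes)
        if sample_mask is not None:
            sample_mask = np.asarray(sample_mask, dtype=bool)
            values = values[sample_mask]
            sample_ids = [s for s, keep in zip(sample_ids, sample_mask) if keep]
            if classes is not None:
                classes = [c for c, keep in zip(classes, sample_mask) if keep]
        return ExpressionMatrix(
            condition_name=self.condition_name,
            gene_ids=gene_ids,
            sample_ids=sample_ids,
            values=values,
            value_kind=self.value_kind,
            sample_class=classes,
        )


@dataclass
class SurvivalTable:
    """Overall-survival records for one condition: patient, follow-up time, event."""

    condition_name: str
    patient_id: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        _check_unique(self.patient_id, "patient")
        if (self.time < 0).any():
            raise ValidationError("survival time must be >= 0")
        if not np.isin(self.event, [0, 1]).all():
            raise ValidationError("event indicator must be 0 or 1")

    def __len__(self) -> int:
        return len(self.patient_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": self.patient_id, "time": self.time, "event": self.event}
        )


@dataclass
class EdgeList:
    """Undirected gene-gene interactions; self-loops dropped, duplicates collapsed."""

    edges: list[tuple[str, str]]
    annotations: dict[tuple[str, str], str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], None] = {}
        for a, b in self.edges:
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            seen.setdefault(key, None)
        self.edges = list(seen)

    def __len__(self) -> int:
        return len(self.edges)


def _check_unique(ids: Sequence[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        counts = pd.Series(list(ids)).value_counts()
        dupes = sorted(counts[counts > 1].index.tolist())
        raise ValidationError(f"duplicate {kind} IDs: {dupes[:10]}")


def _gene_indices(matrix: ExpressionMatrix, genes: Sequence[str]) -> np.ndarray:
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise ValidationError(
            f"genes missing from condition {matrix.condition_name!r}: {missing[:10]}"
        )
    return np.asarray([pos[g] for g in genes], dtype=int)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(
    path: str | Path,
    orientation: str = "genes_in_rows",
    value_kind: str = "log2_fpkm",
    condition_name: str | None = None,
    sample_class: Mapping[str, str] | Sequence[str] | None = None,
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited genes x samples (or samples x genes) matrix.

    The first column holds row IDs; the header row holds column IDs.  Tumor /
    normal labels may be passed as a mapping ``sample_id -> class`` or a list
    aligned with the file's sample order; when omitted, a label embedded in
    the sample ID (substring ``tumor`` / ``normal``, case-insensitive) is
    used if every sample carries one, otherwise the matrix is unlabelled.
    """
    path = Path(path)
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    if sep is None:
        sep = "," if path.name.replace(".gz", "").endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValidationError(
            f"non-numeric cell in {path.name} at row {row!r}, column {col!r}"
        )
    if df.isna().any().any():
        raise ValidationError(f"missing values in {path.name}; imputation unsupported")
    if orientation == "genes_in_rows":
        df = df.T  # -> samples x genes
    gene_ids = [str(g) for g in df.columns]
    sample_ids = [str(s) for s in df.index]
    classes = _resolve_sample_class(sample_ids, sample_class)
    return ExpressionMatrix(
        condition_name=condition_name or path.stem.replace(".tsv", "").replace(".csv", ""),
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=df.to_numpy(dtype=float),
        value_kind=value_kind,
        sample_class=classes,
    )


def _resolve_sample_class(sample_ids, sample_class):
    if sample_class is None:
        inferred = []
        for s in sample_ids:
            low = s.lower()
            if TUMOR in low:
                inferred.append(TUMOR)
            elif NORMAL in low:
                inferred.append(NORMAL)
            else:
                return None
        return inferred
    if isinstance(sample_class, Mapping):
        missing = [s for s in sample_ids if s not in sample_class]
        if missing:
            raise ValidationError(f"no class label for samples {missing[:10]}")
        return [sample_class[s] for s in sample_ids]
    return list(sample_class)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, orientation: str = "genes_in_rows"
) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.sample_ids, columns=matrix.gene_ids)
    if orientation == "genes_in_rows":
        df = df.T
        df.index.name = "gene_id"
    else:
        df.index.name = "sample_id"
    if matrix.value_kind == "raw_count":
        df = df.astype(int)
    df.to_csv(path, sep="\t")


def align_gene_panels(
    matrices: Sequence[ExpressionMatrix], gene_set: Sequence[str]
) -> list[ExpressionMatrix]:
    """Reorder every matrix's columns to ``gene_set``; error on any absent gene.

    Required because the decomposition shares a single right basis across
    conditions, so column ``j`` must mean the same gene everywhere.
    Idempotent: aligning aligned matrices is a no-op.
    """
    gene_set = list(gene_set)
    _check_unique(gene_set, "gene")
    missing = [
        (g, m.condition_name)
        for m in matrices
        for g in set(gene_set) - set(m.gene_ids)
    ]
    if missing:
        raise ValidationError(f"genes missing from panels: {sorted(missing)[:10]}")
    return [m.subset(genes=gene_set) for m in matrices]


def log2_fpkm_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(FPKM + 1) of a linear-scale matrix; +1 keeps zero FPKM finite."""
    if (matrix.values < 0).any():
        raise ValidationError("linear FPKM values must be non-negative")
    return ExpressionMatrix(
        condition_name=matrix.condition_name,
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
        values=np.log2(matrix.values + 1.0),
        value_kind="log2_fpkm",
        sample_class=list(matrix.sample_class) if matrix.sample_class else None,
    )


# ---------------------------------------------------------------------------
# survival


def read_survival_table(
    path: str | Path,
    condition_name: str | None = None,
    patient_col: str = "patient_id",
    time_col: str = "time",
    event_col: str = "event",
    sep: str = "\t",
) -> SurvivalTable:
    """Read a clinical table; patients appearing on multiple rows are removed
    entirely (repeated samples disqualify a patient, they are never merged)."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    for col in (patient_col, time_col, event_col):
        if col not in df.columns:
            raise ValidationError(
                f"{path.name}: expected columns {patient_col!r}, {time_col!r}, "
                f"{event_col!r}; found {list(df.columns)}"
            )
    df[patient_col] = df[patient_col].astype(str)
    df = df[~df[patient_col].duplicated(keep=False)]
    events = []
    for raw in df[event_col]:
        key = str(raw).strip().lower()
        if key not in _EVENT_ALIASES:
            raise ValidationError(
                f"unrecognized event value {raw!r}; accepted: 0/1, alive/dead, "
                "LIVING/DECEASED"
            )
        events.append(_EVENT_ALIASES[key])
    times = pd.to_numeric(df[time_col], errors="coerce")
    if times.isna().any():
        raise ValidationError("non-numeric survival time")
    return SurvivalTable(
        condition_name=condition_name or path.stem,
        patient_id=df[patient_col].tolist(),
        time=times.to_numpy(),
        event=np.asarray(events),
    )


def write_survival_table(table: SurvivalTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ID maps, edge lists, gene sets


def read_id_map(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Two-column source -> canonical gene ID table; a source mapping to two
    different canonical IDs is an error."""
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("ID map needs two columns (source, canonical)")
    mapping: dict[str, str] = {}
    for src, canon in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if src in mapping and mapping[src] != canon:
            raise ValidationError(f"source ID {src!r} maps to multiple canonical IDs")
        mapping[src] = canon
    return mapping


def read_edge_list(path: str | Path, sep: str = "\t") -> EdgeList:
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("edge list needs two columns")
    edges = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    annotations = {}
    if df.shape[1] >= 3:
        for a, b, note in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]):
            key = (a, b) if a <= b else (b, a)
            annotations[key] = note
    return EdgeList(edges=edges, annotations=annotations, source=str(path))


def write_edge_list(edge_list: EdgeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(edge_list.edges):
            fh.write(f"{a}\t{b}\n")


def read_gene_set(path: str | Path) -> list[str]:
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    _check_unique(genes, "gene")
    return genes


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
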