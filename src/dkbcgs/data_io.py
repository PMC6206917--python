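"""Reading and writing expression matrices, labels, weight tables and configs.

File conventions
----------------
Expression matrix: delimited text (comma for ``.csv``, tab otherwise) with a
header row of gene identifiers and a first column of sample identifiers.  Rows
are samples by default; ``orientation="genes"`` transposes on load for files
that store genes in rows.

Labels: either a single column of labels (one per sample, matrix row order) or
a two-column ``sample_id<sep>label`` file with a header, aligned by sample id.

Weight table: TSV with columns rank, gene_id, weight, sorted by rank; weights
are printed with 17 significant digits so a round trip is bit-exact.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "NormalizationRecord",
    "load_expression",
    "write_expression",
    "zscore_normalize",
    "write_weight_table",
    "read_weight_table",
    "read_kv_config",
    "write_kv_config",
]


@dataclass
class ExpressionDataset:
    """An n-samples x l-genes real-valued expression matrix with labels."""

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.validate()

    def validate(self) -> None:
        n, l = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"matrix has {n} rows but {len(self.sample_ids)} sample ids"
            )
        if len(self.gene_ids) != l:
            raise ValueError(
                f"matrix has {l} columns but {len(self.gene_ids)} gene ids"
            )
        if len(self.labels) != n:
            raise ValueError(f"{n} samples vs {len(self.labels)} labels")
        dup = _duplicates(self.gene_ids)
        if dup:
            raise ValueError(f"duplicate gene ids: {sorted(dup)}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValueError(f"duplicate sample ids: {sorted(dup)}")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"missing value at sample {self.sample_ids[i]!r} "
                f"(row {i}), gene {self.gene_ids[j]!r} (column {j})"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def l(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list:
        """Distinct class labels in first-appearance order."""
        seen: dict = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    def subset_samples(self, idx) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return ExpressionDataset(
            self.values[idx],
            [self.sample_ids[i] for i in idx],
            self.gene_ids,
            self.labels[idx],
        )


@dataclass
class NormalizationRecord:
    """Per-gene mean/sd used by z-scoring, plus the constant-gene index set."""

    mean: np.ndarray
    std: np.ndarray  # sample (n-1 denominator) standard deviation
    zero_variance_genes: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int)
    )


def _duplicates(items) -> set:
    seen, dup = set(), set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


def _sep_for(path, delimiter=None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def load_expression(
    matrix_path,
    labels_path=None,
    *,
    orientation: str = "samples",
    label_column: str | None = None,
    delimiter: str | None = None,
    missing: str = "reject",
) -> ExpressionDataset:
    """Load a delimited expression matrix plus class labels.

    Parameters
    ----------
    matrix_path
        Delimited text file, header row of gene ids, first column sample ids.
    labels_path
        Label file (see module docstring).  Required unless ``label_column``
        names a column of the matrix file to use as labels.
    orientation
        ``"samples"`` (rows are samples, default) or ``"genes"`` (rows are
        genes; transposed on load).
    missing
        ``"reject"`` (default) raises on any missing cell; ``"impute"``
        replaces missing cells with the gene mean.
    """
    if orientation not in ("samples", "genes"):
        raise ValueError(f"orientation must be 'samples' or 'genes', got {orientation!r}")
    sep = _sep_for(matrix_path, delimiter)
    with open(matrix_path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup = _duplicates(header)
    if dup:  # pandas would silently rename duplicated header cells
        kind = "gene" if orientation == "samples" else "sample"
        raise ValueError(f"duplicate {kind} ids: {sorted(dup)}")
    raw = pd.read_csv(matrix_path, sep=sep, index_col=0, dtype=str)
    if orientation == "genes":
        raw = raw.T

    labels_from_column = None
    if label_column is not None:
        if label_column not in raw.columns:
            raise ValueError(f"label column {label_column!r} not found in matrix file")
        labels_from_column = raw[label_column].to_numpy()
        raw = raw.drop(columns=[label_column])

    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(np.isnan(values) & raw.notna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-numeric value {raw.iat[i, j]!r} at row {raw.index[i]!r}, "
            f"column {raw.columns[j]!r}"
        )
    if np.isnan(values).any():
        if missing == "impute":
            mu = np.nanmean(values, axis=0)
            idx = np.where(np.isnan(values))
            values[idx] = np.take(mu, idx[1])
        else:
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing value at row {raw.index[i]!r}, column {raw.columns[j]!r} "
                "(use missing='impute' to fill with gene means)"
            )

    sample_ids = [str(s) for s in raw.index]
    gene_ids = [str(g) for g in raw.columns]

    if labels_from_column is not None:
        labels = labels_from_column
    elif labels_path is not None:
        labels = _load_labels(labels_path, sample_ids, delimiter)
    else:
        raise ValueError("labels_path or label_column is required")

    if len(labels) != len(sample_ids):
        raise ValueError(f"{len(sample_ids)} samples vs {len(labels)} labels")
    return ExpressionDataset(values, sample_ids, gene_ids, np.asarray(labels))


def _load_labels(path, sample_ids, delimiter=None) -> np.ndarray:
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if df.shape[1] == 1:
        return df.iloc[:, 0].str.strip().to_numpy()
    # two columns: header row (sample_id, label), align by sample id
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(
            f"label file must have 1 or 2 columns, got {df.shape[1]}"
        )
    mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1]))
    if len(mapping) != len(sample_ids):
        raise ValueError(f"{len(sample_ids)} samples vs {len(mapping)} labels")
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"labels missing for samples: {missing[:5]}")
    return np.array([mapping[s] for s in sample_ids])


def write_expression(ds: ExpressionDataset, matrix_path, labels_path) -> None:
    """Write the matrix (samples x genes TSV/CSV) and a sample_id/label file."""
    sep = _sep_for(matrix_path)
    df = pd.DataFrame(ds.values, index=ds.sample_ids, columns=ds.gene_ids)
    with _atomic(matrix_path) as tmp:
        df.to_csv(tmp, sep=sep, float_format="%.17g", index_label="sample_id")
    lab = pd.DataFrame({"sample_id": ds.sample_ids, "label": ds.labels})
    with _atomic(labels_path) as tmp:
        lab.to_csv(tmp, sep=_sep_for(labels_path), index=False)


def zscore_normalize(
    ds: ExpressionDataset,
) -> tuple[ExpressionDataset, NormalizationRecord]:
    """Z-score each gene: (x - mean) / sd across samples, sample (n-1) sd.

    Constant genes (sd == 0) map to all-zero columns and are recorded in
    ``zero_variance_genes`` rather than raising: real matrices contain
    constant probes, and a zero column simply carries no class structure.
    """
    if ds.n < 2:
        raise ValueError("z-score normalization needs at least 2 samples")
    mu = ds.values.mean(axis=0)
    sd = ds.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    safe = np.where(sd == 0, 1.0, sd)
    z = (ds.values - mu) / safe
    if zero.size:
        z[:, zero] = 0.0
    out = ExpressionDataset(z, ds.sample_ids, ds.gene_ids, ds.labels)
    return out, NormalizationRecord(mean=mu, std=sd, zero_variance_genes=zero)


def _rank_order(w: np.ndarray) -> np.ndarray:
    # descending weight, ties broken by gene index ascending
    return np.lexsort((np.arange(w.size), -w))


def write_weight_table(weights, gene_ids, path) -> None:
    """Write a rank/gene_id/weight TSV, best gene first.

    ``weights`` may be a plain vector or any object with a ``w`` attribute.
    Weights are printed with 17 significant digits so the round trip through
    :func:`read_weight_table` is bit-exact.
    """
    w = np.asarray(getattr(weights, "w", weights), dtype=float)
    if w.size != len(gene_ids):
        raise ValueError(f"{w.size} weights vs {len(gene_ids)} gene ids")
    order = getattr(weights, "order", None)
    if order is None:
        order = _rank_order(w)
    with _atomic(path) as tmp:
        with open(tmp, "w") as fh:
            fh.write("rank\tgene_id\tweight\n")
            for rank, g in enumerate(order, start=1):
                fh.write(f"{rank}\t{gene_ids[g]}\t{w[g]:.17g}\n")


def read_weight_table(path) -> pd.DataFrame:
    """Read a weight table back as a DataFrame with rank, gene_id, weight."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, float_precision="round_trip")
    expected = ["rank", "gene_id", "weight"]
    if list(df.columns) != expected:
        raise ValueError(f"weight table must have columns {expected}, got {list(df.columns)}")
    return df


def weights_vector(table: pd.DataFrame, gene_ids) -> np.ndarray:
    """Re-assemble the weight vector in the given gene order."""
    mapping = dict(zip(table["gene_id"], table["weight"]))
    missing = [g for g in gene_ids if str(g) not in mapping]
    if missing:
        raise ValueError(f"weight table missing genes: {missing[:5]}")
    return np.array([mapping[str(g)] for g in gene_ids], dtype=float)


def read_kv_config(path) -> dict[str, str]:
    """Read a flat ``key = value`` text config; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def write_kv_config(cfg: dict, path) -> None:
    with _atomic(path) as tmp:
        with open(tmp, "w") as fh:
            for k, v in cfg.items():
                fh.write(f"{k} = {v}\n")


class _atomic:
    """Write to a temp file in the target directory, rename on success."""

    def __init__(self, path):
        self.path = str(path)

    def __enter__(self) -> str:
        d = os.path.dirname(self.path) or "."
        fd, self.tmp = tempfile.mkstemp(dir=d, prefix=".tmp-")
        os.close(fd)
        return self.tmp

    def __exit__(self, exc_type, exc, tb):
        if exc_type is None:
            os.replace(self.tmp, self.path)
        else:
            try:
                os.unlink(self.tmp)
            except OSError:
                pass
        return False
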