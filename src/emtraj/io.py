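"""Containers and file formats for expression data.

The package-wide orientation is fixed: expression matrices are genes x
samples.  Values are log-scale expression.  Two on-disk layouts are
supported: a dense delimited table (first column gene ids, header row
sample ids) and a Matrix Market coordinate file with one-id-per-line
``genes.txt`` / ``samples.txt`` sidecars.

Gene identifiers are matched as exact strings; there is no alias or
synonym resolution.  Missing values are rejected at read time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

STATE_LABELS = ("EPI", "hEMT", "MES")


class ExpressionIOError(ValueError):
    """Raised for malformed expression files or invalid containers."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dups = s[s.duplicated()].unique().tolist()
        raise ExpressionIOError(f"duplicate {what} id(s): {dups}")


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of (log-scale) expression values.

    Optional per-sample annotations carry batch and tissue labels and
    tumour purity (fraction of malignant cells) in [0, 1].
    """

    values: np.ndarray
    gene_ids: pd.Index
    sample_ids: pd.Index
    batch: Optional[np.ndarray] = None
    tissue: Optional[np.ndarray] = None
    purity: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = pd.Index([str(g) for g in self.gene_ids])
        self.sample_ids = pd.Index([str(s) for s in self.sample_ids])
        if self.values.ndim != 2:
            raise ExpressionIOError("values must be a 2-D array (genes x samples)")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ExpressionIOError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ExpressionIOError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        for name in ("batch", "tissue"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=object)
                if v.shape != (self.n_samples,):
                    raise ExpressionIOError(f"{name} must have one entry per sample")
                setattr(self, name, v)
        if self.purity is not None:
            p = np.asarray(self.purity, dtype=float)
            if p.shape != (self.n_samples,):
                raise ExpressionIOError("purity must have one entry per sample")
            finite = np.isfinite(p)
            if np.any(finite & ((p < 0) | (p > 1))):
                raise ExpressionIOError("purity values must lie in [0, 1]")
            self.purity = p

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_ids.get_indexer(list(genes))
        if np.any(idx < 0):
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise KeyError(f"genes not present: {missing}")
        return replace(self, values=self.values[idx, :], gene_ids=pd.Index(list(genes)))

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = self.sample_ids.get_indexer(list(samples))
        if np.any(idx < 0):
            missing = [s for s, i in zip(samples, idx) if i < 0]
            raise KeyError(f"samples not present: {missing}")
        take = lambda a: None if a is None else a[idx]
        return ExpressionMatrix(
            self.values[:, idx],
            self.gene_ids,
            pd.Index(list(samples)),
            batch=take(self.batch),
            tissue=take(self.tissue),
            purity=take(self.purity),
        )


@dataclass
class ReferenceTrajectory:
    """A single-cell reference: expression plus per-cell pseudotime.

    Pseudotime is on the canonical [0, 100] scale used throughout the
    package; it is the template axis bulk samples are mapped onto.
    """

    expression: ExpressionMatrix
    pseudotime: np.ndarray
    name: str = "reference"

    def __post_init__(self) -> None:
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        if self.pseudotime.shape != (self.expression.n_samples,):
            raise ExpressionIOError("pseudotime must have one entry per cell")
        if np.any(~np.isfinite(self.pseudotime)):
            raise ExpressionIOError("pseudotime contains non-finite values")
        if self.pseudotime.min() < 0 or self.pseudotime.max() > 100:
            raise ExpressionIOError("pseudotime must lie in [0, 100]")

    @property
    def n_cells(self) -> int:
        return self.expression.n_samples


@dataclass
class CohortAnnotations:
    """Optional per-sample annotations attached downstream of projection."""

    stage: Optional[np.ndarray] = None
    state_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.state_labels is not None:
            bad = set(np.asarray(self.state_labels, dtype=object)) - set(STATE_LABELS)
            if bad:
                raise ExpressionIOError(
                    f"state labels must be drawn from {STATE_LABELS}; got {sorted(bad)}"
                )


# ---------------------------------------------------------------------------
# readers / writers


def _read_dense(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, comment="#")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = df.index[bad.to_numpy()][0]
            token = df.loc[row, col]
            raise ExpressionIOError(
                f"non-numeric value {token!r} at gene {row!r}, sample {col!r}"
            )
        out[col] = converted.to_numpy()
    return out


def read_expression_matrix(path: str | Path, format: str = "dense") -> ExpressionMatrix:
    """Read an expression matrix from ``dense`` or ``mm`` (Matrix Market) layout.

    For the sparse layout ``path`` is the ``.mtx`` file and ``genes.txt`` /
    ``samples.txt`` sidecars must sit next to it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dense":
        df = _read_dense(path)
        return ExpressionMatrix(df.to_numpy(), pd.Index(df.index), pd.Index(df.columns))
    if format == "mm":
        genes_f = path.parent / "genes.txt"
        samples_f = path.parent / "samples.txt"
        for f in (genes_f, samples_f):
            if not f.exists():
                raise ExpressionIOError(f"missing sidecar file {f}")
        genes = [ln.strip() for ln in genes_f.read_text().splitlines() if ln.strip()]
        samples = [ln.strip() for ln in samples_f.read_text().splitlines() if ln.strip()]
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        return ExpressionMatrix(np.asarray(mat, float), pd.Index(genes), pd.Index(samples))
    raise ValueError(f"unknown format {format!r}; use 'dense' or 'mm'")


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, format: str = "dense"
) -> Path:
    """Write a matrix so that ``read_expression_matrix`` round-trips it."""
    path = Path(path)
    if m.n_genes == 0 or m.n_samples == 0:
        raise ExpressionIOError("refusing to write an empty expression matrix")
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "dense":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        m.to_frame().to_csv(path, sep=sep, float_format="%.12g")
    elif format == "mm":
        coo = sparse.coo_matrix(m.values)
        coo.eliminate_zeros()
        spio.mmwrite(str(path), coo, precision=14)
        (path.parent / "genes.txt").write_text("\n".join(m.gene_ids) + "\n")
        (path.parent / "samples.txt").write_text("\n".join(m.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; use 'dense' or 'mm'")
    return path


def log_normalize(counts: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Library-size normalise and log-transform raw counts.

    Per sample j: ``value_ij = log(1 + scale * count_ij / sum_i count_ij)``.
    A sample whose counts sum to zero maps to an all-zero column.
    """
    v = counts.values
    if np.any(v < 0):
        raise ExpressionIOError("log_normalize requires non-negative counts")
    colsum = v.sum(axis=0)
    safe = np.where(colsum > 0, colsum, 1.0)
    out = np.log1p(scale * v / safe)
    out[:, colsum == 0] = 0.0
    return replace(counts, values=out)


def align_genes(
    bulk: ExpressionMatrix, refs: Sequence[ReferenceTrajectory]
) -> tuple[ExpressionMatrix, list[ReferenceTrajectory]]:
    """Restrict bulk and references to their shared genes, sorted.

    Idempotent and insensitive to the order of ``refs``.
    """
    shared = set(bulk.gene_ids)
    for r in refs:
        shared &= set(r.expression.gene_ids)
    shared = sorted(shared)
    if len(shared) < 2:
        raise ExpressionIOError(
            f"only {len(shared)} gene(s) shared between bulk and references; need >= 2"
        )
    out_refs = [
        replace(r, expression=r.expression.subset_genes(shared)) for r in refs
    ]
    return bulk.subset_genes(shared), out_refs


# ---------------------------------------------------------------------------
# directory bundles

_EXPR_BASENAMES = ("expression.tsv", "expression.csv", "expression.mtx")


def _read_expression_from_dir(d: Path) -> ExpressionMatrix:
    for base in _EXPR_BASENAMES:
        f = d / base
        if f.exists():
            fmt = "mm" if f.suffix == ".mtx" else "dense"
            return read_expression_matrix(f, format=fmt)
    raise ExpressionIOError(f"no expression file ({'/'.join(_EXPR_BASENAMES)}) in {d}")


def read_reference_bundle(directory: str | Path) -> ReferenceTrajectory:
    """Read one reference trajectory directory.

    Layout: an expression file, ``pseudotime.tsv`` (cell_id, pseudotime)
    and ``meta.json`` with at least a ``name`` key.
    """
    d = Path(directory)
    expr = _read_expression_from_dir(d)
    pt = pd.read_csv(d / "pseudotime.tsv", sep="\t", comment="#")
    pt = pt.set_index(pt.columns[0])[pt.columns[1]]
    missing = [c for c in expr.sample_ids if c not in pt.index]
    if missing:
        raise ExpressionIOError(f"cells missing from pseudotime.tsv: {missing[:5]}")
    meta_f = d / "meta.json"
    name = d.name
    if meta_f.exists():
        name = json.loads(meta_f.read_text()).get("name", name)
    return ReferenceTrajectory(expr, pt.loc[expr.sample_ids].to_numpy(), name=name)


def write_reference_bundle(ref: ReferenceTrajectory, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(ref.expression, d / "expression.tsv")
    pd.DataFrame(
        {"cell_id": ref.expression.sample_ids, "pseudotime": ref.pseudotime}
    ).to_csv(d / "pseudotime.tsv", sep="\t", index=False, float_format="%.12g")
    (d / "meta.json").write_text(json.dumps({"name": ref.name}) + "\n")
    return d


def read_bulk_dir(directory: str | Path) -> ExpressionMatrix:
    """Read a bulk cohort directory: expression file + optional annotations.tsv.

    ``annotations.tsv`` columns recognised: sample_id, purity, tissue, batch.
    """
    d = Path(directory)
    expr = _read_expression_from_dir(d)
    ann_f = d / "annotations.tsv"
    if ann_f.exists():
        ann = pd.read_csv(ann_f, sep="\t", comment="#").set_index("sample_id")
        missing = [s for s in expr.sample_ids if s not in ann.index]
        if missing:
            raise ExpressionIOError(f"samples missing from annotations.tsv: {missing[:5]}")
        ann = ann.loc[expr.sample_ids]
        kwargs = {}
        if "purity" in ann:
            kwargs["purity"] = ann["purity"].to_numpy(float)
        if "tissue" in ann:
            kwargs["tissue"] = ann["tissue"].to_numpy(object)
        if "batch" in ann:
            kwargs["batch"] = ann["batch"].to_numpy(object)
        expr = replace(expr, **kwargs)
    return expr


def write_bulk_dir(expr: ExpressionMatrix, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(expr, d / "expression.tsv")
    cols = {"sample_id": expr.sample_ids}
    if expr.purity is not None:
        cols["purity"] = expr.purity
    if expr.tissue is not None:
        cols["tissue"] = expr.tissue
    if expr.batch is not None:
        cols["batch"] = expr.batch
    if len(cols) > 1:
        pd.DataFrame(cols).to_csv(
            d / "annotations.tsv", sep="\t", index=False, float_format="%.12g"
        )
    return d
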