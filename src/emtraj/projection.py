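"""Bulk-to-single-cell EMT pseudotime projection.

Bulk samples are merged with a single-cell reference trajectory, batch
effects between the two platforms are removed with parametric empirical
Bayes (ComBat) correction, the merged matrix is embedded with PCA, and
each bulk sample receives the mean pseudotime of its k nearest reference
cells in the embedding.  Repeating the procedure over several references
and averaging yields the consensus pseudotime on the [0, 100] scale.

An optional pre-step regresses bulk expression on tumour purity gene by
gene, removing stromal/immune contamination signal before projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionMatrix, ReferenceTrajectory, align_genes

logger = logging.getLogger(__name__)

_VAR_EPS = 1e-12


@dataclass(frozen=True)
class ProjectionConfig:
    """Settings for the projection pipeline.

    ``n_components`` is the PCA dimensionality (default 25) and
    ``k_neighbors`` the number of reference cells averaged per bulk
    sample (default 10).
    """

    n_components: int = 25
    k_neighbors: int = 10
    purity_adjust: bool = False
    references: Optional[tuple[str, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass
class EmbeddingModel:
    """A fitted PCA embedding: loadings, gene means, explained variance."""

    component_loadings: np.ndarray  # genes x components
    gene_means: np.ndarray
    explained_variance: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Project a genes x samples matrix into the embedding."""
        return (values - self.gene_means[:, None]).T @ self.component_loadings


@dataclass
class PseudotimeResult:
    """Per-reference pseudotimes and their consensus mean."""

    per_reference: pd.DataFrame  # samples x references
    consensus: pd.Series

    def __post_init__(self) -> None:
        if self.per_reference.shape[1] == 0:
            raise ValueError("per_reference must have at least one column")
        vals = self.per_reference.to_numpy(float)
        if vals.min() < -1e-9 or vals.max() > 100 + 1e-9:
            raise ValueError("pseudotimes must lie in [0, 100]")
        if not np.allclose(self.consensus.to_numpy(float), vals.mean(axis=1), atol=1e-9):
            raise ValueError("consensus must equal the row mean of per_reference")


# ---------------------------------------------------------------------------
# stages


def correct_batch(merged: ExpressionMatrix, batch: Sequence[str]) -> ExpressionMatrix:
    """Parametric empirical-Bayes (ComBat) location/scale batch correction.

    Per gene the data are standardised after a least-squares fit of batch
    effects, per-batch location and scale parameters are shrunk toward
    batch-level moments (normal / inverse-gamma priors), and the shrunken
    effects are removed.  A single batch is a no-op; genes whose
    within-batch variance is numerically zero are mean-equalised only.
    """
    batch = np.asarray(batch, dtype=object)
    if batch.shape != (merged.n_samples,):
        raise ValueError("batch must have one label per sample")
    labels, counts = np.unique(batch, return_counts=True)
    if len(labels) == 1:
        return merged
    if counts.min() < 2:
        singles = labels[counts < 2].tolist()
        raise ValueError(f"batch(es) with a single sample: {singles}")

    values = merged.values
    # Genes without residual within-batch variance cannot be standardised;
    # equalise their batch means directly.
    within_var = np.zeros(merged.n_genes)
    for lab in labels:
        cols = values[:, batch == lab]
        within_var += cols.var(axis=1) * cols.shape[1]
    within_var /= merged.n_samples
    degenerate = within_var < _VAR_EPS

    out = values.copy()
    if degenerate.any():
        grand = values[degenerate].mean(axis=1, keepdims=True)
        for lab in labels:
            mask = batch == lab
            sub = out[np.ix_(degenerate, mask)]
            out[np.ix_(degenerate, mask)] = sub - sub.mean(axis=1, keepdims=True) + grand

    keep = ~degenerate
    if 0 < keep.sum() < 3:
        # too few genes to estimate empirical-Bayes priors across genes:
        # plain location/scale equalisation toward pooled moments
        idx = np.flatnonzero(keep)
        pooled_mean = values[idx].mean(axis=1, keepdims=True)
        pooled_sd = np.sqrt(within_var[idx])[:, None]
        for lab in labels:
            mask = batch == lab
            sub = values[np.ix_(idx, mask)]
            mu = sub.mean(axis=1, keepdims=True)
            sd = sub.std(axis=1, keepdims=True)
            sd = np.where(sd > 0, sd, 1.0)
            out[np.ix_(idx, mask)] = (sub - mu) / sd * pooled_sd + pooled_mean
    elif keep.any():
        import anndata as ad
        import scanpy as sc

        adata = ad.AnnData(
            X=values[keep].T.astype(np.float64),
            obs=pd.DataFrame({"batch": pd.Categorical(batch)},
                             index=merged.sample_ids),
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            corrected = sc.pp.combat(adata, key="batch", inplace=False)
        out[keep] = np.asarray(corrected).T
    return replace(merged, values=out)


def fit_embedding(
    corrected: ExpressionMatrix, n_components: int
) -> tuple[EmbeddingModel, np.ndarray]:
    """PCA on samples; deterministic up to a fixed sign convention.

    The sign of each component is chosen so its largest-magnitude gene
    loading is positive.  Returns the model and samples x components
    coordinates.
    """
    if n_components > min(corrected.n_genes, corrected.n_samples):
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, samples)="
            f"{min(corrected.n_genes, corrected.n_samples)}"
        )
    X = corrected.values.T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x components
    for j in range(n_components):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            coords[:, j] *= -1
    model = EmbeddingModel(loadings, pca.mean_.copy(), pca.explained_variance_.copy())
    return model, coords


def map_to_reference(
    bulk_coords: np.ndarray,
    ref_coords: np.ndarray,
    ref_pseudotime: np.ndarray,
    k: int,
) -> np.ndarray:
    """k-NN pseudotime transfer: mean pseudotime of the k nearest cells.

    Euclidean distance in the embedding; each bulk sample is mapped
    independently of all others.
    """
    ref_pseudotime = np.asarray(ref_pseudotime, float)
    if k > ref_coords.shape[0]:
        raise ValueError(f"k={k} exceeds number of reference cells {ref_coords.shape[0]}")
    if bulk_coords.shape[1] != ref_coords.shape[1]:
        raise ValueError("bulk and reference coordinates must share dimensionality")
    nn = NearestNeighbors(n_neighbors=k, algorithm="brute", metric="euclidean")
    nn.fit(ref_coords)
    _, idx = nn.kneighbors(bulk_coords)
    return ref_pseudotime[idx].mean(axis=1)


def consensus_pseudotime(per_reference: pd.DataFrame) -> pd.Series:
    """Unweighted mean across references; identity for one reference."""
    if per_reference.shape[1] == 0:
        raise ValueError("per_reference has no columns")
    return per_reference.mean(axis=1)


def adjust_for_purity(bulk: ExpressionMatrix) -> ExpressionMatrix:
    """Remove purity-correlated expression gene by gene.

    Each gene is replaced by the residuals of a univariate regression on
    tumour purity, re-centred at the gene's original mean, so the output
    is exactly uncorrelated with purity.
    """
    if bulk.purity is None:
        raise ValueError("purity annotation required for purity adjustment")
    bad = np.flatnonzero(~np.isfinite(bulk.purity))
    if bad.size:
        raise ValueError(
            f"samples with missing purity: {list(bulk.sample_ids[bad][:10])}"
        )
    p = bulk.purity - bulk.purity.mean()
    denom = float(p @ p)
    if denom < _VAR_EPS:  # constant purity: nothing to remove
        return bulk
    slope = (bulk.values @ p) / denom
    out = bulk.values - slope[:, None] * p[None, :]
    return replace(bulk, values=out)


def reconstruct_pseudotime(
    bulk: ExpressionMatrix,
    refs: Sequence[ReferenceTrajectory],
    cfg: ProjectionConfig = ProjectionConfig(),
) -> PseudotimeResult:
    """Full projection pipeline with consensus over references.

    Per reference: align genes -> optional purity adjustment -> merge ->
    batch-correct (bulk vs reference) -> PCA -> k-NN pseudotime transfer.
    The consensus is the unweighted mean over references.
    """
    if not refs:
        raise ValueError("at least one reference trajectory is required")
    logger.info(
        "projection: %d bulk samples, references=%s, k=%d, components=%d, "
        "purity_adjust=%s, seed=%d",
        bulk.n_samples, [r.name for r in refs], cfg.k_neighbors,
        cfg.n_components, cfg.purity_adjust, cfg.seed,
    )
    columns = {}
    for pos, ref in enumerate(refs):
        b, (r,) = align_genes(bulk, [ref])
        if cfg.purity_adjust:
            b = adjust_for_purity(b)
        merged_values = np.hstack([b.values, r.expression.values])
        merged_ids = pd.Index(
            [f"b:{s}" for s in b.sample_ids] + [f"r:{c}" for c in r.expression.sample_ids]
        )
        merged = ExpressionMatrix(merged_values, b.gene_ids, merged_ids)
        batch = np.array(
            ["bulk"] * b.n_samples + ["reference"] * r.expression.n_samples, dtype=object
        )
        corrected = correct_batch(merged, batch)
        # Genes that are flat across the merged cohort carry no geometry.
        usable = corrected.values.var(axis=1) > _VAR_EPS
        values = corrected.values[usable]
        n_comp = cfg.n_components
        if n_comp > min(int(usable.sum()), merged.n_samples):
            raise ValueError(
                f"n_components={n_comp} exceeds usable genes ({int(usable.sum())}) "
                f"or samples ({merged.n_samples}) for reference {ref.name!r}"
            )
        sub = ExpressionMatrix(values, corrected.gene_ids[usable], merged_ids)
        _, coords = fit_embedding(sub, n_comp)
        pt = map_to_reference(
            coords[: b.n_samples], coords[b.n_samples:], r.pseudotime, cfg.k_neighbors
        )
        name = ref.name if ref.name not in columns else f"{ref.name}#{pos}"
        columns[name] = pt
    per_ref = pd.DataFrame(columns, index=bulk.sample_ids)
    return PseudotimeResult(per_ref, consensus_pseudotime(per_ref))
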