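"""Bulk expression-matrix processing: tissue filtering, quantile
normalization, and pathway-gene tissue ranking.

The workflow mirrors how tissue-level bulk RNA-seq compendia are screened
for a pathway of interest: drop tissues with too few samples (default
minimum 20), force all samples onto a common value distribution by quantile
normalization, then rank tissues by the median expression of a gene set
(here the PINK1/Parkin mitophagy genes), combining per-gene ranks by their
mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mitoquant.synthetic_data import ExpressionMatrix, PATHWAY_GENES

__all__ = [
    "filter_tissues",
    "quantile_normalize",
    "rank_tissues",
    "filter_samples_by_distribution",
    "load_expression_tsv",
    "save_expression_tsv",
]


def filter_tissues(matrix: ExpressionMatrix, min_samples: int = 20) -> ExpressionMatrix:
    """Drop tissues represented by fewer than ``min_samples`` samples."""
    if min_samples < 1:
        raise ValueError(f"min_samples must be >= 1, got {min_samples}")
    counts = matrix.samples_per_tissue()
    keep_tissues = set(counts.index[counts >= min_samples])
    keep_samples = [s for s in matrix.values.columns if matrix.tissues[s] in keep_tissues]
    if not keep_samples:
        raise ValueError(
            f"no tissue has >= {min_samples} samples; largest has {counts.max() if len(counts) else 0}"
        )
    return ExpressionMatrix(
        values=matrix.values[keep_samples].copy(),
        tissues=matrix.tissues.loc[keep_samples].copy(),
        normalized=matrix.normalized,
    )


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean empirical distribution.

    Each sample's values are replaced by the across-sample means of the
    order statistics at each rank; ties within a sample receive the mean of
    the reference values at the tied positions, so the transform is
    deterministic and permutation-equivariant.
    """
    X = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_genes)
        assigned[order] = reference
        # average reference values over tie groups
        sorted_vals = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        for grp in np.split(order, boundaries):
            if len(grp) > 1:
                assigned[grp] = assigned[grp].mean()
        out[:, j] = assigned
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values=values, tissues=matrix.tissues.copy(), normalized=True)


def rank_tissues(
    matrix: ExpressionMatrix, gene_set: list[str] | tuple[str, ...] = PATHWAY_GENES
) -> pd.DataFrame:
    """Rank tissues by combined pathway-gene expression.

    For each gene in ``gene_set`` the per-tissue median expression is
    computed and tissues are ranked per gene (rank 1 = highest median). The
    combined score is the mean of a tissue's per-gene ranks; tissues are
    returned sorted by ascending combined score, ties broken alphabetically.
    """
    missing = [g for g in gene_set if g not in matrix.values.index]
    if missing:
        raise ValueError(f"genes absent from the matrix: {missing}")
    tissues = matrix.tissues.loc[matrix.values.columns]
    medians = (
        matrix.values.loc[list(gene_set)]
        .T.groupby(tissues)
        .median()
    )  # tissues x genes
    ranks = medians.rank(ascending=False, method="average")
    out = medians.copy()
    out.columns = [f"median_{g}" for g in out.columns]
    out["combined_score"] = ranks.mean(axis=1)
    # deterministic ordering: score, then tissue name
    out = out.iloc[np.lexsort((out.index.to_numpy(), out["combined_score"].to_numpy()))]
    out.index.name = "tissue"
    return out


def filter_samples_by_distribution(
    matrix: ExpressionMatrix, k_mad: float = 5.0
) -> ExpressionMatrix:
    """Optional QC filter: drop samples with aberrant expression distributions.

    A sample is removed when its median log1p expression deviates from its
    tissue's median of those medians by more than ``k_mad`` median absolute
    deviations. Disabled by default in the pipeline; when used, the removed
    samples are reported via the returned matrix's shape.
    """
    if k_mad <= 0:
        raise ValueError(f"k_mad must be > 0, got {k_mad}")
    logmed = pd.Series(
        np.median(np.log1p(matrix.values.to_numpy(dtype=float)), axis=0),
        index=matrix.values.columns,
    )
    tissues = matrix.tissues.loc[matrix.values.columns]
    keep = []
    for tname, idx in logmed.groupby(tissues).groups.items():
        vals = logmed.loc[idx]
        center = vals.median()
        mad = (vals - center).abs().median()
        if mad == 0:
            keep.extend(idx)
            continue
        keep.extend(vals.index[(vals - center).abs() <= k_mad * mad])
    keep = [s for s in matrix.values.columns if s in set(keep)]
    if not keep:
        raise ValueError("distribution QC removed every sample")
    return ExpressionMatrix(
        values=matrix.values[keep].copy(),
        tissues=matrix.tissues.loc[keep].copy(),
        normalized=matrix.normalized,
    )


def load_expression_tsv(values_path, annotation_path) -> ExpressionMatrix:
    """Load a genes x samples TSV plus a sample -> tissue annotation TSV."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
    if "tissue" not in ann.columns:
        raise ValueError("annotation TSV must have a 'tissue' column")
    return ExpressionMatrix(values=values, tissues=ann["tissue"])


def save_expression_tsv(matrix: ExpressionMatrix, values_path, annotation_path) -> None:
    matrix.values.to_csv(values_path, sep="\t")
    ann = pd.DataFrame({"tissue": matrix.tissues.loc[matrix.values.columns]})
    ann.index.name = "sample_id"
    ann.to_csv(annotation_path, sep="\t")
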