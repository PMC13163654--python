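"""Expression preprocessing and group comparison.

Batch adjustment (per-gene location-scale standardization), principal
component checks, Wilcoxon rank-sum differential expression with
Benjamini-Hochberg correction, and per-cell-type single-cell expression
summaries (mean log-normalized level, fraction of cells expressing, 10%
detection floor).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import scipy.sparse
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthdata import ExpressionBundle

__all__ = [
    "batch_adjust",
    "principal_components",
    "diff_expr",
    "sc_expression_summary",
    "wilcoxon_p",
]


def batch_adjust(bundle: ExpressionBundle) -> ExpressionBundle:
    """Remove per-gene batch location and scale differences.

    Each gene's values within a batch are standardized to the batch mean and
    (population) standard deviation, then rescaled to the gene's pooled mean
    and standard deviation.  This preserves each gene's pooled first two
    moments and is idempotent.  A conscious simplification of empirical-Bayes
    batch correction: no shrinkage across genes is applied.
    """
    x = bundle.matrix.to_numpy(dtype=float).copy()
    batches = bundle.samples["batch"].to_numpy()
    for b in np.unique(batches):
        if np.sum(batches == b) < 2:
            raise ValueError(
                f"batch {b!r} has a single sample; merge it before adjusting")
    pooled_mean = x.mean(axis=1, keepdims=True)
    pooled_sd = x.std(axis=1, keepdims=True)
    out = np.empty_like(x)
    for b in np.unique(batches):
        cols = batches == b
        sub = x[:, cols]
        m = sub.mean(axis=1, keepdims=True)
        s = sub.std(axis=1, keepdims=True)
        s = np.where(s > 0, s, 1.0)
        out[:, cols] = (sub - m) / s * pooled_sd + pooled_mean
    matrix = pd.DataFrame(out, index=bundle.matrix.index,
                          columns=bundle.matrix.columns)
    return replace(bundle, matrix=matrix)


def principal_components(bundle: ExpressionBundle, k: int = 2) -> dict:
    """Sample coordinates on the top-k principal components.

    Genes are centered; coordinates come from the singular value
    decomposition of the centered matrix.  Returns sample coordinates
    (samples x k) and the variance-explained fraction per component.
    """
    x = bundle.matrix.to_numpy(dtype=float)
    if k > min(x.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(x.shape)}")
    xc = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    varexp = s ** 2 / np.sum(s ** 2)
    coords = pd.DataFrame((vt[:k].T * s[:k]),
                          index=bundle.matrix.columns,
                          columns=[f"PC{i + 1}" for i in range(k)])
    return {"coordinates": coords, "variance_explained": varexp[:k]}


def wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided unpaired Wilcoxon rank-sum p.

    Exact enumeration when both groups have at most 8 observations and no
    ties straddle the groups; otherwise the normal approximation with
    mid-ranks and tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.array_equal(np.sort(a), np.sort(b)):
        return 1.0
    use_exact = (len(a) <= 8 and len(b) <= 8
                 and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b))
    method = "exact" if use_exact else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def diff_expr(bundle: ExpressionBundle, group_a: str = "disease",
              group_b: str = "control") -> pd.DataFrame:
    """Per-gene Wilcoxon differential expression, BH-corrected.

    ``log2fc`` is the difference of group means of the (log2-scale)
    expression values, group_a minus group_b.
    """
    groups = bundle.samples["group"].to_numpy()
    in_a = groups == group_a
    in_b = groups == group_b
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ValueError(f"empty group among ({group_a!r}, {group_b!r})")
    x = bundle.matrix.to_numpy(dtype=float)
    log2fc = x[:, in_a].mean(axis=1) - x[:, in_b].mean(axis=1)
    pvals = np.array([wilcoxon_p(row[in_a], row[in_b]) for row in x])
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({"log2fc": log2fc, "p": pvals, "padj": padj},
                        index=bundle.matrix.index)


def sc_expression_summary(counts, cell_meta: pd.DataFrame,
                          genes: list[str],
                          query_genes: list[str] | None = None,
                          detection_floor: float = 0.10) -> pd.DataFrame:
    """Per (gene, cell type) expression summary from raw counts.

    Log-normalization is ln(1 + 1e4 * count / cell_total).  Genes detected
    in fewer than ``detection_floor`` of a type's cells are marked
    ``filtered``.  ``p_vs_rest`` is the Wilcoxon p of the gene's
    log-normalized values in the type versus all other cells.
    """
    counts = scipy.sparse.csr_matrix(counts)
    if counts.shape[1] != len(cell_meta):
        raise ValueError("cell metadata must cover every matrix column")
    if query_genes is None:
        query_genes = list(genes)
    unknown = [g for g in query_genes if g not in genes]
    if unknown:
        raise ValueError(f"unknown gene ids: {unknown}")
    totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    totals[totals == 0] = 1.0
    gene_index = {g: i for i, g in enumerate(genes)}
    types = cell_meta["cell_type"].to_numpy()
    rows = []
    for g in query_genes:
        vec = np.asarray(counts[gene_index[g]].todense()).ravel().astype(float)
        lognorm = np.log1p(1e4 * vec / totals)
        for t in np.unique(types):
            in_t = types == t
            frac = float(np.mean(vec[in_t] > 0))
            p_rest = (wilcoxon_p(lognorm[in_t], lognorm[~in_t])
                      if 0 < in_t.sum() < len(types) else float("nan"))
            rows.append({
                "gene": g,
                "cell_type": t,
                "mean_lognorm": float(lognorm[in_t].mean()),
                "frac_expressing": frac,
                "filtered": frac < detection_floor,
                "p_vs_rest": p_rest,
            })
    return pd.DataFrame(rows)
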