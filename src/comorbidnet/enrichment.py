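"""Gene-set enrichment scoring and pathway-activity stratification.

The enrichment score of a gene set is the signed extreme deviation of a
running sum over a ranked gene list (Kolmogorov-Smirnov-style walk): hits
add 1/|S in list|, misses subtract 1/(N - |S in list|).  Significance comes
from phenotype-label permutation.  Single-sample pathway activity is the
same walk computed on each sample's own expression ranking; lesional
samples are median-split into high/low activity groups for heterogeneity
analysis against hub-gene expression, serum CRP and disease subtype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import wilcoxon_p
from .synthdata import ExpressionBundle

__all__ = [
    "gsea_es",
    "gsea_permutation",
    "sample_scores",
    "score_group_diff",
    "stratify",
]


def gsea_es(ranked_genes, members, weights: np.ndarray | None = None,
            p: float = 1.0) -> float:
    """Enrichment score of a gene set on a ranked list.

    Unweighted by default (each hit adds 1/n_hits).  With ``weights`` (the
    per-gene ranking metric aligned to ``ranked_genes``), hits add
    |metric|^p / sum over hits, the weighted variant.  Returns the signed
    extreme of the running sum; a set covering the whole list returns +1 by
    convention.
    """
    ranked_genes = list(ranked_genes)
    member_set = set(members)
    n = len(ranked_genes)
    hit = np.array([g in member_set for g in ranked_genes])
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("no gene-set member appears in the ranked list")
    if n_hit == n:
        return 1.0
    if weights is None:
        hit_inc = np.where(hit, 1.0 / n_hit, 0.0)
    else:
        w = np.abs(np.asarray(weights, dtype=float)) ** p
        denom = w[hit].sum()
        if denom == 0:
            hit_inc = np.where(hit, 1.0 / n_hit, 0.0)
        else:
            hit_inc = np.where(hit, w / denom, 0.0)
    miss_inc = np.where(hit, 0.0, 1.0 / (n - n_hit))
    walk = np.cumsum(hit_inc - miss_inc)
    return float(walk[np.argmax(np.abs(walk))])


def gsea_permutation(bundle: ExpressionBundle, phenotype: str,
                     members, n_perm: int = 1000, seed: int = 0) -> dict:
    """Phenotype-permutation significance of a gene set's enrichment.

    The ranking metric is the per-gene difference of group means (phenotype
    group vs the rest, descending).  The permutation p uses the +1
    correction: p = (1 + #{|ES_null| >= |ES_obs|}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    labels = bundle.samples["group"].to_numpy()
    x = bundle.matrix.to_numpy(dtype=float)
    genes = np.asarray(bundle.matrix.index)
    in_g = labels == phenotype
    if in_g.sum() == 0 or (~in_g).sum() == 0:
        raise ValueError(f"phenotype {phenotype!r} does not split the samples")

    def es_for(mask: np.ndarray) -> float:
        metric = x[:, mask].mean(axis=1) - x[:, ~mask].mean(axis=1)
        order = np.argsort(-metric, kind="stable")
        return gsea_es(genes[order], members)

    es_obs = es_for(in_g)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(in_g)
        if abs(es_for(perm)) >= abs(es_obs):
            exceed += 1
    return {"es": es_obs, "p_perm": (1 + exceed) / (1 + n_perm),
            "n_perm": n_perm}


def sample_scores(bundle: ExpressionBundle, members) -> pd.Series:
    """Single-sample pathway activity scores.

    For each sample, genes are ranked by that sample's expression
    (descending) and the unweighted running-sum extreme is the score.
    Rank-based, hence invariant to within-sample monotone transforms.
    """
    genes = np.asarray(bundle.matrix.index)
    x = bundle.matrix.to_numpy(dtype=float)
    scores = {}
    for j, sample in enumerate(bundle.matrix.columns):
        order = np.argsort(-x[:, j], kind="stable")
        scores[sample] = gsea_es(genes[order], members)
    return pd.Series(scores, name="activity_score")


def score_group_diff(scores: pd.Series, labels: pd.Series,
                     n_perm: int = 1000, seed: int = 0) -> dict:
    """Standardized activity-score difference between two groups.

    Cohen's d with pooled standard deviation, with a two-sided
    label-permutation p.  The difference is group_a minus group_b; when the
    labels are disease/control, disease is group_a, otherwise groups come in
    sorted order.
    """
    labels = pd.Series(np.asarray(labels), index=scores.index)
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    if set(levels) == {"disease", "control"}:
        levels = ["disease", "control"]
    a = scores[labels == levels[0]].to_numpy()
    b = scores[labels == levels[1]].to_numpy()

    def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
        na, nb = len(a), len(b)
        pooled = np.sqrt(((na - 1) * np.var(a, ddof=1)
                          + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2))
        if pooled == 0:
            return 0.0
        return float((a.mean() - b.mean()) / pooled)

    d_obs = cohens_d(a, b)
    rng = np.random.default_rng(seed)
    pool = np.concatenate([a, b])
    exceed = 0
    for _ in range(n_perm):
        rng.shuffle(pool)
        if abs(cohens_d(pool[:len(a)], pool[len(a):])) >= abs(d_obs):
            exceed += 1
    return {"d": d_obs, "p_perm": (1 + exceed) / (1 + n_perm),
            "group_a": levels[0], "group_b": levels[1]}


def stratify(scores: pd.Series, bundle: ExpressionBundle,
             hub_genes) -> dict:
    """Median-split heterogeneity analysis of lesional samples.

    Lesion (disease) samples are split at the median activity score (ties
    go to the low group).  Hub genes are compared high vs low by Wilcoxon
    with BH correction; the score-CRP Spearman correlation is computed on
    lesional samples; per-subtype score summaries report each subtype's
    standardized difference (Cohen's d) versus controls.
    """
    samples = bundle.samples.set_index("sample")
    lesion = samples.index[samples["group"] == "disease"]
    s_lesion = scores.loc[lesion]
    med = float(s_lesion.median())
    degenerate = bool(np.ptp(s_lesion.to_numpy()) == 0)
    assignment = pd.Series(np.where(s_lesion > med, "high", "low"),
                           index=lesion, name="activity_group")

    hub_rows = []
    high = assignment.index[assignment == "high"]
    low = assignment.index[assignment == "low"]
    for g in hub_genes:
        if g not in bundle.matrix.index:
            raise ValueError(f"hub gene {g!r} absent from expression matrix")
        vals = bundle.matrix.loc[g]
        p = (wilcoxon_p(vals[high].to_numpy(), vals[low].to_numpy())
             if len(high) and len(low) else np.nan)
        hub_rows.append({
            "gene": g,
            "mean_high": float(vals[high].mean()) if len(high) else np.nan,
            "mean_low": float(vals[low].mean()) if len(low) else np.nan,
            "p": p})
    hub_table = pd.DataFrame(hub_rows)
    if len(hub_table) and hub_table["p"].notna().all():
        hub_table["padj"] = multipletests(hub_table["p"], method="fdr_bh")[1]

    crp = samples.loc[lesion, "crp"].to_numpy(dtype=float)
    if np.ptp(crp) > 0 and not degenerate:
        crp_r, crp_p = stats.spearmanr(s_lesion.to_numpy(), crp)
    else:
        crp_r, crp_p = np.nan, np.nan

    controls = samples.index[samples["group"] == "control"]
    s_control = scores.loc[controls].to_numpy()
    subtype_rows = []
    for st in sorted(set(samples.loc[lesion, "subtype"]) - {"NA"}):
        sel = lesion[samples.loc[lesion, "subtype"] == st]
        vals = scores.loc[sel].to_numpy()
        na, nb = len(vals), len(s_control)
        pooled = np.sqrt(((na - 1) * np.var(vals, ddof=1)
                          + (nb - 1) * np.var(s_control, ddof=1))
                         / max(1, na + nb - 2))
        d = float((vals.mean() - s_control.mean()) / pooled) if pooled > 0 else 0.0
        subtype_rows.append({"subtype": st, "n": na,
                             "mean_score": float(vals.mean()),
                             "d_vs_control": d})
    return {
        "assignment": assignment,
        "median": med,
        "degenerate": degenerate,
        "hub_comparison": hub_table,
        "crp_spearman_r": float(crp_r) if np.isfinite(crp_r) else np.nan,
        "crp_spearman_p": float(crp_p) if np.isfinite(crp_p) else np.nan,
        "subtype_summary": pd.DataFrame(subtype_rows),
    }
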