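"""Weighted co-expression network analysis.

Soft-threshold scan for scale-free topology, unsigned adjacency
a_ij = |cor(x_i, x_j)|^beta, topological overlap transformation, module
detection by average-linkage clustering of the TOM dissimilarity, module
eigengenes, module-trait correlation, and cross-dataset module preservation
(Zsummary from density and connectivity permutation Z-scores).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .synthdata import ExpressionBundle

__all__ = [
    "SoftThresholdScan",
    "soft_threshold_scan",
    "adjacency",
    "tom",
    "detect_modules",
    "module_eigengene",
    "module_trait_cor",
    "module_preservation",
]

logger = logging.getLogger(__name__)

DEFAULT_POWER = 12
DEFAULT_POWERS = tuple(range(2, 21))


@dataclass(frozen=True)
class SoftThresholdScan:
    table: pd.DataFrame            # power, r2_signed, mean_connectivity
    selected_power: int
    criterion_met: bool            # True if some r2_signed >= threshold


def _abs_correlation(bundle: ExpressionBundle) -> np.ndarray:
    x = bundle.matrix.to_numpy(dtype=float)
    c = np.corrcoef(x)
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 1.0)
    return np.abs(np.clip(c, -1.0, 1.0))


def adjacency(bundle: ExpressionBundle, beta: int = DEFAULT_POWER) -> np.ndarray:
    """Unsigned adjacency |pearson(x_i, x_j)|^beta with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    return _abs_correlation(bundle) ** beta


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free fit index from a 10-bin log-log degree regression.

    Returns -sign(slope) * R^2 of log10 p(k) on log10 mean-k per bin; NaN
    when the connectivities are degenerate.
    """
    if np.ptp(k) <= 0:
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        mk = k[sel].mean()
        pk = sel.mean()
        if mk > 0 and pk > 0:
            xs.append(np.log10(mk))
            ys.append(np.log10(pk))
    if len(xs) < 3:
        return float("nan")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r ** 2)


def soft_threshold_scan(bundle: ExpressionBundle,
                        powers=DEFAULT_POWERS,
                        r2_threshold: float = 0.90) -> SoftThresholdScan:
    """Scan candidate soft-threshold powers for scale-free topology.

    The selected power is the smallest with signed fit index at or above
    ``r2_threshold``; if no power qualifies, the argmax is returned with
    ``criterion_met`` False.
    """
    powers = sorted(set(int(p) for p in powers))
    c = _abs_correlation(bundle)
    np.fill_diagonal(c, 0.0)
    rows = []
    for beta in powers:
        k = (c ** beta).sum(axis=1)
        mean_k = float(k.mean())
        # a network thresholded below unit mean connectivity is vacuous;
        # its log-log fit says nothing about scale-free structure
        r2 = _scale_free_fit(k) if mean_k >= 1.0 else float("nan")
        rows.append({"power": beta,
                     "r2_signed": r2,
                     "mean_connectivity": mean_k})
    table = pd.DataFrame(rows)
    ok = table["r2_signed"] >= r2_threshold
    if ok.any():
        selected = int(table.loc[ok, "power"].iloc[0])
        met = True
    else:
        if table["r2_signed"].notna().any():
            selected = int(table.loc[table["r2_signed"].idxmax(), "power"])
        else:
            selected = powers[0]
        met = False
        logger.warning("no power reached r2 >= %.2f; falling back to "
                       "argmax power %d", r2_threshold, selected)
    return SoftThresholdScan(table=table, selected_power=selected,
                             criterion_met=met)


def tom(a: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency matrix.

    omega_ij = (sum_{u not in {i,j}} a_iu a_uj + a_ij)
               / (min(k_i, k_j) + 1 - a_ij),
    with connectivity k_i excluding the self-adjacency; diagonal set to 1.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    shared = a0 @ a0                      # u=i and u=j terms vanish (zero diag)
    numer = shared + a0
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        w = numer / denom
    w = np.nan_to_num(w, nan=0.0)
    np.fill_diagonal(w, 1.0)
    return np.clip(w, 0.0, 1.0)


def detect_modules(tom_matrix: np.ndarray, gene_ids=None,
                   cut_height: float = 0.995,
                   min_module_size: int = 30) -> pd.Series:
    """Assign genes to modules by static-cut average-linkage clustering.

    The dendrogram is built on the TOM dissimilarity 1 - omega and cut at
    ``cut_height`` times the maximum merge height; clusters smaller than
    ``min_module_size`` are labelled 0 (unassigned).  Labels are contiguous
    positive integers ordered by decreasing module size, so label 1 is the
    largest (``blue``) module.
    """
    n = tom_matrix.shape[0]
    if gene_ids is None:
        gene_ids = [f"G{i}" for i in range(n)]
    d = 1.0 - np.asarray(tom_matrix, dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = linkage(squareform(d, checks=False), method="average")
    max_h = z[:, 2].max() if len(z) else 0.0
    if max_h <= 0:
        return pd.Series(0, index=gene_ids)
    raw = fcluster(z, t=cut_height * max_h, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size].index
    # order surviving clusters by size, largest first
    for new, old in enumerate(sorted(keep, key=lambda c: -sizes[c]), start=1):
        labels[raw == old] = new
    return pd.Series(labels, index=gene_ids)


def module_eigengene(bundle: ExpressionBundle,
                     modules: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardized submatrix.

    The eigengene sign is oriented so its mean correlation with member genes
    is positive.  Returns a module x sample data frame indexed by module
    label.
    """
    x = bundle.matrix
    eigengenes = {}
    for label in sorted(set(modules) - {0}):
        members = modules.index[modules == label]
        sub = x.loc[members].to_numpy(dtype=float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        zs = (sub - mu) / sd
        u, s, vt = np.linalg.svd(zs, full_matrices=False)
        eg = vt[0]
        if np.mean([np.corrcoef(eg, row)[0, 1] for row in zs]) < 0:
            eg = -eg
        eigengenes[label] = eg
    return pd.DataFrame(eigengenes, index=x.columns).T


def module_trait_cor(eigengenes: pd.DataFrame,
                     traits: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of each eigengene with each numeric trait.

    Returns a long-form table (module, trait, r, p) suitable for a
    module-trait heatmap.
    """
    rows = []
    for label, eg in eigengenes.iterrows():
        for trait in traits.columns:
            vals = traits[trait].to_numpy(dtype=float)
            mask = np.isfinite(vals)
            r, p = stats.spearmanr(eg.to_numpy()[mask], vals[mask])
            rows.append({"module": label, "trait": trait,
                         "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def module_preservation(ref_bundle: ExpressionBundle,
                        test_bundle: ExpressionBundle,
                        modules: pd.Series, n_perm: int = 200,
                        seed: int = 0, beta: int = DEFAULT_POWER) -> pd.DataFrame:
    """Permutation Zsummary preservation of modules in an independent dataset.

    For each module, the observed test-set density (mean within-module
    adjacency) and connectivity preservation (correlation of intramodular
    connectivities between reference and test) are compared with a null of
    random same-size gene sets; zsummary is the mean of the two Z-scores.
    A Zsummary above 10 reads as strong preservation, 2-10 as moderate.
    """
    if n_perm < 10:
        logger.warning("n_perm=%d gives an unstable permutation sd; "
                       "interpret Z-scores with caution", n_perm)
    missing = set(modules.index) - set(test_bundle.matrix.index)
    if missing & set(modules.index[modules != 0]):
        raise ValueError(
            f"module genes absent from test data: {sorted(missing)[:5]}")
    common = [g for g in modules.index if g in set(test_bundle.matrix.index)]
    a_ref = adjacency(
        ExpressionBundle(matrix=ref_bundle.matrix.loc[common],
                         samples=ref_bundle.samples), beta)
    a_test = adjacency(
        ExpressionBundle(matrix=test_bundle.matrix.loc[common],
                         samples=test_bundle.samples), beta)
    pos = {g: i for i, g in enumerate(common)}
    rng = np.random.default_rng(seed)
    n = len(common)

    def density_conn(idx: np.ndarray) -> tuple[float, float]:
        sub_t = a_test[np.ix_(idx, idx)]
        sub_r = a_ref[np.ix_(idx, idx)]
        m = len(idx)
        off = ~np.eye(m, dtype=bool)
        density = float(sub_t[off].mean())
        k_r = sub_r.sum(axis=1) - 1.0
        k_t = sub_t.sum(axis=1) - 1.0
        if np.std(k_r) == 0 or np.std(k_t) == 0:
            conn = 0.0
        else:
            conn = float(np.corrcoef(k_r, k_t)[0, 1])
        return density, conn

    rows = []
    for label in sorted(set(modules) - {0}):
        members = [g for g in modules.index[modules == label] if g in pos]
        idx = np.array([pos[g] for g in members])
        obs_d, obs_c = density_conn(idx)
        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        for s in range(n_perm):
            perm = rng.choice(n, size=len(idx), replace=False)
            null_d[s], null_c[s] = density_conn(perm)
        z_d = (obs_d - null_d.mean()) / max(null_d.std(ddof=1), 1e-12)
        z_c = (obs_c - null_c.mean()) / max(null_c.std(ddof=1), 1e-12)
        rows.append({"module": label, "size": len(idx),
                     "z_density": float(z_d), "z_connectivity": float(z_c),
                     "zsummary": float((z_d + z_c) / 2.0),
                     "n_permutations": n_perm})
    return pd.DataFrame(rows)
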