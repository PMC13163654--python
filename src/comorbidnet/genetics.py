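"""Genetic correlation, Mendelian randomization and Bayesian colocalization.

Implements the genetic stage of the comorbidity analysis: cross-trait
LD-score regression (no sample-overlap intercept), two-sample MR with
inverse-variance weighting, weighted median and Egger regression, Cochran's
Q heterogeneity, an MR-PRESSO-style global/outlier residual test,
leave-one-out sensitivity, and single-causal-variant colocalization via
Wakefield approximate Bayes factors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "InstrumentSet",
    "MrResult",
    "RgResult",
    "ColocResult",
    "instruments_from_summaries",
    "ldsc_rg",
    "mr_fit",
    "heterogeneity_q",
    "mr_presso",
    "leave_one_out",
    "coloc_abf",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InstrumentSet:
    """Per-SNP exposure/outcome effect estimates for two-sample MR."""

    bx: np.ndarray
    se_bx: np.ndarray
    by: np.ndarray
    se_by: np.ndarray

    def __post_init__(self):
        for name in ("bx", "se_bx", "by", "se_by"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        n = len(self.bx)
        if not all(len(getattr(self, f)) == n for f in ("se_bx", "by", "se_by")):
            raise ValueError("instrument arrays must share a length")
        if n < 2:
            raise ValueError("at least 2 instruments required")
        if (self.se_bx <= 0).any() or (self.se_by <= 0).any():
            raise ValueError("standard errors must be positive")

    def __len__(self) -> int:
        return len(self.bx)

    @property
    def wald_ratios(self) -> np.ndarray:
        return self.by / self.bx


def instruments_from_summaries(exposure: pd.DataFrame,
                               outcome: pd.DataFrame) -> InstrumentSet:
    """Join exposure and outcome summary tables on snp id."""
    merged = exposure.merge(outcome, on="snp", suffixes=("_x", "_y"))
    if len(merged) < len(exposure):
        missing = set(exposure["snp"]) - set(outcome["snp"])
        logger.warning("dropping %d instruments absent from outcome: %s",
                       len(missing), sorted(missing)[:5])
    return InstrumentSet(bx=merged["beta_x"].to_numpy(),
                         se_bx=merged["se_x"].to_numpy(),
                         by=merged["beta_y"].to_numpy(),
                         se_by=merged["se_y"].to_numpy())


@dataclass(frozen=True)
class MrResult:
    method: str
    estimate: float            # log odds ratio
    se: float
    ci_low: float              # odds-ratio scale
    ci_high: float
    p: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.estimate)


@dataclass(frozen=True)
class RgResult:
    rg: float
    se: float
    p: float
    h2_trait1: float
    h2_trait2: float
    flagged: bool = False
    note: str = ""


@dataclass(frozen=True)
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    p1: float
    p2: float
    p12: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


# ---------------------------------------------------------------------------
# LD-score regression
# ---------------------------------------------------------------------------


def _ldsc_slopes(y: np.ndarray, l: np.ndarray) -> float:
    """OLS slope of y on l with intercept."""
    lc = l - l.mean()
    return float(lc @ (y - y.mean()) / (lc @ lc))


def ldsc_rg(sum1: pd.DataFrame, sum2: pd.DataFrame,
            n_blocks: int = 200) -> RgResult:
    """Cross-trait LD-score regression without a sample-overlap intercept.

    Univariate regressions of z^2 on the LD score estimate each trait's
    heritability (h2 = slope * M / N); the cross-trait regression of z1*z2
    estimates rg = slope * M / (sqrt(N1 N2) * sqrt(h2_1 h2_2)).  The rg
    standard error comes from a delete-one block jackknife over contiguous
    SNP blocks.
    """
    merged = sum1.merge(sum2, on="snp", suffixes=("_1", "_2"))
    if len(merged) == 0:
        raise ValueError("no shared snp ids between the two summary tables")
    m = len(merged)
    if m < n_blocks:
        logger.warning("only %d SNPs; reducing jackknife blocks from %d",
                       m, n_blocks)
        n_blocks = max(2, m // 2)
    l = merged["ldscore_1"].to_numpy(dtype=float)
    z1 = (merged["beta_1"] / merged["se_1"]).to_numpy()
    z2 = (merged["beta_2"] / merged["se_2"]).to_numpy()
    n1 = float(merged["n_1"].median())
    n2 = float(merged["n_2"].median())

    def estimate(idx: np.ndarray) -> tuple[float, float, float]:
        h2_1 = _ldsc_slopes(z1[idx] ** 2, l[idx]) * m / n1
        h2_2 = _ldsc_slopes(z2[idx] ** 2, l[idx]) * m / n2
        slope_x = _ldsc_slopes(z1[idx] * z2[idx], l[idx])
        if h2_1 <= 0 or h2_2 <= 0:
            return math.nan, h2_1, h2_2
        rg = slope_x * m / (math.sqrt(n1 * n2) * math.sqrt(h2_1 * h2_2))
        return rg, h2_1, h2_2

    all_idx = np.arange(m)
    rg_full, h2_1, h2_2 = estimate(all_idx)
    if math.isnan(rg_full):
        return RgResult(rg=math.nan, se=math.nan, p=math.nan,
                        h2_trait1=h2_1, h2_trait2=h2_2, flagged=True,
                        note="non-positive heritability estimate; rg undefined")
    blocks = np.array_split(all_idx, n_blocks)
    deleted = []
    for b in blocks:
        keep = np.setdiff1d(all_idx, b, assume_unique=True)
        deleted.append(estimate(keep)[0])
    deleted = np.array(deleted)
    nb = len(deleted)
    pseudo = nb * rg_full - (nb - 1) * deleted
    se = float(np.sqrt(np.var(pseudo, ddof=1) / nb))
    p = 2.0 * stats.norm.sf(abs(rg_full) / se) if se > 0 else math.nan
    flagged = not (-1.0 <= rg_full <= 1.0)
    rg_rep = float(np.clip(rg_full, -1.25, 1.25))
    return RgResult(rg=rg_rep, se=se, p=p, h2_trait1=h2_1, h2_trait2=h2_2,
                    flagged=flagged,
                    note="rg outside [-1, 1]" if flagged else "")


# ---------------------------------------------------------------------------
# Mendelian randomization estimators
# ---------------------------------------------------------------------------


def _ivw_closed_form(inst: InstrumentSet) -> tuple[float, float]:
    """Weighted least squares of by on bx through the origin (weights 1/se_by^2)."""
    w = 1.0 / inst.se_by ** 2
    denom = np.sum(w * inst.bx ** 2)
    est = float(np.sum(w * inst.bx * inst.by) / denom)
    se = float(1.0 / math.sqrt(denom))
    return est, se


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w        # Bowden's centred cumulative weights
    below = np.where(cum < 0.5)[0]
    if len(below) == 0:
        return float(r[0])
    j = below[-1]
    if j == len(r) - 1:
        return float(r[-1])
    return float(r[j] + (r[j + 1] - r[j]) * (0.5 - cum[j]) / (cum[j + 1] - cum[j]))


def mr_fit(instruments: InstrumentSet, method: str = "ivw",
           n_boot: int = 1000, seed: int = 0) -> MrResult:
    """Fit a two-sample MR estimator.

    ``ivw`` is the primary analysis (weighted regression through the
    origin); ``weighted_median`` is Bowden's weighted median of Wald ratios
    with a seeded parametric-bootstrap SE; ``egger`` adds a free intercept
    whose p-value is the horizontal-pleiotropy read-out.
    """
    n = len(instruments)
    if method == "ivw":
        if n < 2:
            raise ValueError("ivw requires at least 2 instruments")
        est, se = _ivw_closed_form(instruments)
        intercept = intercept_se = intercept_p = None
    elif method == "weighted_median":
        if n < 3:
            raise ValueError("weighted_median requires at least 3 instruments")
        ratios = instruments.wald_ratios
        w = instruments.bx ** 2 / instruments.se_by ** 2   # inverse ratio variance
        est = _weighted_median(ratios, w)
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bx = instruments.bx + rng.normal(0, instruments.se_bx)
            by = instruments.by + rng.normal(0, instruments.se_by)
            boots[b] = _weighted_median(by / bx, bx ** 2 / instruments.se_by ** 2)
        se = float(np.std(boots, ddof=1))
        intercept = intercept_se = intercept_p = None
    elif method == "egger":
        if n < 3:
            raise ValueError("egger requires at least 3 instruments")
        w = 1.0 / instruments.se_by ** 2
        X = np.column_stack([np.ones(n), instruments.bx])
        WX = X * w[:, None]
        xtwx = X.T @ WX
        beta = np.linalg.solve(xtwx, WX.T @ instruments.by)
        resid = instruments.by - X @ beta
        dof = n - 2
        sigma2 = max(1.0, float(resid @ (w * resid) / dof))  # multiplicative
        cov = np.linalg.inv(xtwx) * sigma2
        est, se = float(beta[1]), float(math.sqrt(cov[1, 1]))
        intercept, intercept_se = float(beta[0]), float(math.sqrt(cov[0, 0]))
        tstat = intercept / intercept_se if intercept_se > 0 else math.inf
        intercept_p = float(2.0 * stats.t.sf(abs(tstat), dof))
    else:
        raise ValueError(f"unknown MR method: {method!r}")
    p = float(2.0 * stats.norm.sf(abs(est) / se)) if se > 0 else 0.0
    return MrResult(method=method, estimate=est, se=se,
                    ci_low=math.exp(est - 1.96 * se),
                    ci_high=math.exp(est + 1.96 * se), p=p,
                    intercept=intercept, intercept_se=intercept_se,
                    intercept_p=intercept_p)


def heterogeneity_q(instruments: InstrumentSet) -> dict:
    """Cochran's Q over per-instrument Wald ratios with IVW ratio weights."""
    if len(instruments) < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    ratios = instruments.wald_ratios
    w = instruments.bx ** 2 / instruments.se_by ** 2
    theta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - theta) ** 2))
    df = len(instruments) - 1
    return {"Q": q, "df": df, "p": float(stats.chi2.sf(q, df))}


def _loo_ivw_estimates(inst: InstrumentSet) -> np.ndarray:
    """Vector of IVW estimates each excluding one instrument."""
    w = 1.0 / inst.se_by ** 2
    sxy = np.sum(w * inst.bx * inst.by)
    sxx = np.sum(w * inst.bx ** 2)
    return (sxy - w * inst.bx * inst.by) / (sxx - w * inst.bx ** 2)


def mr_presso(instruments: InstrumentSet, n_sim: int = 1000,
              seed: int = 0) -> dict:
    """Residual-sum-of-squares global pleiotropy test with outlier flags.

    The observed RSS of outcome effects around leave-one-out IVW predictions
    is compared with ``n_sim`` parametric simulations under the no-pleiotropy
    model; per-SNP squared residuals give outlier p-values, flagged after
    Bonferroni correction.
    """
    n = len(instruments)
    if n < 4:
        raise ValueError("mr_presso requires at least 4 instruments")
    if n_sim < 1:
        raise ValueError("n_sim must be positive")
    rng = np.random.default_rng(seed)
    theta_loo = _loo_ivw_estimates(instruments)
    resid_obs = (instruments.by - theta_loo * instruments.bx) ** 2
    rss_obs = float(resid_obs.sum())

    sim_rss = np.empty(n_sim)
    exceed = np.zeros(n)
    for s in range(n_sim):
        by_sim = theta_loo * instruments.bx + rng.normal(0, instruments.se_by)
        sim = InstrumentSet(bx=instruments.bx, se_bx=instruments.se_bx,
                            by=by_sim, se_by=instruments.se_by)
        r2 = (by_sim - _loo_ivw_estimates(sim) * instruments.bx) ** 2
        sim_rss[s] = r2.sum()
        exceed += r2 >= resid_obs
    global_p = float((1 + np.sum(sim_rss >= rss_obs)) / (1 + n_sim))
    snp_p = (1 + exceed) / (1 + n_sim)
    flags = snp_p * n < 0.05
    return {"global_p": global_p, "rss_obs": rss_obs,
            "outlier_p": snp_p, "outlier_flags": flags}


def leave_one_out(instruments: InstrumentSet) -> pd.DataFrame:
    """IVW estimate excluding each instrument in turn.

    The ``inside_full_ci`` column records whether each leave-one-out odds
    ratio lies inside the full-set 95% confidence interval.
    """
    full = mr_fit(instruments, method="ivw")
    estimates = _loo_ivw_estimates(instruments)
    ors = np.exp(estimates)
    return pd.DataFrame({
        "excluded_index": np.arange(len(instruments)),
        "estimate": estimates,
        "odds_ratio": ors,
        "inside_full_ci": (ors >= full.ci_low) & (ors <= full.ci_high),
    })


# ---------------------------------------------------------------------------
# Bayesian colocalization
# ---------------------------------------------------------------------------


def _log_abf(beta: np.ndarray, se: np.ndarray, w: float) -> np.ndarray:
    """Per-SNP log Wakefield approximate Bayes factor, prior variance w."""
    v = se ** 2
    z2 = (beta / se) ** 2
    r = w / (v + w)
    return 0.5 * (np.log(1 - r) + z2 * r)


def coloc_abf(region1: pd.DataFrame, region2: pd.DataFrame,
              p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5,
              prior_sd: float = 0.15) -> ColocResult:
    """Single-shared-causal-variant colocalization on two regional tables.

    Uses log-space accumulation of Wakefield ABFs under the five standard
    hypotheses (no association; trait-1 only; trait-2 only; two distinct
    causal variants; one shared causal variant).
    """
    s1, s2 = set(region1["snp"]), set(region2["snp"])
    if s1 != s2:
        diff = sorted(s1.symmetric_difference(s2))
        raise ValueError(f"regions disagree on SNPs: {diff[:10]}")
    merged = region1.merge(region2, on="snp", suffixes=("_1", "_2"))
    w = prior_sd ** 2
    labf1 = _log_abf(merged["beta_1"].to_numpy(), merged["se_1"].to_numpy(), w)
    labf2 = _log_abf(merged["beta_2"].to_numpy(), merged["se_2"].to_numpy(), w)

    lsum1 = logsumexp(labf1)
    lsum2 = logsumexp(labf2)
    lsum12 = logsumexp(labf1 + labf2)          # shared causal variant
    # sum over i != j of ABF1_i * ABF2_j
    both = lsum1 + lsum2
    frac = min(1.0, math.exp(min(0.0, lsum12 - both)))
    lsum3 = (both + math.log1p(-frac)) if frac < 1.0 else -math.inf

    lh = np.array([
        0.0,
        math.log(p1) + lsum1,
        math.log(p2) + lsum2,
        math.log(p1) + math.log(p2) + lsum3,
        math.log(p12) + lsum12,
    ])
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(*pp, p1=p1, p2=p2, p12=p12)
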