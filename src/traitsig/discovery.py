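"""Quantitative-trait gene discovery: permutation-FDR SAM statistic,
empirical-Bayes moderated regression, per-gene Pearson correlation, and the
FDR-bounded intersection of the two procedures.

Both procedures regress each gene's log expression on a continuous clinical
covariate (percent weight loss by default).  The SAM arm scores genes with
d = slope / (se + s0) and estimates FDR from a seeded covariate-permutation
null; the moderated arm shrinks residual variances toward a common prior and
applies Benjamini-Hochberg to the moderated-t p-values.  Genes called by both
arms below the FDR bound with agreeing direction form the signature.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from .study import ExpressionStudy

logger = logging.getLogger(__name__)

#: sample count at or below which covariate permutations are enumerated
EXHAUSTIVE_MAX_N = 7


# -- shared least-squares core -------------------------------------------

def _regression_stats(values: np.ndarray, y: np.ndarray):
    """Per-gene simple regression of expression on the centered covariate.

    Returns (slope, slope_se, resid_var, syy, df_resid).  ``slope_se`` uses
    the per-gene residual variance with n - 2 degrees of freedom.
    """
    n = y.size
    yc = y - y.mean()
    syy = float(yc @ yc)
    if syy == 0:
        raise ValueError("covariate is constant across samples")
    slope = values @ yc / syy
    centered = values - values.mean(axis=1, keepdims=True)
    ssx = (centered**2).sum(axis=1)
    sse = np.maximum(ssx - slope**2 * syy, 0.0)
    df = n - 2
    resid_var = sse / df
    slope_se = np.sqrt(resid_var / syy)
    return slope, slope_se, resid_var, syy, df


# -- SAM quantitative ----------------------------------------------------

def _choose_s0(slope: np.ndarray, se: np.ndarray) -> float:
    """SAM's fudge-factor selection: the percentile of the standard errors
    minimising the coefficient of variation of MAD(d) across se windows."""
    if se.size < 10 or np.ptp(se) == 0:
        return float(np.percentile(se, 5))
    n_bins = int(min(100, max(2, se.size // 10)))
    ranks = stats.rankdata(se, method="ordinal") - 1
    groups = np.minimum((ranks * n_bins) // se.size, n_bins - 1).astype(int)
    best_alpha, best_cv = 0.05, np.inf
    for alpha in np.arange(0.0, 1.0001, 0.05):
        w = float(np.quantile(se, alpha))
        d_alpha = slope / (se + w)
        mads = np.array(
            [
                stats.median_abs_deviation(d_alpha[groups == g], scale="normal")
                for g in range(n_bins)
                if (groups == g).any()
            ]
        )
        mean_mad = mads.mean()
        if mean_mad <= 0:
            continue
        cv = mads.std(ddof=0) / mean_mad
        if cv < best_cv:
            best_cv, best_alpha = cv, float(alpha)
    return float(np.quantile(se, best_alpha))


def _permutation_matrix(y: np.ndarray, n_permutations: int, seed: int):
    """Columns of permuted covariates; exhaustive for small sample counts."""
    n = y.size
    if n <= EXHAUSTIVE_MAX_N:
        perms = np.array(list(itertools.permutations(range(n))))
        return y[perms.T], True
    rng = np.random.default_rng(seed)
    cols = np.empty((n, n_permutations))
    for j in range(n_permutations):
        cols[:, j] = y[rng.permutation(n)]
    return cols, False


def sam_quantitative(
    study: ExpressionStudy,
    covariate_name: str = "weight_loss_pct",
    n_permutations: int = 200,
    s0_mode: str = "auto",
    s0_value: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Quantitative-response SAM: d = slope / (se + s0) with permutation FDR.

    The permutation null permutes the covariate across samples (all n!
    arrangements when n <= 7, else ``n_permutations`` seeded draws).  The
    estimated FDR at a cutoff c is ``pi0 * mean permuted count of |d| >= c /
    observed count``; each gene reports the smallest FDR at which it is
    called, which is non-increasing in |d| by construction.

    Returns a DataFrame indexed by gene with columns ``slope``, ``slope_se``,
    ``d_stat`` and ``sam_fdr``; ``s0``, ``pi0`` and the permutation count are
    stored in ``.attrs``.
    """
    y = study.covariate(covariate_name)
    n = y.size
    if n < 3:
        raise ValueError("sam_quantitative requires >= 3 samples")
    if np.ptp(y) == 0:
        raise ValueError("covariate is constant across samples")
    if n_permutations < 25:
        logger.warning(
            "n_permutations=%d is low; FDR estimates will be coarse", n_permutations
        )
    values = study.values
    m = values.shape[0]
    slope, se, _, syy, df = _regression_stats(values, y)

    if s0_mode == "auto":
        s0 = _choose_s0(slope, se)
    elif s0_mode == "percentile":
        s0 = float(np.percentile(se, 5))
    elif s0_mode == "fixed":
        if s0_value is None:
            raise ValueError("s0_mode='fixed' requires s0_value")
        s0 = float(s0_value)
    else:
        raise ValueError(f"unknown s0_mode {s0_mode!r}")
    if s0 < 0:
        raise ValueError("s0 must be non-negative")

    d = slope / (se + s0)

    perm_cols, exhaustive = _permutation_matrix(y, n_permutations, seed)
    perm_centered = perm_cols - perm_cols.mean(axis=0, keepdims=True)
    slopes_p = values @ perm_centered / syy
    centered = values - values.mean(axis=1, keepdims=True)
    ssx = (centered**2).sum(axis=1)
    sse_p = np.maximum(ssx[:, None] - slopes_p**2 * syy, 0.0)
    se_p = np.sqrt(sse_p / (df * syy)) if df > 0 else np.zeros_like(sse_p)
    d_p = slopes_p / (se_p + s0)
    n_perm = d_p.shape[1]

    # pi0 from the fraction of observed d inside the permuted interquartile range
    q25, q75 = np.percentile(d_p, [25, 75])
    pi0 = min(1.0, ((d > q25) & (d < q75)).sum() / (0.5 * m))

    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    absd_sorted = absd[order]
    # observed and mean-permuted counts of |d| >= each cutoff (ties included)
    obs_count = m - np.searchsorted(absd_sorted, absd_sorted, side="left")
    perm_sorted = np.sort(np.abs(d_p).ravel())
    # count permuted |d| >= cutoff with a relative tie tolerance so the
    # observed arrangement's own d (recomputed through a different BLAS path)
    # is always counted as an exceedance of itself
    cutoffs = absd_sorted * (1 - 1e-9) - 1e-12
    perm_exceed = perm_sorted.size - np.searchsorted(perm_sorted, cutoffs, side="left")
    mean_count = perm_exceed / n_perm
    fdr_sorted = np.minimum(pi0 * mean_count / obs_count, 1.0)
    q_sorted = np.minimum.accumulate(fdr_sorted)
    sam_fdr = np.empty(m)
    sam_fdr[order] = q_sorted

    out = pd.DataFrame(
        {"slope": slope, "slope_se": se, "d_stat": d, "sam_fdr": sam_fdr},
        index=pd.Index(study.gene_ids, name="gene_id"),
    )
    out.attrs.update(
        s0=s0, pi0=pi0, n_permutations=n_perm, exhaustive=exhaustive, seed=seed
    )
    return out


# -- empirical-Bayes moderated regression --------------------------------

def _trigamma_inverse(target: float) -> float:
    if target <= 0:
        return math.inf
    lo, hi = 1e-8, 1e8
    f = lambda x: special.polygamma(1, x) - target
    if f(lo) < 0:  # target above trigamma(1e-8): unreachable in practice
        return 2e-8
    if f(hi) > 0:
        return math.inf
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def _fit_variance_prior(resid_var: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior
    on log residual variances; returns (prior df d0, prior scale s0^2)."""
    positive = resid_var[resid_var > 0]
    if positive.size < 2:
        return math.inf, float(resid_var.mean() if resid_var.size else 1.0)
    z = np.log(positive)
    evar = float(np.var(z, ddof=1)) - float(special.polygamma(1, df / 2))
    mean_adj = float(z.mean()) - float(special.digamma(df / 2)) + math.log(df / 2)
    if evar <= 0:
        return math.inf, float(math.exp(mean_adj))
    half_d0 = _trigamma_inverse(evar)
    if math.isinf(half_d0):
        return math.inf, float(math.exp(mean_adj))
    d0 = 2 * half_d0
    log_s0sq = mean_adj + float(special.digamma(half_d0)) - math.log(half_d0)
    return d0, float(math.exp(log_s0sq))


def moderated_covariate_test(
    study: ExpressionStudy,
    covariate_name: str = "weight_loss_pct",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-gene regression with empirical-Bayes variance shrinkage.

    Residual variances are shrunk toward a common prior: posterior variance
    = (d0 s0^2 + df s^2) / (d0 + df) with (d0, s0^2) estimated by the method
    of moments on log residual variances.  The moderated t uses d0 + df
    degrees of freedom; FDR is Benjamini-Hochberg over two-sided p-values.
    ``prior_df`` overrides the estimated d0 (``0`` disables shrinkage and
    recovers the ordinary regression t).
    """
    y = study.covariate(covariate_name)
    n = y.size
    if np.ptp(y) == 0:
        raise ValueError("covariate is constant across samples")
    if n - 2 < 1:
        raise ValueError("need at least 1 residual degree of freedom (n >= 3)")
    slope, _, resid_var, syy, df = _regression_stats(study.values, y)

    if prior_df is None:
        d0, s0sq = _fit_variance_prior(resid_var, df)
    elif prior_df == 0:
        d0, s0sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0sq = _fit_variance_prior(resid_var, df)
    if math.isinf(d0):
        post_var = np.full_like(resid_var, s0sq)
        df_total = math.inf
    else:
        post_var = (d0 * s0sq + df * resid_var) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        mod_se = np.sqrt(post_var / syy)
        t = np.where(mod_se > 0, slope / np.where(mod_se > 0, mod_se, 1.0), 0.0)
    if math.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    fdr = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "slope": slope,
            "slope_se": mod_se,
            "mod_t": t,
            "mod_p": p,
            "mod_fdr": fdr,
        },
        index=pd.Index(study.gene_ids, name="gene_id"),
    )
    out.attrs.update(prior_df=d0, prior_var=s0sq, df_resid=df)
    return out


# -- Pearson correlation per gene ----------------------------------------

def pearson_per_gene(
    study: ExpressionStudy, covariate_name: str = "weight_loss_pct"
) -> pd.DataFrame:
    """Product-moment correlation of each gene with the covariate; two-sided
    p from the t transform with n - 2 df.  Zero-variance genes report NaN."""
    y = study.covariate(covariate_name)
    n = y.size
    if n < 3:
        raise ValueError("pearson_per_gene requires >= 3 samples")
    yc = y - y.mean()
    syy = float(yc @ yc)
    if syy == 0:
        raise ValueError("covariate is constant across samples")
    centered = study.values - study.values.mean(axis=1, keepdims=True)
    ssx = (centered**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = centered @ yc / np.sqrt(ssx * syy)
    r = np.clip(r, -1.0, 1.0)
    flat = ssx == 0
    if flat.any():
        logger.warning(
            "pearson_per_gene: %d zero-variance gene(s) reported as missing",
            int(flat.sum()),
        )
        r[flat] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return pd.DataFrame(
        {"pearson_r": r, "pearson_p": p},
        index=pd.Index(study.gene_ids, name="gene_id"),
    )


# -- intersection --------------------------------------------------------

@dataclass
class SignatureSet:
    """Direction-annotated genes called by both procedures at the FDR bound."""

    genes: list[str]
    directions: dict[str, str]
    fdr_bound: float

    def __post_init__(self) -> None:
        if set(self.genes) != set(self.directions):
            raise ValueError("directions must cover exactly the signature genes")
        bad = set(self.directions.values()) - {"positive", "negative"}
        if bad:
            raise ValueError(f"invalid directions: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.genes)

    def genes_in_direction(self, direction: str) -> list[str]:
        return [g for g in self.genes if self.directions[g] == direction]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.genes,
                "direction": [self.directions[g] for g in self.genes],
                "fdr_bound": self.fdr_bound,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SignatureSet":
        df = pd.read_csv(path, sep="\t")
        return cls(
            genes=list(df["gene_id"].astype(str)),
            directions=dict(zip(df["gene_id"].astype(str), df["direction"])),
            fdr_bound=float(df["fdr_bound"].iloc[0]) if len(df) else float("nan"),
        )


def intersect_signature(
    sam: pd.DataFrame, moderated: pd.DataFrame, fdr_bound: float = 0.10
) -> SignatureSet:
    """Genes below the FDR bound in both procedures with agreeing sign."""
    if not 0 <= fdr_bound <= 1:
        raise ValueError(f"fdr_bound must be in [0, 1], got {fdr_bound}")
    if set(sam.index) != set(moderated.index):
        raise ValueError("SAM and moderated tables cover different gene universes")
    moderated = moderated.reindex(sam.index)
    sign_agree = np.sign(sam["d_stat"]) * np.sign(moderated["mod_t"]) > 0
    called = (
        (sam["sam_fdr"] < fdr_bound) & (moderated["mod_fdr"] < fdr_bound) & sign_agree
    )
    genes = [str(g) for g in sam.index[called]]
    directions = {
        g: "positive" if sam.loc[g, "d_stat"] > 0 else "negative" for g in genes
    }
    return SignatureSet(genes=genes, directions=directions, fdr_bound=fdr_bound)


def gene_stat_table(
    sam: pd.DataFrame, moderated: pd.DataFrame, pearson: pd.DataFrame
) -> pd.DataFrame:
    """Join the three per-gene tables into one stats table (shared index)."""
    joined = sam.join(moderated[["mod_t", "mod_p", "mod_fdr"]]).join(pearson)
    joined.attrs.update(sam.attrs)
    return joined
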