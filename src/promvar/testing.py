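"""Per-variant differential allelic activity tests, FDR and pi1.

Each variant is tested by comparing the expression of the oligo carrying its
RM allele to the matched BY oligo across replicates, with a paired t-test on
per-replicate activity differences.  With moderation on (default), the
per-variant variance is shrunk toward a global prior estimated across all
variants by fitting a scaled inverse-chi-square distribution to the sample
variances (method of moments on log variances, limma-style), and the t-test
gains the prior degrees of freedom.  Positive log2 fold-change means the RM
allele drives higher expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats, optimize
from statsmodels.stats.multitest import multipletests


@dataclass
class ModerationPrior:
    df_prior: float  # may be inf when variances are homogeneous
    var_prior: float


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton, as in limma's fitFDist)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def estimate_moderation_prior(variances: np.ndarray, df: int) -> ModerationPrior:
    """Fit the scaled-F prior for empirical-Bayes variance shrinkage.

    ``variances`` are per-variant sample variances on ``df`` degrees of
    freedom.  Uses moments of log(s^2): the excess spread beyond what a
    chi-square with ``df`` explains determines the prior df.
    """
    s2 = np.asarray(variances, dtype=float)
    s2 = s2[np.isfinite(s2)]
    positive = s2[s2 > 0]
    if len(positive) < 2:
        return ModerationPrior(df_prior=np.inf, var_prior=float(np.mean(s2) if len(s2) else 1.0))
    z = np.log(positive)
    e_z = z.mean()
    var_z = z.var(ddof=1)
    resid = var_z - special.polygamma(1, df / 2.0)
    if resid <= 0:
        # no excess variability: variances look exchangeable, infinite prior df
        return ModerationPrior(
            df_prior=np.inf,
            var_prior=float(np.exp(e_z - special.digamma(df / 2.0) + np.log(df / 2.0))),
        )
    d0 = 2.0 * _trigamma_inverse(resid)
    log_s0 = (
        e_z
        - special.digamma(df / 2.0)
        + np.log(df / 2.0)
        + special.digamma(d0 / 2.0)
        - np.log(d0 / 2.0)
    )
    return ModerationPrior(df_prior=float(d0), var_prior=float(np.exp(log_s0)))


def paired_allelic_test(
    diffs: np.ndarray, moderation: bool = True
) -> pd.DataFrame:
    """Test each row of per-replicate activity differences (RM - BY).

    Returns a DataFrame with logFC, t, df, p per row.  With moderation, the
    variance used is ``(d0*s0^2 + df*s^2) / (d0 + df)`` and the t reference
    distribution has ``df + d0`` degrees of freedom.
    """
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    n = diffs.shape[1]
    if n < 2:
        raise ValueError("need at least 2 replicates for a paired test")
    df = n - 1
    mean = diffs.mean(axis=1)
    s2 = diffs.var(axis=1, ddof=1)

    if moderation:
        prior = estimate_moderation_prior(s2, df)
        if np.isinf(prior.df_prior):
            s2_post = np.full_like(s2, prior.var_prior)
            df_total = np.inf
        else:
            s2_post = (prior.df_prior * prior.var_prior + df * s2) / (
                prior.df_prior + df
            )
            df_total = df + prior.df_prior
    else:
        s2_post = s2
        df_total = df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(s2_post / n)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # degenerate rows: zero variance
    zero_var = s2_post == 0
    p = np.where(zero_var & (mean == 0), 1.0, p)
    p = np.where(zero_var & (mean != 0), np.finfo(float).tiny, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {"logFC": mean, "t": t, "df": df_total, "p": p}
    )


def test_variants(
    activity: pd.DataFrame,
    comparisons: pd.DataFrame,
    moderation: bool = True,
) -> pd.DataFrame:
    """Run the allelic test for a table of BY/RM oligo comparisons.

    ``activity`` is oligo x replicate; ``comparisons`` needs columns
    variant, oligo_by, oligo_rm and optionally library, strand.  Comparisons
    whose oligos failed the expression filter are skipped.
    """
    cols = comparisons.columns
    keep = comparisons["oligo_by"].isin(activity.index) & comparisons[
        "oligo_rm"
    ].isin(activity.index)
    usable = comparisons.loc[keep].reset_index(drop=True)
    if usable.empty:
        return pd.DataFrame(
            columns=["variant", "library", "strand", "logFC", "t", "df", "p", "q"]
        )
    diffs = (
        activity.loc[usable["oligo_rm"]].to_numpy()
        - activity.loc[usable["oligo_by"]].to_numpy()
    )
    res = paired_allelic_test(diffs, moderation=moderation)
    out = pd.concat([usable, res], axis=1)
    out["q"] = adjust_fdr(out["p"].to_numpy())
    out["n_replicates"] = activity.shape[1]
    if "library" not in cols:
        out["library"] = "NA"
    if "strand" not in cols:
        out["strand"] = "+"
    return out


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to adjust")
    return multipletests(p, method="fdr_bh")[1]


def aggregate_across_contexts(
    results: pd.DataFrame,
    by: tuple[str, ...] = ("variant",),
) -> pd.DataFrame:
    """Keep the smallest-p record per variant (optionally per strand).

    When a variant was assayed in both libraries or multiple windows, the
    most significant record and its fold-change are carried forward.  Ties
    in p go to the larger absolute fold-change.
    """
    if results.empty:
        raise ValueError("no results to aggregate")
    ranked = results.assign(_absfc=results["logFC"].abs()).sort_values(
        ["p", "_absfc"], ascending=[True, False]
    )
    out = ranked.groupby(list(by), sort=False).head(1).drop(columns="_absfc")
    return out.reset_index(drop=True)


@dataclass
class Pi1Estimate:
    pi0: float
    lambdas: np.ndarray

    @property
    def pi1(self) -> float:
        return 1.0 - self.pi0


def estimate_pi1(
    pvalues, lambdas=0.5, smooth: bool = False
) -> Pi1Estimate:
    """Estimate pi1 = 1 - pi0 from the p-value distribution.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)).  Default is the fixed
    lambda = 0.5 estimator; with ``smooth`` and a lambda grid, a cubic
    smoother over pi0(lambda) is evaluated at the largest lambda
    (qvalue-package style extrapolation toward lambda -> 1).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    lam = np.atleast_1d(np.asarray(lambdas, dtype=float))
    if np.any((lam < 0) | (lam >= 1)):
        raise ValueError("lambda must lie in [0, 1)")
    pi0_lam = np.array(
        [(p > l).sum() / (p.size * (1.0 - l)) for l in lam]
    )
    if smooth and lam.size >= 4:
        coeffs = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = float(np.polyval(coeffs, lam.max()))
    else:
        pi0 = float(pi0_lam[-1] if lam.size > 1 else pi0_lam[0])
    pi0 = float(np.clip(pi0, 0.0, 1.0))
    return Pi1Estimate(pi0=pi0, lambdas=lam)


def classify_variants(
    results: pd.DataFrame, causal_q: float = 0.05, noncausal_p: float = 0.2
) -> pd.Series:
    """Label variants causal (q <= causal_q), non-causal (raw p >
    noncausal_p) or excluded (in between)."""
    labels = pd.Series("excluded", index=results.index, dtype=object)
    labels[results["q"] <= causal_q] = "causal"
    labels[(results["p"] > noncausal_p) & (results["q"] > causal_q)] = "non-causal"
    return labels
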