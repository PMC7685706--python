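"""Gene-level aggregation of variant effects and comparison to local eQTLs.

Variant log2 fold-changes (RM minus BY throughout) are summed per gene --
either over all assayed variants or only the significant ones -- or reduced
to the most (or second-most) significant variant, and compared with local
eQTL effect estimates by Spearman correlation, direction-of-effect Fisher
tests, and allele-specific-expression enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio


def aggregate_gene_effects(
    results: pd.DataFrame, causal_q: float = 0.05, nominal_p: float = 0.05
) -> pd.DataFrame:
    """Per-gene aggregates of variant results.

    ``results`` needs columns gene, variant, logFC, p, q.  Sums are over all
    variants and over significant (q <= causal_q) variants; top1/top2 are
    the most and second-most significant variant's logFC among significant
    variants (NaN when absent).
    """
    needed = {"gene", "logFC", "p", "q"}
    if not needed.issubset(results.columns):
        raise ValueError(f"results must have columns {sorted(needed)}")
    rows = []
    for gene, grp in results.groupby("gene"):
        sig = grp[grp["q"] <= causal_q].sort_values("p")
        rows.append(
            {
                "gene": gene,
                "sum_all": float(grp["logFC"].sum()),
                "sum_significant": float(sig["logFC"].sum()) if len(sig) else np.nan,
                "top1": float(sig["logFC"].iloc[0]) if len(sig) >= 1 else np.nan,
                "top2": float(sig["logFC"].iloc[1]) if len(sig) >= 2 else np.nan,
                "n_significant": int(len(sig)),
                "n_nominal": int((grp["p"] < nominal_p).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def spearman_ci(
    x, y, alpha: float = 0.05
) -> tuple[float, float, tuple[float, float]]:
    """Spearman rho with p and a Fisher-z confidence interval.

    The z variance uses the rank-based adjustment 1.06 / (n - 3); n must be
    at least 4 (5 recommended).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 paired observations")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    z = np.arctanh(np.clip(rho, -0.999999, 0.999999))
    se = np.sqrt(1.06 / (n - 3))
    crit = stats.norm.ppf(1 - alpha / 2)
    ci = (float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se)))
    return rho, float(res.pvalue), ci


def correlate_with_eqtl(
    gene_effects: pd.Series,
    eqtl: pd.DataFrame,
    lod_min: float = 0.0,
    strata: pd.Series | None = None,
) -> pd.DataFrame:
    """Correlate per-gene aggregated MPRA effects with local eQTL effects.

    ``eqtl`` needs columns gene, effect, lod.  Rows: overall plus one per
    stratum when ``strata`` (a gene-indexed label series, e.g. nucleosome
    state) is given.
    """
    table = eqtl.set_index("gene")
    table = table[table["lod"] >= lod_min]
    merged = pd.concat(
        [gene_effects.rename("mpra"), table["effect"].rename("eqtl")],
        axis=1, join="inner",
    ).dropna()
    if len(merged) < 5:
        raise ValueError("fewer than 5 genes after filtering")

    def _row(name: str, sub: pd.DataFrame) -> dict:
        rho, p, ci = spearman_ci(sub["mpra"], sub["eqtl"])
        return {"stratum": name, "n": len(sub), "rho": rho, "p": p,
                "ci_low": ci[0], "ci_high": ci[1]}

    rows = [_row("overall", merged)]
    if strata is not None:
        for level, genes in strata.groupby(strata):
            sub = merged.loc[merged.index.intersection(genes.index)]
            if len(sub) >= 5:
                rows.append(_row(str(level), sub))
    return pd.DataFrame(rows)


@dataclass
class FetReport:
    table: np.ndarray
    odds_ratio: float  # conditional MLE
    sample_odds_ratio: float
    p: float


def fisher_2x2(table) -> FetReport:
    """Two-sided Fisher's exact test with the conditional-MLE odds ratio."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if t.sum() == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a margin is zero")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    cmle = _odds_ratio(t, kind="conditional").statistic
    with np.errstate(divide="ignore", invalid="ignore"):
        sample = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]) if t[0, 1] * t[1, 0] else np.inf
    return FetReport(
        table=t, odds_ratio=float(cmle), sample_odds_ratio=float(sample), p=float(p)
    )


def directional_agreement(
    mpra_effects: pd.Series, eqtl_effects: pd.Series
) -> FetReport:
    """2x2 Fisher test of sign concordance between per-gene top-variant MPRA
    effects and local eQTL effects (zero effects are dropped)."""
    merged = pd.concat(
        [mpra_effects.rename("m"), eqtl_effects.rename("e")], axis=1, join="inner"
    ).dropna()
    merged = merged[(merged["m"] != 0) & (merged["e"] != 0)]
    if merged.empty:
        raise ValueError("no genes with both signs available")
    m_pos = merged["m"] > 0
    e_pos = merged["e"] > 0
    table = [
        [int((m_pos & e_pos).sum()), int((m_pos & ~e_pos).sum())],
        [int((~m_pos & e_pos).sum()), int((~m_pos & ~e_pos).sum())],
    ]
    return fisher_2x2(table)


def ase_enrichment(
    has_causal: pd.Series, ase_significant: pd.Series
) -> FetReport:
    """Fisher test of whether genes with significant allele-specific
    expression are more likely to carry a causal MPRA variant."""
    merged = pd.concat(
        [has_causal.rename("c").astype(bool), ase_significant.rename("a").astype(bool)],
        axis=1, join="inner",
    ).dropna()
    if merged.empty:
        raise ValueError("no genes shared between the two flag vectors")
    table = [
        [int((merged["a"] & merged["c"]).sum()), int((merged["a"] & ~merged["c"]).sum())],
        [int((~merged["a"] & merged["c"]).sum()), int((~merged["a"] & ~merged["c"]).sum())],
    ]
    return fisher_2x2(table)
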