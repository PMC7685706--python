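"""Non-additive interaction tests for variant pairs, and pairwise LD.

For a promoter with exactly two assayed variants, the TSS design contains
all four allele combinations (BY/BY, RM/BY, BY/RM, RM/RM).  The interaction
model is

    y = b0 + b1*x1 + b2*x2 + b3*x1*x2 + e

on per-replicate activities with allele indicators x1, x2 in {0, 1}; the
interaction p-value is the F-test of the full model against the model
without the b3 term (equivalently, the t-test on b3).

Linkage disequilibrium between two markers is computed from haploid (or
homozygous-diploid) genotypes over a panel of isolates, using the two most
frequent alleles at each marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats

from .testing import adjust_fdr

ALLELE_COMBOS = ("BY/BY", "RM/BY", "BY/RM", "RM/RM")


@dataclass
class PairDesign:
    gene: str
    v1: str
    v2: str
    #: activity vectors over replicates, keyed by allele combination
    activities: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = set(ALLELE_COMBOS) - set(self.activities)
        if missing:
            raise ValueError(f"missing allele combinations: {sorted(missing)}")


@dataclass
class InteractionResult:
    gene: str
    v1: str
    v2: str
    beta0: float
    beta1: float
    beta2: float
    beta3: float
    p: float
    q: float = np.nan


def test_interaction(pair: PairDesign) -> InteractionResult:
    """OLS fit of the two-variant interaction model for one pair."""
    ys, x1s, x2s = [], [], []
    for combo, values in pair.activities.items():
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError(f"no replicates for {combo}")
        a1, a2 = combo.split("/")
        ys.append(values)
        x1s.append(np.full(values.size, a1 == "RM", dtype=float))
        x2s.append(np.full(values.size, a2 == "RM", dtype=float))
    y = np.concatenate(ys)
    x1 = np.concatenate(x1s)
    x2 = np.concatenate(x2s)
    n = y.size
    X = np.column_stack([np.ones(n), x1, x2, x1 * x2])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("rank-deficient design: an allele combination is missing")
    if n <= 4:
        raise ValueError("no residual degrees of freedom")

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = n - 4
    sigma2 = resid @ resid / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    if sigma2 == 0:
        p = 1.0 if beta[3] == 0 else float(np.finfo(float).tiny)
    else:
        se3 = np.sqrt(sigma2 * xtx_inv[3, 3])
        t = beta[3] / se3
        p = float(2.0 * stats.t.sf(abs(t), df_resid))
    return InteractionResult(
        gene=pair.gene, v1=pair.v1, v2=pair.v2,
        beta0=float(beta[0]), beta1=float(beta[1]),
        beta2=float(beta[2]), beta3=float(beta[3]), p=p,
    )


def test_interactions(pairs: list[PairDesign]) -> pd.DataFrame:
    """Test every pair and attach BH q-values over all tested pairs."""
    results = [test_interaction(p) for p in pairs]
    out = pd.DataFrame([r.__dict__ for r in results])
    if not out.empty:
        out["q"] = adjust_fdr(out["p"].to_numpy())
    return out


@dataclass
class LDResult:
    D: float
    d_prime: float
    r2: float
    p_a: float  # frequency of the major allele at marker 1
    p_b: float  # frequency of the major allele at marker 2
    n: int


def compute_ld(genotypes: np.ndarray | pd.DataFrame) -> LDResult:
    """D, D' and r^2 from an isolates x 2 matrix of haploid allele calls.

    Heterozygous or missing calls (None/NaN or strings containing "/") are
    dropped.  Each marker is reduced to its two most frequent alleles;
    isolates carrying rarer alleles are excluded.  D' is reported as
    |D| / D_max in [0, 1].
    """
    arr = np.asarray(genotypes, dtype=object)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an isolates x 2 genotype matrix")

    def valid(call) -> bool:
        if call is None:
            return False
        if isinstance(call, float) and np.isnan(call):
            return False
        s = str(call)
        if "/" in s:  # heterozygous diploid call
            a, b = s.split("/", 1)
            return a == b
        return s != ""

    calls = []
    for g1, g2 in arr:
        if valid(g1) and valid(g2):
            s1, s2 = str(g1).split("/")[0], str(g2).split("/")[0]
            calls.append((s1, s2))
    if len(calls) < 2:
        raise ValueError("need >= 2 isolates with non-missing calls at both markers")

    m1 = Counter(c[0] for c in calls)
    m2 = Counter(c[1] for c in calls)
    if len(m1) < 2 or len(m2) < 2:
        raise ValueError("monomorphic marker: LD undefined")
    top1 = [a for a, _ in m1.most_common(2)]
    top2 = [a for a, _ in m2.most_common(2)]
    kept = [c for c in calls if c[0] in top1 and c[1] in top2]
    n = len(kept)
    a_major, b_major = top1[0], top2[0]
    p_a = sum(c[0] == a_major for c in kept) / n
    p_b = sum(c[1] == b_major for c in kept) / n
    p_ab = sum(c == (a_major, b_major) for c in kept) / n

    D = p_ab - p_a * p_b
    if D > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(D) / d_max if d_max > 0 else np.nan
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = D * D / denom if denom > 0 else np.nan
    return LDResult(D=float(D), d_prime=float(d_prime), r2=float(r2),
                    p_a=float(p_a), p_b=float(p_b), n=n)
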