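"""Per-variant feature computation: allelic TFBS scores and non-TF features.

For each transcription factor, binding propensity of each allele is scored
by sliding a window of the PWM's length over the variant in 1-bp steps and
summing the position weights for the window's bases.  Windows at or above
the TF's score cutoff are "strong" sites, windows below it are "weak".
Five allelic metrics (absolute between-allele differences in best score,
mean score and strong-site count, plus best/mean over weak windows) are
computed in three strand contexts (plus, minus, strand-agnostic), giving 15
features per TF, and 27 summary features aggregate them across TFs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import reverse_complement

CONTEXTS = ("plus", "minus", "agnostic")
TF_METRICS = ("best_strong", "mean_strong", "n_strong", "best_weak", "mean_weak")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PWM:
    """Position weight matrix with a strong-site score cutoff."""

    name: str
    matrix: np.ndarray  # length x 4, columns A, C, G, T
    cutoff: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or len(self.matrix) < 1:
            raise ValueError("PWM matrix must be length x 4 with length >= 1")
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")

    def __len__(self) -> int:
        return len(self.matrix)

    def score(self, window: str) -> float:
        if len(window) != len(self.matrix):
            raise ValueError("window length != PWM length")
        try:
            idx = [_BASE_INDEX[b] for b in window]
        except KeyError as exc:
            raise ValueError(f"non-ACGT base in window: {exc}") from None
        return float(self.matrix[np.arange(len(idx)), idx].sum())


def parse_pwm_text(text: str, name: str, cutoff: float) -> PWM:
    """Parse a ScerTF-style whitespace matrix (rows A/C/G/T, '|' or ':'
    separated)."""
    rows: dict[str, list[float]] = {}
    for line in text.strip().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", ">")):
            continue
        m = re.match(r"^([ACGT])\s*[|:]?\s*(.*)$", line)
        if not m:
            continue
        rows[m.group(1)] = [float(x) for x in m.group(2).split()]
    if set(rows) != set("ACGT"):
        raise ValueError(f"PWM {name!r}: need rows for A, C, G and T")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"PWM {name!r}: ragged rows")
    matrix = np.column_stack([rows[b] for b in "ACGT"])
    return PWM(name=name, matrix=matrix, cutoff=cutoff)


def load_pwms(matrix_paths: dict[str, str], cutoffs: pd.DataFrame) -> list[PWM]:
    """Load PWMs from per-TF matrix files and a (tf, cutoff) table."""
    cut = cutoffs.set_index("tf")["cutoff"]
    pwms = []
    for tf, path in matrix_paths.items():
        with open(path) as fh:
            pwms.append(parse_pwm_text(fh.read(), tf, float(cut[tf])))
    return pwms


def _window_starts(seq_len: int, span: tuple[int, int], L: int) -> range:
    """Start offsets of all length-L windows overlapping >= 1 base of span.

    ``span`` is 0-based half-open within the sequence; a zero-length span
    (pure deletion junction) is widened to the single junction base.
    """
    s0, s1 = span
    if s1 <= s0:
        s0, s1 = max(s0 - 1, 0), max(s0, 1)
    lo = max(s0 - L + 1, 0)
    hi = min(s1 - 1, seq_len - L)
    return range(lo, hi + 1)


def score_windows(
    seq: str, span: tuple[int, int], pwm: PWM, context: str = "plus"
) -> np.ndarray:
    """TFBS scores of all PWM-length windows overlapping the variant span.

    ``seq`` is one allele's sequence including flanks; flanks must extend at
    least ``len(pwm) - 1`` bases on both sides of the span.  ``minus``
    analyzes the reverse complement; ``agnostic`` pools both strands'
    windows.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown strand context {context!r}")
    L = len(pwm)
    s0, s1 = span
    if s0 < L - 1 or (len(seq) - max(s1, s0 + 1)) < L - 1:
        raise ValueError("insufficient flank for PWM length")
    if context == "agnostic":
        return np.concatenate(
            [score_windows(seq, span, pwm, "plus"),
             score_windows(seq, span, pwm, "minus")]
        )
    if context == "minus":
        seq = reverse_complement(seq)
        s0, s1 = len(seq) - span[1], len(seq) - span[0]
        if s1 <= s0:  # zero-length span mirrors around the junction
            s0, s1 = len(seq) - span[0], len(seq) - span[0]
    starts = _window_starts(len(seq), (s0, s1), L)
    return np.array([pwm.score(seq[s : s + L]) for s in starts], dtype=float)


def _abs_diff_if_both(by: np.ndarray, rm: np.ndarray, stat) -> float:
    """|stat(rm) - stat(by)| when both allele sets are non-empty, else 0."""
    if by.size == 0 or rm.size == 0:
        return 0.0
    return float(abs(stat(rm) - stat(by)))


def tf_features(
    by_seq: str,
    by_span: tuple[int, int],
    rm_seq: str,
    rm_span: tuple[int, int],
    pwm: PWM,
) -> dict[str, float]:
    """The 15 allelic binding features of one variant for one TF.

    Returns ``{f"{tf}_{context}_{metric}": value}`` for the three strand
    contexts and five metrics.  Best/mean metrics over an empty strong (or
    weak) window set on either allele are defined as 0; the strong-site
    count difference is always defined.
    """
    out: dict[str, float] = {}
    for context in CONTEXTS:
        by = score_windows(by_seq, by_span, pwm, context)
        rm = score_windows(rm_seq, rm_span, pwm, context)
        by_strong, rm_strong = by[by >= pwm.cutoff], rm[rm >= pwm.cutoff]
        by_weak, rm_weak = by[by < pwm.cutoff], rm[rm < pwm.cutoff]
        prefix = f"{pwm.name}_{context}"
        out[f"{prefix}_best_strong"] = _abs_diff_if_both(by_strong, rm_strong, np.max)
        out[f"{prefix}_mean_strong"] = _abs_diff_if_both(by_strong, rm_strong, np.mean)
        out[f"{prefix}_n_strong"] = float(abs(rm_strong.size - by_strong.size))
        out[f"{prefix}_best_weak"] = _abs_diff_if_both(by_weak, rm_weak, np.max)
        out[f"{prefix}_mean_weak"] = _abs_diff_if_both(by_weak, rm_weak, np.mean)
    return out


def variant_tf_features(
    by_seq: str,
    by_span: tuple[int, int],
    rm_seq: str,
    rm_span: tuple[int, int],
    pwms: list[PWM],
) -> dict[str, float]:
    """Per-TF feature block for one variant: 15 features x n_TF."""
    out: dict[str, float] = {}
    for pwm in pwms:
        out.update(tf_features(by_seq, by_span, rm_seq, rm_span, pwm))
    return out


def aggregate_tf_features(
    per_tf: dict[str, float], tf_names: list[str]
) -> dict[str, float]:
    """The 27 summary features aggregating the per-TF block across TFs.

    Per strand context: the total number of strong sites changed (3), and
    the maximum and average across TFs of the best/mean score differences,
    separately for strong and weak windows (12 + 12).
    """
    if not tf_names:
        raise ValueError("need at least one TF")
    out: dict[str, float] = {}
    for context in CONTEXTS:
        n_changed = [per_tf[f"{tf}_{context}_n_strong"] for tf in tf_names]
        out[f"agg_{context}_n_strong_changed"] = float(np.sum(n_changed))
        for strength in ("strong", "weak"):
            for metric in ("best", "mean"):
                vals = np.array(
                    [per_tf[f"{tf}_{context}_{metric}_{strength}"] for tf in tf_names]
                )
                out[f"agg_{context}_{strength}_{metric}_max"] = float(vals.max())
                out[f"agg_{context}_{strength}_{metric}_avg"] = float(vals.mean())
    return out


TATA_CONSENSUS = re.compile(r"(?=TATA[AT]A[AT][AG])")
ATG = re.compile(r"(?=ATG)")


def count_tata(seq: str) -> int:
    """Occurrences (overlapping) of the TATA-box consensus TATA(A/T)A(A/T)(A/G)."""
    return len(TATA_CONSENSUS.findall(seq.upper()))


def count_atg(seq: str) -> int:
    """Occurrences (overlapping) of the start codon ATG."""
    return len(ATG.findall(seq.upper()))


def nucleosome_bound(pos: int, centers, halfwidth: int = 72) -> bool:
    """True when ``pos`` lies within [center - halfwidth, center + halfwidth]
    (closed on both ends) of any reported nucleosome center."""
    centers = np.asarray(list(centers), dtype=float)
    return bool(np.any(np.abs(centers - pos) <= halfwidth))


def derived_allele(ref: str, alt: str, outgroup_call: str | None) -> str | None:
    """The allele absent from the outgroup isolate; None when the outgroup
    call is missing, heterozygous, or matches neither allele."""
    if outgroup_call is None:
        return None
    s = str(outgroup_call)
    if "/" in s:
        a, b = s.split("/", 1)
        if a != b:
            return None
        s = a
    if s == ref:
        return alt
    if s == alt:
        return ref
    return None


def nontf_features(
    variant,
    by_seq: str,
    rm_seq: str,
    nucleosome_centers=(),
    outgroup_call: str | None = None,
    alt_frequency: float | None = None,
    gene_annotations: pd.Series | None = None,
) -> dict[str, float]:
    """Non-TF feature set for one variant.

    Sequence features are computed on the flanked allele sequences; external
    annotations (nucleosome centers, outgroup genotype, population allele
    frequency, gene-level columns) are joined, not computed.  Missing
    annotations yield NaN, to be dropped by the NA rule downstream.
    """
    out: dict[str, float] = {
        "is_snv": float(variant.variant_class == "SNV"),
        "indel_length": float(abs(len(variant.ref) - len(variant.alt))),
        "tata_by": float(count_tata(by_seq)),
        "tata_rm": float(count_tata(rm_seq)),
        "tata_diff": float(abs(count_tata(rm_seq) - count_tata(by_seq))),
        "atg_by": float(count_atg(by_seq)),
        "atg_rm": float(count_atg(rm_seq)),
        "atg_diff": float(abs(count_atg(rm_seq) - count_atg(by_seq))),
        "nucleosome_bound": float(
            nucleosome_bound(variant.pos, nucleosome_centers)
        ) if len(list(nucleosome_centers)) else np.nan,
    }
    derived = derived_allele(variant.ref, variant.alt, outgroup_call)
    if derived is None or alt_frequency is None:
        out["derived_allele_frequency"] = np.nan
    else:
        out["derived_allele_frequency"] = (
            alt_frequency if derived == variant.alt else 1.0 - alt_frequency
        )
    if gene_annotations is not None:
        for key, value in gene_annotations.items():
            out[str(key)] = float(value) if pd.notna(value) else np.nan
    return out


def zscore_features(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Z-score each numeric column by its across-variant mean and SD
    (population SD); returns (z-scored matrix, constant columns excluded)."""
    out = matrix.copy()
    constant: list[str] = []
    for col in matrix.columns:
        x = matrix[col].astype(float)
        sd = x.std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            constant.append(col)
            continue
        out[col] = (x - x.mean()) / sd
    out = out.drop(columns=constant)
    return out, constant
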