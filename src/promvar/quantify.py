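"""Demultiplexing, barcode counting, oligo aggregation and expression.

The central object is a :class:`CountMatrix`: a features x samples integer
table plus a sample sheet carrying assay (DNA/RNA), replicate and batch
metadata.  Expression of an oligo in a replicate is
``log2((RNA_cpm + pc) / (DNA_cpm + pc))`` after counts-per-million library
size normalization; only oligos with nonzero summed counts in every
replicate of both assays are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """features x samples counts with a sample sheet.

    ``samples`` is indexed by sample name with columns ``assay`` (DNA/RNA),
    ``replicate`` and ``batch``; ``level`` is "barcode" or "oligo".
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    level: str = "barcode"

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")

    def sample_names(self, assay: str) -> list[str]:
        return list(self.samples.index[self.samples["assay"] == assay])


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("index length mismatch")
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    index_reads: list[str], expected: dict[str, str], max_mismatch: int = 1
) -> list[str | None]:
    """Assign each index read to the unique expected sample index within
    ``max_mismatch`` substitutions; ambiguous or unmatched reads get None.
    """
    out = []
    for read in index_reads:
        hits = [s for s, idx in expected.items()
                if hamming(read, idx) <= max_mismatch]
        out.append(hits[0] if len(hits) == 1 else None)
    return out


def count_barcodes(
    reads_per_sample: dict[str, list[str]],
    dictionary: pd.DataFrame,
    samples: pd.DataFrame,
) -> CountMatrix:
    """Exact-match counting of annotated barcodes per sample.

    Reads whose barcode was not seen in the annotation (no dictionary entry)
    are discarded.  Technical replicates (same sample name) are summed by
    construction of ``reads_per_sample``.
    """
    known = pd.Index(dictionary["barcode"])
    counts = pd.DataFrame(0, index=known, columns=list(reads_per_sample))
    for sample, reads in reads_per_sample.items():
        if not reads:
            continue
        vc = pd.Series(reads).value_counts()
        vc = vc[vc.index.isin(known)]
        counts.loc[vc.index, sample] = vc.astype(int)
    counts.index.name = "barcode"
    return CountMatrix(counts=counts, samples=samples, level="barcode")


def sum_technical_replicates(
    counts: pd.DataFrame, groups: dict[str, str]
) -> pd.DataFrame:
    """Sum columns belonging to the same biological sample.

    ``groups`` maps technical column name -> biological sample name.
    """
    return counts.T.groupby(counts.columns.map(groups)).sum().T


def aggregate_to_oligos(matrix: CountMatrix, dictionary: pd.DataFrame) -> CountMatrix:
    """Sum barcode counts to their oligo, per sample."""
    if matrix.level != "barcode":
        raise ValueError("expected a barcode-level matrix")
    mapping = dictionary.set_index("barcode")["oligo_id"]
    usable = matrix.counts.index.intersection(mapping.index)
    agg = matrix.counts.loc[usable].groupby(mapping.loc[usable]).sum()
    agg.index.name = "oligo_id"
    return CountMatrix(counts=agg, samples=matrix.samples, level="oligo")


def handle_missing_dna(
    matrix: CountMatrix,
    missing_rna_samples: list[str],
    policy: str = "same_batch",
    annotation_counts: pd.Series | None = None,
) -> CountMatrix:
    """Give RNA samples that lack a DNA partner a DNA column per policy.

    Policies: ``same_batch`` copies the DNA column of another sample in the
    same batch; ``sum_all`` uses the elementwise sum of all DNA samples;
    ``annotation`` uses read support from the annotation run; ``drop``
    removes the RNA sample.  Provenance lands in a ``dna_source`` column of
    the sample sheet.
    """
    counts = matrix.counts.copy()
    samples = matrix.samples.copy()
    if "dna_source" not in samples.columns:
        samples["dna_source"] = "measured"
    dna_cols = matrix.sample_names("DNA")

    for rna in missing_rna_samples:
        if rna not in samples.index or samples.loc[rna, "assay"] != "RNA":
            raise ValueError(f"{rna!r} is not a known RNA sample")
        new_col = f"DNA_for_{rna}"
        if policy == "drop":
            counts = counts.drop(columns=[rna])
            samples = samples.drop(index=[rna])
            continue
        if policy == "same_batch":
            batch = samples.loc[rna, "batch"]
            partners = [s for s in dna_cols if samples.loc[s, "batch"] == batch]
            if not partners:
                raise ValueError(f"no DNA sample in batch {batch!r} for {rna}")
            counts[new_col] = counts[partners[0]]
            source = f"copied:{partners[0]}"
        elif policy == "sum_all":
            counts[new_col] = counts[dna_cols].sum(axis=1)
            source = "sum_all_dna"
        elif policy == "annotation":
            if annotation_counts is None:
                raise ValueError("annotation policy requires annotation_counts")
            counts[new_col] = annotation_counts.reindex(counts.index).fillna(0).astype(int)
            source = "annotation_run"
        else:
            raise ValueError(f"unknown policy {policy!r}")
        samples.loc[new_col] = {
            "assay": "DNA",
            "replicate": samples.loc[rna, "replicate"],
            "batch": samples.loc[rna, "batch"],
            "dna_source": source,
        }
    return CountMatrix(counts=counts, samples=samples, level=matrix.level)


@dataclass
class ExpressionTable:
    """oligo x replicate log2(RNA/DNA) activities after CPM normalization."""

    activity: pd.DataFrame
    size_factors: pd.Series
    pseudocount: float


def compute_expression(
    matrix: CountMatrix, pseudocount: float = 0.5
) -> ExpressionTable:
    """Per-replicate log2 RNA/DNA activity on CPM-normalized oligo counts.

    Pairs DNA and RNA samples by replicate id.  Oligos with a zero count in
    any replicate of either assay are excluded before the ratio is formed.
    """
    if matrix.level != "oligo":
        raise ValueError("expected an oligo-level matrix")
    samples = matrix.samples
    counts = matrix.counts

    replicates = sorted(samples.loc[samples["assay"] == "RNA", "replicate"].unique())
    pairs = {}
    for rep in replicates:
        rna = samples.index[(samples["assay"] == "RNA") & (samples["replicate"] == rep)]
        dna = samples.index[(samples["assay"] == "DNA") & (samples["replicate"] == rep)]
        if len(rna) != 1 or len(dna) != 1:
            raise ValueError(f"replicate {rep!r} lacks a unique DNA/RNA pair")
        pairs[rep] = (dna[0], rna[0])

    used = [s for pair in pairs.values() for s in pair]
    keep = (counts[used] > 0).all(axis=1)
    if not keep.any():
        raise ValueError("no oligo passes the all-replicates-nonzero filter")
    kept = counts.loc[keep]

    totals = counts[used].sum(axis=0).astype(float)
    cpm = kept[used] / totals * 1e6
    activity = pd.DataFrame(index=kept.index, columns=list(pairs), dtype=float)
    for rep, (dna, rna) in pairs.items():
        activity[rep] = np.log2(
            (cpm[rna] + pseudocount) / (cpm[dna] + pseudocount)
        )
    sf = totals / 1e6
    sf.name = "size_factor"
    return ExpressionTable(activity=activity, size_factors=sf, pseudocount=pseudocount)


def gene_level_expression(
    expression: ExpressionTable, manifest: pd.DataFrame
) -> pd.Series:
    """Mean activity over all oligos designed from a gene's promoter,
    averaged over replicates -- a proxy for native promoter strength."""
    gene_of = manifest.set_index("oligo_id")["gene"]
    mean_act = expression.activity.mean(axis=1)
    genes = gene_of.reindex(mean_act.index)
    return mean_act.groupby(genes).mean()
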