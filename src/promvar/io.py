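"""Readers and writers for the pipeline's plain-text interchange formats.

FASTA goes through Biopython; tables are tab-separated and read/written
with pandas.  Variant tables are 1-based (chrom, pos, ref, alt, gene).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import VariantRecord
from .simulate import GroundTruth


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(reference: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_variants(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    return [
        VariantRecord(
            chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt,
            gene=str(getattr(row, "gene", "")),
        )
        for row in df.itertuples()
    ]


def write_variants(variants: list[VariantRecord], path) -> None:
    pd.DataFrame(
        [
            {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
             "gene": v.gene, "variant_class": v.variant_class}
            for v in variants
        ]
    ).to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_merged_reads(path) -> list[str]:
    """Merged amplicon reads from FASTA or FASTQ (by extension)."""
    path = str(path)
    fmt = "fastq" if path.endswith(("fastq", "fq")) else "fasta"
    return [str(rec.seq) for rec in SeqIO.parse(path, fmt)]


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "variant_effects": truth.variant_effects,
        "interaction_effects": {
            f"{a}|{b}": eff for (a, b), eff in truth.interaction_effects.items()
        },
        "gene_effects": truth.gene_effects,
        "variant_gene": truth.variant_gene,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        variant_effects=payload["variant_effects"],
        interaction_effects={
            tuple(k.split("|")): v
            for k, v in payload["interaction_effects"].items()
        },
        gene_effects=payload["gene_effects"],
        variant_gene=payload.get("variant_gene", {}),
    )
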