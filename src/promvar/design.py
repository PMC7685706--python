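"""Oligo-block and barcode design for the promoter-variant MPRA.

Two library designs are supported:

* **TSS** -- for each gene, all variants in the 144 bp immediately upstream of
  the transcription start site are placed on a block of oligos: one oligo with
  the BY (reference) allele at every variant, one oligo per variant carrying
  the RM (alternative) allele at that variant only, and one oligo with the RM
  allele at all variants.
* **Upstream** -- one block per variant, a pair of oligos representing 144 bp
  of genomic sequence centered on the variant, carrying the BY or the RM
  allele; any other variant covered by the window stays BY in both oligos.

Coordinates are 1-based inclusive on input (variant ``pos``, ``tss``);
windows are handled 0-based half-open internally.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Fixed adapter context used to assemble full oligos.  The 5' adapter is the
# SfiI-A site; the 3' adapters are the cloning/priming stretch between the
# oligo and the barcode and double as the invariant anchors used during
# barcode annotation.  They intentionally contain the cloning sites, so the
# restriction-site screen is applied to the variable insert only.
FIVE_PRIME_ADAPTER = "GGCCGTAATGGCC"
THREE_PRIME_ADAPTER = {
    "TSS": "CCTGCAGGGGTTTAGCCGGCGTG",
    "Upstream": "CCTGCAGGGTTCCGCAGCCACAC",
}

#: Enzymes used during cloning: SfiI, AscI, SbfI.  ``N`` matches any base.
DEFAULT_RESTRICTION_SITES = ("GGCCNNNNNGGCC", "GGCGCGCC", "CCTGCAGG")

TSS_WINDOW = 144
UPSTREAM_WINDOW = 144
MAX_OLIGO_LENGTH = 200


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class VariantRecord:
    """One BY/RM sequence difference, VCF-style left-aligned.

    ``ref`` is the BY (reference) allele, ``alt`` the RM allele; ``pos`` is
    the 1-based position of the first ref base.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt for variant at {self.chrom}:{self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("empty allele; use anchored (VCF-style) indel alleles")

    @property
    def variant_class(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def end(self) -> int:
        """1-based inclusive end of the ref allele."""
        return self.pos + len(self.ref) - 1

    @property
    def vid(self) -> str:
        return f"{self.chrom}:{self.pos}_{self.ref}/{self.alt}"


@dataclass
class Oligo:
    oligo_id: str
    gene: str
    library: str
    allele_config: tuple[str, ...]  # over the block's variants, "BY"/"RM"
    insert_sequence: str
    full_sequence: str = ""
    strand_flipped: bool = False


@dataclass
class OligoBlock:
    gene: str
    library: str
    variants: list[VariantRecord]
    oligos: list[Oligo] = field(default_factory=list)


class DesignError(ValueError):
    pass


def _substitute(window_seq: str, window_start0: int, variants, config) -> str:
    """Splice RM alleles into a plus-strand window sequence.

    ``window_start0`` is the 0-based genome coordinate of the first window
    base.  Substitutions run right to left so earlier coordinates stay valid
    when indels shift lengths.
    """
    seq = window_seq
    for variant, allele in sorted(
        zip(variants, config), key=lambda t: -t[0].pos
    ):
        if allele == "BY":
            continue
        off = (variant.pos - 1) - window_start0
        if off < 0 or off + len(variant.ref) > len(window_seq):
            raise DesignError(f"variant {variant.vid} not fully inside window")
        if window_seq[off : off + len(variant.ref)] != variant.ref:
            raise DesignError(
                f"reference mismatch for {variant.vid}: window has "
                f"{window_seq[off:off + len(variant.ref)]!r}"
            )
        seq = seq[:off] + variant.alt + seq[off + len(variant.ref) :]
    return seq


def _assemble(
    insert: str, library: str, oriented: str | None = None
) -> str:
    return FIVE_PRIME_ADAPTER + insert + THREE_PRIME_ADAPTER[library]


def _window_sequence(reference: dict, chrom: str, start0: int, end0: int) -> str:
    try:
        seq = reference[chrom]
    except KeyError:
        raise DesignError(f"chromosome {chrom!r} missing from reference") from None
    seq = str(seq)
    if start0 < 0 or end0 > len(seq):
        raise DesignError(f"window [{start0}, {end0}) outside {chrom}")
    return seq[start0:end0].upper()


def design_tss_block(
    gene: str,
    chrom: str,
    tss: int,
    strand: str,
    variants: list[VariantRecord],
    reference: dict,
    window: int = TSS_WINDOW,
) -> OligoBlock:
    """Design the TSS oligo block for one gene.

    The window covers the ``window`` bases immediately upstream of the TSS,
    orientation-aware: positions ``tss-window .. tss-1`` for plus-strand
    genes, ``tss+1 .. tss+window`` (reverse-complemented) for minus-strand
    genes.  The TSS base itself is excluded.
    """
    if strand == "+":
        start0, end0 = tss - 1 - window, tss - 1
    elif strand == "-":
        start0, end0 = tss, tss + window
    else:
        raise DesignError(f"bad strand {strand!r}")

    for v in variants:
        if not (start0 < v.pos <= end0 and v.end <= end0):
            raise DesignError(f"variant {v.vid} outside TSS window of {gene}")

    block = OligoBlock(gene=gene, library="TSS", variants=list(variants))
    if not variants:
        return block

    window_seq = _window_sequence(reference, chrom, start0, end0)
    k = len(variants)
    configs = [("BY",) * k]
    for i in range(k):
        cfg = ["BY"] * k
        cfg[i] = "RM"
        configs.append(tuple(cfg))
    configs.append(("RM",) * k)

    seen: dict[str, Oligo] = {}
    for idx, cfg in enumerate(configs):
        ins = _substitute(window_seq, start0, variants, cfg)
        if strand == "-":
            ins = reverse_complement(ins)
        if ins in seen:
            continue
        oligo = Oligo(
            oligo_id=f"{gene}_TSS_{idx}",
            gene=gene,
            library="TSS",
            allele_config=cfg,
            insert_sequence=ins,
            full_sequence=_assemble(ins, "TSS"),
        )
        seen[ins] = oligo
    block.oligos = list(seen.values())
    return block


def design_upstream_block(
    variant: VariantRecord,
    chrom: str,
    strand: str,
    reference: dict,
    other_variants: list[VariantRecord] | None = None,
    window: int = UPSTREAM_WINDOW,
) -> OligoBlock:
    """Design the two-oligo Upstream block centered on one variant.

    The window is computed on the BY reference; the RM oligo keeps the same
    flanks, so an indel changes the RM insert length.  Any other variant
    covered by the window carries the BY allele in both oligos.
    """
    half = window // 2
    start0 = variant.pos - 1 - half + 1  # variant base sits at offset half-1
    end0 = start0 + window
    window_seq = _window_sequence(reference, chrom, start0, end0)

    by_ins = window_seq
    rm_ins = _substitute(window_seq, start0, [variant], ("RM",))
    if strand == "-":
        by_ins = reverse_complement(by_ins)
        rm_ins = reverse_complement(rm_ins)

    block = OligoBlock(gene=variant.gene, library="Upstream", variants=[variant])
    for tag, cfg, ins in (("BY", ("BY",), by_ins), ("RM", ("RM",), rm_ins)):
        block.oligos.append(
            Oligo(
                oligo_id=f"{variant.gene}_{variant.vid}_Up_{tag}",
                gene=variant.gene,
                library="Upstream",
                allele_config=cfg,
                insert_sequence=ins,
                full_sequence=_assemble(ins, "Upstream"),
            )
        )
    return block


def _site_regex(site: str) -> re.Pattern:
    return re.compile(site.replace("N", "[ACGT]"))


def filter_blocks(
    blocks: list[OligoBlock],
    restriction_sites: tuple[str, ...] = DEFAULT_RESTRICTION_SITES,
    max_len: int = MAX_OLIGO_LENGTH,
) -> tuple[list[OligoBlock], list[tuple[OligoBlock, str]]]:
    """Drop whole blocks with a restriction site in any insert (either
    strand) or an over-length full oligo.  Returns (kept, dropped_with_reason).
    """
    patterns = [_site_regex(s) for s in restriction_sites]
    kept, dropped = [], []
    for block in blocks:
        reason = None
        for oligo in block.oligos:
            if len(oligo.full_sequence) > max_len:
                reason = f"oligo {oligo.oligo_id} longer than {max_len} bp"
                break
            ins = oligo.insert_sequence
            both = (ins, reverse_complement(ins))
            hit = next(
                (s for s, pat in zip(restriction_sites, patterns)
                 if any(pat.search(x) for x in both)),
                None,
            )
            if hit is not None:
                reason = f"oligo {oligo.oligo_id} contains restriction site {hit}"
                break
        if reason is None:
            kept.append(block)
        else:
            dropped.append((block, reason))
    return kept, dropped


def maybe_reverse_complement(oligo: Oligo) -> Oligo:
    """Flip the synthesized sequence when it has strictly more A than T.

    A-rich sequences are hard to synthesize; since the library is PCR
    amplified before use, the reverse complement behaves identically.  Ties
    are not flipped.
    """
    seq = oligo.full_sequence
    if seq.count("A") > seq.count("T"):
        return replace(
            oligo, full_sequence=reverse_complement(seq), strand_flipped=True
        )
    return replace(oligo, strand_flipped=False)


#: Per-position alphabets of the constrained random barcode (1-based
#: positions): pos 1 in {C,T}; pos 2-4 and even pos 6..20 G-free; remaining
#: odd positions unconstrained.  G depletion in the transcribed barcode
#: protects reporter mRNA levels.
def _barcode_alphabets(length: int) -> list[str]:
    alphabets = []
    for pos in range(1, length + 1):
        if pos == 1:
            alphabets.append("CT")
        elif pos <= 4 or pos % 2 == 0:
            alphabets.append("ACT")
        else:
            alphabets.append("ACGT")
    return alphabets


def barcode_space_size(length: int = 20) -> int:
    out = 1
    for a in _barcode_alphabets(length):
        out *= len(a)
    return out


def generate_barcodes(
    n: int, length: int = 20, rng: np.random.Generator | None = None
) -> list[str]:
    """Draw ``n`` distinct random barcodes obeying the composition rules."""
    if n < 0:
        raise ValueError("n must be non-negative")
    space = barcode_space_size(length)
    if n > space:
        raise ValueError(f"{n} barcodes requested but only {space} exist")
    rng = np.random.default_rng() if rng is None else rng
    alphabets = _barcode_alphabets(length)
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        m = max(64, int((n - len(out)) * 1.2))
        draws = [rng.integers(0, len(a), size=m) for a in alphabets]
        for row in zip(*draws):
            bc = "".join(a[i] for a, i in zip(alphabets, row))
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
                if len(out) == n:
                    break
    return out


def blocks_to_manifest(blocks: list[OligoBlock]):
    """Flatten blocks to a manifest table (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for block in blocks:
        for oligo in block.oligos:
            rows.append(
                {
                    "oligo_id": oligo.oligo_id,
                    "gene": oligo.gene,
                    "library": oligo.library,
                    "allele_config": ",".join(oligo.allele_config),
                    "variants": ";".join(v.vid for v in block.variants),
                    "insert_sequence": oligo.insert_sequence,
                    "full_sequence": oligo.full_sequence,
                    "strand_flipped": oligo.strand_flipped,
                }
            )
    return pd.DataFrame(rows)
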