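"""Barcode-to-oligo dictionary construction from merged amplicon reads.

Each well-formed merged read has the layout::

    ... upstream_anchor  OLIGO  between_anchor  BARCODE ...

The two invariant anchors locate the oligo and the 20-nt barcode.  A barcode
seen with several oligo sequences (PCR/synthesis artifacts) is assigned its
modal "primary" oligo; barcodes whose primary oligo does not perfectly match
a designed sequence are discarded, because a single erroneous base could
mimic or mask the small allelic effects under study.  Barcodes are never
collapsed by sequence similarity.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import pandas as pd

from .design import THREE_PRIME_ADAPTER, FIVE_PRIME_ADAPTER


@dataclass(frozen=True)
class AnchorSpec:
    """Invariant sequences flanking the oligo in a merged read."""

    between_anchor: str  # between oligo and barcode
    upstream_anchor: str  # upstream of the oligo

    def __post_init__(self) -> None:
        if not self.between_anchor or not self.upstream_anchor:
            raise ValueError("anchors must be non-empty")


#: Library-specific defaults matching the adapters used at design time.
DEFAULT_ANCHORS = {
    lib: AnchorSpec(between_anchor=THREE_PRIME_ADAPTER[lib],
                    upstream_anchor=FIVE_PRIME_ADAPTER)
    for lib in THREE_PRIME_ADAPTER
}

REJECT_MISSING_UPSTREAM = "missing_upstream_anchor"
REJECT_MISSING_BETWEEN = "missing_between_anchor"
REJECT_DUPLICATED_ANCHOR = "duplicated_anchor"
REJECT_SHORT_BARCODE = "truncated_barcode"


def _find_once(read: str, anchor: str) -> int | None:
    """Offset of ``anchor`` if it occurs exactly once, else None (-1 if absent)."""
    first = read.find(anchor)
    if first == -1:
        return -1
    if read.find(anchor, first + 1) != -1:
        return None
    return first


def parse_read(
    read: str, anchors: AnchorSpec, barcode_len: int = 20
) -> tuple[str, str] | str:
    """Extract (barcode, observed oligo sequence) or a rejection reason code.

    Both anchors must occur exactly once (exact string match); the barcode is
    the ``barcode_len`` bases immediately 3' of the between-anchor, the oligo
    the substring between the two anchors.
    """
    up = _find_once(read, anchors.upstream_anchor)
    if up is None:
        return REJECT_DUPLICATED_ANCHOR
    if up == -1:
        return REJECT_MISSING_UPSTREAM
    bet = _find_once(read, anchors.between_anchor)
    if bet is None:
        return REJECT_DUPLICATED_ANCHOR
    if bet == -1:
        return REJECT_MISSING_BETWEEN
    oligo_start = up + len(anchors.upstream_anchor)
    if bet < oligo_start:
        return REJECT_MISSING_BETWEEN
    bc_start = bet + len(anchors.between_anchor)
    barcode = read[bc_start : bc_start + barcode_len]
    if len(barcode) < barcode_len:
        return REJECT_SHORT_BARCODE
    return barcode, read[oligo_start:bet]


def resolve_primary(
    pairs: list[tuple[str, str]]
) -> dict[str, tuple[str, int, int, float]]:
    """Per barcode: (primary oligo sequence, primary reads, total reads,
    primary fraction).  A tie for the modal oligo discards the barcode.
    """
    by_barcode: dict[str, Counter] = defaultdict(Counter)
    for barcode, oligo_seq in pairs:
        by_barcode[barcode][oligo_seq] += 1
    out = {}
    for barcode, counts in by_barcode.items():
        ranked = counts.most_common(2)
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            continue  # ambiguous modal oligo
        seq, n = ranked[0]
        total = sum(counts.values())
        out[barcode] = (seq, n, total, n / total)
    return out


def match_to_design(primary_seq: str, design_index: dict[str, str]) -> str | None:
    """Exact full-length match of a primary oligo against the design;
    ``design_index`` maps full oligo sequence -> oligo_id."""
    return design_index.get(primary_seq)


def design_index_from_manifest(manifest: pd.DataFrame) -> dict[str, str]:
    """Variable-sequence -> oligo_id lookup from a design manifest.

    Reads carry the construct in its designed orientation (A-rich synthesis
    flips are undone by PCR), with the invariant adapters as anchors; the
    observed oligo between the anchors is therefore the variable insert.
    """
    return {
        row.insert_sequence: row.oligo_id for row in manifest.itertuples()
    }


def build_dictionary(
    reads,
    anchors: AnchorSpec,
    manifest: pd.DataFrame,
    barcode_len: int = 20,
    min_reads: int = 1,
    min_primary_fraction: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the barcode dictionary from an iterable of merged read strings.

    Returns (dictionary, rejection report).  The dictionary has columns
    barcode, oligo_id, reads, primary_fraction; each barcode maps to exactly
    one designed oligo.
    """
    rejects: Counter = Counter()
    pairs = []
    for read in reads:
        parsed = parse_read(str(read), anchors, barcode_len)
        if isinstance(parsed, str):
            rejects[parsed] += 1
        else:
            pairs.append(parsed)

    primaries = resolve_primary(pairs)
    index = design_index_from_manifest(manifest)
    rows = []
    for barcode, (seq, n_primary, n_total, frac) in primaries.items():
        if n_primary < min_reads:
            rejects["insufficient_read_support"] += 1
            continue
        if min_primary_fraction is not None and frac < min_primary_fraction:
            rejects["low_primary_fraction"] += 1
            continue
        oligo_id = match_to_design(seq, index)
        if oligo_id is None:
            rejects["primary_oligo_not_in_design"] += 1
            continue
        rows.append(
            {"barcode": barcode, "oligo_id": oligo_id,
             "reads": n_primary, "primary_fraction": frac}
        )
    dictionary = pd.DataFrame(
        rows, columns=["barcode", "oligo_id", "reads", "primary_fraction"]
    )
    report = pd.DataFrame(
        sorted(rejects.items()), columns=["reason", "n"]
    )
    return dictionary, report
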