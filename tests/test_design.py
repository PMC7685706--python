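"""Oligo-block design, restriction filtering and barcode generation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from promvar.design import (
    DEFAULT_RESTRICTION_SITES,
    OligoBlock,
    Oligo,
    VariantRecord,
    barcode_space_size,
    design_tss_block,
    design_upstream_block,
    filter_blocks,
    generate_barcodes,
    maybe_reverse_complement,
    reverse_complement,
)

RNG = np.random.default_rng(0)


def random_ref(length=600, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def reference():
    return {"chrI": random_ref(seed=1)}


def test_variant_record_validation():
    with pytest.raises(ValueError):
        VariantRecord("chrI", 5, "A", "A")
    v = VariantRecord("chrI", 5, "A", "AGG")
    assert v.variant_class == "indel" and v.end == 5


class TestTssBlock:
    def test_two_variants_give_four_unique_oligos(self, reference):
        seq = reference["chrI"]
        tss = 400
        p1, p2 = 300, 340
        variants = [
            VariantRecord("chrI", p1, seq[p1 - 1], "A" if seq[p1 - 1] != "A" else "C", "G1"),
            VariantRecord("chrI", p2, seq[p2 - 1], "A" if seq[p2 - 1] != "A" else "C", "G1"),
        ]
        block = design_tss_block("G1", "chrI", tss, "+", variants, reference)
        assert len(block.oligos) == 4
        configs = {o.allele_config for o in block.oligos}
        assert configs == {("BY", "BY"), ("RM", "BY"), ("BY", "RM"), ("RM", "RM")}
        # every insert equals the BY insert with RM alleles spliced in
        by = next(o for o in block.oligos if o.allele_config == ("BY", "BY"))
        assert by.insert_sequence == seq[tss - 1 - 144 : tss - 1]

    def test_single_variant_deduplicates_to_two(self, reference):
        seq = reference["chrI"]
        v = VariantRecord("chrI", 320, seq[319], "A" if seq[319] != "A" else "C", "G1")
        block = design_tss_block("G1", "chrI", 400, "+", [v], reference)
        assert len(block.oligos) == 2  # RM-all duplicates the single-RM oligo

    def test_zero_variants_empty_block(self, reference):
        block = design_tss_block("G1", "chrI", 400, "+", [], reference)
        assert block.oligos == []

    def test_variant_outside_window_rejected(self, reference):
        v = VariantRecord("chrI", 100, reference["chrI"][99], "A", "G1")
        with pytest.raises(ValueError, match="outside"):
            design_tss_block("G1", "chrI", 400, "+", [v], reference)

    def test_minus_strand_insert_is_revcomp_of_plus_window(self, reference):
        seq = reference["chrI"]
        tss = 200
        pos = 250
        v = VariantRecord("chrI", pos, seq[pos - 1],
                          "A" if seq[pos - 1] != "A" else "C", "G1")
        block = design_tss_block("G1", "chrI", tss, "-", [v], reference)
        by = next(o for o in block.oligos if o.allele_config == ("BY",))
        assert reverse_complement(by.insert_sequence) == seq[tss : tss + 144]

    def test_splice_oracle_on_random_blocks(self):
        """Each oligo's insert equals the BY insert with RM alleles spliced
        at exactly the allele-config positions (string-splice oracle)."""
        rng = np.random.default_rng(5)
        for trial in range(30):
            seq = random_ref(seed=100 + trial)
            ref = {"chrI": seq}
            tss = 400
            positions = sorted(rng.choice(np.arange(260, 395), size=2, replace=False))
            variants = []
            for p in positions:
                base = seq[p - 1]
                alt = rng.choice([b for b in "ACGT" if b != base])
                variants.append(VariantRecord("chrI", int(p), base, str(alt), "G"))
            block = design_tss_block("G", "chrI", tss, "+", variants, ref)
            window = seq[tss - 1 - 144 : tss - 1]
            for oligo in block.oligos:
                expected = list(window)
                for v, allele in zip(variants, oligo.allele_config):
                    if allele == "RM":
                        expected[v.pos - (tss - 144)] = v.alt
                assert oligo.insert_sequence == "".join(expected)


class TestUpstreamBlock:
    def test_snv_pair_lengths_and_single_difference(self, reference):
        seq = reference["chrI"]
        pos = 300
        v = VariantRecord("chrI", pos, seq[pos - 1],
                          "A" if seq[pos - 1] != "A" else "C", "G1")
        block = design_upstream_block(v, "chrI", "+", reference)
        by, rm = block.oligos
        assert len(by.insert_sequence) == 144 and len(rm.insert_sequence) == 144
        diffs = sum(a != b for a, b in zip(by.insert_sequence, rm.insert_sequence))
        assert diffs == 1

    def test_by_deletion_lengthens_rm_insert(self, reference):
        # RM carries 3 extra bases relative to BY (a "BY deletion")
        seq = reference["chrI"]
        pos = 300
        v = VariantRecord("chrI", pos, seq[pos - 1], seq[pos - 1] + "AAA", "G1")
        block = design_upstream_block(v, "chrI", "+", reference)
        by, rm = block.oligos
        assert len(by.insert_sequence) == 144
        assert len(rm.insert_sequence) == 147

    def test_neighbor_variant_stays_by_in_both_oligos(self, reference):
        seq = reference["chrI"]
        v = VariantRecord("chrI", 300, seq[299], "A" if seq[299] != "A" else "C", "G1")
        block = design_upstream_block(v, "chrI", "+", reference)
        # the block targets a single variant; any neighbor is untouched
        window = seq[300 - 72 - 1 + 1 : 300 - 72 - 1 + 1 + 144]
        assert block.oligos[0].insert_sequence == window


class TestFilterBlocks:
    def _block(self, insert):
        oligo = Oligo("o1", "G", "TSS", ("BY",), insert, "X" * 10 + insert)
        return OligoBlock("G", "TSS", [], [oligo])

    def test_restriction_site_drops_whole_block(self):
        bad = self._block("ACGT" * 10 + "GGCGCGCC" + "ACGT" * 10)
        good = self._block("ACGT" * 36)
        kept, dropped = filter_blocks([bad, good])
        assert kept == [good]
        assert "GGCGCGCC" in dropped[0][1]

    def test_site_on_reverse_strand_also_drops(self):
        # non-palindromic site present only on the minus strand of the insert
        site = "GGTCTC"
        block = self._block("ATCATC" * 8 + reverse_complement(site) + "ATCATC" * 8)
        kept, dropped = filter_blocks([block], restriction_sites=(site,))
        assert kept == [] and dropped

    def test_overlong_oligo_drops_block(self):
        oligo = Oligo("o1", "G", "TSS", ("BY",), "A" * 150, "C" * 201)
        kept, dropped = filter_blocks([OligoBlock("G", "TSS", [], [oligo])])
        assert not kept and "longer" in dropped[0][1]

    def test_clean_195_to_200bp_block_kept(self):
        oligo = Oligo("o1", "G", "TSS", ("BY",), "AT" * 72, "AT" * 100)
        kept, dropped = filter_blocks([OligoBlock("G", "TSS", [], [oligo])])
        assert kept and not dropped


class TestReverseComplementRule:
    def test_a_rich_is_flipped(self):
        oligo = Oligo("o", "G", "TSS", ("BY",), "", "A" * 10 + "T" * 5 + "C" * 5)
        out = maybe_reverse_complement(oligo)
        assert out.strand_flipped
        assert out.full_sequence == reverse_complement(oligo.full_sequence)

    def test_tie_not_flipped(self):
        oligo = Oligo("o", "G", "TSS", ("BY",), "", "ATATGC")
        assert not maybe_reverse_complement(oligo).strand_flipped

    @given(st.text(alphabet="ACGT", min_size=1, max_size=80))
    @settings(max_examples=50, deadline=None)
    def test_revcomp_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestBarcodes:
    def test_composition_rules(self):
        barcodes = generate_barcodes(2000, rng=np.random.default_rng(1))
        assert len(set(barcodes)) == 2000
        for bc in barcodes:
            assert bc[0] in "CT"
            for pos in (2, 3, 4, 6, 8, 10, 12, 14, 16, 18, 20):
                assert bc[pos - 1] != "G", f"G at even/early position {pos}"

    def test_zero_barcodes(self):
        assert generate_barcodes(0, rng=np.random.default_rng(0)) == []

    def test_space_size(self):
        assert barcode_space_size(20) == 2 * 3**11 * 4**8

    def test_space_exhaustion_raises(self):
        with pytest.raises(ValueError, match="exist"):
            generate_barcodes(2 * 3 + 1, length=2, rng=np.random.default_rng(0))

    def test_positionwise_uniformity_chi_square(self):
        """Every position is uniform over its legal alphabet (alpha=0.001)."""
        barcodes = generate_barcodes(100_000, rng=np.random.default_rng(2))
        arr = np.array([list(b) for b in barcodes])
        for pos in range(20):
            column = arr[:, pos]
            values, counts = np.unique(column, return_counts=True)
            p = stats.chisquare(counts).pvalue
            assert p > 0.001, f"position {pos + 1} non-uniform (p={p:.2e})"
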