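"""Ground-truth-known synthetic data for the MPRA pipeline.

The generator emulates the statistical structure the analysis assumes: toy
promoter references with BY/RM variants in the 144-bp TSS window, oligo
blocks designed from them, hundreds of random barcodes per oligo, replicate
DNA/RNA count matrices with negative-binomial noise in which the RNA mean of
a barcode is the DNA mean times 2^(baseline activity + planted allelic
effect + planted interaction) times a replicate library-size factor, and
gene-level eQTL effects equal to noisy sums of the planted variant effects.
A fixed seed makes every draw reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    FIVE_PRIME_ADAPTER,
    THREE_PRIME_ADAPTER,
    OligoBlock,
    VariantRecord,
    blocks_to_manifest,
    design_tss_block,
    generate_barcodes,
)
from .quantify import CountMatrix

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    n_genes: int = 100
    mean_variants_per_gene: float = 2.0  # the libraries' median is two per gene
    snv_fraction: float = 0.8
    causal_fraction: float = 0.11
    effect_sd: float = 0.5  # log2; most observed allelic effects are < 1 (2-fold)
    fixed_effect: float | None = None  # plant |effect| at this value instead
    interaction_fraction: float = 0.0
    n_replicates: int = 6
    barcodes_per_oligo: float = 100.0
    dna_mean: float = 50.0
    nb_dispersion: float = 0.1
    baseline_sd: float = 1.0  # log2 SD of log-normal baseline activities
    libsize_sd: float = 0.3  # log SD of replicate library-size factors
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snv_fraction", "causal_fraction", "interaction_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")
        for name in ("mean_variants_per_gene", "barcodes_per_oligo", "dna_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.effect_sd <= 0 or self.baseline_sd < 0 or self.libsize_sd < 0:
            raise ValueError("spread parameters must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Planted effects: log2 fold-changes per variant, pairwise interaction
    effects, and per-gene true summed cis effects (the noiseless sum)."""

    variant_effects: dict[str, float] = field(default_factory=dict)
    interaction_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    gene_effects: dict[str, float] = field(default_factory=dict)
    variant_gene: dict[str, str] = field(default_factory=dict)


CONTIG_LENGTH = 600
TSS_PLUS = 400  # 1-based TSS for plus-strand genes; window 256..399
TSS_MINUS = 200  # minus-strand TSS; window 201..344


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def simulate_promoters(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[VariantRecord], pd.DataFrame]:
    """Toy references, variant table and TSS table.

    One contig per gene; variants fall in the gene's 144-bp TSS window
    (1-based coordinates), with the SNV/indel mix set by ``snv_fraction``
    and indel lengths geometric on 1..20 bp.
    """
    rng = config.rng() if rng is None else rng
    reference: dict[str, str] = {}
    variants: list[VariantRecord] = []
    tss_rows = []
    for g in range(config.n_genes):
        gene = f"G{g:04d}"
        chrom = f"chr_{gene}"
        seq = _random_seq(rng, CONTIG_LENGTH)
        strand = "+" if rng.random() < 0.5 else "-"
        tss = TSS_PLUS if strand == "+" else TSS_MINUS
        if strand == "+":
            win_lo, win_hi = tss - 144, tss - 1  # 1-based inclusive
        else:
            win_lo, win_hi = tss + 1, tss + 144
        reference[chrom] = seq
        tss_rows.append({"gene": gene, "chrom": chrom, "tss_pos": tss, "strand": strand})

        k = min(int(rng.poisson(config.mean_variants_per_gene)), 4)
        if k == 0:
            continue
        # keep variants >= 25 bp apart so anchored indels never collide
        slots = np.arange(win_lo, win_hi - 21)
        positions = []
        for _ in range(200):
            cand = int(rng.choice(slots))
            if all(abs(cand - p) >= 25 for p in positions):
                positions.append(cand)
            if len(positions) == k:
                break
        for pos in sorted(positions):
            ref_base = seq[pos - 1]
            if rng.random() < config.snv_fraction:
                alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                ref = ref_base
            else:
                length = int(min(rng.geometric(0.5), 20))
                if rng.random() < 0.5:  # RM insertion
                    ref = ref_base
                    alt = ref_base + _random_seq(rng, length)
                else:  # RM deletion
                    ref = seq[pos - 1 : pos + length]
                    alt = ref_base
            variants.append(
                VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene)
            )
    return reference, variants, pd.DataFrame(tss_rows)


def plant_truth(
    variants: list[VariantRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> GroundTruth:
    """Assign each variant a planted log2 effect (0 for non-causal) and
    plant pairwise interactions between the first two variants of a gene."""
    truth = GroundTruth()
    by_gene: dict[str, list[str]] = {}
    for v in variants:
        causal = rng.random() < config.causal_fraction
        if not causal:
            effect = 0.0
        elif config.fixed_effect is not None:
            effect = config.fixed_effect * (1 if rng.random() < 0.5 else -1)
        else:
            effect = float(rng.normal(0.0, config.effect_sd))
        truth.variant_effects[v.vid] = effect
        truth.variant_gene[v.vid] = v.gene
        by_gene.setdefault(v.gene, []).append(v.vid)
    for gene, vids in by_gene.items():
        if len(vids) >= 2 and rng.random() < config.interaction_fraction:
            truth.interaction_effects[(vids[0], vids[1])] = float(
                rng.normal(0.0, config.effect_sd)
            )
        truth.gene_effects[gene] = float(
            sum(truth.variant_effects[v] for v in vids)
        )
    return truth


def design_blocks(
    reference: dict[str, str],
    variants: list[VariantRecord],
    tss_table: pd.DataFrame,
) -> list[OligoBlock]:
    """TSS oligo blocks for every gene with at least one variant."""
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_gene.setdefault(v.gene, []).append(v)
    blocks = []
    for row in tss_table.itertuples():
        vs = by_gene.get(row.gene, [])
        if not vs:
            continue
        blocks.append(
            design_tss_block(
                row.gene, row.chrom, row.tss_pos, row.strand, vs, reference
            )
        )
    return blocks


def assign_barcodes(
    manifest: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Poisson-many random barcodes per oligo (at least one)."""
    n_per = np.maximum(rng.poisson(config.barcodes_per_oligo, size=len(manifest)), 1)
    barcodes = generate_barcodes(int(n_per.sum()), rng=rng)
    rows, i = [], 0
    for oligo_id, n in zip(manifest["oligo_id"], n_per):
        for _ in range(n):
            rows.append({"barcode": barcodes[i], "oligo_id": oligo_id,
                         "reads": 1, "primary_fraction": 1.0})
            i += 1
    return pd.DataFrame(rows)


def _oligo_activity(manifest: pd.DataFrame, truth: GroundTruth,
                    baseline: dict[str, float]) -> pd.Series:
    """log2 activity per oligo: gene baseline + planted allelic effects of
    RM alleles + planted interaction when both partners carry RM."""
    acts = {}
    for row in manifest.itertuples():
        config = row.allele_config.split(",")
        vids = row.variants.split(";") if row.variants else []
        act = baseline[row.gene]
        rm = {v for v, a in zip(vids, config) if a == "RM"}
        act += sum(truth.variant_effects.get(v, 0.0) for v in rm)
        for (va, vb), eff in truth.interaction_effects.items():
            if va in rm and vb in rm:
                act += eff
        acts[row.oligo_id] = act
    return pd.Series(acts, name="log2_activity")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    manifest: pd.DataFrame,
    barcode_assignment: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, pd.Series]:
    """Barcode-level replicate DNA/RNA counts.

    Returns (CountMatrix, per-oligo true log2 activities).  DNA counts are
    negative binomial around ``dna_mean`` times a replicate size factor; RNA
    counts around ``dna_mean * 2**activity`` times its own size factor.
    """
    rng = config.rng() if rng is None else rng
    unknown = set(barcode_assignment["oligo_id"]) - set(manifest["oligo_id"])
    if unknown:
        raise ValueError(f"barcodes map to unknown oligos: {sorted(unknown)[:3]}")

    genes = manifest["gene"].unique()
    baseline = {
        g: float(rng.normal(0.0, config.baseline_sd)) for g in genes
    }
    activity = _oligo_activity(manifest, truth, baseline)
    per_bc_activity = activity.loc[barcode_assignment["oligo_id"]].to_numpy()
    n_bc = len(barcode_assignment)

    counts = {}
    sample_rows = {}
    for rep in range(1, config.n_replicates + 1):
        sf_dna = float(np.exp(rng.normal(0.0, config.libsize_sd)))
        sf_rna = float(np.exp(rng.normal(0.0, config.libsize_sd)))
        dna_mu = np.full(n_bc, config.dna_mean * sf_dna)
        rna_mu = config.dna_mean * (2.0 ** per_bc_activity) * sf_rna
        counts[f"DNA_rep{rep}"] = _nb_draw(rng, dna_mu, config.nb_dispersion)
        counts[f"RNA_rep{rep}"] = _nb_draw(rng, rna_mu, config.nb_dispersion)
        sample_rows[f"DNA_rep{rep}"] = {"assay": "DNA", "replicate": rep, "batch": "b1"}
        sample_rows[f"RNA_rep{rep}"] = {"assay": "RNA", "replicate": rep, "batch": "b1"}

    count_df = pd.DataFrame(counts, index=pd.Index(barcode_assignment["barcode"], name="barcode"))
    samples = pd.DataFrame.from_dict(sample_rows, orient="index")
    return CountMatrix(counts=count_df, samples=samples, level="barcode"), activity


def simulate_eqtl_table(
    truth: GroundTruth, noise_sd: float, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-gene local eQTL effects: true summed cis effect plus Gaussian
    noise, with a LOD-score proxy monotone in |effect| / noise."""
    rng = np.random.default_rng() if rng is None else rng
    rows = []
    for gene, true_eff in truth.gene_effects.items():
        obs = true_eff + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        lod = (obs / max(noise_sd, 1e-6)) ** 2 / (2.0 * np.log(10.0))
        rows.append({"gene": gene, "effect": obs, "lod": lod})
    return pd.DataFrame(rows)


def variant_comparisons(manifest: pd.DataFrame) -> pd.DataFrame:
    """BY/RM oligo pairs to test, one row per (variant, gene block).

    For TSS blocks the oligo with the RM allele at one variant is compared
    to the all-BY oligo; for Upstream blocks the two oligos are compared.
    """
    rows = []
    for (gene, library), grp in manifest.groupby(["gene", "library"]):
        configs = {
            row.oligo_id: tuple(row.allele_config.split(","))
            for row in grp.itertuples()
        }
        vids = grp["variants"].iloc[0].split(";")
        k = len(vids)
        by_all = next(
            (o for o, c in configs.items() if all(a == "BY" for a in c)), None
        )
        if by_all is None:
            continue
        for i, vid in enumerate(vids):
            want = tuple("RM" if j == i else "BY" for j in range(k))
            rm = next((o for o, c in configs.items() if c == want), None)
            if rm is None and k == 1:
                rm = next(
                    (o for o, c in configs.items() if c == ("RM",)), None
                )
            if rm is not None:
                rows.append(
                    {"variant": vid, "gene": gene, "library": library,
                     "strand": "+", "oligo_by": by_all, "oligo_rm": rm}
                )
    return pd.DataFrame(rows)


def reads_from_assignment(
    manifest: pd.DataFrame,
    barcode_assignment: pd.DataFrame,
    reads_per_barcode: int = 2,
) -> list[str]:
    """Well-formed merged amplicon reads reconstructed from the design, for
    exercising the annotation stage."""
    insert_of = manifest.set_index("oligo_id")["insert_sequence"]
    lib_of = manifest.set_index("oligo_id")["library"]
    reads = []
    for row in barcode_assignment.itertuples():
        lib = lib_of[row.oligo_id]
        read = (
            FIVE_PRIME_ADAPTER
            + insert_of[row.oligo_id]
            + THREE_PRIME_ADAPTER[lib]
            + row.barcode
        )
        reads.extend([read] * reads_per_barcode)
    return reads


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    reference: dict[str, str]
    variants: list[VariantRecord]
    tss_table: pd.DataFrame
    manifest: pd.DataFrame
    barcode_assignment: pd.DataFrame
    truth: GroundTruth
    counts: CountMatrix
    oligo_activity: pd.Series
    comparisons: pd.DataFrame


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Run the generator end to end: promoters -> blocks -> barcodes ->
    counts, with the planted truth attached."""
    rng = config.rng()
    reference, variants, tss_table = simulate_promoters(config, rng)
    truth = plant_truth(variants, config, rng)
    blocks = design_blocks(reference, variants, tss_table)
    manifest = blocks_to_manifest(blocks)
    if manifest.empty:
        raise ValueError("simulation produced no oligos; increase n_genes")
    assignment = assign_barcodes(manifest, config, rng)
    counts, activity = simulate_counts(manifest, assignment, truth, config, rng)
    comparisons = variant_comparisons(manifest)
    return SimulatedExperiment(
        config=config,
        reference=reference,
        variants=variants,
        tss_table=tss_table,
        manifest=manifest,
        barcode_assignment=assignment,
        truth=truth,
        counts=counts,
        oligo_activity=activity,
        comparisons=comparisons,
    )
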