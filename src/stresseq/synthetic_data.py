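"""Ground-truth synthetic data for every stage of the pipeline.

Emulates the study design the pipeline targets: two strains (WT and a
regulator-cluster mutant) x two conditions (unstressed / peroxide-stressed)
x two biological replicates of stranded paired-end mapped reads over a toy
high-GC (0.72) single-replicon genome, with a designated set of up- and
down-regulated genes of known log2 fold change.  The mutant is simulated as
fully deregulated: every planted gene has fold change 1 in the mutant, so a
mutant contrast should call (almost) nothing.

Per-gene fragment counts are negative binomial around condition-specific
means; fragments are placed uniformly within the CDS with Gaussian insert
lengths, and configurable fractions of orphan mates (one mate lost) and
wide pairs (outer span > 1 kb) exercise the single-read retention and
pair-discard rules of the assembly step.

Also generates 200-bp upstream promoter regions with planted, degenerate
copies of a reference operator site (exact mismatch count, hence known
expected percent identity), and qRT-PCR crossing-point tables with known
true fold changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CdsFeature, write_annotation_gff3
from .motif_scan import SENR_SITE_III, ungapped_identity
from .qpcr import CpRecord

logger = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype="S1")

STRAIN_WT = "WT"
STRAIN_MUTANT = "mutant"
COND_UNSTRESSED = "unstressed"
COND_STRESSED = "stressed"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the emulated experiment: 1000 genes on a GC-0.72
    replicon, 30 up- and 30 down-regulated genes at |log2FC| = 3 in the
    stressed wild type, 2 biological replicates per strain/condition,
    200k fragments per library of 75-bp paired reads with ~200-bp inserts.
    """

    seed: int = 42
    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (300, 3000)
    gc_content: float = 0.72
    n_up: int = 30
    n_down: int = 30
    log2fc: float = 3.0
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.01
    fragments_per_sample: int = 200_000
    insert_mean: float = 200.0
    insert_sd: float = 30.0
    orphan_rate: float = 0.05
    wide_pair_rate: float = 0.01
    read_len: int = 75
    intergenic_bp: int = 250
    upstream_len: int = 200
    n_replicates: int = 2
    ref_id: str = "toygenome"

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("more planted DE genes than genes")
        for rate in (self.orphan_rate, self.wide_pair_rate, self.gc_content):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p).tobytes().decode()


# ---------------------------------------------------------------------------
# genome


def simulate_genome(
    config: SimConfig,
) -> tuple[str, list[CdsFeature], pd.DataFrame]:
    """Toy single-replicon genome with non-overlapping CDSs on both strands.

    Returns the genome sequence, the annotation, and the truth table with
    each gene's baseline expression weight (lognormal) and planted log2
    fold change (0 for null genes).  Fully deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    strands = rng.choice(np.array(["+", "-"]), size=config.n_genes)

    gap = config.intergenic_bp
    if gap < 1:
        raise ValueError("genes cannot be placed without overlap; use a larger replicon (intergenic_bp >= 1)")
    features: list[CdsFeature] = []
    pos = gap
    for i in range(config.n_genes):
        start = pos
        end = start + int(lengths[i])
        features.append(
            CdsFeature(config.ref_id, start, end, f"GENE{i:04d}", str(strands[i]))
        )
        pos = end + gap
    genome = _random_sequence(rng, pos, config.gc_content)

    baseline = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sd, size=config.n_genes
    )
    log2fc = np.zeros(config.n_genes)
    de_idx = rng.choice(config.n_genes, size=config.n_up + config.n_down, replace=False)
    log2fc[de_idx[: config.n_up]] = config.log2fc
    log2fc[de_idx[config.n_up :]] = -config.log2fc

    truth = pd.DataFrame(
        {
            "gene_id": [f.gene_id for f in features],
            "ref_id": config.ref_id,
            "start": [f.start for f in features],
            "end": [f.end for f in features],
            "strand": [f.strand for f in features],
            "length_bp": [f.length_bp for f in features],
            "baseline_weight": baseline,
            "log2fc": log2fc,
        }
    ).set_index("gene_id", drop=False)
    return genome, features, truth


# ---------------------------------------------------------------------------
# reads


def sample_plan(config: SimConfig) -> list[dict]:
    """The 2 strains x 2 conditions x n_replicates library layout."""
    plan = []
    for strain in (STRAIN_WT, STRAIN_MUTANT):
        for condition in (COND_UNSTRESSED, COND_STRESSED):
            for rep in range(1, config.n_replicates + 1):
                plan.append(
                    {
                        "sample_id": f"{strain}_{condition}_r{rep}",
                        "strain": strain,
                        "condition": condition,
                        "replicate": rep,
                    }
                )
    return plan


def _nb_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial counts with Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(means)
    size = 1.0 / dispersion
    p = size / (size + means)
    return rng.negative_binomial(size, p)


def _sample_sam_lines(
    rng: np.random.Generator,
    truth: pd.DataFrame,
    config: SimConfig,
    fold: np.ndarray,
    sample_id: str,
    genome_len: int,
) -> list[str]:
    w = truth["baseline_weight"].to_numpy() * fold
    means = config.fragments_per_sample * w / w.sum()
    counts = _nb_counts(rng, means, config.nb_dispersion)

    gene_idx = np.repeat(np.arange(len(truth)), counts)
    n = len(gene_idx)
    g_start = truth["start"].to_numpy()[gene_idx]
    g_end = truth["end"].to_numpy()[gene_idx]
    g_len = g_end - g_start
    g_strand = truth["strand"].to_numpy()[gene_idx]

    rlen = config.read_len
    insert = np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n)).astype(
        np.int64
    )
    insert = np.maximum(insert, rlen)
    truncated = insert > g_len
    if truncated.any():
        logger.warning(
            "%s: %d inserts longer than their gene; truncated", sample_id, int(truncated.sum())
        )
        insert = np.minimum(insert, g_len)
    start = g_start + (rng.random(n) * (g_len - insert + 1)).astype(np.int64)

    u = rng.random(n)
    wide = u < config.wide_pair_rate
    orphan = (~wide) & (u < config.wide_pair_rate + config.orphan_rate)

    # mate intervals: mate1 at the fragment's 5' end on the fragment strand
    left1 = np.where(g_strand == "+", start, start + insert - rlen)
    left2 = np.where(g_strand == "+", start + insert - rlen, start)
    # wide pairs: push mate2 out beyond the 1 kb combination limit
    span = 1001 + rng.integers(0, 1000, size=n)
    wstart = np.minimum(start, genome_len - span - 1)
    wleft2 = np.where(g_strand == "+", wstart + span - rlen, wstart)
    wleft1 = np.where(g_strand == "+", wstart, wstart + span - rlen)
    left1 = np.where(wide, wleft1, left1)
    left2 = np.where(wide, wleft2, left2)

    m1_rev = g_strand == "-"
    m2_rev = ~m1_rev
    keep_first = rng.random(n) < 0.5  # which mate an orphan keeps

    flag1 = 0x1 | 0x40 | np.where(m1_rev, 0x10, 0) | np.where(m2_rev, 0x20, 0)
    flag2 = 0x1 | 0x80 | np.where(m2_rev, 0x10, 0) | np.where(m1_rev, 0x20, 0)
    flag1 = np.where(orphan & keep_first, flag1 | 0x8, flag1)
    flag2 = np.where(orphan & ~keep_first, flag2 | 0x8, flag2)

    cigar = f"{rlen}M"
    ref = config.ref_id
    lines: list[str] = []
    emit1 = ~orphan | keep_first
    emit2 = ~orphan | ~keep_first
    for i in range(n):
        qname = f"{sample_id}:{i}"
        if emit1[i]:
            lines.append(
                f"{qname}\t{int(flag1[i])}\t{ref}\t{int(left1[i]) + 1}\t255\t{cigar}\t*\t0\t0\t*\t*\n"
            )
        if emit2[i]:
            lines.append(
                f"{qname}\t{int(flag2[i])}\t{ref}\t{int(left2[i]) + 1}\t255\t{cigar}\t*\t0\t0\t*\t*\n"
            )
    return lines


def simulate_reads(
    config: SimConfig, truth: pd.DataFrame, out_dir: str | Path
) -> dict[str, Path]:
    """Write one SAM file of mapped paired reads per sample.

    WT stressed libraries express the planted genes at ``2**log2fc`` times
    their baseline; all other libraries (including both mutant conditions)
    are at baseline.  Returns sample_id -> SAM path and writes a
    ``manifest.tsv`` alongside.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    genome_len = int(truth["end"].max()) + config.intergenic_bp

    header = f"@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:{config.ref_id}\tLN:{genome_len}\n"
    paths: dict[str, Path] = {}
    manifest_rows = []
    for sample in sample_plan(config):
        stressed_wt = (
            sample["strain"] == STRAIN_WT and sample["condition"] == COND_STRESSED
        )
        fold = 2.0 ** truth["log2fc"].to_numpy() if stressed_wt else np.ones(len(truth))
        lines = _sample_sam_lines(
            rng, truth, config, fold, sample["sample_id"], genome_len
        )
        path = out_dir / f"{sample['sample_id']}.sam"
        with open(path, "w") as fh:
            fh.write(header)
            fh.writelines(lines)
        paths[sample["sample_id"]] = path
        manifest_rows.append({**sample, "reads_path": str(path)})
    pd.DataFrame(manifest_rows).to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# upstream regions / motif planting


@dataclass(frozen=True)
class PlantSpec:
    """One planted operator copy: length-L window of the reference with
    exactly k mismatches (expected reported identity round(100*(L-k)/L))."""

    gene_id: str
    length: int
    mismatches: int


def resolve_mismatches(length: int, target_identity: int) -> int:
    """Mismatch count k whose rounded identity 100*(L-k)/L hits the target."""
    achievable = {}
    for k in range(length + 1):
        achievable[int(math.floor(100.0 * (length - k) / length + 0.5))] = k
    if target_identity not in achievable:
        raise ValueError(
            f"identity {target_identity}% unreachable at length {length}; "
            f"achievable: {sorted(achievable, reverse=True)}"
        )
    return achievable[target_identity]


def plant_motifs(
    config: SimConfig,
    reference: str = SENR_SITE_III,
    plants: Sequence[PlantSpec] | None = None,
    n_regions: int = 20,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Upstream regions (at genome GC) with planted degenerate operator copies.

    Returns ``{gene_id: upstream_seq}`` and a truth table with the planted
    position, mismatch count, expected reported identity and distance to the
    start codon.  Regions not named in ``plants`` carry no planted site.
    """
    rng = np.random.default_rng(config.seed + 2)
    L_ref = len(reference)
    if plants is None:
        # a spread of site lengths and degeneracies, akin to a predicted-
        # operator table: full-length exact copy down to heavily degenerate
        plants = [
            PlantSpec("GENE0000", 16, 0),
            PlantSpec("GENE0001", 10, 1),
            PlantSpec("GENE0002", 11, 1),
            PlantSpec("GENE0003", 15, 2),
            PlantSpec("GENE0004", 14, 4),
            PlantSpec("GENE0005", 16, 5),
        ]
    planted_ids = [p.gene_id for p in plants]
    region_ids = planted_ids + [
        f"GENE{i:04d}"
        for i in range(config.n_genes)
        if f"GENE{i:04d}" not in set(planted_ids)
    ]
    region_ids = region_ids[:max(n_regions, len(planted_ids))]

    ulen = config.upstream_len
    regions = {g: _random_sequence(rng, ulen, config.gc_content) for g in region_ids}

    rows = []
    for spec in plants:
        if not 4 <= spec.length <= L_ref:
            raise ValueError(f"site length {spec.length} outside 4..{L_ref}")
        if spec.mismatches > spec.length:
            raise ValueError("more mismatches than positions")
        offset = int(rng.integers(0, L_ref - spec.length + 1))
        site = list(reference[offset : offset + spec.length])
        mut_pos = rng.choice(spec.length, size=spec.mismatches, replace=False)
        for p in mut_pos:
            alternatives = [b for b in "ACGT" if b != site[p]]
            site[p] = alternatives[int(rng.integers(0, 3))]
        site = "".join(site)
        pos = int(rng.integers(0, ulen - spec.length + 1))
        seq = regions[spec.gene_id]
        regions[spec.gene_id] = seq[:pos] + site + seq[pos + spec.length :]
        expected = int(
            math.floor(100.0 * (spec.length - spec.mismatches) / spec.length + 0.5)
        )
        rows.append(
            {
                "gene_id": spec.gene_id,
                "planted_site": site,
                "position": pos,
                "length": spec.length,
                "mismatches": spec.mismatches,
                "expected_identity": expected,
                "distance_to_start": ulen - (pos + spec.length),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "planted_site", "position", "length",
            "mismatches", "expected_identity", "distance_to_start",
        ],
    )
    return regions, truth


def write_upstream_fasta(regions: Mapping[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=g, description="") for g, s in regions.items()]
    seqio_write(records, str(path), "fasta")


def write_genome_fasta(genome: str, config: SimConfig, path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(genome), id=config.ref_id, description="")], str(path), "fasta"
    )


# ---------------------------------------------------------------------------
# qPCR crossing points


def simulate_cp(
    true_folds: Mapping[str, float],
    noise_sd: float = 0.15,
    tech_sd: float = 0.05,
    n_bio: int = 3,
    n_tech: int = 2,
    base_cp: float = 20.0,
    strain: str = STRAIN_WT,
    seed: int | np.random.Generator = 0,
) -> list[CpRecord]:
    """CP tables for a stressed-vs-unstressed contrast with known fold change.

    The stressed condition's true CP is ``base_cp - log2(fold)`` (one cycle
    earlier per doubling of template); each biological replicate adds
    Gaussian noise of ``noise_sd`` cycles and each technical replicate a
    smaller ``tech_sd`` jitter.  ``noise_sd=0`` gives exact inversion:
    the analysed relative amount equals the true fold.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    records: list[CpRecord] = []
    for gene_id, fold in true_folds.items():
        if fold <= 0:
            raise ValueError("fold changes must be positive")
        for condition, true_cp in (
            (COND_UNSTRESSED, base_cp),
            (COND_STRESSED, base_cp - math.log2(fold)),
        ):
            for bio in range(1, n_bio + 1):
                bio_cp = true_cp + rng.normal(0.0, noise_sd)
                for tech in range(1, n_tech + 1):
                    records.append(
                        CpRecord(
                            gene_id=gene_id,
                            strain=strain,
                            condition=condition,
                            bio_rep=bio,
                            tech_rep=tech,
                            cp=bio_cp + rng.normal(0.0, tech_sd),
                        )
                    )
    return records


def write_cp_table(records: Sequence[CpRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# one-call dataset


def simulate_dataset(config: SimConfig, out_dir: str | Path) -> dict[str, object]:
    """Write the full synthetic dataset: genome FASTA, GFF3 annotation,
    per-sample SAM files, upstream FASTA, CP table and truth TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome, annotation, truth = simulate_genome(config)
    write_genome_fasta(genome, config, out_dir / "genome.fasta")
    write_annotation_gff3(annotation, out_dir / "annotation.gff3")
    truth.to_csv(out_dir / "truth_genes.tsv", sep="\t", index=False)
    sam_paths = simulate_reads(config, truth, out_dir / "reads")
    regions, motif_truth = plant_motifs(config)
    write_upstream_fasta(regions, out_dir / "upstream.fasta")
    motif_truth.to_csv(out_dir / "truth_motifs.tsv", sep="\t", index=False)
    cp_records = simulate_cp({"GENE0000": 5.0, "GENE0001": 1.0}, seed=config.seed + 3)
    write_cp_table(cp_records, out_dir / "cp_table.tsv")
    return {
        "annotation": annotation,
        "truth": truth,
        "sam_paths": sam_paths,
        "motif_truth": motif_truth,
    }
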