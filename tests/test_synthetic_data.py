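"""Determinism, composition and closed-loop consistency of the generator."""

import numpy as np
import pandas as pd
import pytest

from stresseq.expression import rpkm_matrix
from stresseq.fragment_assembly import assemble_fragments
from stresseq.io_formats import read_mapped_reads
from stresseq.motif_scan import SENR_SITE_III, scan_upstream, ungapped_identity
from stresseq.pipeline import quantify_samples
from stresseq.synthetic_data import (
    PlantSpec,
    SimConfig,
    plant_motifs,
    resolve_mismatches,
    simulate_genome,
    simulate_reads,
)

SMALL = SimConfig(
    seed=1, n_genes=60, n_up=4, n_down=4, fragments_per_sample=6000,
    gene_length_range=(400, 1200),
)


class TestGenome:
    def test_deterministic_under_seed(self):
        g1, a1, t1 = simulate_genome(SMALL)
        g2, a2, t2 = simulate_genome(SMALL)
        assert g1 == g2
        assert a1 == a2
        pd.testing.assert_frame_equal(t1, t2)

    def test_gene_count_and_lengths(self):
        cfg = SimConfig(seed=2, n_genes=10, n_up=2, n_down=2,
                        gene_length_range=(500, 500))
        _, ann, truth = simulate_genome(cfg)
        assert len(ann) == 10
        assert all(f.length_bp == 500 for f in ann)
        assert (truth["log2fc"] != 0).sum() == cfg.n_up + cfg.n_down

    def test_cds_non_overlapping_and_sorted(self):
        _, ann, _ = simulate_genome(SMALL)
        for a, b in zip(ann, ann[1:]):
            assert a.end < b.start

    def test_gc_content_within_one_percent(self):
        genome, _, _ = simulate_genome(SimConfig(seed=3, n_genes=100))
        assert len(genome) >= 100_000
        gc = (genome.count("G") + genome.count("C")) / len(genome)
        assert abs(gc - 0.72) <= 0.01


@pytest.fixture(scope="module")
def dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("reads")
    _, ann, truth = simulate_genome(SMALL)
    paths = simulate_reads(SMALL, truth, out)
    return ann, truth, paths


class TestReads:

    def test_sam_files_deterministic(self, dataset, tmp_path):
        _, truth, paths = dataset
        again = simulate_reads(SMALL, truth, tmp_path)
        sample = "WT_stressed_r1"
        assert paths[sample].read_bytes() == again[sample].read_bytes()

    def test_read_conservation_on_every_sample(self, dataset):
        _, _, paths = dataset
        for path in paths.values():
            _, st = assemble_fragments(read_mapped_reads(path))
            assert (
                2 * st.combined + 2 * st.discarded_pairs + st.singles
                == st.total_reads
            )

    def test_orphan_and_wide_rates_exercised(self, dataset):
        _, _, paths = dataset
        _, st = assemble_fragments(read_mapped_reads(paths["WT_unstressed_r1"]))
        assert st.discarded_pairs > 0  # wide pairs planted
        assert st.singles > 0  # orphans planted

    def test_clean_config_yields_only_paired_fragments(self, tmp_path):
        cfg = SimConfig(
            seed=4, n_genes=20, n_up=0, n_down=0, fragments_per_sample=2000,
            orphan_rate=0.0, wide_pair_rate=0.0,
        )
        _, _, truth = simulate_genome(cfg)
        paths = simulate_reads(cfg, truth, tmp_path)
        frags, st = assemble_fragments(read_mapped_reads(paths["WT_unstressed_r1"]))
        assert st.discarded_pairs == 0 and st.singles == 0
        assert all(f.origin == "paired" for f in frags)

    def test_counts_track_expected_means_with_low_dispersion(self, tmp_path):
        cfg = SimConfig(
            seed=5, n_genes=100, n_up=0, n_down=0, nb_dispersion=0.0,
            fragments_per_sample=50_000, orphan_rate=0.0, wide_pair_rate=0.0,
            baseline_log_sd=0.0,  # equal expression: expected 500 per gene
        )
        _, ann, truth = simulate_genome(cfg)
        paths = simulate_reads(cfg, truth, tmp_path)
        matrix, _ = quantify_samples(
            {"s": paths["WT_unstressed_r1"]}, ann
        )
        counts = matrix.counts["s"]
        # Poisson with mean 500: all genes within ~4 sigma
        assert ((counts - 500).abs() < 4 * np.sqrt(500)).all()
        assert counts.sum() == pytest.approx(50_000, rel=0.02)

    def test_mutant_samples_show_no_planted_fold_change(self, dataset):
        ann, truth, paths = dataset
        matrix, _ = quantify_samples(
            {k: paths[k] for k in paths if k.startswith("mutant")}, ann
        )
        rp = rpkm_matrix(matrix)
        m = np.log2(rp[["mutant_stressed_r1", "mutant_stressed_r2"]].mean(axis=1)) - \
            np.log2(rp[["mutant_unstressed_r1", "mutant_unstressed_r2"]].mean(axis=1))
        planted = truth.loc[truth["log2fc"] != 0, "gene_id"]
        assert abs(m[planted].mean()) < 0.3


class TestMotifPlanting:
    def test_exact_copy_recovered_at_planted_position(self):
        regions, truth = plant_motifs(SMALL, plants=[PlantSpec("GENE0000", 16, 0)])
        row = truth.iloc[0]
        hits = scan_upstream(regions["GENE0000"], min_identity=100)
        # ties at 100% prefer longer windows, so the winning hit may extend
        # beyond the plant but must cover it
        assert any(
            h.pct_identity == 100.0
            and h.upstream_position <= row["position"]
            and h.upstream_position + h.length >= row["position"] + row["length"]
            for h in hits
        )

    def test_planted_site_scores_expected_identity(self):
        plants = [PlantSpec("GENE0001", 10, 1), PlantSpec("GENE0002", 14, 3)]
        _, truth = plant_motifs(SMALL, plants=plants)
        for _, row in truth.iterrows():
            hit = ungapped_identity(row["planted_site"], SENR_SITE_III)
            assert hit.reported_identity >= row["expected_identity"]
        assert truth.loc[truth["length"] == 10, "expected_identity"].iloc[0] == 90

    def test_unreachable_identity_lists_achievable_values(self):
        with pytest.raises(ValueError, match="achievable"):
            resolve_mismatches(10, 95)
        assert resolve_mismatches(10, 90) == 1
        assert resolve_mismatches(16, 100) == 0

    def test_background_hit_rate_low_at_high_identity(self):
        # the empirical null of the scanner: at GC 0.72 the background
        # resembles the GC-rich operator, so moderate-identity windows are
        # common (~30% of regions at 85%) while near-exact ones stay rare
        cfg = SimConfig(seed=6, n_genes=200)
        regions, _ = plant_motifs(cfg, plants=[], n_regions=100)
        with_hit = sum(
            bool(scan_upstream(seq, min_identity=95)) for seq in regions.values()
        )
        assert with_hit / len(regions) < 0.05

    def test_gc_rich_background_inflates_moderate_identity_null(self):
        high = SimConfig(seed=6, n_genes=200)
        low = SimConfig(seed=6, n_genes=200, gc_content=0.5)
        rate = {}
        for name, cfg in (("high", high), ("low", low)):
            regions, _ = plant_motifs(cfg, plants=[], n_regions=60)
            rate[name] = sum(
                bool(scan_upstream(s, min_identity=85)) for s in regions.values()
            ) / len(regions)
        assert rate["high"] > rate["low"]

    def test_deterministic_under_seed(self):
        r1, t1 = plant_motifs(SMALL)
        r2, t2 = plant_motifs(SMALL)
        assert r1 == r2
        pd.testing.assert_frame_equal(t1, t2)
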