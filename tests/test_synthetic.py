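"""Generator determinism, conservation laws and planted-effect fidelity."""

import numpy as np
import pandas as pd
import pytest

from bifate import synthetic
from bifate.motifs import Motif, scan_motif
from bifate.synthetic import SimulationConfig


def small_config(**kw):
    defaults = dict(seed=5, n_genes=120, n_chroms=2, chrom_length=2_400_000,
                    background_peak_count=20)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenome:
    def test_deterministic_for_fixed_seed(self):
        a, _ = synthetic.simulate_genome(small_config())
        b, _ = synthetic.simulate_genome(small_config())
        pd.testing.assert_frame_equal(a, b)

    def test_zero_genes_empty_table(self):
        table, sizes = synthetic.simulate_genome(small_config(n_genes=0))
        assert len(table) == 0 and len(sizes) == 2

    def test_per_chrom_counts_sum(self):
        table, _ = synthetic.simulate_genome(small_config(n_genes=101))
        assert table.groupby("chrom").size().sum() == 101

    def test_tss_within_bounds_and_ids_unique(self):
        cfg = small_config()
        table, sizes = synthetic.simulate_genome(cfg)
        assert table["gene"].is_unique
        assert (table["tss"] >= 0).all()
        assert (table["tss"] < cfg.chrom_length).all()

    def test_invalid_config_raises(self):
        with pytest.raises(ValueError):
            synthetic.simulate_genome(small_config(chrom_length=-5))


class TestLabels:
    def test_class_counts_match_fractions(self):
        cfg = small_config(n_genes=1000)
        table, _ = synthetic.simulate_genome(cfg)
        labels = synthetic.assign_gene_labels(cfg, table)
        counts = pd.Series(labels).value_counts()
        for cls, frac in cfg.class_fractions.items():
            assert abs(counts.get(cls, 0) - frac * 1000) <= 1


class TestExpression:
    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            small_config(nb_dispersion=-0.1).validate()

    def test_unknown_label_rejected(self):
        cfg = small_config()
        with pytest.raises(ValueError, match="unknown gene labels"):
            synthetic.simulate_expression(cfg, {"g1": "mystery_class"})

    def test_low_dispersion_recovers_planted_log2fc(self):
        # law-of-large-numbers check: tiny dispersion, many replicates
        cfg = small_config(n_genes=400, nb_dispersion=0.001, n_replicates_expr=10,
                          baseline_mean=500.0)
        table, _ = synthetic.simulate_genome(cfg)
        labels = synthetic.assign_gene_labels(cfg, table)
        m = synthetic.simulate_expression(cfg, labels)
        teno = m.samples_of(["remote_tenocyte", "adjacent_tenocyte"])
        chon = m.samples_of(["remote_chondrocyte", "adjacent_chondrocyte"])
        lab = pd.Series(labels)
        for cls in ("tenogenic_mixed", "chondrogenic_mixed"):
            genes = lab.index[lab == cls]
            # per-sample library factors cancel in the cross-gene mean ratio
            # only approximately; normalize by the unclassified baseline
            base = lab.index[lab == "unclassified"]
            ratio_t = m.counts.loc[genes, teno].mean().mean() / m.counts.loc[base, teno].mean().mean()
            ratio_c = m.counts.loc[genes, chon].mean().mean() / m.counts.loc[base, chon].mean().mean()
            observed = np.log2(ratio_t / ratio_c)
            expected = cfg.planted_log2fc if cls == "tenogenic_mixed" else -cfg.planted_log2fc
            assert observed == pytest.approx(expected, abs=0.2)

    def test_null_config_flat_means(self):
        cfg = small_config(planted_log2fc=0.0, nb_dispersion=0.0)
        table, _ = synthetic.simulate_genome(cfg)
        labels = synthetic.assign_gene_labels(cfg, table)
        m = synthetic.simulate_expression(cfg, labels)
        lab = pd.Series(labels)
        planted = m.counts.loc[lab.index[lab == "tenogenic_mixed"]].mean(axis=1)
        flat = m.counts.loc[lab.index[lab == "unclassified"]].mean(axis=1)
        assert planted.mean() == pytest.approx(flat.mean(), rel=0.1)


class TestAtac:
    def test_total_peak_conservation(self):
        cfg = small_config()
        table, _ = synthetic.simulate_genome(cfg)
        labels = synthetic.assign_gene_labels(cfg, table)
        ds = synthetic.simulate_atac(cfg, labels, table)
        n_labelled = sum(1 for l in labels.values() if l != "unclassified")
        assert len(ds.peak_coords) == cfg.n_genes + n_labelled + cfg.background_peak_count

    def test_planted_class_controls_expected_counts(self):
        cfg = small_config()
        table, _ = synthetic.simulate_genome(cfg)
        labels = synthetic.assign_gene_labels(cfg, table)
        ds = synthetic.simulate_atac(cfg, labels, table)
        share = ds.ground_truth.peak_sharing
        tissue_cols = {t: [s for s in ds.counts.columns if ds.tissue_map[s] == t]
                       for t in ("tenocyte", "attachment", "chondrocyte")}
        ac_peaks = [p for p, c in share.items() if c == "AC" and p.startswith("dist_")]
        assert ac_peaks
        teno_mean = ds.counts.loc[ac_peaks, tissue_cols["tenocyte"]].mean().mean()
        att_mean = ds.counts.loc[ac_peaks, tissue_cols["attachment"]].mean().mean()
        assert teno_mean < 30 < att_mean

    def test_replicate_beds_list_only_open_tissues(self):
        cfg = small_config()
        table, _ = synthetic.simulate_genome(cfg)
        labels = synthetic.assign_gene_labels(cfg, table)
        ds = synthetic.simulate_atac(cfg, labels, table)
        ta_peaks = {p for p, c in ds.ground_truth.peak_sharing.items() if c == "TA"}
        chon_bed = set(ds.replicate_beds["chondrocyte_rep1"]["name"])
        assert not (ta_peaks & chon_bed)

    def test_excessive_peak_width_rejected(self):
        cfg = small_config()
        cfg.peak_width_range = (100, 5_000_000)
        with pytest.raises(ValueError):
            cfg.validate()


class TestMotifPlanting:
    def test_bearing_peaks_contain_consensus(self):
        cfg = small_config()
        table, _ = synthetic.simulate_genome(cfg)
        labels = synthetic.assign_gene_labels(cfg, table)
        ds = synthetic.simulate_atac(cfg, labels, table)
        sequences, motif = synthetic.plant_motifs(ds.peak_coords, ds.ground_truth, cfg)
        for pid in ds.ground_truth.motif_bearing_peaks:
            assert len(scan_motif(sequences[pid], motif)) >= 1

    def test_enrichment_ratio_one_equalizes_fractions(self):
        cfg = small_config(n_genes=600, chrom_length=12_000_000,
                          motif_enrichment_ratio=1.0, motif_p_fg=0.5,
                          background_peak_count=0)
        table, _ = synthetic.simulate_genome(cfg)
        labels = synthetic.assign_gene_labels(cfg, table)
        ds = synthetic.simulate_atac(cfg, labels, table)
        synthetic.plant_motifs(ds.peak_coords, ds.ground_truth, cfg)
        bearing = ds.ground_truth.motif_bearing_peaks
        fg_labels = {"tenogenic_mixed", "chondrogenic_mixed", "attachment_up"}
        link, glab = ds.ground_truth.peak_gene_link, ds.ground_truth.gene_labels
        fg = [p for p in ds.peak_coords["name"] if link[p] and glab[link[p]] in fg_labels]
        bg = [p for p in ds.peak_coords["name"] if p not in fg]
        frac_fg = np.mean([p in bearing for p in fg])
        frac_bg = np.mean([p in bearing for p in bg])
        # both arms planted at 0.5; allow 4 sigma of the smaller arm
        assert abs(frac_fg - frac_bg) < 4 * np.sqrt(0.25 / min(len(fg), len(bg)))

    def test_invalid_consensus_rejected(self):
        with pytest.raises(ValueError):
            small_config(motif_consensus="CACQC").validate()


class TestDatasetDeterminism:
    def test_written_files_hash_equal(self, tmp_path):
        import hashlib

        cfg = small_config()
        hashes = []
        for sub in ("a", "b"):
            ds = synthetic.simulate_dataset(small_config())
            paths = synthetic.write_dataset(ds, tmp_path / sub)
            digest = hashlib.sha256()
            for key in sorted(paths):
                digest.update((tmp_path / paths[key]).read_bytes())
            hashes.append(digest.hexdigest())
        assert hashes[0] == hashes[1]
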