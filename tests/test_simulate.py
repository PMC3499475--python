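"""Ground-truth generators: determinism, feasibility, and planted structure."""

import numpy as np
import pandas as pd
import pytest

from nrcistrome import (
    CapacityError,
    SimulationConfig,
    ValidationError,
    annotate_peaks,
    best_arrangement,
    filter_peaks,
    generate_genes,
    generate_peak_sequences,
    generate_peaks,
    generate_expression,
    location_distribution,
    scan_half_sites,
)
from nrcistrome.simulate import _category_window


def dummy_peaks(n: int) -> pd.DataFrame:
    return pd.DataFrame({"peak_id": [f"p{i:05d}" for i in range(n)]})


class TestConfigValidation:
    def test_mixture_must_sum_to_one(self):
        cfg = SimulationConfig(location_mixture={"ingene": 0.5, "promoter": 0.4})
        with pytest.raises(ValidationError):
            cfg.validate()

    def test_nonpositive_noise_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(noise_sd=0.0).validate()

    def test_window_shorter_than_element_rejected(self):
        cfg = SimulationConfig(motif_mixture={"ER8": 1.0}, seq_flank=9)
        with pytest.raises(ValidationError):
            cfg.validate()

    def test_malformed_motif_key_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(motif_mixture={"XR1": 1.0}).validate()


class TestGenes:
    def test_deterministic_given_seed(self, small_config):
        a = generate_genes(small_config)
        b = generate_genes(small_config)
        assert a.to_csv() == b.to_csv()

    def test_different_seed_differs(self, small_config):
        a = generate_genes(small_config)
        b = generate_genes(SimulationConfig(**{**small_config.__dict__, "seed": 8}))
        assert not a.equals(b)

    def test_no_overlap_brute_force(self):
        cfg = SimulationConfig(seed=2, n_genes=10, n_chroms=2, chrom_length=8_000_000)
        genes = generate_genes(cfg)
        assert len(genes) == 10
        rows = list(genes.itertuples(index=False))
        for i, a in enumerate(rows):
            for b in rows[i + 1 :]:
                if a.chrom == b.chrom:
                    assert a.end <= b.start or b.end <= a.start

    def test_end_clearance(self, small_config):
        genes = generate_genes(small_config)
        assert (genes["start"] >= 100_000).all()
        assert (genes["end"] <= small_config.chrom_length - 100_000).all()

    def test_zero_genes(self):
        assert len(generate_genes(SimulationConfig(n_genes=0))) == 0

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            generate_genes(SimulationConfig(n_genes=1_000, n_chroms=1, chrom_length=2_000_000))


class TestPeaks:
    def test_promoter_only_mixture(self):
        cfg = SimulationConfig(seed=4, n_genes=30, n_chroms=2, chrom_length=10_000_000,
                               location_mixture={"promoter": 1.0})
        genes = generate_genes(cfg)
        peaks, truth = generate_peaks(genes, cfg)
        gene_rows = {g.gene_id: g for g in genes.itertuples(index=False)}
        for p in peaks.itertuples(index=False):
            gene = gene_rows[truth.anchor_gene_by_peak[p.peak_id]]
            lo, hi = _category_window("promoter", gene.strand, gene.start, gene.end)
            assert lo <= p.summit < hi

    def test_frac_bound_zero_no_peaks(self, small_config):
        genes = generate_genes(small_config)
        cfg = SimulationConfig(**{**small_config.__dict__, "frac_bound": 0.0})
        peaks, truth = generate_peaks(genes, cfg)
        assert len(peaks) == 0 and truth.bound_genes == set()

    def test_bound_gene_count_exact_after_filtering(self):
        cfg = SimulationConfig(seed=6, n_genes=100, n_chroms=2, chrom_length=16_000_000,
                               frac_bound=0.4)
        genes = generate_genes(cfg)
        peaks, truth = generate_peaks(genes, cfg)
        assert len(truth.bound_genes) == 40
        filtered = filter_peaks(peaks)
        realized = {
            truth.anchor_gene_by_peak[p]
            for p in filtered["peak_id"]
            if truth.anchor_gene_by_peak[p] is not None
        }
        assert realized == truth.bound_genes

    def test_filter_fail_fraction_violates_thresholds(self):
        cfg = SimulationConfig(seed=6, n_genes=50, n_chroms=2, chrom_length=12_000_000,
                               frac_filter_fail=0.5, peaks_per_gene_mean=5)
        genes = generate_genes(cfg)
        peaks, truth = generate_peaks(genes, cfg)
        for p in peaks.itertuples(index=False):
            passes = p.fdr <= 0.1 and p.pvalue < 1e-5
            assert passes == truth.passes_filter_by_peak[p.peak_id]
        assert 0 < sum(not v for v in truth.passes_filter_by_peak.values()) < len(peaks)

    def test_all_score_bins_present(self, small_bundle):
        scores = small_bundle.peaks["score"]
        assert (scores < 100).any() and ((scores >= 100) & (scores < 200)).any() and (scores >= 200).any()

    def test_planted_mixture_recovered_by_annotation(self):
        cfg = SimulationConfig(seed=10, n_genes=150, n_chroms=3, chrom_length=16_000_000,
                               frac_bound=1.0, peaks_per_gene_mean=15.0,
                               location_mixture={"ingene": 0.4, "promoter": 0.1,
                                                 "upstream": 0.2, "downstream": 0.2,
                                                 "intergenic": 0.1})
        genes = generate_genes(cfg)
        peaks, truth = generate_peaks(genes, cfg)
        annotation = annotate_peaks(peaks, genes)
        # the annotation must agree with the planted category peak by peak
        planted = truth.planted_location_by_peak
        for row in annotation.primary.itertuples(index=False):
            assert row.category == planted[row.peak_id]
        dist = location_distribution(annotation)
        for cat, frac in cfg.location_mixture.items():
            assert dist[cat] == pytest.approx(frac, abs=0.03)


class TestSequences:
    def test_planted_dr1_everywhere(self, consensus_model):
        from nrcistrome import classify_arrangements

        cfg = SimulationConfig(seed=9, motif_mixture={"DR1": 1.0})
        seqs, truth = generate_peak_sequences(dummy_peaks(60), cfg)
        for rec in seqs:
            assert truth.planted_motif_by_peak[rec.id] == "DR1"
            calls = classify_arrangements(scan_half_sites(str(rec.seq), consensus_model))
            # two same-orientation half-sites one base apart are present
            assert any(c.arrangement == "DR" and c.spacer == 1 for c in calls)

    def test_clean_background_leaves_only_planted_hits(self, consensus_model):
        cfg = SimulationConfig(seed=9, motif_mixture={"IR3": 0.5, "none": 0.5},
                               clean_background=True)
        seqs, truth = generate_peak_sequences(dummy_peaks(80), cfg)
        for rec in seqs:
            hits = scan_half_sites(str(rec.seq), consensus_model)
            if truth.planted_motif_by_peak[rec.id] == "none":
                assert hits == []
            else:
                assert len(hits) == 2
                call = best_arrangement(str(rec.seq), consensus_model)
                assert call.label == "IR3"

    def test_background_half_site_rate_matches_enumeration(self, consensus_model):
        """Uniform background: P(hexamer matches RGGTCA) = (1/2)(1/4)^5 per
        strand, so expected hits per 201-bp window = 196 * 2/2048."""
        cfg = SimulationConfig(seed=14, motif_mixture={"none": 1.0})
        seqs, _ = generate_peak_sequences(dummy_peaks(5_000), cfg)
        total = sum(len(scan_half_sites(str(r.seq), consensus_model)) for r in seqs)
        expected = 5_000 * 196 * 2 / 2_048
        sd = np.sqrt(expected)  # hit counts are near-Poisson
        assert abs(total - expected) < 6 * sd

    def test_deterministic_fasta(self):
        cfg = SimulationConfig(seed=12)
        a, _ = generate_peak_sequences(dummy_peaks(20), cfg)
        b, _ = generate_peak_sequences(dummy_peaks(20), cfg)
        assert [str(r.seq) for r in a] == [str(r.seq) for r in b]


class TestExpression:
    def test_noiseless_limit_fold_change(self):
        cfg = SimulationConfig(seed=15, noise_sd=1e-9, frac_uik=0.5, frac_dik=0.0,
                               frac_undetected=0.0, effect_log2fc=1.0)
        matrix, truth = generate_expression([f"g{i}" for i in range(100)], cfg)
        for gene, label in truth.de_label_by_gene.items():
            ratio = matrix.ko.loc[gene].mean() / matrix.wt.loc[gene].mean()
            assert ratio == pytest.approx(2.0 if label == "UIK" else 1.0, rel=1e-6)

    def test_deterministic_matrix(self):
        cfg = SimulationConfig(seed=16)
        genes = [f"g{i}" for i in range(50)]
        a, _ = generate_expression(genes, cfg)
        b, _ = generate_expression(genes, cfg)
        assert a.values.equals(b.values)

    def test_label_counts_exact(self):
        cfg = SimulationConfig(seed=17, frac_undetected=0.2, frac_uik=0.1, frac_dik=0.05)
        _, truth = generate_expression([f"g{i}" for i in range(1_000)], cfg)
        labels = pd.Series(truth.de_label_by_gene)
        assert (labels == "undetected").sum() == 200
        assert (labels == "UIK").sum() == 80
        assert (labels == "DIK").sum() == 40

    def test_undetected_sit_below_threshold(self):
        cfg = SimulationConfig(seed=18, frac_undetected=0.5, noise_sd=1.0)
        matrix, truth = generate_expression([f"g{i}" for i in range(200)], cfg)
        undetected = [g for g, lab in truth.de_label_by_gene.items() if lab == "undetected"]
        assert (matrix.wt.loc[undetected].mean(axis=1) < cfg.detect_tau).all()
        assert (matrix.ko.loc[undetected].mean(axis=1) < cfg.detect_tau).all()


def test_truth_labels_partition_genes(small_bundle):
    labels = small_bundle.truth.de_label_by_gene
    assert set(labels) == set(small_bundle.genes["gene_id"])
    assert set(labels.values()) <= {"UIK", "DIK", "unchanged", "undetected"}
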