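"""Generator truth round-trips: genomes, plantings, panels, blocks."""

import numpy as np
import pytest

from auxre.annotation import REGION_SPECS, extract_region, partition_genome
from auxre.association import call_regulation, meta_association
from auxre.composites import spacer_class
from auxre.conservation import call_site_conservation, filter_blocks
from auxre.sequence_core import SequenceRecord, SiteHit, parse_iupac, \
    scan_consensus
from auxre.synthetic import (
    ConservationRules,
    ExpressionRules,
    GeneratorConfig,
    PlantingRule,
    generate_alignment_blocks,
    generate_expression_panel,
    generate_genome,
    generate_training_set,
    plant_sites,
)


class TestGenome:
    def test_gene_count_structure_and_bounds(self):
        cfg = GeneratorConfig(seed=1, n_genes=10, chrom_length=100_000)
        genome = generate_genome(cfg)
        assert len(genome.genes) == 10
        prev_end = -1
        for g in sorted(genome.genes, key=lambda x: x.start):
            assert 0 <= g.start < g.end <= 100_000
            assert g.start > prev_end  # non-overlapping
            prev_end = g.end
            assert g.utr5 and g.utr3 and g.cds_exons
            tss = g.start if g.strand == "+" else g.end - 1
            assert g.tss == tss

    def test_background_gc_within_three_se(self):
        cfg = GeneratorConfig(seed=2, n_genes=2, chrom_length=100_000,
                              gc_content=0.36)
        genome = generate_genome(cfg)
        seq = genome.chroms["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        se = np.sqrt(0.36 * 0.64 / len(seq))
        assert abs(gc - 0.36) < 3 * se

    def test_same_seed_byte_identical(self):
        cfg = GeneratorConfig(seed=3, n_genes=5, chrom_length=60_000)
        g1, g2 = generate_genome(cfg), generate_genome(cfg)
        assert g1.chroms == g2.chroms
        assert [vars(a) for a in g1.genes] == [vars(b) for b in g2.genes]

    def test_genes_not_fitting_raises(self):
        cfg = GeneratorConfig(seed=4, n_genes=50, chrom_length=30_000)
        with pytest.raises(ValueError, match="fit"):
            generate_genome(cfg)


class TestPlanting:
    def test_planted_sites_recovered_by_scanner(self):
        cfg = GeneratorConfig(seed=5, n_genes=15, chrom_length=150_000)
        genome = generate_genome(cfg)
        rule = PlantingRule(pattern="TGTCTC", motif_id="m",
                            region="promoter_prox", probability=1.0)
        genome = plant_sites(genome, [rule], seed=6)
        hits = scan_consensus(
            SequenceRecord("chr1", genome.chroms["chr1"]),
            parse_iupac("TGTCTC"),
        )
        found = {(h.start, h.strand) for h in hits}
        truth = {
            (s.start, s.strand) for s in genome.truth.planted_sites
        }
        assert truth <= found
        # every gene got a planting inside its proximal promoter
        assert len(truth) == 15
        for s in genome.truth.planted_sites:
            gene = next(g for g in genome.genes if g.gene_id == s.gene_id)
            region, _ = extract_region(
                gene, REGION_SPECS["promoter_prox"], 150_000
            )
            assert region.start <= s.start < region.end

    def test_orientation_probabilities_respected(self):
        cfg = GeneratorConfig(seed=7, n_genes=30, chrom_length=300_000)
        genome = generate_genome(cfg)
        rule = PlantingRule(pattern="TGTCTC", motif_id="m",
                            probability=1.0, orientation_direct_prob=1.0)
        genome = plant_sites(genome, [rule], seed=8)
        gene_strand = {g.gene_id: g.strand for g in genome.genes}
        for s in genome.truth.planted_sites:
            assert s.strand == gene_strand[s.gene_id]

    # the overlapped class is only letter-compatible with Y-patch on the
    # 3' flank (its reported overlapping configuration)
    @pytest.mark.parametrize(
        "cls,side",
        [("overlapped", "3p"), ("short", "5p"), ("long", "5p")],
    )
    def test_composite_spacer_classes_round_trip(self, cls, side):
        cfg = GeneratorConfig(seed=9, n_genes=12, chrom_length=150_000)
        genome = generate_genome(cfg)
        rule = PlantingRule(
            pattern="TGTCTC", motif_id="anchor", probability=1.0,
            coupling_pattern="TCTCCTYT", coupling_id="yp",
            coupling_spacer_class=cls, coupling_side=side,
        )
        genome = plant_sites(genome, [rule], seed=10)
        anchors = [s for s in genome.truth.planted_sites
                   if s.role == "anchor"]
        assert anchors
        for s in anchors:
            assert s.spacer_class == cls
            assert spacer_class(s.center_distance) == cls
            # planted words still match their patterns in the genome
            got = genome.chroms[s.chrom][s.start : s.start + len(s.word)]
            want = s.word if s.strand == "+" else None
            m = parse_iupac(s.pattern)
            probe = got if s.strand == "+" else \
                __import__("auxre.sequence_core",
                           fromlist=["reverse_complement"]
                           ).reverse_complement(got)
            assert m.matches(probe)
            del want

    def test_probability_zero_leaves_sequence_unchanged(self):
        cfg = GeneratorConfig(seed=11, n_genes=5, chrom_length=60_000)
        genome = generate_genome(cfg)
        before = dict(genome.chroms)
        rule = PlantingRule(pattern="TGTCTC", motif_id="m", probability=0.0)
        genome = plant_sites(genome, [rule], seed=12)
        assert genome.chroms == before
        assert genome.truth.planted_sites == []


class TestTrainingSet:
    def test_default_shape(self):
        aln, truth = generate_training_set(seed=13)
        assert len(aln) == 25
        assert aln.length == 106
        assert aln.core_offset == 50
        m = parse_iupac("TGTCNN")
        assert all(m.matches(r[50:56]) for r in aln.records)

    def test_planted_coupling_at_truth_offsets(self):
        aln, truth = generate_training_set(
            planted_couplings=[("TCTCCTYT", "5p", 4)], seed=14
        )
        m = parse_iupac("TCTCCTYT")
        for rec, t in zip(aln.records, truth):
            off = t["TCTCCTYT"]
            assert m.matches(rec[off : off + 8])
            assert off + 8 + 4 == 50  # 4 nt short of the core start

    def test_flank_gc_within_three_se(self):
        aln, _ = generate_training_set(n=50, gc=0.5, seed=15)
        flanks = "".join(r[:50] + r[56:] for r in aln.records)
        gc = (flanks.count("G") + flanks.count("C")) / len(flanks)
        se = np.sqrt(0.25 / len(flanks))
        assert abs(gc - 0.5) < 3 * se


class TestExpressionPanel:
    def test_call_recovery_sensitivity_and_fdr(self):
        """delta=log2(3), sd 0.2, pi=0.8, pi0=0.05, 2000 genes, 4+4
        replicates: calls recover responder truth with sensitivity >= 0.95
        and FDR <= 0.1."""
        genes = [f"g{i}" for i in range(2000)]
        element = set(genes[:1000])
        rules = ExpressionRules(
            n_experiments=1, replicates=4, noise_sd=0.2,
            pi=0.8, pi0=0.05, n_single_replicate=0,
        )
        from auxre.synthetic import TruthTable

        truth = TruthTable()
        (exp,) = generate_expression_panel(genes, element, rules, seed=16,
                                           truth=truth)
        calls = call_regulation(exp)
        responders = truth.responders[exp.id]
        called_up = set(calls.index[calls["direction"] == "up"])
        tp = len(called_up & responders)
        sensitivity = tp / len(responders)
        fdr = (len(called_up) - tp) / max(len(called_up), 1)
        assert sensitivity >= 0.95
        assert fdr <= 0.1

    def test_null_panel_meta_association_rarely_flags(self):
        """pi == pi0: the planted subset is uninformative."""
        genes = [f"g{i}" for i in range(400)]
        element = set(genes[:100])
        flagged = 0
        n_rep = 100
        for rep in range(n_rep):
            rules = ExpressionRules(pi=0.1, pi0=0.1, replicates=3,
                                    n_single_replicate=0)
            exps = generate_expression_panel(genes, element, rules,
                                             seed=1000 + rep)
            calls = [(e.id, call_regulation(e)) for e in exps]
            flagged += meta_association(element, calls).influential
        assert flagged / n_rep < 0.05

    def test_single_replicate_experiment_has_one_sample_per_arm(self):
        genes = [f"g{i}" for i in range(10)]
        rules = ExpressionRules(n_experiments=3, n_single_replicate=1)
        exps = generate_expression_panel(genes, set(), rules, seed=17)
        assert [not e.replicated for e in exps] == [False, False, True]
        last = exps[-1]
        assert len(last.treatment) == len(last.control) == 1


class TestAlignmentBlocks:
    @staticmethod
    def _planted_genome(seed=18):
        cfg = GeneratorConfig(seed=seed, n_genes=12, chrom_length=150_000)
        genome = generate_genome(cfg)
        rule = PlantingRule(pattern="TGTCTC", motif_id="m",
                            region="prox_utr", probability=1.0)
        return plant_sites(genome, [rule], seed=seed + 1)

    def test_zero_coverage_means_no_blocks(self):
        genome = self._planted_genome()
        blocks = generate_alignment_blocks(
            genome, ConservationRules(coverage=0.0), seed=19
        )
        assert blocks == []
        s = genome.truth.planted_sites[0]
        call = call_site_conservation(
            SiteHit(s.chrom, s.start, 6, s.strand), blocks
        )
        assert not call.conserved

    def test_core_protection_keeps_in_block_sites_conserved(self):
        genome = self._planted_genome(seed=20)
        rules = ConservationRules(coverage=1.0, mu=0.2,
                                  core_protection=True, region="prox_utr")
        blocks = filter_blocks(
            generate_alignment_blocks(genome, rules, seed=21)
        )
        assert blocks
        for s in genome.truth.planted_sites:
            call = call_site_conservation(
                SiteHit(s.chrom, s.start, 6, s.strand), blocks
            )
            if call.in_block:
                assert call.core_conserved
        assert any(
            call_site_conservation(
                SiteHit(s.chrom, s.start, 6, s.strand), blocks
            ).in_block
            for s in genome.truth.planted_sites
        )

    def test_unprotected_conservation_rate_matches_binomial(self):
        genome = self._planted_genome(seed=22)
        mu = 0.08
        rules = ConservationRules(coverage=1.0, mu=mu,
                                  core_protection=False, region="ext_utr")
        # sample many TGTCNN anchors genome-wide inside blocks
        conserved = in_block = 0
        for rep in range(25):
            blocks = filter_blocks(
                generate_alignment_blocks(genome, rules, seed=300 + rep)
            )
            hits = scan_consensus(
                SequenceRecord("chr1", genome.chroms["chr1"]),
                parse_iupac("TGTCNN"),
            )
            for h in hits:
                call = call_site_conservation(h, blocks)
                if call.in_block:
                    in_block += 1
                    conserved += call.core_conserved
        p_col = 1 - mu  # substitutions always change the letter
        expected = p_col ** 16
        se = np.sqrt(expected * (1 - expected) / in_block)
        assert abs(conserved / in_block - expected) < 3 * se


def test_partition_of_generated_genome_is_total():
    cfg = GeneratorConfig(seed=23, n_genes=20, chrom_length=200_000)
    genome = generate_genome(cfg)
    part = partition_genome(genome.genes, genome.chrom_lengths)
    assert sum(part.class_lengths().values()) == 200_000
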