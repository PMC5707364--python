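"""Substitution classes, triplet-context enrichment, coding effect vs a
translation oracle, compartment contrasts, and the clustering test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tmpop.genome import build_genome, collapse_triplet
from tmpop.spectrum import (
    ASA_CSG_CLASSES,
    ClusterTestResult,
    classify_substitution,
    clustering_test,
    coding_effect,
    compartment_contrast,
    deleterious_fraction,
    ns_s_ratio,
    triplet_context_table,
    ts_tv,
)


class TestSubstitutionClasses:
    def test_a_to_g_is_transition(self):
        assert classify_substitution("A", "G") == "transition"

    def test_twelve_directed_substitutions_split_4_to_8(self):
        classes = [
            classify_substitution(r, a)
            for r, a in itertools.permutations("ACGT", 2)
        ]
        assert classes.count("transition") == 4
        assert classes.count("transversion") == 8

    def test_toy_ts_tv_ratio(self):
        ts, tv, ratio = ts_tv([("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")])
        assert (ts, tv, ratio) == (2, 2, 1.0)

    def test_non_snv_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "A")
        with pytest.raises(ValueError):
            classify_substitution("N", "G")


class Mut:
    def __init__(self, chrom, pos):
        self.chrom, self.pos = chrom, pos  # pos 1-based


class TestTripletContext:
    def test_context_is_centered_reference_triplet(self, small_genome):
        chrom = "chr1"
        pos0 = 5000
        t = small_genome.sequence[chrom][pos0 - 1 : pos0 + 2]
        table, ledger = triplet_context_table([Mut(chrom, pos0 + 1)], small_genome)
        assert table.loc[collapse_triplet(t), "count"] == 1
        assert ledger == {"input": 1, "excluded_edge_or_N": 0, "counted": 1}

    def test_chromosome_edge_excluded_via_ledger(self, small_genome):
        table, ledger = triplet_context_table([Mut("chr1", 1)], small_genome)
        assert ledger["excluded_edge_or_N"] == 1
        assert table["count"].sum() == 0

    def test_uniform_planting_gives_flat_enrichment(self, small_genome):
        rng = np.random.default_rng(8)
        muts = [
            Mut("chr1", int(p) + 1)
            for p in rng.integers(1, 999_999, size=10_000)
        ]
        table, _ = triplet_context_table(muts, small_genome)
        assert table["enrichment"].between(0.8, 1.2).all()
        # genomic-frequency-weighted mean enrichment is 1 by construction
        w = (table["enrichment"] * table["genomic_share"]).sum()
        assert w == pytest.approx(1.0, abs=1e-9)

    def test_planted_excess_in_asa_contexts_recovered(self, small_genome):
        """Plant 3x mutations at ASA-motif centers; those classes should
        show ~3-fold enrichment, the rest ~1."""
        seq = small_genome.sequence["chr1"]
        rng = np.random.default_rng(9)
        asa_pos = [
            i + 1
            for i in range(1, 400_000)
            if collapse_triplet(seq[i - 1 : i + 2]) in ("ACA", "AGA")
        ]
        muts = [Mut("chr1", int(p) + 1) for p in rng.integers(1, 999_999, 4000)]
        muts += [Mut("chr1", int(p)) for p in rng.choice(asa_pos, 1500)]
        table, _ = triplet_context_table(muts, small_genome)
        assert table.loc["ACA", "enrichment"] > 2.0
        assert table.loc["AGA", "enrichment"] > 2.0
        # non-planted classes are uniformly diluted by the planted excess
        others = table.drop(index=list(ASA_CSG_CLASSES))
        assert others["enrichment"].between(0.5, 1.0).all()


class TestCodingEffect:
    def test_intergenic_is_noncoding(self, small_genome):
        g = small_genome.genes[0]
        assert coding_effect(g.chrom, g.start - 1000, "A", "C", small_genome) in (
            "noncoding",
        )

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_all_nine_codon_snvs_match_translation_oracle(self, strand, small_genome):
        from Bio.Seq import Seq
        from tmpop.genome import revcomp

        gene = next(g for g in small_genome.genes if g.strand == strand)
        cds = "".join(
            small_genome.sequence[gene.chrom][s:e] for s, e in gene.exons
        )
        if strand == "-":
            cds = revcomp(cds)
        # walk one full codon in genomic coordinates within the first exon
        exon_s, _ = gene.exons[0]
        for off in range(3):
            pos = exon_s + 3 + off  # inside exon, codon-aligned region
            ref = small_genome.sequence[gene.chrom][pos]
            for alt in "ACGT":
                if alt == ref:
                    continue
                got = coding_effect(gene.chrom, pos, ref, alt, small_genome)
                # oracle: mutate the CDS string directly and translate
                cds_i = pos - exon_s if strand == "+" else len(cds) - 1 - (pos - exon_s)
                alt_c = alt if strand == "+" else revcomp(alt)
                mutant_cds = cds[:cds_i] + alt_c + cds[cds_i + 1 :]
                n = len(cds) - len(cds) % 3
                same = str(Seq(cds[:n]).translate()) == str(Seq(mutant_cds[:n]).translate())
                assert got == ("synonymous" if same else "nonsynonymous")

    def test_wobble_position_synonymous(self):
        """GGA->GGG (Gly->Gly): build a one-gene genome where the first
        codon is GGA and mutate its third base."""
        from tmpop.genome import Gene, GenomeModel

        seq = "A" * 50 + "GGA" + "GGT" + "TAA" + "A" * 44
        gm = GenomeModel(
            chromosomes=[("c", len(seq))],
            sequence={"c": seq},
            genes=[Gene("g", "c", 50, 59, "+", [(50, 59)], (50, 50), (59, 59))],
        )
        assert coding_effect("c", 52, "A", "G", gm) == "synonymous"
        assert coding_effect("c", 51, "G", "T", gm) == "nonsynonymous"


class TestCompartmentContrast:
    def test_printed_count_ratios(self):
        assert round(ns_s_ratio(11, 8), 2) == 1.38
        assert round(ns_s_ratio(140, 120), 2) == 1.17
        assert round(deleterious_fraction(5, 19), 2) == 0.26
        assert round(deleterious_fraction(32, 260), 2) == 0.12

    def test_zero_coding_compartment_reports_na(self):
        assert np.isnan(deleterious_fraction(0, 0))

    def test_contrast_table_counts(self):
        class R:
            def __init__(self, comp, eff, dele):
                self.compartment, self.effect, self.deleterious = comp, eff, dele

        recs = (
            [R("pericentromere", "nonsynonymous", True)] * 11
            + [R("pericentromere", "synonymous", False)] * 8
            + [R("arm", "nonsynonymous", False)] * 140
            + [R("arm", "synonymous", False)] * 120
        )
        t = compartment_contrast(recs)
        assert round(t.loc["pericentromere", "ns_s_ratio"], 2) == 1.38
        assert round(t.loc["arm", "ns_s_ratio"], 2) == 1.17


class TestClusteringTest:
    SPACE = {"chr1": [(0, 1_000_000)]}

    def test_requires_ten_positions(self):
        with pytest.raises(ValueError):
            clustering_test([("chr1", i) for i in range(5)], self.SPACE)

    def test_position_outside_callable_space_rejected(self):
        pos = [("chr1", i * 1000) for i in range(20)] + [("chr1", 2_000_000)]
        with pytest.raises(ValueError, match="outside"):
            clustering_test(pos, self.SPACE)

    def test_statistic_equals_brute_force_ecdf_scan(self):
        rng = np.random.default_rng(2)
        pos = [("chr1", int(p)) for p in np.sort(rng.integers(0, 1_000_000, 20))]
        res = clustering_test(pos, self.SPACE, n_null=5, seed=3)
        obs, null = res.observed_distances, res.null_distances
        grid = np.unique(np.concatenate([obs, null]))
        d = max(
            abs((obs <= x).mean() - (null <= x).mean()) for x in grid
        )
        assert res.statistic == pytest.approx(d, abs=1e-12)

    def test_planted_clusters_detected(self):
        rng = np.random.default_rng(4)
        detected = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            base = rng.integers(0, 1_000_000, 70)
            centers = rng.integers(0, 999_000, 6)
            clustered = np.concatenate(
                [c + rng.integers(0, 1000, 5) for c in centers]
            )
            pos = [("chr1", int(p)) for p in np.concatenate([base, clustered])]
            res = clustering_test(pos, self.SPACE, n_null=50, seed=rep,
                                  p_method="asymp")
            detected += res.pvalue < 1e-3
        assert detected >= 19
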