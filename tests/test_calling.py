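"""Mutation filter cascade: per-rule prefilter vs independent rule checks,
one-vs-rest candidate scan vs brute force, cluster masking, support and
recurrence filters, and exact planted-truth recovery on noiseless data."""

import numpy as np
import pandas as pd
import pytest

from tmpop import intervals as iv
from tmpop.calling import (
    PrefilterParams,
    SupportParams,
    apply_mutation_filters,
    mask_heterozygosity_clusters,
    prefilter_sites,
    scan_candidates,
)
from tmpop.evidence import SiteEvidenceTable
from tmpop.segments import SharedRegion, shared_regions

from conftest import make_evidence_df

OKLINE = (0, 20, 0, 20, 0, 58.0, 1)  # hom-ref line, depth 20, clean


def _site(chrom, pos, lines, site_mq=58.0, **overrides):
    s = {"chrom": chrom, "pos": pos, "ref": "A", "alt": "G", "site_mq": site_mq}
    for lid in lines:
        s[lid] = overrides.get(lid, OKLINE)
    return s


class TestPrefilter:
    LINES = ["x", "y"]

    def toy(self):
        mk = _site
        alt = (2, 0, 20, 0, 20, 58.0, 1)
        return SiteEvidenceTable(
            make_evidence_df(
                [
                    mk("chr1", 100, self.LINES, y=alt),
                    mk("chr1", 300, self.LINES, site_mq=29.0),  # rule 1
                    mk("chr1", 500, self.LINES, x=(0, 41, 0, 41, 0, 58.0, 1)),  # rule 2
                    mk("chr1", 700, self.LINES, y=alt),
                    mk("chr1", 900, self.LINES, y=alt),
                    mk("chr1", 903, self.LINES, y=alt),  # rule 3: close pair
                    mk("chr1", 1200, self.LINES, y=(1, 17, 3, 17, 3, 58.0, 1)),  # rule 4
                    mk("chr2", 100, self.LINES, y=alt),
                ],
                self.LINES,
            )
        )

    def test_empty_stream(self):
        ev = SiteEvidenceTable(self.toy().df.iloc[:0])
        out, ledger = prefilter_sites(ev)
        assert len(out) == 0 and ledger["input"] == ledger["output"] == 0

    def test_toy_survivors_match_independent_rule_checks(self):
        ev = self.toy()
        out, ledger = prefilter_sites(ev)
        p = PrefilterParams()
        # independent re-derivation of each rule
        df = ev.df
        ok_mq = df["site_mq"] >= p.mq_min
        ok_depth = np.ones(len(df), bool)
        for lid in self.LINES:
            d = df[f"{lid}.ad_ref"] + df[f"{lid}.ad_alt"]
            ok_depth &= ((d == 0) | ((d >= p.depth_min) & (d <= p.depth_max))).to_numpy()
        alive = (ok_mq & ok_depth).to_numpy()
        ok_gap = np.ones(len(df), bool)
        for i in range(len(df)):
            for j in range(len(df)):
                if (
                    i != j
                    and alive[i]
                    and alive[j]
                    and df["chrom"][i] == df["chrom"][j]
                    and abs(int(df["pos"][i]) - int(df["pos"][j])) < p.min_gap
                ):
                    ok_gap[i] = False
        minor = np.minimum(
            sum(df[f"{l}.ad_alt"] for l in self.LINES),
            sum(df[f"{l}.ad_ref"] for l in self.LINES),
        )
        ok_minor = (minor >= p.minor_depth_min).to_numpy()
        expect = df["pos"][alive & ok_gap & ok_minor].tolist()
        # note rule-4 keeps only sites with real minor-allele support
        assert out.df["pos"].tolist() == expect
        assert expect == [100, 700, 100]  # chr1:100,700 then chr2:100
        assert ledger["input"] == ledger["output"] + ledger["mq"] + ledger[
            "depth"
        ] + ledger["spacing"] + ledger["minor_depth"]

    def test_depth_41_rejected_at_boundary(self):
        ev = SiteEvidenceTable(
            make_evidence_df(
                [_site("chr1", 10, self.LINES, x=(2, 0, 41, 0, 41, 58.0, 1))],
                self.LINES,
            )
        )
        out, ledger = prefilter_sites(ev)
        assert len(out) == 0 and ledger["depth"] == 1

    def test_unsorted_stream_rejected(self):
        df = self.toy().df.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            prefilter_sites(SiteEvidenceTable(df))


LINES5 = [f"L{i}" for i in range(1, 6)]
REGION = [SharedRegion("chr1", 0, 10_000, tuple(LINES5), 5)]


def _ev5(sites):
    return SiteEvidenceTable(make_evidence_df(sites, LINES5))


def alt_line(depth=20, hq=None):
    hq = depth if hq is None else hq
    return (2, 0, depth, 0, hq, 58.0, 1)


class TestScanCandidates:
    def test_concordant_site_is_not_a_candidate(self):
        cands, hets = scan_candidates(_ev5([_site("chr1", 50, LINES5)]), REGION)
        assert len(cands) == 0 and len(hets) == 0

    def test_single_discordant_homozygote_is_a_candidate(self):
        ev = _ev5([_site("chr1", 50, LINES5, L3=alt_line())])
        cands, _ = scan_candidates(ev, REGION)
        assert len(cands) == 1
        assert cands.iloc[0]["carrier"] == "L3"
        assert cands.iloc[0]["mutant_allele"] == "G"

    def test_heterozygous_carrier_routed_to_het_list(self):
        ev = _ev5([_site("chr1", 50, LINES5, L2=(1, 10, 10, 10, 10, 58.0, 1))])
        cands, hets = scan_candidates(ev, REGION)
        assert len(cands) == 0 and hets["pos"].tolist() == [50]

    def test_matches_brute_force_one_vs_rest_oracle(self):
        rng = np.random.default_rng(3)
        sites = []
        for i in range(20):
            overrides = {}
            for lid in LINES5:
                gt = int(rng.choice([0, 0, 0, 2, 1], p=[0.6, 0.1, 0.1, 0.15, 0.05]))
                if gt == 2:
                    overrides[lid] = alt_line()
                elif gt == 1:
                    overrides[lid] = (1, 10, 10, 10, 10, 58.0, 1)
            sites.append(_site("chr1", 100 + 10 * i, LINES5, **overrides))
        ev = _ev5(sites)
        cands, _ = scan_candidates(ev, REGION)
        got = {(int(r.pos), r.carrier) for r in cands.itertuples()}
        expect = set()
        for s in sites:
            gts = {lid: (0 if s[lid] == OKLINE else (2 if s[lid][0] == 2 else 1)) for lid in LINES5}
            if any(g == 1 for g in gts.values()):
                continue
            for lid in LINES5:
                others = [gts[o] for o in LINES5 if o != lid]
                if len(set(others)) == 1 and others[0] != gts[lid]:
                    expect.add((s["pos"], lid))
        assert got == expect


class TestHetClusterMask:
    def test_scattered_sites_not_masked(self):
        sites = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [100, 90_000]})
        assert mask_heterozygosity_clusters(sites) == {}

    def test_masks_are_disjoint_and_sorted(self):
        rng = np.random.default_rng(1)
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": np.sort(rng.integers(0, 200_000, 150))}
        )
        masks = mask_heterozygosity_clusters(sites)["chr1"]
        assert masks == iv.merge(masks)

    def test_simulated_het_block_mostly_masked(self):
        """A 50-kb residual-het block emitting ~1 site/kb is >= 95% masked
        on average over 100 seeded replicates."""
        cov = []
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            pos = np.sort(rng.integers(100_000, 150_000, size=50)) + 1
            masks = mask_heterozygosity_clusters(
                pd.DataFrame({"chrom": "chr1", "pos": pos})
            ).get("chr1", [])
            cov.append(iv.overlap_length(masks, [(100_000, 150_000)]) / 50_000)
        assert np.mean(cov) >= 0.95

    def test_mask_extends_to_segment_boundaries(self):
        sites = pd.DataFrame({"chrom": "chr1", "pos": [5000, 5400, 5900]})
        masks = mask_heterozygosity_clusters(
            sites, segment_boundaries={"chr1": [0, 4000, 8000]}
        )
        assert masks["chr1"] == [(4000, 8000)]


class TestMutationFilters:
    def cand(self, pos=50, carrier="L3", **kw):
        base = {
            "chrom": "chr1", "pos": pos, "ref": "A", "alt": "G",
            "carrier": carrier, "mutant_allele": "G", "shared_allele": "A",
            "region_carriers": tuple(LINES5),
        }
        base.update(kw)
        return base

    def test_four_supporting_reads_rejected(self):
        ev = _ev5([_site("chr1", 50, LINES5, L3=alt_line(depth=20, hq=4))])
        cands = pd.DataFrame([self.cand()])
        recs, ledger = apply_mutation_filters(cands, ev)
        assert recs == [] and ledger["support"] == 1

    def test_recurrent_in_two_lines_both_rejected(self):
        ev = _ev5(
            [_site("chr1", 50, LINES5, L2=alt_line(), L3=alt_line())]
        )
        cands = pd.DataFrame([self.cand(carrier="L2"), self.cand(carrier="L3")])
        recs, ledger = apply_mutation_filters(cands, ev)
        assert recs == [] and ledger["recurrent"] == 2

    def test_masked_candidate_rejected(self):
        ev = _ev5([_site("chr1", 50, LINES5, L3=alt_line())])
        recs, ledger = apply_mutation_filters(
            pd.DataFrame([self.cand()]), ev, masks={"chr1": [(0, 100)]}
        )
        assert recs == [] and ledger["mask"] == 1

    def test_improper_pairs_fail_support(self):
        ev = _ev5(
            [_site("chr1", 50, LINES5, L3=(2, 0, 20, 0, 20, 58.0, 0))]
        )
        recs, _ = apply_mutation_filters(pd.DataFrame([self.cand()]), ev)
        assert recs == []

    def test_surviving_set_independent_of_rule_order(self):
        ev = _ev5(
            [
                _site("chr1", 50, LINES5, L3=alt_line()),
                _site("chr1", 5000, LINES5, L2=alt_line(hq=3)),
                _site("chr1", 7000, LINES5, L1=alt_line()),
            ]
        )
        cands = pd.DataFrame(
            [
                self.cand(pos=50, carrier="L3"),
                self.cand(pos=5000, carrier="L2"),
                self.cand(pos=7000, carrier="L1"),
            ]
        )
        masks = {"chr1": [(6000, 8000)]}
        import itertools

        results = set()
        for order in itertools.permutations(["recurrent", "mask", "support"]):
            recs, ledger = apply_mutation_filters(
                cands, ev, masks=masks, rule_order=order
            )
            results.add(tuple((r.chrom, r.pos, r.carrier) for r in recs))
            assert ledger["candidates"] == ledger["output"] + sum(
                ledger[r] for r in order
            )
        assert results == {(("chr1", 50, "L3"),)}


class TestPlantedRecovery:
    def test_noiseless_precision_and_recall_are_one(
        self, truth6, small_genome, noiseless_evidence
    ):
        segs = [truth6.lines[l].segments for l in truth6.line_ids]
        shared = shared_regions(segs, "MO17", 2)
        filt, _ = prefilter_sites(noiseless_evidence)
        cands, hets = scan_candidates(filt, shared)
        masks = mask_heterozygosity_clusters(
            pd.concat([cands[["chrom", "pos"]], hets], ignore_index=True)
        )
        recs, _ = apply_mutation_filters(cands, filt, masks, genome=small_genome)
        expected = set()
        for m in truth6.all_mutations():
            if m.recurrent:
                continue
            for r in shared:
                if (
                    r.chrom == m.chrom
                    and r.start <= m.pos < r.end
                    and m.carriers[0] in r.carriers
                ):
                    masked = m.chrom in masks and iv.contains(masks[m.chrom], m.pos)
                    if not masked:
                        expected.add((m.chrom, m.pos + 1, m.carriers[0]))
        called = {(r.chrom, r.pos, r.carrier) for r in recs}
        assert called == expected
        assert len(called) > 20  # non-trivial instance
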