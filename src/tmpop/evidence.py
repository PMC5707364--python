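"""Per-site read evidence: the emission model and its VCF-backed table.

:class:`SiteEvidenceTable` holds, per site and per line, the called
genotype, per-allele read depths, per-allele counts of uniquely-mapped
high-quality (MQ >= 50) reads, a per-line mapping quality, and a
properly-paired-on-same-chromosome flag — everything the mutation filter
cascade inspects.  Serialization is VCF v4.2 via pysam with custom FORMAT
fields (AD, HQD, MQL, PP).

:func:`emit_site_evidence` generates the table from a simulated truth
table: true mutations emit mutant-allele support in their carriers,
residual-heterozygosity blocks emit clustered heterozygous sites, and
background sites give the prefilter something to chew on.  Read counts are
Poisson (optionally fixed) depths with a symmetric per-read error rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .pedigree import TruthTable

PER_LINE_FIELDS = ("gt", "ad_ref", "ad_alt", "hq_ref", "hq_alt", "mq", "pp")


@dataclass
class SiteEvidenceTable:
    """Wide per-site table: columns ``chrom, pos, ref, alt, site_mq`` plus
    ``{line}.{field}`` for each line and field in :data:`PER_LINE_FIELDS`.
    ``pos`` is 1-based (VCF convention); genotypes are alt-allele dosage
    (0/1/2, -1 missing)."""

    df: pd.DataFrame

    @property
    def lines(self) -> List[str]:
        return sorted({c.split(".")[0] for c in self.df.columns if "." in c})

    def __len__(self) -> int:
        return len(self.df)

    def is_sorted(self) -> bool:
        d = self.df[["chrom", "pos"]]
        return d.equals(d.sort_values(["chrom", "pos"], ignore_index=True))

    def col(self, line: str, field: str) -> np.ndarray:
        return self.df[f"{line}.{field}"].to_numpy()

    # -- VCF round trip ------------------------------------------------- #
    def to_vcf(self, path: str | Path, chrom_lengths: Dict[str, int]) -> None:
        import pysam

        header = pysam.VariantHeader()
        for c in sorted(chrom_lengths):
            header.contigs.add(c, length=chrom_lengths[c])
        header.info.add("MQ", 1, "Float", "Site mapping quality")
        header.formats.add("GT", 1, "String", "Genotype")
        header.formats.add("AD", "R", "Integer", "Per-allele read depth")
        header.formats.add(
            "HQD", "R", "Integer", "Per-allele uniquely-mapped MQ>=50 read count"
        )
        header.formats.add("MQL", 1, "Float", "Per-sample mapping quality")
        header.formats.add(
            "PRP", 1, "Integer", "Paired reads properly mapped to same chromosome"
        )
        lines = self.lines
        for lid in lines:
            header.add_sample(lid)
        gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (None, None)}
        with pysam.VariantFile(str(path), "w", header=header) as vf:
            for row in self.df.to_dict("records"):
                rec = vf.new_record(
                    contig=row["chrom"],
                    start=int(row["pos"]) - 1,
                    alleles=(row["ref"], row["alt"]),
                )
                rec.info["MQ"] = float(row["site_mq"])
                for lid in lines:
                    s = rec.samples[lid]
                    s["GT"] = gt_map[int(row[f"{lid}.gt"])]
                    s["AD"] = (int(row[f"{lid}.ad_ref"]), int(row[f"{lid}.ad_alt"]))
                    s["HQD"] = (int(row[f"{lid}.hq_ref"]), int(row[f"{lid}.hq_alt"]))
                    s["MQL"] = float(row[f"{lid}.mq"])
                    s["PRP"] = int(row[f"{lid}.pp"])
                vf.write(rec)

    @classmethod
    def from_vcf(cls, path: str | Path) -> "SiteEvidenceTable":
        import pysam

        rows: List[dict] = []
        with pysam.VariantFile(str(path)) as vf:
            samples = list(vf.header.samples)
            for rec in vf:
                row = {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "site_mq": float(rec.info["MQ"]),
                }
                for lid in samples:
                    s = rec.samples[lid]
                    gt = s["GT"]
                    row[f"{lid}.gt"] = (
                        -1 if gt is None or gt[0] is None else int(sum(gt))
                    )
                    row[f"{lid}.ad_ref"], row[f"{lid}.ad_alt"] = map(int, s["AD"])
                    row[f"{lid}.hq_ref"], row[f"{lid}.hq_alt"] = map(int, s["HQD"])
                    row[f"{lid}.mq"] = float(s["MQL"])
                    row[f"{lid}.pp"] = int(s["PRP"])
                rows.append(row)
        return cls(pd.DataFrame(rows))


# ---------------------------------------------------------------------- #
# emission model
# ---------------------------------------------------------------------- #


@dataclass
class EvidenceParams:
    depth_mean: float = 20.0
    error_rate: float = 1e-3
    depth_model: str = "poisson"  # poisson | fixed | nbinom
    nb_dispersion: float = 0.1  # only for nbinom: var = mean(1 + disp*mean)
    mq_mean: float = 58.0
    mq_sd: float = 3.0
    low_mq_fraction: float = 0.0  # sites emitted with MQ < 30 (filter fodder)
    hq_read_prob: float = 1.0  # P(read is uniquely mapped with MQ >= 50)
    improper_pair_fraction: float = 0.0
    het_sites_per_kb: float = 1.0
    n_background_sites: int = 0

    def __post_init__(self) -> None:
        if self.depth_mean <= 0:
            raise ValueError("depth_mean > 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate in [0, 0.5)")


def _depths(rng: np.random.Generator, p: EvidenceParams, n: int) -> np.ndarray:
    if p.depth_model == "fixed":
        return np.full(n, int(round(p.depth_mean)), dtype=np.int64)
    if p.depth_model == "nbinom":
        m = p.depth_mean
        r = 1.0 / p.nb_dispersion
        return rng.negative_binomial(r, r / (r + m), size=n)
    return rng.poisson(p.depth_mean, size=n)


_BASES = "ACGT"


def emit_site_evidence(
    truth: TruthTable,
    genome: GenomeModel,
    params: EvidenceParams | None = None,
    seed: int = 0,
) -> SiteEvidenceTable:
    """Emit the site-evidence table implied by a truth table.

    Sites emitted: every true mutation; clustered heterozygous sites inside
    residual-heterozygosity blocks (deterministic count of
    ``round(len_kb * het_sites_per_kb)`` per block, uniform positions);
    ``n_background_sites`` monomorphic positions.  With ``error_rate=0`` and
    a fixed depth model the called genotypes equal the truth exactly.
    """
    p = params or EvidenceParams()
    rng = np.random.default_rng(seed)
    lines = truth.line_ids
    lengths = truth.chrom_lengths
    chroms = sorted(lengths)

    # site registry: (chrom, pos0) -> (ref, alt, {line: true_gt})
    sites: Dict[Tuple[str, int], Tuple[str, str, Dict[str, int]]] = {}

    for m in truth.all_mutations():
        key = (m.chrom, m.pos)
        if key in sites:
            continue
        gts = {}
        for lid in m.carriers:
            origin = truth.lines[lid].segments.origin_at(m.chrom, m.pos)
            gts[lid] = 1 if origin == "HET" else 2
        sites[key] = (m.ref, m.alt, gts)

    for lid in lines:
        for chrom, blocks in truth.lines[lid].het_blocks.items():
            for s, e in blocks:
                n_het = int(round((e - s) / 1000.0 * p.het_sites_per_kb))
                for pos in rng.integers(s, e, size=n_het):
                    pos = int(pos)
                    ref = genome.base(chrom, pos)
                    if ref == "N":
                        continue
                    key = (chrom, pos)
                    if key not in sites:
                        alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
                        sites[key] = (ref, alt, {})
                    # every line holding a het block over this site is het
                    for lid2 in lines:
                        for s2, e2 in truth.lines[lid2].het_blocks.get(chrom, []):
                            if s2 <= pos < e2:
                                sites[key][2][lid2] = 1

    sizes = np.array([lengths[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    for _ in range(p.n_background_sites):
        c = chroms[rng.choice(len(chroms), p=probs)]
        pos = int(rng.integers(lengths[c]))
        ref = genome.base(c, pos)
        if ref == "N" or (c, pos) in sites:
            continue
        alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
        sites[(c, pos)] = (ref, alt, {})

    keys = sorted(sites)
    n = len(keys)
    cols: Dict[str, np.ndarray] = {
        "chrom": np.array([k[0] for k in keys], dtype=object),
        "pos": np.array([k[1] + 1 for k in keys], dtype=np.int64),
        "ref": np.array([sites[k][0] for k in keys], dtype=object),
        "alt": np.array([sites[k][1] for k in keys], dtype=object),
    }
    site_mq = rng.normal(p.mq_mean, p.mq_sd, size=n)
    if p.low_mq_fraction > 0:
        low = rng.random(n) < p.low_mq_fraction
        site_mq[low] = rng.uniform(10, 29.9, size=int(low.sum()))
    cols["site_mq"] = np.round(site_mq, 2)

    e = p.error_rate
    p_alt_by_gt = {0: e / 3.0, 1: 0.5, 2: 1.0 - e}
    for lid in lines:
        true_gt = np.array([sites[k][2].get(lid, 0) for k in keys], dtype=np.int64)
        d = _depths(rng, p, n)
        p_alt = np.array([p_alt_by_gt[g] for g in true_gt])
        ad_alt = rng.binomial(d, p_alt)
        ad_ref = d - ad_alt
        hq_ref = rng.binomial(ad_ref, p.hq_read_prob)
        hq_alt = rng.binomial(ad_alt, p.hq_read_prob)
        with np.errstate(invalid="ignore"):
            frac = np.divide(ad_alt, d, out=np.zeros(n), where=d > 0)
        gt = np.where(frac >= 0.8, 2, np.where(frac <= 0.2, 0, 1))
        gt[d == 0] = -1
        pp = (rng.random(n) >= p.improper_pair_fraction).astype(np.int64)
        cols[f"{lid}.gt"] = gt
        cols[f"{lid}.ad_ref"] = ad_ref
        cols[f"{lid}.ad_alt"] = ad_alt
        cols[f"{lid}.hq_ref"] = hq_ref
        cols[f"{lid}.hq_alt"] = hq_alt
        cols[f"{lid}.mq"] = np.round(rng.normal(p.mq_mean, p.mq_sd, size=n), 2)
        cols[f"{lid}.pp"] = pp

    return SiteEvidenceTable(pd.DataFrame(cols))


def emit_marker_genotypes(
    truth: TruthTable,
    spacing: int = 50_000,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Array-style marker genotypes (long TSV layout: line_id, chrom, pos,
    code) on a regular grid, read off the true segment sets with optional
    genotyping error and missingness."""
    rng = np.random.default_rng(seed)
    code_of = {"MO17": "A", "MEX": "B", "HET": "H"}
    rows = []
    for lid in truth.line_ids:
        segs = truth.lines[lid].segments
        for chrom, L in sorted(truth.chrom_lengths.items()):
            for pos in range(spacing // 2, L, spacing):
                code = code_of[segs.origin_at(chrom, pos)]
                r = rng.random()
                if r < missing_rate:
                    code = "."
                elif r < missing_rate + error_rate:
                    code = rng.choice([c for c in "ABH" if c != code])
                rows.append((lid, chrom, pos, code))
    return pd.DataFrame(rows, columns=["line_id", "chrom", "pos", "code"])
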