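"""Spontaneous-mutation calling: site prefilter, one-vs-rest candidate scan
over shared-origin regions, heterozygosity-cluster masking, and the final
read-support / recurrence filter cascade.

The candidate definition: within a region where several lines share the
same parental origin, a site where exactly one of the sharing lines is
homozygous for an allele different from the allele all other sharing lines
agree on.  Filters then require strong unique-read support for both alleles,
drop candidates inside clustered-heterozygosity masks (residual
heterozygosity mimics clustered mutations), and drop alleles seen as a
candidate in two or more lines anywhere (recurrent, i.e. preexisting in the
shared parent).  Every stage returns a rejection ledger that conserves
counts: input = output + sum(rejections).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import intervals as iv
from .evidence import SiteEvidenceTable
from .genome import GenomeModel, collapse_triplet
from .segments import SharedRegion
from .spectrum import coding_effect


# ---------------------------------------------------------------------- #
# prefilter
# ---------------------------------------------------------------------- #


@dataclass
class PrefilterParams:
    mq_min: float = 30.0
    depth_min: int = 5
    depth_max: int = 40
    min_gap: int = 5  # adjacent retained sites must be >= this many bp apart
    minor_depth_min: int = 5


def prefilter_sites(
    ev: SiteEvidenceTable, params: PrefilterParams | None = None
) -> Tuple[SiteEvidenceTable, Dict[str, int]]:
    """Site-level SNP filters applied as a cascade.

    (1) site MQ >= mq_min; (2) per-line total depth within
    [depth_min, depth_max] for every genotyped line; (3) no other surviving
    site within ``min_gap`` bp; (4) site minor-allele depth (summed over
    lines) >= minor_depth_min.  Rejections are attributed to the first
    failing rule; the ledger conserves counts.  Raises on unsorted input.
    """
    p = params or PrefilterParams()
    if not ev.is_sorted():
        raise ValueError("evidence stream must be sorted by (chrom, pos)")
    df = ev.df
    n = len(df)
    ledger = {"input": n, "mq": 0, "depth": 0, "spacing": 0, "minor_depth": 0}
    if n == 0:
        ledger["output"] = 0
        return SiteEvidenceTable(df.copy()), ledger

    lines = ev.lines
    fail_mq = df["site_mq"].to_numpy() < p.mq_min

    fail_depth = np.zeros(n, dtype=bool)
    for lid in lines:
        d = ev.col(lid, "ad_ref") + ev.col(lid, "ad_alt")
        fail_depth |= (d > 0) & ((d < p.depth_min) | (d > p.depth_max))
    fail_depth &= ~fail_mq

    alive = ~(fail_mq | fail_depth)
    fail_gap = np.zeros(n, dtype=bool)
    chroms = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    idx = np.where(alive)[0]
    for a, b in zip(idx, idx[1:]):
        if chroms[a] == chroms[b] and pos[b] - pos[a] < p.min_gap:
            fail_gap[a] = fail_gap[b] = True

    alt_tot = np.zeros(n, dtype=np.int64)
    ref_tot = np.zeros(n, dtype=np.int64)
    for lid in lines:
        alt_tot += ev.col(lid, "ad_alt")
        ref_tot += ev.col(lid, "ad_ref")
    fail_minor = np.minimum(alt_tot, ref_tot) < p.minor_depth_min
    fail_minor &= alive & ~fail_gap

    ledger["mq"] = int(fail_mq.sum())
    ledger["depth"] = int(fail_depth.sum())
    ledger["spacing"] = int((fail_gap & alive).sum())
    ledger["minor_depth"] = int(fail_minor.sum())
    keep = alive & ~fail_gap & ~fail_minor
    ledger["output"] = int(keep.sum())
    assert ledger["input"] == ledger["output"] + sum(
        ledger[k] for k in ("mq", "depth", "spacing", "minor_depth")
    )
    return SiteEvidenceTable(df[keep].reset_index(drop=True)), ledger


# ---------------------------------------------------------------------- #
# candidate scan
# ---------------------------------------------------------------------- #


def scan_candidates(
    ev: SiteEvidenceTable, shared: Sequence[SharedRegion]
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """One-vs-rest scan inside shared-origin regions.

    Returns ``(candidates, het_sites)``.  A candidate is a site where
    exactly one region carrier is homozygous for an allele the other
    carriers do not hold, and all other carriers are concordantly homozygous
    for the shared allele.  Sites with a heterozygous or missing carrier are
    not candidates; heterozygous ones are returned separately as fodder for
    the residual-heterozygosity mask.
    """
    df = ev.df
    cand_rows: List[dict] = []
    het_rows: List[dict] = []
    chrom_arr = df["chrom"].to_numpy()
    pos_arr = df["pos"].to_numpy()
    by_chrom = {c: np.where(chrom_arr == c)[0] for c in pd.unique(chrom_arr)}
    for reg in shared:
        idxs = by_chrom.get(reg.chrom)
        if idxs is None:
            continue
        # site pos is 1-based; region [start, end) is 0-based half-open
        sel = idxs[(pos_arr[idxs] - 1 >= reg.start) & (pos_arr[idxs] - 1 < reg.end)]
        for i in sel:
            row = df.iloc[i]
            gts = {lid: int(row[f"{lid}.gt"]) for lid in reg.carriers}
            if any(g == 1 for g in gts.values()):
                het_rows.append({"chrom": reg.chrom, "pos": int(row["pos"])})
                continue
            if any(g == -1 for g in gts.values()):
                continue
            n_alt = sum(1 for g in gts.values() if g == 2)
            if n_alt == 1:
                carrier = next(l for l, g in gts.items() if g == 2)
                mutant, shared_allele = row["alt"], row["ref"]
            elif n_alt == len(gts) - 1 and len(gts) >= 2:
                carrier = next(l for l, g in gts.items() if g == 0)
                mutant, shared_allele = row["ref"], row["alt"]
            else:
                continue
            cand_rows.append(
                {
                    "chrom": reg.chrom,
                    "pos": int(row["pos"]),
                    "ref": row["ref"],
                    "alt": row["alt"],
                    "carrier": carrier,
                    "mutant_allele": mutant,
                    "shared_allele": shared_allele,
                    "region_carriers": reg.carriers,
                }
            )
    cand = pd.DataFrame(
        cand_rows,
        columns=[
            "chrom", "pos", "ref", "alt", "carrier",
            "mutant_allele", "shared_allele", "region_carriers",
        ],
    )
    het = pd.DataFrame(het_rows, columns=["chrom", "pos"])
    return cand, het


# ---------------------------------------------------------------------- #
# heterozygosity-cluster mask
# ---------------------------------------------------------------------- #


def mask_heterozygosity_clusters(
    sites: pd.DataFrame,
    min_sites: int = 3,
    window_bp: int = 10_000,
    segment_boundaries: Optional[Dict[str, Sequence[int]]] = None,
) -> Dict[str, List[Tuple[int, int]]]:
    """Mask any stretch where >= ``min_sites`` flagged sites fall within
    ``window_bp``; masks are merged, sorted, and optionally extended outward
    to the nearest segment boundaries.

    ``sites`` has columns chrom, pos (1-based); output intervals are 0-based
    half-open.
    """
    masks: Dict[str, List[Tuple[int, int]]] = {}
    if len(sites) == 0:
        return masks
    for chrom, sub in sites.groupby("chrom"):
        p = np.sort(sub["pos"].unique())
        raw = []
        for i in range(len(p) - min_sites + 1):
            j = i + min_sites - 1
            if p[j] - p[i] <= window_bp:
                raw.append((int(p[i]) - 1, int(p[j])))
        if raw:
            merged = iv.merge(raw)
            if segment_boundaries and chrom in segment_boundaries:
                bnd = np.sort(np.asarray(segment_boundaries[chrom]))
                ext = []
                for s, e in merged:
                    lo = bnd[bnd <= s]
                    hi = bnd[bnd >= e]
                    ext.append(
                        (int(lo[-1]) if len(lo) else s, int(hi[0]) if len(hi) else e)
                    )
                merged = iv.merge(ext)
            masks[str(chrom)] = merged
    return masks


# ---------------------------------------------------------------------- #
# final filter cascade
# ---------------------------------------------------------------------- #


@dataclass
class SupportParams:
    min_mutant_hq: int = 5  # unique MQ>=50 reads on the mutant allele (carrier)
    min_shared_hq: int = 5  # same, shared allele, in every other carrier
    require_proper_pair: bool = True


@dataclass
class MutationRecord:
    chrom: str
    pos: int  # 1-based
    ref: str  # shared allele
    alt: str  # mutant allele
    carrier: str
    triplet: Optional[str] = None
    feature: Optional[str] = None
    compartment: Optional[str] = None
    effect: Optional[str] = None
    deleterious: bool = False
    generation: Optional[int] = None


RULE_ORDER = ("recurrent", "mask", "support")


def apply_mutation_filters(
    cands: pd.DataFrame,
    ev: SiteEvidenceTable,
    masks: Optional[Dict[str, List[Tuple[int, int]]]] = None,
    params: SupportParams | None = None,
    genome: Optional[GenomeModel] = None,
    deleterious_flags: Optional[Dict[Tuple[str, int], bool]] = None,
    compartment_flank: int = 0,
    rule_order: Sequence[str] = RULE_ORDER,
) -> Tuple[List[MutationRecord], Dict[str, int]]:
    """Apply the read-support, cluster-mask, and recurrence filters.

    Each rule is evaluated on the full candidate set, so the surviving set
    is independent of ``rule_order`` (which only attributes rejections in
    the ledger).  Survivors are annotated against ``genome`` (triplet
    context, feature class, pericentromere/arm compartment, coding effect)
    and the supplied deleterious flags.
    """
    p = params or SupportParams()
    masks = masks or {}
    ledger = {"candidates": len(cands), **{r: 0 for r in rule_order}}
    if len(cands) == 0:
        ledger["output"] = 0
        return [], ledger

    df = ev.df
    key_index = {
        (c, pos): i
        for i, (c, pos) in enumerate(zip(df["chrom"].to_numpy(), df["pos"].to_numpy()))
    }

    # recurrent: same mutant allele candidate in >= 2 distinct carriers
    grp = cands.groupby(["chrom", "pos", "mutant_allele"])["carrier"].nunique()
    recurrent_keys = set(grp[grp >= 2].index)

    fails: Dict[str, np.ndarray] = {r: np.zeros(len(cands), dtype=bool) for r in rule_order}
    for ci, row in enumerate(cands.itertuples(index=False)):
        if (row.chrom, row.pos, row.mutant_allele) in recurrent_keys:
            fails["recurrent"][ci] = True
        if row.chrom in masks and iv.contains(masks[row.chrom], row.pos - 1):
            fails["mask"][ci] = True
        i = key_index[(row.chrom, row.pos)]
        mutant_is_alt = row.mutant_allele == row.alt
        hq_field = "hq_alt" if mutant_is_alt else "hq_ref"
        sh_field = "hq_ref" if mutant_is_alt else "hq_alt"
        ok = df.at[i, f"{row.carrier}.{hq_field}"] >= p.min_mutant_hq
        if p.require_proper_pair:
            ok = ok and df.at[i, f"{row.carrier}.pp"] == 1
        for other in row.region_carriers:
            if other == row.carrier:
                continue
            ok = ok and df.at[i, f"{other}.{sh_field}"] >= p.min_shared_hq
        if not ok:
            fails["support"][ci] = True

    rejected = np.zeros(len(cands), dtype=bool)
    for r in rule_order:
        newly = fails[r] & ~rejected
        ledger[r] = int(newly.sum())
        rejected |= fails[r]
    keep = ~rejected
    ledger["output"] = int(keep.sum())

    records: List[MutationRecord] = []
    dele = deleterious_flags or {}
    for row in cands[keep].itertuples(index=False):
        rec = MutationRecord(
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.shared_allele,
            alt=row.mutant_allele,
            carrier=row.carrier,
            deleterious=bool(dele.get((row.chrom, int(row.pos)), False)),
        )
        if genome is not None:
            pos0 = rec.pos - 1
            t = genome.triplet_at(rec.chrom, pos0)
            rec.triplet = collapse_triplet(t) if t else None
            rec.feature = genome.feature_class(rec.chrom, pos0)
            rec.compartment = genome.compartment(rec.chrom, pos0, compartment_flank)
            rec.effect = (
                coding_effect(rec.chrom, pos0, rec.ref, rec.alt, genome)
                if rec.feature == "exon"
                else "noncoding"
            )
        records.append(rec)
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records, ledger
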