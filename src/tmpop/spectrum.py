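"""Mutation spectrum: substitution classes, triplet context, coding effect,
compartment contrasts, and the inter-mutation distance clustering test.

Conventions: transitions are A<->G and C<->T; triplet contexts are the
reference trinucleotide centered on the mutated base, strand-collapsed with
its reverse complement into 32 classes; enrichment of a class is its share
of observed mutations divided by its share of callable genomic triplets, so
the genomic-frequency-weighted mean enrichment is 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals as iv
from .genome import Gene, GenomeModel, TRIPLET_CLASSES, collapse_triplet, revcomp

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_VALID = set("ACGT")


def classify_substitution(ref: str, alt: str) -> str:
    """'transition' (A<->G, C<->T) or 'transversion'; raises on non-SNVs."""
    if ref not in _VALID or alt not in _VALID or ref == alt or len(ref) != 1:
        raise ValueError(f"not a SNV: {ref}>{alt}")
    same_family = (ref in _PURINES) == (alt in _PURINES)
    return "transition" if same_family else "transversion"


def collapse_substitution(ref: str, alt: str) -> str:
    """Pyrimidine-reference collapsed class (6 classes, e.g. A>G -> T>C)."""
    if ref in _PURINES:
        comp = str.maketrans("ACGT", "TGCA")
        ref, alt = ref.translate(comp), alt.translate(comp)
    return f"{ref}>{alt}"


def ts_tv(pairs: Iterable[Tuple[str, str]]) -> Tuple[int, int, float]:
    """(n_transitions, n_transversions, ratio); ratio is inf when tv == 0."""
    ts = tv = 0
    for r, a in pairs:
        if classify_substitution(r, a) == "transition":
            ts += 1
        else:
            tv += 1
    return ts, tv, (ts / tv if tv else float("inf"))


# ---------------------------------------------------------------------- #
# triplet context
# ---------------------------------------------------------------------- #


def triplet_context_table(
    mutations: Sequence, genome: GenomeModel
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Per-class triplet table with enrichment, plus an exclusion ledger.

    ``mutations`` need ``chrom`` and 1-based ``pos`` attributes.  Mutations
    whose flanking base is off-chromosome or N are excluded and counted in
    the ledger.
    """
    counts = {t: 0 for t in TRIPLET_CLASSES}
    ledger = {"input": 0, "excluded_edge_or_N": 0, "counted": 0}
    for m in mutations:
        ledger["input"] += 1
        t = genome.triplet_at(m.chrom, m.pos - 1)
        if t is None:
            ledger["excluded_edge_or_N"] += 1
            continue
        counts[collapse_triplet(t)] += 1
        ledger["counted"] += 1
    gcounts = genome.triplet_counts
    g_total = sum(gcounts.values())
    n_total = sum(counts.values())
    rows = []
    for t in TRIPLET_CLASSES:
        g_share = gcounts[t] / g_total if g_total else np.nan
        o_share = counts[t] / n_total if n_total else np.nan
        rows.append(
            {
                "triplet": t,
                "count": counts[t],
                "genomic_count": gcounts[t],
                "genomic_share": g_share,
                "observed_share": o_share,
                "enrichment": (o_share / g_share) if g_share else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("triplet"), ledger


#: strand-collapsed classes covered by the ASA / CSG motifs (S = C or G)
ASA_CSG_CLASSES = tuple(
    sorted({collapse_triplet(t) for t in ("ACA", "AGA", "CCG", "CGG")})
)


def asa_csg_excess(table: pd.DataFrame) -> float:
    """Mean enrichment of the ASA/CSG classes over the unweighted mean
    enrichment of the remaining classes."""
    sel = table.index.isin(ASA_CSG_CLASSES)
    return float(table.loc[sel, "enrichment"].mean() / table.loc[~sel, "enrichment"].mean())


# ---------------------------------------------------------------------- #
# coding effect
# ---------------------------------------------------------------------- #


def coding_effect(chrom: str, pos: int, ref: str, alt: str, genome: GenomeModel) -> str:
    """Classify a SNV (``pos`` 0-based) as synonymous / nonsynonymous /
    noncoding from the gene model and the standard codon table."""
    from Bio.Seq import Seq

    for gene in genome.genes:
        if gene.chrom != chrom or not (gene.start <= pos < gene.end):
            continue
        offset = 0
        hit = None
        for s, e in gene.exons:
            if s <= pos < e:
                hit = offset + (pos - s)
                break
            offset += e - s
        if hit is None:
            continue
        cds_len = sum(e - s for s, e in gene.exons)
        cds = "".join(genome.sequence[chrom][s:e] for s, e in gene.exons)
        if gene.strand == "-":
            cds = revcomp(cds)
            hit = cds_len - 1 - hit
            alt_base = revcomp(alt)
        else:
            alt_base = alt
        codon_i = hit // 3
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        if len(codon) < 3:
            return "noncoding"  # trailing partial codon
        mutant = codon[: hit % 3] + alt_base + codon[hit % 3 + 1 :]
        aa0 = str(Seq(codon).translate())
        aa1 = str(Seq(mutant).translate())
        return "synonymous" if aa0 == aa1 else "nonsynonymous"
    return "noncoding"


# ---------------------------------------------------------------------- #
# compartment contrasts
# ---------------------------------------------------------------------- #


def ns_s_ratio(n_nonsyn: int, n_syn: int) -> float:
    return n_nonsyn / n_syn if n_syn else float("nan")


def deleterious_fraction(n_deleterious: int, n_coding: int) -> float:
    """Deleterious mutations over coding mutations; NA when there are no
    coding mutations."""
    return n_deleterious / n_coding if n_coding else float("nan")


def compartment_contrast(records: Sequence) -> pd.DataFrame:
    """ns/s ratio and deleterious fraction per compartment.

    ``records`` need ``compartment``, ``effect`` and ``deleterious``
    attributes (e.g. :class:`~tmpop.calling.MutationRecord`).
    """
    rows = []
    for comp in ("pericentromere", "arm"):
        sub = [r for r in records if r.compartment == comp]
        ns = sum(1 for r in sub if r.effect == "nonsynonymous")
        s = sum(1 for r in sub if r.effect == "synonymous")
        coding = ns + s
        dele = sum(
            1 for r in sub if r.deleterious and r.effect != "noncoding"
        )
        rows.append(
            {
                "compartment": comp,
                "nonsynonymous": ns,
                "synonymous": s,
                "ns_s_ratio": ns_s_ratio(ns, s),
                "n_coding": coding,
                "n_deleterious": dele,
                "deleterious_fraction": deleterious_fraction(dele, coding),
            }
        )
    return pd.DataFrame(rows).set_index("compartment")


# ---------------------------------------------------------------------- #
# spatial clustering test
# ---------------------------------------------------------------------- #


@dataclass
class ClusterTestResult:
    observed_distances: np.ndarray
    null_distances: np.ndarray
    statistic: float  # two-sample KS D
    pvalue: float
    n_null: int
    seed: int


def _map_to_callable(
    positions: Sequence[Tuple[str, int]],
    callable_space: Dict[str, List[Tuple[int, int]]],
) -> Tuple[np.ndarray, int]:
    """Concatenate callable intervals into one linear axis and map positions
    (0-based) onto it; raises if any position falls outside."""
    offsets: Dict[str, List[Tuple[int, int, int]]] = {}
    cum = 0
    for c in sorted(callable_space):
        lst = []
        for s, e in iv.merge(callable_space[c]):
            lst.append((s, e, cum))
            cum += e - s
        offsets[c] = lst
    mapped = []
    for c, p in positions:
        for s, e, off in offsets.get(c, []):
            if s <= p < e:
                mapped.append(off + (p - s))
                break
        else:
            raise ValueError(f"position {c}:{p} outside callable space")
    return np.array(sorted(mapped), dtype=np.int64), cum


def clustering_test(
    positions: Sequence[Tuple[str, int]],
    callable_space: Dict[str, List[Tuple[int, int]]],
    n_null: int = 100,
    seed: int = 0,
    p_method: str = "mc",
) -> ClusterTestResult:
    """Two-sample KS test of observed adjacent-mutation distances against
    the same number of positions dropped uniformly over callable space
    (``n_null`` replicate draws, pooled).

    ``p_method='mc'`` (default) ranks the observed KS D among the per-
    replicate D values of the null draws themselves, a Monte-Carlo p that
    stays calibrated even though distances within one draw are negatively
    correlated; ``'asymp'`` reports the (conservative) asymptotic
    two-sample p against the pooled null.  The smallest attainable MC p is
    ``1/(n_null + 1)``.
    """
    if len(positions) < 10:
        raise ValueError("need >= 10 positions")
    mapped, total = _map_to_callable(positions, callable_space)
    if total <= 0:
        raise ValueError("callable space is empty")
    obs = np.diff(mapped)
    rng = np.random.default_rng(seed)
    n = len(mapped)
    null_parts = [
        np.diff(np.sort(rng.integers(0, total, size=n))) for _ in range(n_null)
    ]
    null = np.concatenate(null_parts)
    d_obs = float(stats.ks_2samp(obs, null).statistic)
    if p_method == "asymp":
        pvalue = float(stats.ks_2samp(obs, null).pvalue)
    elif p_method == "mc":
        d_null = [
            float(stats.ks_2samp(part, null).statistic) for part in null_parts
        ]
        pvalue = (1 + sum(d >= d_obs for d in d_null)) / (n_null + 1)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return ClusterTestResult(
        observed_distances=obs,
        null_distances=null,
        statistic=d_obs,
        pvalue=float(pvalue),
        n_null=n_null,
        seed=seed,
    )
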