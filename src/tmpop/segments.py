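"""Parental-origin segments: calling from marker genotypes and line selection.

A backcross-derived inbred line is a mosaic of recurrent-parent (MO17) and
donor (MEX) chromosome segments, with occasional residual-heterozygosity
blocks (HET).  This module calls that mosaic from array-style marker
genotypes with a three-state changepoint model, picks a minimal line subset
tiling the donor genome (greedy maximum coverage), and computes the regions
where several lines share the same parental origin — the substrate on which
spontaneous mutations are detected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import intervals as iv

ORIGINS = ("MO17", "MEX", "HET")
#: genotype code -> per-state match indicator (state order MO17, MEX, HET)
_CODE_MATCH = {
    "A": (1, 0, 0),
    "B": (0, 1, 0),
    "H": (0, 0, 1),
    ".": None,  # missing: no evidence
}


@dataclass
class SegmentSet:
    """Per-line parental-origin intervals partitioning each chromosome."""

    line_id: str
    #: chrom -> list of (start, end, origin, n_supporting_markers)
    intervals: Dict[str, List[Tuple[int, int, str, int]]]

    def intervals_of(self, origin: str) -> Dict[str, List[Tuple[int, int]]]:
        return {
            c: [(s, e) for s, e, o, _ in segs if o == origin]
            for c, segs in self.intervals.items()
        }

    def origin_at(self, chrom: str, pos: int) -> Optional[str]:
        for s, e, o, _ in self.intervals.get(chrom, []):
            if s <= pos < e:
                return o
        return None

    def donor_fraction(self, donor: str = "MEX") -> float:
        """Diploid donor-genome dosage: donor segments count 1, HET 0.5."""
        tot = donor_bp = 0
        for segs in self.intervals.values():
            for s, e, o, _ in segs:
                tot += e - s
                if o == donor:
                    donor_bp += e - s
                elif o == "HET":
                    donor_bp += (e - s) / 2
        return donor_bp / tot if tot else 0.0

    def validate_partition(self, chrom_lengths: Dict[str, int]) -> bool:
        for c, L in chrom_lengths.items():
            segs = sorted(self.intervals.get(c, []))
            if not segs or segs[0][0] != 0 or segs[-1][1] != L:
                return False
            for (s1, e1, *_), (s2, e2, *_) in zip(segs, segs[1:]):
                if s2 != e1:
                    return False
        return True


@dataclass
class LineGenotypes:
    """Marker genotypes for one line; codes A=recurrent, B=donor, H=het,
    '.'=missing, sorted by (chrom, pos)."""

    line_id: str
    markers: pd.DataFrame  # columns chrom, pos, code

    def __post_init__(self) -> None:
        m = self.markers
        if not m[["chrom", "pos"]].equals(
            m[["chrom", "pos"]].sort_values(["chrom", "pos"]).reset_index(drop=True)
        ):
            self.markers = m.sort_values(["chrom", "pos"]).reset_index(drop=True)
        bad = set(self.markers["code"]) - set(_CODE_MATCH)
        if bad:
            raise ValueError(f"invalid genotype codes: {bad}")


# ---------------------------------------------------------------------- #
# changepoint segment calling
# ---------------------------------------------------------------------- #


def score_path(codes: Sequence[str], states: Sequence[int],
               switch_penalty: float, match: float = 1.0,
               mismatch: float = 1.0) -> float:
    """Objective value of an origin path (used by both the DP and the
    brute-force oracle in the tests)."""
    score = 0.0
    for i, (code, st) in enumerate(zip(codes, states)):
        m = _CODE_MATCH[code]
        if m is not None:
            score += match if m[st] else -mismatch
        if i and states[i] != states[i - 1]:
            score -= switch_penalty
    return score


def _viterbi(codes: Sequence[str], switch_penalty: float,
             match: float, mismatch: float) -> List[int]:
    n = len(codes)
    emit = np.zeros((n, 3))
    for i, code in enumerate(codes):
        m = _CODE_MATCH[code]
        if m is not None:
            emit[i] = [match if x else -mismatch for x in m]
    S = emit[0].copy()
    back = np.zeros((n, 3), dtype=np.int64)
    for i in range(1, n):
        trans = S[None, :].repeat(3, axis=0)
        for s in range(3):
            trans[s] = S - switch_penalty * (np.arange(3) != s)
        back[i] = np.argmax(trans, axis=1)
        S = emit[i] + trans[np.arange(3), back[i]]
    path = [int(np.argmax(S))]
    for i in range(n - 1, 0, -1):
        path.append(int(back[i, path[-1]]))
    return path[::-1]


def call_segments(
    g: LineGenotypes,
    chrom_lengths: Dict[str, int],
    min_markers: int = 2,
    switch_penalty: float = 1.5,
    match: float = 1.0,
    mismatch: float = 1.0,
) -> SegmentSet:
    """Maximum-score origin path under a three-state changepoint model.

    Each marker scores ``+match`` if its genotype agrees with the state
    (A~MO17, B~MEX, H~HET), ``-mismatch`` otherwise, missing scores 0; each
    origin change costs ``switch_penalty``.  Segment boundaries are placed at
    midpoints between flanking discordant markers; terminal segments extend
    to the chromosome ends.  Internal segments supported by fewer than
    ``min_markers`` markers are absorbed into their better-supported
    neighbor.
    """
    out: Dict[str, List[Tuple[int, int, str, int]]] = {}
    m = g.markers
    nonmiss = m[m["code"] != "."]
    if len(nonmiss):
        majority = (
            nonmiss["code"].map({"A": "MO17", "B": "MEX", "H": "HET"}).mode().iloc[0]
        )
    else:
        majority = "MO17"

    for chrom, L in chrom_lengths.items():
        sub = m[m["chrom"] == chrom]
        codes = list(sub["code"])
        pos = list(sub["pos"])
        informative = [c for c in codes if c != "."]
        if len(informative) == 0:
            warnings.warn(
                f"{g.line_id}/{chrom}: no informative markers; "
                f"labeling whole chromosome {majority}"
            )
            out[chrom] = [(0, L, majority, 0)]
            continue
        if len(informative) < 2:
            warnings.warn(f"{g.line_id}/{chrom}: fewer than 2 informative markers")
        path = _viterbi(codes, switch_penalty, match, mismatch)
        segs = _path_to_segments(pos, codes, path, L)
        segs = _enforce_min_markers(segs, min_markers)
        out[chrom] = segs
    return SegmentSet(g.line_id, out)


def _path_to_segments(
    pos: Sequence[int], codes: Sequence[str], path: Sequence[int], L: int
) -> List[Tuple[int, int, str, int]]:
    segs: List[Tuple[int, int, str, int]] = []
    start = 0
    run_start = 0
    for i in range(1, len(path) + 1):
        if i == len(path) or path[i] != path[i - 1]:
            end = L if i == len(path) else (pos[i - 1] + pos[i] + 1) // 2
            n_sup = sum(
                1
                for j in range(run_start, i)
                if codes[j] != "." and _CODE_MATCH[codes[j]][path[j]]
            )
            segs.append((start, end, ORIGINS[path[i - 1]], n_sup))
            start = end
            run_start = i
    return segs


def _enforce_min_markers(
    segs: List[Tuple[int, int, str, int]], min_markers: int
) -> List[Tuple[int, int, str, int]]:
    segs = list(segs)
    while len(segs) > 1:
        internal = [
            (n, i) for i, (_, _, _, n) in enumerate(segs)
            if 0 < i < len(segs) - 1 and n < min_markers
        ]
        if not internal:
            break
        _, i = min(internal)
        prev_n = segs[i - 1][3]
        next_n = segs[i + 1][3]
        j = i - 1 if prev_n >= next_n else i + 1  # absorb into stronger side
        s = min(segs[i][0], segs[j][0])
        e = max(segs[i][1], segs[j][1])
        merged = (s, e, segs[j][2], segs[j][3])
        lo, hi = min(i, j), max(i, j)
        segs[lo:hi + 1] = [merged]
        # fuse neighbors that now share an origin
        k = 0
        while k < len(segs) - 1:
            if segs[k][2] == segs[k + 1][2]:
                segs[k:k + 2] = [
                    (segs[k][0], segs[k + 1][1], segs[k][2], segs[k][3] + segs[k + 1][3])
                ]
            else:
                k += 1
    return segs


# ---------------------------------------------------------------------- #
# greedy line selection
# ---------------------------------------------------------------------- #


@dataclass
class SelectionResult:
    line_ids: List[str]
    coverage_fractions: List[float]  # cumulative, after each pick
    per_line_donor_fraction: Dict[str, float]
    total_target_bp: int


def select_lines(
    segments: Sequence[SegmentSet], k: int, target_origin: str = "MEX"
) -> SelectionResult:
    """Greedy maximum-coverage selection of ``k`` lines over the target
    origin; ties broken by lowest line id."""
    if k < 1 or not segments:
        raise ValueError("k >= 1 and non-empty segment list required")
    if k > len(segments):
        warnings.warn("k exceeds population size; selecting all lines")
        k = len(segments)
    per_line = {
        s.line_id: {c: iv.merge(ivs) for c, ivs in s.intervals_of(target_origin).items()}
        for s in segments
    }
    all_ivs: Dict[str, List[Tuple[int, int]]] = {}
    for d in per_line.values():
        for c, ivs in d.items():
            all_ivs.setdefault(c, []).extend(ivs)
    total = sum(iv.total_length(ivs) for ivs in all_ivs.values())

    covered: Dict[str, List[Tuple[int, int]]] = {}
    picked: List[str] = []
    fractions: List[float] = []
    remaining = sorted(per_line)
    cov_bp = 0
    for _ in range(k):
        best, best_gain = None, -1
        for lid in remaining:
            gain = sum(
                iv.total_length(iv.subtract(ivs, covered.get(c, [])))
                for c, ivs in per_line[lid].items()
            )
            if gain > best_gain:
                best, best_gain = lid, gain
        picked.append(best)
        remaining.remove(best)
        for c, ivs in per_line[best].items():
            covered[c] = iv.merge(covered.get(c, []) + ivs)
        cov_bp = sum(iv.total_length(ivs) for ivs in covered.values())
        fractions.append(cov_bp / total if total else 0.0)
    donor_fracs = {s.line_id: s.donor_fraction(target_origin) for s in segments}
    return SelectionResult(picked, fractions, donor_fracs, total)


# ---------------------------------------------------------------------- #
# shared-origin regions
# ---------------------------------------------------------------------- #


@dataclass(frozen=True)
class SharedRegion:
    chrom: str
    start: int
    end: int
    carriers: Tuple[str, ...]
    count: int


def shared_regions(
    segments: Sequence[SegmentSet], origin: str = "MO17", min_lines: int = 2
) -> List[SharedRegion]:
    """Maximal regions where >= ``min_lines`` lines carry ``origin``.

    Intervals are emitted at carrier-set granularity: output is split where
    the carrier set changes, so each region lists exactly the lines sharing
    it.  The union of output intervals equals the set of bases with carrier
    count >= min_lines.
    """
    if min_lines < 1:
        raise ValueError("min_lines >= 1")
    events: Dict[str, List[Tuple[int, int, str]]] = {}
    for s in segments:
        for c, ivs in s.intervals_of(origin).items():
            for a, b in ivs:
                events.setdefault(c, []).append((a, 1, s.line_id))
                events.setdefault(c, []).append((b, -1, s.line_id))
    out: List[SharedRegion] = []
    for c in sorted(events):
        evs = sorted(events[c], key=lambda t: (t[0], t[1]))
        active: set = set()
        prev_pos = None
        for pos, delta, lid in evs + [(None, 0, "")]:
            if prev_pos is not None and pos != prev_pos and len(active) >= min_lines:
                carriers = tuple(sorted(active))
                if (
                    out
                    and out[-1].chrom == c
                    and out[-1].end == prev_pos
                    and out[-1].carriers == carriers
                ):
                    out[-1] = SharedRegion(c, out[-1].start, pos, carriers, len(carriers))
                else:
                    out.append(SharedRegion(c, prev_pos, pos, carriers, len(carriers)))
            if pos is None:
                break
            if delta == 1:
                active.add(lid)
            else:
                active.discard(lid)
            prev_pos = pos
    return out
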