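"""Presence/absence variation (PAV) interval calling.

Two complementary interval-logic approaches: low-coverage-run merging on a
read-depth track (regions of depth <= 2, runs separated by <= 50 bp
bridged, surviving intervals strictly > 100 bp and free of N), and
unaligned-segment extraction on a query assembly (complement of alignments
and assembly gaps, with a second-pass rescue-alignment mask subtracted).
PAVs containing >= 80% transposable-element sequence are classified as
TE-related.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import intervals as iv
from .genome import _runs_from_mask


@dataclass
class PAVInterval:
    genome: str
    chrom: str
    start: int
    end: int
    method: str  # unaligned | low_coverage
    te_fraction: float = 0.0
    te_related: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def _merge_close_runs(
    runs: List[Tuple[int, int]], merge_gap: int
) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for s, e in runs:
        if out and s - out[-1][1] <= merge_gap:
            out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def low_coverage_pav(
    depth: Dict[str, np.ndarray],
    depth_le: int = 2,
    merge_gap: int = 50,
    min_len: int = 101,
    n_mask: Optional[Dict[str, Sequence[Tuple[int, int]]]] = None,
    genome_label: str = "query",
) -> List[PAVInterval]:
    """PAVs from a per-base depth track.

    Maximal runs of depth <= ``depth_le``; runs separated by <= ``merge_gap``
    bp are bridged; intervals of length >= ``min_len`` (i.e. strictly more
    than 100 bp at the default) that contain no N (``n_mask``) are kept.
    Raises on negative depths.
    """
    out: List[PAVInterval] = []
    for chrom in sorted(depth):
        arr = np.asarray(depth[chrom])
        if np.any(arr < 0):
            raise ValueError(f"negative depth on {chrom}")
        runs = _runs_from_mask(arr <= depth_le)
        merged = _merge_close_runs(runs, merge_gap)
        nmask = iv.merge(n_mask.get(chrom, [])) if n_mask else []
        for s, e in merged:
            if e - s < min_len:
                continue
            if nmask and iv.overlap_length([(s, e)], nmask) > 0:
                continue
            out.append(PAVInterval(genome_label, chrom, s, e, "low_coverage"))
    return out


def unaligned_pav(
    aligned: Dict[str, Sequence[Tuple[int, int]]],
    query_lengths: Dict[str, int],
    gap_intervals: Optional[Dict[str, Sequence[Tuple[int, int]]]] = None,
    rescue_mask: Optional[Dict[str, Sequence[Tuple[int, int]]]] = None,
    min_len: int = 101,
    genome_label: str = "query",
) -> List[PAVInterval]:
    """PAVs as unaligned query segments.

    Per query sequence: complement of (alignments union assembly gaps),
    kept if >= ``min_len``; a second-pass rescue-alignment mask is then
    subtracted and surviving pieces re-filtered by length.  Overlapping
    alignment records are normalized by union.
    """
    gaps = gap_intervals or {}
    rescue = rescue_mask or {}
    out: List[PAVInterval] = []
    for chrom in sorted(query_lengths):
        L = query_lengths[chrom]
        ivs = list(aligned.get(chrom, []))
        for s, e in ivs:
            if not (0 <= s < e <= L):
                raise ValueError(f"alignment outside query bounds on {chrom}")
        covered = iv.merge(list(ivs) + list(gaps.get(chrom, [])))
        pieces = [p for p in iv.complement(covered, L) if p[1] - p[0] >= min_len]
        pieces = iv.subtract(pieces, rescue.get(chrom, []))
        for s, e in pieces:
            if e - s >= min_len:
                out.append(PAVInterval(genome_label, chrom, s, e, "unaligned"))
    return out


def classify_te_pav(
    pavs: Sequence[PAVInterval],
    te_intervals: Dict[str, Sequence[Tuple[int, int]]],
    threshold: float = 0.8,
) -> List[PAVInterval]:
    """Annotate each PAV with its TE overlap fraction; ``te_related`` when
    the fraction is >= ``threshold`` (inclusive)."""
    for p in pavs:
        ov = iv.overlap_length([(p.start, p.end)], te_intervals.get(p.chrom, []))
        p.te_fraction = ov / p.length if p.length else 0.0
        p.te_related = p.te_fraction >= threshold
    return list(pavs)
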