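"""Simulated per-base coverage tracks with planted deletions.

Generates the input of the read-depth PAV caller: Poisson depth around
``depth_mean`` in present sequence, near-zero depth (mean ``del_depth_mean``)
inside planted deletions.  The companion truth BED records the planted
intervals for recovery tests.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np


def simulate_coverage(
    chrom_lengths: Dict[str, int],
    planted_deletions: Dict[str, Sequence[Tuple[int, int]]] | None = None,
    depth_mean: float = 30.0,
    del_depth_mean: float = 0.3,
    seed: int = 0,
) -> Tuple[Dict[str, np.ndarray], Dict[str, List[Tuple[int, int]]]]:
    """Return (per-chromosome depth arrays, truth deletion intervals)."""
    if depth_mean <= 2:
        raise ValueError("depth_mean must exceed 2")
    planted = planted_deletions or {}
    for c, ivs in planted.items():
        for s, e in ivs:
            if c not in chrom_lengths or not (0 <= s < e <= chrom_lengths[c]):
                raise ValueError(f"planted deletion outside genome: {c}:{s}-{e}")
    rng = np.random.default_rng(seed)
    depth: Dict[str, np.ndarray] = {}
    truth: Dict[str, List[Tuple[int, int]]] = {}
    for c in sorted(chrom_lengths):
        L = chrom_lengths[c]
        arr = rng.poisson(depth_mean, size=L)
        for s, e in planted.get(c, []):
            arr[s:e] = rng.poisson(del_depth_mean, size=e - s)
        depth[c] = arr
        truth[c] = sorted((int(s), int(e)) for s, e in planted.get(c, []))
    return depth, truth
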