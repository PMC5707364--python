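"""Simulated IBD tracts between maize lines and two teosinte panels.

Stands in for a fastIBD-style tract list: under the null, each
maize-line x panel-member pair shares a Poisson number of tracts placed
uniformly at random, with the same rate for the mexicana and parviglumis
panels, so the windowed rIBD scan should center on zero.  Planted
introgression windows add dense mexicana-panel tracts covering the window
for a chosen fraction of maize lines — the controlled truth the downstream
caller must recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

TRACT_COLUMNS = ["line_id", "panel_member_id", "panel", "chrom", "start", "end", "score"]


@dataclass
class PlantedWindow:
    chrom: str
    start: int
    end: int
    line_fraction: float  # fraction of maize lines carrying the introgression


def simulate_ibd_tracts(
    chrom_lengths: Dict[str, int],
    n_maize: int,
    n_mex_panel: int,
    n_par_panel: int,
    baseline_rate: float = 2e-8,  # tracts per bp per line-member pair
    tract_len_mean: int = 200_000,
    planted_windows: Sequence[PlantedWindow] = (),
    member_prob: float = 0.9,  # panel members sharing a planted window
    seed: int = 0,
) -> pd.DataFrame:
    """Return a tract table (columns :data:`TRACT_COLUMNS`).

    Raises ``ValueError`` for a planted window outside the genome.
    """
    if n_maize < 1 or n_mex_panel < 1 or n_par_panel < 1:
        raise ValueError("all population sizes must be >= 1")
    for w in planted_windows:
        if w.chrom not in chrom_lengths or not (
            0 <= w.start < w.end <= chrom_lengths[w.chrom]
        ):
            raise ValueError(f"planted window outside genome: {w}")

    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    sizes = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    G = float(sizes.sum())

    maize = [f"L{i + 1:04d}" for i in range(n_maize)]
    panels = {
        "mex": [f"mex{i + 1:03d}" for i in range(n_mex_panel)],
        "par": [f"par{i + 1:03d}" for i in range(n_par_panel)],
    }

    rows: List[tuple] = []
    for line in maize:
        for panel, members in panels.items():
            for member in members:
                for _ in range(rng.poisson(baseline_rate * G)):
                    c = chroms[rng.choice(len(chroms), p=probs)]
                    L = chrom_lengths[c]
                    length = max(10_000, int(rng.exponential(tract_len_mean)))
                    start = int(rng.integers(max(1, L - length + 1)))
                    end = min(L, start + length)
                    rows.append((line, member, panel, c, start, end, 1.0))

    for w in planted_windows:
        k = int(round(w.line_fraction * n_maize))
        chosen = rng.choice(maize, size=k, replace=False)
        for line in chosen:
            for member in panels["mex"]:
                if rng.random() < member_prob:
                    rows.append((line, member, "mex", w.chrom, w.start, w.end, 1.0))
    df = pd.DataFrame(rows, columns=TRACT_COLUMNS)
    return df.sort_values(["chrom", "start", "line_id"], ignore_index=True)
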