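"""Windowed rIBD introgression scan.

The genome is tiled into fixed windows (100 kb by default; a final partial
window is kept when it is at least half a window long).  For each maize
line and window, nIBD against a teosinte panel is the fraction of panel
members sharing an IBD tract overlapping the window, normalized to [0, 1];
window-level nIBD is the mean over maize lines, and
``rIBD = nIBD_mex - nIBD_par``.  Windows with below-average SNP density are
removed before the mean and SD of rIBD are taken; a window is flagged as
introgressed under the z-score rule ``(rIBD - mu) / sigma > 2`` (default)
or the printed-form rule ``(rIBD - mu) / (sigma * rIBD) > 2``, which is
kept as an alternate mode because its scale-odd normalization looks like a
typeset z-score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals as iv


@dataclass
class WindowStats:
    """Per-window scan state: the summary frame plus per-line sharing."""

    df: pd.DataFrame  # chrom, start, end, nibd_mex, nibd_par, ribd
    per_line_mex: np.ndarray  # (n_windows, n_lines)
    per_line_par: np.ndarray
    lines: List[str]
    panel_sizes: Dict[str, int]


def tile_windows(
    chrom_lengths: Dict[str, int], window_bp: int = 100_000
) -> pd.DataFrame:
    """Fixed tiling from position 0; the final partial window is retained
    when >= 50% of window_bp, otherwise merged into its predecessor."""
    if window_bp <= 0:
        raise ValueError("window_bp > 0")
    rows = []
    for c in sorted(chrom_lengths):
        L = chrom_lengths[c]
        starts = list(range(0, L, window_bp))
        wins = [(s, min(s + window_bp, L)) for s in starts]
        if len(wins) > 1 and wins[-1][1] - wins[-1][0] < window_bp / 2:
            last = wins.pop()
            wins[-1] = (wins[-1][0], last[1])
        rows += [(c, s, e) for s, e in wins]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_nibd(
    tracts: pd.DataFrame,
    chrom_lengths: Dict[str, int],
    window_bp: int = 100_000,
    panel_sizes: Optional[Dict[str, int]] = None,
    maize_lines: Optional[Sequence[str]] = None,
) -> WindowStats:
    """Compute per-window, per-line nIBD for both panels and window rIBD.

    A tract contributes to every window it overlaps.  Raises if a tract
    extends beyond its chromosome.
    """
    if panel_sizes is None:
        panel_sizes = {
            p: tracts.loc[tracts["panel"] == p, "panel_member_id"].nunique()
            for p in ("mex", "par")
        }
    for p in ("mex", "par"):
        if panel_sizes.get(p, 0) < 1:
            raise ValueError(f"panel size for {p!r} must be >= 1")
    lines = sorted(maize_lines if maize_lines is not None else tracts["line_id"].unique())
    line_idx = {l: i for i, l in enumerate(lines)}

    wdf = tile_windows(chrom_lengths, window_bp)
    win_index: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for c, sub in wdf.groupby("chrom"):
        win_index[c] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub.index.to_numpy(),
        )

    n_win = len(wdf)
    members: Dict[str, List[List[set]]] = {
        "mex": [[set() for _ in lines] for _ in range(n_win)],
        "par": [[set() for _ in lines] for _ in range(n_win)],
    }
    for row in tracts.itertuples(index=False):
        if row.chrom not in chrom_lengths:
            raise ValueError(f"tract on unknown chromosome {row.chrom}")
        if row.end > chrom_lengths[row.chrom] or row.start < 0:
            raise ValueError(f"tract beyond chromosome end: {row}")
        if row.line_id not in line_idx:
            continue
        starts, ends, gidx = win_index[row.chrom]
        hit = (starts < row.end) & (ends > row.start)
        li = line_idx[row.line_id]
        for w in gidx[hit]:
            members[row.panel][w][li].add(row.panel_member_id)

    per_line = {}
    for p in ("mex", "par"):
        arr = np.zeros((n_win, len(lines)))
        for w in range(n_win):
            for li in range(len(lines)):
                arr[w, li] = len(members[p][w][li]) / panel_sizes[p]
        per_line[p] = arr
    wdf = wdf.copy()
    wdf["nibd_mex"] = per_line["mex"].mean(axis=1) if lines else 0.0
    wdf["nibd_par"] = per_line["par"].mean(axis=1) if lines else 0.0
    wdf["ribd"] = wdf["nibd_mex"] - wdf["nibd_par"]
    return WindowStats(wdf, per_line["mex"], per_line["par"], lines, dict(panel_sizes))


@dataclass
class RibdSummary:
    mu: float
    sigma: float
    threshold_mode: str
    windows: pd.DataFrame  # with retained + flagged columns
    flagged: pd.DataFrame  # flagged windows only
    per_line_flags: np.ndarray  # (n_windows, n_lines) bool
    lines: List[str]

    def per_line_proportion(self, genome_bp: int) -> Dict[str, float]:
        lengths = (self.windows["end"] - self.windows["start"]).to_numpy()
        return {
            l: float((lengths * self.per_line_flags[:, i]).sum()) / genome_bp
            for i, l in enumerate(self.lines)
        }

    def union_proportion(self, genome_bp: int) -> float:
        lengths = (self.windows["end"] - self.windows["start"]).to_numpy()
        any_flag = self.per_line_flags.any(axis=1)
        return float(lengths[any_flag].sum()) / genome_bp


def call_introgression(
    stats_in: WindowStats,
    snp_density: Sequence[float],
    threshold_mode: str = "zscore",
    z: float = 2.0,
) -> RibdSummary:
    """Flag putative introgression windows.

    Windows with SNP density strictly below the genome mean are removed
    first; ``mu`` and ``sigma`` are then taken over the retained rIBD
    values.  Modes: 'zscore' flags ``(rIBD - mu)/sigma > z``; 'as-printed'
    flags ``(rIBD - mu)/(sigma * rIBD) > z``.  A line is credited with a
    flagged window when its own rIBD there is positive.  Raises when fewer
    than 10 windows are retained or sigma is zero (degenerate scan).
    """
    wdf = stats_in.df.copy()
    dens = np.asarray(snp_density, dtype=float)
    if len(dens) != len(wdf):
        raise ValueError("snp_density length must match window count")
    retained = dens >= dens.mean()
    if retained.sum() < 10:
        raise ValueError("fewer than 10 windows retained")
    r = wdf["ribd"].to_numpy()
    mu = float(r[retained].mean())
    sigma = float(r[retained].std(ddof=0))
    if sigma <= 1e-12:  # all retained rIBD equal up to rounding
        raise ValueError("sigma of rIBD is zero: degenerate scan")
    if threshold_mode == "zscore":
        score = (r - mu) / sigma
    elif threshold_mode == "as-printed":
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(r != 0, (r - mu) / (sigma * r), -np.inf)
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    flagged = retained & (score > z)
    wdf["snp_density"] = dens
    wdf["retained"] = retained
    wdf["score"] = score
    wdf["flagged"] = flagged

    line_r = stats_in.per_line_mex - stats_in.per_line_par
    per_line_flags = flagged[:, None] & (line_r > 0)
    return RibdSummary(
        mu=mu,
        sigma=sigma,
        threshold_mode=threshold_mode,
        windows=wdf,
        flagged=wdf[flagged],
        per_line_flags=per_line_flags,
        lines=stats_in.lines,
    )


def hotspot_detection(
    summary: RibdSummary, min_lines: int = 2
) -> List[Tuple[str, int, int, int]]:
    """Maximal runs of adjacent flagged windows shared by >= ``min_lines``
    lines; returns (chrom, start, end, max sharing count) tuples."""
    if min_lines < 2:
        raise ValueError("min_lines >= 2")
    wdf = summary.windows
    share = summary.per_line_flags.sum(axis=1)
    out: List[Tuple[str, int, int, int]] = []
    cur = None
    for i in range(len(wdf)):
        ok = share[i] >= min_lines
        row = wdf.iloc[i]
        if ok:
            if cur is not None and cur[0] == row["chrom"] and cur[2] == row["start"]:
                cur = (cur[0], cur[1], int(row["end"]), max(cur[3], int(share[i])))
            else:
                if cur is not None:
                    out.append(cur)
                cur = (row["chrom"], int(row["start"]), int(row["end"]), int(share[i]))
        else:
            if cur is not None:
                out.append(cur)
                cur = None
    if cur is not None:
        out.append(cur)
    return out


def elevation_association(
    proportions: Sequence[float], elevations: Sequence[float]
) -> Tuple[float, float]:
    """Spearman rank correlation between per-line introgression proportion
    and elevation; returns (rho, p).  NA when either variable is constant."""
    x = np.asarray(proportions, float)
    y = np.asarray(elevations, float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need paired data with n >= 5")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def group_compare(
    highland: Sequence[float], lowland: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test of highland vs lowland
    introgression proportions; returns (U, p)."""
    res = stats.mannwhitneyu(highland, lowland, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
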