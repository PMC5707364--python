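"""File formats: FASTA, BED, BedGraph, tract/genotype/mutation TSV, and a
JSON genome annotation.

Coordinate dialects at the boundaries: BED and BedGraph are 0-based
half-open (the internal convention), VCF is 1-based (handled in
:mod:`tmpop.evidence`), TSV tract and genotype tables use internal 0-based
coordinates.  FASTA goes through Biopython; the tabular formats through
pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .calling import MutationRecord
from .genome import Gene, GenomeModel
from .segments import SegmentSet

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


# -- FASTA -------------------------------------------------------------- #


def read_fasta(path: str | Path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -- BED ---------------------------------------------------------------- #


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED6_COLUMNS)
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


# -- BedGraph ----------------------------------------------------------- #


def write_bedgraph(depth: Dict[str, np.ndarray], path: str | Path) -> None:
    """Run-length encode per-base depth arrays."""
    with open(path, "w") as fh:
        for chrom in sorted(depth):
            arr = np.asarray(depth[chrom])
            if arr.size == 0:
                continue
            change = np.where(np.diff(arr) != 0)[0] + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]}\n")


def read_bedgraph(
    path: str | Path, chrom_lengths: Dict[str, int]
) -> Dict[str, np.ndarray]:
    depth = {c: np.zeros(L, dtype=np.int64) for c, L in chrom_lengths.items()}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )
    for row in df.itertuples(index=False):
        depth[row.chrom][row.start : row.end] = row.value
    return depth


# -- tracts & genotypes -------------------------------------------------- #


def write_tracts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tracts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"line_id": str, "chrom": str, "code": str}
    )


# -- segment sets -------------------------------------------------------- #


def write_segments(segsets: Sequence[SegmentSet], path: str | Path) -> None:
    rows = []
    for ss in segsets:
        for chrom, segs in sorted(ss.intervals.items()):
            for s, e, origin, n in segs:
                rows.append((chrom, s, e, f"{ss.line_id}:{origin}", n, "."))
    pd.DataFrame(rows, columns=BED6_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_segments(path: str | Path) -> List[SegmentSet]:
    df = read_bed(path)
    out: Dict[str, Dict[str, list]] = {}
    for row in df.itertuples(index=False):
        lid, origin = str(row.name).split(":")
        out.setdefault(lid, {}).setdefault(row.chrom, []).append(
            (int(row.start), int(row.end), origin, int(row.score))
        )
    return [SegmentSet(lid, ivs) for lid, ivs in sorted(out.items())]


# -- mutations ----------------------------------------------------------- #


def write_mutations(records: Sequence[MutationRecord], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, sep="\t", index=False)


def read_mutations(path: str | Path) -> List[MutationRecord]:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return []
    recs = []
    for row in df.to_dict("records"):
        row = {k: (None if pd.isna(v) else v) for k, v in row.items()}
        row["pos"] = int(row["pos"])
        row["deleterious"] = bool(row["deleterious"])
        recs.append(MutationRecord(**row))
    return recs


# -- genome annotation JSON ---------------------------------------------- #


def write_genome_json(genome: GenomeModel, path: str | Path) -> None:
    doc = {
        "chromosomes": [[c, L] for c, L in genome.chromosomes],
        "flank_bp": genome.flank_bp,
        "centromeres": {c: list(v) for c, v in genome.centromeres.items()},
        "te_intervals": {
            c: [list(t) for t in v] for c, v in genome.te_intervals.items()
        },
        "genes": [
            {
                "name": g.name,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "exons": [list(t) for t in g.exons],
                "utr5": list(g.utr5),
                "utr3": list(g.utr3),
            }
            for g in genome.genes
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_genome_json(path: str | Path, fasta: str | Path | None = None) -> GenomeModel:
    doc = json.loads(Path(path).read_text())
    seq = read_fasta(fasta) if fasta else None
    return GenomeModel(
        chromosomes=[(c, int(L)) for c, L in doc["chromosomes"]],
        sequence=seq,
        genes=[
            Gene(
                g["name"], g["chrom"], g["start"], g["end"], g["strand"],
                [tuple(t) for t in g["exons"]],
                tuple(g["utr5"]), tuple(g["utr3"]),
            )
            for g in doc["genes"]
        ],
        centromeres={c: tuple(v) for c, v in doc["centromeres"].items()},
        te_intervals={
            c: [tuple(t) for t in v] for c, v in doc["te_intervals"].items()
        },
        flank_bp=doc["flank_bp"],
    )
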