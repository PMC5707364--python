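"""Genome model: sequence, annotation frame, and genetic map.

The :class:`GenomeModel` is the coordinate frame every other stage works in.
It carries chromosome sequences, a gene annotation (gene body split into
UTR/exon/intron sub-features plus 5-kb upstream/downstream flanks), one
centromere interval per chromosome, transposable-element intervals, and the
strand-collapsed trinucleotide composition used to normalize mutation-context
enrichments.

:func:`build_genome` synthesizes a genome with requested genic / GC / TE
fractions so the whole pipeline is testable without any external assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import intervals as iv

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Feature classes in precedence order for overlapping annotations.
FEATURE_PRECEDENCE = ("exon", "UTR", "intron", "up5kb", "down5kb")
FEATURE_CLASSES = FEATURE_PRECEDENCE + ("intergenic",)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def collapse_triplet(triplet: str) -> str:
    """Strand-collapsed canonical form: the lexicographic min of a triplet
    and its reverse complement (64 -> 32 classes)."""
    rc = revcomp(triplet)
    return min(triplet, rc)


#: The 32 canonical strand-collapsed trinucleotide classes.
TRIPLET_CLASSES = tuple(
    sorted(
        {
            collapse_triplet(a + b + c)
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
        }
    )
)


@dataclass
class Gene:
    """A protein-coding gene with a fixed sub-feature layout.

    ``exons`` are CDS intervals in genomic order; the coding frame starts at
    the strand-appropriate end (leftmost exon for ``+``, rightmost for ``-``).
    """

    name: str
    chrom: str
    start: int  # gene body start (incl. UTRs), 0-based
    end: int  # gene body end, half-open
    strand: str
    exons: List[Tuple[int, int]]
    utr5: Tuple[int, int]
    utr3: Tuple[int, int]

    @property
    def introns(self) -> List[Tuple[int, int]]:
        out = []
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


@dataclass
class GenomeModel:
    chromosomes: List[Tuple[str, int]]
    sequence: Optional[Dict[str, str]] = None
    genes: List[Gene] = field(default_factory=list)
    centromeres: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    te_intervals: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)
    flank_bp: int = 5000

    # ------------------------------------------------------------------ #
    def __post_init__(self) -> None:
        self._lengths = dict(self.chromosomes)

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def base(self, chrom: str, pos: int) -> str:
        return self.sequence[chrom][pos]

    def triplet_at(self, chrom: str, pos: int) -> Optional[str]:
        """Reference triplet centered on ``pos`` (0-based); None at chromosome
        edges or when a flank is N."""
        if pos < 1 or pos + 2 > self._lengths[chrom]:
            return None
        t = self.sequence[chrom][pos - 1 : pos + 2]
        return None if "N" in t else t

    # -- annotation geometry ------------------------------------------- #
    def gene_flanks(self, gene: Gene) -> Tuple[Tuple[int, int], Tuple[int, int]]:
        """(up5kb, down5kb) intervals of a gene, strand-aware, clipped."""
        L = self._lengths[gene.chrom]
        left = (max(0, gene.start - self.flank_bp), gene.start)
        right = (gene.end, min(L, gene.end + self.flank_bp))
        return (left, right) if gene.strand == "+" else (right, left)

    @cached_property
    def genic_intervals(self) -> Dict[str, List[Tuple[int, int]]]:
        """Union of gene bodies and their 5-kb flanks, per chromosome (the
        "genic region" of the rate stratification)."""
        per: Dict[str, List[Tuple[int, int]]] = {c: [] for c, _ in self.chromosomes}
        for g in self.genes:
            up, down = self.gene_flanks(g)
            per[g.chrom] += [(g.start, g.end), up, down]
        return {c: iv.merge(ivs) for c, ivs in per.items()}

    @cached_property
    def feature_partition(self) -> Dict[str, Dict[str, List[Tuple[int, int]]]]:
        """Precedence-resolved partition of each chromosome into the six
        feature classes (exon > UTR > intron > up5kb > down5kb > intergenic)."""
        raw: Dict[str, Dict[str, List[Tuple[int, int]]]] = {
            cls: {c: [] for c, _ in self.chromosomes} for cls in FEATURE_PRECEDENCE
        }
        for g in self.genes:
            raw["exon"][g.chrom] += g.exons
            raw["UTR"][g.chrom] += [g.utr5, g.utr3]
            raw["intron"][g.chrom] += g.introns
            up, down = self.gene_flanks(g)
            raw["up5kb"][g.chrom].append(up)
            raw["down5kb"][g.chrom].append(down)
        out: Dict[str, Dict[str, List[Tuple[int, int]]]] = {}
        assigned: Dict[str, List[Tuple[int, int]]] = {c: [] for c, _ in self.chromosomes}
        for cls in FEATURE_PRECEDENCE:
            out[cls] = {}
            for c, _ in self.chromosomes:
                out[cls][c] = iv.subtract(raw[cls][c], assigned[c])
                assigned[c] = iv.merge(assigned[c] + out[cls][c])
        out["intergenic"] = {
            c: iv.complement(assigned[c], L) for c, L in self.chromosomes
        }
        return out

    def feature_class(self, chrom: str, pos: int) -> str:
        for cls in FEATURE_CLASSES:
            if iv.contains(self.feature_partition[cls][chrom], pos):
                return cls
        return "intergenic"

    def compartment_partition(
        self, flank: int = 0
    ) -> Dict[str, Dict[str, List[Tuple[int, int]]]]:
        """Pericentromere (centromere +/- flank) vs chromosome arms."""
        peri: Dict[str, List[Tuple[int, int]]] = {}
        arm: Dict[str, List[Tuple[int, int]]] = {}
        for c, L in self.chromosomes:
            s, e = self.centromeres.get(c, (L // 2, L // 2))
            p = [(max(0, s - flank), min(L, e + flank))]
            peri[c] = iv.merge(p)
            arm[c] = iv.complement(peri[c], L)
        return {"pericentromere": peri, "arm": arm}

    def compartment(self, chrom: str, pos: int, flank: int = 0) -> str:
        part = self.compartment_partition(flank)
        return (
            "pericentromere"
            if iv.contains(part["pericentromere"][chrom], pos)
            else "arm"
        )

    @cached_property
    def callable_intervals(self) -> Dict[str, List[Tuple[int, int]]]:
        """Non-N sequence per chromosome."""
        out: Dict[str, List[Tuple[int, int]]] = {}
        for c, L in self.chromosomes:
            if self.sequence is None:
                out[c] = [(0, L)]
                continue
            arr = np.frombuffer(self.sequence[c].encode(), dtype=np.uint8)
            mask = arr != ord("N")
            out[c] = _runs_from_mask(mask)
        return out

    @cached_property
    def triplet_counts(self) -> Dict[str, int]:
        """Count of each of the 32 strand-collapsed trinucleotides over all
        callable (non-N) windows."""
        code = np.full(256, 4, dtype=np.int64)
        for i, b in enumerate(b"ACGT"):
            code[b] = i
        counts64 = np.zeros(64, dtype=np.int64)
        for c, _ in self.chromosomes:
            arr = code[np.frombuffer(self.sequence[c].encode(), dtype=np.uint8)]
            if len(arr) < 3:
                continue
            a, b_, d = arr[:-2], arr[1:-1], arr[2:]
            valid = (a < 4) & (b_ < 4) & (d < 4)
            idx = (a * 16 + b_ * 4 + d)[valid]
            counts64 += np.bincount(idx, minlength=64)
        out = {t: 0 for t in TRIPLET_CLASSES}
        bases = "ACGT"
        for i in range(64):
            t = bases[i // 16] + bases[(i // 4) % 4] + bases[i % 4]
            out[collapse_triplet(t)] += int(counts64[i])
        return out

    # -- serialization -------------------------------------------------- #
    def write_fasta(self, path: str | Path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        recs = [
            SeqRecord(Seq(self.sequence[c]), id=c, description="")
            for c, _ in self.chromosomes
        ]
        SeqIO.write(recs, str(path), "fasta")

    def write_annotation_beds(self, outdir: str | Path) -> Dict[str, Path]:
        """Write genes / centromeres / TEs as BED6 files; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        with open(outdir / "genes.bed", "w") as fh:
            for g in self.genes:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")
        paths["genes"] = outdir / "genes.bed"
        with open(outdir / "centromeres.bed", "w") as fh:
            for c, _ in self.chromosomes:
                if c in self.centromeres:
                    s, e = self.centromeres[c]
                    fh.write(f"{c}\t{s}\t{e}\tcentromere\t0\t.\n")
        paths["centromeres"] = outdir / "centromeres.bed"
        with open(outdir / "te.bed", "w") as fh:
            for c, ivs in self.te_intervals.items():
                for s, e in ivs:
                    fh.write(f"{c}\t{s}\t{e}\tTE\t0\t.\n")
        paths["te"] = outdir / "te.bed"
        return paths


def _runs_from_mask(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal True runs of a boolean array as half-open intervals."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.where(diff == 1)[0] + 1)
    ends = list(np.where(diff == -1)[0] + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        ends = ends + [mask.size]
    return list(zip(starts, ends))


# ---------------------------------------------------------------------- #
# genome synthesis
# ---------------------------------------------------------------------- #


def _spread(n_units: int, unit_lengths: Sequence[int], L: int, rng) -> List[int]:
    """Start coordinates for non-overlapping units laid left to right with
    multinomially distributed gaps."""
    slack = L - int(sum(unit_lengths))
    if slack < 0:
        raise ValueError("annotation budget exceeds chromosome length")
    gaps = rng.multinomial(slack, np.full(n_units + 1, 1.0 / (n_units + 1)))
    starts = []
    pos = 0
    for i in range(n_units):
        pos += int(gaps[i])
        starts.append(pos)
        pos += int(unit_lengths[i])
    return starts


def build_genome(
    chrom_lengths: Sequence[int] | Dict[str, int],
    genic_fraction: float = 0.3,
    gc: float = 0.47,
    te_fraction: float = 0.3,
    centromere_fraction: float = 0.15,
    seed: int = 0,
    gene_body_bp: int = 4000,
    flank_bp: int = 5000,
    utr_bp: int = 200,
    n_exons: int = 3,
    exon_bp: int = 300,
) -> GenomeModel:
    """Synthesize a :class:`GenomeModel`.

    ``genic_fraction`` is the target fraction of the genome covered by gene
    bodies plus their up/downstream flanks; ``te_fraction`` the fraction
    covered by TE intervals (TEs may overlap genes, as in real maize).
    Chromosome lengths must be >= 10 kb.

    Raises ``ValueError`` if any requested annotation budget exceeds the
    genome.
    """
    if isinstance(chrom_lengths, dict):
        chroms = list(chrom_lengths.items())
    else:
        chroms = [(f"chr{i + 1}", int(L)) for i, L in enumerate(chrom_lengths)]
    for c, L in chroms:
        if L < 10_000:
            raise ValueError(f"chromosome {c} shorter than 10 kb")
    for name, f in [
        ("genic", genic_fraction),
        ("te", te_fraction),
        ("centromere", centromere_fraction),
    ]:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} fraction {f} outside [0, 1]")

    rng = np.random.default_rng(seed)
    seq: Dict[str, str] = {}
    genes: List[Gene] = []
    cents: Dict[str, Tuple[int, int]] = {}
    tes: Dict[str, List[Tuple[int, int]]] = {}

    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)

    body = 2 * utr_bp + n_exons * exon_bp + max(0, n_exons - 1)
    intron_bp = 0
    if n_exons > 1:
        intron_bp = max(50, (gene_body_bp - 2 * utr_bp - n_exons * exon_bp) // (n_exons - 1))
    body = 2 * utr_bp + n_exons * exon_bp + (n_exons - 1) * intron_bp
    unit = body + 2 * flank_bp

    gidx = 0
    for c, L in chroms:
        seq[c] = alphabet[rng.choice(4, size=L, p=p)].tobytes().decode()

        cl = int(round(centromere_fraction * L))
        cents[c] = ((L - cl) // 2, (L - cl) // 2 + cl)

        n_genes = int(round(genic_fraction * L / unit)) if genic_fraction > 0 else 0
        if n_genes * unit > L:
            raise ValueError("requested genic annotation exceeds chromosome")
        starts = _spread(n_genes, [unit] * n_genes, L, rng)
        for s0 in starts:
            bs = s0 + flank_bp  # body start
            strand = "+" if rng.random() < 0.5 else "-"
            utr5 = (bs, bs + utr_bp)
            exons = []
            pos = bs + utr_bp
            for e in range(n_exons):
                exons.append((pos, pos + exon_bp))
                pos += exon_bp + (intron_bp if e < n_exons - 1 else 0)
            utr3 = (pos, pos + utr_bp)
            be = pos + utr_bp
            if strand == "-":
                utr5, utr3 = utr3, utr5
            genes.append(
                Gene(f"gene{gidx:05d}", c, bs, be, strand, exons, utr5, utr3)
            )
            gidx += 1

        te_len = 3000
        n_te = int(round(te_fraction * L / te_len)) if te_fraction > 0 else 0
        if n_te * te_len > L:
            raise ValueError("requested TE annotation exceeds chromosome")
        tes[c] = [
            (s, s + te_len) for s in _spread(n_te, [te_len] * n_te, L, rng)
        ]

    return GenomeModel(
        chromosomes=chroms,
        sequence=seq,
        genes=genes,
        centromeres=cents,
        te_intervals=tes,
        flank_bp=flank_bp,
    )


# ---------------------------------------------------------------------- #
# genetic map
# ---------------------------------------------------------------------- #


@dataclass
class GeneticMap:
    """Monotone cM(bp) map per chromosome, as (bp anchors, cM values)."""

    anchors: Dict[str, Tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValueError("empty genetic map")
        for c, (bp, cm) in self.anchors.items():
            if len(bp) < 2 or np.any(np.diff(cm) < 0):
                raise ValueError(f"map for {c} not a monotone function")

    @classmethod
    def uniform(
        cls, chrom_lengths: Dict[str, int], cm_per_chrom: float = 150.0
    ) -> "GeneticMap":
        return cls(
            {
                c: (np.array([0.0, float(L)]), np.array([0.0, cm_per_chrom]))
                for c, L in chrom_lengths.items()
            }
        )

    def morgans(self, chrom: str) -> float:
        _, cm = self.anchors[chrom]
        return float(cm[-1] - cm[0]) / 100.0

    def bp_at_cm(self, chrom: str, cm_pos: np.ndarray) -> np.ndarray:
        bp, cm = self.anchors[chrom]
        return np.interp(cm_pos, cm, bp)

    def total_cm(self) -> float:
        return sum(float(cm[-1] - cm[0]) for _, cm in self.anchors.values())
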