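"""Forward simulation of a backcross-selfing (BC_b F_s) pedigree.

The population design being emulated: a single F1 from a cross between the
recurrent parent (MO17) and the donor (MEX) is backcrossed ``n_backcrosses``
times to the recurrent parent, then selfed.  Every simulated individual
descends from the same F1.  The expected donor-genome fraction after ``b``
backcrosses is ``0.5**(b+1)`` regardless of the map, which with b=2 gives
the 12.5% expectation of a BC2F7 design.

Meiosis draws a Poisson number of crossovers on genetic distance, with an
optional obligate crossover per chromosome; interference is not modeled.
Mutations are planted afterwards (:func:`plant_mutations`) on the lineage
reaching each final individual, the accounting the site-generations rate
denominator assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome import GeneticMap, GenomeModel
from .segments import SegmentSet

Hap = List[Tuple[int, int, str]]  # (start, end, origin) partition of [0, L)


@dataclass
class PedigreeConfig:
    n_backcrosses: int = 2
    #: selfing generations; default chosen so total generations = 10
    n_self_generations: Optional[int] = None
    obligate_crossover: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_backcrosses < 0:
            raise ValueError("n_backcrosses >= 0")
        if self.n_self_generations is None:
            self.n_self_generations = max(0, 10 - (self.n_backcrosses + 1))

    @property
    def total_generations(self) -> int:
        """Mutation-accumulating generations: F1 formation + backcrosses +
        selfing rounds."""
        return self.n_backcrosses + 1 + self.n_self_generations


@dataclass
class TrueMutation:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    carriers: Tuple[str, ...]
    generation: int  # 0 = preexisting in a parent (recurrent-by-descent)
    origin: str  # parental origin of the carrier segment at pos

    @property
    def recurrent(self) -> bool:
        return len(self.carriers) > 1


@dataclass
class LineTruth:
    segments: SegmentSet
    mutations: List[TrueMutation] = field(default_factory=list)
    het_blocks: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)


@dataclass
class TruthTable:
    chrom_lengths: Dict[str, int]
    lines: Dict[str, LineTruth]
    config: PedigreeConfig

    @property
    def line_ids(self) -> List[str]:
        return sorted(self.lines)

    def all_mutations(self) -> List[TrueMutation]:
        seen = set()
        out = []
        for lt in self.lines.values():
            for m in lt.mutations:
                key = (m.chrom, m.pos, m.alt, m.carriers)
                if key not in seen:
                    seen.add(key)
                    out.append(m)
        return sorted(out, key=lambda m: (m.chrom, m.pos))

    def mean_donor_fraction(self, donor: str = "MEX") -> float:
        return float(
            np.mean([lt.segments.donor_fraction(donor) for lt in self.lines.values()])
        )


# ---------------------------------------------------------------------- #
# meiosis
# ---------------------------------------------------------------------- #


def _gamete(
    hapA: Hap, hapB: Hap, L: int, gmap: GeneticMap, chrom: str,
    rng: np.random.Generator, obligate: bool,
) -> Hap:
    morgans = gmap.morgans(chrom)
    n_xo = rng.poisson(morgans)
    if n_xo == 0 and obligate and morgans > 0:
        n_xo = 1
    bp0, cm = gmap.anchors[chrom]
    if n_xo:
        cm_pos = rng.uniform(cm[0], cm[-1], size=n_xo)
        xo = np.unique(np.round(gmap.bp_at_cm(chrom, np.sort(cm_pos))).astype(np.int64))
        xo = [int(x) for x in xo if 0 < x < L]
    else:
        xo = []
    cur = int(rng.integers(2))
    haps = (hapA, hapB)
    bounds = [0] + xo + [L]
    out: Hap = []
    for a, b in zip(bounds, bounds[1:]):
        for s, e, o in haps[cur]:
            s2, e2 = max(s, a), min(e, b)
            if s2 < e2:
                if out and out[-1][1] == s2 and out[-1][2] == o:
                    out[-1] = (out[-1][0], e2, o)
                else:
                    out.append((s2, e2, o))
        cur = 1 - cur
    return out


def _diploid_segments(hapA: Hap, hapB: Hap) -> List[Tuple[int, int, str, int]]:
    """Overlay a homolog pair into diploid origin segments (HET where the
    homologs disagree)."""
    bps = sorted({s for s, _, _ in hapA + hapB} | {e for _, e, _ in hapA + hapB})

    def origin_at(hap: Hap, pos: int) -> str:
        for s, e, o in hap:
            if s <= pos < e:
                return o
        raise ValueError("haplotype does not cover position")

    out: List[Tuple[int, int, str, int]] = []
    for a, b in zip(bps, bps[1:]):
        oa, ob = origin_at(hapA, a), origin_at(hapB, a)
        o = oa if oa == ob else "HET"
        if out and out[-1][1] == a and out[-1][2] == o:
            out[-1] = (out[-1][0], b, o, 0)
        else:
            out.append((a, b, o, 0))
    return out


def simulate_pedigree(
    genome: GenomeModel | Dict[str, int],
    gmap: GeneticMap,
    cfg: PedigreeConfig,
    n_individuals: int,
) -> TruthTable:
    """Simulate ``n_individuals`` lines through the configured pedigree and
    return their true parental-origin segment sets.

    ``genome`` may be a full :class:`GenomeModel` or just a chromosome-length
    dict (sequence is not needed for segment simulation).
    """
    if n_individuals < 1:
        raise ValueError("n_individuals >= 1")
    lengths = genome.chrom_lengths if isinstance(genome, GenomeModel) else dict(genome)
    missing = set(lengths) - set(gmap.anchors)
    if missing:
        raise ValueError(f"genetic map missing chromosomes: {sorted(missing)}")

    children = np.random.SeedSequence(cfg.seed).spawn(n_individuals)
    lines: Dict[str, LineTruth] = {}
    for i in range(n_individuals):
        rng = np.random.default_rng(children[i])
        lid = f"L{i + 1:04d}"
        segs: Dict[str, List[Tuple[int, int, str, int]]] = {}
        for chrom, L in lengths.items():
            mo17: Hap = [(0, L, "MO17")]
            mex: Hap = [(0, L, "MEX")]
            hapA, hapB = mo17, mex  # the F1
            for _ in range(cfg.n_backcrosses):
                hapA, hapB = (
                    _gamete(hapA, hapB, L, gmap, chrom, rng, cfg.obligate_crossover),
                    list(mo17),
                )
            for _ in range(cfg.n_self_generations):
                hapA, hapB = (
                    _gamete(hapA, hapB, L, gmap, chrom, rng, cfg.obligate_crossover),
                    _gamete(hapA, hapB, L, gmap, chrom, rng, cfg.obligate_crossover),
                )
            segs[chrom] = _diploid_segments(hapA, hapB)
        lines[lid] = LineTruth(segments=SegmentSet(lid, segs))
    return TruthTable(chrom_lengths=lengths, lines=lines, config=cfg)


# ---------------------------------------------------------------------- #
# mutation planting
# ---------------------------------------------------------------------- #

_BASES = "ACGT"


def plant_mutations(
    truth: TruthTable,
    genome: GenomeModel,
    mu: float,
    seed: int = 0,
    recurrent_fraction: float = 0.0,
) -> TruthTable:
    """Plant spontaneous point mutations into the truth table (in place).

    For each line and each of the ``g`` counted generations, a Poisson
    ``mu * genome_length`` number of mutations is placed uniformly over the
    genome of the lineage reaching the final individual; each is a
    single-carrier event.  ``recurrent_fraction`` additionally plants
    preexisting-variant sites shared by two or more lines
    (recurrent-by-descent, generation label 0) at the given fraction of the
    expected unique-mutation count — the confounder the recurrent filter
    removes.
    """
    if mu < 0:
        raise ValueError("mu >= 0")
    rng = np.random.default_rng(seed)
    lengths = truth.chrom_lengths
    chroms = sorted(lengths)
    sizes = np.array([lengths[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    G = int(sizes.sum())
    g = truth.config.total_generations

    def draw_site() -> Tuple[str, int, str, str]:
        c = chroms[rng.choice(len(chroms), p=probs)]
        pos = int(rng.integers(lengths[c]))
        ref = genome.base(c, pos)
        if ref == "N":
            return draw_site()
        alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
        return c, pos, ref, alt

    for lid in truth.line_ids:
        lt = truth.lines[lid]
        for gen in range(1, g + 1):
            for _ in range(rng.poisson(mu * G)):
                c, pos, ref, alt = draw_site()
                origin = lt.segments.origin_at(c, pos) or "MO17"
                lt.mutations.append(
                    TrueMutation(c, pos, ref, alt, (lid,), gen, origin)
                )

    if recurrent_fraction > 0:
        n_lines = len(truth.line_ids)
        expected_unique = mu * G * g * n_lines
        n_rec = rng.poisson(expected_unique * recurrent_fraction)
        for _ in range(n_rec):
            c, pos, ref, alt = draw_site()
            k = int(rng.integers(2, n_lines + 1))
            carriers = tuple(
                sorted(rng.choice(truth.line_ids, size=k, replace=False))
            )
            m = TrueMutation(c, pos, ref, alt, carriers, 0, "MO17")
            for lid in carriers:
                truth.lines[lid].mutations.append(m)
    return truth


def plant_residual_heterozygosity(
    truth: TruthTable,
    seed: int = 0,
    line_fraction: float = 0.3,
    blocks_per_line: float = 1.0,
    block_len_mean: int = 50_000,
) -> TruthTable:
    """Plant residual-heterozygosity blocks (ancestral MO17-source
    heterozygous intervals) into a random subset of lines."""
    rng = np.random.default_rng(seed)
    lengths = truth.chrom_lengths
    chroms = sorted(lengths)
    sizes = np.array([lengths[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    for lid in truth.line_ids:
        if rng.random() >= line_fraction:
            continue
        lt = truth.lines[lid]
        for _ in range(max(1, rng.poisson(blocks_per_line))):
            c = chroms[rng.choice(len(chroms), p=probs)]
            length = max(1000, int(rng.exponential(block_len_mean)))
            start = int(rng.integers(max(1, lengths[c] - length)))
            end = min(lengths[c], start + length)
            lt.het_blocks.setdefault(c, []).append((start, end))
    return truth
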