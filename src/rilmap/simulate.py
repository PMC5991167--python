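"""Forward simulator of single-seed-descent (SSD) recombinant inbred lines.

Two fully inbred founders are crossed to give a single F1; each subsequent
generation selfs one plant per lineage. Meiosis is modelled on a four-chromatid
bivalent: under the obligate-chiasma model exactly one chiasma forms per
chromosome arm, its position uniform on the arm, and each chiasma exchanges one
randomly chosen chromatid of each homologue, so a randomly sampled gamete
chromatid carries on average one crossover junction per chromosome — the
classic "one crossover per chromosome arm per meiosis" expectation. A
per-chromosome suppression probability lets a bivalent resolve with no
crossover at all (the gamete receives an intact parental haplotype), which is
the phenomenological stand-in for the tendency of chromosomes to assort
without recombining. A Poisson crossover model (rate = arm length in Morgans)
is available for map-expansion work.

Coordinates are genetic (cM) throughout; a chromosome spans ``[0, L]`` with
the centromere at ``left_arm_cM``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CALL_H, MATERNAL, PATERNAL, genotype_call

OBLIGATE = "obligate_one_per_arm"
POISSON = "poisson_per_cM"

_REJECTION_CAP = 100_000


@dataclass(frozen=True)
class ChromosomeModel:
    name: str
    left_arm_cM: float
    right_arm_cM: float

    def __post_init__(self) -> None:
        if self.left_arm_cM <= 0 or self.right_arm_cM <= 0:
            raise ValueError(f"arm lengths must be > 0 on {self.name}")

    @property
    def length(self) -> float:
        return self.left_arm_cM + self.right_arm_cM


@dataclass(frozen=True)
class ViabilityLocus:
    """A locus with genotype-dependent offspring viability weights in (0, 1]."""

    chromosome: str
    pos_cM: float
    w_A: float = 1.0
    w_H: float = 1.0
    w_B: float = 1.0

    def __post_init__(self) -> None:
        ws = (self.w_A, self.w_H, self.w_B)
        if any(w < 0 or w > 1 for w in ws):
            raise ValueError("fitness weights must lie in [0, 1]")
        if max(ws) != 1.0:
            raise ValueError("at least one fitness weight must equal 1")

    def weight(self, call: str) -> float:
        return {"A": self.w_A, "H": self.w_H, "B": self.w_B}[call]


@dataclass
class GenomeModel:
    """Genome layout plus the meiosis model parameters."""

    chromosomes: list[ChromosomeModel]
    crossover_model: str = OBLIGATE
    suppression_prob: dict[str, float] = field(default_factory=dict)
    viability_loci: list[ViabilityLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.crossover_model not in (OBLIGATE, POISSON):
            raise ValueError(f"unknown crossover model {self.crossover_model!r}")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, p in self.suppression_prob.items():
            if name not in names:
                raise ValueError(f"suppression for unknown chromosome {name!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError("suppression_prob must lie in [0, 1]")

    def suppression(self, chromosome: str) -> float:
        return self.suppression_prob.get(chromosome, 0.0)

    def chromosome(self, name: str) -> ChromosomeModel:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def total_length_cM(self) -> float:
        return sum(c.length for c in self.chromosomes)

    @classmethod
    def ryegrass_default(
        cls,
        suppression: float = 0.0,
        crossover_model: str = OBLIGATE,
    ) -> "GenomeModel":
        """Seven chromosome pairs, 75 cM arms (1050 cM total map)."""
        chroms = [ChromosomeModel(f"LG{i}", 75.0, 75.0) for i in range(1, 8)]
        supp = {c.name: suppression for c in chroms} if suppression else {}
        return cls(chroms, crossover_model=crossover_model, suppression_prob=supp)


# ---------------------------------------------------------------------------
# Haplotypes


@dataclass
class Haplotype:
    """One chromosome copy: ordered founder-origin segments tiling [0, L]."""

    chromosome: str
    segments: list[tuple[float, float, int]]

    def validate(self, length: float) -> None:
        if not self.segments:
            raise ValueError("empty haplotype")
        if self.segments[0][0] != 0.0 or abs(self.segments[-1][1] - length) > 1e-9:
            raise ValueError("segments do not span [0, L]")
        for (s0, e0, f0), (s1, _e1, f1) in zip(self.segments, self.segments[1:]):
            if abs(e0 - s1) > 1e-9:
                raise ValueError("gap/overlap between segments")
            if f0 == f1:
                raise ValueError("adjacent segments share a founder")
        for s, e, _f in self.segments:
            if e <= s:
                raise ValueError("empty or inverted segment")

    @property
    def n_junctions(self) -> int:
        return len(self.segments) - 1

    def founder_at(self, pos: float) -> int:
        for s, e, f in self.segments:
            if s <= pos < e:
                return f
        return self.segments[-1][2]  # pos == L

    def founders_at(self, positions: np.ndarray) -> np.ndarray:
        """Vectorised founder lookup for sorted or unsorted positions."""
        bounds = np.array([e for _s, e, _f in self.segments])
        founders = np.array([f for _s, _e, f in self.segments])
        idx = np.minimum(np.searchsorted(bounds, positions, side="right"), len(founders) - 1)
        return founders[idx]

    def copy(self) -> "Haplotype":
        return Haplotype(self.chromosome, list(self.segments))


def _merge(segments: list[tuple[float, float, int]]) -> list[tuple[float, float, int]]:
    out = [segments[0]]
    for s, e, f in segments[1:]:
        ps, pe, pf = out[-1]
        if f == pf:
            out[-1] = (ps, e, f)
        else:
            out.append((s, e, f))
    return out


def _slice(
    segments: list[tuple[float, float, int]], a: float, b: float
) -> list[tuple[float, float, int]]:
    """The [a, b) portion of a segment list."""
    out: list[tuple[float, float, int]] = []
    for s, e, f in segments:
        lo, hi = max(s, a), min(e, b)
        if hi > lo:
            out.append((lo, hi, f))
    return out


@dataclass
class DiploidGenome:
    """Per chromosome, an ordered pair of haplotypes."""

    pairs: dict[str, tuple[Haplotype, Haplotype]]

    def is_homozygous(self, chromosome: str) -> bool:
        h0, h1 = self.pairs[chromosome]
        return h0.segments == h1.segments

    def call_at(self, chromosome: str, pos: float) -> str:
        h0, h1 = self.pairs[chromosome]
        return genotype_call(h0.founder_at(pos), h1.founder_at(pos))

    def total_junctions(self) -> int:
        return sum(h0.n_junctions + h1.n_junctions for h0, h1 in self.pairs.values())


@dataclass
class SSDLine:
    line_id: str
    generation: int  # F1 = 1
    genome: DiploidGenome
    parent_id: str | None = None

    @property
    def generation_label(self) -> str:
        return f"F{self.generation}"


# ---------------------------------------------------------------------------
# Meiosis and selfing


def make_founder_f1(genome: GenomeModel, line_id: str = "F1") -> SSDLine:
    """The single F1: one intact maternal + one intact paternal copy per pair."""
    pairs = {}
    for c in genome.chromosomes:
        mat = Haplotype(c.name, [(0.0, c.length, MATERNAL)])
        pat = Haplotype(c.name, [(0.0, c.length, PATERNAL)])
        pairs[c.name] = (mat, pat)
    return SSDLine(line_id=line_id, generation=1, genome=DiploidGenome(pairs))


def _chiasma_positions(chrom: ChromosomeModel, model: str, rng: np.random.Generator) -> list[float]:
    if model == OBLIGATE:
        return [
            rng.uniform(0.0, chrom.left_arm_cM),
            rng.uniform(chrom.left_arm_cM, chrom.length),
        ]
    positions: list[float] = []
    for lo, hi in ((0.0, chrom.left_arm_cM), (chrom.left_arm_cM, chrom.length)):
        # bivalent chiasma rate = 2x the arm's map length in Morgans, so that
        # a sampled chromatid (each chiasma transmits w.p. 1/2) sees crossovers
        # at the map rate and cM coordinates are Haldane map distance
        k = rng.poisson(2.0 * (hi - lo) / 100.0)
        positions.extend(rng.uniform(lo, hi, size=k))
    return sorted(positions)


def meiose_chromosome(
    h0: Haplotype,
    h1: Haplotype,
    chrom: ChromosomeModel,
    genome: GenomeModel,
    rng: np.random.Generator,
) -> Haplotype:
    """Sample one gamete chromatid from a four-strand bivalent.

    Chiasmata form between the synapsed homologue axes before resolution:
    each chiasma joins one of the two chromatids of homologue 1 (axes 0, 1,
    carrying ``h0``) and one of the two of homologue 2 (axes 2, 3, carrying
    ``h1``), chosen at random and independently per chiasma. A gamete
    chromatid is read off by walking one random axis left to right, hopping
    to the partner axis at every chiasma involving the current axis — so
    each chiasma is transmitted to the sampled chromatid with probability
    1/2, giving one expected junction per chromosome under the obligate
    one-chiasma-per-arm model.
    """
    if rng.random() < genome.suppression(chrom.name):
        return (h0 if rng.random() < 0.5 else h1).copy()
    if h0.segments == h1.segments:  # homozygous: any chromatid is identical
        return h0.copy()
    chiasmata = sorted(
        (x, int(rng.integers(2)), 2 + int(rng.integers(2)))
        for x in _chiasma_positions(chrom, genome.crossover_model, rng)
    )
    axis = int(rng.integers(4))
    content = (h0, h0, h1, h1)
    pieces: list[tuple[float, float, Haplotype]] = []
    start = 0.0
    for x, m, p in chiasmata:
        if axis == m or axis == p:
            pieces.append((start, x, content[axis]))
            axis = p if axis == m else m
            start = x
    pieces.append((start, chrom.length, content[axis]))
    segments: list[tuple[float, float, int]] = []
    for s, e, hap in pieces:
        segments.extend(_slice(hap.segments, s, e))
    return Haplotype(chrom.name, _merge(segments))


def simulate_meiosis(
    parent: DiploidGenome, genome: GenomeModel, rng_seed: int | np.random.Generator
) -> dict[str, Haplotype]:
    """Draw one gamete (one haplotype per chromosome) from ``parent``."""
    rng = _as_rng(rng_seed)
    names = {c.name for c in genome.chromosomes}
    if set(parent.pairs) != names:
        raise ValueError("parent/genome chromosome mismatch")
    gamete = {}
    for c in genome.chromosomes:
        h0, h1 = parent.pairs[c.name]
        gamete[c.name] = meiose_chromosome(h0, h1, c, genome, rng)
    return gamete


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("rng seed must be an int or numpy Generator")
    return np.random.default_rng(int(seed))


def _viability_weight(genome: GenomeModel, offspring: DiploidGenome) -> float:
    w = 1.0
    for locus in genome.viability_loci:
        w *= locus.weight(offspring.call_at(locus.chromosome, locus.pos_cM))
    return w


def self_once(
    line: SSDLine,
    genome: GenomeModel,
    rng_seed: int | np.random.Generator,
    child_id: str | None = None,
) -> SSDLine:
    """Self-pollinate: two independent gametes from the same plant.

    With viability loci present the offspring is accepted by rejection
    sampling with probability proportional to the product of its genotype
    fitness weights.
    """
    rng = _as_rng(rng_seed)
    for _ in range(_REJECTION_CAP):
        g1 = simulate_meiosis(line.genome, genome, rng)
        g2 = simulate_meiosis(line.genome, genome, rng)
        offspring = DiploidGenome({c: (g1[c], g2[c]) for c in g1})
        if not genome.viability_loci or rng.random() < _viability_weight(genome, offspring):
            return SSDLine(
                line_id=child_id or f"{line.line_id}.s",
                generation=line.generation + 1,
                genome=offspring,
                parent_id=line.line_id,
            )
    raise RuntimeError("rejection sampling cap exceeded: degenerate fitness weights")


@dataclass
class Cohort:
    """All lines of an SSD pedigree, keyed by generation (F1 = 1)."""

    generations: dict[int, list[SSDLine]]
    genome: GenomeModel

    def lines(self, generation: int) -> list[SSDLine]:
        return self.generations[generation]

    @property
    def final_generation(self) -> int:
        return max(self.generations)

    def pedigree(self) -> pd.DataFrame:
        rows = [
            {"line_id": ln.line_id, "generation": ln.generation_label, "parent_id": ln.parent_id or ""}
            for g in sorted(self.generations)
            for ln in self.generations[g]
        ]
        return pd.DataFrame(rows, columns=["line_id", "generation", "parent_id"])

    def truth_junctions(self, generation: int) -> pd.DataFrame:
        rows = []
        for ln in self.generations[generation]:
            for name, (h0, h1) in ln.genome.pairs.items():
                xs = [f"{s:.4f}" for s, _e, _f in h0.segments[1:]] + [
                    f"{s:.4f}" for s, _e, _f in h1.segments[1:]
                ]
                rows.append(
                    {"line_id": ln.line_id, "chromosome": name, "junctions": ",".join(xs)}
                )
        return pd.DataFrame(rows, columns=["line_id", "chromosome", "junctions"])


def advance_ssd(
    n_lines: int,
    target_generation: int,
    genome: GenomeModel,
    rng_seed: int | np.random.Generator,
    attrition_rate: float = 0.0,
) -> Cohort:
    """Advance ``n_lines`` independent lineages from one F1 to F``target``.

    Every intermediate generation is retained so lineal F2-vs-F6 comparisons
    are possible. Attrition discards a lineage with the given probability at
    each generation step (purely cosmetic cohort shrinkage; default 0).
    """
    if target_generation < 2:
        raise ValueError("target generation must be F2 or later")
    if not 0.0 <= attrition_rate < 1.0:
        raise ValueError("attrition_rate must lie in [0, 1)")
    rng = _as_rng(rng_seed)
    f1 = make_founder_f1(genome)
    generations: dict[int, list[SSDLine]] = {1: [f1]}
    lineages = [
        self_once(f1, genome, rng, child_id=f"L{i:04d}_F2") for i in range(n_lines)
    ]
    generations[2] = list(lineages)
    for g in range(3, target_generation + 1):
        nxt = []
        for ln in lineages:
            if attrition_rate and rng.random() < attrition_rate:
                continue
            stem = ln.line_id.rsplit("_", 1)[0]
            nxt.append(self_once(ln, genome, rng, child_id=f"{stem}_F{g}"))
        if not nxt:
            raise RuntimeError(f"all lineages extinct before F{g}")
        lineages = nxt
        generations[g] = list(lineages)
    return Cohort(generations=generations, genome=genome)


# ---------------------------------------------------------------------------
# Truth extraction


def truth_genotype_matrix(lines: list[SSDLine], panel) -> "GenotypeMatrix":
    """Error-free genotype calls for ``lines`` at the panel's SNP markers."""
    from .containers import GenotypeMatrix

    table = panel.table if hasattr(panel, "table") else panel
    n_ind, n_mark = len(lines), len(table)
    calls = np.empty((n_ind, n_mark), dtype="<U1")
    for chrom, sub in table.groupby("chromosome", sort=False):
        pos = sub["pos_cM"].to_numpy(float)
        cols = sub.index.to_numpy()
        for i, ln in enumerate(lines):
            h0, h1 = ln.genome.pairs[chrom]
            f0 = h0.founders_at(pos)
            f1 = h1.founders_at(pos)
            row = np.where(f0 == f1, np.where(f0 == PATERNAL, "A", "B"), CALL_H)
            calls[i, cols] = row
    return GenotypeMatrix(
        individuals=[ln.line_id for ln in lines],
        markers=table.copy(),
        calls=calls,
    )


def heterozygous_genome_fraction(line: SSDLine) -> float:
    """Fraction of total map length where the two haplotypes differ in origin."""
    het = 0.0
    total = 0.0
    for _name, (h0, h1) in line.genome.pairs.items():
        bounds = sorted(
            {s for s, _e, _f in h0.segments + h1.segments}
            | {h0.segments[-1][1]}
        )
        for a, b in zip(bounds, bounds[1:]):
            mid = 0.5 * (a + b)
            total += b - a
            if h0.founder_at(mid) != h1.founder_at(mid):
                het += b - a
    return het / total
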