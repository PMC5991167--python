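"""RIL genomic-constitution analytics.

Crossover counting on graphical genotypes under a confirmation rule (a state
change is a recombination event only when the new state persists for at
least three consecutive non-missing calls), whole-chromosome recombinant /
non-recombinant classification (class 1 = intact maternal homozygote, 2 =
intact paternal homozygote, 0 = recombinant), residual-heterozygosity
statistics, lineal-descent coherence between an ancestor and a descendant
generation, and the closed-form expectation for the number of *observable*
crossovers: with one obligate crossover per chromosome arm per meiosis a
7-chromosome genome shows B0 = 14 crossovers at F1, the observable number
halves each selfing generation (new junctions are progressively masked by
fixed parental segments), and the cumulative expectation at generation G is
sum over g <= G of B0 * (1/2)^(g-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CALL_A, CALL_B, CALL_H, MISSING, GenotypeMatrix

CLASS_RECOMBINANT = "0"
CLASS_MATERNAL = "1"
CLASS_PATERNAL = "2"
CLASS_UNCLASSIFIED = "U"


@dataclass
class Block:
    state: str
    start: int  # marker index (map order) of first call in block
    end: int  # marker index of last call in block


def count_crossovers(
    calls: np.ndarray | list[str],
    min_confirm: int = 3,
    count_includes_first: bool = True,
    end_exempt: bool = False,
) -> tuple[list[Block], int]:
    """Count confirmed recombination events along one ordered chromosome.

    Over the subsequence of non-missing calls, a state change opens a new
    block only if the new state persists for at least ``min_confirm``
    consecutive non-missing calls (including the first call of the block when
    ``count_includes_first``, which is the default reading). Unconfirmed
    short runs are skipped and the scan keeps comparing against the last
    confirmed state. Each confirmed A<->B, A<->H or H<->B change counts as
    exactly one event. Blocks truncated by the chromosome end must still
    reach ``min_confirm`` unless ``end_exempt`` is set.

    Returns (confirmed blocks with marker-index spans, event count).
    """
    calls = np.asarray(calls, dtype="<U1")
    nm_idx = np.flatnonzero(calls != MISSING)
    if len(nm_idx) == 0:
        return [], 0
    seq = calls[nm_idx]
    # run-length encode the non-missing sequence
    runs: list[tuple[str, int, int]] = []  # (state, start offset, length)
    start = 0
    for k in range(1, len(seq) + 1):
        if k == len(seq) or seq[k] != seq[start]:
            runs.append((seq[start], start, k - start))
            start = k
    required = min_confirm if count_includes_first else min_confirm + 1

    state0, off0, len0 = runs[0]
    blocks = [Block(state0, int(nm_idx[off0]), int(nm_idx[off0 + len0 - 1]))]
    confirmed = state0
    events = 0
    for state, off, length in runs[1:]:
        if state == confirmed:
            blocks[-1].end = int(nm_idx[off + length - 1])
            continue
        is_last = off + length == len(seq)
        if length >= required or (end_exempt and is_last):
            events += 1
            confirmed = state
            blocks.append(Block(state, int(nm_idx[off]), int(nm_idx[off + length - 1])))
        # else: unconfirmed short run, skipped
    return blocks, events


def classify_chromosome(
    calls: np.ndarray | list[str], min_informative: int = 10
) -> str:
    """Whole-chromosome class code: 1 maternal, 2 paternal, 0 recombinant, U.

    A chromosome with fewer than ``min_informative`` non-missing calls is
    unclassified rather than risk labelling a mostly-missing chromosome.
    """
    calls = np.asarray(calls, dtype="<U1")
    nm = calls[calls != MISSING]
    if len(nm) < min_informative:
        return CLASS_UNCLASSIFIED
    if (nm == CALL_B).all():
        return CLASS_MATERNAL
    if (nm == CALL_A).all():
        return CLASS_PATERNAL
    return CLASS_RECOMBINANT


@dataclass
class ConstitutionReport:
    """Per-individual x chromosome crossover blocks, counts and class codes."""

    individuals: list[str]
    chromosomes: list[str]
    blocks: dict[tuple[str, str], list[Block]]
    junctions: pd.DataFrame  # individuals x chromosomes event counts
    class_codes: pd.DataFrame  # individuals x chromosomes codes
    per_locus_het: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    average_het: float = np.nan

    def total_junctions(self) -> pd.Series:
        return self.junctions.sum(axis=1)

    def mean_junctions_per_individual(self) -> float:
        return float(self.total_junctions().mean())


def analyze_constitution(
    matrix: GenotypeMatrix,
    min_confirm: int = 3,
    min_informative: int = 10,
    het_denominator: str = "all_individuals",
) -> ConstitutionReport:
    """Run crossover counting, classification and heterozygosity in one pass."""
    chroms = matrix.chromosomes()
    junc = pd.DataFrame(0, index=matrix.individuals, columns=chroms)
    codes = pd.DataFrame(CLASS_UNCLASSIFIED, index=matrix.individuals, columns=chroms)
    blocks: dict[tuple[str, str], list[Block]] = {}
    for chrom, sub in matrix.markers.groupby("chromosome", sort=False):
        order = sub.sort_values("pos_cM", kind="stable").index.to_numpy()
        for i, ind in enumerate(matrix.individuals):
            row = matrix.calls[i, order]
            blist, n_events = count_crossovers(row, min_confirm=min_confirm)
            blocks[(ind, chrom)] = blist
            junc.loc[ind, chrom] = n_events
            codes.loc[ind, chrom] = classify_chromosome(row, min_informative)
    per_locus, avg = heterozygosity_stats(matrix, denominator=het_denominator)
    return ConstitutionReport(
        individuals=list(matrix.individuals),
        chromosomes=chroms,
        blocks=blocks,
        junctions=junc,
        class_codes=codes,
        per_locus_het=per_locus,
        average_het=avg,
    )


def heterozygosity_stats(
    matrix: GenotypeMatrix, denominator: str = "all_individuals"
) -> tuple[pd.Series, float]:
    """Per-locus heterozygote fraction and its average across all loci.

    The default denominator is the total number of individuals (missing calls
    included), the convention of locus-genotype-frequency tables; the
    ``nonmissing`` variant divides by genotyped individuals only.
    """
    n_h = (matrix.calls == CALL_H).sum(axis=0)
    if denominator == "all_individuals":
        denom = np.full(matrix.n_markers, matrix.n_individuals, dtype=float)
    elif denominator == "nonmissing":
        denom = (matrix.calls != MISSING).sum(axis=0).astype(float)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, n_h / denom, np.nan)
    per_locus = pd.Series(frac, index=matrix.marker_ids, name="het_fraction")
    return per_locus, float(np.nanmean(frac)) if len(frac) else np.nan


# ---------------------------------------------------------------------------
# Expected observable crossovers


@dataclass(frozen=True)
class CrossoverTheory:
    """Observable-crossover model: B0 at F1, halving each generation."""

    base_observable: float = 14.0  # 7 chromosome pairs x 2 arms

    def __post_init__(self) -> None:
        if self.base_observable <= 0:
            raise ValueError("base observable count must be > 0")

    def per_generation(self, g: int) -> float:
        if g < 1:
            raise ValueError("generation index starts at F1 = 1")
        return self.base_observable * 0.5 ** (g - 1)

    def cumulative(self, G: int) -> float:
        return sum(self.per_generation(g) for g in range(1, G + 1))


def floor_one_decimal(x: float) -> float:
    """Truncate at one decimal place (27.5625 -> 27.5), as printed in reports."""
    return math.floor(x * 10.0) / 10.0


def expected_observable_crossovers(
    generation: int,
    theory: CrossoverTheory | None = None,
    cumulative: bool = False,
    floored: bool = False,
) -> float:
    theory = theory or CrossoverTheory()
    value = theory.cumulative(generation) if cumulative else theory.per_generation(generation)
    return floor_one_decimal(value) if floored else value


# ---------------------------------------------------------------------------
# Lineal descent


def lineal_coherence(
    ancestor: np.ndarray | list[str], descendant: np.ndarray | list[str]
) -> tuple[float, list[int]]:
    """Fraction of legal ancestor->descendant transitions at shared loci.

    Homozygous states must be maintained under selfing (A->A, B->B);
    heterozygous ancestors may resolve either way or stay heterozygous
    (H->{A,H,B}). Missing on either side is uninformative.
    """
    anc = np.asarray(ancestor, dtype="<U1")
    des = np.asarray(descendant, dtype="<U1")
    if anc.shape != des.shape:
        raise ValueError("ancestor/descendant call vectors differ in length")
    if anc.size == 0:
        raise ValueError("shared locus set is empty")
    informative = (anc != MISSING) & (des != MISSING)
    if not informative.any():
        return np.nan, []
    violation = informative & np.isin(anc, (CALL_A, CALL_B)) & (anc != des)
    n_inf = int(informative.sum())
    violations = [int(i) for i in np.flatnonzero(violation)]
    return 1.0 - len(violations) / n_inf, violations


# ---------------------------------------------------------------------------
# Cohort summary


def cohort_summary(report: ConstitutionReport) -> dict:
    """Non-recombinant rates over the individuals x chromosomes denominator.

    The denominator is the full chromosome-pair count (41 individuals x 7
    chromosomes = 287 in the F6 study design); numerators are the per-class
    counts, with per-chromosome and per-parent breakdowns.
    """
    codes = report.class_codes
    n_ind, n_chrom = codes.shape
    denominator = n_ind * n_chrom
    flat = codes.to_numpy().ravel()
    n_maternal = int((flat == CLASS_MATERNAL).sum())
    n_paternal = int((flat == CLASS_PATERNAL).sum())
    n_recomb = int((flat == CLASS_RECOMBINANT).sum())
    n_unclassified = int((flat == CLASS_UNCLASSIFIED).sum())
    per_chrom = {
        chrom: {
            "maternal": int((codes[chrom] == CLASS_MATERNAL).sum()),
            "paternal": int((codes[chrom] == CLASS_PATERNAL).sum()),
            "recombinant": int((codes[chrom] == CLASS_RECOMBINANT).sum()),
            "non_recombinant": int(
                ((codes[chrom] == CLASS_MATERNAL) | (codes[chrom] == CLASS_PATERNAL)).sum()
            ),
        }
        for chrom in codes.columns
    }
    return {
        "n_individuals": n_ind,
        "n_chromosomes": n_chrom,
        "denominator": denominator,
        "non_recombinant": n_maternal + n_paternal,
        "non_recombinant_fraction": (n_maternal + n_paternal) / denominator,
        "maternal_non_recombinant": n_maternal,
        "paternal_non_recombinant": n_paternal,
        "recombinant": n_recomb,
        "unclassified": n_unclassified,
        "per_chromosome": per_chrom,
        "mean_junctions_per_individual": report.mean_junctions_per_individual(),
        "average_heterozygosity": report.average_het,
    }


def chromosome_pair_denominator(n_individuals: int, n_chromosomes: int) -> int:
    """The cohort chromosome-pair count: individuals x chromosome pairs."""
    return n_individuals * n_chromosomes


# ---------------------------------------------------------------------------
# Truth oracle helpers (brute-force, for validation against the simulator)


def truth_transition_count(line, panel_table: pd.DataFrame) -> pd.Series:
    """Brute-force observable junction count from truth haplotype segments.

    Evaluates founder origin of both chromosome copies at every marker
    position (segment/marker intersection) and counts genotype-state
    transitions along the map — independent of the observation pipeline and
    of the confirmation-rule scanner.
    """
    out = {}
    for chrom, sub in panel_table.groupby("chromosome", sort=False):
        pos = np.sort(sub["pos_cM"].to_numpy(float))
        h0, h1 = line.genome.pairs[chrom]
        f0 = h0.founders_at(pos)
        f1 = h1.founders_at(pos)
        state = np.where(f0 == f1, np.where(f0 == 1, "A", "B"), "H")
        out[chrom] = int((state[1:] != state[:-1]).sum())
    return pd.Series(out)
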