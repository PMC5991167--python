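"""GBS-like observation model over true RIL genomes.

Produces (a) a codominant SNP genotype matrix with per-call read depths under
a negative-binomial depth model with binomial per-read allele sampling at
heterozygous sites — so a heterozygote seen at depth ``d`` is mis-called as a
homozygote with probability ``2 * (1/2)^d`` (allele dropout), the error mode
that motivates read-depth stringency filtering — and (b) a minimal valid SAM
stream of properly-paired alignment records for dominant presence/absence
(PAV) markers, with configurable non-proper-pair noise records.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CALL_H, MISSING, PAV, SNP, GenotypeMatrix, MarkerPanel
from .simulate import Cohort, GenomeModel, SSDLine, _as_rng

PROPER_PAIR_FLAGS = ((99, 147), (83, 163))
NOISE_FLAGS = (0, 16, 2048)


@dataclass
class DepthModel:
    """Negative-binomial read-depth model.

    ``mean_depth`` is the expected read (pair) count per call; ``dispersion``
    is the NB size parameter (smaller = more overdispersed; the zero mass at
    mean 8, size 1 is ~11%, a realistic GBS dropout rate). ``missing_rate``
    is an extra independent per-call missingness on top of depth-0 dropout.
    """

    mean_depth: float = 8.0
    dispersion: float = 1.0
    missing_rate: float = 0.15

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    def sample_depths(self, shape, rng: np.random.Generator) -> np.ndarray:
        p = self.dispersion / (self.dispersion + self.mean_depth)
        return rng.negative_binomial(self.dispersion, p, size=shape)

    def het_miscall_probability(self) -> float:
        """P(heterozygote called homozygous | called at all), closed form.

        Conditional on depth d >= 1 and the call not being masked as missing,
        a true heterozygote is mis-called iff all d sampled reads carry the
        same allele: P = E[2 * (1/2)^d | d >= 1].
        """
        from scipy import stats

        p = self.dispersion / (self.dispersion + self.mean_depth)
        d = np.arange(1, max(200, int(self.mean_depth * 20)))
        pmf = stats.nbinom.pmf(d, self.dispersion, p)
        pmf /= pmf.sum()
        return float(np.sum(pmf * 2.0 * 0.5**d))


def sample_marker_panel(
    genome: GenomeModel,
    n_snp: int,
    n_pav: int,
    rng_seed: int | np.random.Generator,
) -> MarkerPanel:
    """Draw marker positions uniformly over the genome (length-proportional).

    PAV donors are assigned 50/50 maternal/paternal. Reference coordinates for
    PAV emission are one synthetic scaffold per chromosome with unique 1-based
    positions derived from the cM position.
    """
    if n_snp < 0 or n_pav < 0:
        raise ValueError("marker counts must be >= 0")
    if genome.total_length_cM <= 0:
        raise ValueError("zero-length genome")
    rng = _as_rng(rng_seed)
    lengths = np.array([c.length for c in genome.chromosomes])
    probs = lengths / lengths.sum()
    rows = []
    for kind, n, prefix in ((SNP, n_snp, "S"), (PAV, n_pav, "P")):
        chrom_idx = rng.choice(len(lengths), size=n, p=probs)
        pos = rng.uniform(0.0, lengths[chrom_idx])
        donors = rng.integers(2, size=n) if kind == PAV else np.full(n, -1)
        for k in range(n):
            c = genome.chromosomes[int(chrom_idx[k])]
            rows.append(
                {
                    "marker_id": f"{prefix}{k:05d}",
                    "chromosome": c.name,
                    "pos_cM": float(pos[k]),
                    "kind": kind,
                    "pav_donor": int(donors[k]),
                    "reference_name": f"scaf_{c.name}",
                    "reference_pos": 0,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "marker_id", "chromosome", "pos_cM", "kind",
            "pav_donor", "reference_name", "reference_pos",
        ],
    )
    table = table.sort_values(["chromosome", "pos_cM"], kind="stable").reset_index(drop=True)
    # unique reference positions per scaffold, monotone in map position
    is_pav = table["kind"] == PAV
    for _scaf, sub in table[is_pav].groupby("reference_name", sort=False):
        base = (sub["pos_cM"].to_numpy() * 10_000).astype(int)
        table.loc[sub.index, "reference_pos"] = base + np.arange(len(sub)) + 1
    return MarkerPanel(table)


# ---------------------------------------------------------------------------
# SNP observation


def observe_snps(
    lines: list[SSDLine],
    panel: MarkerPanel,
    depth_model: DepthModel,
    rng_seed: int | np.random.Generator,
) -> GenotypeMatrix:
    """Observed codominant SNP matrix with per-call depths.

    True homozygotes are called correctly whenever depth >= 1; a true
    heterozygote is called H only if both alleles appear among ``d``
    binomial(d, 1/2) per-read allele draws, otherwise it collapses to the
    observed homozygote. Depth 0 or a missing-rate hit gives a missing call.
    """
    from .simulate import truth_genotype_matrix

    rng = _as_rng(rng_seed)
    snp_panel = panel.subset(SNP)
    if len(snp_panel) == 0:
        raise ValueError("panel contains no SNP markers")
    truth = truth_genotype_matrix(lines, snp_panel)
    depths = depth_model.sample_depths(truth.calls.shape, rng)
    calls = truth.calls.copy()

    het = truth.calls == CALL_H
    d_het = depths[het]
    maternal_reads = rng.binomial(d_het, 0.5)
    collapsed = np.where(maternal_reads == 0, "A", np.where(maternal_reads == d_het, "B", "H"))
    calls[het] = collapsed

    missing = (depths == 0) | (rng.random(calls.shape) < depth_model.missing_rate)
    calls[missing] = MISSING
    return GenotypeMatrix(
        individuals=truth.individuals,
        markers=snp_panel.table.copy(),
        calls=calls,
        depths=depths,
    )


# ---------------------------------------------------------------------------
# PAV alignment emission


def _carries_donor(line: SSDLine, chrom: str, pos: float, donor: int) -> bool:
    h0, h1 = line.genome.pairs[chrom]
    return h0.founder_at(pos) == donor or h1.founder_at(pos) == donor


def emit_pav_alignments(
    lines: list[SSDLine],
    panel: MarkerPanel,
    depth_model: DepthModel,
    rng_seed: int | np.random.Generator,
    path: str | os.PathLike,
    noise_fraction: float = 0.0,
    min_pairs: int = 0,
) -> pd.DataFrame:
    """Write a merged SAM file of proper read pairs at PAV positions.

    For each individual carrying the donor allele at a PAV position, ``k``
    read pairs are emitted (k from the depth model, floored at ``min_pairs``),
    each pair as two records with flags (99,147) or (83,163), sharing the
    marker's reference name and 1-based position. Individuals lacking the
    donor allele emit nothing. ``noise_fraction`` adds that proportion of
    extra non-proper records (flags 0/16/2048) which a caller must ignore.
    The sample is carried in the RG tag (one @RG per individual).

    Returns the truth presence table (individuals x PAV markers, bool).
    """
    rng = _as_rng(rng_seed)
    pav_panel = panel.subset(PAV)
    if len(pav_panel) == 0:
        raise ValueError("panel contains no PAV markers")
    if not 0.0 <= noise_fraction < 1.0:
        raise ValueError("noise_fraction must lie in [0, 1)")

    truth = np.zeros((len(lines), len(pav_panel)), dtype=bool)
    records: list[str] = []
    qname = 0
    for j, row in pav_panel.table.iterrows():
        chrom, pos, donor = row["chromosome"], row["pos_cM"], int(row["pav_donor"])
        rname, rpos = row["reference_name"], int(row["reference_pos"])
        for i, ln in enumerate(lines):
            if not _carries_donor(ln, chrom, pos, donor):
                continue
            truth[i, j] = True
            k = max(int(depth_model.sample_depths((), rng)), min_pairs)
            for _ in range(k):
                f1, f2 = PROPER_PAIR_FLAGS[int(rng.integers(2))]
                for flag in (f1, f2):
                    records.append(_sam_line(f"r{qname:08d}", flag, rname, rpos, ln.line_id))
                qname += 1
    if noise_fraction:
        n_noise = int(round(noise_fraction * len(records)))
        pav_rows = pav_panel.table
        for _ in range(n_noise):
            row = pav_rows.iloc[int(rng.integers(len(pav_rows)))]
            ln = lines[int(rng.integers(len(lines)))]
            flag = int(NOISE_FLAGS[int(rng.integers(len(NOISE_FLAGS)))])
            records.append(
                _sam_line(f"n{qname:08d}", flag, row["reference_name"],
                          int(row["reference_pos"]), ln.line_id)
            )
            qname += 1

    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for scaf in pav_panel.table["reference_name"].unique():
            max_pos = int(pav_panel.table.loc[
                pav_panel.table["reference_name"] == scaf, "reference_pos"].max())
            fh.write(f"@SQ\tSN:{scaf}\tLN:{max_pos + 1000}\n")
        for ln_ in lines:
            fh.write(f"@RG\tID:{ln_.line_id}\tSM:{ln_.line_id}\n")
        fh.write("\n".join(records))
        if records:
            fh.write("\n")

    return pd.DataFrame(
        truth, index=[ln.line_id for ln in lines], columns=pav_panel.marker_ids
    )


def _sam_line(qname: str, flag: int, rname: str, pos: int, sample: str) -> str:
    # minimal-valid 11 mandatory columns + RG tag; dummy CIGAR/SEQ/QUAL
    mate = pos
    tlen = 66 if flag in (99, 163) else (-66 if flag in (147, 83) else 0)
    return "\t".join(
        [
            qname, str(flag), rname, str(pos), "60", "66M",
            "=", str(mate), str(tlen), "*", "*", f"RG:Z:{sample}",
        ]
    )


def observe_cohort(
    cohort: Cohort,
    panel: MarkerPanel,
    depth_model: DepthModel,
    rng_seed: int,
    sam_path: str | os.PathLike | None = None,
    generation: int | None = None,
    noise_fraction: float = 0.0,
    pav_depth_model: DepthModel | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame | None]:
    """Observe the final (or requested) generation: SNP matrix + PAV SAM.

    PAV read pairs can use their own depth model (GBS pair depth at PAV
    positions is much shallower than the depth supporting retained SNPs).
    """
    rng = _as_rng(rng_seed)
    lines = cohort.lines(generation or cohort.final_generation)
    matrix = observe_snps(lines, panel, depth_model, rng)
    truth_presence = None
    if sam_path is not None and len(panel.subset(PAV)):
        truth_presence = emit_pav_alignments(
            lines, panel, pav_depth_model or depth_model, rng, sam_path,
            noise_fraction=noise_fraction,
        )
    return matrix, truth_presence
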