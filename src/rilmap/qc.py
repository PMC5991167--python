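"""SNP-marker filtering and correction rules, applied in the canonical order:

monomorphic exclusion -> missingness exclusion (> 35%) -> read-depth
stringency masking (depth < 20 scored missing) -> singleton correction
(isolated discordant calls replaced with missing) -> redundant-locus binning.

Each operation returns a new matrix plus a :class:`QCReport`; matrices carry
their QC history so out-of-order application can be flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .containers import CALL_A, CALL_B, MISSING, GenotypeMatrix

STAGE_ORDER = ["monomorphic", "missing", "stringency", "singleton", "bin"]


@dataclass
class QCReport:
    stage: str
    n_markers_in: int
    n_markers_out: int
    n_calls_masked: int = 0
    disposition: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_markers_removed(self) -> int:
        return self.n_markers_in - self.n_markers_out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": self.stage,
                    "markers_in": self.n_markers_in,
                    "markers_out": self.n_markers_out,
                    "markers_removed": self.n_markers_removed,
                    "calls_masked": self.n_calls_masked,
                    "warnings": ";".join(self.warnings),
                }
            ]
        )


def _check_order(matrix: GenotypeMatrix, stage: str, report: QCReport) -> None:
    done = [s for s in matrix.qc_history if s in STAGE_ORDER]
    expected_before = STAGE_ORDER[: STAGE_ORDER.index(stage)]
    skipped = [s for s in expected_before if s not in done]
    out_of_order = [s for s in done if STAGE_ORDER.index(s) > STAGE_ORDER.index(stage)]
    if out_of_order:
        msg = f"stage '{stage}' applied after later stage(s) {out_of_order}"
        report.warnings.append(msg)
        warnings.warn(msg, stacklevel=3)
    elif skipped:
        report.warnings.append(f"stage '{stage}' applied with earlier stage(s) {skipped} not run")


def filter_monomorphic(matrix: GenotypeMatrix, strict: bool = False
                       ) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers with fewer than two distinct non-missing call states.

    ``strict`` instead requires both parental homozygote classes (A and B)
    to be present.
    """
    report = QCReport("monomorphic", matrix.n_markers, 0)
    _check_order(matrix, "monomorphic", report)
    keep = np.zeros(matrix.n_markers, dtype=bool)
    for j in range(matrix.n_markers):
        col = matrix.calls[:, j]
        states = set(col[col != MISSING])
        keep[j] = (CALL_A in states and CALL_B in states) if strict else len(states) >= 2
    out = matrix.take_markers(np.flatnonzero(keep))
    out.qc_history.append("monomorphic")
    report.n_markers_out = out.n_markers
    report.disposition = {
        mid: ("retained" if k else "removed:monomorphic")
        for mid, k in zip(matrix.marker_ids, keep)
    }
    return out, report


def filter_missing(matrix: GenotypeMatrix, max_missing: float = 0.35
                   ) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers whose missing fraction (over all individuals) > threshold."""
    if not 0.0 < max_missing < 1.0:
        raise ValueError("max_missing must lie in (0, 1)")
    report = QCReport("missing", matrix.n_markers, 0)
    _check_order(matrix, "missing", report)
    frac = (matrix.calls == MISSING).mean(axis=0)
    keep = frac <= max_missing
    out = matrix.take_markers(np.flatnonzero(keep))
    out.qc_history.append("missing")
    report.n_markers_out = out.n_markers
    report.disposition = {
        mid: ("retained" if k else f"removed:missing({f:.3f})")
        for mid, k, f in zip(matrix.marker_ids, keep, frac)
    }
    return out, report


def stringency_mask(matrix: GenotypeMatrix, min_depth: int = 20
                    ) -> tuple[GenotypeMatrix, QCReport]:
    """Score calls with read depth below ``min_depth`` as missing.

    Low-depth heterozygote calls are unreliable (allele dropout), so only
    high-depth calls are trusted; depths are retained for audit.
    """
    if matrix.depths is None:
        raise ValueError(
            "no per-call depths available; skip the stringency stage for this matrix"
        )
    report = QCReport("stringency", matrix.n_markers, matrix.n_markers)
    _check_order(matrix, "stringency", report)
    out = matrix.copy()
    mask = (out.depths < min_depth) & (out.calls != MISSING)
    out.calls[mask] = MISSING
    out.qc_history.append("stringency")
    report.n_calls_masked = int(mask.sum())
    report.disposition = {mid: "retained" for mid in matrix.marker_ids}
    return out, report


def correct_singletons(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, QCReport]:
    """Replace isolated discordant calls (singletons) with missing.

    Per individual per chromosome, over the sequence of non-missing calls in
    map order: a call whose nearest non-missing neighbours on both sides are
    equal to each other and differ from it is set to missing. Terminal calls
    are never modified; one pass only. Singletons mimic double crossovers and
    are overwhelmingly genotyping errors in inbred material.
    """
    report = QCReport("singleton", matrix.n_markers, matrix.n_markers)
    _check_order(matrix, "singleton", report)
    out = matrix.copy()
    n_masked = 0
    for _chrom, sub in out.markers.groupby("chromosome", sort=False):
        order = sub.sort_values("pos_cM", kind="stable").index.to_numpy()
        for i in range(out.n_individuals):
            row = out.calls[i, order]
            nm = np.flatnonzero(row != MISSING)
            if len(nm) < 3:
                continue
            vals = row[nm]
            is_singleton = (vals[1:-1] != vals[:-2]) & (vals[:-2] == vals[2:])
            hit = nm[1:-1][is_singleton]
            out.calls[i, order[hit]] = MISSING
            n_masked += len(hit)
    out.qc_history.append("singleton")
    report.n_calls_masked = n_masked
    report.disposition = {mid: "retained" for mid in matrix.marker_ids}
    return out, report


@dataclass
class MarkerBin:
    representative: str
    members: list[str]
    chromosome: str


def bin_redundant(matrix: GenotypeMatrix, min_overlap: float = 0.5
                  ) -> tuple[GenotypeMatrix, QCReport, list[MarkerBin]]:
    """Merge same-chromosome markers with identical segregation patterns.

    Two markers match when their call vectors agree at every individual where
    both are non-missing (missing acts as a wildcard) and they share at least
    ``min_overlap`` of individuals mutually non-missing. Binning is by
    transitive closure; the representative is the member with least
    missingness (ties broken by map order). Only representatives are carried
    forward as framework loci.
    """
    report = QCReport("bin", matrix.n_markers, 0)
    _check_order(matrix, "bin", report)
    n_ind = matrix.n_individuals
    keep_idx: list[int] = []
    bins: list[MarkerBin] = []
    for chrom, sub in matrix.markers.groupby("chromosome", sort=False):
        order = sub.sort_values("pos_cM", kind="stable").index.to_numpy()
        cols = matrix.calls[:, order]
        present = cols != MISSING
        m = len(order)
        rows_i, cols_j = [], []
        for a in range(m):
            for b in range(a + 1, m):
                both = present[:, a] & present[:, b]
                if both.sum() < min_overlap * n_ind:
                    continue
                if np.array_equal(cols[both, a], cols[both, b]):
                    rows_i.append(a)
                    cols_j.append(b)
        graph = csr_matrix(
            (np.ones(len(rows_i)), (rows_i, cols_j)), shape=(m, m)
        )
        _n, labels = connected_components(graph, directed=False)
        for lab in np.unique(labels):
            members_local = np.flatnonzero(labels == lab)
            missing_counts = (~present[:, members_local]).sum(axis=0)
            rep_local = members_local[int(np.argmin(missing_counts))]
            keep_idx.append(int(order[rep_local]))
            bins.append(
                MarkerBin(
                    representative=matrix.marker_ids[order[rep_local]],
                    members=[matrix.marker_ids[order[k]] for k in members_local],
                    chromosome=chrom,
                )
            )
    keep_idx_arr = np.sort(np.asarray(keep_idx))
    out = matrix.take_markers(keep_idx_arr)
    out.qc_history.append("bin")
    report.n_markers_out = out.n_markers
    rep_of = {mid: b.representative for b in bins for mid in b.members}
    report.disposition = {
        mid: ("retained" if rep_of.get(mid) == mid else f"binned:{rep_of.get(mid)}")
        for mid in matrix.marker_ids
    }
    return out, report, bins


def qc_pipeline(
    matrix: GenotypeMatrix,
    max_missing: float = 0.35,
    min_depth: int = 20,
    strict_monomorphic: bool = False,
    apply_stringency: bool = True,
) -> tuple[GenotypeMatrix, list[QCReport], list[MarkerBin]]:
    """Run the full filtering/correction cascade in the canonical order."""
    reports: list[QCReport] = []
    m, rep = filter_monomorphic(matrix, strict=strict_monomorphic)
    reports.append(rep)
    m, rep = filter_missing(m, max_missing=max_missing)
    reports.append(rep)
    if apply_stringency and m.depths is not None:
        m, rep = stringency_mask(m, min_depth=min_depth)
        reports.append(rep)
    m, rep = correct_singletons(m)
    reports.append(rep)
    m, rep, bins = bin_redundant(m)
    reports.append(rep)
    return m, reports, bins
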