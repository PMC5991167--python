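"""Two-point linkage estimation, grouping, segregation distortion and LD.

Recombination fractions between marker pairs are estimated either under
``ril_self`` coding (heterozygotes excluded pairwise; the observed fraction
R among homozygous calls relates to the per-meiosis fraction r through the
selfing-series limit R = 2r/(1+2r)) or under ``f2`` coding (full 1:2:1 x
1:2:1 two-point likelihood maximised by EM, with dominant markers handled by
collapsing the genotype classes they cannot distinguish). LOD scores are
likelihood-ratio ("linkage") LODs against r = 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .containers import CALL_A, CALL_B, CALL_H, MISSING, GenotypeMatrix

RIL_SELF = "ril_self"
F2 = "f2"


@dataclass
class PairwiseLinkage:
    marker_a: str
    marker_b: str
    rf_hat: float
    lod: float
    n_informative: int
    valid: bool = True


def rf_ril_to_meiotic(R: float) -> float:
    """Invert R = 2r/(1+2r): the per-meiosis r behind an observed RIL fraction."""
    if not 0.0 <= R < 0.5:
        raise ValueError("R must lie in [0, 0.5)")
    return R / (2.0 - 2.0 * R)


def rf_meiotic_to_ril(r: float) -> float:
    """Expected observed fraction among fixed selfing-RIL loci: R = 2r/(1+2r)."""
    return 2.0 * r / (1.0 + 2.0 * r)


def _ril_lod(n_c: int, n_d: int) -> float:
    n = n_c + n_d
    if n == 0:
        return 0.0
    r = n_d / n
    lod = 0.0
    if n_c:
        lod += n_c * np.log10(2.0 * (1.0 - r))
    if n_d:
        lod += n_d * np.log10(2.0 * r)
    return float(lod)


def estimate_rf(
    matrix: GenotypeMatrix,
    pair: tuple[str, str],
    coding: str = RIL_SELF,
) -> PairwiseLinkage:
    """Two-point RF and LOD for one marker pair."""
    a, b = pair
    u = matrix.column(a)
    v = matrix.column(b)
    if coding == RIL_SELF:
        mask = np.isin(u, (CALL_A, CALL_B)) & np.isin(v, (CALL_A, CALL_B))
        n = int(mask.sum())
        if n < 2:
            return PairwiseLinkage(a, b, np.nan, np.nan, n, valid=False)
        n_d = int((u[mask] != v[mask]).sum())
        rf = min(n_d / n, 0.5)
        return PairwiseLinkage(a, b, rf, _ril_lod(n - n_d, n_d), n)
    if coding == F2:
        return _estimate_rf_f2(matrix, a, b)
    raise ValueError(f"unknown coding {coding!r}")


def pairwise_ril(
    matrix: GenotypeMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All-pairs RF/LOD under ril_self coding, vectorised.

    Returns (rf, lod, n_informative) as marker x marker DataFrames.
    """
    ids = list(matrix.marker_ids)
    is_a = (matrix.calls == CALL_A).astype(float)
    is_b = (matrix.calls == CALL_B).astype(float)
    n_c = is_a.T @ is_a + is_b.T @ is_b
    n_d = is_a.T @ is_b + is_b.T @ is_a
    n = n_c + n_d
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(n > 0, n_d / np.maximum(n, 1), np.nan)
        lod = np.where(
            n_c > 0, n_c * np.log10(np.maximum(2.0 * (1.0 - r), 1e-300)), 0.0
        ) + np.where(n_d > 0, n_d * np.log10(np.maximum(2.0 * r, 1e-300)), 0.0)
    rf = np.minimum(r, 0.5)
    rf[n < 2] = np.nan
    lod[n < 2] = np.nan
    np.fill_diagonal(rf, 0.0)
    return (
        pd.DataFrame(rf, index=ids, columns=ids),
        pd.DataFrame(lod, index=ids, columns=ids),
        pd.DataFrame(n.astype(int), index=ids, columns=ids),
    )


# ---------------------------------------------------------------------------
# F2 two-point EM

_GAMETES = [(1, 1), (0, 0), (1, 0), (0, 1)]  # (allele@locus1, allele@locus2); 1=paternal
_N_REC = np.array([0, 0, 1, 1])


def _gamete_probs(r: float) -> np.ndarray:
    return np.array([(1 - r) / 2, (1 - r) / 2, r / 2, r / 2])


def _obs_classes(call: str, kind: str, donor: str) -> tuple[int, ...]:
    """Compatible true genotypes (# paternal alleles) for an observed call."""
    if kind == "codominant":
        return {CALL_A: (2,), CALL_H: (1,), CALL_B: (0,)}[call]
    # dominant presence/absence markers: the donor homozygote symbol encodes
    # presence; presence is compatible with any genotype carrying the donor
    if donor == CALL_A:
        return (1, 2) if call == CALL_A else (0,)
    return (0, 1) if call == CALL_B else (2,)


def _estimate_rf_f2(
    matrix: GenotypeMatrix,
    a: str,
    b: str,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> PairwiseLinkage:
    meta = matrix.markers.set_index("marker_id")
    kinds, donors = {}, {}
    for mid in (a, b):
        k = meta.loc[mid, "kind"] if "kind" in meta.columns else "SNP_codominant"
        kinds[mid] = "dominant" if str(k).startswith("PAV") else "codominant"
        donors[mid] = "A"
        if kinds[mid] == "dominant" and "pav_donor" in meta.columns:
            donors[mid] = "B" if int(meta.loc[mid, "pav_donor"]) == 0 else "A"
    u, v = matrix.column(a), matrix.column(b)
    ok = (u != MISSING) & (v != MISSING)
    cells: dict[tuple[str, str], int] = {}
    for cu, cv in zip(u[ok], v[ok]):
        cells[(cu, cv)] = cells.get((cu, cv), 0) + 1
    n = int(ok.sum())
    if n < 2:
        return PairwiseLinkage(a, b, np.nan, np.nan, n, valid=False)

    # enumerate the 16 egg x sperm gamete combos once
    combos = list(product(range(4), range(4)))
    combo_geno = [
        (_GAMETES[e][0] + _GAMETES[s][0], _GAMETES[e][1] + _GAMETES[s][1])
        for e, s in combos
    ]
    combo_rec = np.array([_N_REC[e] + _N_REC[s] for e, s in combos])

    def cell_combo_mask(cell: tuple[str, str]) -> np.ndarray:
        g1 = _obs_classes(cell[0], kinds[a], donors[a])
        g2 = _obs_classes(cell[1], kinds[b], donors[b])
        return np.array([(x in g1) and (y in g2) for x, y in combo_geno])

    masks = {cell: cell_combo_mask(cell) for cell in cells}

    def loglik(r: float) -> float:
        gp = _gamete_probs(r)
        cp = np.array([gp[e] * gp[s] for e, s in combos])
        ll = 0.0
        for cell, cnt in cells.items():
            p = cp[masks[cell]].sum()
            ll += cnt * np.log(max(p, 1e-300))
        return ll

    r = 0.25
    for _ in range(max_iter):
        gp = _gamete_probs(r)
        cp = np.array([gp[e] * gp[s] for e, s in combos])
        exp_rec = 0.0
        for cell, cnt in cells.items():
            w = cp[masks[cell]]
            exp_rec += cnt * float((w * combo_rec[masks[cell]]).sum() / max(w.sum(), 1e-300))
        r_new = exp_rec / (2.0 * n)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    r = min(max(r, 0.0), 0.5)
    lod = (loglik(r) - loglik(0.5)) / np.log(10.0)
    return PairwiseLinkage(a, b, r, max(lod, 0.0), n)


# ---------------------------------------------------------------------------
# Grouping


def group_markers(
    rf: pd.DataFrame,
    lod: pd.DataFrame,
    min_lod: float = 6.0,
    max_rf: float = 0.35,
    lod_sweep: tuple[float, ...] = (6.0, 7.0, 8.0, 9.0),
) -> tuple[list[list[str]], dict[float, int]]:
    """Single-linkage transitive closure on (lod >= min_lod) & (rf <= max_rf).

    Returns groups sorted by decreasing size, plus the group count across a
    LOD sweep so grouping stability can be assessed.
    """
    ids = list(rf.index)

    def n_groups_at(lod_thr: float) -> tuple[int, np.ndarray]:
        adj = (lod.to_numpy() >= lod_thr) & (rf.to_numpy() <= max_rf)
        np.fill_diagonal(adj, False)
        ncomp, labels = connected_components(csr_matrix(adj), directed=False)
        return ncomp, labels

    _n, labels = n_groups_at(min_lod)
    groups = [
        [ids[i] for i in np.flatnonzero(labels == lab)] for lab in np.unique(labels)
    ]
    groups.sort(key=len, reverse=True)
    sweep = {thr: n_groups_at(thr)[0] for thr in lod_sweep}
    return groups, sweep


# ---------------------------------------------------------------------------
# Segregation distortion


@dataclass
class SDResult:
    marker_id: str
    n_A: int
    n_H: int
    n_B: int
    chi2: float
    p_value: float
    distorted: bool
    skipped: bool = False


def segregation_test(
    matrix: GenotypeMatrix,
    alpha: float = 0.05,
    coding: str = RIL_SELF,
) -> tuple[list[SDResult], pd.Series]:
    """Chi-square goodness of fit per marker.

    ``ril_self``: homozygote counts vs 1:1 (df=1), heterozygotes excluded;
    ``f2``: A:H:B vs 1:2:1 (df=2). Also returns the per-chromosome fraction
    of distorted loci among testable loci.
    """
    results: list[SDResult] = []
    for j, mid in enumerate(matrix.marker_ids):
        col = matrix.calls[:, j]
        n_a = int((col == CALL_A).sum())
        n_h = int((col == CALL_H).sum())
        n_b = int((col == CALL_B).sum())
        if coding == RIL_SELF:
            total = n_a + n_b
            if total == 0:
                results.append(SDResult(mid, n_a, n_h, n_b, np.nan, np.nan, False, True))
                continue
            chi2, p = stats.chisquare([n_a, n_b])
        else:
            total = n_a + n_h + n_b
            if total == 0:
                results.append(SDResult(mid, n_a, n_h, n_b, np.nan, np.nan, False, True))
                continue
            chi2, p = stats.chisquare(
                [n_a, n_h, n_b], f_exp=[total / 4, total / 2, total / 4]
            )
        results.append(SDResult(mid, n_a, n_h, n_b, float(chi2), float(p), p < alpha))
    per_chrom = {}
    for chrom, sub in matrix.markers.groupby("chromosome", sort=False):
        idx = sub.index.to_numpy()
        tested = [results[i] for i in idx if not results[i].skipped]
        per_chrom[chrom] = (
            sum(r.distorted for r in tested) / len(tested) if tested else np.nan
        )
    return results, pd.Series(per_chrom, name="distorted_fraction")


def sd_results_frame(results: list[SDResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# Linkage disequilibrium


def ld_r2(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Squared allele-frequency correlation (r^2) between all marker pairs.

    Dosage coding A=0, H=1, B=2; complete-case per pair; diagonal 1; pairs
    with zero variance in either marker are undefined (NaN).
    """
    if matrix.n_markers < 2:
        raise ValueError("need at least two markers for LD")
    dosage = np.full(matrix.calls.shape, np.nan)
    dosage[matrix.calls == CALL_A] = 0.0
    dosage[matrix.calls == CALL_H] = 1.0
    dosage[matrix.calls == CALL_B] = 2.0
    m = ~np.isnan(dosage)
    x = np.where(m, dosage, 0.0)
    mf = m.astype(float)
    n = mf.T @ mf
    sx = x.T @ mf
    sy = sx.T
    sxx = (x * x).T @ mf
    syy = sxx.T
    sxy = x.T @ x
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = n * sxy - sx * sy
        var_x = n * sxx - sx**2
        var_y = n * syy - sy**2
        r2 = cov**2 / (var_x * var_y)
    r2[(var_x <= 0) | (var_y <= 0) | (n < 2)] = np.nan
    np.fill_diagonal(r2, 1.0)
    ids = list(matrix.marker_ids)
    return pd.DataFrame(r2, index=ids, columns=ids)


def ld_long_table(r2: pd.DataFrame, markers: pd.DataFrame) -> pd.DataFrame:
    """Long-format upper-triangle LD table with chromosome annotations."""
    chrom = markers.set_index("marker_id")["chromosome"]
    ids = list(r2.index)
    rows = []
    arr = r2.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rows.append(
                {
                    "marker_a": ids[i],
                    "marker_b": ids[j],
                    "chrom_a": chrom[ids[i]],
                    "chrom_b": chrom[ids[j]],
                    "same_chromosome": chrom[ids[i]] == chrom[ids[j]],
                    "r2": arr[i, j],
                }
            )
    return pd.DataFrame(rows)
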