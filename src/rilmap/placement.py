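"""Placement of dominant PAV markers onto a framework SNP map.

Each PAV is assigned to the bin (map position) of the framework marker with
which it shows the lowest recombination fraction, subject to RF <= 0.2 and
LOD >= 11; ties are broken by the highest LOD, then the smallest map
position, making placement deterministic regardless of marker order. PAVs
with no framework marker passing both thresholds stay unplaced.

PAVs are treated as pseudo-codominant against the near-fixed RIL background
(presence -> donor homozygote symbol), with heterozygous framework calls
excluded pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CALL_A, CALL_B, GenotypeMatrix
from .linkage import _ril_lod


@dataclass
class PlacementResult:
    pav_id: str
    framework_id: str | None
    chromosome: str | None
    pos_cM: float | None
    rf_hat: float
    lod: float
    status: str  # "placed" | "unplaced"


def place_pavs(
    framework: GenotypeMatrix,
    pav: GenotypeMatrix,
    rf_max: float = 0.2,
    lod_min: float = 11.0,
) -> list[PlacementResult]:
    """Assign each PAV marker to a framework bin by the min-RF / max-LOD rule."""
    if framework.individuals != pav.individuals:
        raise ValueError("framework and PAV matrices must share the same individuals")

    fw_a = (framework.calls == CALL_A).astype(float)
    fw_b = (framework.calls == CALL_B).astype(float)
    pv_a = (pav.calls == CALL_A).astype(float)
    pv_b = (pav.calls == CALL_B).astype(float)
    # concordant / discordant homozygote counts: PAVs x framework markers
    n_c = pv_a.T @ fw_a + pv_b.T @ fw_b
    n_d = pv_a.T @ fw_b + pv_b.T @ fw_a
    n = n_c + n_d

    fw_meta = framework.markers
    fw_pos = fw_meta["pos_cM"].to_numpy(float)
    results: list[PlacementResult] = []
    for i, pav_id in enumerate(pav.marker_ids):
        best = None
        for j in range(framework.n_markers):
            if n[i, j] < 2:
                continue
            rf = min(n_d[i, j] / n[i, j], 0.5)
            if rf > rf_max:
                continue
            lod = _ril_lod(int(n_c[i, j]), int(n_d[i, j]))
            if lod < lod_min:
                continue
            key = (rf, -lod, fw_pos[j])
            if best is None or key < best[0]:
                best = (key, j, rf, lod)
        if best is None:
            results.append(
                PlacementResult(pav_id, None, None, None, np.nan, np.nan, "unplaced")
            )
        else:
            _key, j, rf, lod = best
            results.append(
                PlacementResult(
                    pav_id,
                    fw_meta["marker_id"].iloc[j],
                    fw_meta["chromosome"].iloc[j],
                    float(fw_pos[j]),
                    rf,
                    lod,
                    "placed",
                )
            )
    return results


def placements_frame(results: list[PlacementResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pav_id": r.pav_id,
                "chromosome": r.chromosome or "",
                "pos_cM": r.pos_cM,
                "framework_id": r.framework_id or "",
                "rf": r.rf_hat,
                "lod": r.lod,
                "status": r.status,
            }
            for r in results
        ]
    )
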