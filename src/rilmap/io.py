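"""Readers and writers for genotype matrices and graphical-genotype reports.

Two dialects are supported: ``rqtl_csv`` (the R/qtl cross CSV layout — marker
ids, chromosome and cM position header rows, then one row of calls per
individual) and ``loc_like`` (a JoinMap locus-genotype-file flavour: one
record per marker with a call string over ``a h b -``). Missing is ``-`` in
both. The loc dialect carries no map metadata; chromosome/position survive a
round trip only in ``rqtl_csv``.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import CALL_ALPHABET, GenotypeMatrix

_LOC_TO_CALL = {"a": "A", "h": "H", "b": "B", "-": "-"}


def _sorted_marker_order(markers: pd.DataFrame) -> np.ndarray:
    """Stable within-chromosome position sort; chromosome blocks keep file order."""
    order: list[int] = []
    for _chrom, sub in markers.groupby("chromosome", sort=False):
        order.extend(sub.sort_values("pos_cM", kind="stable").index)
    return np.asarray(order)


def write_genotype_csv(matrix: GenotypeMatrix, path: str | os.PathLike,
                       dialect: str = "rqtl_csv") -> None:
    if dialect == "rqtl_csv":
        _write_rqtl(matrix, path)
    elif dialect == "loc_like":
        _write_loc(matrix, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_genotype_csv(path: str | os.PathLike, dialect: str = "rqtl_csv") -> GenotypeMatrix:
    if dialect == "rqtl_csv":
        return _read_rqtl(path)
    if dialect == "loc_like":
        return _read_loc(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _fmt_pos(x: float) -> str:
    return repr(float(x))


def _write_rqtl(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    order = _sorted_marker_order(matrix.markers)
    m = matrix.take_markers(order)
    with open(path, "w") as fh:
        fh.write("id," + ",".join(m.marker_ids) + "\n")
        fh.write("," + ",".join(m.markers["chromosome"].astype(str)) + "\n")
        fh.write("," + ",".join(_fmt_pos(p) for p in m.markers["pos_cM"]) + "\n")
        for i, ind in enumerate(m.individuals):
            fh.write(ind + "," + ",".join(m.calls[i]) + "\n")


def _read_rqtl(path: str | os.PathLike) -> GenotypeMatrix:
    with open(path) as fh:
        rows = [line.rstrip("\n").split(",") for line in fh if line.strip()]
    if len(rows) < 4:
        raise ValueError("rqtl_csv file needs 3 header rows plus >=1 individual")
    width = len(rows[0])
    for k, r in enumerate(rows):
        if len(r) != width:
            raise ValueError(f"ragged row {k + 1}: {len(r)} fields, expected {width}")
    marker_ids = rows[0][1:]
    chroms = rows[1][1:]
    pos = [float(p) for p in rows[2][1:]]
    individuals = [r[0] for r in rows[3:]]
    calls = np.array([r[1:] for r in rows[3:]], dtype="<U1")
    for i, ind in enumerate(individuals):
        for j, c in enumerate(calls[i]):
            if c not in CALL_ALPHABET:
                raise ValueError(
                    f"unknown genotype symbol {c!r} at individual {ind!r}, "
                    f"marker {marker_ids[j]!r}"
                )
    markers = pd.DataFrame(
        {"marker_id": marker_ids, "chromosome": chroms, "pos_cM": pos,
         "kind": "SNP_codominant"}
    )
    return GenotypeMatrix(individuals=individuals, markers=markers, calls=calls)


def _write_loc(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    order = _sorted_marker_order(matrix.markers)
    m = matrix.take_markers(order)
    with open(path, "w") as fh:
        fh.write(f"; nind = {m.n_individuals}\n")
        fh.write("; individuals = " + " ".join(m.individuals) + "\n")
        for j, mid in enumerate(m.marker_ids):
            fh.write(mid + "\t" + "".join(m.calls[:, j]).lower() + "\n")


def _read_loc(path: str | os.PathLike) -> GenotypeMatrix:
    individuals: list[str] | None = None
    marker_ids: list[str] = []
    columns: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(";"):
                if "individuals =" in line:
                    individuals = line.split("=", 1)[1].split()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"ragged record at line {lineno}")
            mid, callstr = parts
            col = []
            for k, ch in enumerate(callstr.lower()):
                if ch not in _LOC_TO_CALL:
                    raise ValueError(
                        f"unknown genotype symbol {ch!r} at marker {mid!r}, "
                        f"individual index {k}"
                    )
                col.append(_LOC_TO_CALL[ch])
            marker_ids.append(mid)
            columns.append(col)
    lengths = {len(c) for c in columns}
    if len(lengths) > 1:
        raise ValueError("ragged call strings across markers")
    n_ind = lengths.pop() if lengths else 0
    if individuals is None:
        individuals = [f"ind{i + 1}" for i in range(n_ind)]
    if len(individuals) != n_ind:
        raise ValueError("individual list does not match call-string length")
    calls = np.array(columns, dtype="<U1").T if columns else np.empty((n_ind, 0), "<U1")
    markers = pd.DataFrame(
        {"marker_id": marker_ids, "chromosome": "un", "pos_cM": np.nan,
         "kind": "SNP_codominant"}
    )
    return GenotypeMatrix(individuals=individuals, markers=markers, calls=calls)


def parse_loc_string(callstr: str) -> list[str]:
    """Map a loc-dialect call string (case-insensitive) to call symbols."""
    out = []
    for ch in callstr.lower():
        if ch not in _LOC_TO_CALL:
            raise ValueError(f"unknown genotype symbol {ch!r}")
        out.append(_LOC_TO_CALL[ch])
    return out


# ---------------------------------------------------------------------------
# Graphical genotypes


def write_graphical_genotypes(
    matrix: GenotypeMatrix,
    class_codes: pd.DataFrame,
    path: str | os.PathLike | None = None,
    png_path: str | os.PathLike | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-chromosome call tables with a footer row of chromosome class codes.

    ``class_codes`` is individuals x chromosomes with entries 0 (recombinant),
    1 (maternal non-recombinant), 2 (paternal non-recombinant) or ``U``
    (unclassified), as produced by the constitution analysis.
    """
    if list(class_codes.index) != list(matrix.individuals):
        raise ValueError("class_codes individuals do not match matrix")
    if set(class_codes.columns) != set(matrix.chromosomes()):
        raise ValueError("class_codes chromosomes do not match matrix")
    reports: dict[str, pd.DataFrame] = {}
    for chrom, sub in matrix.markers.groupby("chromosome", sort=False):
        order = sub.sort_values("pos_cM", kind="stable").index.to_numpy()
        block = pd.DataFrame(
            matrix.calls[:, order].T,
            index=matrix.markers["marker_id"].iloc[order],
            columns=matrix.individuals,
        )
        footer = pd.DataFrame(
            [class_codes[chrom].astype(str).to_numpy()],
            index=["class_code"],
            columns=matrix.individuals,
        )
        reports[chrom] = pd.concat([block, footer])
    if path is not None:
        with open(path, "w") as fh:
            for chrom, rep in reports.items():
                fh.write(f"# chromosome {chrom}\n")
                rep.to_csv(fh, sep="\t", index_label="marker")
    if png_path is not None:
        _graphical_png(matrix, png_path)
    return reports


def _graphical_png(matrix: GenotypeMatrix, png_path: str | os.PathLike) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    coding = {"A": 0, "H": 1, "B": 2, "-": 3}
    img = np.vectorize(coding.get)(matrix.calls)
    cmap = ListedColormap(["#4477cc", "#eecc33", "#ee88aa", "#cccccc"])
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.imshow(img, aspect="auto", cmap=cmap, interpolation="nearest", vmin=0, vmax=3)
    ax.set_xlabel("marker (map order)")
    ax.set_ylabel("individual")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)


def write_ld_heatmap(r2: pd.DataFrame, png_path: str | os.PathLike) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(r2.to_numpy(), cmap="Reds", vmin=0, vmax=1, interpolation="nearest")
    fig.colorbar(im, ax=ax, label=r"$r^2$")
    ax.set_xlabel("marker (map order)")
    ax.set_ylabel("marker (map order)")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
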