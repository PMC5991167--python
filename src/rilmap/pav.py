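"""Presence/absence variant (PAV) calling from paired-end alignment records.

Dominant PAV markers are scored from read-pair depth at unique alignment
start positions: only properly-paired records on both strands (SAM flags 99
pairing with 147, and 83 pairing with 163) contribute, a pair is counted once
via its first-in-pair flag (99 or 83), and positions are keyed on the RNAME
and 1-based leftmost POS fields. Candidate positions are then filtered for
1:1 presence segregation (+/-20% either side, so a presence frequency inside
[0.3, 0.7]) and a mean pair depth of at least 8 among the samples exhibiting
alignments.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

FIRST_IN_PAIR_FLAGS = frozenset({99, 83})
PROPER_FLAGS = frozenset({99, 147, 83, 163})


class AlignmentRecord(NamedTuple):
    sample: str
    flag: int
    reference_name: str
    position: int  # 1-based leftmost


def read_sam_records(
    path: str | os.PathLike, sample: str | None = None
) -> tuple[list[AlignmentRecord], int]:
    """Parse a SAM text file into minimal alignment records.

    The sample is taken from the RG:Z tag when present, else from ``sample``
    (defaulting to the file stem) — supporting both per-sample files and a
    single merged file. Malformed lines are skipped and counted; more than
    10% malformed among non-header lines is a hard error.

    Returns (records, n_malformed).
    """
    default_sample = sample if sample is not None else Path(path).stem
    records: list[AlignmentRecord] = []
    n_malformed = 0
    n_lines = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            if not line.strip():
                continue
            n_lines += 1
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                n_malformed += 1
                continue
            try:
                flag = int(fields[1])
                pos = int(fields[3])
            except ValueError:
                n_malformed += 1
                continue
            if flag < 0 or pos < 1:
                n_malformed += 1
                continue
            samp = default_sample
            for tag in fields[11:]:
                if tag.startswith("RG:Z:"):
                    samp = tag[5:]
                    break
            records.append(AlignmentRecord(samp, flag, fields[2], pos))
    if n_lines and n_malformed / n_lines > 0.10:
        raise ValueError(
            f"{n_malformed}/{n_lines} malformed SAM lines in {path} (>10%)"
        )
    return records, n_malformed


@dataclass
class PAVTable:
    """Pair-depth counts and presence calls at alignment start positions.

    ``counts``: positions (MultiIndex reference_name, position) x samples.
    ``presence``: same shape, boolean, filled by :func:`call_presence`.
    """

    counts: pd.DataFrame
    presence: pd.DataFrame | None = None
    filter_report: pd.DataFrame | None = None
    n_malformed: int = 0

    @property
    def n_positions(self) -> int:
        return len(self.counts)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def presence_frequency(self) -> pd.Series:
        if self.presence is None:
            raise ValueError("presence not yet called")
        return self.presence.mean(axis=1)

    def mean_depth_present(self) -> pd.Series:
        if self.presence is None:
            raise ValueError("presence not yet called")
        masked = self.counts.where(self.presence)
        return masked.mean(axis=1, skipna=True).fillna(0.0)


def count_pair_depth(
    records: Iterable[AlignmentRecord], samples: list[str] | None = None
) -> PAVTable:
    """Pair-depth per (reference_name, position, sample).

    Only flags in {99, 147, 83, 163} qualify; a pair is counted exactly once
    through its first-in-pair record (flag 99 or 83). All other flags are
    ignored.
    """
    tallies: dict[tuple[str, int, str], int] = {}
    seen_samples: dict[str, None] = {}
    for rec in records:
        if rec.flag not in PROPER_FLAGS:
            continue
        seen_samples.setdefault(rec.sample, None)
        if rec.flag not in FIRST_IN_PAIR_FLAGS:
            continue
        key = (rec.reference_name, rec.position, rec.sample)
        tallies[key] = tallies.get(key, 0) + 1
    cols = samples if samples is not None else sorted(seen_samples)
    if tallies:
        df = pd.Series(tallies).rename_axis(["reference_name", "position", "sample"])
        counts = (
            df.unstack("sample", fill_value=0)
            .reindex(columns=cols, fill_value=0)
            .sort_index()
        )
    else:
        counts = pd.DataFrame(
            index=pd.MultiIndex.from_tuples([], names=["reference_name", "position"]),
            columns=cols,
            dtype=int,
        )
    counts.columns.name = "sample"
    return PAVTable(counts=counts.astype(int))


def call_presence(table: PAVTable, min_pair_depth: int = 1) -> PAVTable:
    """Present iff pair depth >= ``min_pair_depth``; otherwise absent.

    For dominant markers, absence of alignments and missing data are
    indistinguishable and are both recorded as absent.
    """
    table.presence = table.counts >= min_pair_depth
    return table


def filter_segregating(
    table: PAVTable,
    band: tuple[float, float] = (0.3, 0.7),
    min_mean_depth: float = 8.0,
) -> tuple[PAVTable, pd.DataFrame]:
    """Keep positions segregating near 1:1 with adequate depth.

    A position is retained iff its presence frequency over all samples lies
    inside ``band`` (inclusive; default the 1:1 expectation 0.5 +/- 0.2) and
    its mean pair depth among present samples is >= ``min_mean_depth``.
    """
    if table.presence is None:
        raise ValueError("call_presence must run before filter_segregating")
    if len(table.samples) == 0:
        raise ValueError("zero samples in PAV table")
    freq = table.presence_frequency()
    depth = table.mean_depth_present()
    in_band = (freq >= band[0]) & (freq <= band[1])
    deep = depth >= min_mean_depth
    keep = in_band & deep
    report = pd.DataFrame(
        {
            "presence_frequency": freq,
            "mean_depth_present": depth,
            "in_band": in_band,
            "depth_ok": deep,
            "retained": keep,
        }
    )
    out = PAVTable(
        counts=table.counts.loc[keep],
        presence=table.presence.loc[keep],
        filter_report=report,
        n_malformed=table.n_malformed,
    )
    return out, report


def call_pavs_from_sam(
    sam_paths: list[str | os.PathLike],
    samples: list[str] | None = None,
    min_pair_depth: int = 1,
    band: tuple[float, float] = (0.3, 0.7),
    min_mean_depth: float = 8.0,
) -> tuple[PAVTable, pd.DataFrame]:
    """End-to-end PAV calling from one merged or several per-sample SAM files."""
    records: list[AlignmentRecord] = []
    n_malformed = 0
    for p in sam_paths:
        recs, bad = read_sam_records(p)
        records.extend(recs)
        n_malformed += bad
    table = count_pair_depth(records, samples=samples)
    table.n_malformed = n_malformed
    table = call_presence(table, min_pair_depth=min_pair_depth)
    return filter_segregating(table, band=band, min_mean_depth=min_mean_depth)


def presence_to_matrix(table: PAVTable, panel=None, donor_symbol: str = "A"):
    """Dominant PAV matrix in the four-symbol alphabet.

    Present -> the donor homozygote symbol, absent -> the other homozygote.
    When a marker panel is supplied, positions are matched back to PAV marker
    metadata (chromosome, cM position, per-marker donor symbol from the
    founder convention A=paternal, B=maternal); otherwise markers are named
    from their reference coordinates with a uniform donor symbol.
    """
    from .containers import PAV, GenotypeMatrix

    if table.presence is None:
        raise ValueError("presence not yet called")
    other = {"A": "B", "B": "A"}[donor_symbol]
    pres = table.presence.T  # samples x positions
    meta_rows = []
    calls = np.empty(pres.shape, dtype="<U1")
    if panel is not None:
        ptab = panel.table[panel.table["kind"] == PAV]
        lookup = {
            (r["reference_name"], int(r["reference_pos"])): r
            for _i, r in ptab.iterrows()
        }
    for j, (rname, rpos) in enumerate(pres.columns):
        row = None if panel is None else lookup.get((rname, int(rpos)))
        if row is not None:
            donor = "B" if int(row["pav_donor"]) == 0 else "A"
            meta_rows.append(
                {
                    "marker_id": row["marker_id"],
                    "chromosome": row["chromosome"],
                    "pos_cM": row["pos_cM"],
                    "kind": PAV,
                }
            )
        else:
            donor = donor_symbol
            meta_rows.append(
                {
                    "marker_id": f"{rname}:{rpos}",
                    "chromosome": "un",
                    "pos_cM": np.nan,
                    "kind": PAV,
                }
            )
        anti = {"A": "B", "B": "A"}[donor]
        calls[:, j] = np.where(pres.iloc[:, j].to_numpy(), donor, anti)
    return GenotypeMatrix(
        individuals=list(pres.index),
        markers=pd.DataFrame(meta_rows),
        calls=calls,
    )
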