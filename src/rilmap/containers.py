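"""Core in-memory containers shared across the pipeline.

Genotype calls use the four-symbol alphabet of biparental mapping work:

* ``A`` – homozygous for the paternal founder allele,
* ``B`` – homozygous for the maternal founder allele,
* ``H`` – heterozygous,
* ``-`` – missing / not called.

Founder origin along simulated haplotypes is encoded as the integers
:data:`MATERNAL` (0) and :data:`PATERNAL` (1); the genotype at a locus is the
pair of founder origins carried by the two chromosome copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MATERNAL = 0
PATERNAL = 1
FOUNDER_NAMES = {MATERNAL: "maternal", PATERNAL: "paternal"}

CALL_A = "A"
CALL_B = "B"
CALL_H = "H"
MISSING = "-"
CALL_ALPHABET = frozenset({CALL_A, CALL_B, CALL_H, MISSING})

SNP = "SNP_codominant"
PAV = "PAV_dominant"


def genotype_call(founder_0: int, founder_1: int) -> str:
    """Genotype symbol for a pair of founder origins at one locus."""
    if founder_0 == founder_1:
        return CALL_A if founder_0 == PATERNAL else CALL_B
    return CALL_H


@dataclass
class MarkerPanel:
    """An ordered set of markers with map and reference coordinates.

    ``table`` columns: ``marker_id``, ``chromosome``, ``pos_cM``, ``kind``
    (:data:`SNP` or :data:`PAV`), ``pav_donor`` (founder int, or -1 for SNPs),
    ``reference_name`` and ``reference_pos`` (1-based; used only when emitting
    PAV alignments).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker_id", "chromosome", "pos_cM", "kind"}
        missing_cols = required - set(self.table.columns)
        if missing_cols:
            raise ValueError(f"marker table missing columns {sorted(missing_cols)}")
        if self.table["marker_id"].duplicated().any():
            raise ValueError("marker ids must be unique")
        if "pav_donor" not in self.table.columns:
            self.table = self.table.assign(pav_donor=-1)
        if "reference_name" not in self.table.columns:
            self.table = self.table.assign(reference_name="", reference_pos=0)
        pav = self.table[self.table["kind"] == PAV]
        if (pav["pav_donor"] < 0).any():
            raise ValueError("PAV markers must carry a donor founder")
        if pav.duplicated(subset=["reference_name", "reference_pos"]).any():
            raise ValueError("PAV reference positions must be unique per reference")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    def subset(self, kind: str) -> "MarkerPanel":
        return MarkerPanel(self.table[self.table["kind"] == kind].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Individuals x markers genotype calls with optional per-call read depth.

    ``calls`` is a 2-D array of single-character strings over the four-symbol
    alphabet; ``depths`` (if present) has the same shape. ``markers`` carries
    the marker metadata row-aligned with the call columns.
    """

    individuals: list[str]
    markers: pd.DataFrame  # marker_id, chromosome, pos_cM, kind at minimum
    calls: np.ndarray
    depths: np.ndarray | None = None
    qc_history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U1")
        n_ind, n_mark = self.calls.shape
        if len(self.individuals) != n_ind:
            raise ValueError("individual ids do not match call rows")
        if len(self.markers) != n_mark:
            raise ValueError("marker metadata does not match call columns")
        bad = set(np.unique(self.calls)) - CALL_ALPHABET
        if bad:
            raise ValueError(f"calls outside alphabet: {sorted(bad)}")
        if self.depths is not None:
            self.depths = np.asarray(self.depths)
            if self.depths.shape != self.calls.shape:
                raise ValueError("depth matrix shape mismatch")
            if (self.depths < 0).any():
                raise ValueError("negative read depth")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def marker_ids(self) -> np.ndarray:
        return self.markers["marker_id"].to_numpy()

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            individuals=list(self.individuals),
            markers=self.markers.copy(),
            calls=self.calls.copy(),
            depths=None if self.depths is None else self.depths.copy(),
            qc_history=list(self.qc_history),
        )

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """Column subset by positional marker index, preserving order."""
        return GenotypeMatrix(
            individuals=list(self.individuals),
            markers=self.markers.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index],
            depths=None if self.depths is None else self.depths[:, index],
            qc_history=list(self.qc_history),
        )

    def column(self, marker_id: str) -> np.ndarray:
        j = int(np.flatnonzero(self.marker_ids == marker_id)[0])
        return self.calls[:, j]

    def chromosomes(self) -> list[str]:
        """Chromosome names in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.markers["chromosome"]:
            seen.setdefault(c, None)
        return list(seen)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.individuals == other.individuals
            and list(self.marker_ids) == list(other.marker_ids)
            and np.array_equal(self.calls, other.calls)
        )
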