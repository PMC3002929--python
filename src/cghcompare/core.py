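"""Shared domain containers for aCGH cohort analysis.

The central objects are :class:`ProbeMap` (an ordered genomic probe layout,
emulating a ~1 Mb BAC/PAC array), :class:`AcghCohort` (a probes x samples
matrix of log2 ratios plus a sample sheet) and :class:`GenomicRegion`
(an interval of gain or loss reported in megabases).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: NCBI Build 36 (Hg18) chromosome lengths rounded to 1 Mb, in Mb.
#: 22 autosomes plus X; ~3.02 Gb total, so a 1 Mb-spaced synthetic platform
#: carries ~3,000 probes, comparable to the 3,500-clone BAC/PAC arrays used
#: for genome-wide tumor profiling.
HG18_CHROM_MB: dict[str, int] = {
    "1": 247, "2": 243, "3": 200, "4": 191, "5": 181, "6": 171, "7": 159,
    "8": 146, "9": 140, "10": 135, "11": 134, "12": 132, "13": 114,
    "14": 106, "15": 100, "16": 89, "17": 79, "18": 76, "19": 64,
    "20": 62, "21": 47, "22": 50, "X": 155,
}


def hg18_chrom_lengths_bp() -> dict[str, int]:
    """Default synthetic genome: Hg18 chromosome lengths in base pairs."""
    return {c: mb * 1_000_000 for c, mb in HG18_CHROM_MB.items()}


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Canonical chromosome ordering: 1..22, then X, Y, then lexical."""
    c = chrom.removeprefix("chr")
    if c.isdigit():
        return (0, int(c), "")
    if c in ("X", "Y"):
        return (1, 0 if c == "X" else 1, "")
    return (2, 0, c)


@dataclass(frozen=True)
class ProbeMap:
    """Ordered genomic probe layout.

    ``table`` has columns chrom, start, end, midpos, probe_id with 0-based
    half-open bp coordinates; probes are sorted by (chrom, midpos).
    ``chrom_lengths`` (bp) is optional; when absent, the extent of each
    chromosome is taken as the maximum probe end.
    """

    table: pd.DataFrame
    chrom_lengths: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        t = self.table
        required = ["chrom", "start", "end", "midpos", "probe_id"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"probe table missing columns: {missing}")
        if (t["start"] >= t["end"]).any():
            bad = t.loc[t["start"] >= t["end"], "probe_id"].iloc[0]
            raise ValueError(f"probe {bad!r} has start >= end")
        expected_mid = (t["start"].to_numpy() + t["end"].to_numpy()) // 2
        if not np.array_equal(expected_mid, t["midpos"].to_numpy()):
            raise ValueError("midpos must equal floor((start+end)/2)")
        if t["probe_id"].duplicated().any():
            dup = t.loc[t["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicate probe_id {dup!r}")
        keys = t["chrom"].map(chrom_sort_key)
        order = pd.DataFrame({"k": keys, "m": t["midpos"]})
        if not order.equals(order.sort_values(["k", "m"], kind="stable")):
            raise ValueError("probes must be sorted by (chrom, midpos)")

    @property
    def n_probes(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_extent_bp(self, chrom: str) -> int:
        if self.chrom_lengths is not None and chrom in self.chrom_lengths:
            return int(self.chrom_lengths[chrom])
        sel = self.table["chrom"] == chrom
        if not sel.any():
            raise KeyError(f"unknown chromosome {chrom!r}")
        return int(self.table.loc[sel, "end"].max())

    def iter_chrom_indices(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (chrom, integer row indices) in genomic order."""
        chroms = self.table["chrom"].to_numpy()
        for c in self.chromosomes:
            yield c, np.flatnonzero(chroms == c)

    def same_layout(self, other: "ProbeMap") -> bool:
        """Positional identity: same (chrom, midpos) sequence."""
        a, b = self.table, other.table
        return len(a) == len(b) and bool(
            (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["midpos"].to_numpy() == b["midpos"].to_numpy()).all()
        )


@dataclass
class AcghCohort:
    """A log2-ratio matrix (probes x samples) with its probe map and sample sheet.

    ``samples`` has columns sample_id, group, platform.
    """

    map: ProbeMap
    values: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[0] != self.map.n_probes:
            raise ValueError(
                f"matrix has {self.values.shape[0]} rows for "
                f"{self.map.n_probes} probes"
            )
        if self.values.shape[1] != len(self.samples):
            raise ValueError(
                f"matrix has {self.values.shape[1]} columns for "
                f"{len(self.samples)} samples"
            )
        for col in ("sample_id", "group", "platform"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    def sample_index(self, sample_id: str) -> int:
        idx = np.flatnonzero(self.samples["sample_id"].to_numpy() == sample_id)
        if idx.size == 0:
            raise KeyError(f"unknown sample {sample_id!r}")
        return int(idx[0])

    def group_columns(self, group: str) -> np.ndarray:
        cols = np.flatnonzero(self.samples["group"].to_numpy() == group)
        if cols.size == 0:
            raise KeyError(f"unknown group {group!r}")
        return cols

    def subset_samples(self, columns: Sequence[int]) -> "AcghCohort":
        cols = np.asarray(columns, dtype=int)
        return AcghCohort(
            map=self.map,
            values=self.values[:, cols].copy(),
            samples=self.samples.iloc[cols].reset_index(drop=True),
        )

    def copy(self) -> "AcghCohort":
        return AcghCohort(self.map, self.values.copy(), self.samples.copy())


@dataclass(frozen=True)
class GenomicRegion:
    """A gained or lost genomic interval reported in megabases.

    ``peaks_mb`` are recurrence-peak positions; a peak may fall slightly
    outside [start_mb, end_mb) (flagged in ``peaks_outside``), as happens when
    intersecting regions from two comparisons.
    """

    chrom: str
    start_mb: float
    end_mb: float
    direction: str  # "gain" | "loss"
    source_group: str = ""
    peaks_mb: tuple[float, ...] = ()
    peaks_outside: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be gain/loss, got {self.direction!r}")
        if not self.start_mb < self.end_mb:
            raise ValueError(
                f"region {self.chrom} [{self.start_mb}, {self.end_mb}) "
                "has start >= end"
            )
        if self.peaks_outside and len(self.peaks_outside) != len(self.peaks_mb):
            raise ValueError("peaks_outside length mismatch")

    def length_mb(self) -> float:
        return self.end_mb - self.start_mb

    def with_peaks(
        self, peaks_mb: Sequence[float], peaks_outside: Sequence[bool] | None = None
    ) -> "GenomicRegion":
        outside = tuple(peaks_outside) if peaks_outside is not None else tuple(
            not (self.start_mb <= p < self.end_mb) for p in peaks_mb
        )
        return replace(self, peaks_mb=tuple(peaks_mb), peaks_outside=outside)
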