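"""Reading, writing, normalizing and merging aCGH cohorts and region tables.

File formats are plain TSV: a BED-like 4-column probe map (chrom, start, end,
probe_id), a probes x samples log2-ratio matrix with a probe_id index column,
a sample sheet (sample_id, group, platform) and a region table mirroring the
published layout (chrom_region, start/end in Mb with 2 decimals, direction,
group, semicolon-separated peaks; a trailing ``*`` marks a peak falling just
outside the region).

Cross-platform normalization z-scales each platform's pooled log2 ratios
(all probes x all samples of that platform) to mean 0, SD 1, which removes
the systematically wider log2-ratio spread of FFPE-derived DNA relative to
fresh-frozen tissue without touching between-tumor differences.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AcghCohort, GenomicRegion, ProbeMap, chrom_sort_key

logger = logging.getLogger(__name__)

MAX_MISSING_FRACTION = 0.2  # probes with more missing values than this are dropped


def read_probe_map(path) -> ProbeMap:
    """Read a BED-like probe map (no header: chrom, start, end, probe_id)."""
    try:
        t = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "probe_id"],
            dtype={"chrom": str, "probe_id": str},
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"cannot read probe map {path}: {exc}") from exc
    if t.empty:
        raise ValueError(f"empty probe map: {path}")
    for col in ("start", "end"):
        if not pd.api.types.is_integer_dtype(t[col]):
            bad = t.index[pd.to_numeric(t[col], errors="coerce").isna()]
            line = int(bad[0]) + 1 if len(bad) else "?"
            raise ValueError(f"probe map {path}: non-integer {col} at line {line}")
    t["midpos"] = (t["start"] + t["end"]) // 2
    t = t.sort_values(
        ["chrom", "midpos"], key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
        kind="stable",
    ).reset_index(drop=True)
    return ProbeMap(t[["chrom", "start", "end", "midpos", "probe_id"]])


def write_probe_map(pmap: ProbeMap, path) -> None:
    pmap.table[["chrom", "start", "end", "probe_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_acgh(probe_path, matrix_path, samples_path) -> AcghCohort:
    """Load a cohort from probe-map, matrix and sample-sheet TSVs.

    Probes with more than 20% missing values are dropped; remaining missing
    cells are imputed with the sample's per-chromosome median. Counts of
    dropped/imputed entries are logged.
    """
    pmap = read_probe_map(probe_path)
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if matrix.empty or matrix.shape[1] == 0:
        raise ValueError(f"empty matrix: {matrix_path}")
    samples = pd.read_csv(samples_path, sep="\t", dtype=str)
    for col in ("sample_id", "group", "platform"):
        if col not in samples.columns:
            raise ValueError(f"sample sheet {samples_path} missing column {col!r}")
    matrix.index = matrix.index.astype(str)
    probe_ids = pmap.table["probe_id"]
    missing_ids = probe_ids[~probe_ids.isin(matrix.index)].tolist()
    extra_ids = [i for i in matrix.index if i not in set(probe_ids)]
    offenders = missing_ids + extra_ids
    if offenders:
        raise ValueError(
            f"probe IDs disagree between map and matrix; first offenders: "
            f"{offenders[:5]}"
        )
    sheet_ids = samples["sample_id"].tolist()
    mat_ids = [str(c) for c in matrix.columns]
    if set(sheet_ids) != set(mat_ids):
        off = sorted(set(sheet_ids) ^ set(mat_ids))
        raise ValueError(f"sample IDs disagree; first offenders: {off[:5]}")
    matrix = matrix.loc[probe_ids, sheet_ids]  # probe-map order, sheet order
    values = matrix.to_numpy(dtype=float)

    missing = np.isnan(values)
    frac = missing.mean(axis=1)
    keep = frac <= MAX_MISSING_FRACTION
    n_dropped = int((~keep).sum())
    if n_dropped:
        pmap = ProbeMap(
            pmap.table.loc[keep].reset_index(drop=True), pmap.chrom_lengths
        )
        values = values[keep]
        missing = missing[keep]
    n_imputed = int(missing.sum())
    if n_imputed:
        chroms = pmap.table["chrom"].to_numpy()
        for c in pmap.chromosomes:
            rows = chroms == c
            block = values[rows]
            med = np.nanmedian(block, axis=0)  # per-sample chromosome median
            hole = np.isnan(block)
            block[hole] = np.broadcast_to(med, block.shape)[hole]
            values[rows] = block
    if np.isnan(values).any():
        raise ValueError("matrix still contains missing values after imputation")
    logger.info("read_acgh: %d probes dropped, %d cells imputed", n_dropped, n_imputed)
    return AcghCohort(pmap, values, samples[["sample_id", "group", "platform"]])


def write_acgh(cohort: AcghCohort, probe_path, matrix_path, samples_path) -> None:
    write_probe_map(cohort.map, probe_path)
    pd.DataFrame(
        cohort.values,
        index=pd.Index(cohort.map.table["probe_id"], name="probe_id"),
        columns=cohort.sample_ids,
    ).to_csv(matrix_path, sep="\t")
    cohort.samples.to_csv(samples_path, sep="\t", index=False)


def zscale_platform(cohort: AcghCohort) -> AcghCohort:
    """Standardize each platform's pooled log2 ratios to mean 0, SD 1.

    The mean and SD pool over every cell (all probes x all samples) of the
    platform, so the transform is a single affine map per platform and
    preserves relative structure within it.
    """
    out = cohort.copy()
    platforms = out.samples["platform"].to_numpy()
    for platform in dict.fromkeys(platforms):
        cols = np.flatnonzero(platforms == platform)
        block = out.values[:, cols]
        if block.shape[0] < 2 or block.shape[1] < 2:
            raise ValueError(
                f"platform {platform!r} stratum too small for standardization"
            )
        sd = float(block.std())  # population SD over the pooled cells
        if sd == 0.0:
            raise ValueError(f"platform {platform!r} has zero variance")
        out.values[:, cols] = (block - float(block.mean())) / sd
    return out


def merge_cohorts(
    a: AcghCohort,
    b: AcghCohort,
    duplicates: Sequence[tuple[str, str]] = (),
    keep: str = "a",
) -> AcghCohort:
    """Concatenate two cohorts on an identical probe layout.

    Each pair in ``duplicates`` names the same tumor in both cohorts; it is
    included once, taken from the ``keep`` side ('a' or 'b').
    """
    if keep not in ("a", "b"):
        raise ValueError("keep must be 'a' or 'b'")
    if not a.map.same_layout(b.map):
        raise ValueError("probe maps differ (chrom/midpos layout mismatch)")
    ids_a, ids_b = set(a.sample_ids), set(b.sample_ids)
    for id_a, id_b in duplicates:
        if id_a not in ids_a:
            raise ValueError(f"duplicate sample {id_a!r} not found in cohort a")
        if id_b not in ids_b:
            raise ValueError(f"duplicate sample {id_b!r} not found in cohort b")
    if keep == "a":
        drop = {id_b for _, id_b in duplicates}
        keep_b = [j for j, s in enumerate(b.sample_ids) if s not in drop]
        keep_a = list(range(a.n_samples))
    else:
        drop = {id_a for id_a, _ in duplicates}
        keep_a = [j for j, s in enumerate(a.sample_ids) if s not in drop]
        keep_b = list(range(b.n_samples))
    values = np.column_stack([a.values[:, keep_a], b.values[:, keep_b]])
    samples = pd.concat(
        [a.samples.iloc[keep_a], b.samples.iloc[keep_b]], ignore_index=True
    )
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(
            f"sample {dup!r} appears in both cohorts but is not listed as a duplicate"
        )
    return AcghCohort(a.map, values, samples)


# --- region tables ----------------------------------------------------------

REGION_COLUMNS = ["chrom_region", "start_mb", "end_mb", "direction", "group", "peaks_mb"]


def _format_peaks(region: GenomicRegion) -> str:
    outside = region.peaks_outside or tuple(False for _ in region.peaks_mb)
    return ";".join(
        f"{p:.2f}" + ("*" if o else "") for p, o in zip(region.peaks_mb, outside)
    )


def write_regions(regions: Sequence[GenomicRegion], path) -> None:
    rows = [
        (
            r.chrom,
            f"{r.start_mb:.2f}",
            f"{r.end_mb:.2f}",
            r.direction,
            r.source_group,
            _format_peaks(r),
        )
        for r in regions
    ]
    pd.DataFrame(rows, columns=REGION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_regions(path) -> list[GenomicRegion]:
    try:
        t = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    if t.empty:
        return []
    missing = [c for c in REGION_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"region table {path} missing columns {missing}")
    regions = []
    for i, row in t.iterrows():
        line = i + 2  # header is line 1
        try:
            start, end = float(row["start_mb"]), float(row["end_mb"])
        except ValueError as exc:
            raise ValueError(f"region table {path} line {line}: {exc}") from exc
        if start >= end:
            raise ValueError(
                f"region table {path} line {line}: start {start} >= end {end}"
            )
        peaks, outside = [], []
        for token in str(row["peaks_mb"]).split(";"):
            token = token.strip()
            if not token:
                continue
            flag = token.endswith("*")
            peaks.append(float(token.rstrip("*")))
            outside.append(flag)
        regions.append(
            GenomicRegion(
                chrom=row["chrom_region"],
                start_mb=start,
                end_mb=end,
                direction=row["direction"],
                source_group=row["group"],
                peaks_mb=tuple(peaks),
                peaks_outside=tuple(outside),
            )
        )
    return regions
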