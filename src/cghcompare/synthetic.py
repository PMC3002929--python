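"""Synthetic aCGH cohorts and TP53 mutation tables.

Emulates a ~1 Mb-spaced BAC/PAC genome-wide platform: per-tumor segmental
gains/losses with group-specific penetrance, a single tumor-cell fraction
scaling all aberration amplitudes, i.i.d. Gaussian probe noise, and a
platform-wide multiplicative scale that mimics the wider log2-ratio
distributions of FFPE-derived DNA relative to fresh-frozen tissue.

The mutation-table generator emits Table-1-style mutation strings that
round-trip through :mod:`cghcompare.tp53` with the intended class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AcghCohort, ProbeMap, chrom_sort_key, hg18_chrom_lengths_bp

PROBE_CLONE_BP = 150_000  # nominal BAC clone insert size


@dataclass(frozen=True)
class CnaSegmentSpec:
    """One recurrent copy-number segment with group-specific penetrance.

    amplitude_mean/amplitude_sd are in log2-ratio units before tumor-fraction
    and platform scaling; amplitude_mean must be positive for gains and
    negative for losses.
    """

    chrom: str
    start_bp: int
    end_bp: int
    direction: str  # "gain" | "loss"
    amplitude_mean: float
    amplitude_sd: float = 0.0
    penetrance_by_group: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError(f"segment {self.chrom}:{self.start_bp}-{self.end_bp} empty")
        if self.direction == "gain" and self.amplitude_mean <= 0:
            raise ValueError("gain segment needs amplitude_mean > 0")
        if self.direction == "loss" and self.amplitude_mean >= 0:
            raise ValueError("loss segment needs amplitude_mean < 0")
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"bad direction {self.direction!r}")
        for g, p in self.penetrance_by_group.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"penetrance for group {g!r} outside [0,1]")


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to simulate one aCGH cohort."""

    n_per_group: Mapping[str, int]
    segments: Sequence[CnaSegmentSpec] = ()
    probe_noise_sd: float = 0.15
    tumor_fraction_range: tuple[float, float] = (0.5, 1.0)
    platform_by_group: Mapping[str, str] = field(default_factory=dict)
    platform_scale: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be >= 1")
        if self.probe_noise_sd < 0:
            raise ValueError("probe_noise_sd must be >= 0")
        lo, hi = self.tumor_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("tumor_fraction_range must be within [0,1]")
        if any(s <= 0 for s in self.platform_scale.values()):
            raise ValueError("platform_scale must be > 0")

    def platform_of(self, group: str) -> str:
        return self.platform_by_group.get(group, "frozen")

    def scale_of(self, platform: str) -> float:
        return float(self.platform_scale.get(platform, 1.0))


@dataclass(frozen=True)
class MutationProfileSpec:
    """Per-group TP53 mutation-class probabilities (must sum to 1)."""

    class_probs: Mapping[str, Mapping[str, float]]
    seed: int = 0

    CLASSES = ("wildtype", "complex", "deleterious_missense", "tolerated_missense")

    def __post_init__(self) -> None:
        for group, probs in self.class_probs.items():
            unknown = set(probs) - set(self.CLASSES)
            if unknown:
                raise ValueError(f"group {group!r}: unknown classes {unknown}")
            total = sum(probs.get(c, 0.0) for c in self.CLASSES)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"group {group!r}: probabilities sum to {total}")
            if any(p < 0 or p > 1 for p in probs.values()):
                raise ValueError(f"group {group!r}: probability outside [0,1]")


def make_probe_map(
    chrom_lengths: Mapping[str, int] | None = None,
    spacing_bp: int = 1_000_000,
    jitter_bp: int = 0,
    seed: int = 0,
) -> ProbeMap:
    """Lay out probes every ``spacing_bp`` with uniform positional jitter.

    Per chromosome, probe i is centred at (i + 1/2)*spacing + U(-jitter, +jitter),
    clipped to the chromosome. Deterministic given ``seed``.
    """
    if chrom_lengths is None:
        chrom_lengths = hg18_chrom_lengths_bp()
    if not chrom_lengths:
        raise ValueError("no genome: chrom_lengths is empty")
    if spacing_bp <= 0:
        raise ValueError("spacing_bp must be > 0")
    if jitter_bp >= spacing_bp / 2:
        raise ValueError("jitter_bp must be < spacing_bp/2")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in sorted(chrom_lengths, key=chrom_sort_key):
        length = int(chrom_lengths[chrom])
        n = length // spacing_bp
        if n == 0:
            continue
        centers = (np.arange(n) + 0.5) * spacing_bp
        if jitter_bp > 0:
            centers = centers + rng.uniform(-jitter_bp, jitter_bp, size=n)
        half = min(PROBE_CLONE_BP // 2, spacing_bp // 2)
        centers = np.clip(centers, half, max(half, length - half)).astype(np.int64)
        start = np.maximum(centers - half, 0)
        end = np.minimum(centers + half, length)
        mid = (start + end) // 2
        order = np.argsort(mid, kind="stable")
        for j, k in enumerate(order):
            rows.append((chrom, int(start[k]), int(end[k]), int(mid[k]),
                         f"P_{chrom}_{j:04d}"))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "midpos", "probe_id"])
    return ProbeMap(table, chrom_lengths=dict(chrom_lengths))


def simulate_cohort(
    probe_map: ProbeMap, spec: CohortSpec
) -> tuple[AcghCohort, pd.DataFrame]:
    """Simulate a cohort and return (cohort, truth table).

    Probe value for a tumor = sum over present segments of
    drawn_amplitude * tumor_fraction on the probes whose midposition falls in
    the segment, plus N(0, probe_noise_sd), the whole multiplied by the
    platform scale. The truth table records each (tumor, segment) draw.
    """
    t = probe_map.table
    chroms = set(t["chrom"])
    for seg in spec.segments:
        if seg.chrom not in chroms:
            raise ValueError(f"segment on unknown chromosome {seg.chrom!r}")
        if seg.end_bp > probe_map.chrom_extent_bp(seg.chrom):
            raise ValueError(
                f"segment {seg.chrom}:{seg.start_bp}-{seg.end_bp} "
                "extends past the chromosome"
            )
        missing = set(seg.penetrance_by_group) - set(spec.n_per_group)
        if missing:
            raise ValueError(f"segment penetrance for unknown groups {missing}")
    rng = np.random.default_rng(spec.seed)
    mids = t["midpos"].to_numpy()
    chrom_arr = t["chrom"].to_numpy()
    seg_masks = [
        (chrom_arr == s.chrom) & (mids >= s.start_bp) & (mids < s.end_bp)
        for s in spec.segments
    ]
    lo, hi = spec.tumor_fraction_range
    cols, sheet_rows, truth_rows = [], [], []
    for group in spec.n_per_group:
        platform = spec.platform_of(group)
        scale = spec.scale_of(platform)
        for i in range(spec.n_per_group[group]):
            sample_id = f"{group}_{i:03d}"
            tf = float(rng.uniform(lo, hi))
            signal = np.zeros(probe_map.n_probes)
            for k, seg in enumerate(spec.segments):
                pen = float(seg.penetrance_by_group.get(group, 0.0))
                present = bool(rng.random() < pen)
                amp = float(rng.normal(seg.amplitude_mean, seg.amplitude_sd))
                if present:
                    signal[seg_masks[k]] += amp * tf
                truth_rows.append(
                    (sample_id, group, k, seg.chrom, seg.start_bp, seg.end_bp,
                     seg.direction, int(present), amp, tf)
                )
            noise = rng.normal(0.0, spec.probe_noise_sd, size=probe_map.n_probes) \
                if spec.probe_noise_sd > 0 else 0.0
            cols.append((signal + noise) * scale)
            sheet_rows.append((sample_id, group, platform))
    values = np.column_stack(cols) if cols else np.zeros((probe_map.n_probes, 0))
    samples = pd.DataFrame(sheet_rows, columns=["sample_id", "group", "platform"])
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "group", "segment", "chrom", "start_bp", "end_bp",
                 "direction", "present", "amplitude", "tumor_fraction"],
    )
    return AcghCohort(probe_map, values, samples), truth


def reconstruct_from_truth(
    probe_map: ProbeMap, truth: pd.DataFrame, spec: CohortSpec
) -> np.ndarray:
    """Rebuild the noise-free, platform-scaled signal matrix from a truth table."""
    t = probe_map.table
    mids = t["midpos"].to_numpy()
    chrom_arr = t["chrom"].to_numpy()
    sample_ids = truth["sample_id"].drop_duplicates().tolist()
    out = np.zeros((probe_map.n_probes, len(sample_ids)))
    group_of = dict(zip(truth["sample_id"], truth["group"]))
    for j, sid in enumerate(sample_ids):
        rows = truth[truth["sample_id"] == sid]
        for _, r in rows.iterrows():
            if not r["present"]:
                continue
            mask = (
                (chrom_arr == r["chrom"])
                & (mids >= r["start_bp"])
                & (mids < r["end_bp"])
            )
            out[mask, j] += r["amplitude"] * r["tumor_fraction"]
        out[:, j] *= spec.scale_of(spec.platform_of(group_of[sid]))
    return out


# --- TP53 mutation-table synthesis -----------------------------------------

_COMPLEX_TEMPLATES = (
    "R{c}X",            # nonsense
    "{c} insT",         # 1-nt frameshift insertion
    "{c}delC",          # 1-nt frameshift deletion
    "{c}_{c2}del",      # codon-range in-frame deletion
    "{c}delGTG",        # 3-nt in-frame deletion
    "IVS{e}-2 A > G (splice)",
)
_AA = "ACDEFGHIKLMNPQRSTVWY"


def simulate_mutation_table(
    spec: MutationProfileSpec, n_per_group: Mapping[str, int]
) -> pd.DataFrame:
    """Draw one mutation class per tumor and emit a Table-1-style table.

    Columns: sample_id, group, raw, predicted_deleterious, abundance.
    """
    unknown = set(n_per_group) - set(spec.class_probs)
    if unknown:
        raise ValueError(f"unknown groups {unknown}")
    rng = np.random.default_rng(spec.seed)
    classes = list(MutationProfileSpec.CLASSES)
    rows = []
    for group, n in n_per_group.items():
        probs = [spec.class_probs[group].get(c, 0.0) for c in classes]
        for i in range(n):
            sample_id = f"{group}_{i:03d}"
            cls = classes[int(rng.choice(len(classes), p=probs))]
            if cls == "wildtype":
                rows.append((sample_id, group, "wild type", "NA", "NA"))
                continue
            codon = int(rng.integers(30, 330))
            if cls == "complex":
                tmpl = _COMPLEX_TEMPLATES[int(rng.integers(len(_COMPLEX_TEMPLATES)))]
                raw = tmpl.format(c=codon, c2=codon + 1, e=int(rng.integers(2, 10)))
                rows.append((sample_id, group, raw, "true", "NA"))
            else:
                ref, alt = rng.choice(list(_AA), size=2, replace=False)
                while alt == "X":  # never emitted by _AA but keep invariant explicit
                    alt = rng.choice(list(_AA))
                raw = f"{ref}{codon}{alt}"
                flag = "true" if cls == "deleterious_missense" else "false"
                rows.append((sample_id, group, raw, flag, "NA"))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "raw", "predicted_deleterious", "abundance"]
    )
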