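"""Between-group comparison of smoothed aCGH profiles.

Each tumor's signed profile is smoothed individually; at every grid position
the two groups' KSE values give a signal-to-noise ratio

    SNR(x) = (mu_A(x) - mu_B(x)) / (sd_A(x) + sd_B(x) + eps)

with population SDs and a small eps guard. Class-label permutations of the
tumors provide an empirical null; the positive and negative tails are
thresholded separately at the target false discovery rate, where
FDR(t) = E_perm[#null points >= t] / #observed points >= t, scanned over the
observed SNR values. Supra-threshold runs become differential regions whose
peaks are the local maxima of the group-mean difference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AcghCohort, GenomicRegion
from .kcsmart import (
    DEFAULT_GRID_STEP_BP,
    GenomeGrid,
    KernelSpec,
    KseCurve,
    Smoother,
    _runs_above,
)

logger = logging.getLogger(__name__)

SNR_EPS = 1e-8


@dataclass
class CohortKse:
    """Per-tumor signed KSE curves on a shared grid (grid points x tumors)."""

    grid: GenomeGrid
    values: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != (self.grid.n_points, len(self.samples)):
            raise ValueError("KSE matrix shape does not match grid/samples")

    def group_columns(self, group: str) -> np.ndarray:
        cols = np.flatnonzero(self.samples["group"].to_numpy() == group)
        if cols.size == 0:
            raise KeyError(f"unknown group {group!r}")
        return cols

    def curve(self, sample_id: str) -> KseCurve:
        j = np.flatnonzero(self.samples["sample_id"].to_numpy() == sample_id)
        if j.size == 0:
            raise KeyError(f"unknown sample {sample_id!r}")
        return KseCurve(self.grid, self.values[:, int(j[0])], label=sample_id)


def per_tumor_kse(
    cohort: AcghCohort,
    spec: KernelSpec = KernelSpec(),
    grid_step_bp: int = DEFAULT_GRID_STEP_BP,
    smoother: Smoother | None = None,
) -> CohortKse:
    """Smooth every tumor's signed profile once, for reuse downstream."""
    sm = smoother or Smoother(cohort.map, spec, grid_step_bp)
    return CohortKse(sm.grid, sm.smooth(cohort.values), cohort.samples.copy())


@dataclass(frozen=True)
class PermutationConfig:
    n_perm: int = 6000
    fdr: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 20:
            raise ValueError("n_perm must be >= 20")
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must be in (0, 1)")


@dataclass
class SnrCurve:
    grid: GenomeGrid
    snr: np.ndarray
    mu_a: np.ndarray
    mu_b: np.ndarray
    sd_a: np.ndarray
    sd_b: np.ndarray
    group_a: str = ""
    group_b: str = ""

    def swapped(self) -> "SnrCurve":
        return SnrCurve(
            self.grid, -self.snr, self.mu_b, self.mu_a, self.sd_b, self.sd_a,
            self.group_b, self.group_a,
        )


@dataclass(frozen=True)
class DifferentialRegion(GenomicRegion):
    """A differential interval favoring one group, with the threshold used."""

    favored_group: str = ""
    threshold_used: float = float("nan")


def _snr_stats(values: np.ndarray, in_a: np.ndarray):
    a = values[:, in_a]
    b = values[:, ~in_a]
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a, sd_b = a.std(axis=1), b.std(axis=1)  # population SD
    snr = (mu_a - mu_b) / (sd_a + sd_b + SNR_EPS)
    return snr, mu_a, mu_b, sd_a, sd_b


def _two_group_selection(
    kse: CohortKse, group_a: str, group_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Columns of the two groups in canonical (sample-sheet) order, plus the
    group-A membership mask. Canonical order makes group-swap symmetric."""
    groups = kse.samples["group"].to_numpy()
    n_a, n_b = int((groups == group_a).sum()), int((groups == group_b).sum())
    if n_a == 0:
        raise KeyError(f"unknown group {group_a!r}")
    if n_b == 0:
        raise KeyError(f"unknown group {group_b!r}")
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 tumors per group")
    sel = np.flatnonzero((groups == group_a) | (groups == group_b))
    return sel, groups[sel] == group_a


def snr_curve(kse: CohortKse, group_a: str, group_b: str) -> SnrCurve:
    """Observed SNR curve between two groups of per-tumor KSE profiles."""
    sel, in_a = _two_group_selection(kse, group_a, group_b)
    snr, mu_a, mu_b, sd_a, sd_b = _snr_stats(kse.values[:, sel], in_a)
    return SnrCurve(kse.grid, snr, mu_a, mu_b, sd_a, sd_b, group_a, group_b)


def permutation_fdr_threshold(
    kse: CohortKse, group_a: str, group_b: str, cfg: PermutationConfig
) -> tuple[float, float]:
    """FDR-controlling SNR thresholds for the positive and negative tails.

    Returns (t_pos, t_neg), both positive magnitudes: points with
    SNR >= t_pos favor group_a, points with SNR <= -t_neg favor group_b.
    Either is +inf when no scanned threshold reaches the target FDR.
    """
    sel, in_a = _two_group_selection(kse, group_a, group_b)
    n_a = int(in_a.sum())
    values = kse.values[:, sel]
    finite_rows = np.all(np.isfinite(values), axis=1)
    values = values[finite_rows]
    observed = _snr_stats(values, in_a)[0]

    n_distinct = math.comb(sel.size, n_a)
    if n_distinct < cfg.n_perm:
        logger.warning(
            "only %d distinct label permutations for %d requested; "
            "sampling with replacement", n_distinct, cfg.n_perm,
        )
    rng = np.random.default_rng(cfg.seed)

    pos_cand = np.sort(observed[observed > 0])
    neg_cand = np.sort(-observed[observed < 0])
    null_pos = np.zeros(pos_cand.size)
    null_neg = np.zeros(neg_cand.size)
    for _ in range(cfg.n_perm):
        perm_in_a = np.zeros(sel.size, dtype=bool)
        perm_in_a[rng.permutation(sel.size)[:n_a]] = True
        null = _snr_stats(values, perm_in_a)[0]
        ns = np.sort(null)
        # count of null values >= t for each candidate t (and <= -t)
        null_pos += ns.size - np.searchsorted(ns, pos_cand, side="left")
        null_neg += np.searchsorted(ns, -neg_cand, side="right")

    def tail_threshold(cand: np.ndarray, null_counts: np.ndarray) -> float:
        if cand.size == 0:
            return float("inf")
        obs_counts = cand.size - np.arange(cand.size)  # observed >= cand[i]
        fdr = (null_counts / cfg.n_perm) / np.maximum(obs_counts, 1)
        ok = np.flatnonzero(fdr <= cfg.fdr)
        return float(cand[ok[0]]) if ok.size else float("inf")

    return tail_threshold(pos_cand, null_pos), tail_threshold(neg_cand, null_neg)


def _local_peaks(x: np.ndarray) -> np.ndarray:
    """Indices of local maxima; falls back to the argmax for monotone runs."""
    if x.size == 1:
        return np.array([0])
    interior = np.flatnonzero(
        (np.r_[True, x[1:] > x[:-1]]) & (np.r_[x[:-1] > x[1:], True])
    )
    return interior if interior.size else np.array([int(np.argmax(x))])


def call_differential_regions(
    snr: SnrCurve,
    thresholds: tuple[float, float],
    merge_gap_steps: int = 1,
) -> list[DifferentialRegion]:
    """Supra-threshold runs of the SNR curve as differential regions.

    Runs separated by at most ``merge_gap_steps`` grid steps are merged.
    Positive-tail runs (SNR >= t_pos) have the higher mean KSE in group A,
    negative-tail runs in group B; the CNA itself is attributed to the group
    whose mean KSE inside the region has the larger magnitude (a loss that is
    specific to group B raises group A's relative signal), and the region
    direction is the sign of that group's mean. Peaks are local maxima of
    |mu_A - mu_B|, in Mb.
    """
    t_pos, t_neg = thresholds
    out: list[DifferentialRegion] = []
    half = snr.grid.step_bp / 2
    diff = np.abs(snr.mu_a - snr.mu_b)
    for thr, mask in (
        (t_pos, np.isfinite(snr.snr) & (snr.snr >= t_pos)),
        (t_neg, np.isfinite(snr.snr) & (snr.snr <= -t_neg)),
    ):
        if not mask.any():
            continue
        runs = _runs_above(mask, snr.grid)
        merged: list[tuple[str, int, int]] = []
        for c, s, e in runs:
            if merged and merged[-1][0] == c and s - merged[-1][2] <= merge_gap_steps:
                merged[-1] = (c, merged[-1][1], e)
            else:
                merged.append((c, s, e))
        for c, s, e in merged:
            mean_a, mean_b = snr.mu_a[s:e].mean(), snr.mu_b[s:e].mean()
            if abs(mean_a) >= abs(mean_b):
                favored, fav_mean = snr.group_a, mean_a
            else:
                favored, fav_mean = snr.group_b, mean_b
            direction = "gain" if fav_mean > 0 else "loss"
            peak_idx = s + _local_peaks(diff[s:e])
            peaks = tuple(round(p, 2) for p in snr.grid.pos_bp[peak_idx] / 1e6)
            out.append(
                DifferentialRegion(
                    chrom=c,
                    start_mb=(snr.grid.pos_bp[s] - half) / 1e6,
                    end_mb=(snr.grid.pos_bp[e - 1] + half) / 1e6,
                    direction=direction,
                    source_group=favored,
                    peaks_mb=peaks,
                    peaks_outside=tuple(False for _ in peaks),
                    favored_group=favored,
                    threshold_used=float(thr),
                )
            )
    return out


def overlap_regions(
    regions_1: list[GenomicRegion], regions_2: list[GenomicRegion]
) -> list[GenomicRegion]:
    """Same-direction interval intersections between two comparisons.

    Peaks of both inputs are carried over; peaks falling outside the
    intersection are kept but flagged.
    """
    out = []
    for r1 in regions_1:
        for r2 in regions_2:
            if r1.chrom != r2.chrom or r1.direction != r2.direction:
                continue
            start = max(r1.start_mb, r2.start_mb)
            end = min(r1.end_mb, r2.end_mb)
            if start >= end:
                continue
            peaks = tuple(r1.peaks_mb) + tuple(r2.peaks_mb)
            region = GenomicRegion(
                chrom=r1.chrom,
                start_mb=start,
                end_mb=end,
                direction=r1.direction,
                source_group="&".join(
                    p for p in (r1.source_group, r2.source_group) if p
                ),
            ).with_peaks(peaks)
            out.append(region)
    out.sort(key=lambda r: (r.chrom, r.start_mb, r.end_mb, r.direction))
    return out
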