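"""Kernel-smoothed estimates (KSE) of aCGH profiles.

A truncated Gaussian kernel is placed at each probe's genomic midposition
with height equal to its log2 ratio, and the locally normalized sum of
kernels (a Nadaraya-Watson weighted mean) is evaluated on a fixed genomic
grid. Normalizing by the local kernel mass keeps the curve in log2-ratio
units, so amplitude cutoffs remain meaningful on SD-1 normalized data.
Kernels never cross chromosome boundaries.

The nominal kernel width W (default 20 Mb, the scale at which smoothed
profiles recapitulate ~1 Mb BAC-array data well) is interpreted as total
effective support: sigma = W/4 with truncation at 2 sigma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
from scipy import sparse

from .core import AcghCohort, GenomicRegion, ProbeMap

logger = logging.getLogger(__name__)

DEFAULT_GRID_STEP_BP = 100_000


@dataclass(frozen=True)
class KernelSpec:
    """Truncated Gaussian smoothing kernel.

    width_mb is the nominal total support in Mb; sigma_mb = width_mb/4;
    weights vanish beyond ``truncation`` sigma.
    """

    width_mb: float = 20.0
    truncation: float = 2.0

    def __post_init__(self) -> None:
        if self.width_mb <= 0:
            raise ValueError("width_mb must be > 0")
        if self.truncation < 2:
            raise ValueError("truncation must be >= 2 sigma")

    @property
    def sigma_mb(self) -> float:
        return self.width_mb / 4.0

    @property
    def sigma_bp(self) -> float:
        return self.sigma_mb * 1e6

    @property
    def support_bp(self) -> float:
        return self.truncation * self.sigma_bp


def kernel_weight(d_bp, spec: KernelSpec = KernelSpec()):
    """Gaussian weight K(d) = exp(-d^2 / 2 sigma^2), zero beyond truncation."""
    d = np.asarray(d_bp, dtype=float)
    w = np.exp(-(d**2) / (2.0 * spec.sigma_bp**2))
    w = np.where(np.abs(d) <= spec.support_bp, w, 0.0)
    return w if w.ndim else float(w)


@dataclass(frozen=True)
class GenomeGrid:
    """Regularly spaced evaluation positions, per chromosome."""

    chroms: tuple[str, ...]
    pos_bp: np.ndarray  # flat, concatenated per chromosome
    chrom_slices: tuple[tuple[str, slice], ...]
    step_bp: int

    @property
    def n_points(self) -> int:
        return len(self.pos_bp)

    def chrom_of_points(self) -> np.ndarray:
        out = np.empty(self.n_points, dtype=object)
        for c, sl in self.chrom_slices:
            out[sl] = c
        return out

    def pos_mb(self) -> np.ndarray:
        return self.pos_bp / 1e6

    def same_grid(self, other: "GenomeGrid") -> bool:
        return (
            self.chroms == other.chroms
            and self.step_bp == other.step_bp
            and np.array_equal(self.pos_bp, other.pos_bp)
        )


@dataclass
class KseCurve:
    """One smoothed curve on a genome grid. NaN marks absent positions."""

    grid: GenomeGrid
    values: np.ndarray
    label: str = ""
    flavor: str = "signed"  # signed | gains | losses

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_points,):
            raise ValueError("curve length does not match grid")
        finite = self.values[np.isfinite(self.values)]
        if self.flavor == "gains" and (finite < -1e-12).any():
            raise ValueError("gains curve must be >= 0")
        if self.flavor == "losses" and (finite > 1e-12).any():
            raise ValueError("losses curve must be <= 0")


def build_grid(pmap: ProbeMap, step_bp: int = DEFAULT_GRID_STEP_BP) -> GenomeGrid:
    chroms, positions, slices = [], [], []
    offset = 0
    for c in pmap.chromosomes:
        extent = pmap.chrom_extent_bp(c)
        pos = np.arange(step_bp // 2, extent, step_bp, dtype=np.int64)
        if pos.size == 0:
            logger.warning("chromosome %s shorter than one grid step; skipped", c)
            continue
        chroms.append(c)
        positions.append(pos)
        slices.append((c, slice(offset, offset + pos.size)))
        offset += pos.size
    return GenomeGrid(
        chroms=tuple(chroms),
        pos_bp=np.concatenate(positions) if positions else np.empty(0, np.int64),
        chrom_slices=tuple(slices),
        step_bp=step_bp,
    )


class Smoother:
    """Precomputed kernel-weight operator from probes to a genome grid.

    Building the sparse weight matrix once makes smoothing a mat-vec, which
    is what permutation nulls need (thousands of re-smoothings of permuted
    probe values on a fixed layout).
    """

    def __init__(
        self,
        pmap: ProbeMap,
        spec: KernelSpec = KernelSpec(),
        grid_step_bp: int = DEFAULT_GRID_STEP_BP,
    ) -> None:
        if grid_step_bp > spec.width_mb * 1e6 / 4:
            raise ValueError("grid step must be <= kernel width / 4")
        self.map = pmap
        self.spec = spec
        self.grid = build_grid(pmap, grid_step_bp)
        mids = pmap.table["midpos"].to_numpy()
        probe_chroms = pmap.table["chrom"].to_numpy()
        blocks = []
        for c, sl in self.grid.chrom_slices:
            gpos = self.grid.pos_bp[sl].astype(float)
            rows = np.flatnonzero(probe_chroms == c)
            if rows.size == 0:
                blocks.append((sl, None, rows))
                continue
            d = gpos[:, None] - mids[rows][None, :].astype(float)
            w = kernel_weight(d, spec)
            blocks.append((sl, sparse.csr_matrix(w), rows))
        self._blocks = blocks
        self.weight_sums = self._apply_weights(np.ones((pmap.n_probes, 1)))[:, 0]

    def _apply_weights(self, probe_values: np.ndarray) -> np.ndarray:
        out = np.zeros((self.grid.n_points, probe_values.shape[1]))
        for sl, w, rows in self._blocks:
            if w is not None:
                out[sl] = w @ probe_values[rows]
        return out

    def smooth(self, probe_values: np.ndarray) -> np.ndarray:
        """Locally normalized smoothing of one or more probe-value columns."""
        v = np.asarray(probe_values, dtype=float)
        single = v.ndim == 1
        if single:
            v = v[:, None]
        if v.shape[0] != self.map.n_probes:
            raise ValueError("probe_values length does not match probe map")
        num = self._apply_weights(v)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / self.weight_sums[:, None]
        out[self.weight_sums == 0] = np.nan
        return out[:, 0] if single else out


def kse_profile(
    cohort: AcghCohort,
    sample_id: str,
    spec: KernelSpec = KernelSpec(),
    grid_step_bp: int = DEFAULT_GRID_STEP_BP,
    smoother: Smoother | None = None,
) -> KseCurve:
    """Signed smoothed profile of one tumor."""
    sm = smoother or Smoother(cohort.map, spec, grid_step_bp)
    j = cohort.sample_index(sample_id)
    return KseCurve(sm.grid, sm.smooth(cohort.values[:, j]), label=sample_id)


def group_kse(
    cohort: AcghCohort,
    group: str,
    spec: KernelSpec = KernelSpec(),
    grid_step_bp: int = DEFAULT_GRID_STEP_BP,
    smoother: Smoother | None = None,
) -> tuple[KseCurve, KseCurve]:
    """Pooled gains and losses curves across all tumors of a group.

    Every tumor's probes contribute; with a shared probe layout the pooled
    locally-normalized kernel sum over positive (negative) parts equals
    smoothing the probe-wise group mean of max(a,0) (min(a,0)).
    """
    cols = cohort.group_columns(group)
    sm = smoother or Smoother(cohort.map, spec, grid_step_bp)
    block = cohort.values[:, cols]
    gains = sm.smooth(np.maximum(block, 0.0).mean(axis=1))
    losses = sm.smooth(np.minimum(block, 0.0).mean(axis=1))
    return (
        KseCurve(sm.grid, gains, label=group, flavor="gains"),
        KseCurve(sm.grid, losses, label=group, flavor="losses"),
    )


def _runs_above(mask: np.ndarray, grid: GenomeGrid) -> list[tuple[str, int, int]]:
    """Maximal runs of True within chromosomes, as (chrom, start_idx, end_idx)."""
    runs = []
    for c, sl in grid.chrom_slices:
        m = mask[sl]
        if not m.any():
            continue
        padded = np.concatenate([[False], m, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for s, e in zip(starts, ends):
            runs.append((c, sl.start + int(s), sl.start + int(e)))
    return runs


def runs_to_regions(
    mask: np.ndarray, grid: GenomeGrid, direction: str, source_group: str = ""
) -> list[GenomicRegion]:
    """Convert a significance mask to Mb regions (grid-cell boundaries)."""
    regions = []
    half = grid.step_bp / 2
    for c, s, e in _runs_above(mask, grid):
        start_mb = (grid.pos_bp[s] - half) / 1e6
        end_mb = (grid.pos_bp[e - 1] + half) / 1e6
        regions.append(
            GenomicRegion(c, start_mb, end_mb, direction, source_group=source_group)
        )
    return regions


def single_group_threshold(
    cohort: AcghCohort,
    group: str,
    spec: KernelSpec = KernelSpec(),
    grid_step_bp: int = DEFAULT_GRID_STEP_BP,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    smoother: Smoother | None = None,
) -> tuple[tuple[float, float], list[GenomicRegion]]:
    """Genome-wide significance thresholds for one group's gains/losses curves.

    The null permutes each tumor's log2 ratios across probe positions
    independently, preserving per-tumor value distributions; the gain
    threshold is the (1-alpha) quantile of the null curves' genome-wide
    maxima (losses analogously on minima). Returns ((gain_thr, loss_thr),
    significant regions). loss_thr is negative.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    cols = cohort.group_columns(group)
    sm = smoother or Smoother(cohort.map, spec, grid_step_bp)
    block = cohort.values[:, cols]
    gains, losses = group_kse(cohort, group, spec, grid_step_bp, smoother=sm)
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    min_null = np.empty(n_perm)
    for p in range(n_perm):
        perm = np.column_stack(
            [rng.permutation(block[:, j]) for j in range(block.shape[1])]
        )
        g = sm.smooth(np.maximum(perm, 0.0).mean(axis=1))
        l = sm.smooth(np.minimum(perm, 0.0).mean(axis=1))
        max_null[p] = np.nanmax(g)
        min_null[p] = np.nanmin(l)
    gain_thr = float(np.quantile(max_null, 1.0 - alpha))
    loss_thr = float(np.quantile(min_null, alpha))
    with np.errstate(invalid="ignore"):
        gain_mask = gains.values > gain_thr
        loss_mask = losses.values < loss_thr
    regions = runs_to_regions(gain_mask, sm.grid, "gain", group) + runs_to_regions(
        loss_mask, sm.grid, "loss", group
    )
    return (gain_thr, loss_thr), regions


def write_curve_tsv(curve: KseCurve, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "chrom": curve.grid.chrom_of_points(),
            "pos_bp": curve.grid.pos_bp,
            "value": curve.values,
        }
    ).to_csv(path, sep="\t", index=False)
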