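"""Genomic-instability burden sweeps and region-based tumor clustering.

Burden: each tumor's smoothed signed profile is thresholded over a grid of
symmetric KSE cutoffs; gains exceeding +t and losses exceeding -t are
counted. The counting unit is the aberration peak: a plateau-aware local
maximum of the curve above +t (resp. local minimum below -t), never spanning
chromosomes. Counting supra-threshold runs instead would not be monotone in
the cutoff (one run splits in two as the cutoff rises past a saddle); peak
counts are exactly non-increasing. Group medians are reported and group
means compared with Welch's two-sided t-test per cutoff.

Clustering: tumors are described by the mean KSE within a fixed set of
regions, then hierarchically clustered with correlation distance
(1 - Pearson r), complete linkage and optimal leaf ordering; the tree is cut
into two branches and the per-group branch composition tabulated. Regions
are clustered the same way on the transpose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import GenomicRegion
from .comparative import CohortKse
from .kcsmart import KseCurve

DEFAULT_CUTOFFS = np.round(np.arange(0.02, 1.0 + 1e-9, 0.02), 2)


def _plateau_peak_heights(v: np.ndarray) -> np.ndarray:
    """Heights of plateau-aware local maxima of a finite 1-D segment.

    Consecutive equal values collapse to one plateau; a plateau higher than
    both neighbours (chromosome ends count as open boundaries) is one peak.
    """
    if v.size == 0:
        return np.empty(0)
    c = v[np.r_[True, np.diff(v) != 0]]
    if c.size == 1:
        return c.copy()
    up = np.r_[True, c[1:] > c[:-1]]
    down = np.r_[c[:-1] > c[1:], True]
    return c[up & down]


def _count_peaks(values: np.ndarray, cutoff: float, chrom_slices) -> int:
    """Aberration peaks above +cutoff plus troughs below -cutoff."""
    n = 0
    for _, sl in chrom_slices:
        v = values[sl]
        v = v[np.isfinite(v)]
        n += int((_plateau_peak_heights(v) > cutoff).sum())
        n += int((_plateau_peak_heights(-v) > cutoff).sum())
    return n


def count_cna_segments(curve: KseCurve, cutoff: float) -> int:
    """Number of CNAs in one tumor's signed curve at a symmetric cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    return _count_peaks(curve.values, cutoff, curve.grid.chrom_slices)


@dataclass
class BurdenTable:
    """Per-sample CNA counts over a cutoff grid, with group summaries."""

    cutoffs: np.ndarray
    counts: pd.DataFrame  # samples x cutoffs
    group_medians: pd.DataFrame  # groups x cutoffs
    group_means: pd.DataFrame
    p_values: pd.Series | None  # per cutoff; None if no test groups given


def burden_table(
    kse: CohortKse,
    cutoffs: np.ndarray | None = None,
    test_groups: tuple[str, str] | None = None,
) -> BurdenTable:
    """Count CNAs per tumor across a cutoff grid and test two groups.

    ``test_groups`` names the pair compared with Welch's t-test on the mean
    counts; a group with < 2 samples yields no p-value for any cutoff.
    """
    cut = DEFAULT_CUTOFFS if cutoffs is None else np.asarray(cutoffs, dtype=float)
    if (np.diff(cut) <= 0).any() or (cut <= 0).any():
        raise ValueError("cutoffs must be positive and strictly ascending")
    sample_ids = kse.samples["sample_id"].tolist()
    groups = kse.samples["group"].to_numpy()
    counts = np.empty((len(sample_ids), cut.size), dtype=int)
    for j in range(len(sample_ids)):
        col = kse.values[:, j]
        for k, t in enumerate(cut):
            counts[j, k] = _count_peaks(col, t, kse.grid.chrom_slices)
    counts_df = pd.DataFrame(counts, index=sample_ids, columns=cut)
    med = counts_df.groupby(groups).median()
    mean = counts_df.groupby(groups).mean()
    p_values = None
    if test_groups is not None:
        ga, gb = test_groups
        a = counts[groups == ga]
        b = counts[groups == gb]
        if len(a) < 2 or len(b) < 2:
            import logging

            logging.getLogger(__name__).warning(
                "group with < 2 samples; Welch test skipped"
            )
        else:
            p_values = pd.Series(
                stats.ttest_ind(a, b, axis=0, equal_var=False).pvalue, index=cut
            )
    return BurdenTable(cut, counts_df, med, mean, p_values)


def region_mean_matrix(
    kse: CohortKse, regions: list[GenomicRegion]
) -> pd.DataFrame:
    """samples x regions matrix of mean KSE within each region.

    A region whose chromosome is absent from the grid is an error; a region
    covering no grid point yields NaN for every sample.
    """
    grid_chroms = kse.grid.chrom_of_points()
    pos = kse.grid.pos_bp
    known = set(kse.grid.chroms)
    cols = {}
    for r in regions:
        if r.chrom not in known:
            raise ValueError(f"region on unknown chromosome {r.chrom!r}")
        mask = (
            (grid_chroms == r.chrom)
            & (pos >= r.start_mb * 1e6)
            & (pos < r.end_mb * 1e6)
        )
        name = f"{r.chrom}:{r.start_mb:.2f}-{r.end_mb:.2f}:{r.direction}"
        cols[name] = (
            kse.values[mask].mean(axis=0) if mask.any() else np.full(len(kse.samples), np.nan)
        )
    return pd.DataFrame(cols, index=kse.samples["sample_id"].tolist())


@dataclass
class ClusterResult:
    features: pd.DataFrame  # samples x regions
    sample_linkage: np.ndarray
    region_linkage: np.ndarray
    branches: pd.Series  # sample -> 1..n_branches
    composition: pd.DataFrame  # groups x branches


def _correlation_linkage(matrix: np.ndarray, names: list[str]) -> np.ndarray:
    sds = matrix.std(axis=1)
    if (sds == 0).any():
        bad = names[int(np.flatnonzero(sds == 0)[0])]
        raise ValueError(f"zero-variance feature vector for {bad!r}")
    dist = 1.0 - np.corrcoef(matrix)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.complete(condensed)
    return hierarchy.optimal_leaf_ordering(linkage, condensed)


def cluster_tumors(
    features: pd.DataFrame,
    groups: pd.Series | None = None,
    n_branches: int = 2,
) -> ClusterResult:
    """Two-dimensional hierarchical clustering of the region-mean matrix."""
    if len(features) < 3:
        raise ValueError("need >= 3 samples to cluster")
    if features.shape[1] < 2:
        raise ValueError("need >= 2 regions for correlation distance")
    if features.isna().any().any():
        raise ValueError("feature matrix contains absent entries")
    x = features.to_numpy(dtype=float)
    sample_linkage = _correlation_linkage(x, list(features.index))
    region_linkage = _correlation_linkage(x.T, list(features.columns))
    assignment = hierarchy.fcluster(sample_linkage, t=n_branches, criterion="maxclust")
    branches = pd.Series(assignment, index=features.index, name="branch")
    if groups is None:
        groups = pd.Series("all", index=features.index)
    groups = pd.Series(np.asarray(groups), index=features.index, name="group")
    composition = (
        pd.crosstab(groups, branches)
        .reindex(sorted(set(groups)), fill_value=0)
    )
    return ClusterResult(features, sample_linkage, region_linkage, branches, composition)


def branch_purity(branches: pd.Series, groups: pd.Series, split: dict[str, int]) -> float:
    """Fraction of samples whose branch matches the expected side.

    ``split`` maps each group label to its expected branch; computed over the
    best of the two branch labelings (branch ids are arbitrary).
    """
    g = np.asarray(groups)
    b = np.asarray(branches)
    expected = np.array([split[x] for x in g])
    acc = (b == expected).mean()
    flipped = (b == (3 - expected)).mean()  # swap branch ids 1<->2
    return float(max(acc, flipped))


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a SciPy linkage tree as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
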