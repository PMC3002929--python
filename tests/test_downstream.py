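"""CNA-burden counting, region means and hierarchical clustering."""

from itertools import groupby

import numpy as np
import pandas as pd
import pytest

from cghcompare import downstream as ds, kcsmart as kc, synthetic as syn
from cghcompare.comparative import CohortKse, per_tumor_kse
from cghcompare.core import GenomicRegion
from cghcompare.downstream import (
    burden_table,
    branch_purity,
    cluster_tumors,
    count_cna_segments,
    linkage_to_newick,
    region_mean_matrix,
)
from cghcompare.kcsmart import KernelSpec, KseCurve

from conftest import make_two_group_cohort

SPEC = KernelSpec(width_mb=20.0)


@pytest.fixture(scope="module")
def grid(small_map):
    return kc.build_grid(small_map, 1_000_000)


def _curve(grid, values):
    return KseCurve(grid, values, label="t")


def _kse(grid, matrix, groups):
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(matrix.shape[1])],
        "group": groups, "platform": "P",
    })
    return CohortKse(grid, matrix, samples)


def oracle_count(values, cutoff, chrom_slices):
    """Independent pure-python scan: plateau-aware peaks exceeding the cutoff."""
    n = 0
    for _, sl in chrom_slices:
        for sign in (1, -1):
            compressed = [k for k, _ in groupby(sign * x for x in values[sl])]
            for i, x in enumerate(compressed):
                left = compressed[i - 1] if i > 0 else float("-inf")
                right = compressed[i + 1] if i < len(compressed) - 1 else float("-inf")
                if x > left and x > right and x > cutoff:
                    n += 1
    return n


def test_flat_curve_has_no_segments(grid):
    assert count_cna_segments(_curve(grid, np.zeros(grid.n_points)), 0.3) == 0


def test_plateau_counting(grid):
    v = np.zeros(grid.n_points)
    v[20:50] = 0.5
    assert count_cna_segments(_curve(grid, v), 0.3) == 1
    assert count_cna_segments(_curve(grid, v), 0.6) == 0
    v[60:70] = -0.7  # a loss counts too
    assert count_cna_segments(_curve(grid, v), 0.3) == 2


def test_runs_do_not_span_chromosomes(grid):
    sl1 = dict(grid.chrom_slices)["1"]
    sl2 = dict(grid.chrom_slices)["2"]
    v = np.zeros(grid.n_points)
    v[sl1.stop - 5:sl1.stop] = 1.0
    v[sl2.start:sl2.start + 5] = 1.0
    assert count_cna_segments(_curve(grid, v), 0.5) == 2


def test_counts_match_scan_oracle(grid):
    rng = np.random.default_rng(3)
    v = rng.normal(scale=0.5, size=grid.n_points)
    for t in (0.1, 0.3, 0.5, 0.9):
        assert count_cna_segments(_curve(grid, v), t) == oracle_count(
            v, t, grid.chrom_slices
        )


def test_cutoff_must_be_positive(grid):
    with pytest.raises(ValueError):
        count_cna_segments(_curve(grid, np.zeros(grid.n_points)), 0.0)


def test_burden_counts_monotone_in_cutoff(grid):
    rng = np.random.default_rng(4)
    kse = _kse(grid, rng.normal(scale=0.4, size=(grid.n_points, 6)), ["A"] * 6)
    table = burden_table(kse, np.arange(0.05, 1.0, 0.05))
    diffs = np.diff(table.counts.to_numpy(), axis=1)
    assert (diffs <= 0).all()


def test_burden_welch_matches_closed_form(grid):
    counts_a = np.array([4.0, 6.0, 5.0])
    counts_b = np.array([1.0, 2.0, 3.0])
    matrix = np.zeros((grid.n_points, 6))
    # plant exactly k unit plateaus for tumor k
    for j, k in enumerate(np.concatenate([counts_a, counts_b]).astype(int)):
        for run in range(k):
            matrix[run * 10:(run * 10) + 4, j] = 1.0
    kse = _kse(grid, matrix, ["A"] * 3 + ["B"] * 3)
    table = burden_table(kse, np.array([0.5]), test_groups=("A", "B"))
    np.testing.assert_array_equal(table.counts.to_numpy().ravel(),
                                  np.concatenate([counts_a, counts_b]))
    ma, mb = counts_a.mean(), counts_b.mean()
    va, vb = counts_a.var(ddof=1) / 3, counts_b.var(ddof=1) / 3
    t_stat = (ma - mb) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
    from scipy import stats

    expected = 2 * stats.t.sf(abs(t_stat), df)
    assert table.p_values.iloc[0] == pytest.approx(expected, rel=1e-12)


def test_burden_contrast_significant_over_contiguous_range(quad_map):
    """A high-burden group separates from a low-burden one across cutoffs."""
    def segs(group, n, other):
        out = []
        for k in range(n):
            chrom = str(k % 4 + 1)
            start = 10_000_000 + (k // 4) * 40_000_000
            sign = 1 if k % 2 == 0 else -1
            out.append(syn.CnaSegmentSpec(
                chrom, start, start + 25_000_000, "gain" if sign > 0 else "loss",
                0.8 * sign, 0.0, {group: 1.0, other: 0.0}))
        return out

    segments = segs("A", 8, "B") + [
        syn.CnaSegmentSpec("4", 110_000_000, 135_000_000, "gain", 0.8, 0.0,
                           {"B": 1.0, "A": 0.0}),
        syn.CnaSegmentSpec("2", 110_000_000, 135_000_000, "loss", -0.8, 0.0,
                           {"B": 1.0, "A": 0.0}),
    ]
    cohort, _ = make_two_group_cohort(quad_map, tuple(segments), n_a=20, n_b=20,
                                      noise_sd=0.2, seed=11)
    kse = per_tumor_kse(cohort, SPEC, 1_000_000)
    cutoffs = np.round(np.arange(0.02, 1.0 + 1e-9, 0.02), 2)
    table = burden_table(kse, cutoffs, test_groups=("A", "B"))
    mid = (cutoffs >= 0.1) & (cutoffs <= 0.6)
    med_a = table.group_medians.loc["A"].to_numpy()[mid]
    med_b = table.group_medians.loc["B"].to_numpy()[mid]
    assert (med_a > med_b).all()
    sig = table.p_values.to_numpy() < 0.01
    longest = max(
        (len(list(g)) for k, g in groupby(sig) if k), default=0
    )
    assert longest >= 5  # a contiguous band of significant cutoffs


def test_burden_small_group_yields_no_pvalues(grid):
    rng = np.random.default_rng(5)
    kse = _kse(grid, rng.normal(size=(grid.n_points, 3)), ["A", "A", "B"])
    table = burden_table(kse, np.array([0.5]), test_groups=("A", "B"))
    assert table.p_values is None


# --- region means -----------------------------------------------------------


def test_region_means_constant_curve(grid):
    kse = _kse(grid, np.full((grid.n_points, 2), 0.37), ["A", "A"])
    m = region_mean_matrix(kse, [GenomicRegion("1", 10.0, 40.0, "gain")])
    np.testing.assert_allclose(m.to_numpy(), 0.37)


def test_region_means_plateau_and_oracle(grid):
    rng = np.random.default_rng(6)
    matrix = rng.normal(size=(grid.n_points, 3))
    kse = _kse(grid, matrix, ["A"] * 3)
    regions = [GenomicRegion("1", 12.5, 61.5, "gain"),
               GenomicRegion("2", 80.0, 149.0, "loss")]
    m = region_mean_matrix(kse, regions)
    chroms = grid.chrom_of_points()
    for col, r in zip(m.columns, regions):
        mask = (chroms == r.chrom) & (grid.pos_bp >= r.start_mb * 1e6) \
            & (grid.pos_bp < r.end_mb * 1e6)
        np.testing.assert_allclose(m[col].to_numpy(), matrix[mask].mean(axis=0))


def test_region_mean_unknown_chromosome(grid):
    kse = _kse(grid, np.zeros((grid.n_points, 2)), ["A", "A"])
    with pytest.raises(ValueError, match="unknown chromosome"):
        region_mean_matrix(kse, [GenomicRegion("17", 1.0, 2.0, "gain")])


def test_region_without_grid_points_is_nan(grid):
    kse = _kse(grid, np.zeros((grid.n_points, 2)), ["A", "A"])
    m = region_mean_matrix(kse, [GenomicRegion("1", 10.1, 10.2, "gain")])
    assert m.isna().all().all()


# --- clustering -------------------------------------------------------------


def _feature_frame(seed=0, n=12, k=6):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n, k)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"r{j}" for j in range(k)],
    )


def test_duplicated_sample_lands_in_same_branch():
    f = _feature_frame(seed=1)
    f.loc["twin"] = f.loc["s0"]
    res = cluster_tumors(f)
    assert res.branches["twin"] == res.branches["s0"]


def test_cluster_partition_invariant_to_sample_order():
    f = _feature_frame(seed=2)
    res1 = cluster_tumors(f)
    perm = np.random.default_rng(3).permutation(len(f))
    res2 = cluster_tumors(f.iloc[perm])
    part1 = {}
    for b in (1, 2):
        part1[b] = frozenset(res1.branches[res1.branches == b].index)
    parts2 = {frozenset(res2.branches[res2.branches == b].index) for b in (1, 2)}
    assert {part1[1], part1[2]} == parts2


def test_cluster_zero_variance_sample_named():
    f = _feature_frame(seed=4)
    f.loc["flatliner"] = 1.0
    with pytest.raises(ValueError, match="flatliner"):
        cluster_tumors(f)


def test_cluster_rejects_missing_entries():
    f = _feature_frame(seed=5)
    f.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="absent"):
        cluster_tumors(f)


def test_cluster_composition_and_purity():
    rng = np.random.default_rng(6)
    a = rng.normal(loc=[1, 1, 1, 0, 0, 0], scale=0.2, size=(10, 6))
    b = rng.normal(loc=[0, 0, 0, 1, 1, 1], scale=0.2, size=(10, 6))
    f = pd.DataFrame(np.vstack([a, b]), index=[f"s{i}" for i in range(20)])
    groups = pd.Series(["A"] * 10 + ["B"] * 10, index=f.index)
    res = cluster_tumors(f, groups=groups)
    assert res.composition.to_numpy().sum() == 20
    split = {"A": 1, "B": 2}
    assert branch_purity(res.branches, groups, split) == 1.0


def test_newick_export_contains_all_leaves():
    f = _feature_frame(seed=7, n=6)
    res = cluster_tumors(f)
    nwk = linkage_to_newick(res.sample_linkage, list(f.index))
    assert nwk.endswith(";")
    assert nwk.count("(") == nwk.count(")") == 5
    for label in f.index:
        assert label in nwk
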