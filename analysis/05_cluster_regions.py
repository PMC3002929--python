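#!/usr/bin/env python
"""Hierarchical clustering of tumors on region-mean KSE values.

The feature set is the simulated differential architecture (the six truth
segments from 01_simulate_cohort.py); each tumor is summarized by its mean
smoothed log2 ratio per region, then clustered with Pearson-correlation
distance, complete linkage and optimal leaf ordering. The two-branch cut is
compared against group labels. Run 01_simulate_cohort.py first. Outputs go
to results/cluster/.
"""

from pathlib import Path

import pandas as pd

from cghcompare import comparative as cmp
from cghcompare import downstream as ds
from cghcompare import io as aio
from cghcompare import kcsmart as kc
from cghcompare.core import GenomicRegion

BASE = Path(__file__).resolve().parent.parent / "results"
IN_DIR = BASE / "sim_cohort"
OUT = BASE / "cluster"


def main() -> None:
    cohort = aio.read_acgh(IN_DIR / "probes.bed", IN_DIR / "matrix.tsv",
                           IN_DIR / "samples.tsv")
    cohort = aio.zscale_platform(cohort)
    kse = cmp.per_tumor_kse(cohort, kc.KernelSpec(20.0), 1_000_000)

    truth = pd.read_csv(IN_DIR / "truth.tsv", sep="\t",
                        dtype={"chrom": str})
    segs = truth[["chrom", "start_bp", "end_bp", "direction"]].drop_duplicates()
    regions = [
        GenomicRegion(r.chrom, r.start_bp / 1e6, r.end_bp / 1e6, r.direction)
        for r in segs.itertuples()
    ]
    features = ds.region_mean_matrix(kse, regions)
    groups = cohort.samples.set_index("sample_id")["group"]
    result = ds.cluster_tumors(features, groups=groups)

    OUT.mkdir(parents=True, exist_ok=True)
    features.rename_axis("sample_id").to_csv(OUT / "region_means.tsv", sep="\t")
    result.branches.rename_axis("sample_id").to_csv(OUT / "branches.tsv", sep="\t")
    result.composition.rename_axis("group").to_csv(
        OUT / "branch_composition.tsv", sep="\t")
    (OUT / "dendrogram.nwk").write_text(
        ds.linkage_to_newick(result.sample_linkage, list(features.index)) + "\n")

    print("branch composition (rows: group, columns: branch):")
    print(result.composition.to_string())
    basal = result.branches[groups.isin(["BRCA1", "BLBC"])]
    majority = basal.mode().iloc[0]
    n_together = int((basal == majority).sum())
    print(f"{n_together} of {len(basal)} BRCA1-like/basal-like tumors share "
          f"one branch")
    print(f"wrote {OUT}/{{region_means,branches,branch_composition}}.tsv "
          f"and dendrogram.nwk")


if __name__ == "__main__":
    main()
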