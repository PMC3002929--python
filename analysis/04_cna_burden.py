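#!/usr/bin/env python
"""CNA-burden sweep: aberration counts per tumor over a grid of KSE cutoffs.

Each tumor's normalized profile is smoothed once; aberration peaks exceeding
each symmetric cutoff (0.02 to 1.00, step 0.02) are counted, group medians
reported, and group means compared with Welch's two-sided t-test. Run
01_simulate_cohort.py first. Outputs go to results/burden/.
"""

from itertools import groupby
from pathlib import Path

from cghcompare import comparative as cmp
from cghcompare import downstream as ds
from cghcompare import io as aio
from cghcompare import kcsmart as kc

BASE = Path(__file__).resolve().parent.parent / "results"
IN_DIR = BASE / "sim_cohort"
OUT = BASE / "burden"

PAIRS = [("BRCA1", "luminal"), ("BLBC", "luminal"), ("BRCA1", "BLBC")]


def main() -> None:
    cohort = aio.read_acgh(IN_DIR / "probes.bed", IN_DIR / "matrix.tsv",
                           IN_DIR / "samples.tsv")
    cohort = aio.zscale_platform(cohort)
    kse = cmp.per_tumor_kse(cohort, kc.KernelSpec(20.0), 1_000_000)
    OUT.mkdir(parents=True, exist_ok=True)

    for ga, gb in PAIRS:
        table = ds.burden_table(kse, test_groups=(ga, gb))
        tag = f"{ga}_vs_{gb}"
        table.counts.rename_axis("sample_id").to_csv(
            OUT / f"counts.{tag}.tsv", sep="\t")
        table.group_medians.rename_axis("group").to_csv(
            OUT / f"medians.{tag}.tsv", sep="\t")
        table.p_values.rename("p").rename_axis("cutoff").to_csv(
            OUT / f"welch_p.{tag}.tsv", sep="\t")
        sig = table.p_values < 0.01
        bands = []
        cuts = list(table.cutoffs)
        i = 0
        for flag, run in groupby(sig):
            n = len(list(run))
            if flag:
                bands.append((cuts[i], cuts[i + n - 1]))
            i += n
        band_txt = ", ".join(f"{a:.2f}-{b:.2f}" for a, b in bands) or "none"
        print(f"{ga} vs {gb}: cutoff bands with Welch p < 0.01: {band_txt}")
    print(f"wrote burden tables to {OUT}")


if __name__ == "__main__":
    main()
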