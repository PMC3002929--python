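#!/usr/bin/env python
"""Simulate a two-platform breast-tumor aCGH cohort on a ~1 Mb BAC-style grid.

Three groups are generated: BRCA1-like and basal-like tumors sharing a
"basal" CNA architecture (3q gain, 5q loss enriched) profiled on an
FFPE-like platform and a fresh-frozen platform respectively, and a luminal
group (1q gain, 16q loss enriched) on the fresh-frozen platform. The FFPE
platform is given 1.5x wider log2 ratios, mimicking the systematic spread
difference between archival and fresh-frozen DNA. Outputs go to
results/sim_cohort/.
"""

from pathlib import Path

from cghcompare import io as aio
from cghcompare import synthetic as syn

OUT = Path(__file__).resolve().parent.parent / "results" / "sim_cohort"
SEED = 42

# Basal-type tumors carry both a distinct architecture and a higher overall
# CNA burden; luminal tumors carry the 1q-gain / 16q-loss pattern.
SEGMENTS = [
    # basal/BRCA1-enriched aberrations
    syn.CnaSegmentSpec("3", 151_000_000, 171_000_000, "gain", 0.9, 0.1,
                       {"BRCA1": 0.85, "BLBC": 0.8, "luminal": 0.1}),
    syn.CnaSegmentSpec("5", 90_000_000, 130_000_000, "loss", -0.8, 0.1,
                       {"BRCA1": 0.8, "BLBC": 0.8, "luminal": 0.1}),
    syn.CnaSegmentSpec("10", 1_000_000, 13_000_000, "gain", 0.8, 0.1,
                       {"BRCA1": 0.75, "BLBC": 0.75, "luminal": 0.1}),
    syn.CnaSegmentSpec("14", 48_000_000, 93_000_000, "loss", -0.7, 0.1,
                       {"BRCA1": 0.75, "BLBC": 0.7, "luminal": 0.1}),
    syn.CnaSegmentSpec("8", 100_000_000, 146_000_000, "gain", 0.8, 0.1,
                       {"BRCA1": 0.7, "BLBC": 0.7, "luminal": 0.1}),
    syn.CnaSegmentSpec("12", 0, 12_000_000, "gain", 0.8, 0.1,
                       {"BRCA1": 0.7, "BLBC": 0.65, "luminal": 0.1}),
    syn.CnaSegmentSpec("4", 15_000_000, 50_000_000, "loss", -0.7, 0.1,
                       {"BRCA1": 0.65, "BLBC": 0.7, "luminal": 0.1}),
    # luminal-enriched aberrations (1q/16p gains with the 16q loss)
    syn.CnaSegmentSpec("1", 176_000_000, 215_000_000, "gain", 0.9, 0.1,
                       {"BRCA1": 0.1, "BLBC": 0.1, "luminal": 0.85}),
    syn.CnaSegmentSpec("16", 45_000_000, 88_000_000, "loss", -0.9, 0.1,
                       {"BRCA1": 0.1, "BLBC": 0.1, "luminal": 0.85}),
    syn.CnaSegmentSpec("16", 4_000_000, 28_000_000, "gain", 0.8, 0.1,
                       {"BRCA1": 0.1, "BLBC": 0.1, "luminal": 0.8}),
]


def main() -> None:
    probe_map = syn.make_probe_map(spacing_bp=1_000_000, jitter_bp=200_000,
                                   seed=SEED)
    spec = syn.CohortSpec(
        n_per_group={"BRCA1": 20, "BLBC": 20, "luminal": 20},
        segments=SEGMENTS,
        probe_noise_sd=0.15,
        tumor_fraction_range=(0.5, 1.0),
        platform_by_group={"BRCA1": "FFPE", "BLBC": "frozen",
                           "luminal": "frozen"},
        platform_scale={"FFPE": 1.5, "frozen": 1.0},
        seed=SEED,
    )
    cohort, truth = syn.simulate_cohort(probe_map, spec)
    OUT.mkdir(parents=True, exist_ok=True)
    aio.write_acgh(cohort, OUT / "probes.bed", OUT / "matrix.tsv",
                   OUT / "samples.tsv")
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    n_present = int(truth["present"].sum())
    print(f"probe platform: {probe_map.n_probes} probes on "
          f"{len(probe_map.chromosomes)} chromosomes")
    print(f"cohort: {cohort.n_samples} tumors "
          f"({dict(cohort.samples['group'].value_counts())})")
    print(f"truth table: {n_present} segment presences drawn")
    print(f"wrote {OUT}/{{probes.bed,matrix.tsv,samples.tsv,truth.tsv}}")


if __name__ == "__main__":
    main()
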