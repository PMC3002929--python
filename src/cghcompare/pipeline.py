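"""End-to-end pipeline: simulate -> normalize -> smooth -> compare -> burden
-> cluster -> TP53 statistics, with one root seed and a reproducible manifest.

The configuration is a flat YAML mapping; unknown keys are rejected so typos
fail before any computation. All stage outputs are TSV/Newick/JSON text files
whose SHA-256 digests are recorded in ``manifest.json``; rerunning with the
same config and seed reproduces every output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import comparative, downstream, io as aio, kcsmart, synthetic, tp53
from .core import AcghCohort

logger = logging.getLogger(__name__)

_STAGE_SEED_OFFSETS = {"simulate": 11, "single_group": 23, "compare": 37}


@dataclass
class PipelineConfig:
    kernel_width_mb: float = 20.0
    grid_step_kb: int = 100
    n_perm: int = 6000
    fdr: float = 0.05
    alpha: float = 0.05
    cutoff_start: float = 0.02
    cutoff_stop: float = 1.0
    cutoff_step: float = 0.02
    abundance_min: float = 0.25
    seed: int = 0
    # synthetic cohort
    n_per_group: dict = field(default_factory=lambda: {"BRCA1": 10, "BLBC": 10, "luminal": 10})
    segments: list = field(default_factory=list)  # list of CnaSegmentSpec kwargs
    probe_noise_sd: float = 0.15
    tumor_fraction_range: list = field(default_factory=lambda: [0.5, 1.0])
    platform_by_group: dict = field(default_factory=dict)
    platform_scale: dict = field(default_factory=dict)
    chrom_lengths_mb: dict | None = None
    probe_spacing_kb: int = 1000
    probe_jitter_kb: int = 0
    comparisons: list = field(default_factory=lambda: [["BRCA1", "BLBC"]])
    burden_groups: list | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must be in (0, 1)")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.kernel_width_mb <= 0 or self.grid_step_kb <= 0:
            raise ValueError("kernel width and grid step must be positive")
        if self.n_perm < 20:
            raise ValueError("n_perm must be >= 20")
        if not 0.0 <= self.abundance_min < 1.0:
            raise ValueError("abundance_min must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def kernel_spec(self) -> kcsmart.KernelSpec:
        return kcsmart.KernelSpec(width_mb=self.kernel_width_mb)

    def cohort_spec(self) -> synthetic.CohortSpec:
        segments = tuple(synthetic.CnaSegmentSpec(**s) for s in self.segments)
        return synthetic.CohortSpec(
            n_per_group=self.n_per_group,
            segments=segments,
            probe_noise_sd=self.probe_noise_sd,
            tumor_fraction_range=tuple(self.tumor_fraction_range),
            platform_by_group=self.platform_by_group,
            platform_scale=self.platform_scale,
            seed=self.seed + _STAGE_SEED_OFFSETS["simulate"],
        )

    def cutoffs(self) -> np.ndarray:
        return np.round(
            np.arange(self.cutoff_start, self.cutoff_stop + 1e-9, self.cutoff_step), 6
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage; return the manifest (also written to manifest.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "outputs": {}}

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].setdefault(stage, [])
        for p in paths:
            manifest["stages"][stage].append(p.name)
            manifest["outputs"][p.name] = _sha256(p)

    try:
        # simulate
        lengths = (
            {c: int(mb) * 1_000_000 for c, mb in config.chrom_lengths_mb.items()}
            if config.chrom_lengths_mb
            else None
        )
        pmap = synthetic.make_probe_map(
            lengths,
            spacing_bp=config.probe_spacing_kb * 1000,
            jitter_bp=config.probe_jitter_kb * 1000,
            seed=config.seed + _STAGE_SEED_OFFSETS["simulate"],
        )
        cohort, truth = synthetic.simulate_cohort(pmap, config.cohort_spec())
        aio.write_acgh(cohort, out / "probes.bed", out / "matrix.tsv", out / "samples.tsv")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        record("simulate", out / "probes.bed", out / "matrix.tsv",
               out / "samples.tsv", out / "truth.tsv")

        # normalize
        cohort = aio.zscale_platform(cohort)
        aio.write_acgh(
            cohort, out / "probes.bed", out / "matrix.normalized.tsv", out / "samples.tsv"
        )
        record("normalize", out / "matrix.normalized.tsv")

        # smooth
        spec = config.kernel_spec()
        smoother = kcsmart.Smoother(cohort.map, spec, config.grid_step_kb * 1000)
        kse = comparative.per_tumor_kse(cohort, spec, smoother=smoother)
        for group in dict.fromkeys(cohort.samples["group"]):
            gains, losses = kcsmart.group_kse(cohort, group, spec, smoother=smoother)
            kcsmart.write_curve_tsv(gains, out / f"kse_gains.{group}.tsv")
            kcsmart.write_curve_tsv(losses, out / f"kse_losses.{group}.tsv")
            record("smooth", out / f"kse_gains.{group}.tsv", out / f"kse_losses.{group}.tsv")

        # compare
        for ga, gb in config.comparisons:
            cfg = comparative.PermutationConfig(
                n_perm=config.n_perm, fdr=config.fdr,
                seed=config.seed + _STAGE_SEED_OFFSETS["compare"],
            )
            curve = comparative.snr_curve(kse, ga, gb)
            thresholds = comparative.permutation_fdr_threshold(kse, ga, gb, cfg)
            regions = comparative.call_differential_regions(curve, thresholds)
            tag = f"{ga}_vs_{gb}"
            import pandas as pd

            pd.DataFrame(
                {
                    "chrom": curve.grid.chrom_of_points(),
                    "pos_bp": curve.grid.pos_bp,
                    "snr": curve.snr,
                }
            ).to_csv(out / f"snr.{tag}.tsv", sep="\t", index=False)
            aio.write_regions(regions, out / f"regions.{tag}.tsv")
            record("compare", out / f"snr.{tag}.tsv", out / f"regions.{tag}.tsv")

        # burden
        bt_groups = tuple(config.burden_groups) if config.burden_groups else None
        burden = downstream.burden_table(kse, config.cutoffs(), bt_groups)
        burden.counts.rename_axis("sample_id").to_csv(out / "burden_counts.tsv", sep="\t")
        burden.group_medians.rename_axis("group").to_csv(
            out / "burden_medians.tsv", sep="\t"
        )
        if burden.p_values is not None:
            burden.p_values.rename("p_value").rename_axis("cutoff").to_csv(
                out / "burden_pvalues.tsv", sep="\t"
            )
            record("burden", out / "burden_pvalues.tsv")
        record("burden", out / "burden_counts.tsv", out / "burden_medians.tsv")

        # cluster on the configured segment regions (whole chromosomes if none)
        from .core import GenomicRegion

        if len(config.segments) >= 2:
            cluster_regions = [
                GenomicRegion(
                    s["chrom"], s["start_bp"] / 1e6, s["end_bp"] / 1e6, s["direction"]
                )
                for s in config.segments
            ]
        else:
            cluster_regions = [
                GenomicRegion(c, 0.0, cohort.map.chrom_extent_bp(c) / 1e6, "gain")
                for c in cohort.map.chromosomes
            ]
        features = downstream.region_mean_matrix(kse, cluster_regions)
        result = downstream.cluster_tumors(
            features, groups=cohort.samples.set_index("sample_id")["group"]
        )
        features.rename_axis("sample_id").to_csv(out / "region_means.tsv", sep="\t")
        result.branches.rename_axis("sample_id").to_csv(out / "branches.tsv", sep="\t")
        result.composition.rename_axis("group").to_csv(
            out / "branch_composition.tsv", sep="\t"
        )
        (out / "dendrogram.nwk").write_text(
            downstream.linkage_to_newick(result.sample_linkage, list(features.index))
            + "\n"
        )
        record(
            "cluster", out / "region_means.tsv", out / "branches.tsv",
            out / "branch_composition.tsv", out / "dendrogram.nwk",
        )

        # tp53 statistics on the packaged fixture
        records = tp53.load_table1_records()
        groups = sorted({r.group for r in records})
        summaries = {
            g: tp53.group_summary(records, g, config.abundance_min) for g in groups
        }
        rows = [asdict(s) for s in summaries.values()]
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "tp53_summary.tsv", sep="\t", index=False)
        record("tp53", out / "tp53_summary.tsv")
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
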