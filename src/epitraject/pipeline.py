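"""End-to-end pipeline with plain-file handoff between stages.

Stages (simulate -> quantify -> callpeaks -> trajectories -> structure ->
integrate -> report) communicate only through TSV/BED/JSON files in the
output directory, so any stage can be re-run in isolation and inspected.
The report echoes the fully resolved configuration; re-running from that
echo reproduces the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import annotation as ann
from . import integrate as integ
from .intervals import GenomicInterval, ReadSet, read_alignment_bed, write_bed
from .peaks import (DifferentialConfig, PeakCallerConfig, call_peaks,
                    peak_length_distribution, pool_merge_peaks)
from .quantify import build_density_matrix
from .simulate import CohortConfig, SampleMeta, simulate_cohort
from .structure import build_differential_matrix, group_separation_score, pca_scores
from .trajectory import (TrajectoryCallConfig, assign_age_groups,
                         classify_up_down, filter_and_normalize_for_clustering,
                         geneset_mean_expression, kmeans_profiles, mean_profile)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("simulate", "quantify", "callpeaks", "trajectories",
          "structure", "integrate", "report")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the analysis defaults.

    The simulate-stage scale defaults are deliberately modest (file-based
    handoff writes every read as a BED line); the in-memory study
    configurations used for recovery experiments live in
    :mod:`epitraject.simulate`.
    """

    outdir: str = "epitraject_out"
    seed: int = 1
    # simulate scale: a compact demonstration cohort (strong planted
    # effects, sparse toy genome) so the BED handoff stays small
    n_samples: int = 12  # 0 = the full 31-sample design
    n_regions: int = 60
    region_pitch: int = 400_000
    background_depth: int = 35_000
    d_low: float = 0.1
    d_high: float = 0.5
    promoter_signal_load: float = 0.995
    anti_rho: float = 0.8
    # promoters / quantify
    promoter_flank: int = 2000
    # caller
    bw: int = 230
    tsize: int = 36
    caller_p: float = 1e-5
    # differential / structure
    diff_p: float = 1e-5
    diff_ratio: float = 2.0
    diff_density: float = 0.005
    # trajectory
    density_floor: float = 0.01
    min_fold: float = 2.0
    max_p: float = 0.05
    min_length: int = 1000
    k_clusters: int = 5
    # integration
    fdr_cutoff: float = 0.05
    alt_promoter_span: int = 100_000
    enrichment_inclusion_fdr: float = 0.85

    def __post_init__(self):
        if not (0 < self.caller_p < 1 and 0 < self.diff_p <= 1):
            raise ValueError("p thresholds must lie in (0, 1)")
        if not (0 < self.max_p < 1):
            raise ValueError("max_p must lie in (0, 1)")
        if not (0 <= self.anti_rho <= 1):
            raise ValueError("anti_rho must lie in [0, 1]")
        for name in ("promoter_flank", "bw", "tsize", "min_length",
                     "k_clusters", "n_regions", "background_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def cohort_config(self) -> CohortConfig:
        from .simulate import TABLE1_SAMPLES

        chip = [s for s in TABLE1_SAMPLES if s.fraction == "chip"]
        inputs = [s for s in TABLE1_SAMPLES if s.fraction == "input"]
        if self.n_samples:
            chip = chip[: self.n_samples]
        return CohortConfig(
            samples=chip + inputs,
            n_regions=self.n_regions,
            region_pitch=self.region_pitch,
            background_depth=self.background_depth,
            d_low=self.d_low,
            d_high=self.d_high,
            promoter_signal_load=self.promoter_signal_load,
            n_bipromoter_genes=0,
            seed=self.seed,
        )

    def caller_config(self) -> PeakCallerConfig:
        return PeakCallerConfig(bw=self.bw, tsize=self.tsize,
                                p_threshold=self.caller_p)

    def diff_config(self) -> DifferentialConfig:
        return DifferentialConfig(p_threshold=self.diff_p,
                                  min_ratio=self.diff_ratio,
                                  min_density=self.diff_density)

    def trajectory_config(self) -> TrajectoryCallConfig:
        return TrajectoryCallConfig(
            density_floor=self.density_floor, min_fold=self.min_fold,
            max_p=self.max_p, min_length=self.min_length,
        )


def _read_samples(outdir: Path) -> list[SampleMeta]:
    import pandas as pd

    df = pd.read_csv(outdir / "samples.tsv", sep="\t")
    return [
        SampleMeta(r.sample_id, float(r.age_years), r.fraction, r.cell_class, r.sex)
        for r in df.itertuples()
    ]


def _read_readsets(outdir: Path, samples) -> dict[str, ReadSet]:
    return {
        s.sample_id: read_alignment_bed(
            outdir / "reads" / f"{s.sample_id}.bed", sample_id=s.sample_id
        )
        for s in samples
    }


def _chip_ids(samples) -> list[str]:
    return [s.sample_id for s in samples if s.fraction == "chip"]


def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    import pandas as pd

    ccfg = cfg.cohort_config()
    cohort = simulate_cohort(ccfg, anti_rho=cfg.anti_rho)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    for sid, rs in cohort.readsets.items():
        rs.write_bed(outdir / "reads" / f"{sid}.bed")
    pd.DataFrame(
        [(s.sample_id, s.age_years, s.fraction, s.cell_class, s.sex)
         for s in cohort.samples],
        columns=["sample_id", "age_years", "fraction", "cell_class", "sex"],
    ).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    ann.write_annotation_tsv(outdir / "annotation.tsv", cohort.annotation)
    pd.DataFrame(
        [(m.region.chrom, m.region.start, m.region.end, m.gene_id, m.klass,
          m.d_start, m.d_inf, m.tau, m.proximal)
         for m in cohort.models],
        columns=["chrom", "start", "end", "gene_id", "klass",
                 "d_start", "d_inf", "tau", "proximal"],
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    cohort.methylation.to_csv(outdir / "methylation.tsv", sep="\t", index=False)
    cohort.expression.to_csv(outdir / "expression.tsv", sep="\t")
    with open(outdir / "genome.json", "w") as fh:
        json.dump(ccfg.chrom_sizes, fh, sort_keys=True)
    return {"n_samples": len(cohort.samples), "n_regions": ccfg.n_regions}


def _stage_quantify(cfg: PipelineConfig, outdir: Path) -> dict:
    samples = _read_samples(outdir)
    annotation = ann.read_annotation_tsv(outdir / "annotation.tsv")
    promoters = ann.build_promoters(annotation, flank=cfg.promoter_flank)
    readsets = _read_readsets(outdir, [s for s in samples if s.fraction == "chip"])
    dm = build_density_matrix(readsets, promoters.regions, promoters)
    dm.to_frame().to_csv(outdir / "promoter_density.tsv", sep="\t")
    from .quantify import pairwise_pearson
    import pandas as pd

    R = pairwise_pearson(dm)
    pd.DataFrame(R, index=dm.sample_ids, columns=dm.sample_ids).to_csv(
        outdir / "correlation.tsv", sep="\t"
    )
    return {"n_promoter_regions": len(promoters),
            "n_quantified_samples": len(dm.sample_ids)}


def _stage_callpeaks(cfg: PipelineConfig, outdir: Path) -> dict:
    import pandas as pd

    samples = _read_samples(outdir)
    with open(outdir / "genome.json") as fh:
        genome = json.load(fh)
    inputs = [s for s in samples if s.fraction == "input"]
    if not inputs:
        raise RuntimeError("callpeaks: no input sample in samples.tsv")
    control = read_alignment_bed(
        outdir / "reads" / f"{inputs[0].sample_id}.bed",
        sample_id=inputs[0].sample_id,
    )
    (outdir / "peaks").mkdir(exist_ok=True)
    per_sample = []
    rows = []
    for sid in _chip_ids(samples):
        rs = read_alignment_bed(outdir / "reads" / f"{sid}.bed", sample_id=sid)
        pks = call_peaks(rs, control, cfg.caller_config(), genome=genome)
        per_sample.append(pks)
        with open(outdir / "peaks" / f"{sid}.bed", "w") as fh:
            for p in pks:
                fh.write(
                    f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                    f"\t{sid}\t{-10 * p.log10_p:.1f}\t.\t{p.count}\t{p.lam:.3f}"
                    f"\t{p.ratio:.3f}\n"
                )
        counts, props = peak_length_distribution(pks)
        rows.append([sid, len(pks)] + [counts[b] for b in sorted(counts)])
    consensus = pool_merge_peaks(per_sample)
    write_bed(outdir / "consensus_peaks.bed", consensus.regions)
    pd.DataFrame(
        rows, columns=["sample_id", "n_peaks", "gt500", "gt1k", "gt2k",
                       "gt3k", "gt4k", "gt5k"],
    ).to_csv(outdir / "peak_lengths.tsv", sep="\t", index=False)
    return {"n_consensus_peaks": len(consensus)}


def _density_over_consensus(cfg: PipelineConfig, outdir: Path):
    from .intervals import read_bed

    samples = _read_samples(outdir)
    chip = [s for s in samples if s.fraction == "chip"]
    annotation = ann.read_annotation_tsv(outdir / "annotation.tsv")
    promoters = ann.build_promoters(annotation, flank=cfg.promoter_flank)
    regions = read_bed(outdir / "consensus_peaks.bed")
    regions = [GenomicInterval(r.chrom, r.start, r.end) for r in regions]
    readsets = _read_readsets(outdir, chip)
    dm = build_density_matrix(readsets, regions, promoters)
    ages = np.array(
        [s.age_years for s in chip if s.sample_id in dm.sample_ids]
    )
    return dm, ages, annotation


def _stage_trajectories(cfg: PipelineConfig, outdir: Path) -> dict:
    import pandas as pd

    dm, ages, _ = _density_over_consensus(cfg, outdir)
    calls = classify_up_down(dm, ages, cfg.trajectory_config())
    calls.to_csv(outdir / "trajectory_calls.tsv", sep="\t", index=False)

    profiles = {}
    for klass in ("up", "down"):
        idx = np.flatnonzero((calls["klass"] == klass).to_numpy())
        if idx.size:
            profiles[klass] = mean_profile(dm, idx)
    prof_df = pd.DataFrame(
        {"sample_id": dm.sample_ids, "age_years": ages,
         **{f"{k}_mean_density": v for k, v in profiles.items()}}
    )
    prof_df.to_csv(outdir / "profiles.tsv", sep="\t", index=False)

    norm, idx = filter_and_normalize_for_clustering(dm, ages, cfg.trajectory_config())
    n_kept = norm.shape[0]
    cluster_info = {}
    if n_kept >= cfg.k_clusters:
        cl = kmeans_profiles(norm, idx, ages, k=cfg.k_clusters, seed=cfg.seed)
        pd.DataFrame(
            {
                "chrom": [dm.regions[i].chrom for i in cl.region_indices],
                "start": [dm.regions[i].start for i in cl.region_indices],
                "end": [dm.regions[i].end for i in cl.region_indices],
                "cluster": cl.assignments,
                "trend": [cl.trends[c] for c in cl.assignments],
            }
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        cluster_info = {"cluster_trends": cl.trends}
    return {
        "n_up": int((calls["klass"] == "up").sum()),
        "n_down": int((calls["klass"] == "down").sum()),
        "n_clustered_regions": int(n_kept),
        **cluster_info,
    }


def _stage_structure(cfg: PipelineConfig, outdir: Path) -> dict:
    import pandas as pd

    samples = _read_samples(outdir)
    chip = [s for s in samples if s.fraction == "chip"]
    with open(outdir / "genome.json") as fh:
        genome = json.load(fh)
    annotation = ann.read_annotation_tsv(outdir / "annotation.tsv")
    promoters = ann.build_promoters(annotation, flank=cfg.promoter_flank)
    readsets = _read_readsets(outdir, chip)
    M = build_differential_matrix(
        readsets, promoters.regions, cfg.caller_config(), cfg.diff_config(),
        genome=genome,
    )
    M.to_csv(outdir / "diffmatrix.tsv", sep="\t")
    pca = pca_scores(M)
    k = min(5, pca.scores.shape[1])
    score_df = pd.DataFrame(
        pca.scores[:, :k], index=pca.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    score_df.to_csv(outdir / "pca_scores.tsv", sep="\t")
    groups = assign_age_groups([s.age_years for s in chip])
    sep = group_separation_score(pca, groups)
    return {
        "variance_fractions": [float(v) for v in pca.variance_fractions[:k]],
        **{k_: float(v) for k_, v in sep.items()},
    }


def _stage_integrate(cfg: PipelineConfig, outdir: Path) -> dict:
    import pandas as pd

    samples = _read_samples(outdir)
    chip = [s for s in samples if s.fraction == "chip"]
    ages = np.array([s.age_years for s in chip])
    annotation = ann.read_annotation_tsv(outdir / "annotation.tsv")
    calls = pd.read_csv(outdir / "trajectory_calls.tsv", sep="\t")
    peaks = [
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in calls.itertuples()
    ]
    assignment = integ.peaks_to_genes(
        peaks, annotation, window=cfg.promoter_flank,
        klasses=list(calls["klass"]),
    )
    assignment.to_csv(outdir / "gene_assignment.tsv", sep="\t", index=False)
    alt = integ.alternative_promoter_classes(assignment, cfg.alt_promoter_span)
    pd.DataFrame(sorted(alt.items()), columns=["gene_id", "class"]).to_csv(
        outdir / "alternative_promoters.tsv", sep="\t", index=False
    )

    gene_classes = (
        assignment[assignment["klass"].isin(["up", "down"])]
        .drop_duplicates("gene_id")
        .set_index("gene_id")["klass"]
        .to_dict()
    )
    meth = pd.read_csv(outdir / "methylation.tsv", sep="\t")
    cpg = integ.cpg_age_test(meth, ages, fdr_cutoff=cfg.fdr_cutoff)
    cpg.to_csv(outdir / "methylation_results.tsv", sep="\t", index=False)
    contingency = integ.direction_contingency(cpg, gene_classes)
    with open(outdir / "contingency.json", "w") as fh:
        json.dump(contingency, fh, indent=2)

    expr = pd.read_csv(outdir / "expression.tsv", sep="\t", index_col=0)
    expr_rows = {"sample_id": list(expr.columns), "age_years": ages}
    for klass in ("up", "down"):
        genes = [g for g, c in gene_classes.items() if c == klass]
        if genes:
            expr_rows[f"{klass}_mean_expression"] = geneset_mean_expression(expr, genes)
    pd.DataFrame(expr_rows).to_csv(
        outdir / "expression_profiles.tsv", sep="\t", index=False
    )
    return {
        "n_gene_links": int(len(assignment)),
        "n_alternative_promoter_genes": len(alt),
        "contingency_p": contingency["p_hypergeometric"],
    }


def _stage_report(cfg: PipelineConfig, outdir: Path, stage_info: dict) -> dict:
    report = {"config": cfg.to_dict(), "stages": stage_info}
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return {"report": str(outdir / "report.json")}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "callpeaks": _stage_callpeaks,
    "trajectories": _stage_trajectories,
    "structure": _stage_structure,
    "integrate": _stage_integrate,
}


def run_pipeline(
    cfg: PipelineConfig,
    stages: tuple[str, ...] = STAGES,
) -> dict:
    """Execute the requested stages in order; returns the report dict.

    Each stage reads only files emitted by earlier stages.  A stage
    failure halts the run with the stage name attached.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_info = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        if stage == "report":
            stage_info["report"] = _stage_report(cfg, outdir, stage_info)
            continue
        logger.info("stage %s starting", stage)
        try:
            info = _STAGE_FUNCS[stage](cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s: %s", stage, info)
        stage_info[stage] = info
    return stage_info
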