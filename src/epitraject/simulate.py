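"""Synthetic age-structured ChIP-seq cohort with planted developmental kinetics.

The generator emulates the design of a postmortem prefrontal-cortex
H3K4me3 study: ~31 immunoprecipitated samples spanning late gestation to
old age plus one antibody-free input control, single-end 36 bp reads, a
toy multi-chromosome genome with TSS-anchored enrichment regions, and --
per region -- a monotone-saturating density trajectory in age

    d(age) = d_inf + (d_start - d_inf) * exp(-(age - a0) / tau)

with a0 the earliest cohort age.  Up regions gain density with age, down
regions lose it, flat regions stay constant.  Companion tables of CpG
methylation (anti-correlated with the histone trajectories) and gene
expression (correlated with them) make the cross-omic stages testable.

Prenatal ages are encoded as negative years relative to a 40-gestational-
week term birth: age_years = (gw - 40) * 7 / 365.25.

All randomness flows from one master seed through named substreams
(annotation, trajectory models, one per sample, methylation, expression),
so outputs are reproducible and stable under reordering of the calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import TSS, GeneAnnotation, build_promoters
from .intervals import GenomicInterval, ReadSet

__all__ = [
    "SampleMeta",
    "TrajectoryModel",
    "CohortConfig",
    "Cohort",
    "gw_to_years",
    "TABLE1_SAMPLES",
    "REDUCED_12_SAMPLES",
    "trajectory_density",
    "simulate_annotation",
    "simulate_sample_reads",
    "simulate_methylation",
    "simulate_expression",
    "simulate_cohort",
]

DAYS_PER_YEAR = 365.25
TERM_GW = 40


def gw_to_years(gw: float) -> float:
    """Convert a gestational-week age to (negative) years relative to term."""
    return (gw - TERM_GW) * 7.0 / DAYS_PER_YEAR


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    age_years: float
    fraction: str = "chip"  # chip | input
    cell_class: str = "NeuN+"
    sex: str = "unknown"

    def __post_init__(self):
        if not (-0.15 <= self.age_years <= 110):
            raise ValueError(f"age {self.age_years} outside plausible range")
        if self.fraction not in ("chip", "input"):
            raise ValueError(f"unknown fraction {self.fraction!r}")


def _meta(i, age, sex, fraction="chip"):
    return SampleMeta(f"S{i:02d}", age, fraction, "NeuN+", sex)


# The 31-sample neuronal cohort design (ages and sexes of the emulated
# study; gestational-week ages converted to negative years) plus the one
# input control.
_TABLE1 = [
    (gw_to_years(34), "F"), (gw_to_years(39), "F"), (gw_to_years(40), "F"),
    (0.5, "M"), (0.6, "M"), (0.8, "F"),
    (1.3, "M"), (2.8, "F"), (4.0, "F"), (4.7, "M"), (8.8, "M"), (14.0, "M"),
    (17.0, "M"), (18.0, "M"), (19.0, "M"), (20.0, "M"), (23.0, "M"),
    (24.0, "M"), (24.0, "M"), (26.0, "M"), (28.0, "F"), (38.0, "M"),
    (41.0, "F"), (55.0, "M"), (63.0, "M"), (64.0, "M"), (68.0, "F"),
    (69.0, "F"), (74.0, "M"), (74.0, "F"), (81.0, "M"),
]

TABLE1_SAMPLES: list[SampleMeta] = [
    _meta(i + 1, age, sex) for i, (age, sex) in enumerate(_TABLE1)
] + [SampleMeta("input", 69.0, "input", "NeuN+", "F")]

# 12-sample design for the reduced cohort-structure analysis: three samples
# in each of four age strata (gestational, 0-1 yr, 3-14 yr, 15-25 yr).
_REDUCED = [
    (gw_to_years(34), "F"), (gw_to_years(39), "F"), (gw_to_years(40), "F"),
    (0.5, "M"), (0.6, "M"), (0.8, "F"),
    (4.0, "F"), (8.8, "M"), (14.0, "M"),
    (17.0, "M"), (19.0, "M"), (23.0, "M"),
]

REDUCED_12_SAMPLES: list[SampleMeta] = [
    _meta(i + 1, age, sex) for i, (age, sex) in enumerate(_REDUCED)
] + [SampleMeta("input", 69.0, "input", "NeuN+", "F")]


@dataclass(frozen=True)
class TrajectoryModel:
    """Planted density kinetics of one region."""

    region: GenomicInterval
    gene_id: str
    klass: str  # up | down | flat
    d_start: float
    d_inf: float
    tau: float
    proximal: bool = True

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if min(self.d_start, self.d_inf) < 0:
            raise ValueError("densities must be non-negative")
        if self.klass == "up" and not self.d_inf > self.d_start:
            raise ValueError("up model requires d_inf > d_start")
        if self.klass == "down" and not self.d_inf < self.d_start:
            raise ValueError("down model requires d_inf < d_start")
        if self.klass == "flat" and self.d_inf != self.d_start:
            raise ValueError("flat model requires d_inf == d_start")


def trajectory_density(model: TrajectoryModel, age_years, a0: float):
    """Expected density of ``model`` at ``age_years`` (scalar or array)."""
    age = np.asarray(age_years, dtype=float)
    if np.any(age < a0 - 1e-12):
        raise ValueError(f"age below earliest cohort age a0={a0}")
    d = model.d_inf + (model.d_start - model.d_inf) * np.exp(-(age - a0) / model.tau)
    return float(d) if np.isscalar(age_years) else d


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Density units match the promoter-anchored normalization (reads per bp
    per million promoter-anchored reads), so the analysis thresholds
    (density floor 0.01, differential floor 0.005) sit on the planted
    scale.  ``promoter_signal_load`` is the fraction of promoter-anchored
    reads contributed by region enrichment rather than background; the
    read-placement scale is solved per sample so that realized densities
    match the planted ones in expectation.
    """

    samples: list[SampleMeta] = field(default_factory=lambda: list(TABLE1_SAMPLES))
    n_regions: int = 2000
    p_up: float = 0.05
    p_down: float = 0.10
    n_chroms: int = 4
    region_pitch: int = 32_000
    region_length_range: tuple[int, int] = (1200, 3000)
    fraction_proximal: float = 0.66
    n_bipromoter_genes: int = 20
    bipromoter_max_span: int = 100_000
    background_depth: int = 100_000
    input_depth_factor: float = 2.0
    promoter_signal_load: float = 0.985
    d_low: float = 0.01
    d_high: float = 0.04
    flat_sigma_log: float = 0.6
    tau_range: tuple[float, float] = (0.5, 2.0)
    read_length: int = 36
    fragment_half: int = 115  # half the ~230 bp fragment size
    n_cpgs_per_gene: int = 2
    meth_noise_sd: float = 0.05
    expression_noise_sd: float = 0.3
    expression_slope: float = 25.0
    seed: int = 1

    def __post_init__(self):
        if self.p_up + self.p_down > 1:
            raise ValueError("p_up + p_down must be <= 1")
        if self.background_depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 < self.promoter_signal_load < 1):
            raise ValueError("promoter_signal_load must be in (0, 1)")
        lo, hi = self.region_length_range
        if self.region_pitch < hi + 6000:
            raise ValueError(
                "region_pitch too small for region length plus promoter flanks; "
                "increase region_pitch (or shrink regions)"
            )

    @property
    def chip_samples(self) -> list[SampleMeta]:
        return [s for s in self.samples if s.fraction == "chip"]

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age_years for s in self.chip_samples])

    @property
    def a0(self) -> float:
        return float(self.ages.min())

    @property
    def chrom_sizes(self) -> dict[str, int]:
        per = -(-self.n_regions // self.n_chroms)  # ceil
        size = per * self.region_pitch + self.region_pitch
        return {f"chr{i + 1}": size for i in range(self.n_chroms)}

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_sizes.values())


def _rng(config: CohortConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


# substream domains
_DOM_ANNOT, _DOM_MODELS, _DOM_READS, _DOM_METH, _DOM_EXPR = 0, 1, 2, 3, 4


def simulate_annotation(
    config: CohortConfig,
) -> tuple[GeneAnnotation, list[TrajectoryModel]]:
    """Lay out enrichment regions and their genes; plant the kinetics.

    Regions sit on a jittered grid (one per ``region_pitch`` bp), each
    tied to one gene.  A ``fraction_proximal`` share of regions carry
    their gene's TSS inside the region; the rest have the TSS 3-10 kb
    away (distal).  Up/down/flat classes are assigned in exact rounded
    proportion; a configurable number of gene pairs within 100 kb are
    fused into two-promoter genes for the alternative-promoter analysis.
    """
    rng = _rng(config, _DOM_ANNOT)
    n = config.n_regions
    chroms = list(config.chrom_sizes)
    per = -(-n // config.n_chroms)
    lo, hi = config.region_length_range

    regions: list[GenomicInterval] = []
    for i in range(n):
        chrom = chroms[i // per]
        slot = i % per
        length = int(rng.integers(lo, hi + 1))
        jitter = int(rng.integers(0, config.region_pitch - length - 6000))
        start = slot * config.region_pitch + 3000 + jitter
        regions.append(GenomicInterval(chrom, start, start + length))

    # class assignment: exact rounded counts, shuffled
    n_up = round(config.p_up * n)
    n_down = round(config.p_down * n)
    klasses = np.array(
        ["up"] * n_up + ["down"] * n_down + ["flat"] * (n - n_up - n_down)
    )
    rng.shuffle(klasses)

    proximal = rng.random(n) < config.fraction_proximal

    mrng = _rng(config, _DOM_MODELS)
    taus = mrng.uniform(*config.tau_range, size=n)
    flat_d = np.exp(mrng.normal(0.0, config.flat_sigma_log, size=n))

    # scale flat densities so that, at the regulated midpoint, the
    # TSS-proximal sum of density*length hits the configured promoter
    # signal load on the million-promoter-read scale
    lengths = np.array([len(r) for r in regions], dtype=float)
    d_mid = np.where(
        klasses == "flat", flat_d, 0.5 * (config.d_low + config.d_high)
    )
    s_reg = float(np.sum(d_mid[(klasses != "flat") & proximal]
                         * lengths[(klasses != "flat") & proximal]))
    flat_prox = (klasses == "flat") & proximal
    s_flat_raw = float(np.sum(flat_d[flat_prox] * lengths[flat_prox]))
    target = config.promoter_signal_load * 1e6 - s_reg
    if target <= 0 or s_flat_raw <= 0:
        raise ValueError("infeasible promoter signal load for this design")
    flat_d *= target / s_flat_raw

    genes: dict[str, list[TSS]] = {}
    models: list[TrajectoryModel] = []
    gene_of_region: list[str] = []
    for i, reg in enumerate(regions):
        gid = f"G{i:05d}"
        gene_of_region.append(gid)
        if proximal[i]:
            pos = reg.start + len(reg) // 4
        else:
            offset = int(rng.integers(3000, 10_000))
            pos = reg.end + offset if rng.random() < 0.5 else max(0, reg.start - offset)
        genes[gid] = [TSS(reg.chrom, pos, "+")]

    # fuse pairs of adjacent regulated proximal regions into two-promoter genes
    reg_idx = [i for i in range(n) if klasses[i] != "flat" and proximal[i]]
    pairs = [
        (a, b)
        for a, b in zip(reg_idx, reg_idx[1:])
        if regions[a].chrom == regions[b].chrom
        and regions[b].start - regions[a].end <= config.bipromoter_max_span
    ]
    order = rng.permutation(len(pairs))
    fused = 0
    used: set[int] = set()
    for j in order:
        if fused >= config.n_bipromoter_genes:
            break
        a, b = pairs[j]
        if a in used or b in used:
            continue
        used.update((a, b))
        ga, gb = gene_of_region[a], gene_of_region[b]
        genes[ga] = genes[ga] + genes.pop(gb)
        gene_of_region[b] = ga
        fused += 1

    for i, reg in enumerate(regions):
        k = str(klasses[i])
        if k == "up":
            d0, d1 = config.d_low, config.d_high
        elif k == "down":
            d0, d1 = config.d_high, config.d_low
        else:
            d0 = d1 = float(flat_d[i])
        models.append(
            TrajectoryModel(
                region=reg, gene_id=gene_of_region[i], klass=k,
                d_start=d0, d_inf=d1, tau=float(taus[i]),
                proximal=bool(proximal[i]),
            )
        )
    return GeneAnnotation(genes), models


def _expected_counts(models, age, a0, config) -> np.ndarray:
    """Expected enriched read count per region for one sample.

    The scale is solved so that the promoter-anchored total (background
    in promoters + TSS-proximal enrichment) matches one realized density
    unit, i.e. realized densities ~ planted densities in expectation.
    """
    d = np.array([trajectory_density(m, age, a0) for m in models])
    lengths = np.array([len(m.region) for m in models], dtype=float)
    prox = np.array([m.proximal for m in models])
    s_prom = float(np.sum(d[prox] * lengths[prox]))
    if s_prom >= 1e6:
        raise ValueError("planted promoter signal exceeds normalization budget")
    prom_bp = 4000.0 * len(models)  # one 4 kb promoter per region's TSS
    bg_prom = config.background_depth * min(prom_bp / config.genome_size, 1.0)
    scale = bg_prom / (1e6 - s_prom)
    return d * lengths * scale


def simulate_sample_reads(
    sample: SampleMeta,
    models: list[TrajectoryModel],
    config: CohortConfig,
    stream: int = 0,
) -> ReadSet:
    """Simulate one sample's mapped reads.

    Background reads are uniform over the toy genome with Poisson total;
    ChIP samples add per-region enriched reads (Poisson counts with the
    trajectory-determined expectation) placed uniformly within the region
    extended by half a fragment each side, so summits sit inside the
    region.  Input samples receive background only.
    """
    rng = _rng(config, _DOM_READS, stream)
    if config.background_depth == 0:
        warnings.warn(f"{sample.sample_id}: zero depth, empty read set")
        return ReadSet(starts={}, read_length=config.read_length,
                       sample_id=sample.sample_id)
    sizes = config.chrom_sizes
    chroms = list(sizes)
    L = config.read_length

    # input libraries are sequenced to full depth but contain background
    # only, so their background rate exceeds a ChIP sample's
    depth = config.background_depth
    if sample.fraction == "input":
        depth = int(round(depth * config.input_depth_factor))
    n_bg = rng.poisson(depth)
    probs = np.array([sizes[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    bg_chrom = rng.choice(len(chroms), size=n_bg, p=probs)
    starts: dict[str, list[np.ndarray]] = {c: [] for c in chroms}
    for ci, c in enumerate(chroms):
        k = int(np.sum(bg_chrom == ci))
        starts[c].append(rng.integers(0, sizes[c] - L, size=k))

    if sample.fraction == "chip":
        mu = _expected_counts(models, sample.age_years, config.a0, config)
        for m, mu_r in zip(models, mu):
            # reads are placed uniformly in the region extended by half a
            # fragment per side; inflate the draw so the expected number
            # of reads OVERLAPPING the region equals mu_r
            lo = max(0, m.region.start - config.fragment_half)
            hi = m.region.end + config.fragment_half - L
            span = hi - lo
            overlap = min(len(m.region) + L - 1, span)
            k = rng.poisson(mu_r * span / overlap)
            if k:
                starts[m.region.chrom].append(rng.integers(lo, hi, size=int(k)))

    arrs = {
        c: np.sort(np.concatenate(v).astype(np.int64))
        for c, v in starts.items() if v
    }
    return ReadSet(starts=arrs, read_length=L, sample_id=sample.sample_id)


def simulate_methylation(
    models: list[TrajectoryModel],
    config: CohortConfig,
    anti_rho: float = 0.8,
) -> "pandas.DataFrame":
    """CpG beta-value table anti-correlated with the histone trajectories.

    For a fraction ``anti_rho`` of up-class genes the promoter CpGs lose
    methylation with age (beta 0.7 -> 0.3 along the same saturating
    kinetics); down-class genes mirror this (0.3 -> 0.7); all remaining
    CpGs are age-flat.  Truncated Gaussian noise keeps beta in [0, 1].
    """
    import pandas as pd

    if not (0 <= anti_rho <= 1):
        raise ValueError("anti_rho must be in [0, 1]")
    rng = _rng(config, _DOM_METH)
    samples = config.chip_samples
    ages = config.ages
    a0 = config.a0
    rows = []
    betas = []
    cpg_i = 0
    for m in models:
        coupled = m.klass in ("up", "down") and rng.random() < anti_rho
        for _ in range(config.n_cpgs_per_gene):
            pos = int(rng.integers(m.region.start, m.region.end))
            if coupled:
                b0, b1 = (0.7, 0.3) if m.klass == "up" else (0.3, 0.7)
                beta = b1 + (b0 - b1) * np.exp(-(ages - a0) / m.tau)
            else:
                beta = np.full(ages.shape, rng.uniform(0.2, 0.8))
            beta = beta + rng.normal(0.0, config.meth_noise_sd, size=ages.shape)
            betas.append(np.clip(beta, 0.0, 1.0))
            rows.append((f"cpg{cpg_i:05d}", m.gene_id, m.region.chrom, pos))
            cpg_i += 1
    df = pd.DataFrame(rows, columns=["cpg_id", "gene_id", "chrom", "pos"])
    mat = pd.DataFrame(
        np.array(betas), columns=[s.sample_id for s in samples], index=df.index
    )
    return pd.concat([df, mat], axis=1)


def simulate_expression(
    models: list[TrajectoryModel],
    config: CohortConfig,
    corr_strength: float = 1.0,
) -> "pandas.DataFrame":
    """Gene x sample log2-expression table correlated with the trajectories.

    Expression is an affine image of the gene's region density plus
    Gaussian noise; flat genes therefore stay flat.  ``corr_strength``
    scales the coupling (0 decouples expression from the planted classes).
    """
    import pandas as pd

    rng = _rng(config, _DOM_EXPR)
    samples = config.chip_samples
    ages = config.ages
    a0 = config.a0
    seen: dict[str, np.ndarray] = {}
    for m in models:
        d = trajectory_density(m, ages, a0)
        base = rng.normal(6.0, 1.0)
        noise = rng.normal(0.0, config.expression_noise_sd, size=ages.shape)
        expr = base + corr_strength * config.expression_slope * (d - d.mean()) + noise
        if m.gene_id in seen:  # two-promoter gene: average the signals
            seen[m.gene_id] = 0.5 * (seen[m.gene_id] + expr)
        else:
            seen[m.gene_id] = expr
    genes = sorted(seen)
    return pd.DataFrame(
        np.array([seen[g] for g in genes]),
        index=pd.Index(genes, name="gene_id"),
        columns=[s.sample_id for s in samples],
    )


@dataclass
class Cohort:
    """A fully simulated cohort: reads, annotation, planted truth, tables."""

    config: CohortConfig
    samples: list[SampleMeta]
    annotation: GeneAnnotation
    models: list[TrajectoryModel]
    readsets: dict[str, ReadSet]
    methylation: "pandas.DataFrame | None" = None
    expression: "pandas.DataFrame | None" = None

    @property
    def regions(self) -> list[GenomicInterval]:
        return [m.region for m in self.models]

    @property
    def planted_classes(self) -> np.ndarray:
        return np.array([m.klass for m in self.models])

    def promoters(self, flank: int = 2000):
        return build_promoters(self.annotation, flank=flank)


def simulate_cohort(
    config: CohortConfig,
    with_methylation: bool = True,
    with_expression: bool = True,
    anti_rho: float = 0.8,
) -> Cohort:
    """Run the full generator: annotation, per-sample reads, omics tables."""
    annotation, models = simulate_annotation(config)
    readsets = {
        s.sample_id: simulate_sample_reads(s, models, config, stream=i)
        for i, s in enumerate(config.samples)
    }
    meth = simulate_methylation(models, config, anti_rho) if with_methylation else None
    expr = simulate_expression(models, config) if with_expression else None
    return Cohort(
        config=config, samples=list(config.samples), annotation=annotation,
        models=models, readsets=readsets, methylation=meth, expression=expr,
    )


def reduced_config(seed: int = 1, **overrides) -> CohortConfig:
    """The 12-sample, 300-region configuration for cohort-structure work.

    Pairwise differential calling needs the real-data geometry in which
    enriched regions occupy ~1% of the genome and the background rate is
    far below per-window enrichment, so this configuration spreads the
    regions over a sparser toy chromosome and sequences deeper than the
    default (classification-only) cohort.
    """
    base = dict(
        samples=list(REDUCED_12_SAMPLES), n_regions=300, n_chroms=1,
        region_pitch=400_000, background_depth=2_260_000,
        n_bipromoter_genes=0, seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)
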