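"""Recovery studies on the synthetic cohort: the package's self-checks.

Each function runs one complete experiment at the study conditions --
simulate a cohort with planted truth, run the analysis under test, and
score the result against the truth.  They are used by both the test
suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .integrate import cpg_age_test, direction_contingency
from .peaks import DifferentialConfig, PeakCallerConfig, _window_lambda, poisson_upper_tail
from .quantify import build_density_matrix
from .simulate import CohortConfig, reduced_config, simulate_annotation, simulate_cohort, simulate_methylation
from .structure import build_differential_matrix, group_separation_score, pca_scores
from .trajectory import (assign_age_groups, classify_up_down,
                         filter_and_normalize_for_clustering, kmeans_profiles)

__all__ = [
    "classification_recovery",
    "structure_separation_p",
    "clustering_capture",
    "null_window_fraction",
    "contingency_p_for_rho",
]

# pairwise differential calling on the synthetic libraries runs at the
# caller's own window threshold; the printed deep-library threshold is
# not transferable to this caller (see docs/methods.md)
STRUCTURE_CALLER = PeakCallerConfig(p_threshold=1e-4)
STRUCTURE_DIFF = DifferentialConfig(p_threshold=1e-4, min_ratio=2.0,
                                    min_density=0.005)


def _chip_density(cohort):
    cfg = cohort.config
    chip = {s.sample_id: cohort.readsets[s.sample_id] for s in cfg.chip_samples}
    return build_density_matrix(chip, cohort.regions, cohort.promoters())


def classification_recovery(seed: int) -> dict[str, float]:
    """Sensitivity and false-discovery proportion of the up/down caller
    against planted labels on the default cohort."""
    cohort = simulate_cohort(CohortConfig(seed=seed),
                             with_methylation=False, with_expression=False)
    dm = _chip_density(cohort)
    calls = classify_up_down(dm, cohort.config.ages)
    truth = cohort.planted_classes
    called = calls["klass"].isin(["up", "down"]).to_numpy()
    hits = (calls["klass"].to_numpy() == truth) & called
    return {
        "sensitivity": float(hits.sum() / (truth != "flat").sum()),
        "fdp": float((called & ~hits).sum() / max(called.sum(), 1)),
        "n_regions": int(len(truth)),
    }


def structure_separation_p(seed: int) -> float:
    """PC1 prenatal-vs-rest rank-test p on the reduced 12-sample cohort."""
    cfg = reduced_config(seed=seed)
    cohort = simulate_cohort(cfg, with_methylation=False, with_expression=False)
    chip = {s.sample_id: cohort.readsets[s.sample_id] for s in cfg.chip_samples}
    M = build_differential_matrix(
        chip, cohort.promoters().regions, STRUCTURE_CALLER, STRUCTURE_DIFF,
        genome=cfg.chrom_sizes,
    )
    pca = pca_scores(M)
    sep = group_separation_score(pca, assign_age_groups(cfg.ages))
    return float(sep["pc1_prenatal_vs_rest"])


def clustering_capture(seed: int) -> dict[str, float]:
    """Fraction of planted directional regions captured by up/down-trend
    k-means clusters (k = 5) on max-normalized profiles."""
    cohort = simulate_cohort(CohortConfig(seed=seed),
                             with_methylation=False, with_expression=False)
    dm = _chip_density(cohort)
    ages = cohort.config.ages
    norm, idx = filter_and_normalize_for_clustering(dm, ages)
    res = kmeans_profiles(norm, idx, ages, k=5, seed=seed)
    truth = cohort.planted_classes[idx]
    directional = np.isin(truth, ["up", "down"])
    trend_of_region = np.array([res.trends[c] for c in res.assignments])
    captured = directional & np.isin(trend_of_region, ["up", "down"])
    return {
        "capture": float(captured.sum() / directional.sum()),
        "has_up_cluster": float("up" in res.trends),
        "has_down_cluster": float("down" in res.trends),
        "n_directional": int(directional.sum()),
    }


def null_window_fraction(
    seeds, depth: int = 100_000, genome_size: int = 10_000_000,
    config: PeakCallerConfig = PeakCallerConfig(),
) -> float:
    """Fraction of windows called significant when treatment and control
    are independent draws from the same homogeneous background."""
    from .intervals import ReadSet
    from .peaks import _bin_counts

    n_sig = n_win = 0
    for seed in seeds:
        rng = np.random.default_rng(seed)
        t = ReadSet({"chr1": np.sort(rng.integers(0, genome_size, depth))})
        c = ReadSet({"chr1": np.sort(rng.integers(0, genome_size, depth))})
        nbins = genome_size // config.bw + 2
        tb = _bin_counts(t, "chr1", config.bw, nbins)
        cb = _bin_counts(c, "chr1", config.bw, nbins)
        w = tb[:-1] + tb[1:]
        lam = np.maximum(_window_lambda(cb, t.total / c.total, config), 1e-9)
        logp = poisson_upper_tail(w, lam)
        n_sig += int((logp <= np.log10(config.p_threshold)).sum())
        n_win += w.size
    return n_sig / n_win


def contingency_p_for_rho(seed: int, anti_rho: float) -> float:
    """Anti-correlation contingency p at a given planted methylation
    coupling, using the planted histone classes (no read simulation)."""
    cfg = CohortConfig(seed=seed)
    _, models = simulate_annotation(cfg)
    meth = simulate_methylation(models, cfg, anti_rho=anti_rho)
    res = cpg_age_test(meth, cfg.ages)
    gene_classes = {}
    for m in models:  # skip two-promoter genes carrying both classes
        if m.klass in ("up", "down"):
            if m.gene_id in gene_classes and gene_classes[m.gene_id] != m.klass:
                gene_classes[m.gene_id] = None
            else:
                gene_classes.setdefault(m.gene_id, m.klass)
    gene_classes = {g: k for g, k in gene_classes.items() if k}
    return float(
        direction_contingency(res, gene_classes)["p_hypergeometric"]
    )
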