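"""Peak-to-gene assignment, methylation age-tests and cross-omic statistics.

Connects trajectory-called peaks to genes through TSS proximity (2 kb by
default), classifies multi-promoter genes by the concordance of their
called promoters, tests each promoter CpG for a prenatal-vs-older
methylation shift (Welch t, Benjamini-Hochberg FDR) and cross-tabulates
the histone-trajectory direction against significant methylation loss --
the anti-correlation contingency, scored with a hypergeometric upper
tail.  A generic hypergeometric over-representation test with
-log10(FDR) enrichment scores stands in for web-based ontology tools.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneAnnotation
from .intervals import GenomicInterval
from .trajectory import assign_age_groups

logger = logging.getLogger(__name__)

__all__ = [
    "peaks_to_genes",
    "alternative_promoter_classes",
    "bh_fdr",
    "cpg_age_test",
    "hypergeometric_upper_tail",
    "direction_contingency",
    "overrepresentation",
    "enrichment_score_correlation",
]


def _tss_distance(peak: GenomicInterval, pos: int) -> int:
    """Base-pair gap between a TSS and the nearest covered base (0 if inside)."""
    if peak.start <= pos < peak.end:
        return 0
    if pos < peak.start:
        return peak.start - pos
    return pos - (peak.end - 1)


def peaks_to_genes(
    peaks: list[GenomicInterval],
    annotation: GeneAnnotation,
    window: int = 2000,
    klasses: list[str] | None = None,
) -> "pandas.DataFrame":
    """Link peaks to genes whose TSS lies within ``window`` bp (inclusive).

    A peak may map to several genes and vice versa; unlinked peaks are
    distal.  Returns a link table (gene_id, peak index/coords, distance,
    and the peak's trajectory class when ``klasses`` is given).
    """
    import pandas as pd

    if window <= 0:
        raise ValueError("window must be positive")
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gid, t in annotation.tss_items():
        tss_by_chrom.setdefault(t.chrom, []).append((t.position, gid))
    for v in tss_by_chrom.values():
        v.sort()
    rows = []
    for i, pk in enumerate(peaks):
        cands = tss_by_chrom.get(pk.chrom, [])
        positions = [p for p, _ in cands]
        import bisect

        lo = bisect.bisect_left(positions, pk.start - window)
        hi = bisect.bisect_right(positions, (pk.end - 1) + window)
        for pos, gid in cands[lo:hi]:
            d = _tss_distance(pk, pos)
            if d <= window:
                rows.append(
                    (gid, i, pk.chrom, pk.start, pk.end, d,
                     klasses[i] if klasses is not None else None)
                )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "peak_index", "chrom", "start", "end",
                 "distance", "klass"],
    )
    return df


def alternative_promoter_classes(
    assignment: "pandas.DataFrame",
    max_span: int = 100_000,
) -> dict[str, str]:
    """Classify genes with >= 2 called promoter peaks within ``max_span``.

    For every gene whose distinct up/down-called peaks form at least one
    pair no more than ``max_span`` apart: 'up+down' if any such pair is
    discordant, otherwise 'up+up' or 'down+down'.  Genes without a
    qualifying pair are omitted (single-class reporting only).
    """
    out: dict[str, str] = {}
    called = assignment[assignment["klass"].isin(["up", "down"])]
    for gid, grp in called.groupby("gene_id"):
        peaks = grp.drop_duplicates("peak_index")
        if len(peaks) < 2:
            continue
        recs = peaks[["start", "end", "klass"]].to_records(index=False)
        best = None
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                gap = max(recs[j].start - recs[i].end,
                          recs[i].start - recs[j].end, 0)
                if gap > max_span:
                    continue
                pair = {recs[i].klass, recs[j].klass}
                label = "up+down" if len(pair) == 2 else f"{recs[i].klass}+{recs[j].klass}"
                if label == "up+down":
                    best = label
                elif best is None:
                    best = label
        if best is not None:
            out[gid] = best
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def cpg_age_test(
    meth: "pandas.DataFrame",
    ages,
    fdr_cutoff: float = 0.05,
) -> "pandas.DataFrame":
    """Per-CpG Welch t-test of prenatal vs >1 yr beta values, with BH FDR.

    ``meth`` is the simulator's layout: cpg_id / gene_id / chrom / pos
    then one beta column per sample, in the order matching ``ages``.
    Constant CpGs (zero variance in both groups) are excluded from the
    FDR family.  Direction is the sign of (older - prenatal) mean at the
    given FDR cutoff; 'none' otherwise.
    """
    import pandas as pd

    meta_cols = ["cpg_id", "gene_id", "chrom", "pos"]
    beta = meth.drop(columns=[c for c in meta_cols if c in meth.columns])
    groups = assign_age_groups(ages)
    pren = groups == "prenatal"
    older = groups == "older"
    if pren.sum() < 2 or older.sum() < 2:
        raise ValueError("need >= 2 samples per tested group")
    A = beta.to_numpy(dtype=float)[:, pren]
    B = beta.to_numpy(dtype=float)[:, older]
    with np.errstate(invalid="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    delta = B.mean(axis=1) - A.mean(axis=1)
    tested = np.isfinite(p)
    if not np.all(tested):
        logger.info("excluding %d constant CpGs from the FDR family",
                    int((~tested).sum()))
    fdr = np.full(p.shape, np.nan)
    if np.any(tested):
        fdr[tested] = bh_fdr(p[tested])
    direction = np.where(
        tested & (fdr <= fdr_cutoff),
        np.where(delta < 0, "decrease", "increase"),
        "none",
    )
    out = pd.DataFrame(
        {
            "cpg_id": meth["cpg_id"].to_numpy() if "cpg_id" in meth else np.arange(len(p)),
            "gene_id": meth["gene_id"].to_numpy() if "gene_id" in meth else "",
            "t": t,
            "p_value": p,
            "fdr": fdr,
            "delta_older_minus_prenatal": delta,
            "direction": direction,
        }
    )
    return out


def hypergeometric_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent margins: k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    if k > min(n, K):
        return 0.0
    return float(np.exp(stats.hypergeom.logsf(k - 1, N, K, n)))


def direction_contingency(
    cpg_results: "pandas.DataFrame",
    gene_classes: dict[str, str],
) -> dict:
    """2x2 contingency of histone direction vs significant methylation loss.

    Rows: CpGs in promoters of genes with up- vs down-trajectory histone
    calls; columns: methylation significantly decreased with age or not.
    The upper-tail hypergeometric p asks whether methylation loss is
    over-represented in the up row -- the anti-correlation test.
    """
    klass = cpg_results["gene_id"].map(gene_classes)
    up_row = cpg_results[klass == "up"]
    down_row = cpg_results[klass == "down"]
    k_up = int((up_row["direction"] == "decrease").sum())
    k_down = int((down_row["direction"] == "decrease").sum())
    n_up, n_down = len(up_row), len(down_row)
    N = n_up + n_down
    K = k_up + k_down
    if n_up == 0 or n_down == 0:
        warnings.warn("empty contingency row: p undefined")
        p = float("nan")
    else:
        p = hypergeometric_upper_tail(k_up, n_up, K, N)
    return {
        "counts": {
            "up": {"decreased": k_up, "not_decreased": n_up - k_up},
            "down": {"decreased": k_down, "not_decreased": n_down - k_down},
        },
        "p_hypergeometric": p,
    }


def overrepresentation(
    gene_set,
    term_annotation: dict[str, set],
    universe,
) -> "pandas.DataFrame":
    """Hypergeometric over-representation of a gene set across terms.

    Per term: P(overlap >= k) drawing |gene_set| genes from the universe
    with the term's in-universe genes as successes; BH FDR across terms;
    score = -log10(FDR).  Terms disjoint from the universe are skipped.
    """
    import pandas as pd

    universe = set(universe)
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValueError("gene_set must be contained in the universe")
    rows = []
    for term in sorted(term_annotation):
        tg = set(term_annotation[term]) & universe
        if not tg:
            logger.info("term %s disjoint from universe: skipped", term)
            continue
        k = len(gene_set & tg)
        p = hypergeometric_upper_tail(k, len(gene_set), len(tg), len(universe))
        rows.append((term, k, len(tg), p))
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p_value"])
    if len(df):
        df["fdr"] = bh_fdr(df["p_value"].to_numpy())
        with np.errstate(divide="ignore"):
            df["score"] = -np.log10(df["fdr"])
    return df


def enrichment_score_correlation(
    results_a: "pandas.DataFrame",
    results_b: "pandas.DataFrame",
    inclusion_fdr: float = 0.85,
) -> tuple[float, int]:
    """Pearson R between two enrichment-score landscapes over shared terms.

    A term enters if its FDR is below ``inclusion_fdr`` in either result
    list; scores are -log10(FDR).  Returns (R, number of terms); R is
    NaN (with a warning) when fewer than three terms qualify.
    """
    import pandas as pd

    merged = pd.merge(
        results_a[["term", "fdr", "score"]],
        results_b[["term", "fdr", "score"]],
        on="term", suffixes=("_a", "_b"),
    )
    inc = merged[(merged["fdr_a"] < inclusion_fdr) | (merged["fdr_b"] < inclusion_fdr)]
    if len(inc) < 3:
        warnings.warn("fewer than 3 shared terms pass the inclusion FDR")
        return float("nan"), len(inc)
    r = float(np.corrcoef(inc["score_a"], inc["score_b"])[0, 1])
    return r, len(inc)
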