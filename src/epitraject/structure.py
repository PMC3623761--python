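"""Sample-structure analysis: pairwise differential-peak counts and PCA.

Every ordered sample pair (i, j) is scored by the number of peaks
enriched in i when called against j as control, giving an n x n
(generally asymmetric) count matrix whose rows serve as per-sample
feature vectors.  PCA of the column-centered rows places samples along
axes of epigenomic dissimilarity; in an age-structured cohort the first
component separates the prenatal samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import ReadSet
from .peaks import (DifferentialConfig, PeakCallerConfig, _bin_counts,
                    _chrom_nbins, _peaks_from_bins, filter_differential_peaks)
from .quantify import count_reads

__all__ = [
    "build_differential_matrix",
    "PcaResult",
    "pca_scores",
    "group_separation_score",
]


def build_differential_matrix(
    readsets: dict[str, ReadSet],
    promoter_regions,
    caller_config: PeakCallerConfig = PeakCallerConfig(),
    diff_config: DifferentialConfig = DifferentialConfig(),
    genome: dict[str, int] | None = None,
) -> "pandas.DataFrame":
    """n x n matrix of differential peak counts over all ordered pairs.

    Element (i, j) is the number of peaks enriched in sample i relative
    to sample j.  The diagonal is zero.  Deterministic given the inputs.
    """
    import pandas as pd

    ids = list(readsets)
    if len(ids) < 3:
        raise ValueError("need at least three samples")
    totals = {
        sid: float(count_reads(rs, promoter_regions).sum())
        for sid, rs in readsets.items()
    }
    for sid, t in totals.items():
        if t <= 0:
            raise ValueError(f"sample {sid} has no promoter reads")
    # bin every sample once; each ordered pair then only re-scores windows
    chroms = sorted({c for rs in readsets.values() for c in rs.chromosomes()})
    nbins = _chrom_nbins(chroms, *readsets.values(), bw=caller_config.bw,
                         genome=genome)
    bins = {
        sid: {c: _bin_counts(rs, c, caller_config.bw, nbins[c]) for c in chroms}
        for sid, rs in readsets.items()
    }
    from .peaks import _window_lambda

    lam_units = {
        sid: {c: _window_lambda(bins[sid][c], 1.0, caller_config) for c in chroms}
        for sid in ids
    }
    read_totals = {sid: rs.total for sid, rs in readsets.items()}
    n = len(ids)
    M = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i == j:
                continue
            scale = read_totals[a] / read_totals[b]
            count = 0
            for c in chroms:
                pks = _peaks_from_bins(
                    bins[a][c], bins[b][c], scale, c, caller_config, a,
                    lam_unit=lam_units[b][c],
                )
                count += len(
                    filter_differential_peaks(
                        pks, scale, totals[a], totals[b], diff_config
                    )
                )
            M[i, j] = count
    return pd.DataFrame(M, index=ids, columns=ids)


@dataclass
class PcaResult:
    sample_ids: list[str]
    scores: np.ndarray  # (n_samples, n_components)
    variance_fractions: np.ndarray

    def __post_init__(self):
        vf = np.asarray(self.variance_fractions)
        if np.any(vf < -1e-12) or abs(vf.sum() - 1.0) > 1e-9:
            raise ValueError("variance fractions must be in [0,1] and sum to 1")


def pca_scores(matrix) -> PcaResult:
    """PCA of the differential-count matrix, rows as per-sample features.

    Columns are mean-centered (no variance scaling: the counts share a
    scale, and scaling would inflate near-empty columns); components come
    from the eigendecomposition of the column covariance, ordered by
    descending eigenvalue.  Each component's sign is fixed by making the
    first sample's loading non-negative, so scores are reproducible.
    """
    import pandas as pd

    if isinstance(matrix, pd.DataFrame):
        ids = list(matrix.index)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        ids = [f"s{i}" for i in range(X.shape[0])]
    if not np.all(np.isfinite(X)):
        raise ValueError("differential matrix has missing entries; PCA refused")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ValueError("no structure: centered matrix is identically zero")
    C = Xc.T @ Xc / max(X.shape[0] - 1, 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):
        col = evecs[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            evecs[:, k] = -col
    scores = Xc @ evecs
    return PcaResult(
        sample_ids=ids,
        scores=scores,
        variance_fractions=evals / evals.sum(),
    )


def group_separation_score(pca: PcaResult, groups) -> dict[str, float]:
    """Rank-based separation p-values of the canonical age contrasts.

    Tests PC1 for prenatal vs all other samples and PC2 for
    prenatal+infant vs older, with a two-sided Mann-Whitney rank test
    (two-sided because the PCA sign convention is arbitrary with respect
    to age).  Returns NaN where a group is empty.
    """
    groups = np.asarray(groups)

    def _p(scores, mask):
        a, b = scores[mask], scores[~mask]
        if a.size == 0 or b.size == 0:
            return float("nan")
        if np.all(scores == scores[0]):
            return 1.0
        return float(
            stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        )

    pren = groups == "prenatal"
    young = pren | (groups == "infant")
    return {
        "pc1_prenatal_vs_rest": _p(pca.scores[:, 0], pren),
        "pc2_young_vs_rest": _p(pca.scores[:, 1], young)
        if pca.scores.shape[1] > 1 else float("nan"),
    }
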