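"""Read counting, promoter-anchored normalization, density and correlation matrices.

Densities are expressed as reads per bp per million promoter-anchored
reads: a region's raw count divided by (region length x promoter-read
total / 1e6).  Anchoring the library size on promoter-overlapping reads
(rather than all mapped reads) makes samples comparable when the genome-
wide background varies, and puts the analysis thresholds (density floor
0.01, differential floor 0.005) on a common scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .annotation import PromoterSet
from .intervals import GenomicInterval, ReadSet

__all__ = [
    "count_reads",
    "promoter_normalized_density",
    "DensityMatrix",
    "build_density_matrix",
    "pairwise_pearson",
]


def _check_disjoint_sorted(regions: list[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Group regions per chromosome; reject overlapping sets."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end, i))
    out = {}
    for chrom, triples in by_chrom.items():
        triples.sort()
        starts = np.array([t[0] for t in triples], dtype=np.int64)
        ends = np.array([t[1] for t in triples], dtype=np.int64)
        idx = np.array([t[2] for t in triples], dtype=np.int64)
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(
                f"regions overlap on {chrom}; merge them first (merge_intervals)"
            )
        out[chrom] = (starts, ends, idx)
    return out


def count_reads(reads: ReadSet, regions: list[GenomicInterval]) -> np.ndarray:
    """Count reads overlapping each of a disjoint region set.

    A read contributes to a region iff it overlaps at least one base of
    it; a read spanning a gap between two regions is assigned to the
    leftmost region it overlaps, so every read is counted at most once.
    """
    layout = _check_disjoint_sorted(regions)
    counts = np.zeros(len(regions), dtype=np.int64)
    L = reads.read_length
    for chrom, (starts, ends, idx) in layout.items():
        s = reads.starts.get(chrom)
        if s is None or s.size == 0:
            continue
        j = np.searchsorted(starts, s, side="right") - 1
        jc = np.clip(j, 0, None)
        in_j = (j >= 0) & (s < ends[jc])
        nxt = j + 1
        has_next = nxt < starts.size
        in_next = (~in_j) & has_next & (starts[np.clip(nxt, None, starts.size - 1)] < s + L)
        assign = np.where(in_j, jc, np.where(in_next, np.clip(nxt, None, starts.size - 1), -1))
        hit = assign >= 0
        if np.any(hit):
            local = np.bincount(assign[hit], minlength=starts.size)
            counts[idx] += local
    return counts


def promoter_normalized_density(count, region_length, promoter_total) -> np.ndarray | float:
    """reads / bp / million promoter-anchored reads (vectorized)."""
    pt = np.asarray(promoter_total, dtype=float)
    if np.any(pt <= 0):
        raise ValueError("promoter_total must be positive (sample unusable)")
    rl = np.asarray(region_length, dtype=float)
    if np.any(rl <= 0):
        raise ValueError("region_length must be positive")
    out = np.asarray(count, dtype=float) / (rl * pt / 1e6)
    return float(out) if out.ndim == 0 else out


@dataclass
class DensityMatrix:
    """Regions x samples promoter-normalized densities."""

    regions: list[GenomicInterval]
    sample_ids: list[str]
    values: np.ndarray  # (n_regions, n_samples), float
    promoter_totals: np.ndarray  # per sample
    counts: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regions), len(self.sample_ids)):
            raise ValueError("density matrix dimensions inconsistent")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("densities must be finite and non-negative")
        if np.any(np.asarray(self.promoter_totals) <= 0):
            raise ValueError("promoter totals must be positive")

    @property
    def region_lengths(self) -> np.ndarray:
        return np.array([len(r) for r in self.regions], dtype=float)

    def subset_samples(self, mask) -> np.ndarray:
        return self.values[:, np.asarray(mask)]

    def to_frame(self):
        import pandas as pd

        index = [f"{r.chrom}:{r.start}-{r.end}" for r in self.regions]
        return pd.DataFrame(self.values, index=index, columns=self.sample_ids)


def build_density_matrix(
    readsets: dict[str, ReadSet],
    regions: list[GenomicInterval],
    promoters: PromoterSet,
) -> DensityMatrix:
    """Count every sample over ``regions`` and normalize per sample.

    The per-sample denominator is the number of reads overlapping any
    merged promoter region.  Samples with zero promoter reads are
    excluded with a warning rather than producing infinite densities.
    """
    sample_ids, cols, totals = [], [], []
    lengths = np.array([len(r) for r in regions], dtype=float)
    for sid, rs in readsets.items():
        pt = int(count_reads(rs, promoters.regions).sum())
        if pt == 0:
            warnings.warn(f"sample {sid} has no promoter reads; excluded")
            continue
        cnt = count_reads(rs, regions)
        sample_ids.append(sid)
        cols.append(cnt)
        totals.append(pt)
    counts = np.column_stack(cols) if cols else np.zeros((len(regions), 0), dtype=np.int64)
    totals_arr = np.array(totals, dtype=float)
    values = counts / (lengths[:, None] * totals_arr[None, :] / 1e6) if cols else counts.astype(float)
    return DensityMatrix(
        regions=list(regions), sample_ids=sample_ids, values=values,
        promoter_totals=totals_arr, counts=counts,
    )


def pairwise_pearson(matrix: DensityMatrix) -> np.ndarray:
    """Pearson correlation over the region dimension for all sample pairs.

    Zero-variance samples get NaN rows/columns (reported via warning).
    The result is exactly symmetric with unit diagonal.
    """
    X = matrix.values
    if X.shape[0] < 2:
        raise ValueError("need at least two regions for correlations")
    sd = X.std(axis=0)
    bad = sd == 0
    if np.any(bad):
        warnings.warn(
            "zero-variance samples in correlation: "
            + ", ".join(np.array(matrix.sample_ids)[bad])
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.asarray(R, dtype=float)
    R[bad, :] = np.nan
    R[:, bad] = np.nan
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    R[~np.isnan(R)] = np.clip(R[~np.isnan(R)], -1.0, 1.0)
    return R
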