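"""Simplified local-Poisson enrichment caller and peak-set operations.

The caller slides a fixed window (width 2*bw, step bw) over each
chromosome and scores the treatment read count in the window against a
Poisson expectation taken as the maximum of depth-scaled control rates
estimated at several scales (1 kb, 5 kb, 10 kb and genome-wide) -- the
"local lambda" idea of MACS-style callers, without model shifting or
duplicate filtering.  Significant windows (upper-tail Poisson p below
threshold) that overlap or abut are merged into peaks.

Reads are reduced to their midpoints and binned at bw resolution, which
keeps the whole genome scan vectorized; a window's count is the sum of
its two member bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, ReadSet, merge_intervals

__all__ = [
    "PeakCallerConfig",
    "Peak",
    "ConsensusPeakSet",
    "DifferentialConfig",
    "poisson_upper_tail",
    "call_peaks",
    "differential_peak_count",
    "pool_merge_peaks",
    "peak_length_distribution",
]

_LOG10 = np.log(10.0)


@dataclass(frozen=True)
class PeakCallerConfig:
    bw: int = 230
    tsize: int = 36
    p_threshold: float = 1e-5
    lambda_windows: tuple[int, ...] = (1000, 5000, 10_000)

    def __post_init__(self):
        if self.bw <= 0 or self.tsize <= 0:
            raise ValueError("bw and tsize must be positive")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")

    @property
    def window(self) -> int:
        return 2 * self.bw


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    count: int
    lam: float
    log10_p: float
    ratio: float
    sample_id: str = ""

    def __post_init__(self):
        if self.count < 0 or self.lam <= 0:
            raise ValueError("peak requires count >= 0 and lambda > 0")
        if self.log10_p > 1e-9:
            raise ValueError("log10 p must be <= 0")

    def __len__(self):
        return len(self.interval)


@dataclass
class ConsensusPeakSet:
    """Disjoint merged peak regions with per-region sample provenance."""

    regions: list[GenomicInterval]
    provenance: list[list[str]]

    def __len__(self):
        return len(self.regions)


def poisson_upper_tail(k, lam):
    """log10 P(X >= k) for X ~ Poisson(lam), stable in log space.

    ``P(X >= 0) = 1`` so k = 0 returns exactly 0.  Vectorized.
    """
    k_arr = np.asarray(k)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ValueError("lambda must be positive")
    if np.any(k_arr < 0):
        raise ValueError("count must be non-negative")
    out = stats.poisson.logsf(k_arr - 1, lam_arr) / _LOG10
    out = np.where(k_arr == 0, 0.0, out)
    return float(out) if np.isscalar(k) and np.isscalar(lam) else out


# ---------------------------------------------------------------------------
# binned representation
# ---------------------------------------------------------------------------


def _bin_counts(rs: ReadSet, chrom: str, bw: int, nbins: int) -> np.ndarray:
    s = rs.starts.get(chrom)
    if s is None or s.size == 0:
        return np.zeros(nbins, dtype=np.int64)
    mid = s + rs.read_length // 2
    b = mid // bw
    b = b[b < nbins]
    return np.bincount(b, minlength=nbins)


def _sliding_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average of a 1-D array with window w bins."""
    if w <= 1:
        return x.astype(float)
    c = np.concatenate(([0.0], np.cumsum(x, dtype=float)))
    n = x.size
    half = w // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + (w - half), 0, n)
    return (c[hi] - c[lo]) / np.maximum(hi - lo, 1)


def _window_lambda(cbins: np.ndarray, scale: float, config: PeakCallerConfig) -> np.ndarray:
    """Max-of-local-lambdas expectation per window (2 bins), depth-scaled."""
    nwin = cbins.size - 1
    genome_rate = cbins.sum() / max(cbins.size, 1)
    lam_bins = np.full(nwin, genome_rate, dtype=float)
    for W in config.lambda_windows:
        w = max(1, int(round(W / config.bw)))
        m = _sliding_mean(cbins, w)
        lam_bins = np.maximum(lam_bins, 0.5 * (m[:-1] + m[1:]))
    return 2.0 * lam_bins * scale


def _peaks_from_bins(
    tbins: np.ndarray,
    cbins: np.ndarray,
    scale: float,
    chrom: str,
    config: PeakCallerConfig,
    sample_id: str,
    lam_unit: np.ndarray | None = None,
) -> list[Peak]:
    bw = config.bw
    if tbins.size < 2:
        return []
    wcounts = tbins[:-1] + tbins[1:]
    if lam_unit is None:
        lam = _window_lambda(cbins, scale, config)
    else:
        lam = lam_unit * scale  # precomputed unit-scale control lambda
    lam = np.maximum(lam, 1e-9)
    log_thr = np.log10(config.p_threshold)
    cand = wcounts > lam  # cheap pre-filter before exact tails
    logp = np.zeros(wcounts.size)
    if np.any(cand):
        logp[cand] = poisson_upper_tail(wcounts[cand], lam[cand])
    sig = np.flatnonzero(logp <= log_thr)
    if sig.size == 0:
        return []
    peaks = []
    run_start = sig[0]
    prev = sig[0]
    runs = []
    for i in sig[1:]:
        if i - prev <= 2:  # windows i, i+1 overlap; i, i+2 abut
            prev = i
        else:
            runs.append((run_start, prev))
            run_start = prev = i
    runs.append((run_start, prev))
    csum = np.concatenate(([0], np.cumsum(tbins)))
    ccsum = np.concatenate(([0], np.cumsum(cbins)))
    for i0, i1 in runs:
        b0, b1 = i0, i1 + 2  # member bins [b0, b1)
        count = int(csum[b1] - csum[b0])
        lam_peak = float((ccsum[b1] - ccsum[b0]) * scale)
        if lam_peak <= 0:  # empty control stretch: fall back to local window rate
            lam_peak = float(max(lam[i0:i1 + 1].max() * (b1 - b0) / 2.0, 1e-9))
        member = logp[i0:i1 + 1]
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, int(b0 * bw), int(b1 * bw)),
                count=count,
                lam=lam_peak,
                log10_p=float(member.min()),
                ratio=float(count / lam_peak),
                sample_id=sample_id,
            )
        )
    return peaks


def _chrom_nbins(chroms, *readsets, bw: int, genome: dict[str, int] | None) -> dict[str, int]:
    out = {}
    for chrom in chroms:
        if genome and chrom in genome:
            out[chrom] = genome[chrom] // bw + 2
        else:
            hi = 0
            for rs in readsets:
                s = rs.starts.get(chrom)
                if s is not None and s.size:
                    hi = max(hi, int(s[-1]) + rs.read_length)
            out[chrom] = hi // bw + 2
    return out


def call_peaks(
    treatment: ReadSet,
    control: ReadSet,
    config: PeakCallerConfig = PeakCallerConfig(),
    genome: dict[str, int] | None = None,
) -> list[Peak]:
    """Call enriched peaks of ``treatment`` against ``control``.

    The control may be an input sample or another ChIP sample (the
    latter yields differential peaks).  Control rates are scaled by the
    ratio of total mapped reads.  A chromosome with treatment reads but
    no control reads falls back to the control's genome-wide rate.
    """
    if treatment.total == 0:
        warnings.warn("empty treatment read set: no peaks")
        return []
    if control.total == 0:
        raise ValueError("control read set is empty")
    scale = treatment.total / control.total
    nbins = _chrom_nbins(
        treatment.chromosomes(), treatment, control, bw=config.bw, genome=genome
    )
    genome_rate = control.total / max(sum(nbins.values()), 1)
    peaks: list[Peak] = []
    for chrom in treatment.chromosomes():
        tb = _bin_counts(treatment, chrom, config.bw, nbins[chrom])
        cb = _bin_counts(control, chrom, config.bw, nbins[chrom])
        if cb.sum() == 0:
            warnings.warn(
                f"{chrom}: no control reads; using genome-wide control rate"
            )
            cb = np.full(nbins[chrom], genome_rate)
        peaks.extend(
            _peaks_from_bins(tb, cb, scale, chrom, config, treatment.sample_id)
        )
    return peaks


@dataclass(frozen=True)
class DifferentialConfig:
    """Filters applied to sample-vs-sample peaks before counting them.

    The printed thresholds of the original deep-library analysis are
    p < 1e-20, ratio > 4, density > 0.005; the p threshold is tied to the
    original caller and library depth, so it is exposed here rather than
    hard-wired.
    """

    p_threshold: float = 1e-20
    min_ratio: float = 4.0
    min_density: float = 0.005


def filter_differential_peaks(
    peaks: list[Peak],
    scale: float,
    promoter_total_a: float,
    promoter_total_b: float,
    diff_config: DifferentialConfig = DifferentialConfig(),
) -> list[Peak]:
    """Apply the differential filters to peaks of a called against b.

    A peak survives iff its p-value is below the differential threshold,
    the a-over-b promoter-normalized density ratio exceeds ``min_ratio``
    (zero density in b counts as an infinite ratio) and the a-density
    exceeds ``min_density``.  The control read count is recovered from
    the peak's lambda (``lam / scale``).
    """
    log_thr = np.log10(diff_config.p_threshold)
    kept = []
    for pk in peaks:
        if pk.log10_p > log_thr:
            continue
        length = len(pk.interval)
        dens_a = pk.count / (length * promoter_total_a / 1e6)
        count_b = pk.lam / scale
        dens_b = count_b / (length * promoter_total_b / 1e6)
        ratio = np.inf if dens_b == 0 else dens_a / dens_b
        if ratio > diff_config.min_ratio and dens_a > diff_config.min_density:
            kept.append(pk)
    return kept


def differential_peak_count(
    sample_a: ReadSet,
    sample_b: ReadSet,
    promoter_total_a: float,
    promoter_total_b: float,
    caller_config: PeakCallerConfig = PeakCallerConfig(),
    diff_config: DifferentialConfig = DifferentialConfig(),
    genome: dict[str, int] | None = None,
) -> int:
    """Number of peaks enriched in a over b passing the differential filters.

    Peaks come from calling a (treatment) against b (control), then
    :func:`filter_differential_peaks` is applied.
    """
    peaks = call_peaks(sample_a, sample_b, caller_config, genome=genome)
    if not peaks:
        return 0
    scale = sample_a.total / sample_b.total
    return len(
        filter_differential_peaks(
            peaks, scale, promoter_total_a, promoter_total_b, diff_config
        )
    )


def pool_merge_peaks(per_sample_peaks: list[list[Peak]]) -> ConsensusPeakSet:
    """Merge all samples' peaks into a disjoint consensus set with provenance."""
    if not per_sample_peaks:
        raise ValueError("need at least one sample's peaks")
    all_peaks = [p for plist in per_sample_peaks for p in plist]
    merged = merge_intervals([p.interval for p in all_peaks])
    prov: list[set[str]] = [set() for _ in merged]
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(merged):
        by_chrom.setdefault(r.chrom, []).append(i)
    import bisect

    starts = {c: [merged[i].start for i in idx] for c, idx in by_chrom.items()}
    for p in all_peaks:
        idxs = by_chrom[p.interval.chrom]
        j = bisect.bisect_right(starts[p.interval.chrom], p.interval.start) - 1
        prov[idxs[j]].add(p.sample_id)
    return ConsensusPeakSet(regions=merged, provenance=[sorted(s) for s in prov])


def peak_length_distribution(
    peaks: list[Peak] | list[GenomicInterval],
    breakpoints: tuple[int, ...] = (500, 1000, 2000, 3000, 4000, 5000),
):
    """Counts and proportions of peaks longer than each breakpoint."""
    if list(breakpoints) != sorted(set(breakpoints)):
        raise ValueError("breakpoints must be strictly increasing")
    lengths = np.array(
        [len(p) for p in peaks], dtype=float
    )
    total = lengths.size
    counts = {bp: int(np.sum(lengths > bp)) for bp in breakpoints}
    props = {
        bp: (counts[bp] / total if total else float("nan")) for bp in breakpoints
    }
    return counts, props
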