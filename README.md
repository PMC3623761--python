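# epitraject

Developmental trajectory analysis of histone-mark ChIP-seq landscapes
across an age-structured cohort.

## The problem

Post-mitotic neurons remodel their chromatin for decades. Profiling a
promoter-associated mark such as H3K4me3 in sorted neuronal nuclei from
donors spanning late gestation to old age turns that remodeling into a
statistical question: which genomic regions gain or lose the mark with
age, how fast, and how does that relate to promoter DNA methylation and
gene expression?  `epitraject` implements the full analysis chain for
such cohorts:

1. **Quantification** — reads per region, normalized per sample by the
   total number of reads mapping within 2 kb of any TSS
   ("promoter-anchored" normalization): `d = c / (L · N_prom / 10^6)`,
   reads per bp per million promoter reads.
2. **Peak calling** — a documented local-Poisson caller: sliding windows
   (width `2·bw`, step `bw`, default `bw = 230`, reads 36 bp), each
   window's count tested against `λ_local = max(λ_1kb, λ_5kb, λ_10kb,
   λ_genome)` estimated from a depth-scaled control.
3. **Trajectory calling** — a region is *down* if its prenatal mean
   density ≥ 0.01, prenatal/older fold ≥ 2, Welch t-test p ≤ 0.05
   (3 prenatal vs. the samples older than 1 year; infants held out) and
   length ≥ 1 kb; *up* by the reciprocal criteria.
4. **Cohort structure** — element (i, j) of an n×n matrix counts peaks
   enriched in sample i called against sample j (p, density-ratio and
   density filters); PCA of the row vectors places samples along axes of
   epigenomic dissimilarity.
5. **Clustering** — k-means (k = 5) over max-normalized per-region age
   profiles, with Spearman-vs-age trend labels per cluster.
6. **Integration** — peak-to-gene links through TSS proximity,
   alternative-promoter concordance classes, per-CpG prenatal-vs-older
   methylation tests with Benjamini–Hochberg FDR, and the
   histone-direction × methylation-loss contingency scored by a
   hypergeometric upper tail.

Because cohorts of post-mortem sorted nuclei cannot be redistributed, the
package bundles a **synthetic-cohort generator**: 31 ChIP samples plus an
input control at the real design's ages (gestational weeks encoded as
negative years, term = 40 gw), a toy multi-chromosome genome, background
plus peak-shaped enrichment, and per-region monotone-saturating kinetics

    d(age) = d_inf + (d_start − d_inf) · exp(−(age − a0)/τ)

with planted up/down/flat classes, anti-correlated CpG methylation and
correlated expression.  Every stage is validated against this planted
truth.

## Worked example

```python
from epitraject.pipeline import PipelineConfig, run_pipeline

info = run_pipeline(PipelineConfig(outdir="demo", seed=1))
```

or equivalently `epitraject run --outdir demo --seed 1`.  This simulates
a compact 12-sample demonstration cohort (60 regions, 3 planted up and
6 planted down), writes every intermediate as TSV/BED/JSON under
`demo/`, and returns the stage summaries.  With seed 1 it prints:

```
trajectories: n_up=3  n_down=5  cluster_trends=[flat, down, up, down, up]
structure:    variance_fractions=[0.935, 0.032, ...]  pc1_prenatal_vs_rest=0.0091
integrate:    n_gene_links=42  contingency_p=0.0020
```

All three planted up regions and five of six down regions are recovered
(`demo/trajectory_calls.tsv`):

```
chrom   start     end klass  prenatal_mean  older_mean  fold  p_value
chr1  3388360 3389740  down          0.364       0.135  0.37  0.00033
chr2  4219350 4220960  up            0.143       0.415  2.91  0.0000093
...
```

The first principal component of the differential-peak matrix separates
the three prenatal samples from the rest at the smallest rank-test p
achievable for 3 vs 9 (0.0091), and CpGs at up-called genes are enriched
for age-related methylation loss (hypergeometric p = 0.0020) — the
anti-correlation between histone-mark gain and DNA methylation.

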