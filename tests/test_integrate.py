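import itertools

import numpy as np
import pandas as pd
import pytest

from epitraject.annotation import GeneAnnotation, TSS
from epitraject.integrate import (alternative_promoter_classes, bh_fdr,
                                  cpg_age_test, direction_contingency,
                                  enrichment_score_correlation,
                                  hypergeometric_upper_tail,
                                  overrepresentation, peaks_to_genes)
from epitraject.intervals import GenomicInterval


def _ann(*items):
    genes = {}
    for gid, chrom, pos in items:
        genes.setdefault(gid, []).append(TSS(chrom, pos, "+"))
    return GeneAnnotation(genes)


class TestPeaksToGenes:
    def test_within_window_linked(self):
        peaks = [GenomicInterval("chr1", 10_000, 12_000)]
        links = peaks_to_genes(peaks, _ann(("g1", "chr1", 13_500)))
        assert links["gene_id"].tolist() == ["g1"]
        assert links["distance"][0] == 1501  # gap from last covered base

    def test_beyond_window_not_linked(self):
        peaks = [GenomicInterval("chr1", 10_000, 12_000)]
        links = peaks_to_genes(peaks, _ann(("g1", "chr1", 14_500)))
        assert links.empty

    def test_tss_inside_peak_distance_zero(self):
        peaks = [GenomicInterval("chr1", 10_000, 12_000)]
        links = peaks_to_genes(peaks, _ann(("g1", "chr1", 11_000)))
        assert links["distance"][0] == 0

    def test_matches_all_pairs_oracle(self, rng):
        peaks = [GenomicInterval("chr1", int(s), int(s + l))
                 for s, l in zip(rng.integers(0, 200_000, 40),
                                 rng.integers(300, 4000, 40))]
        tss = [("g%d" % i, "chr1", int(p))
               for i, p in enumerate(rng.integers(0, 210_000, 60))]
        links = peaks_to_genes(peaks, _ann(*tss), window=2000)
        got = set(zip(links["gene_id"], links["peak_index"]))
        oracle = set()
        for gid, _, pos in tss:
            for i, pk in enumerate(peaks):
                if pk.start <= pos < pk.end:
                    d = 0
                elif pos < pk.start:
                    d = pk.start - pos
                else:
                    d = pos - (pk.end - 1)
                if d <= 2000:
                    oracle.add((gid, i))
        assert got == oracle

    def test_rebuild_from_emitted_table_reproduces_links(self, rng):
        peaks = [GenomicInterval("chr1", int(s), int(s) + 1000)
                 for s in rng.integers(0, 100_000, 15)]
        ann = _ann(*[("g%d" % i, "chr1", int(p))
                     for i, p in enumerate(rng.integers(0, 110_000, 20))])
        links = peaks_to_genes(peaks, ann)
        rebuilt_peaks = [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in links.drop_duplicates("peak_index").itertuples()
        ]
        links2 = peaks_to_genes(rebuilt_peaks, ann)
        assert set(zip(links["gene_id"], links["start"])) == set(
            zip(links2["gene_id"], links2["start"])
        )


class TestAlternativePromoters:
    def _assignment(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "peak_index", "chrom", "start", "end",
                           "distance", "klass"]
        )

    def test_discordant_pair_within_span(self):
        a = self._assignment([
            ("g", 0, "chr1", 10_000, 12_000, 0, "up"),
            ("g", 1, "chr1", 60_000, 62_000, 0, "down"),
        ])
        assert alternative_promoter_classes(a) == {"g": "up+down"}

    def test_pair_beyond_span_excluded(self):
        a = self._assignment([
            ("g", 0, "chr1", 10_000, 12_000, 0, "up"),
            ("g", 1, "chr1", 170_000, 172_000, 0, "down"),
        ])
        assert alternative_promoter_classes(a) == {}

    def test_concordant_pairs(self):
        a = self._assignment([
            ("g", 0, "chr1", 10_000, 12_000, 0, "down"),
            ("g", 1, "chr1", 40_000, 42_000, 0, "down"),
        ])
        assert alternative_promoter_classes(a) == {"g": "down+down"}

    def test_planted_bipromoter_design_recovered(self, default_cohort):
        """Using the planted classes as calls, each fused two-promoter
        gene is classified exactly as its planted pair dictates."""
        models = default_cohort.models
        by_gene = {}
        for m in models:
            by_gene.setdefault(m.gene_id, []).append(m)
        fused = {g: ms for g, ms in by_gene.items() if len(ms) == 2}
        regulated_fused = {
            g: ms for g, ms in fused.items()
            if all(m.klass in ("up", "down") for m in ms)
        }
        assert regulated_fused  # the generator planted some
        peaks = [m.region for m in models]
        klasses = [m.klass for m in models]
        links = peaks_to_genes(peaks, default_cohort.annotation,
                               klasses=klasses)
        got = alternative_promoter_classes(links)
        for g, ms in regulated_fused.items():
            ks = sorted(m.klass for m in ms)
            expected = "up+down" if ks == ["down", "up"] else f"{ks[0]}+{ks[1]}"
            assert got.get(g) == expected


class TestBhFdr:
    def test_worked_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_hand_step_up_oracle(self, rng):
        """Random p-vectors of length <= 10 against a from-scratch
        step-up implementation."""
        for _ in range(50):
            m = int(rng.integers(1, 11))
            p = rng.random(m)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            assert np.allclose(bh_fdr(p), adj)

    def test_never_fewer_discoveries_than_bonferroni(self, rng):
        for _ in range(20):
            p = rng.random(25)
            q = 0.1
            assert (bh_fdr(p) <= q).sum() >= (p <= q / 25).sum()


class TestHypergeometricUpperTail:
    def test_zero_successes_certain(self):
        assert hypergeometric_upper_tail(0, 5, 3, 10) == 1.0

    def test_small_case_by_enumeration(self):
        # drawing 2 of 4 items with 2 marked: P(both marked) = 1/6
        assert hypergeometric_upper_tail(2, 2, 2, 4) == pytest.approx(1 / 6)

    def test_exhaustive_enumeration_all_small_populations(self):
        """Exact equality with brute-force enumeration of all draws for
        every consistent configuration with N <= 12."""
        from math import comb

        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    total = comb(N, n)
                    for k in range(n + 1):
                        oracle = sum(
                            comb(K, j) * comb(N - K, n - j)
                            for j in range(k, min(n, K) + 1)
                        ) / total
                        got = hypergeometric_upper_tail(k, n, K, N)
                        assert got == pytest.approx(oracle, abs=1e-12)

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_upper_tail(3, 2, 2, 10)
        with pytest.raises(ValueError):
            hypergeometric_upper_tail(1, 5, 11, 10)


class TestCpgAgeTest:
    def _meth(self, betas, genes=None):
        betas = np.asarray(betas, dtype=float)
        n_cpg, n_s = betas.shape
        df = pd.DataFrame({
            "cpg_id": [f"c{i}" for i in range(n_cpg)],
            "gene_id": genes or [f"g{i}" for i in range(n_cpg)],
            "chrom": "chr1",
            "pos": np.arange(n_cpg),
        })
        return pd.concat(
            [df, pd.DataFrame(betas, columns=[f"s{j}" for j in range(n_s)])],
            axis=1,
        )

    def _ages(self):
        return np.array([-0.1, -0.05, -0.02, 2, 3, 4, 5, 6])

    def test_planted_decrease_detected(self):
        betas = [[0.8, 0.81, 0.79, 0.2, 0.21, 0.19, 0.2, 0.2],
                 [0.5, 0.5, 0.51, 0.5, 0.49, 0.5, 0.51, 0.5]]
        res = cpg_age_test(self._meth(betas), self._ages())
        assert res["direction"][0] == "decrease"
        assert res["direction"][1] == "none"

    def test_constant_cpg_excluded_from_family(self):
        betas = [[0.5] * 8, [0.8, 0.81, 0.79, 0.2, 0.21, 0.19, 0.2, 0.2]]
        res = cpg_age_test(self._meth(betas), self._ages())
        assert np.isnan(res["fdr"][0])
        assert res["direction"][0] == "none"

    def test_uniform_p_under_null(self, default_cohort):
        """With anti_rho = 0 the significant fraction stays near the
        nominal level."""
        from epitraject.simulate import simulate_methylation

        cfg = default_cohort.config
        meth = simulate_methylation(default_cohort.models, cfg, anti_rho=0.0)
        res = cpg_age_test(meth, cfg.ages)
        assert (res["direction"] != "none").mean() < 0.05


class TestDirectionContingency:
    def _results(self, genes, directions):
        return pd.DataFrame({
            "cpg_id": [f"c{i}" for i in range(len(genes))],
            "gene_id": genes,
            "direction": directions,
        })

    def test_saturated_rows_give_p_one(self):
        res = self._results(["u1", "u2", "d1", "d2"], ["decrease"] * 4)
        out = direction_contingency(res, {"u1": "up", "u2": "up",
                                          "d1": "down", "d2": "down"})
        assert out["p_hypergeometric"] == 1.0

    def test_counts_delegate_to_hypergeometric(self):
        # the reconstructed published margins: 62/394 vs 46/744
        genes = ["u"] * 394 + ["d"] * 744
        dirs = (["decrease"] * 62 + ["none"] * 332
                + ["decrease"] * 46 + ["none"] * 698)
        out = direction_contingency(self._results(genes, dirs),
                                    {"u": "up", "d": "down"})
        assert out["p_hypergeometric"] == pytest.approx(
            hypergeometric_upper_tail(62, 394, 108, 1138)
        )
        assert out["counts"]["up"] == {"decreased": 62, "not_decreased": 332}

    def test_empty_row_is_nan(self):
        res = self._results(["u1"], ["decrease"])
        with pytest.warns(UserWarning, match="empty contingency row"):
            out = direction_contingency(res, {"u1": "up"})
        assert np.isnan(out["p_hypergeometric"])


class TestOverrepresentation:
    def test_term_equal_to_gene_set_is_most_significant(self):
        universe = [f"g{i}" for i in range(20)]
        gene_set = universe[:5]
        terms = {"match": set(gene_set), "half": set(universe[3:13]),
                 "off": set(universe[10:])}
        res = overrepresentation(gene_set, terms, universe)
        best = res.loc[res["p_value"].idxmin(), "term"]
        assert best == "match"

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = overrepresentation(universe[:3], {"t": set(universe[5:])},
                                 universe)
        assert res["p_value"][0] == 1.0

    def test_matches_enumeration_oracle(self):
        """Toy universe of 20 genes, 3 terms: p equals the exhaustive
        enumeration over all draws of |gene_set| genes."""
        from math import comb

        universe = [f"g{i}" for i in range(20)]
        gene_set = universe[2:8]
        terms = {"a": set(universe[:6]), "b": set(universe[4:14]),
                 "c": set(universe[15:])}
        res = overrepresentation(gene_set, terms, universe).set_index("term")
        for term, tg in terms.items():
            k = len(set(gene_set) & tg)
            K, n, N = len(tg), len(gene_set), 20
            oracle = sum(
                comb(K, j) * comb(N - K, n - j)
                for j in range(k, min(n, K) + 1)
            ) / comb(N, n)
            assert res.loc[term, "p_value"] == pytest.approx(oracle)

    def test_gene_set_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation(["gX"], {"t": {"gX"}}, ["g1"])


class TestEnrichmentScoreCorrelation:
    def _res(self, scores, fdrs=None):
        n = len(scores)
        fdrs = fdrs if fdrs is not None else [0.01] * n
        return pd.DataFrame({"term": [f"t{i}" for i in range(n)],
                             "fdr": fdrs, "score": scores})

    def test_identical_lists_correlate_perfectly(self):
        a = self._res([1.0, 2.0, 3.0, 4.0])
        r, n = enrichment_score_correlation(a, a.copy())
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_negated_scores_anticorrelate(self):
        a = self._res([1.0, 2.0, 3.0])
        b = self._res([-1.0, -2.0, -3.0])
        r, _ = enrichment_score_correlation(a, b)
        assert r == pytest.approx(-1.0)

    def test_matches_direct_pearson_formula(self, rng):
        sa, sb = rng.random(8), rng.random(8)
        r, _ = enrichment_score_correlation(self._res(sa), self._res(sb))
        oracle = (
            ((sa - sa.mean()) * (sb - sb.mean())).sum()
            / np.sqrt(((sa - sa.mean()) ** 2).sum() * ((sb - sb.mean()) ** 2).sum())
        )
        assert r == pytest.approx(oracle)

    def test_inclusion_filter_and_small_overlap(self):
        a = self._res([1.0, 2.0, 3.0], fdrs=[0.9, 0.9, 0.9])
        b = self._res([1.0, 2.0, 3.0], fdrs=[0.9, 0.9, 0.9])
        with pytest.warns(UserWarning, match="fewer than 3"):
            r, n = enrichment_score_correlation(a, b)
        assert np.isnan(r) and n == 0
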