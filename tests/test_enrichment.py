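"""Ranking, DAR weighting/exclusion, the GSEA engine, chromosomal
enrichment and BH adjustment — each checked against an independent
oracle or an exact hand computation."""

import itertools

import numpy as np
import pytest

from dartk.enrichment import (
    RankedGene,
    bh_fdr,
    chromosome_enrichment,
    dar_weight_ranks,
    exclude_by_dar_threshold,
    preranked_gsea,
    ranking_statistic,
    threshold_sweep,
)
from dartk.types import (
    ConfigurationError,
    DataError,
    DeGene,
    GeneDarAssignment,
    GeneSetCollection,
)

from helpers import bh_stepup_oracle, hypergeom_tail_oracle, running_sum_oracle


def de(gene_id, log2fc, pvalue, fdr=None, chrom=None):
    return DeGene(gene_id, log2fc, pvalue, fdr if fdr is not None else pvalue,
                  chrom)


def assignment(gene_id, dar):
    return GeneDarAssignment(gene_id, dar, 0 if dar is None else 1)


class TestRankingStatistic:
    @pytest.mark.parametrize(
        "log2fc, pvalue, expected",
        [(1.0, 0.01, 2.0), (-0.5, 0.001, -3.0), (0.0, 0.5, 0.0)],
    )
    def test_formula(self, log2fc, pvalue, expected):
        ranked = ranking_statistic([de("g", log2fc, pvalue)])
        assert ranked[0].stat == pytest.approx(expected)

    def test_descending_order_with_id_tiebreak(self):
        genes = [de("b", 1.0, 0.1), de("a", 1.0, 0.1), de("c", -1.0, 0.01)]
        ranked = ranking_statistic(genes)
        assert [r.gene_id for r in ranked] == ["a", "b", "c"]


class TestDarWeighting:
    @pytest.mark.parametrize(
        "stat, dar, expected",
        [(2.5, 0.0, 2.5), (2.5, 1.0, 0.0), (2.0, 0.4, 1.2), (-3.0, 0.5, -1.5)],
    )
    def test_weight_factor(self, stat, dar, expected):
        out = dar_weight_ranks([RankedGene("g", stat)], [assignment("g", dar)])
        assert out[0].weighted_stat == pytest.approx(expected)

    def test_absent_dar_keeps_statistic(self):
        out = dar_weight_ranks([RankedGene("g", 2.0)], [assignment("g", None)])
        assert out[0].weighted_stat == 2.0

    def test_invalid_dar_names_gene(self):
        with pytest.raises(DataError, match="gBad"):
            dar_weight_ranks([RankedGene("gBad", 1.0)], [assignment("gBad", 1.5)])

    def test_weighting_contracts_and_order_preservation(self):
        # |weighted| <= |stat|, sign preserved, and a gene never overtakes
        # one with both a larger statistic and no larger DAR
        rng = np.random.default_rng(5)
        stats = rng.normal(0, 3, size=60)
        dars = rng.random(size=60)
        ranked = [RankedGene(f"g{i:02d}", float(s)) for i, s in enumerate(stats)]
        assignments = [assignment(f"g{i:02d}", float(d))
                       for i, d in enumerate(dars)]
        out = dar_weight_ranks(ranked, assignments)
        weighted = {r.gene_id: r.weighted_stat for r in out}
        raw = {r.gene_id: r.stat for r in out}
        dar_of = {a.gene_id: a.dar for a in assignments}
        for r in out:
            assert abs(r.weighted_stat) <= abs(r.stat) + 1e-12
            assert r.weighted_stat * r.stat >= 0
        for g, h in itertools.combinations(weighted, 2):
            if raw[g] > raw[h] >= 0 and dar_of[g] <= dar_of[h]:
                assert weighted[g] >= weighted[h]


class TestExclusion:
    def test_threshold_one_excludes_nothing(self):
        assignments = [assignment("a", 1.0), assignment("b", 0.5)]
        retained, excluded = exclude_by_dar_threshold(["a", "b"], assignments, 1.0)
        assert excluded == []

    def test_strict_inequality(self):
        assignments = [assignment(g, d) for g, d in
                       [("a", 0.0), ("b", 0.1), ("c", 0.5)]]
        retained, excluded = exclude_by_dar_threshold(
            ["a", "b", "c"], assignments, 0.0)
        assert retained == ["a"] and excluded == ["b", "c"]

    def test_gene_at_threshold_retained(self):
        retained, excluded = exclude_by_dar_threshold(
            ["a"], [assignment("a", 0.6)], 0.6)
        assert retained == ["a"]

    def test_absent_dar_always_retained(self):
        retained, _ = exclude_by_dar_threshold(["a"], [assignment("a", None)], 0.0)
        assert retained == ["a"]

    def test_threshold_out_of_range(self):
        with pytest.raises(ConfigurationError):
            exclude_by_dar_threshold(["a"], [], 1.5)

    def test_sweep_nested_and_counts(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(50)]
        assignments = [assignment(g, float(rng.random())) for g in genes]
        de_set = frozenset(genes[:10])
        points = threshold_sweep(genes, assignments, de_set)
        for lo, hi in zip(points, points[1:]):
            assert lo.retained <= hi.retained
            assert lo.n_de_removed + lo.n_non_de_removed == len(lo.excluded)
        assert points[-1].excluded == frozenset()  # threshold 1.0


def collection(**sets):
    return GeneSetCollection({k: frozenset(v) for k, v in sets.items()})


class TestPrerankedGsea:
    def test_hand_computed_singleton_es(self):
        # 3 genes (3, 2, 1), set = top gene: hit +1.0 then misses -0.5
        ranked = [RankedGene(g, s) for g, s in [("a", 3.0), ("b", 2.0), ("c", 1.0)]]
        results = preranked_gsea(ranked, collection(top={"a"}),
                                 n_perm=10, seed=0, min_size=1)
        assert results[0].es == pytest.approx(1.0)
        assert results[0].leading_edge == ("a",)

    def test_higher_position_gives_higher_es(self):
        ranked = [RankedGene(g, s) for g, s in [("a", 3.0), ("b", 2.0), ("c", 1.0)]]
        results = {r.set_name: r for r in preranked_gsea(
            ranked, collection(first={"a"}, last={"c"}),
            n_perm=10, seed=0, min_size=1)}
        assert results["first"].es > results["last"].es

    def test_permutation_p_floor(self):
        ranked = [RankedGene(f"g{i}", float(10 - i)) for i in range(10)]
        results = preranked_gsea(ranked, collection(s={"g0", "g1", "g2"}),
                                 n_perm=10, seed=3, min_size=1)
        assert results[0].pvalue >= 1 / 11

    def test_size_bounds_skip_sets(self):
        ranked = [RankedGene(f"g{i}", float(i)) for i in range(20)]
        results = preranked_gsea(
            ranked,
            collection(tiny={"g1"}, ok={"g1", "g2", "g3", "g4", "g5"},
                       alien={"zz1", "zz2"}),
            n_perm=10, seed=0, min_size=5, max_size=500)
        assert [r.set_name for r in results] == ["ok"]

    def test_es_sign_matches_nes_sign(self):
        rng = np.random.default_rng(1)
        ranked = [RankedGene(f"g{i:02d}", float(s))
                  for i, s in enumerate(rng.normal(0, 2, 40))]
        sets = {f"s{j}": frozenset(f"g{i:02d}"
                                   for i in rng.choice(40, 6, replace=False))
                for j in range(5)}
        for r in preranked_gsea(ranked, GeneSetCollection(sets),
                                n_perm=50, seed=2, min_size=1):
            if r.nes != 0:
                assert np.sign(r.nes) == np.sign(r.es)
            assert -1.0 <= r.es <= 1.0

    @pytest.mark.parametrize("n_genes", [4, 6, 8])
    def test_exhaustive_running_sum_oracle(self, n_genes):
        # every non-empty proper subset of a small universe, three sets
        # per engine call, against the step-by-step oracle
        stats = [3.1, 2.3, 1.7, 0.9, -0.4, -1.2, -2.6, -3.5][:n_genes]
        ranked = [RankedGene(f"g{i}", s) for i, s in enumerate(stats)]
        ids = [r.gene_id for r in ranked]
        abs_stats = [abs(s) for s in stats]
        subsets = [
            frozenset(c)
            for size in range(1, n_genes)
            for c in itertools.combinations(ids, size)
        ]
        for start in range(0, len(subsets), 3):
            chunk = subsets[start : start + 3]
            sets = GeneSetCollection(
                {f"s{start + j}": members for j, members in enumerate(chunk)}
            )
            results = {r.set_name: r for r in preranked_gsea(
                ranked, sets, n_perm=2, seed=0, min_size=1, max_size=500)}
            for j, members in enumerate(chunk):
                hits = [g in members for g in ids]
                expected, _ = running_sum_oracle(abs_stats, hits)
                assert results[f"s{start + j}"].es == pytest.approx(
                    expected, abs=1e-12)

    def test_leading_edge_members_subset_of_set(self):
        rng = np.random.default_rng(4)
        ranked = [RankedGene(f"g{i:02d}", float(s))
                  for i, s in enumerate(rng.normal(0, 2, 30))]
        members = frozenset(f"g{i:02d}" for i in range(0, 30, 4))
        results = preranked_gsea(ranked, collection(s=members),
                                 n_perm=20, seed=0, min_size=1)
        assert set(results[0].leading_edge) <= members
        assert len(results[0].leading_edge) >= 1

    def test_null_type_one_error_calibrated(self):
        # random statistics, random sets: the fraction with p < 0.05
        # should sit within 3 binomial SEs of 0.05
        n_sets_per_seed, size, n_perm = 60, 8, 200
        pvalues = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ranked = [RankedGene(f"g{i:03d}", float(s))
                      for i, s in enumerate(rng.normal(0, 1, 100))]
            sets = {
                f"s{j:02d}": frozenset(
                    f"g{i:03d}" for i in rng.choice(100, size, replace=False))
                for j in range(n_sets_per_seed)
            }
            results = preranked_gsea(ranked, GeneSetCollection(sets),
                                     n_perm=n_perm, seed=seed + 1000, min_size=1)
            pvalues.extend(r.pvalue for r in results)
        fraction = np.mean([p < 0.05 for p in pvalues])
        se = np.sqrt(0.05 * 0.95 / len(pvalues))
        assert abs(fraction - 0.05) <= 3 * se


class TestChromosomeEnrichment:
    def _universe(self, n_total, spec):
        """spec: list of (chrom, n_genes, n_de)."""
        genes = []
        i = 0
        for chrom, n, n_de in spec:
            for j in range(n):
                flag = j < n_de
                genes.append(de(f"g{i:04d}", 1.0, 0.5,
                                fdr=0.01 if flag else 0.5, chrom=chrom))
                i += 1
        assert len(genes) == n_total
        return genes

    def test_matches_exact_tail_on_reference_instance(self):
        # 2000 genes, chrX holds 100 with 10 DE, 20 DE elsewhere
        universe = self._universe(
            2000, [("chrX", 100, 10), ("chrY", 1900, 20)])
        result = {r.chrom: r for r in chromosome_enrichment(universe)}
        expected = hypergeom_tail_oracle(2000, 30, 100, 10)
        assert result["chrX"].p_raw == pytest.approx(expected, rel=1e-10)
        assert result["chrX"].table == (10, 90, 20, 1880)

    def test_zero_de_gives_p_one(self):
        universe = self._universe(30, [("c1", 10, 0), ("c2", 20, 0)])
        for r in chromosome_enrichment(universe):
            assert r.p_raw == pytest.approx(1.0)

    def test_single_chromosome_multiplier_one(self):
        universe = self._universe(20, [("c1", 20, 5)])
        result = chromosome_enrichment(universe)[0]
        assert result.p_bonferroni == pytest.approx(result.p_raw)

    def test_bonferroni_caps_at_one(self):
        universe = self._universe(40, [(f"c{k}", 10, 1) for k in range(4)])
        for r in chromosome_enrichment(universe):
            assert 0 < r.p_bonferroni <= 1.0
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p_raw * 4))

    def test_empty_universe_rejected(self):
        with pytest.raises(ConfigurationError):
            chromosome_enrichment([])

    def test_chrom_from_gene_models_wins(self):
        from dartk.types import GeneModel

        universe = [de("g1", 1.0, 0.5, fdr=0.01, chrom="wrong"),
                    de("g2", 1.0, 0.5, fdr=0.5, chrom="wrong")]
        models = [GeneModel("g1", "right", 1, 10), GeneModel("g2", "right", 20, 30)]
        result = chromosome_enrichment(universe, models)
        assert [r.chrom for r in result] == ["right"]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle_small_universes(self, seed):
        rng = np.random.default_rng(seed)
        n_total = int(rng.integers(4, 61))
        chroms = [f"c{rng.integers(1, 5)}" for _ in range(n_total)]
        flags = rng.random(n_total) < 0.3
        universe = [de(f"g{i:03d}", 1.0, 0.5, fdr=0.01 if f else 0.5, chrom=c)
                    for i, (c, f) in enumerate(zip(chroms, flags))]
        n_de = int(flags.sum())
        for r in chromosome_enrichment(universe):
            n_on = chroms.count(r.chrom)
            de_on = sum(f for c, f in zip(chroms, flags) if c == r.chrom)
            expected = hypergeom_tail_oracle(n_total, n_de, n_on, int(de_on))
            assert r.p_raw == pytest.approx(expected, rel=1e-9)


class TestBhFdr:
    def test_hand_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_fdr([0.5, 0.0])

    def test_matches_independent_step_up_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            n = int(rng.integers(1, 20))
            ps = rng.uniform(1e-12, 1.0, size=n).tolist()
            assert bh_fdr(ps) == pytest.approx(bh_stepup_oracle(ps), abs=1e-12)
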