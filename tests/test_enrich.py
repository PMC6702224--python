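import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mirtemporal.enrich import (
    ContingencyTable,
    cor_gene_test,
    enrichment_score,
    ks_set_enrichment,
    mre_enrichment_p,
    preranked_gsea,
    set_targeting_test,
)
from mirtemporal.io import GeneSet, GeneSetCollection, TargetMap
from mirtemporal.synthetic import (
    CohortConfig,
    PlantedCoR,
    generate_target_map,
    mirna_group_sets,
)


def hypergeom_point_enum(n11, n12, n21, n22) -> float:
    """The printed contingency formula via exact combinatorics."""
    return (
        math.comb(n11 + n21, n11)
        * math.comb(n12 + n22, n12)
        / math.comb(n11 + n12 + n21 + n22, n11 + n12)
    )


def hypergeom_tail_enum(n11, n12, n21, n22) -> float:
    """One-sided enrichment tail by enumerating all tables with the same
    margins and at least n11 group sites in the tested transcript."""
    row1, col1 = n11 + n12, n11 + n21
    total = n11 + n12 + n21 + n22
    p = 0.0
    for k in range(n11, min(row1, col1) + 1):
        if row1 - k <= total - col1:
            p += hypergeom_point_enum(k, row1 - k, col1 - k, total - col1 - (row1 - k))
    return p


class TestEnrichmentScore:
    def test_top_hit_single_member_reaches_one(self):
        # scores (2, 1, 1), set = {top feature}: hit step to 1 before any miss
        mask = np.array([True, False, False])
        assert enrichment_score(mask, np.array([2.0, 1.0, 1.0])) == pytest.approx(1.0)

    def test_bottom_set_is_negative(self):
        mask = np.array([False, False, True])
        es = enrichment_score(mask, np.array([2.0, 1.0, 0.5]))
        assert es < 0

    def test_reversed_ranking_negates_es(self):
        rng = np.random.default_rng(0)
        scores = np.sort(rng.normal(size=30))[::-1]
        mask = np.zeros(30, dtype=bool)
        mask[rng.choice(30, 8, replace=False)] = True
        es = enrichment_score(mask, scores)
        es_rev = enrichment_score(mask[::-1], scores[::-1])
        assert es_rev == pytest.approx(-es, abs=1e-12)

    def test_es_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            scores = np.sort(rng.normal(size=n))[::-1]
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, int(rng.integers(1, n - 1)) or 1, replace=False)] = True
            assert abs(enrichment_score(mask, scores)) <= 1.0 + 1e-12


class TestPrerankedGsea:
    def _ranking(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return [(f"m{i}", s) for i, s in enumerate(np.sort(rng.normal(size=n))[::-1])]

    def test_random_set_not_enriched(self):
        ranked = self._ranking(seed=2)
        rng = np.random.default_rng(3)
        nes, ps = [], []
        for i in range(15):
            members = [f"m{j}" for j in rng.choice(60, 12, replace=False)]
            sets = GeneSetCollection.from_sets([GeneSet("S", members)])
            (res,) = preranked_gsea(ranked, sets, n_perm=200, seed=i)
            nes.append(res.nes)
            ps.append(res.p_value)
        assert abs(np.mean(np.abs(nes)) - 1.0) < 0.35
        assert np.median(ps) > 0.1

    def test_top_loaded_set_enriched(self):
        ranked = self._ranking(seed=4)
        members = [f"m{i}" for i in range(10)]  # the ten best-ranked features
        sets = GeneSetCollection.from_sets([GeneSet("top", members)])
        (res,) = preranked_gsea(ranked, sets, n_perm=500, seed=5)
        assert res.es > 0.5
        assert res.nes > 1.5
        assert res.p_value < 0.05

    def test_determinism(self):
        ranked = self._ranking(seed=6)
        sets = GeneSetCollection.from_sets([GeneSet("S", [f"m{i}" for i in range(5, 20)])])
        a = preranked_gsea(ranked, sets, n_perm=200, seed=9)
        b = preranked_gsea(ranked, sets, n_perm=200, seed=9)
        assert a[0].nes == b[0].nes and a[0].p_value == b[0].p_value

    def test_members_outside_universe_dropped_with_warning(self):
        ranked = self._ranking()
        sets = GeneSetCollection.from_sets([GeneSet("S", ["m1", "m2", "nope"])])
        with pytest.warns(UserWarning, match="outside ranking"):
            preranked_gsea(ranked, sets, n_perm=100, seed=0)

    def test_small_n_perm_rejected(self):
        sets = GeneSetCollection.from_sets([GeneSet("S", ["m1"])])
        with pytest.raises(ValueError, match="n_perm"):
            preranked_gsea(self._ranking(), sets, n_perm=10)

    def test_p_floor_respected(self):
        ranked = self._ranking(seed=7)
        sets = GeneSetCollection.from_sets([GeneSet("top", [f"m{i}" for i in range(8)])])
        (res,) = preranked_gsea(ranked, sets, n_perm=200, seed=1)
        assert res.p_value >= 1.0 / 201.0


class TestMreEnrichment:
    def test_printed_formula_point_case(self):
        # C(4,4) * C(4,0) / C(8,4) = 1/70
        p = mre_enrichment_p(ContingencyTable(4, 0, 0, 4), mode="point")
        assert p == pytest.approx(1.0 / 70.0, rel=1e-12)

    def test_degenerate_empty_transcript(self):
        assert mre_enrichment_p(ContingencyTable(0, 0, 5, 5)) == 1.0

    def test_tail_at_least_point(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            t = ContingencyTable(*rng.integers(0, 8, 4))
            assert mre_enrichment_p(t, "tail") >= mre_enrichment_p(t, "point") - 1e-12

    def test_tail_matches_margin_fixed_enumeration(self):
        """Fisher enrichment tail equals full enumeration for all tables
        with total <= 14 (the complete small-table grid)."""
        for n11, n12, n21, n22 in itertools.product(range(5), repeat=4):
            if n11 + n21 == 0 or n11 + n12 == 0:
                continue
            got = mre_enrichment_p(ContingencyTable(n11, n12, n21, n22), "tail")
            total = n11 + n12 + n21 + n22
            if n11 + n21 == total or n11 + n12 == total:
                assert got == 1.0
                continue
            want = hypergeom_tail_enum(n11, n12, n21, n22)
            assert got == pytest.approx(want, rel=1e-9)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)


def _toy_target_map(rows):
    return TargetMap(
        pd.DataFrame(rows, columns=["mirna_id", "gene_id", "transcript_id", "n_sites"])
    )


class TestCorGeneTest:
    def test_single_group_mirna_never_cor(self):
        rows = [["mA", "g1", "t1", 12]] + [
            [f"mX{i}", f"g{i + 2}", f"t{i + 2}", 1] for i in range(20)
        ]
        res = cor_gene_test(_toy_target_map(rows), {"mA"})
        g1 = next(r for r in res if r.gene_id == "g1")
        assert g1.fdr < 0.05  # heavily enriched transcript...
        assert g1.n_group_mirnas_targeting == 1
        assert not g1.is_cor  # ...but the >= 2 distinct-miRNA rule vetoes it

    def test_group_equal_to_universe_degenerate(self):
        rows = [["mA", "g1", "t1", 3], ["mB", "g2", "t2", 2]]
        res = cor_gene_test(_toy_target_map(rows), {"mA", "mB"})
        assert all(r.best_p == 1.0 for r in res)
        assert not any(r.is_cor for r in res)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cor_gene_test(_toy_target_map([["m", "g", "t", 1]]), set())

    def test_planted_cor_genes_recovered_across_seeds(self):
        """Planted CoR genes are called at FDR < 0.05 in >= 90% of seeds."""
        genes = tuple(f"GENE{i + 1:04d}" for i in range(10))
        hits, trials = 0, 0
        for seed in range(10):
            cfg = CohortConfig(
                n_mirna=90, n_mrna=120, seed=seed,
                planted_cor=PlantedCoR(group=6, genes=genes),
            )
            tm = generate_target_map(cfg)
            group6 = mirna_group_sets(cfg)["Group6"]
            res = {r.gene_id: r for r in cor_gene_test(tm, group6)}
            hits += sum(res[g].is_cor for g in genes)
            trials += len(genes)
        assert hits / trials >= 0.9

    def test_unplanted_map_has_low_cor_rate(self):
        cfg = CohortConfig(n_mirna=90, n_mrna=120, seed=77)
        tm = generate_target_map(cfg)
        group6 = mirna_group_sets(cfg)["Group6"]
        res = cor_gene_test(tm, group6)
        assert sum(r.is_cor for r in res) / len(res) < 0.05


class TestKsSetEnrichment:
    def test_extreme_separation(self):
        p_gene = {f"s{i}": 0.001 * (i + 1) for i in range(5)}
        p_gene.update({f"b{i}": 0.5 + 0.09 * i for i in range(5)})
        D, p, direction = ks_set_enrichment(
            p_gene, {f"s{i}" for i in range(5)}, {f"b{i}" for i in range(5)}
        )
        assert D == pytest.approx(1.0)
        assert direction == "enriched"

    def test_matches_direct_formula_five_vs_five(self):
        set_p = [0.01, 0.03, 0.2, 0.4, 0.9]
        bg_p = [0.1, 0.3, 0.5, 0.7, 0.8]
        p_gene = {f"s{i}": v for i, v in enumerate(set_p)}
        p_gene.update({f"b{i}": v for i, v in enumerate(bg_p)})
        D, p, _ = ks_set_enrichment(
            p_gene, {f"s{i}" for i in range(5)}, {f"b{i}" for i in range(5)}
        )
        # direct empirical-CDF computation
        grid = sorted(set_p + bg_p)
        d_direct = max(
            abs(
                sum(v <= g for v in set_p) / 5 - sum(v <= g for v in bg_p) / 5
            )
            for g in grid
        )
        assert D == pytest.approx(d_direct, abs=1e-12)
        assert 0 < p <= 1

    def test_set_from_background_calibrated(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(40):
            vals = rng.uniform(size=40)
            p_gene = {f"g{i}": v for i, v in enumerate(vals)}
            sub = {f"g{i}" for i in rng.choice(40, 10, replace=False)}
            _, p, _ = ks_set_enrichment(p_gene, sub, set(p_gene))
            ps.append(p)
        assert np.median(ps) > 0.2

    def test_tiny_set_warns(self):
        p_gene = {"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4}
        with pytest.warns(UserWarning, match="smaller than 3"):
            ks_set_enrichment(p_gene, {"a", "b"}, set(p_gene))


class TestSetTargetingTest:
    def test_small_enumeration_example(self):
        # N=10, K=5, n=4, k=4: P(X>=4) = C(5,4) C(5,0) / C(10,4) = 5/210
        tm = _toy_target_map(
            [["mG", f"g{i}", f"t{i}", 1] for i in range(4)]  # group targets g0..g3
        )
        universe = {f"g{i}" for i in range(10)}
        gene_set = {f"g{i}" for i in range(5)}  # K = 5, overlap k = 4
        p = set_targeting_test(tm, {"mG"}, gene_set, universe)
        assert p == pytest.approx(5.0 / 210.0, rel=1e-12)

    def test_zero_overlap_near_one(self):
        tm = _toy_target_map([["mG", "g9", "t9", 1]])
        universe = {f"g{i}" for i in range(10)}
        p = set_targeting_test(tm, {"mG"}, {"g0", "g1"}, universe)
        assert p > 0.7

    def test_matches_enumeration_small_universes(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            N = int(rng.integers(5, 20))
            universe = {f"g{i}" for i in range(N)}
            K = int(rng.integers(1, N))
            gene_set = {f"g{i}" for i in rng.choice(N, K, replace=False)}
            n = int(rng.integers(1, N))
            targeted = [f"g{i}" for i in rng.choice(N, n, replace=False)]
            tm = _toy_target_map([["mG", g, f"t{g}", 1] for g in targeted])
            k = len(set(targeted) & gene_set)
            want = sum(
                math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n)
                for j in range(k, min(K, n) + 1)
            )
            got = set_targeting_test(tm, {"mG"}, gene_set, universe)
            assert got == pytest.approx(want, rel=1e-9)

    def test_disjoint_gene_set_rejected(self):
        tm = _toy_target_map([["mG", "g1", "t1", 1]])
        with pytest.raises(ValueError, match="disjoint"):
            set_targeting_test(tm, {"mG"}, {"zzz"}, {"g1", "g2"})
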