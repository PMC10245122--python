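"""PEI calling, annotation, APA, conservation judgments and enrichment tests."""

import numpy as np
import pandas as pd
import pytest

from hicevo.homology import HomologyMap, LiftFailure
from hicevo.matrix import BinGrid, ContactMatrix, expected_by_distance, observed_over_expected
from hicevo.peis import (
    PEI,
    AlignedPEI,
    BackgroundModel,
    Promoter,
    RegionSet,
    align_pei,
    annotate_enhancers,
    apa,
    call_peis,
    classify_pei,
    classify_peis,
    distance_judgment,
    enrichment_judgment,
    har_permutation_test,
    promoter_valency,
    snp_enrichment,
)
from hicevo.tads import TAD

RES = 10_000


def _null_matrix(n=300, depth=60_000, seed=0):
    rng = np.random.default_rng(seed)
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    mu = (1.0 + d) ** -1.0
    mu *= depth / np.triu(mu).sum()
    counts = rng.poisson(np.triu(mu))
    counts = counts + np.triu(counts, 1).T
    return ContactMatrix(BinGrid("chr1", RES, n), counts.astype(float))


class TestPromoter:
    def test_window_lengths_and_strand(self):
        p = Promoter("g", 100_000, "+")
        assert p.window == (97_800, 100_500)
        m = Promoter("g", 100_000, "-")
        assert m.window == (99_500, 102_200)
        assert p.window[1] - p.window[0] == 2_700

    def test_anchor_is_tss_bin(self):
        assert Promoter("g", 101_000).anchor_bin(RES) == 10


class TestCallPeis:
    def test_null_matrix_rare_discoveries(self):
        m = _null_matrix()
        promoters = [Promoter(f"g{i}", int(b * RES + 5_000)) for i, b in
                     enumerate(range(50, 250, 20))]
        peis, _ = call_peis(m, promoters)
        n_tests = len(promoters) * 2 * (10_000_000 // RES)
        assert len(peis) <= max(1, 0.001 * n_tests)

    def test_short_loop_excluded_by_min_len(self):
        m = _null_matrix(seed=1)
        m.values[100, 101] = m.values[101, 100] = 500.0  # 10-kb separation
        peis, _ = call_peis(m, [Promoter("g", 100 * RES + 5_000)])
        assert all(abs(p.enhancer_bin - p.promoter_bin) >= 2 for p in peis)

    def test_planted_loop_retained(self, pei_species_set):
        ss = pei_species_set
        m = ss.contact_map("human", RES)
        L = ss.spec.chrom_length
        tads = [TAD(s, e, None, None) for s, e in zip(
            [0] + list(ss.truth.boundaries["human"]),
            list(ss.truth.boundaries["human"]) + [L])]
        peis, _ = call_peis(m, ss.truth.promoters, tads)
        present = ss.truth.loops[ss.truth.loops.loop_class != "human_lost"]
        called = {(p.promoter_bin, p.enhancer_bin) for p in peis}
        hits = sum(
            any(abs(a - r.promoter_pos // RES) <= 1 and abs(b - r.enhancer_pos // RES) <= 1
                for a, b in called)
            for _, r in present.iterrows()
        )
        assert hits >= 0.5 * len(present)
        assert all(p.fdr <= 0.001 for p in peis)

    def test_promoter_promoter_pairs_dropped(self):
        m = _null_matrix(seed=2)
        m.values[100, 120] = m.values[120, 100] = 500.0
        proms = [Promoter("a", 100 * RES + 5_000), Promoter("b", 120 * RES + 5_000)]
        peis, _ = call_peis(m, proms)
        assert not any(
            {p.promoter_bin, p.enhancer_bin} == {100, 120} for p in peis
        )


class TestAnnotateEnhancers:
    def _pei(self, enh_bin):
        return PEI("g", 0, enh_bin, 1.0, 0.5, 1e-5)

    def test_se_overlap_rule_and_precedence(self):
        # SE peak overlapping 6 kb of bin 10; RE peak overlapping fully
        se = RegionSet("SE", np.array([104_000]), np.array([112_000]))
        re_ = RegionSet("RE", np.array([100_000]), np.array([110_000]))
        out = annotate_enhancers([self._pei(10)], re_, se, RES)
        assert out[0].enhancer_annotation == "SE"

    def test_small_overlap_is_none(self):
        se = RegionSet("SE", np.array([0]), np.array([1]))
        re_ = RegionSet("RE", np.array([100_000]), np.array([104_000]))  # 4 kb, 40%
        out = annotate_enhancers([self._pei(10)], re_, se, RES)
        assert out[0].enhancer_annotation == "none"

    def test_just_over_5kb_annotated(self):
        se = RegionSet("SE", np.array([0]), np.array([1]))
        re_ = RegionSet("RE", np.array([100_000]), np.array([105_001]))
        out = annotate_enhancers([self._pei(10)], re_, se, RES)
        assert out[0].enhancer_annotation == "RE"


class TestAPA:
    def test_null_pixels_score_near_one(self):
        m = _null_matrix(n=400, depth=400_000, seed=3)
        oe = observed_over_expected(m, expected_by_distance(m, "mean"))
        rng = np.random.default_rng(0)
        peis = [PEI("g", int(i), int(i + d), 1, 1, 1)
                for i, d in zip(rng.integers(30, 250, 80), rng.integers(30, 100, 80))]
        _, score = apa(oe, peis)
        assert 0.8 <= score <= 1.2

    def test_planted_loops_enriched(self, pei_species_set):
        ss = pei_species_set
        m = ss.contact_map("human", RES)
        oe = observed_over_expected(m, expected_by_distance(m, "mean"))
        loops = ss.truth.loops[ss.truth.loops.loop_class != "human_lost"]
        peis = [PEI(r.gene, r.promoter_pos // RES, r.enhancer_pos // RES, 1, 1, 1)
                for _, r in loops.iterrows()]
        _, score = apa(oe, peis)
        assert score > 1.0

    def test_single_pei_identity(self):
        m = _null_matrix(seed=4)
        oe = observed_over_expected(m, expected_by_distance(m, "mean"))
        peis = [PEI("g", 100, 160, 1, 1, 1)]
        agg, _ = apa(oe, peis, half_window=5, corner=3)
        assert np.allclose(agg, oe.values[95:106, 155:166])


class TestAlignment:
    COLS = ["ref_start", "ref_end", "query_chrom", "query_start", "query_end",
            "strand", "reciprocal"]

    def _map(self, rows):
        return HomologyMap(pd.DataFrame(rows, columns=self.COLS), "q")

    def test_clean_alignment(self):
        hmap = HomologyMap.identity(5_000_000)
        pei = PEI("g", 100, 150, 1, 1, 1)
        out = align_pei(pei, hmap, homolog_tss=100 * RES + 5_000)
        assert isinstance(out, AlignedPEI)
        assert out.span == pytest.approx(50 * RES)

    def test_size_out_of_range(self):
        # anchor interval expands 3x in the query
        rows = [[0, 1_000_000, "q1", 0, 1_000_000, "+", True],
                [1_000_000, 1_010_000, "q1", 1_000_000, 1_030_000, "+", True],
                [1_010_000, 5_000_000, "q1", 1_030_000, 5_020_000, "+", True]]
        pei = PEI("g", 100, 150, 1, 1, 1)
        out = align_pei(pei, self._map(rows), None)
        assert isinstance(out, LiftFailure) and out.reason == "size_out_of_range"

    def test_trans_split(self):
        rows = [[0, 1_200_000, "q1", 0, 1_200_000, "+", True],
                [1_200_000, 5_000_000, "q2", 0, 3_800_000, "+", True]]
        pei = PEI("g", 100, 150, 1, 1, 1)
        out = align_pei(pei, self._map(rows), None)
        assert isinstance(out, LiftFailure) and out.reason == "trans_split"

    def test_promoter_displaced(self):
        hmap = HomologyMap.identity(5_000_000)
        pei = PEI("g", 100, 150, 1, 1, 1)
        out = align_pei(pei, hmap, homolog_tss=100 * RES + 50_000)
        assert isinstance(out, LiftFailure) and out.reason == "promoter_displaced"


class TestDistanceJudgment:
    def _aligned(self, pbin, ebin):
        return AlignedPEI((pbin * RES, (pbin + 1) * RES),
                          (ebin * RES, (ebin + 1) * RES), "chr1")

    def test_threshold_is_min_of_r1_span_and_r2(self):
        aligned = self._aligned(0, 20)  # span 200 kb
        near = [PEI("g", 0, 21, 1, 1, 1)]  # enhancer offset 10 kb -> d = 10 kb
        d, ok = distance_judgment(aligned, near, r1=0.2, r2=20_000)
        assert d == pytest.approx(10_000)
        assert ok  # 10 < min(40, 20) kb
        farther = [PEI("g", 0, 23, 1, 1, 1)]  # d = 30 kb
        d2, ok2 = distance_judgment(aligned, farther, r1=0.2, r2=20_000)
        assert not ok2  # 30 > 20
        _, ok3 = distance_judgment(aligned, farther, r1=0.2, r2=50_000)
        assert ok3  # 30 < min(40, 50)

    def test_short_span_shrinks_threshold(self):
        aligned = self._aligned(0, 5)  # span 50 kb -> min(10 kb, 20 kb) = 10 kb
        q = [PEI("g", 0, 6, 1, 1, 1)]  # d = 10 kb, not strictly less
        _, ok = distance_judgment(aligned, q, r1=0.2, r2=20_000)
        assert not ok

    def test_no_query_peis_is_infinite(self):
        d, ok = distance_judgment(self._aligned(0, 20), [])
        assert np.isinf(d) and not ok

    def test_matches_bruteforce_nearest(self):
        rng = np.random.default_rng(8)
        aligned = self._aligned(50, 80)
        qs = [PEI("g", int(a), int(b), 1, 1, 1)
              for a, b in rng.integers(0, 200, size=(30, 2))]
        d, _ = distance_judgment(aligned, qs)
        brute = min(
            np.hypot(aligned.promoter_mid - (q.promoter_bin + 0.5) * RES,
                     aligned.enhancer_mid - (q.enhancer_bin + 0.5) * RES)
            for q in qs
        )
        assert d == pytest.approx(brute)


class TestEnrichmentJudgment:
    def test_strict_exceed_of_quantile(self):
        m = _null_matrix(seed=5)
        model = BackgroundModel(m)
        aligned = AlignedPEI((100 * RES, 101 * RES), (150 * RES, 151 * RES), "chr1")
        score = model.score(100, 150)
        below = np.full(50, score + 1.0)
        assert not enrichment_judgment(aligned, model, below, 0.2)
        above = np.full(50, score - 1.0)
        assert enrichment_judgment(aligned, model, above, 0.2)
        exact = np.full(50, score)
        assert not enrichment_judgment(aligned, model, exact, 0.2)


class TestClassifyPEI:
    def _rec(self, aligned=True, nc=False, ns=False, enr=False):
        return {"aligned": aligned, "near_conserved": nc, "near_specific": ns,
                "enriched": enr}

    def test_enrichment_alone_is_conserved(self):
        per = {"q1": self._rec(enr=True), "q2": self._rec(enr=True)}
        assert classify_pei(per) == "species-conserved"

    def test_far_and_unenriched_is_specific(self):
        per = {"q1": self._rec(), "q2": self._rec()}
        assert classify_pei(per) == "human-specific"

    def test_partial_votes_unclassified(self):
        per = {"q1": self._rec(nc=True), "q2": self._rec()}
        assert classify_pei(per) == "unclassified"

    def test_alignment_failure_unclassified(self):
        per = {"q1": {"aligned": False}, "q2": self._rec(nc=True)}
        assert classify_pei(per) == "unclassified"

    def test_self_comparison_all_conserved(self, pei_species_set):
        ss = pei_species_set
        L = ss.spec.chrom_length
        m = ss.contact_map("human", RES)
        tads = [TAD(s, e, None, None) for s, e in zip(
            [0] + list(ss.truth.boundaries["human"]),
            list(ss.truth.boundaries["human"]) + [L])]
        peis, model = call_peis(m, ss.truth.promoters, tads)
        idmap = HomologyMap.identity(L)
        tss = {p.gene: p.tss for p in ss.truth.promoters}
        table = classify_peis(peis, {"self": idmap}, {"self": peis},
                              {"self": model}, {"self": tss})
        aligned = table[table["self_status"] == "aligned"]
        assert len(aligned) > 0
        assert (aligned["label"] == "species-conserved").all()

    def test_planted_classification_accuracy(self, pei_species_set):
        ss = pei_species_set
        spec = ss.spec
        L = spec.chrom_length
        pei_sets, models = {}, {}
        for sp in spec.species:
            m = ss.contact_map(sp, RES)
            tads = [TAD(s, e, None, None) for s, e in zip(
                [0] + list(ss.truth.boundaries[sp]),
                list(ss.truth.boundaries[sp]) + [L])]
            pei_sets[sp], models[sp] = call_peis(m, ss.truth.promoters, tads, species=sp)
        qs = list(spec.species[1:])
        tss = {sp: {p.gene: p.tss for p in ss.truth.promoters} for sp in qs}
        table = classify_peis(pei_sets["human"], {sp: ss.truth.maps[sp] for sp in qs},
                              {sp: pei_sets[sp] for sp in qs},
                              {sp: models[sp] for sp in qs}, homolog_tss=tss)
        truth_class = {(r.promoter_pos // RES, r.enhancer_pos // RES): r.loop_class
                       for _, r in ss.truth.loops.iterrows()}
        ok = n = 0
        for _, row in table.iterrows():
            key = next(((pb, eb) for (pb, eb) in truth_class
                        if abs(row.promoter_bin - pb) <= 1
                        and abs(row.enhancer_bin - eb) <= 1), None)
            if key is None or row.label == "unclassified":
                continue
            tc = truth_class[key]
            if tc == "human_lost":
                continue
            want = "human-specific" if tc == "human_gained" else "species-conserved"
            n += 1
            ok += row.label == want
        assert n >= 3
        assert ok / n >= 0.85


class TestEnrichmentStats:
    def test_har_target_equals_universe_p_one(self):
        hars = RegionSet("HAR", np.array([5_000]), np.array([5_200]))
        universe = np.arange(50)
        obs, p = har_permutation_test(universe, universe, hars, n_perm=99, seed=0)
        assert p == 1.0

    def test_har_planted_enrichment_significant(self):
        rng = np.random.default_rng(0)
        universe = np.arange(500)
        starts = universe[rng.random(500) < 0.1] * RES + 100
        hars = RegionSet("HAR", starts, starts + 200)
        har_bins = set(starts // RES)
        target = np.array(
            [b for b in universe if b in har_bins][:30]
            + list(rng.choice([b for b in universe if b not in har_bins], 30,
                              replace=False))
        )
        _, p = har_permutation_test(target, universe, hars, n_perm=1000, seed=1)
        assert p <= 0.01

    def test_snp_density_and_identical_classes(self):
        snps = RegionSet("SNP", np.arange(10) * 1_000, np.arange(10) * 1_000 + 1)
        classes = {"HS": np.array([0, 5]), "Cons": np.array([0, 7])}
        df = snp_enrichment(classes, snps, RES)
        dens = df[df.kind == "density"]
        assert np.allclose(dens.density_per_mb, 10 / (2 * RES / 1e6))
        fisher = df[df.kind == "fisher"].iloc[0]
        assert fisher.odds_ratio == pytest.approx(1.0)

    def test_promoter_valency_hand_count(self):
        peis = (
            [PEI("p1", 0, 10, 1, 1, 1)]
            + [PEI("p2", 0, b, 1, 1, 1) for b in (10, 20)]
            + [PEI("p3", 0, b, 1, 1, 1) for b in (10, 20, 30, 40)]
        )
        v = promoter_valency(peis)
        assert v["1"] == pytest.approx(100 / 3)
        assert v["2"] == pytest.approx(100 / 3)
        assert v["3"] == pytest.approx(0.0)
        assert v[">3"] == pytest.approx(100 / 3)
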