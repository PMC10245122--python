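"""Insulation scoring, boundary/TAD calling and conservation labels."""

import numpy as np
import pandas as pd
import pytest

from hicevo.homology import HomologyMap
from hicevo.matrix import BinGrid, ContactMatrix, kr_balance
from hicevo.tads import (
    TAD,
    Boundary,
    UndefinedStrengthError,
    aggregate_tad_map,
    call_boundaries,
    classify_boundaries,
    classify_tads,
    insulation_score,
    tad_composition_stats,
    tad_strength,
    tads_from_boundaries,
)

COLS = ["ref_start", "ref_end", "query_chrom", "query_start", "query_end",
        "strand", "reciprocal"]
RES = 20_000


def _matrix(vals):
    n = vals.shape[0]
    return ContactMatrix(BinGrid("chr1", RES, n), vals)


class TestInsulation:
    def test_constant_matrix_zero_score(self):
        m = _matrix(np.full((40, 40), 5.0))
        tr = insulation_score(m)
        defined = np.isfinite(tr.score)
        assert defined.any()
        assert np.allclose(tr.score[defined], 0.0)
        d = tr.delta[np.isfinite(tr.delta) & defined]
        assert np.allclose(d, 0.0)

    def test_two_blocks_minimum_at_junction(self):
        n = 40
        vals = np.full((n, n), 0.01)
        vals[:20, :20] = 5.0
        vals[20:, 20:] = 5.0
        tr = insulation_score(_matrix(vals))
        defined = np.where(np.isfinite(tr.score))[0]
        assert abs(defined[np.argmin(tr.score[defined])] - 20) <= 1

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.random((40, 40)) + 0.5
        a = a + a.T
        t1 = insulation_score(_matrix(a))
        t2 = insulation_score(_matrix(2 * a))
        f = np.isfinite(t1.score)
        assert np.allclose(t1.score[f], t2.score[f])

    def test_too_short(self):
        with pytest.raises(Exception):
            insulation_score(_matrix(np.ones((10, 10))))


class TestBoundaries:
    def test_flat_track_no_boundaries(self):
        tr = insulation_score(_matrix(np.full((60, 60), 2.0)))
        assert call_boundaries(tr) == []

    def test_noise_threshold_gates_emission(self):
        # two blocks with mild contrast: crossing present, strength moderate
        n = 60
        vals = np.full((n, n), 1.0)
        vals[:30, :30] *= 1.6
        vals[30:, 30:] *= 1.6
        tr = insulation_score(_matrix(vals))
        strong = call_boundaries(tr, noise_threshold=0.3)
        weak = call_boundaries(tr, noise_threshold=5.0)
        assert len(strong) >= 1
        assert weak == []

    def test_planted_boundaries_recovered(self, default_species_set):
        ss = default_species_set
        kr = kr_balance(ss.contact_map("human", RES), tol=1e-8)
        called = np.array([b.bin for b in call_boundaries(insulation_score(kr))])
        planted = np.array(ss.truth.boundaries["human"]) // RES
        recall = np.mean([np.min(np.abs(called - p)) <= 1 for p in planted])
        precision = np.mean([np.min(np.abs(planted - c)) <= 1 for c in called])
        assert recall >= 0.90
        assert precision >= 0.90


class TestTADStrength:
    def test_uniform_matrix_strength_one(self):
        m = _matrix(np.full((40, 40), 2.0))
        t = TAD(10 * RES, 20 * RES, None, None)
        assert tad_strength(m, t) == pytest.approx(1.0)

    def test_hand_ratio_median(self):
        # per-distance intra/inter ratios planted as {2, 3, 4}
        n = 30
        vals = np.ones((n, n))
        t0, t1 = 10, 14  # 4-bin TAD, distances 1..3
        for d, r in zip((1, 2, 3), (2.0, 3.0, 4.0)):
            for i in range(t0, t1 - d):
                vals[i, i + d] = vals[i + d, i] = r
        m = _matrix(vals)
        t = TAD(t0 * RES, t1 * RES, None, None)
        assert tad_strength(m, t) == pytest.approx(3.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(1, 10, size=(50, 50)).astype(float)
        vals = np.triu(vals) + np.triu(vals, 1).T
        m = _matrix(vals)
        t0, t1 = 12, 22
        t = TAD(t0 * RES, t1 * RES, None, None)
        # independent brute force over explicit pair lists
        ln = t1 - t0
        n0, n1 = t0 - ln, t1 + ln
        ratios = []
        for d in range(1, ln):
            intra = [vals[i, i + d] for i in range(t0, t1 - d)]
            inter = [
                vals[min(i, j), max(i, j)]
                for i in range(t0, t1)
                for j in (i - d, i + d)
                if n0 <= j < n1 and not (t0 <= j < t1)
            ]
            if inter and np.median(inter) > 0:
                ratios.append(np.median(intra) / np.median(inter))
        assert tad_strength(m, t) == pytest.approx(np.median(ratios))

    def test_all_inter_zero_is_undefined(self):
        n = 30
        vals = np.zeros((n, n))
        vals[10:14, 10:14] = 3.0
        m = ContactMatrix(BinGrid("chr1", RES, n), vals)
        with pytest.raises(UndefinedStrengthError):
            tad_strength(m, TAD(10 * RES, 14 * RES, None, None))

    def test_planted_gamma_recovered(self, default_species_set):
        ss = default_species_set
        kr = kr_balance(ss.contact_map("human", RES), tol=1e-8)
        bs = call_boundaries(insulation_score(kr))
        tads = tads_from_boundaries(bs, ss.spec.chrom_length, RES)
        strengths = []
        for t in tads:
            try:
                strengths.append(tad_strength(kr, t))
            except UndefinedStrengthError:
                pass
        assert 1.6 <= np.median(strengths) <= 2.4


class TestClassification:
    def _bounds(self, bins, species="ref"):
        return [Boundary(b, b * RES, 1.0, species) for b in bins]

    def _identity_map(self, length=2_000_000):
        return HomologyMap.identity(length)

    def test_self_comparison_all_conserved(self):
        ref = self._bounds([10, 30, 60])
        maps = {"q": self._identity_map()}
        labels = classify_boundaries(ref, {"q": ref}, maps)
        assert (labels["label"] == "species-conserved").all()

    def test_conserved_within_flank(self):
        ref = self._bounds([50])
        q = {"q1": self._bounds([51]), "q2": self._bounds([49])}  # 20 kb away
        maps = {s: self._identity_map() for s in q}
        labels = classify_boundaries(ref, q, maps)
        assert labels["label"].iloc[0] == "species-conserved"

    def test_specific_beyond_100kb(self):
        ref = self._bounds([50])
        q = {"q1": self._bounds([60]), "q2": self._bounds([41])}  # >= 100 kb / >= 100 kb? 9 bins=180kb
        maps = {s: self._identity_map() for s in q}
        labels = classify_boundaries(ref, q, maps)
        assert labels["label"].iloc[0] == "human-specific"

    def test_gray_zone_gives_other(self):
        ref = self._bounds([50])
        q = {"q1": self._bounds([53]), "q2": self._bounds([51])}  # 60 kb and 20 kb
        maps = {s: self._identity_map() for s in q}
        labels = classify_boundaries(ref, q, maps)
        assert labels["label"].iloc[0] == "other"

    def test_unmapped_boundary_unclassified(self):
        ref = self._bounds([50])
        rows = [[0, 500_000, "chr1", 0, 500_000, "+", True]]  # map misses bin 50
        maps = {"q": HomologyMap(pd.DataFrame(rows, columns=COLS), "q")}
        labels = classify_boundaries(ref, {"q": self._bounds([50])}, maps)
        assert labels["verdict_q"].iloc[0] == "unclassified"
        assert labels["label"].iloc[0] == "other"

    def test_tad_labels_from_flanks(self):
        bounds = self._bounds([10, 20, 30, 40])
        labels = pd.DataFrame(
            {
                "position": [b.position for b in bounds],
                "label": ["species-conserved", "species-conserved",
                          "human-specific", "other"],
            }
        )
        tads = tads_from_boundaries(bounds, 50 * RES, RES)
        out = classify_tads(tads, labels)
        assert out == ["Cons", "HS", "HS"]


class TestAggregateAndComposition:
    def test_uniform_tad_flat_aggregate(self):
        m = _matrix(np.full((60, 60), 3.0))
        t = TAD(20 * RES, 30 * RES, None, None)
        agg, ratio = aggregate_tad_map(m, [t], out_size=30)
        assert np.allclose(agg, 3.0)
        assert ratio == pytest.approx(1.0)

    def test_single_tad_equals_own_window(self):
        rng = np.random.default_rng(2)
        vals = rng.random((60, 60)) + 0.5
        vals = vals + vals.T
        m = _matrix(vals)
        t = TAD(20 * RES, 30 * RES, None, None)
        agg, _ = aggregate_tad_map(m, [t], out_size=30)
        assert np.allclose(agg, vals[10:40, 10:40])

    def test_fisher_matches_enumeration(self):
        from math import comb

        tads = [TAD(0, 1_000_000, None, None), TAD(1_000_000, 2_000_000, None, None)]
        labels = ["Cons", "HS"]
        genes_x = np.array([100] * 8 + [1_500_000] * 1)
        genes_y = np.array([200] * 2 + [1_600_000] * 9)
        stats_df = tad_composition_stats(tads, labels, {"x": genes_x, "y": genes_y})
        row = stats_df[(stats_df.kind == "fisher") & (stats_df.gene_set == "x")].iloc[0]
        # hypergeometric enumeration for table [[8,2],[1,9]]
        def hyper_p(a, b, c, d):
            n = a + b + c + d
            denom = comb(n, a + c)
            tail = 0.0
            for x in range(0, min(a + b, a + c) + 1):
                y = a + c - x
                if y < 0 or y > c + d:
                    continue
                p = comb(a + b, x) * comb(c + d, y) / denom
                p_obs = comb(a + b, a) * comb(c + d, c) / denom
                if p <= p_obs + 1e-12:
                    tail += p
            return tail

        assert row.p == pytest.approx(hyper_p(8, 2, 1, 9))

    def test_density_per_mb(self):
        tads = [TAD(0, 1_000_000, None, None)]
        genes = np.arange(10) * 50_000
        df = tad_composition_stats(tads, ["Cons"], {"g": genes})
        assert df[df.kind == "density"].density_per_mb.iloc[0] == pytest.approx(10.0)
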