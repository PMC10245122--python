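"""Promoter-enhancer interaction (PEI) calling and evolutionary classification.

PEIs are called at 10-kb resolution: every bin within +-10 Mb of a promoter
anchor is tested against a domain-aware background — the distance-decay
expected curve rescaled inside each TAD by that TAD's median observed/expected
— with an upper-tail Poisson p-value on the raw count and Benjamini-Hochberg
FDR across all promoter-centered tests.  Retained interactions satisfy
FDR <= 0.001 and length >= 20 kb, and pairs whose distal bin overlaps any
promoter window are dropped.  Enhancer anchors are annotated against regular-
and super-enhancer peak sets, and aggregate peak analysis (APA) summarizes
pixel-level enrichment.

Conservation of a reference PEI in a query species combines two judgments on
its lifted anchors: a distance judgment d < min(r1 * |i-j|, r2) against the
query PEIs of the homologous promoter (r1 = 0.2 with r2 = 20 kb for the
conservation test and 50 kb for the specificity test), and an enrichment
judgment comparing the lifted pixel's observed-minus-expected score with the
20th percentile of the query species' own PEI scores.  Conserved in every
query species => species-conserved; unsupported in every query species =>
human-specific; anything else is unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .homology import HomologyMap, LiftFailure
from .matrix import ContactMatrix, ContractError, DecayCurve, expected_by_distance
from .tads import TAD

__all__ = [
    "Promoter",
    "PEI",
    "RegionSet",
    "BackgroundModel",
    "call_peis",
    "annotate_enhancers",
    "apa",
    "align_pei",
    "distance_judgment",
    "enrichment_judgment",
    "classify_pei",
    "classify_peis",
    "har_permutation_test",
    "snp_enrichment",
    "promoter_valency",
]


@dataclass(frozen=True)
class Promoter:
    """Gene promoter: [TSS-2200, TSS+500) on +, mirrored on - strand."""

    gene: str
    tss: int
    strand: str = "+"
    upstream: int = 2200
    downstream: int = 500

    @property
    def window(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.tss - self.upstream, self.tss + self.downstream
        return self.tss - self.downstream, self.tss + self.upstream

    def anchor_bin(self, resolution: int) -> int:
        # a window straddling two bins takes the bin containing the TSS
        return self.tss // resolution


@dataclass
class PEI:
    gene: str
    promoter_bin: int
    enhancer_bin: int
    observed: float
    expected: float
    p: float
    fdr: float = float("nan")
    enhancer_annotation: str = "none"  # RE | SE | none
    species: str = "ref"

    @property
    def enrichment_score(self) -> float:
        return self.observed - self.expected

    def length(self, resolution: int) -> int:
        return abs(self.enhancer_bin - self.promoter_bin) * resolution


@dataclass
class RegionSet:
    """Named, chromosome-scoped interval collection with BED semantics."""

    name: str
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self):
        order = np.argsort(self.starts)
        self.starts = np.asarray(self.starts)[order]
        self.ends = np.asarray(self.ends)[order]

    @classmethod
    def read_bed(cls, path, name: str | None = None) -> "RegionSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        return cls(name or str(path), df[1].to_numpy(), df[2].to_numpy())

    def overlap_bp(self, start: int, end: int) -> int:
        """Total bp of this set overlapping [start, end)."""
        sel = (self.starts < end) & (self.ends > start)
        return int(
            np.sum(np.minimum(self.ends[sel], end) - np.maximum(self.starts[sel], start))
        )

    def any_overlap(self, start: int, end: int) -> bool:
        return bool(((self.starts < end) & (self.ends > start)).any())


class BackgroundModel:
    """Domain-aware expected contact model.

    expected(i, j) = E(|i-j|) * f_T where E is the distance-decay curve of the
    matrix (mean estimator, so the model is depth-unbiased) and f_T is a
    per-TAD multiplicative factor, the median observed/expected over pairs
    inside the TAD containing both i and j.  Pairs not inside one TAD use the
    global decay (f = 1).
    """

    def __init__(self, m: ContactMatrix, tads: list[TAD] | None = None):
        self.matrix = m
        self.decay = expected_by_distance(m, estimator="mean")
        res = m.grid.resolution
        n = m.n_bins
        self.tad_id = np.full(n, -1)
        self.tad_factor: list[float] = []
        for k, t in enumerate(tads or []):
            t0, t1 = t.start // res, min(t.end // res, n)
            self.tad_id[t0:t1] = k
            ratios = []
            for d in range(1, t1 - t0):
                e = self.decay.values[d]
                if e <= 0:
                    continue
                obs = np.diagonal(m.values, offset=d)[t0 : t1 - d]
                ratios.extend(obs / e)
            self.tad_factor.append(float(np.median(ratios)) if ratios else 1.0)

    def expected(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        i = np.atleast_1d(i)
        j = np.atleast_1d(j)
        d = np.abs(i - j)
        e = self.decay.values[d]
        same = (self.tad_id[i] >= 0) & (self.tad_id[i] == self.tad_id[j])
        f = np.ones(len(e))
        if same.any():
            factors = np.asarray(self.tad_factor)
            f[same] = factors[self.tad_id[i[same]]]
        return e * f

    def score(self, i: int, j: int) -> float:
        """Enrichment score of one pixel: observed minus expected."""
        return float(self.matrix.values[i, j] - self.expected(i, j)[0])


def call_peis(
    m: ContactMatrix,
    promoters: list[Promoter],
    tads: list[TAD] | None = None,
    max_span: int = 10_000_000,
    fdr_cut: float = 0.001,
    min_len: int = 20_000,
    species: str = "ref",
) -> tuple[list[PEI], BackgroundModel]:
    """Call promoter-centered enriched interactions on a raw count matrix.

    Each (promoter anchor, distal bin) pair within ``max_span`` gets an
    upper-tail Poisson p-value against the domain-aware background; FDR is
    Benjamini-Hochberg over all tests jointly.  Retains FDR <= ``fdr_cut``,
    length >= ``min_len``, distal bin not overlapping any promoter window.
    """
    if not np.allclose(m.values, np.round(m.values)):
        raise ContractError("call_peis needs raw integer counts for the count model")
    res = m.grid.resolution
    n = m.n_bins
    model = BackgroundModel(m, tads)
    max_bins = max_span // res
    min_bins = int(np.ceil(min_len / res))

    promoter_windows = [p.window for p in promoters]
    is_promoter_bin = np.zeros(n, dtype=bool)
    for w0, w1 in promoter_windows:
        b0, b1 = max(0, w0 // res), min(n - 1, (max(w1 - 1, 0)) // res)
        is_promoter_bin[b0 : b1 + 1] = True

    anchors: dict[int, list[Promoter]] = {}
    for p in promoters:
        a = p.anchor_bin(res)
        if not 0 <= a < n:
            continue
        if m.masked[a]:
            warnings.warn(f"promoter {p.gene}: anchor bin masked; skipped")
            continue
        anchors.setdefault(a, []).append(p)

    tests: list[tuple[int, int]] = []
    for a in sorted(anchors):
        lo, hi = max(0, a - max_bins), min(n, a + max_bins + 1)
        for j in range(lo, hi):
            if abs(j - a) < min_bins or m.masked[j] or is_promoter_bin[j]:
                continue
            tests.append((a, j))
    if not tests:
        return [], model
    ii = np.array([t[0] for t in tests])
    jj = np.array([t[1] for t in tests])
    obs = m.values[ii, jj]
    exp = model.expected(ii, jj)
    # P(X >= obs) under Poisson(expected); zero-expected pixels are untestable
    pvals = np.where(exp > 0, stats.poisson.sf(obs - 1, np.maximum(exp, 1e-300)), 1.0)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    keep = fdr <= fdr_cut
    out = []
    for a, j, o, e, p, q in zip(ii[keep], jj[keep], obs[keep], exp[keep], pvals[keep], fdr[keep]):
        for prom in anchors[a]:
            out.append(PEI(prom.gene, int(a), int(j), float(o), float(e), float(p), float(q), species=species))
    return out, model


def annotate_enhancers(
    peis: list[PEI],
    re_peaks: RegionSet,
    se_peaks: RegionSet,
    resolution: int = 10_000,
) -> list[PEI]:
    """Label enhancer bins RE / SE by the >50%-or->5-kb overlap rule.

    A 10-kb enhancer bin is annotated against a peak set when its overlap
    with the set exceeds 5 kb or half the bin; super-enhancers take
    precedence over regular enhancers.
    """

    def _passes(peaks: RegionSet, start: int, end: int) -> bool:
        ov = peaks.overlap_bp(start, end)
        return ov > 5_000 or ov > 0.5 * (end - start)

    for pei in peis:
        start = pei.enhancer_bin * resolution
        end = start + resolution
        if _passes(se_peaks, start, end):
            pei.enhancer_annotation = "SE"
        elif _passes(re_peaks, start, end):
            pei.enhancer_annotation = "RE"
        else:
            pei.enhancer_annotation = "none"
    return peis


def apa(
    oe: ContactMatrix,
    peis: list[PEI],
    half_window: int = 5,
    corner: int = 3,
) -> tuple[np.ndarray, float]:
    """Aggregate peak analysis over PEI pixels on an O/E matrix.

    Averages the (2*half_window+1)^2 O/E submatrix centered on each eligible
    pixel (far enough from the matrix edge and the diagonal) and reports the
    APA score: center value over the mean of the corner x corner block in the
    lower-left quadrant (the short-distance corner).  Scores above one mark
    pixel enrichment.
    """
    n = oe.n_bins
    size = 2 * half_window + 1
    margin = half_window + corner
    acc = np.zeros((size, size))
    used = 0
    for p in peis:
        i, j = sorted((p.promoter_bin, p.enhancer_bin))
        if i < margin or j >= n - margin or (j - i) <= margin:
            continue
        acc += oe.values[i - half_window : i + half_window + 1, j - half_window : j + half_window + 1]
        used += 1
    if used == 0:
        raise ContractError("no PEI far enough from edges/diagonal for APA")
    agg = acc / used
    center = agg[half_window, half_window]
    ll = agg[size - corner :, :corner].mean()
    return agg, float(center / ll) if ll > 0 else float("nan")


@dataclass
class AlignedPEI:
    promoter_interval: tuple[int, int]
    enhancer_interval: tuple[int, int]
    chrom: str

    @property
    def promoter_mid(self) -> float:
        return 0.5 * (self.promoter_interval[0] + self.promoter_interval[1])

    @property
    def enhancer_mid(self) -> float:
        return 0.5 * (self.enhancer_interval[0] + self.enhancer_interval[1])

    @property
    def span(self) -> float:
        """Linear distance |i-j| between the two anchors in the query genome."""
        return abs(self.enhancer_mid - self.promoter_mid)


def align_pei(
    pei: PEI,
    hmap: HomologyMap,
    homolog_tss: int | None,
    resolution: int = 10_000,
    size_range: tuple[int, int] = (5_000, 20_000),
    promoter_max_offset: int = 20_000,
):
    """Lift both PEI anchors into a query genome.

    Success requires both anchor bins to map reciprocally onto intervals of
    5-20 kb on one query chromosome, and the mapped promoter to land within
    20 kb of the annotated homologous promoter TSS.  Failures return a
    :class:`LiftFailure` with reason ``unmapped``, ``not_reciprocal``,
    ``size_out_of_range``, ``trans_split`` or ``promoter_displaced``.
    """
    lifted = []
    for b in (pei.promoter_bin, pei.enhancer_bin):
        res_lift = hmap.lift_interval(b * resolution, (b + 1) * resolution)
        if isinstance(res_lift, LiftFailure):
            return res_lift
        chrom, qs, qe = res_lift
        if not size_range[0] <= qe - qs <= size_range[1]:
            return LiftFailure("size_out_of_range")
        lifted.append((chrom, qs, qe))
    if lifted[0][0] != lifted[1][0]:
        return LiftFailure("trans_split")
    aligned = AlignedPEI(lifted[0][1:], lifted[1][1:], lifted[0][0])
    if homolog_tss is not None and abs(aligned.promoter_mid - homolog_tss) >= promoter_max_offset:
        return LiftFailure("promoter_displaced")
    return aligned


def distance_judgment(
    aligned: AlignedPEI,
    query_peis: list[PEI],
    r1: float = 0.2,
    r2: float = 20_000,
    resolution: int = 10_000,
) -> tuple[float, bool]:
    """Two-dimensional nearest-PEI distance test: d < min(r1 * |i-j|, r2).

    d is the Euclidean distance in (promoter midpoint, enhancer midpoint)
    space from the aligned PEI to the closest query PEI of the homologous
    promoter; |i-j| is the aligned PEI's own anchor separation in the query
    genome.  With no query PEIs, d is infinite and the test fails.
    """
    if not query_peis:
        return float("inf"), False
    pm, em = aligned.promoter_mid, aligned.enhancer_mid
    d = min(
        np.hypot(
            pm - (q.promoter_bin + 0.5) * resolution,
            em - (q.enhancer_bin + 0.5) * resolution,
        )
        for q in query_peis
    )
    return float(d), bool(d < min(r1 * aligned.span, r2))


def enrichment_judgment(
    aligned: AlignedPEI,
    query_model: BackgroundModel,
    query_scores: np.ndarray,
    quantile: float = 0.20,
) -> bool:
    """Does the lifted pixel exceed the query PEI enrichment-score threshold?

    The threshold is the ``quantile`` (20th percentile) of the enrichment
    scores (observed - expected) of all PEIs called in the query species;
    strictly exceeding it counts as signal enriched.  Pixels in masked bins
    are never enriched.
    """
    query_scores = np.asarray(query_scores, dtype=float)
    if query_scores.size == 0:
        raise ContractError("query species has no PEI enrichment scores")
    res = query_model.matrix.grid.resolution
    n = query_model.matrix.n_bins
    i = int(aligned.promoter_mid // res)
    j = int(aligned.enhancer_mid // res)
    if not (0 <= i < n and 0 <= j < n):
        return False
    if query_model.matrix.masked[i] or query_model.matrix.masked[j]:
        return False
    thresh = float(np.quantile(query_scores, quantile))
    return query_model.score(min(i, j), max(i, j)) > thresh


def classify_pei(per_species: dict[str, dict]) -> str:
    """Combine per-species judgments into an overall evolutionary label.

    Each species entry carries ``aligned`` (bool), ``near_conserved`` (the
    distance test at r2 = 20 kb), ``near_specific`` (the distance test at
    r2 = 50 kb) and ``enriched``.  Conserved-vote = near_conserved OR
    enriched; specific-vote = NOT near_specific AND NOT enriched.  All
    species voting conserved => species-conserved; all voting specific =>
    human-specific; otherwise unclassified.
    """
    verdicts = []
    for rec in per_species.values():
        if not rec.get("aligned", False):
            return "unclassified"
        if rec["near_conserved"] or rec["enriched"]:
            verdicts.append("conserved")
        elif not rec["near_specific"] and not rec["enriched"]:
            verdicts.append("specific")
        else:
            verdicts.append("ambiguous")
    if all(v == "conserved" for v in verdicts):
        return "species-conserved"
    if all(v == "specific" for v in verdicts):
        return "human-specific"
    return "unclassified"


def classify_peis(
    ref_peis: list[PEI],
    maps: dict[str, HomologyMap],
    query_peis: dict[str, list[PEI]],
    query_models: dict[str, "BackgroundModel"],
    homolog_tss: dict[str, dict[str, int]] | None = None,
    resolution: int = 10_000,
    r1: float = 0.2,
    r2_conserved: float = 20_000,
    r2_specific: float = 50_000,
    score_quantile: float = 0.20,
) -> pd.DataFrame:
    """Run alignment + both judgments for every reference PEI and species.

    ``homolog_tss[species][gene]`` optionally gives the annotated homologous
    promoter TSS in the query genome; when absent the promoter-displacement
    check is skipped.  Returns one row per reference PEI with per-species
    columns and the overall label.
    """
    species = sorted(maps)
    score_dist = {
        sp: np.array([q.enrichment_score for q in query_peis[sp]]) for sp in species
    }
    by_gene = {
        sp: _group_by_gene(query_peis[sp]) for sp in species
    }
    rows = []
    for pei in ref_peis:
        rec = {"gene": pei.gene, "promoter_bin": pei.promoter_bin, "enhancer_bin": pei.enhancer_bin}
        per_species = {}
        for sp in species:
            tss = (homolog_tss or {}).get(sp, {}).get(pei.gene)
            aligned = align_pei(pei, maps[sp], tss, resolution)
            if isinstance(aligned, LiftFailure):
                per_species[sp] = {"aligned": False}
                rec[f"{sp}_status"] = aligned.reason
                continue
            qp = by_gene[sp].get(pei.gene, [])
            d, near_c = distance_judgment(aligned, qp, r1, r2_conserved, resolution)
            _, near_s = distance_judgment(aligned, qp, r1, r2_specific, resolution)
            if score_dist[sp].size:
                enr = enrichment_judgment(aligned, query_models[sp], score_dist[sp], score_quantile)
            else:
                enr = False
            per_species[sp] = {
                "aligned": True,
                "near_conserved": near_c,
                "near_specific": near_s,
                "enriched": enr,
            }
            rec[f"{sp}_status"] = "aligned"
            rec[f"{sp}_d"] = d
            rec[f"{sp}_enriched"] = enr
        rec["label"] = classify_pei(per_species)
        rows.append(rec)
    return pd.DataFrame(rows)


def _group_by_gene(peis: list[PEI]) -> dict[str, list[PEI]]:
    out: dict[str, list[PEI]] = {}
    for p in peis:
        out.setdefault(p.gene, []).append(p)
    return out


def har_permutation_test(
    target_bins: np.ndarray,
    universe_bins: np.ndarray,
    hars: RegionSet,
    n_perm: int = 1000,
    seed: int = 0,
    resolution: int = 10_000,
    tie_break: str = "conservative",
) -> tuple[float, float]:
    """Permutation enrichment of HAR-containing enhancers in a PEI class.

    The statistic is the fraction of target enhancer bins containing at least
    one HAR; the null redraws same-size bin sets from the universe without
    replacement.  p = (1 + #{null >= observed}) / (1 + n_perm).

    The statistic is discrete, so this p-value is conservative at tied null
    values.  ``tie_break="randomized"`` instead splits ties uniformly at
    random (p = (#{null > obs} + U(1 + #{null = obs})) / (1 + n_perm)), the
    construction that is exactly uniform under the null and hence the right
    choice for calibration studies.
    """
    target_bins = np.asarray(target_bins)
    universe_bins = np.asarray(universe_bins)
    if target_bins.size > universe_bins.size:
        raise ContractError("target set larger than universe")
    has_har = np.array(
        [hars.any_overlap(b * resolution, (b + 1) * resolution) for b in universe_bins]
    )
    index = {b: k for k, b in enumerate(universe_bins)}
    obs = float(np.mean([has_har[index[b]] for b in target_bins]))
    rng = np.random.default_rng(seed)
    k = target_bins.size
    null = np.empty(n_perm)
    for t in range(n_perm):
        null[t] = has_har[rng.choice(universe_bins.size, size=k, replace=False)].mean()
    if tie_break == "randomized":
        greater = int((null > obs + 1e-12).sum())
        tied = 1 + int((np.abs(null - obs) <= 1e-12).sum())
        p = (greater + rng.uniform() * tied) / (1 + n_perm)
    else:
        p = (1 + int((null >= obs).sum())) / (1 + n_perm)
    return obs, float(p)


def snp_enrichment(
    class_bins: dict[str, np.ndarray],
    snps: RegionSet,
    resolution: int = 10_000,
) -> pd.DataFrame:
    """SNP density per PEI class and pairwise Fisher comparisons.

    Density is SNPs per Mb of enhancer-bin territory; the Fisher table
    compares SNP-containing vs SNP-free enhancer bins between classes.
    """
    rows = []
    counts = {}
    for name, bins in class_bins.items():
        bins = np.asarray(bins)
        if bins.size == 0:
            counts[name] = (0, 0, 0)
            rows.append({"kind": "density", "class_a": name, "class_b": "", "density_per_mb": np.nan})
            continue
        n_snp = sum(snps.overlap_bp(b * resolution, (b + 1) * resolution) > 0 for b in bins)
        total_snps = sum(
            int(((snps.starts >= b * resolution) & (snps.starts < (b + 1) * resolution)).sum())
            for b in bins
        )
        mb = bins.size * resolution / 1e6
        counts[name] = (n_snp, bins.size - n_snp, total_snps)
        rows.append(
            {"kind": "density", "class_a": name, "class_b": "", "density_per_mb": total_snps / mb}
        )
    names = sorted(class_bins)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if counts[a][0] + counts[a][1] == 0 or counts[b][0] + counts[b][1] == 0:
                orr, p = np.nan, np.nan
            else:
                orr, p = stats.fisher_exact(
                    [[counts[a][0], counts[a][1]], [counts[b][0], counts[b][1]]]
                )
            rows.append(
                {"kind": "fisher", "class_a": a, "class_b": b, "odds_ratio": orr, "p": p}
            )
    return pd.DataFrame(rows)


def promoter_valency(peis: list[PEI]) -> dict[str, float]:
    """Percentage of promoters forming 1, 2, 3 or >3 PEIs."""
    per_gene: dict[str, int] = {}
    for p in peis:
        per_gene[p.gene] = per_gene.get(p.gene, 0) + 1
    n = len(per_gene)
    cats = {"1": 0, "2": 0, "3": 0, ">3": 0}
    for c in per_gene.values():
        cats[str(c) if c <= 3 else ">3"] += 1
    return {k: 100.0 * v / n if n else float("nan") for k, v in cats.items()}
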