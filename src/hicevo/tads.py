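"""Insulation-score TAD calling, TAD strength and evolutionary classification.

Boundaries are insulation-score minima: the raw insulation of a bin is the
mean contact in a square window sliding along the diagonal (window 260 kb,
i.e. 13 bins at 20-kb resolution), log2-normalized to the chromosome mean.
A delta vector (mean insulation over a 200-kb span left of the bin minus the
same span on the right) crosses zero from positive to negative at each
minimum; the crossing is a boundary when the local delta max-minus-min
exceeds the noise threshold (0.5).  TADs tile the chromosome between
consecutive boundaries.

TAD strength is the median over intra-TAD genomic distances of the ratio of
the median intra-TAD contact to the median TAD-vs-neighbor contact at the
same distance, the neighbor region being the TAD extended by its own length
on both sides.

Cross-species labels: a reference boundary lifted into a query genome is
conserved with that species when a query boundary lies within 40 kb (2 bins),
and species-specific when every query boundary is at least 100 kb (5 bins)
away; a boundary conserved against all query species is species-conserved,
one specific against all is reference(human)-specific.  A TAD is conserved
when both flanking boundaries are, and specific when at least one flank is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .homology import HomologyMap, LiftFailure
from .matrix import ContactMatrix, ContractError

__all__ = [
    "InsulationTrack",
    "Boundary",
    "TAD",
    "insulation_score",
    "call_boundaries",
    "tads_from_boundaries",
    "tad_strength",
    "classify_boundaries",
    "classify_tads",
    "aggregate_tad_map",
    "tad_composition_stats",
]


class TooShortError(ValueError):
    """Chromosome shorter than twice the insulation window."""


class UndefinedStrengthError(ValueError):
    """All per-distance inter-TAD medians are zero."""


@dataclass
class InsulationTrack:
    grid_resolution: int
    chrom: str
    raw: np.ndarray       # mean contact in the sliding square; NaN at ends
    score: np.ndarray     # log2(raw / chromosome mean); NaN where undefined
    delta: np.ndarray     # left-span mean IS minus right-span mean IS
    window_bins: int
    delta_bins: int


@dataclass(frozen=True)
class Boundary:
    bin: int
    position: int         # bp of bin start
    strength: float
    species: str = "ref"


@dataclass
class TAD:
    start: int            # bp, half-open
    end: int
    left: Boundary | None
    right: Boundary | None
    strength: float = float("nan")
    gene_count: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


def insulation_score(
    m: ContactMatrix,
    window: int = 260_000,
    delta_span: int = 200_000,
) -> InsulationTrack:
    """Sliding-square insulation with log2 chromosome-mean normalization.

    ``window`` and ``delta_span`` are bp; with the defaults and 20-kb bins the
    square is 13x13 and the delta span 10 bins, matching the standard
    insulation-score parameterization (mean mode, no smoothing).
    """
    res = m.grid.resolution
    w = window // res
    # the delta span covers both sides of the bin: half the span each side
    ds = max(1, delta_span // res // 2)
    n = m.n_bins
    if n < 2 * w + 1:
        raise TooShortError(f"chromosome has {n} bins; needs > {2*w}")
    vals = np.where(m.masked[:, None] | m.masked[None, :], np.nan, m.values)
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        sq = vals[i - w : i, i + 1 : i + w + 1]
        if np.isnan(sq).all():
            continue
        raw[i] = np.nanmean(sq)
    defined = np.isfinite(raw) & (raw > 0)
    if not defined.any():
        raise TooShortError("no defined insulation bins")
    mean_raw = raw[defined].mean()
    score = np.full(n, np.nan)
    score[defined] = np.log2(raw[defined] / mean_raw)
    delta = np.full(n, np.nan)
    for i in range(ds, n - ds):
        left = score[i - ds : i]
        right = score[i + 1 : i + 1 + ds]
        if np.isnan(left).all() or np.isnan(right).all():
            continue
        delta[i] = np.nanmean(left) - np.nanmean(right)
    return InsulationTrack(res, m.grid.chrom, raw, score, delta, w, ds)


def call_boundaries(
    track: InsulationTrack,
    noise_threshold: float = 0.5,
    species: str = "ref",
) -> list[Boundary]:
    """Boundaries at positive-to-negative zero crossings of the delta vector.

    Strength is the local delta maximum left of the crossing minus the local
    minimum right of it, both searched within the delta span; crossings below
    ``noise_threshold`` are dropped.  The crossing bin itself is reported
    (no margin of error), choosing whichever of the two flanking bins has the
    delta value nearer zero.
    """
    d = track.delta
    ds = track.delta_bins
    n = len(d)
    out = []
    for i in range(n - 1):
        if not (np.isfinite(d[i]) and np.isfinite(d[i + 1])):
            continue
        if d[i] > 0 >= d[i + 1]:
            # the delta crossing can sit a few bins off the insulation
            # minimum when the well is asymmetric; report the minimum itself
            half = max(1, ds // 2)
            w0, w1 = max(0, i - half), min(n, i + 1 + half)
            seg = track.score[w0:w1]
            b = int(w0 + np.nanargmin(seg)) if np.isfinite(seg).any() else i
            lo = max(0, b - ds)
            hi = min(n, b + ds + 1)
            left_seg = d[lo : b + 1]
            right_seg = d[b:hi]
            if np.isnan(left_seg).all() or np.isnan(right_seg).all():
                continue
            strength = np.nanmax(left_seg) - np.nanmin(right_seg)
            if strength >= noise_threshold:
                out.append(
                    Boundary(b, b * track.grid_resolution, float(strength), species)
                )
    return out


def tads_from_boundaries(
    boundaries: list[Boundary],
    chrom_length: int,
    resolution: int,
    min_bins: int = 3,
    include_ends: bool = False,
) -> list[TAD]:
    """Tile the intervals between consecutive boundaries into TADs.

    Terminal segments (chromosome start to first boundary, last boundary to
    chromosome end) are included only on request, since they lack one flank.
    """
    bs = sorted(boundaries, key=lambda b: b.bin)
    tads = []
    for left, right in zip(bs, bs[1:]):
        start, end = left.position, right.position
        if (end - start) // resolution >= min_bins:
            tads.append(TAD(start, end, left, right))
    if include_ends and bs:
        first, last = bs[0], bs[-1]
        if first.position // resolution >= min_bins:
            tads.insert(0, TAD(0, first.position, None, first))
        if (chrom_length - last.position) // resolution >= min_bins:
            tads.append(TAD(last.position, chrom_length, last, None))
    return tads


def tad_strength(m: ContactMatrix, tad: TAD) -> float:
    """Median over distances of intra-TAD / inter-TAD median contact ratios.

    For each bin distance d from 1 to the TAD length minus one, the intra
    median is taken over pairs with both ends in the TAD and the inter median
    over pairs with one end in the TAD and the other in the neighbor region
    (the TAD extended by its own length each side, clipped to the
    chromosome).  Distances whose inter median is zero are skipped; if all
    are, the strength is undefined.
    """
    res = m.grid.resolution
    n = m.n_bins
    t0, t1 = tad.start // res, tad.end // res
    ln = t1 - t0
    if ln < 3:
        raise ContractError("TAD shorter than 3 bins")
    n0, n1 = max(0, t0 - ln), min(n, t1 + ln)
    vals = m.values
    ratios = []
    for d in range(1, ln):
        intra = [vals[i, i + d] for i in range(t0, t1 - d)]
        inter = []
        for i in range(t0, t1):
            for j in (i - d, i + d):
                if n0 <= j < n1 and not (t0 <= j < t1):
                    inter.append(vals[min(i, j), max(i, j)])
        if not inter:
            continue
        med_inter = np.median(inter)
        if med_inter == 0:
            continue
        ratios.append(np.median(intra) / med_inter)
    if not ratios:
        raise UndefinedStrengthError(f"TAD {tad.start}-{tad.end}: all inter medians zero")
    return float(np.median(ratios))


def classify_boundaries(
    ref_bounds: list[Boundary],
    query_bounds: dict[str, list[Boundary]],
    maps: dict[str, HomologyMap],
    flank: int = 40_000,
    specific_min: int = 100_000,
) -> pd.DataFrame:
    """Per-boundary conservation labels against every query species.

    Each reference boundary position lifts through the species' homology map;
    the distance from the lifted position to the nearest query boundary gives
    the per-species verdict (``conserved`` within ``flank``, ``specific`` at
    or beyond ``specific_min``, ``unclassified`` between, and for lift
    failures).  The overall label is ``species-conserved`` when conserved
    against all species, ``human-specific`` when specific against all, else
    ``other``.
    """
    if set(query_bounds) != set(maps):
        raise ContractError("query species of boundaries and maps differ")
    species = sorted(maps)
    rows = []
    for b in ref_bounds:
        rec = {"bin": b.bin, "position": b.position}
        verdicts = []
        for sp in species:
            lifted = maps[sp].lift_position(b.position, require_reciprocal=True)
            if isinstance(lifted, LiftFailure):
                rec[f"dist_{sp}"] = np.nan
                verdicts.append("unclassified")
                continue
            _, qpos = lifted
            qb = query_bounds[sp]
            dist = min((abs(q.position - qpos) for q in qb), default=np.inf)
            rec[f"dist_{sp}"] = dist
            if dist <= flank:
                verdicts.append("conserved")
            elif dist >= specific_min:
                verdicts.append("specific")
            else:
                verdicts.append("unclassified")
        for sp, v in zip(species, verdicts):
            rec[f"verdict_{sp}"] = v
        if all(v == "conserved" for v in verdicts):
            rec["label"] = "species-conserved"
        elif all(v == "specific" for v in verdicts):
            rec["label"] = "human-specific"
        else:
            rec["label"] = "other"
        rows.append(rec)
    return pd.DataFrame(rows)


def classify_tads(tads: list[TAD], boundary_labels: pd.DataFrame) -> list[str]:
    """Cons / HS / other per TAD from its flanking boundary labels."""
    by_pos = dict(zip(boundary_labels["position"], boundary_labels["label"]))
    out = []
    for t in tads:
        flanks = [
            by_pos.get(b.position, "other")
            for b in (t.left, t.right)
            if b is not None
        ]
        if flanks and any(f == "human-specific" for f in flanks):
            out.append("HS")
        elif len(flanks) == 2 and all(f == "species-conserved" for f in flanks):
            out.append("Cons")
        else:
            out.append("other")
    return out


def _rescale_window(win: np.ndarray, out_size: int) -> np.ndarray:
    """Overlap-weighted rescaling of a square window to out_size x out_size."""
    n = win.shape[0]
    # weight[a, i] = overlap of output cell a with input cell i, both on [0, 1)
    edges_out = np.linspace(0, n, out_size + 1)
    w = np.zeros((out_size, n))
    for a in range(out_size):
        lo, hi = edges_out[a], edges_out[a + 1]
        i0, i1 = int(np.floor(lo)), int(np.ceil(hi))
        for i in range(i0, min(i1, n)):
            w[a, i] = max(0.0, min(hi, i + 1) - max(lo, i))
    w /= w.sum(axis=1, keepdims=True)
    return w @ win @ w.T


def aggregate_tad_map(
    m: ContactMatrix,
    tads: list[TAD],
    out_size: int = 90,
) -> tuple[np.ndarray, float]:
    """Mean rescaled contact map over TAD windows, plus an aggregate strength.

    Each TAD window spans the TAD extended by its own length on both sides and
    is rescaled to ``out_size`` x ``out_size`` by interval-overlap-weighted
    averaging; windows extending past the chromosome are dropped.  The
    aggregate strength is the central-third block mean divided by the mean of
    the two adjacent (TAD-vs-neighbor) off-diagonal thirds.
    """
    if not tads:
        raise ContractError("no TADs given")
    res = m.grid.resolution
    n = m.n_bins
    acc = np.zeros((out_size, out_size))
    used = 0
    for t in tads:
        t0, t1 = t.start // res, t.end // res
        ln = t1 - t0
        w0, w1 = t0 - ln, t1 + ln
        if w0 < 0 or w1 > n:
            continue
        acc += _rescale_window(m.values[w0:w1, w0:w1], out_size)
        used += 1
    if used == 0:
        raise ContractError("no TAD window fits inside the chromosome")
    agg = acc / used
    third = out_size // 3
    center = agg[third : 2 * third, third : 2 * third].mean()
    flank = 0.5 * (
        agg[third : 2 * third, :third].mean()
        + agg[third : 2 * third, 2 * third :].mean()
    )
    return agg, float(center / flank) if flank > 0 else float("nan")


def tad_composition_stats(
    tads: list[TAD],
    labels: list[str],
    gene_sets: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Gene density per TAD class and pairwise Fisher enrichment per gene set.

    ``gene_sets`` maps a set name to an array of gene positions (bp, e.g.
    TSS).  Returns one row per (class pair, gene set) with counts, odds ratio
    and Fisher's exact p, plus per-class density rows (genes per Mb).
    """
    classes = sorted(set(labels))
    span = {c: 0 for c in classes}
    count = {(c, s): 0 for c in classes for s in gene_sets}
    for t, lab in zip(tads, labels):
        span[lab] += t.length
        for sname, positions in gene_sets.items():
            count[(lab, sname)] += int(
                ((positions >= t.start) & (positions < t.end)).sum()
            )
    rows = []
    for c in classes:
        for sname in gene_sets:
            rows.append(
                {
                    "kind": "density",
                    "class_a": c,
                    "class_b": "",
                    "gene_set": sname,
                    "count_a": count[(c, sname)],
                    "count_b": 0,
                    "density_per_mb": count[(c, sname)] / (span[c] / 1e6)
                    if span[c]
                    else np.nan,
                    "odds_ratio": np.nan,
                    "p": np.nan,
                }
            )
    for ia, ca in enumerate(classes):
        for cb in classes[ia + 1 :]:
            for sname in gene_sets:
                a_in, b_in = count[(ca, sname)], count[(cb, sname)]
                others_a = sum(count[(ca, s)] for s in gene_sets) - a_in
                others_b = sum(count[(cb, s)] for s in gene_sets) - b_in
                if span[ca] == 0 or span[cb] == 0:
                    orr, p = np.nan, np.nan
                else:
                    orr, p = stats.fisher_exact(
                        [[a_in, others_a], [b_in, others_b]]
                    )
                rows.append(
                    {
                        "kind": "fisher",
                        "class_a": ca,
                        "class_b": cb,
                        "gene_set": sname,
                        "count_a": a_in,
                        "count_b": b_in,
                        "density_per_mb": np.nan,
                        "odds_ratio": orr,
                        "p": p,
                    }
                )
    return pd.DataFrame(rows)
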