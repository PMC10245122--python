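"""Synthetic multi-species Hi-C data with planted ground truth.

The generator emulates the statistical structure the pipeline assumes: a
power-law distance-decay background, a compartment checkerboard (per-bin
signs s = +-1 modulating intensity by exp(beta * s_i * s_j)), TAD blocks
(within-domain enrichment gamma), focal loop pixels (amplitude lambda) and
Poisson counting noise, at any of the working resolutions.  Query species are
derived from the reference by planting compartment-block flips, deleted
(human-specific) boundaries, and gained/lost loops, all wired through
blockwise homology maps (piecewise identity with gaps and an optional
inversion) so that every conservation classifier can be scored against known
truth.

Default parameters are the desk-scale study conditions used throughout the
test-suite: a 40-Mb chromosome, 1e5 contacts, decay exponent 1, a 2x
compartment checkerboard contrast (beta = ln(2)/2), TAD enrichment gamma = 2
and loop amplitude 5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .homology import HomologyMap
from .matrix import BinGrid, ContactMatrix, ContractError
from .peis import Promoter

__all__ = ["SimulationSpec", "PlantedTruth", "SpeciesSet", "simulate_species_set",
           "simulate_expression", "simulate_fixtures"]

_HMAP_COLS = ["ref_start", "ref_end", "query_chrom", "query_start", "query_end",
              "strand", "reciprocal"]


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic multi-species chromosome."""

    species: tuple[str, ...] = ("human", "queryB", "queryC")
    chrom: str = "chr1"
    chrom_length: int = 40_000_000
    depth: int = 100_000
    alpha: float = 1.0                     # distance-decay exponent
    beta: float = float(np.log(2) / 2)     # 2x A/A vs A/B checkerboard contrast
    gamma: float = 2.0                     # intra-TAD enrichment
    loop_amplitude: float = 5.0
    compartment_block_range: tuple[int, int] = (1_000_000, 3_000_000)
    tad_length_range: tuple[int, int] = (300_000, 1_000_000)
    n_loops: int = 40
    loop_distance_range: tuple[int, int] = (100_000, 1_000_000)
    flip_fraction: float = 0.2             # compartment blocks flipped per query
    hs_boundary_fraction: float = 0.2      # reference boundaries absent in queries
    gained_loop_fraction: float = 0.2      # loops present only in the reference
    lost_loop_fraction: float = 0.1        # loops present only in queries
    homology_segment: int = 2_000_000
    homology_gap_rate: float = 0.05
    inversion: bool = False
    seed: int = 0

    def __post_init__(self):
        for r in (self.flip_fraction, self.hs_boundary_fraction,
                  self.gained_loop_fraction, self.lost_loop_fraction,
                  self.homology_gap_rate):
            if not 0 <= r <= 1:
                raise ContractError("rates must lie in [0, 1]")
        if self.depth <= 0:
            raise ContractError("depth must be positive")
        if self.tad_length_range[1] > self.chrom_length:
            raise ContractError("TAD longer than chromosome")


@dataclass
class PlantedTruth:
    """Ground truth planted in a species set; serializable to JSON."""

    compartment_blocks: dict[str, list[tuple[int, int, int]]]  # (start, end, sign)
    boundaries: dict[str, list[int]]                           # bp per species
    hs_boundaries: list[int]                                   # reference-only bp
    loops: pd.DataFrame          # gene, promoter_pos, enhancer_pos, loop_class
    promoters: list[Promoter]
    maps: dict[str, HomologyMap]
    gene_density: dict[str, np.ndarray] = field(default_factory=dict)  # per 100-kb bin

    def signs(self, species: str, resolution: int, n_bins: int) -> np.ndarray:
        s = np.zeros(n_bins, dtype=int)
        centers = np.arange(n_bins) * resolution + resolution // 2
        for start, end, sign in self.compartment_blocks[species]:
            s[(centers >= start) & (centers < end)] = sign
        return s

    def to_json(self, path) -> None:
        obj = {
            "compartment_blocks": self.compartment_blocks,
            "boundaries": self.boundaries,
            "hs_boundaries": self.hs_boundaries,
            "loops": self.loops.to_dict(orient="list"),
            "promoters": [
                {"gene": p.gene, "tss": p.tss, "strand": p.strand}
                for p in self.promoters
            ],
            "maps": {sp: m.blocks.to_dict(orient="list") for sp, m in self.maps.items()},
            "gene_density": {sp: g.tolist() for sp, g in self.gene_density.items()},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            compartment_blocks={
                sp: [tuple(b) for b in blocks]
                for sp, blocks in obj["compartment_blocks"].items()
            },
            boundaries={sp: list(b) for sp, b in obj["boundaries"].items()},
            hs_boundaries=list(obj["hs_boundaries"]),
            loops=pd.DataFrame(obj["loops"])[
                ["gene", "promoter_pos", "enhancer_pos", "loop_class"]
            ],
            promoters=[Promoter(p["gene"], p["tss"], p["strand"]) for p in obj["promoters"]],
            maps={
                sp: HomologyMap(pd.DataFrame(blocks)[_HMAP_COLS], sp)
                for sp, blocks in obj["maps"].items()
            },
            gene_density={sp: np.array(g) for sp, g in obj["gene_density"].items()},
        )


@dataclass
class SpeciesSet:
    spec: SimulationSpec
    truth: PlantedTruth

    def contact_map(self, species: str, resolution: int) -> ContactMatrix:
        """Poisson-sampled raw contact matrix, deterministic per (seed, species, resolution)."""
        spec = self.spec
        if species not in spec.species:
            raise ContractError(f"unknown species {species!r}")
        n = spec.chrom_length // resolution
        grid = BinGrid(spec.chrom, resolution, n)
        mu = self._intensity(species, resolution, n)
        rng = np.random.default_rng(
            [spec.seed, spec.species.index(species), resolution]
        )
        counts = rng.poisson(np.triu(mu))
        counts = counts + np.triu(counts, 1).T
        return ContactMatrix(grid, counts.astype(float))

    def _intensity(self, species: str, resolution: int, n: int) -> np.ndarray:
        spec = self.spec
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        mu = (1.0 + d) ** (-spec.alpha)
        s = self.truth.signs(species, resolution, n)
        mu *= np.exp(spec.beta * np.outer(s, s))
        bounds = np.array(self.truth.boundaries[species]) // resolution
        tid = np.searchsorted(bounds, np.arange(n), side="right")
        mu *= np.where(tid[:, None] == tid[None, :], spec.gamma, 1.0)
        loops = self.truth.loops
        for _, row in loops.iterrows():
            present = (
                row.loop_class == "shared"
                or (row.loop_class == "human_gained" and species == spec.species[0])
                or (row.loop_class == "human_lost" and species != spec.species[0])
            )
            if not present:
                continue
            i, j = row.promoter_pos // resolution, row.enhancer_pos // resolution
            if i != j:
                mu[i, j] *= spec.loop_amplitude
                mu[j, i] *= spec.loop_amplitude
        mu *= spec.depth / np.triu(mu).sum()
        return mu


def _draw_blocks(rng, length: int, lo: int, hi: int, unit: int) -> list[tuple[int, int]]:
    blocks = []
    pos = 0
    while pos < length:
        ln = int(rng.integers(lo // unit, hi // unit + 1)) * unit
        end = min(pos + ln, length)
        blocks.append((pos, end))
        pos = end
    return blocks


def simulate_species_set(spec: SimulationSpec) -> SpeciesSet:
    """Plant reference structure, derive query species, build homology maps."""
    rng = np.random.default_rng([spec.seed, 7])
    ref = spec.species[0]
    L = spec.chrom_length

    # compartment checkerboard: alternating-sign blocks
    comp = _draw_blocks(rng, L, *spec.compartment_block_range, 100_000)
    first = int(rng.integers(0, 2)) * 2 - 1
    ref_blocks = [(s, e, first * (-1) ** k) for k, (s, e) in enumerate(comp)]

    # TAD boundaries tile each compartment block, so compartment transitions
    # coincide with domain boundaries (as in real genomes); a truncated
    # remainder shorter than the minimum TAD length merges into its neighbor
    ref_bounds: list[int] = []
    comp_edges: set[int] = set()
    lo_t, hi_t = spec.tad_length_range
    for bs_, be_ in comp:
        pos = bs_
        while pos < be_:
            ln = int(rng.integers(lo_t // 20_000, hi_t // 20_000 + 1)) * 20_000
            end = min(pos + ln, be_)
            if be_ - end < lo_t:
                end = be_
            if end < L:
                ref_bounds.append(end)
            pos = end
        comp_edges.add(be_)
    # human-specific boundaries are drawn from non-edge boundaries only: a
    # compartment step insulates by itself, so deleting an edge boundary in a
    # query species would not remove the insulation signal
    interior = [k for k, b in enumerate(ref_bounds) if b not in comp_edges]
    n_hs = min(
        int(round(spec.hs_boundary_fraction * len(ref_bounds))), len(interior)
    )
    hs_idx = set(rng.choice(interior, size=n_hs, replace=False).tolist())
    hs_bounds = [b for k, b in enumerate(ref_bounds) if k in hs_idx]

    # loops: promoter anchored at a 10-kb bin center, enhancer downstream,
    # both anchors inside one TAD and one compartment block (promoter-enhancer
    # contacts are canonically intra-domain; a cross-boundary loop would sit
    # on a depressed background the domain-aware caller rightly discounts)
    margin = min(2_000_000, L // 10)
    bound_arr = np.array(ref_bounds + [0, L])
    comp_edge_arr = np.array(sorted({s for s, _ in comp} | {e for _, e in comp}))
    loop_rows = []
    used_bins: set[int] = set()
    classes = (
        ["human_gained"] * int(round(spec.gained_loop_fraction * spec.n_loops))
        + ["human_lost"] * int(round(spec.lost_loop_fraction * spec.n_loops))
    )
    classes += ["shared"] * (spec.n_loops - len(classes))
    for k in range(spec.n_loops):
        for _ in range(500):
            p = int(rng.integers(margin, L - margin) // 10_000)
            dist = int(rng.integers(*spec.loop_distance_range) // 10_000)
            e = p + dist
            if e * 10_000 >= L - margin:
                continue
            p_bp, e_bp = p * 10_000 + 5_000, e * 10_000 + 5_000
            if ((bound_arr > p_bp) & (bound_arr < e_bp)).any():
                continue
            if ((comp_edge_arr > p_bp) & (comp_edge_arr < e_bp)).any():
                continue
            if any(abs(p - u) < 2 or abs(e - u) < 2 for u in used_bins):
                continue
            used_bins.update((p, e))
            loop_rows.append(
                {
                    "gene": f"g{k:04d}",
                    "promoter_pos": p * 10_000 + 5_000,
                    "enhancer_pos": e * 10_000 + 5_000,
                    "loop_class": classes[k],
                }
            )
            break
    loops = pd.DataFrame(loop_rows)
    promoters = [Promoter(r.gene, int(r.promoter_pos)) for r in loops.itertuples()]

    blocks = {ref: ref_blocks}
    bounds = {ref: list(ref_bounds)}
    maps: dict[str, HomologyMap] = {}
    for sp in spec.species[1:]:
        srng = np.random.default_rng([spec.seed, 11, spec.species.index(sp)])
        n_flip = int(round(spec.flip_fraction * len(ref_blocks)))
        flip = set(srng.choice(len(ref_blocks), size=n_flip, replace=False).tolist())
        blocks[sp] = [
            (s, e, -sign if k in flip else sign)
            for k, (s, e, sign) in enumerate(ref_blocks)
        ]
        bounds[sp] = [b for k, b in enumerate(ref_bounds) if k not in hs_idx]
        # blockwise identity homology with gaps; optional single inversion
        seg_rows = []
        inv_target = srng.integers(0, L // spec.homology_segment) if spec.inversion else -1
        for si, s in enumerate(range(0, L, spec.homology_segment)):
            e = min(s + spec.homology_segment, L)
            if srng.random() < spec.homology_gap_rate:
                continue
            strand = "-" if si == inv_target else "+"
            seg_rows.append([s, e, spec.chrom, s, e, strand, True])
        maps[sp] = HomologyMap(pd.DataFrame(seg_rows, columns=_HMAP_COLS), sp)

    # gene density: gene-rich in A blocks, at 100-kb bins (orients PC1)
    gd = {}
    for sp in spec.species:
        n100 = L // 100_000
        centers = np.arange(n100) * 100_000 + 50_000
        sgn = np.zeros(n100, dtype=int)
        for s, e, sign in blocks[sp]:
            sgn[(centers >= s) & (centers < e)] = sign
        grng = np.random.default_rng([spec.seed, 13, spec.species.index(sp)])
        gd[sp] = grng.poisson(np.where(sgn > 0, 3.0, 0.5))

    truth = PlantedTruth(blocks, bounds, hs_bounds, loops, promoters, maps, gd)
    return SpeciesSet(spec, truth)


def simulate_expression(
    truth: PlantedTruth,
    species: tuple[str, ...],
    class_effects: dict[str, float] | None = None,
    gene_classes: dict[str, str] | None = None,
    scale_factors: dict[str, float] | None = None,
    n_genes: int = 4000,
    n_reps: int = 2,
    base_mean: float = 6.0,
    base_sd: float = 1.5,
    species_sd: float = 0.4,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict[str, float]]:
    """Log-normal TPM table with planted class divergence and scale factors.

    Genes carry a log2 base level ~ N(base_mean, base_sd); each species adds
    an effect ~ N(0, species_sd * multiplier(class)); replicates add noise.
    Sample columns are multiplied by their planted linear scale factor.
    Returns (TPM table, sample->species map, sample->factor map).
    """
    rng = np.random.default_rng([seed, 17])
    genes = [f"g{k:04d}" for k in range(n_genes)]
    gene_classes = gene_classes or {}
    class_effects = class_effects or {}
    samples = [f"{sp}_r{r}" for sp in species for r in range(1, n_reps + 1)]
    species_of = pd.Series({s: s.rsplit("_r", 1)[0] for s in samples})
    if scale_factors is None:
        defaults = [1.0, 2.0, 4.0]
        scale_factors = {s: defaults[k % 3] for k, s in enumerate(samples)}
    base = rng.normal(base_mean, base_sd, size=n_genes)
    mult = np.array([class_effects.get(gene_classes.get(g, ""), 1.0) for g in genes])
    log2 = np.empty((n_genes, len(samples)))
    sp_eff = {
        sp: rng.normal(0.0, species_sd, size=n_genes) * mult for sp in species
    }
    for c, s in enumerate(samples):
        sp = species_of[s]
        log2[:, c] = (
            base
            + sp_eff[sp]
            + rng.normal(0.0, noise_sd, size=n_genes)
            + np.log2(scale_factors[s])
        )
    tpm = pd.DataFrame(2.0 ** log2, index=genes, columns=samples)
    return tpm, species_of, scale_factors


def simulate_fixtures(
    truth: PlantedTruth,
    universe_bins: np.ndarray,
    target_bins: np.ndarray,
    har_rate: float = 0.1,
    har_density_ratio: float = 1.0,
    n_tfs: int = 20,
    planted_pair: tuple[str, str] = ("TF_E0", "TF_P0"),
    cooc_hs: float = 0.8,
    cooc_cons: float = 0.1,
    n_hs_peis: int = 40,
    n_cons_peis: int = 40,
    seed: int = 0,
    resolution: int = 10_000,
):
    """HAR placements, motif-hit tables and a PPI graph with planted signal.

    HARs land in each universe enhancer bin with probability ``har_rate``,
    multiplied by ``har_density_ratio`` for bins in the target set.  Motif
    hits give the planted enhancer-TF/promoter-TF pair a per-PEI
    co-occurrence probability of ``cooc_hs`` in HS PEIs vs ``cooc_cons`` in
    conserved ones, on a background of independent random hits; the PPI graph
    is a random simple graph guaranteed to contain the planted pair as a
    direct edge.
    """
    import networkx as nx

    from .peis import RegionSet

    rng = np.random.default_rng([seed, 23])
    universe_bins = np.asarray(universe_bins)
    in_target = np.isin(universe_bins, np.asarray(target_bins))
    p = np.clip(har_rate * np.where(in_target, har_density_ratio, 1.0), 0, 1)
    hit = rng.random(universe_bins.size) < p
    starts = universe_bins[hit] * resolution + resolution // 4
    hars = RegionSet("HAR", starts, starts + 200)

    tf_names = [planted_pair[0], planted_pair[1]] + [f"TF{k}" for k in range(n_tfs - 2)]
    pei_hits = {"HS": [], "Cons": []}
    for cls, n_peis, cooc in (("HS", n_hs_peis, cooc_hs), ("Cons", n_cons_peis, cooc_cons)):
        for _ in range(n_peis):
            enh = {t for t in tf_names if rng.random() < 0.15}
            prom = {t for t in tf_names if rng.random() < 0.15}
            if rng.random() < cooc:
                enh.add(planted_pair[0])
                prom.add(planted_pair[1])
            else:
                enh.discard(planted_pair[0])
                prom.discard(planted_pair[1])
            pei_hits[cls].append((enh, prom))

    ppi = nx.gnm_random_graph(n_tfs, 3 * n_tfs, seed=int(rng.integers(2**31)))
    ppi = nx.relabel_nodes(ppi, dict(enumerate(tf_names)))
    ppi.add_edge(*planted_pair)
    ppi.remove_edges_from(nx.selfloop_edges(ppi))
    return {"hars": hars, "pei_hits": pei_hits, "ppi": ppi, "tf_names": tf_names}
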