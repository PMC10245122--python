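# hicevo

Comparative 3D-genome analysis across species, for researchers studying how
chromatin architecture evolves. Given binned intra-chromosomal Hi-C contact
matrices from several species (one designated the reference, typically
human), plus standard annotation tracks, `hicevo` identifies the three layers
of chromatin organization and classifies each as conserved or
reference-specific across the phylogeny:

- **A/B compartments** via the *A-B index*: low-resolution (100-kb) PC1
  labels oriented by gene density, then a 20-kb score
  `AB(i) = A_score(i) − B_score(i)` where `A_score` is the bin's
  observed/expected contact with the low-resolution A compartment regions
  (positive ⇒ A-like). Homologous bins across species are clustered into
  evolutionary states and grouped as CA / WCA / CB / WCB / NC by the
  per-species fraction of A-status bins (>90 % in all species ⇒ conserved A,
  70–90 % ⇒ weakly conserved A, symmetric for B).
- **TADs** via the insulation score (sliding 260-kb square, mean mode,
  log2-normalized to the chromosome mean; delta-vector zero crossings with
  noise threshold 0.5), with
  `TADstrength = median_d( median intra-TAD(d) / median inter-TAD(d) )`
  over the TAD's own length of genomic distances. A reference boundary
  lifted through a homology map is *conserved* with a query species when a
  query boundary lies within 40 kb, *specific* when none lies within 100 kb;
  conserved (specific) against all queries ⇒ species-conserved
  (human-specific). TADs inherit labels from their flanking boundaries.
- **Promoter–enhancer interactions (PEIs)** at 10 kb: every bin within
  ±10 Mb of a promoter anchor (promoter = TSS −2200/+500 bp) is tested
  against a domain-aware background (distance decay rescaled per TAD) with
  an upper-tail Poisson p-value, Benjamini–Hochberg FDR ≤ 0.001, length
  ≥ 20 kb, promoter–promoter pairs dropped. Conservation combines a
  two-dimensional anchor-distance judgment `d < min(r1·|i−j|, r2)`
  (r1 = 0.2; r2 = 20 kb for the conservation test, 50 kb for the specificity
  test) with a signal-enrichment judgment against the 20th percentile of the
  query species' own PEI enrichment scores (observed − expected).

Around these sit the supporting analyses used in cross-species studies:
KR-style matrix balancing, O/E transformation, quantile normalization and
binomial down-sampling; aggregate TAD maps and APA loop scoring; HAR/SNP
permutation and Fisher enrichment tests; conserved-rank expression scaling
(1000 anchor genes) with cross-species CV; and a TF-pair inference framework
(motif occurrence ≥ 3, TPM > 1, direct/indirect PPI, one-sided Mann–Whitney
at p < 0.05, preference by |Δ(−log10 p)| > 5).

Everything is exercisable without external data: `hicevo.synthetic`
generates multi-species contact maps with a power-law distance decay,
compartment checkerboard, TAD blocks, focal loops and Poisson counting
noise, with planted species-specific differences wired through blockwise
homology maps, so every classifier can be scored against known truth.

## Worked example

Simulate the default three-species study conditions (one 40-Mb chromosome,
10⁵ contacts per species, 2× compartment contrast, TAD enrichment γ = 2) and
run all stages:

```
$ hicevo run --seed 11 --out demo
{
 "ab_sign_agreement_pct": {"human": 99.45, "queryB": 98.1, "queryC": 92.7},
 "evostates": {"conserved_fraction_pct": 59.588, "flag": "", "k": 7,
               "k_elbow": 4, "n_homologous_bins": 1700},
 "peis": {"n_called": {"human": 0, "queryB": 0, "queryC": 0},
          "n_human_specific": 0, "n_species_conserved": 0},
 "tads": {"boundary_precision": 0.9844, "boundary_recall": 0.9692,
          "n_boundaries": {"human": 64, "queryB": 55, "queryC": 52},
          "n_human_specific": 10, "n_species_conserved": 42}
}
```

Reading the output: the recovered A-B index assigns the planted compartment
sign to 92–99 % of 20-kb bins per species; 1700 of 2000 reference bins lift
reciprocally into both query species and their seven K-means evolutionary
states put 59.6 % of homologous bins in conserved compartment groups;
insulation calling recovers the planted boundaries at 97 % recall / 98 %
precision, and lifting them into the query species labels 42 boundaries
species-conserved and 10 human-specific (20 % of planted boundaries were
deleted from the query species). No PEIs are called at this coverage —
10⁵ contacts spread over a 40-Mb chromosome leave well under one count per
10-kb pixel, so the Poisson caller correctly reports nothing. Interaction
calling needs dense maps; the bundled fixture concentrates the same depth on
a 1.5-Mb chromosome:

```python
from hicevo.synthetic import SimulationSpec, simulate_species_set
from hicevo.peis import call_peis
from hicevo.tads import TAD

spec = SimulationSpec(chrom_length=1_500_000, depth=100_000, n_loops=12,
                      loop_distance_range=(100_000, 300_000),
                      compartment_block_range=(400_000, 1_000_000),
                      tad_length_range=(300_000, 600_000), seed=1)
ss = simulate_species_set(spec)
bounds = list(ss.truth.boundaries["human"])
tads = [TAD(s, e, None, None)
        for s, e in zip([0] + bounds, bounds + [spec.chrom_length])]
peis, model = call_peis(ss.contact_map("human", 10_000),
                        ss.truth.promoters, tads)
print(len(peis), "PEIs at FDR <= 0.001;",
      sum(p.fdr < 1e-6 for p in peis), "below 1e-6")
```

which prints `11 PEIs at FDR <= 0.001; 11 below 1e-6` — every planted loop
present in the reference species is recovered at its exact pixel, with no
false calls.

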