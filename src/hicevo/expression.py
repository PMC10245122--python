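"""Cross-species expression normalization and variation statistics.

Expression of single-copy orthologous genes (TPM) is made comparable across
samples by conserved-rank scaling: after log2(TPM+1) transformation, genes
inside every sample's interquartile range are ranked within each sample, the
1000 genes with the most stable ranks (lowest across-sample rank variance)
become anchors, and each sample is shifted so its anchor median matches the
cross-sample mean of anchor medians.  A multiplicative library-scale factor
thus becomes an additive log2 shift that the procedure removes.

Downstream statistics: the per-gene coefficient of variation of species-mean
expression across species (CV), and expression contrasts between structure
classes (human-vs-other fold changes with t tests, and pairwise cross-species
Spearman correlation against divergence time with an exponential-decay fit
a*exp(-b*t)+c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .matrix import ContractError

__all__ = ["ScalingResult", "scale_normalize", "cross_species_cv", "class_expression_contrast"]


@dataclass
class ScalingResult:
    normalized: pd.DataFrame      # genes x samples, log2 scale
    shifts: pd.Series             # additive log2 shift applied per sample
    anchors: list[str]            # ids of the conserved-rank anchor genes

    @property
    def factors(self) -> pd.Series:
        """Equivalent multiplicative (linear-scale) factors, 2**shift."""
        return 2.0 ** self.shifts

    @property
    def normalized_linear(self) -> pd.DataFrame:
        return 2.0 ** self.normalized - 1.0


def scale_normalize(
    table: pd.DataFrame,
    n_anchor: int = 1000,
    pseudocount: float = 1.0,
    log_input: bool = False,
) -> ScalingResult:
    """Conserved-rank scaling of a genes x samples TPM table.

    ``log_input=True`` marks a table that is already log2-scale (used for
    idempotent re-application).  Genes must fall within [Q1, Q3] of every
    sample's log distribution to be rank-eligible; if fewer than ``n_anchor``
    qualify, all eligible genes are used with a warning.
    """
    if (np.asarray(table, dtype=float) < 0).any() and not log_input:
        raise ContractError("TPM values must be non-negative")
    log = table.astype(float) if log_input else np.log2(table.astype(float) + pseudocount)
    q1 = log.quantile(0.25)
    q3 = log.quantile(0.75)
    eligible = ((log >= q1) & (log <= q3)).all(axis=1)
    elig = log.loc[eligible]
    if elig.shape[0] < 3:
        raise ContractError("too few interquartile genes to anchor the scaling")
    ranks = elig.rank(axis=0, method="average")
    rank_var = ranks.var(axis=1, ddof=0)
    if elig.shape[0] < n_anchor:
        warnings.warn(
            f"only {elig.shape[0]} interquartile genes; using all as anchors"
        )
        anchors = list(elig.index)
    else:
        anchors = list(rank_var.nsmallest(n_anchor, keep="first").index)
    medians = log.loc[anchors].median()
    shifts = medians.mean() - medians
    normalized = log.add(shifts, axis=1)
    return ScalingResult(normalized, shifts, anchors)


def cross_species_cv(
    table: pd.DataFrame,
    species_of: dict[str, str] | pd.Series,
) -> pd.Series:
    """Per-gene CV (sd/mean, ddof=1) of species-mean expression.

    ``species_of`` maps sample name to species.  Genes whose species-mean
    average is zero get NaN (undefined CV).  Requires at least two species.
    """
    species_of = pd.Series(species_of)
    groups = table.T.groupby(species_of).mean().T  # genes x species
    if groups.shape[1] < 2:
        raise ContractError("CV needs at least two species")
    mean = groups.mean(axis=1)
    sd = groups.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    cv[mean == 0] = np.nan
    return cv


def _exp_decay(t, a, b, c):
    return a * np.exp(-b * t) + c


def class_expression_contrast(
    table: pd.DataFrame,
    species_of: dict[str, str] | pd.Series,
    gene_classes: dict[str, str] | pd.Series,
    divergence_times: dict[tuple[str, str], float] | None = None,
    ref_species: str = "human",
) -> pd.DataFrame:
    """Expression contrasts between structure classes.

    Per class: the mean reference-vs-other-species log-fold difference with a
    one-sample t test across genes, and — when ``divergence_times`` gives
    pairwise species divergence times — the pairwise cross-species Spearman
    correlations with fitted exponential-decay parameters (a, b, c) of
    correlation against time.  Classes with fewer than 3 genes yield NaN.
    """
    species_of = pd.Series(species_of)
    gene_classes = pd.Series(gene_classes)
    sp_means = table.T.groupby(species_of).mean().T
    others = [s for s in sp_means.columns if s != ref_species]
    rows = []
    for cls in sorted(gene_classes.unique()):
        genes = gene_classes.index[gene_classes == cls]
        genes = [g for g in genes if g in table.index]
        rec = {"class": cls, "n_genes": len(genes)}
        if len(genes) < 3:
            warnings.warn(f"class {cls}: fewer than 3 genes; NA")
            rec.update({"ref_log_fold": np.nan, "t_p": np.nan})
            rows.append(rec)
            continue
        diff = sp_means.loc[genes, ref_species] - sp_means.loc[genes, others].mean(axis=1)
        t, p = stats.ttest_1samp(diff, 0.0)
        rec["ref_log_fold"] = float(diff.mean())
        rec["t_p"] = float(p)
        if divergence_times:
            ts, rs = [], []
            cols = list(sp_means.columns)
            for i, s1 in enumerate(cols):
                for s2 in cols[i + 1 :]:
                    t_div = divergence_times.get((s1, s2), divergence_times.get((s2, s1)))
                    if t_div is None:
                        continue
                    rho = stats.spearmanr(
                        sp_means.loc[genes, s1], sp_means.loc[genes, s2]
                    )[0]
                    ts.append(t_div)
                    rs.append(rho)
            rec["pairwise_rho"] = rs
            rec["pairwise_t"] = ts
            if len(ts) >= 3:
                try:
                    popt, _ = optimize.curve_fit(
                        _exp_decay,
                        np.array(ts),
                        np.array(rs),
                        p0=(0.5, 0.01, 0.5),
                        bounds=([0, 0, -1], [2, 10, 1]),
                        maxfev=10000,
                    )
                    rec["decay_a"], rec["decay_b"], rec["decay_c"] = map(float, popt)
                except RuntimeError:
                    rec["decay_a"] = rec["decay_b"] = rec["decay_c"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
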