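"""TF binding preference and TF-pair inference for PEI formation.

Given externally produced motif-enrichment p-values, motif occurrence tables,
TF expression and a protein-protein interaction network, this module (1)
scores each TF's preference for human-specific vs species-conserved PEIs by
the difference of -log10 enrichment p-values (|delta| > 5), (2) proposes
enhancer-TF / promoter-TF pairs that pass occurrence (>= 3 hits) and
expression (TPM > 1) filters and are connected in the PPI network directly or
through one intermediate protein, (3) keeps pairs whose per-PEI co-occurrence
is higher in human-specific than conserved PEIs by a one-sided Mann-Whitney U
test (p < 0.05, exact by permutation enumeration at small n), and (4)
compares binding-site sequence conservation (phastCons) between PEI classes
per TF.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TFPreference",
    "tf_preference",
    "candidate_tf_pairs",
    "mannwhitney_exact",
    "pair_preference_test",
    "cooccurrence_vectors",
    "binding_site_conservation",
]


@dataclass(frozen=True)
class TFPreference:
    tf: str
    neglog_p_hs: float
    neglog_p_cons: float
    delta: float
    preference: str  # HS | Cons | neutral


def tf_preference(
    enrichment: pd.DataFrame,
    delta_cut: float = 5.0,
    p_floor: float = 1e-300,
) -> list[TFPreference]:
    """Class preference per TF from motif-enrichment p-values.

    ``enrichment`` needs columns ``tf``, ``p_hs``, ``p_cons``.  delta =
    -log10(p_hs) + log10(p_cons); strictly above ``delta_cut`` is
    HS-preferring, strictly below its negative Cons-preferring.
    """
    out = []
    for _, row in enrichment.iterrows():
        lh = -np.log10(max(float(row.p_hs), p_floor))
        lc = -np.log10(max(float(row.p_cons), p_floor))
        delta = lh - lc
        pref = "HS" if delta > delta_cut else ("Cons" if delta < -delta_cut else "neutral")
        out.append(TFPreference(row.tf, lh, lc, float(delta), pref))
    return out


def candidate_tf_pairs(
    hits: pd.DataFrame,
    expression: dict[str, float] | pd.Series,
    ppi: nx.Graph,
    min_occ: int = 3,
    min_tpm: float = 1.0,
) -> pd.DataFrame:
    """Enhancer-TF x promoter-TF candidates passing occurrence/expression/PPI.

    ``hits`` needs columns ``tf``, ``region_id``, ``role`` (promoter |
    enhancer), ``count``.  A TF is eligible for a role when its total
    occurrences in that role reach ``min_occ``; its expression must strictly
    exceed ``min_tpm``.  A pair is kept when the PPI shortest path between
    the two TFs is 1 (direct) or 2 (indirect, one intermediate protein).
    """
    expression = pd.Series(expression)
    occ = hits.groupby(["tf", "role"])["count"].sum()

    def eligible(role: str) -> list[str]:
        tfs = [t for (t, r), c in occ.items() if r == role and c >= min_occ]
        out = []
        for t in tfs:
            if t not in expression.index:
                import warnings

                warnings.warn(f"TF {t} absent from expression table; excluded")
                continue
            if expression[t] > min_tpm:
                out.append(t)
        return out

    enh_tfs = eligible("enhancer")
    prom_tfs = eligible("promoter")
    rows = []
    for e_tf in enh_tfs:
        if e_tf not in ppi:
            continue
        reach = nx.single_source_shortest_path_length(ppi, e_tf, cutoff=2)
        for p_tf in prom_tfs:
            mode = {1: "direct", 2: "indirect"}.get(reach.get(p_tf, 99))
            if mode:
                rows.append({"enhancer_tf": e_tf, "promoter_tf": p_tf, "ppi_mode": mode})
    return pd.DataFrame(rows, columns=["enhancer_tf", "promoter_tf", "ppi_mode"])


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mannwhitney_exact(
    x: np.ndarray, y: np.ndarray, alternative: str = "greater", max_enum: int = 200_000
) -> float:
    """One-sided Mann-Whitney p by full permutation enumeration (tie-safe).

    Enumerates every assignment of the pooled observations to the two groups
    and counts assignments with U at least as extreme as observed.  Falls
    back to the normal approximation with tie correction when the number of
    assignments exceeds ``max_enum``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if comb(n1 + n2, n1) > max_enum:
        return float(stats.mannwhitneyu(x, y, alternative=alternative).pvalue)
    pooled = np.concatenate([x, y])
    u_obs = _u_statistic(x, y)
    count = 0
    total = 0
    idx = np.arange(n1 + n2)
    for pick in combinations(idx, n1):
        sel = np.zeros(n1 + n2, dtype=bool)
        sel[list(pick)] = True
        u = _u_statistic(pooled[sel], pooled[~sel])
        if alternative == "greater":
            count += u >= u_obs
        elif alternative == "less":
            count += u <= u_obs
        else:
            mid = n1 * n2 / 2
            count += abs(u - mid) >= abs(u_obs - mid)
        total += 1
    return count / total


def cooccurrence_vectors(
    pair: tuple[str, str],
    pei_hits: list[tuple[set[str], set[str]]],
) -> np.ndarray:
    """Binary per-PEI indicator: enhancer-TF in the enhancer AND promoter-TF
    in the promoter of that PEI."""
    e_tf, p_tf = pair
    return np.array(
        [1.0 if (e_tf in enh and p_tf in prom) else 0.0 for enh, prom in pei_hits]
    )


def pair_preference_test(
    hs_indicator: np.ndarray,
    cons_indicator: np.ndarray,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> tuple[float, bool]:
    """One-sided Mann-Whitney of per-PEI co-occurrence, HS vs conserved.

    Returns (p, keep) with keep = p < alpha.  Either set empty => (nan,
    False).
    """
    hs_indicator = np.asarray(hs_indicator, dtype=float)
    cons_indicator = np.asarray(cons_indicator, dtype=float)
    if hs_indicator.size == 0 or cons_indicator.size == 0:
        return float("nan"), False
    p = mannwhitney_exact(hs_indicator, cons_indicator, alternative=alternative)
    return float(p), bool(p < alpha)


def binding_site_conservation(
    scores: pd.DataFrame,
    min_hits: int = 3,
) -> pd.DataFrame:
    """Per-TF Wilcoxon rank-sum of phastCons scores, HS vs conserved PEIs.

    ``scores`` needs columns ``tf``, ``pei_class`` (HS | Cons) and ``score``.
    Reports the test p and the direction (sign of HS median minus Cons
    median); TFs with fewer than ``min_hits`` in either class get NaN.
    """
    rows = []
    for tf, grp in scores.groupby("tf"):
        hs = grp.loc[grp.pei_class == "HS", "score"].to_numpy()
        cons = grp.loc[grp.pei_class == "Cons", "score"].to_numpy()
        if len(hs) < min_hits or len(cons) < min_hits:
            rows.append({"tf": tf, "p": np.nan, "direction": np.nan})
            continue
        p = float(stats.mannwhitneyu(hs, cons, alternative="two-sided").pvalue)
        direction = float(np.sign(np.median(hs) - np.median(cons)))
        rows.append({"tf": tf, "p": p, "direction": direction})
    return pd.DataFrame(rows)
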