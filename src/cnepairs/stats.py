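"""Enrichment statistics: odds ratios, one-sided Fisher tests, BH-FDR, Wilcoxon.

The group-in-unit enrichment screen cross-tabulates group membership against
SOM-unit membership, reports the odds ratio

    OR = (N_ij / N_ij') / (N_i'j / N_i'j'),

tests overrepresentation with a one-sided (greater) Fisher exact test, and
adjusts the whole group x unit family with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_SIGNED_RANK_MAX_N = 25
EXACT_RANK_SUM_MAX_N = 12


def odds_ratio(table) -> float:
    """Odds ratio of a 2x2 table ((n11, n10), (n01, n00)).

    n11=0 -> 0; n01=0 with n11>0 -> +inf; 0/0 branches -> NaN (flagged
    undefined by callers).
    """
    (n11, n10), (n01, n00) = table
    if min(n11, n10, n01, n00) < 0:
        raise ValueError("contingency counts must be nonnegative")
    if n11 + n10 + n01 + n00 == 0:
        raise ValueError("empty contingency table")
    nan, inf = float("nan"), float("inf")
    odds1 = nan if (n11 == 0 and n10 == 0) else (inf if n10 == 0 else n11 / n10)
    odds2 = nan if (n01 == 0 and n00 == 0) else (inf if n00 == 0 else n01 / n00)
    if np.isnan(odds1) or np.isnan(odds2):
        return nan
    if np.isinf(odds1):
        return nan if np.isinf(odds2) else inf
    if np.isinf(odds2):
        return 0.0
    if odds2 == 0:
        return inf if odds1 > 0 else nan
    return odds1 / odds2


def fisher_one_sided(table) -> float:
    """One-sided (enrichment / "greater") Fisher exact p-value.

    P[X >= n11] under the hypergeometric null with the table's margins fixed.
    """
    (n11, n10), (n01, n00) = table
    N = n11 + n10 + n01 + n00
    r = n11 + n10   # group size
    c = n11 + n01   # unit size
    return float(sps.hypergeom.sf(n11 - 1, N, r, c))


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Wilcoxon tests
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(x, y=None) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (Wilcoxon's original treatment); ties get
    midranks.  Exact null distribution for n <= 25 nonzero differences
    without ties, normal approximation with continuity correction otherwise.
    Identical samples (no nonzero differences) return p = 1.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= EXACT_SIGNED_RANK_MAX_N and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True,
                       alternative="two-sided", method=method)
    return float(res.pvalue)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact for both sample sizes <= 12 without ties; otherwise normal
    approximation with continuity correction and midrank ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = max(len(x), len(y)) <= EXACT_RANK_SUM_MAX_N and not has_ties
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic",
                           use_continuity=True)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# group x unit enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRecord:
    group: object
    unit: object
    n_group_unit: int
    odds_ratio: float
    p: float
    fdr: float
    flags: str = ""


def group_unit_enrichment(groups, units) -> pd.DataFrame:
    """Enrichment of every group in every SOM unit.

    ``groups`` and ``units`` are equal-length per-pair label sequences.
    For each (group g, unit u): n11 = pairs in g assigned to u, etc.; odds
    ratio, one-sided Fisher p, BH-FDR across the full g x u family.  Units
    with no members yield flagged rows with undefined statistics.
    """
    groups = np.asarray(groups)
    units = np.asarray(units)
    if len(groups) != len(units):
        raise ValueError("groups and units must align")
    rows = []
    for g in sorted(set(groups.tolist())):
        in_g = groups == g
        for u in sorted(set(units.tolist())):
            in_u = units == u
            n11 = int(np.sum(in_g & in_u))
            n10 = int(np.sum(in_g & ~in_u))
            n01 = int(np.sum(~in_g & in_u))
            n00 = int(np.sum(~in_g & ~in_u))
            flags = ""
            if n11 + n01 == 0:
                flags = "empty_unit"
            table = ((n11, n10), (n01, n00))
            orv = odds_ratio(table)
            p = fisher_one_sided(table)
            rows.append([g, u, n11, orv, p, flags])
    df = pd.DataFrame(rows, columns=["group", "unit", "n_group_unit",
                                     "odds_ratio", "p", "flags"])
    df["fdr"] = fdr_bh(df["p"].to_numpy())
    return df[["group", "unit", "n_group_unit", "odds_ratio", "p", "fdr", "flags"]]


def compare_groups(values, groups) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests of a numeric column between groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            va = values[(groups == a) & np.isfinite(values)]
            vb = values[(groups == b) & np.isfinite(values)]
            if len(va) == 0 or len(vb) == 0:
                continue
            rows.append([a, b, float(np.median(va)), float(np.median(vb)),
                         wilcoxon_rank_sum(va, vb)])
    return pd.DataFrame(rows, columns=["group_a", "group_b", "median_a",
                                       "median_b", "p"])
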