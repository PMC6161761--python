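"""Core pair statistics: nRDD, nRTD, decile groups, TSS distance, conservation.

The genome-size-normalized relative distance difference for a pair with
present-day midpoint distance ``d_h`` (genome size ``G_h``) and ancestral
distance ``d_r`` (ancestral genome size ``G_r``) is

    nRDD = (d_h/G_h - d_r/G_r) / ((d_h/G_h + d_r/G_r) / 2).

It is a relative difference of genome-size-normalized distances, so it is
bounded in (-2, 2): -2 is reached only in the limit of complete loss, +2 in
the limit of appearance from nothing.  Negative values are contractions
relative to the ancestor, positive values expansions.  nRTD applies the same
form to the transposon-annotated base pairs within the midpoint span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Estimated genome size of the common mammalian ancestor (bp).
ANCESTRAL_GENOME_SIZE = 3_270_000_000


@dataclass(frozen=True)
class GenomeSizes:
    """Present-day (focal) and ancestral genome sizes in bp."""

    G_h: float
    G_r: float = ANCESTRAL_GENOME_SIZE

    def __post_init__(self):
        if self.G_h <= 0 or self.G_r <= 0:
            raise ValueError("genome sizes must be positive")


def nrdd(d_h, d_r, sizes: GenomeSizes):
    """Genome-size-normalized relative distance difference, in (-2, 2).

    Accepts scalars or arrays; requires strictly positive distances.
    """
    d_h = np.asarray(d_h, dtype=float)
    d_r = np.asarray(d_r, dtype=float)
    if np.any(d_h <= 0) or np.any(d_r <= 0):
        raise ValueError("nRDD requires strictly positive distances")
    a = d_h / sizes.G_h
    b = d_r / sizes.G_r
    out = (a - b) / ((a + b) / 2.0)
    return float(out) if out.ndim == 0 else out


def nrtd(T_h, T_r, sizes: GenomeSizes):
    """nRDD-form statistic on transposon-annotated lengths.

    ``T_h = T_r = 0`` (a transposon-free region in both genomes) is undefined
    and returned as NaN so downstream summaries can exclude it; -2 / +2 mark
    complete loss / pure gain.
    """
    T_h = np.asarray(T_h, dtype=float)
    T_r = np.asarray(T_r, dtype=float)
    if np.any(T_h < 0) or np.any(T_r < 0):
        raise ValueError("nRTD requires nonnegative transposon lengths")
    a = T_h / sizes.G_h
    b = T_r / sizes.G_r
    denom = (a + b) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (a - b) / np.where(denom > 0, denom, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def decile_groups(values, ids=None, n_groups: int = 10) -> np.ndarray:
    """Split pairs into ``n_groups`` equal-sized groups by increasing value.

    Group 1 holds the lowest values (strongest contractions), group
    ``n_groups`` the highest (strongest expansions).  With ``n = q*n_groups
    + r`` the first ``r`` groups take the extra element.  Ties are broken by
    pair id, then input order, for determinism.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < n_groups:
        raise ValueError(f"need >= {n_groups} values, got {n}")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)
    order = np.lexsort((ids, values))  # stable: value, then id
    base, rem = divmod(n, n_groups)
    sizes = np.full(n_groups, base, dtype=int)
    sizes[:rem] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    groups = np.empty(n, dtype=int)
    for g in range(n_groups):
        groups[order[bounds[g]:bounds[g + 1]]] = g + 1
    return groups


def group_bin(group: int) -> str:
    """Coarse contraction/conservation/expansion bin of a decile group."""
    if group <= 3:
        return "1-3"
    if group <= 7:
        return "4-7"
    return "8-10"


def tss_distance(pair_span_midpoint: tuple[str, int],
                 tss_positions: list[tuple[str, int]]) -> float:
    """Distance (bp) from a pair-span midpoint to the nearest TSS.

    ``pair_span_midpoint`` is (chrom, position) of the midpoint of the
    complete pair sequence [left.start, right.end).  Returns NaN when the
    chromosome carries no TSS.
    """
    chrom, mid = pair_span_midpoint
    positions = [p for c, p in tss_positions if c == chrom]
    if not positions:
        return float("nan")
    return float(min(abs(p - mid) for p in positions))


def mean_conservation(cne_interval, score_track) -> float:
    """Base-weighted mean per-base conservation score over a CNE.

    Bases absent from the score track count as 0.
    """
    return score_track.mean_over(cne_interval)
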