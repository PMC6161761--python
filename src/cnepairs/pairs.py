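"""From raw conserved-element sets to classified CNE-CNE pairs.

The processing order mirrors the element-set construction: merge elements
closer than 100 bp, drop elements shorter than 100 bp, classify each element
against protein-coding gene annotation (exon > UTR > intron > intergenic
precedence; anything but exon is a CNE), emit pairs of adjacent elements
where both members are noncoding and neither exceeds 1,000 bp, attach
reciprocal-best-hit orthologs, and classify conservation depth.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from .io import GenomicInterval, GtfFeature

logger = logging.getLogger(__name__)

MERGE_GAP = 100          # adjacent elements closer than this are merged
MIN_ELEMENT_LEN = 100    # post-merge elements shorter than this are dropped
MAX_PAIR_MEMBER_LEN = 1000
MAX_ORTHOLOG_DISTANCE = 250_000

#: Nonmammalian vertebrates counted toward "deeply conserved" status.
DEEP_SPECIES = ("lizard", "turtle", "chicken", "zebra_finch", "frog", "fugu", "zebrafish")


@dataclass
class ConservedElement:
    element_id: str
    interval: GenomicInterval
    category: str = "unclassified"  # exon | UTR | intron | intergenic

    @property
    def is_cne(self) -> bool:
        return self.category != "exon"


@dataclass
class CNEPair:
    pair_id: str
    left: ConservedElement
    right: ConservedElement
    conservation: str = "unset"      # mammalian | deeply | both | neither
    nrdd_group: int | None = None
    species_distance: dict[str, float] = field(default_factory=dict)

    @property
    def chrom(self) -> str:
        return self.left.interval.chrom

    @property
    def inter_cne(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.left.interval.end, self.right.interval.start)

    @property
    def d_h(self) -> int:
        """Midpoint-to-midpoint distance in the focal genome."""
        return self.right.interval.midpoint - self.left.interval.midpoint

    @property
    def span(self) -> GenomicInterval:
        """Complete pair sequence, outer edge to outer edge."""
        return GenomicInterval(self.chrom, self.left.interval.start, self.right.interval.end)

    @property
    def midpoint_span(self) -> GenomicInterval:
        """Midpoint-to-midpoint span (transposon length convention)."""
        return GenomicInterval(self.chrom, self.left.interval.midpoint,
                               self.right.interval.midpoint)


# ---------------------------------------------------------------------------
# merge & filter
# ---------------------------------------------------------------------------

def merge_and_filter(intervals, gap: int = MERGE_GAP,
                     min_len: int = MIN_ELEMENT_LEN) -> list[GenomicInterval]:
    """Merge elements with inter-element distance < ``gap``, then drop short ones.

    Merging is transitive left-to-right on the sorted set; post-merge elements
    shorter than ``min_len`` are removed.  Unsorted input is sorted (logged).
    """
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = by_chrom[chrom]
        if any(ivs[i].start > ivs[i + 1].start for i in range(len(ivs) - 1)):
            logger.info("unsorted elements on %s; sorting internally", chrom)
            ivs = sorted(ivs, key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_e < gap:
                cur_e = max(cur_e, iv.end)
            else:
                if cur_e - cur_s >= min_len:
                    out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        if cur_e - cur_s >= min_len:
            out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_PRECEDENCE = ("exon", "UTR", "intron", "intergenic")


def element_id(iv: GenomicInterval) -> str:
    """Coordinate-based element identifier, shared with hit-table query ids."""
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def classify_elements(intervals, features: list[GtfFeature]) -> list[ConservedElement]:
    """Assign each element its highest-precedence annotation category.

    Precedence (descending): exon, UTR, intron, intergenic.  Only
    protein-coding genes count; introns are gene bodies minus exons/UTRs
    (any within-gene overlap that is not exon/UTR).  Element ids are
    coordinate keys (chrom:start-end), matching hit-table query ids.
    """
    coding = [f for f in features if f.gene_type == "protein_coding"]
    exon = _merged({f.interval for f in coding if f.feature == "exon"})
    utr = _merged({f.interval for f in coding if f.feature == "UTR"})
    gene = _merged({f.interval for f in coding if f.feature == "gene"})

    out = []
    for iv in intervals:
        if _overlaps_any(iv, exon):
            cat = "exon"
        elif _overlaps_any(iv, utr):
            cat = "UTR"
        elif _overlaps_any(iv, gene):
            cat = "intron"
        else:
            cat = "intergenic"
        out.append(ConservedElement(element_id(iv), iv, cat))
    return out


def _merged(ivs) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in ivs:
        by_chrom[iv.chrom].append((iv.start, iv.end))
    out = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        ms, me = [], []
        for s, e in spans:
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        out[chrom] = (np.array(ms), np.array(me))
    return out


def _overlaps_any(iv: GenomicInterval, merged) -> bool:
    if iv.chrom not in merged:
        return False
    ms, me = merged[iv.chrom]
    i = np.searchsorted(ms, iv.end)  # first span starting at/after iv.end
    return bool(i > 0 and me[i - 1] > iv.start)


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def build_pairs(elements: list[ConservedElement],
                max_member_len: int = MAX_PAIR_MEMBER_LEN) -> list[CNEPair]:
    """Emit CNE-CNE pairs from classified elements.

    Adjacency is computed over ALL conserved elements (coding included); a
    pair is kept only when both members are noncoding and neither exceeds
    ``max_member_len``.  The inter-CNE interval is [left.end, right.start).
    """
    by_chrom: dict[str, list[ConservedElement]] = defaultdict(list)
    for el in elements:
        by_chrom[el.interval.chrom].append(el)
    pairs = []
    k = 0
    for chrom in sorted(by_chrom):
        els = sorted(by_chrom[chrom], key=lambda e: (e.interval.start, e.interval.end))
        for left, right in zip(els, els[1:]):
            if not (left.is_cne and right.is_cne):
                continue
            if left.interval.length > max_member_len or right.interval.length > max_member_len:
                continue
            if left.interval.end > right.interval.start:
                continue  # overlapping elements cannot form a spaced pair
            pairs.append(CNEPair(f"pair{k:06d}", left, right))
            k += 1
    return pairs


# ---------------------------------------------------------------------------
# orthology (reciprocal best hits)
# ---------------------------------------------------------------------------

def rbh_orthologs(hits_forward: pd.DataFrame, hits_reverse: pd.DataFrame,
                  query_intervals: dict[str, GenomicInterval]) -> dict[str, dict[str, GenomicInterval]]:
    """Reciprocal-best-hit ortholog map: element id -> species -> interval.

    For each (query, species): take the highest-scoring forward hit; accept
    it iff the highest-scoring reverse hit of that target interval overlaps
    (>= 1 bp) the original query interval.  Best-hit score ties break by
    (higher score, smaller target start, lexicographic chrom); logged.
    """
    rev_best = _best_by_query(hits_reverse)
    fwd_best = _best_by_query(hits_forward)
    out: dict[str, dict[str, GenomicInterval]] = defaultdict(dict)
    for (query, species), row in fwd_best.items():
        target = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
        target_id = _target_key(species, target)
        back = rev_best.get((target_id, "focal"))
        if back is None:
            continue
        back_iv = GenomicInterval(back["chrom"], int(back["start"]), int(back["end"]))
        qiv = query_intervals.get(query)
        if qiv is not None and back_iv.overlap_length(qiv) >= 1:
            out[query][species] = target
    return dict(out)


def _best_by_query(hits: pd.DataFrame) -> dict[tuple[str, str], dict]:
    best: dict[tuple[str, str], dict] = {}
    ties = 0
    for row in hits.to_dict("records"):
        key = (row["query"], row["species"])
        cur = best.get(key)
        if cur is None:
            best[key] = row
            continue
        cand = (-row["score"], row["start"], row["chrom"])
        incumbent = (-cur["score"], cur["start"], cur["chrom"])
        if row["score"] == cur["score"]:
            ties += 1
        if cand < incumbent:
            best[key] = row
    if ties:
        logger.info("broke %d best-hit score ties deterministically", ties)
    return best


def _target_key(species: str, iv: GenomicInterval) -> str:
    """Identifier under which a target interval appears as a reverse query."""
    return f"{species}:{iv.chrom}:{iv.start}-{iv.end}"


# ---------------------------------------------------------------------------
# conservation classification
# ---------------------------------------------------------------------------

def ortholog_pair_distances(pair: CNEPair,
                            ortholog_map: dict[str, dict[str, GenomicInterval]],
                            species: list[str]) -> dict[str, float]:
    """Midpoint distance between the two CNE orthologs per species.

    Only species where both CNEs have orthologs on the same chromosome get a
    distance.  The focal-species distance is the pair's own ``d_h``.
    """
    left = ortholog_map.get(pair.left.element_id, {})
    right = ortholog_map.get(pair.right.element_id, {})
    out = {}
    for sp in species:
        a, b = left.get(sp), right.get(sp)
        if a is None or b is None or a.chrom != b.chrom:
            continue
        out[sp] = float(abs(b.midpoint - a.midpoint))
    return out


def classify_conservation(pairs: list[CNEPair],
                          ortholog_map: dict[str, dict[str, GenomicInterval]],
                          species: list[str],
                          focal: str = "human",
                          deep_species: tuple[str, ...] = DEEP_SPECIES,
                          max_distance: int = MAX_ORTHOLOG_DISTANCE) -> list[CNEPair]:
    """Attach per-species distances and a conservation category to each pair.

    A pair is conserved in species S iff both CNEs have orthologs in S on
    the same chromosome at midpoint distance <= 250,000 bp.  Any species
    with ortholog distance above the cap discards the pair entirely (likely
    misassigned orthology or rearrangement).  Categories: "mammalian"
    (conserved in platypus), "deeply" (conserved in >= 2 nonmammalian
    vertebrates), "both", or "neither".
    """
    kept = []
    for pair in pairs:
        dists = ortholog_pair_distances(pair, ortholog_map, species)
        dists[focal] = float(pair.d_h)
        if any(d > max_distance for d in dists.values()):
            continue
        pair.species_distance = dists
        mammalian = "platypus" in dists
        deep = sum(1 for sp in deep_species if sp in dists) >= 2
        pair.conservation = {
            (True, True): "both",
            (True, False): "mammalian",
            (False, True): "deeply",
            (False, False): "neither",
        }[(mammalian, deep)]
        kept.append(pair)
    return kept


# ---------------------------------------------------------------------------
# AO pairs (two-genome orthologous pairs)
# ---------------------------------------------------------------------------

def find_ao_pairs(pairs_a: list[CNEPair], pairs_b: list[CNEPair],
                  ortholog_map_ab: dict[str, dict[str, GenomicInterval]],
                  species_b: str,
                  elements_b: list[ConservedElement]) -> list[tuple[str, str, str]]:
    """Adjacent-orthologous pairs between two genomes, with 9-way categories.

    A pair in genome A is an AO pair iff (1) both its CNEs have orthologs in
    genome B, (2) those orthologs are adjacent in B (no conserved element in
    between), and (3) the orthologs were themselves identified as a pair in
    B.  Returns (pair_id_A, pair_id_B, category) with categories like
    "H1-3; M8-10" from the coarse nRDD-group bins of the two genomes.
    """
    from .metrics import group_bin

    b_elements = sorted(elements_b, key=lambda e: (e.interval.chrom, e.interval.start))
    b_pair_by_members: dict[tuple, CNEPair] = {}
    for p in pairs_b:
        key = tuple(sorted([_iv_key(p.left.interval), _iv_key(p.right.interval)]))
        b_pair_by_members[key] = p

    out = []
    for pa in pairs_a:
        oleft = ortholog_map_ab.get(pa.left.element_id, {}).get(species_b)
        oright = ortholog_map_ab.get(pa.right.element_id, {}).get(species_b)
        if oleft is None or oright is None or oleft.chrom != oright.chrom:
            continue
        lo, hi = sorted([oleft, oright], key=lambda iv: iv.start)
        if _any_element_between(b_elements, lo, hi):
            continue
        pb = b_pair_by_members.get(tuple(sorted([_iv_key(oleft), _iv_key(oright)])))
        if pb is None:
            continue
        if pa.nrdd_group is None or pb.nrdd_group is None:
            cat = "unset"
        else:
            cat = f"H{group_bin(pa.nrdd_group)}; M{group_bin(pb.nrdd_group)}"
        out.append((pa.pair_id, pb.pair_id, cat))
    return out


def _iv_key(iv: GenomicInterval) -> tuple:
    return (iv.chrom, iv.start, iv.end)


def _any_element_between(elements: list[ConservedElement],
                         lo: GenomicInterval, hi: GenomicInterval) -> bool:
    for el in elements:
        iv = el.interval
        if iv.chrom != lo.chrom:
            continue
        if iv.start >= lo.end and iv.end <= hi.start:
            return True
    return False
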