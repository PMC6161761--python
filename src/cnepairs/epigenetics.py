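"""Per-pair histone-mark region summaries and the SOM feature matrix.

For every pair, tissue and mark, four regions are summarized by their mean
fold-enrichment: a 300-bp window centered on each CNE midpoint, the
inter-CNE sequence (inner edges), and the best 200-bp window inside the
inter-CNE sequence.  The two CNEs are relabelled CNE_h / CNE_l by their
overall H3K27ac level across tissues before the feature matrix is built, so
that the matrix is invariant to left/right orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenomicInterval, SignalTrack, HISTONE_MARKS
from . import stats as _stats
from .transposons import sample_matched_intervals

CNE_WINDOW = 300
BEST_WINDOW = 200
DEFAULT_STRIDE = 25
REGIONS = ("CNE_left", "CNE_right", "interCNE", "best200")
SORTED_REGIONS = ("CNE_h", "CNE_l", "interCNE", "best200")
SORT_MARK = "H3K27ac"


@dataclass
class PairSummaries:
    pair_id: str
    # (tissue, mark, region) -> mean fold-enrichment; region in REGIONS
    values: dict[tuple[str, str, str], float]
    flags: list[str]


def cne_window(cne_interval: GenomicInterval, width: int = CNE_WINDOW) -> GenomicInterval:
    """Fixed-width window centered on the CNE midpoint."""
    mid = cne_interval.midpoint
    return GenomicInterval(cne_interval.chrom, mid - width // 2, mid + width - width // 2)


def best_window_mean(track: SignalTrack, region: GenomicInterval,
                     width: int = BEST_WINDOW, stride: int = DEFAULT_STRIDE) -> tuple[float, bool]:
    """Highest mean over width-bp windows sliding at ``stride`` inside region.

    Windows lie fully inside the region; a region shorter than ``width``
    falls back to the whole-region mean (flagged by the second return).  The
    result is floored at the whole-region mean: a strided window scan can
    otherwise undershoot it when signal concentrates at both region edges,
    and the best-window summary is defined to dominate the region average.
    """
    whole = track.mean_over(region)
    if region.length < width:
        return whole, True
    starts = np.arange(region.start, region.end - width + 1, stride, dtype=np.int64)
    if starts[-1] != region.end - width:
        starts = np.append(starts, region.end - width)  # flush right edge
    means = track.window_means(region.chrom, starts, width)
    return max(float(means.max()), whole), False


def region_summaries(pair, tracks: dict[tuple[str, str], SignalTrack],
                     stride: int = DEFAULT_STRIDE) -> PairSummaries:
    """All four region means for every (tissue, mark) track of one pair."""
    values = {}
    flags = []
    wl = cne_window(pair.left.interval)
    wr = cne_window(pair.right.interval)
    inter = pair.inter_cne
    for (tissue, mark), track in tracks.items():
        values[(tissue, mark, "CNE_left")] = track.mean_over(wl)
        values[(tissue, mark, "CNE_right")] = track.mean_over(wr)
        inter_mean = track.mean_over(inter)
        values[(tissue, mark, "interCNE")] = inter_mean
        best, short = best_window_mean(track, inter, stride=stride)
        values[(tissue, mark, "best200")] = best
        if short and "short_interCNE" not in flags:
            flags.append("short_interCNE")
    return PairSummaries(pair.pair_id, values, flags)


def sort_cne_h_l(summaries: PairSummaries, tissues: list[str],
                 sort_mark: str = SORT_MARK) -> str:
    """Which side is CNE_h: the CNE with the higher mean sort-mark level.

    The overall level is the mean of the 300-bp CNE-window summaries for the
    sort mark across all tissues; ties go to the left CNE.  Returns "left"
    or "right".
    """
    left = np.mean([summaries.values[(t, sort_mark, "CNE_left")] for t in tissues])
    right = np.mean([summaries.values[(t, sort_mark, "CNE_right")] for t in tissues])
    return "left" if left >= right else "right"


def feature_columns(tissues: list[str], marks=HISTONE_MARKS) -> list[str]:
    """Deterministic column order: tissue-major, region, then mark (alphabetical)."""
    marks = sorted(marks)
    return [f"{t}|{r}|{m}" for t in tissues for r in SORTED_REGIONS for m in marks]


def build_feature_matrix(all_summaries: list[PairSummaries], tissues: list[str],
                         marks=HISTONE_MARKS) -> pd.DataFrame:
    """Pairs x (tissue x region x mark) matrix of mean fold-enrichments.

    Column count is enforced to n_tissues x 4 x len(marks); the CNE_h/CNE_l
    relabelling is applied per pair before assembly.
    """
    cols = feature_columns(tissues, marks)
    assert len(cols) == len(tissues) * 4 * len(marks)
    marks_sorted = sorted(marks)
    rows = []
    index = []
    for summ in all_summaries:
        h_side = sort_cne_h_l(summ, tissues)
        region_map = {
            "CNE_h": "CNE_left" if h_side == "left" else "CNE_right",
            "CNE_l": "CNE_right" if h_side == "left" else "CNE_left",
            "interCNE": "interCNE",
            "best200": "best200",
        }
        row = [
            summ.values[(t, m, region_map[r])]
            for t in tissues for r in SORTED_REGIONS for m in marks_sorted
        ]
        rows.append(row)
        index.append(summ.pair_id)
    df = pd.DataFrame(rows, columns=cols, index=index)
    if df.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    return df


# ---------------------------------------------------------------------------
# background comparisons
# ---------------------------------------------------------------------------

def above_background(fold_enrichment: float) -> bool:
    """True iff the fold-enrichment exceeds the control baseline (strictly > 1)."""
    return fold_enrichment > 1.0


def coactivity_counts(all_summaries: list[PairSummaries], tissue: str,
                      mark: str) -> tuple[tuple[int, int], tuple[int, int]]:
    """2x2 table of CNE_h-above-background x CNE_l-above-background.

    Uses the raw left/right windows per pair (relabelled via the pair's
    H3K27ac ordering is irrelevant for a symmetric cross-tabulation of
    both-above vs one-above vs neither).  Rows: left CNE above yes/no;
    columns: right CNE above yes/no.
    """
    both = h_only = l_only = neither = 0
    for summ in all_summaries:
        a = above_background(summ.values[(tissue, mark, "CNE_left")])
        b = above_background(summ.values[(tissue, mark, "CNE_right")])
        if a and b:
            both += 1
        elif a:
            h_only += 1
        elif b:
            l_only += 1
        else:
            neither += 1
    return ((both, h_only), (l_only, neither))


def empirical_inter_cne_test(pairs, tracks: dict[tuple[str, str], SignalTrack],
                             genome: dict[str, int], n_rep: int = 1000,
                             alpha: float = 0.05, seed: int = 0,
                             stride: int = DEFAULT_STRIDE) -> dict[tuple[str, str], dict]:
    """Are the best 200-bp inter-CNE windows hotter than random expectation?

    Per (tissue, mark) and replicate: draw one random genomic region per
    inter-CNE sequence (length-matched), extract its best 200-bp window mean
    identically, and compare real vs random with an unpaired rank-sum test.
    Emits prop_significant and empirical_p (same dual convention as the
    transposon depletion test) plus the direction of the median difference.
    """
    if n_rep <= 0:
        raise ValueError("n_rep must be positive")
    rng = np.random.default_rng(seed)
    inters = [p.inter_cne for p in pairs]
    lengths = [iv.length for iv in inters]
    real = {
        key: np.array([best_window_mean(tr, iv, stride=stride)[0] for iv in inters])
        for key, tr in tracks.items()
    }
    sig = {key: 0 for key in tracks}
    med_diff = {key: [] for key in tracks}
    for _ in range(n_rep):
        sampled = sample_matched_intervals(lengths, genome, rng)
        for key, tr in tracks.items():
            rand = np.array([best_window_mean(tr, iv, stride=stride)[0] for iv in sampled])
            if _stats.wilcoxon_rank_sum(real[key], rand) <= alpha:
                sig[key] += 1
            med_diff[key].append(float(np.median(real[key]) - np.median(rand)))
    out = {}
    for key in tracks:
        prop = sig[key] / n_rep
        med = float(np.median(med_diff[key]))
        out[key] = {
            "prop_significant": prop,
            "empirical_p": 1.0 - prop,
            "direction": "none" if med == 0 else ("enriched" if med > 0 else "depleted"),
        }
    return out


def inter_cne_null_calibration(track: SignalTrack, genome: dict[str, int],
                               lengths, n_rep: int = 1000, alpha: float = 0.05,
                               seed: int = 0, stride: int = DEFAULT_STRIDE) -> float:
    """Per-replicate size of the inter-CNE test when real regions are random."""
    rng = np.random.default_rng(seed)
    sig = 0
    for _ in range(n_rep):
        a = [best_window_mean(track, iv, stride=stride)[0]
             for iv in sample_matched_intervals(lengths, genome, rng)]
        b = [best_window_mean(track, iv, stride=stride)[0]
             for iv in sample_matched_intervals(lengths, genome, rng)]
        if _stats.wilcoxon_rank_sum(a, b) <= alpha:
            sig += 1
    return sig / n_rep
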