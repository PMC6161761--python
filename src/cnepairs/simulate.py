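"""Synthetic pipeline inputs with planted ground truth.

The generator emulates the real inputs end to end — conserved-element BED
files for 23 vertebrate species on one synthetic chromosome each, a minimal
protein-coding GTF, forward/reverse alignment hit tables, class-labelled
transposon BEDs, per-tissue per-mark fold-enrichment tracks, and a dated
phylogeny — while recording, per pair, the true ancestral inter-CNE distance,
the contraction/conservation/expansion class, the epigenetic archetype, and
the true ancestral transposon content.  Every downstream stage can therefore
be scored against known truth without any downloads.

Distances evolve by Brownian motion on the dated tree from the common
mammalian ancestor outward; contraction/expansion classes add a deterministic
shift on the focal (human) terminal branch.  Transposon content tracks the
inter-CNE span at class-specific densities, with focal-branch losses for
contracted pairs and SINE/LINE gains for expanded pairs, on top of a
genome-wide background placed at the 0.46 covered-fraction expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .io import (
    GenomicInterval, SignalTrack, HISTONE_MARKS,
    write_bed, write_track, write_hits, write_config, parse_newick_string,
)
from .metrics import ANCESTRAL_GENOME_SIZE
from .pairs import element_id

MAMMALS = (
    "human", "chimp", "rhesus", "marmoset", "mouse", "rat", "microbat",
    "dog", "panda", "pig", "dolphin", "rhinoceros", "elephant", "armadillo",
    "opossum", "platypus",
)
NON_MAMMALS = ("chicken", "zebra_finch", "lizard", "turtle", "frog", "fugu", "zebrafish")
SPECIES = MAMMALS + NON_MAMMALS

#: Approximate divergence times (My) defining the default ultrametric tree;
#: nodes are (age, [children]), leaves are species names.
_TREE_SPEC = (430, [
    (250, ["zebrafish", "fugu"]),
    (350, [
        "frog",
        (320, [
            (280, [
                "lizard",
                (255, ["turtle", (100, ["chicken", "zebra_finch"])]),
            ]),
            (180, [
                "platypus",
                (160, [
                    "opossum",
                    (100, [
                        (95, ["elephant", "armadillo"]),
                        (95, [
                            (90, [
                                (43, ["marmoset",
                                      (29, ["rhesus", (6, ["human", "chimp"])])]),
                                (20, ["mouse", "rat"]),
                            ]),
                            (80, [
                                "microbat",
                                (78, [
                                    (45, ["dog", "panda"]),
                                    (75, ["rhinoceros", (62, ["pig", "dolphin"])]),
                                ]),
                            ]),
                        ]),
                    ]),
                ]),
            ]),
        ]),
    ]),
])

GENOME_SIZES = {
    "human": 3_200_000_000, "chimp": 3_300_000_000, "rhesus": 3_200_000_000,
    "marmoset": 2_900_000_000, "mouse": 2_700_000_000, "rat": 2_800_000_000,
    "microbat": 2_000_000_000, "dog": 2_400_000_000, "panda": 2_300_000_000,
    "pig": 2_800_000_000, "dolphin": 2_400_000_000, "rhinoceros": 2_500_000_000,
    "elephant": 3_200_000_000, "armadillo": 3_200_000_000,
    "opossum": 3_500_000_000, "platypus": 2_000_000_000,
    "chicken": 1_200_000_000, "zebra_finch": 1_200_000_000,
    "lizard": 1_800_000_000, "turtle": 2_200_000_000, "frog": 1_700_000_000,
    "fugu": 400_000_000, "zebrafish": 1_400_000_000,
}

ARCHETYPES = ("inactive", "interCNE_poised", "CNE_poised", "CNE_active")
CLASSES = ("contracted", "conserved", "expanded")

#: Archetype mixture per contraction class.  Contractions/expansions lean
#: toward inactive or isolated inter-CNE hotspots; conserved pairs carry most
#: of the poised/active CNE enhancer signal.  This coupling plants the
#: group-in-unit enrichment signal the enrichment screen must detect.
ARCHETYPE_MIX = {
    "contracted": {"inactive": 0.55, "interCNE_poised": 0.25,
                   "CNE_poised": 0.15, "CNE_active": 0.05},
    "conserved": {"inactive": 0.25, "interCNE_poised": 0.15,
                  "CNE_poised": 0.30, "CNE_active": 0.30},
    "expanded": {"inactive": 0.25, "interCNE_poised": 0.65,
                 "CNE_poised": 0.05, "CNE_active": 0.05},
}

#: Ancestral per-class transposon densities on the midpoint span (depleted
#: relative to the 0.46 genome-wide covered fraction).
ANCESTRAL_TE_DENSITY = {"SINE": 0.05, "LINE": 0.05, "LTR": 0.03, "DNA": 0.02}
#: Genome-wide background class split summing to the 0.46 expectation.
BACKGROUND_TE_DENSITY = {"SINE": 0.13, "LINE": 0.21, "LTR": 0.08, "DNA": 0.04}


def default_tree_newick() -> str:
    """Ultrametric Newick (branch lengths in My) for the default 23 species."""

    def render(node, parent_age):
        if isinstance(node, str):
            return f"{node}:{parent_age:g}"
        age, children = node
        inner = ",".join(render(c, age) for c in children)
        return f"({inner}):{parent_age - age:g}"

    age, children = _TREE_SPEC
    inner = ",".join(render(c, age) for c in children)
    return f"({inner});"


@dataclass
class SimConfig:
    """Study conditions for the synthetic data.  Defaults ARE the conditions."""

    seed: int = 0
    n_pairs: int = 500
    species: tuple = SPECIES
    tree_newick: str = dc_field(default_factory=default_tree_newick)
    genome_sizes: dict = dc_field(default_factory=lambda: dict(GENOME_SIZES))
    ancestor_genome_size: int = ANCESTRAL_GENOME_SIZE
    focal: str = "human"
    class_fractions: dict = dc_field(
        default_factory=lambda: {"contracted": 0.3, "conserved": 0.4, "expanded": 0.3})
    sigma2: float = 10.0              # BM rate, bp^2 / My
    d_r_range: tuple = (1000.0, 50000.0)  # log-uniform ancestral distance range
    min_distance: float = 200.0       # clip floor for tip distances (bp)
    contraction_shift: float = -0.5   # focal-branch shift, units of d_r*
    expansion_shift: float = 1.0
    n_tissues: int = 3
    archetype_mix: dict = dc_field(default_factory=lambda: {k: dict(v) for k, v in ARCHETYPE_MIX.items()})
    signal_amplitude: float = 5.0     # archetype signal above baseline 1.0
    noise_sd: float = 0.25            # per-bin Gaussian noise on tracks
    bin_size: int = 25
    transposon_free_fraction: float = 0.15
    ancestral_te_density: dict = dc_field(default_factory=lambda: dict(ANCESTRAL_TE_DENSITY))
    background_te_density: dict = dc_field(default_factory=lambda: dict(BACKGROUND_TE_DENSITY))
    decoy_fraction: float = 0.0       # fraction of (element, species) with decoy hits
    rbh_violation_fraction: float = 0.0  # fraction whose reverse best maps elsewhere

    def __post_init__(self):
        if abs(sum(self.class_fractions.values()) - 1) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        for mix in self.archetype_mix.values():
            if abs(sum(mix.values()) - 1) > 1e-9:
                raise ValueError("archetype mixtures must sum to 1")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if any(v <= 0 for v in self.genome_sizes.values()):
            raise ValueError("genome sizes must be positive")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i + 1:02d}" for i in range(self.n_tissues)]


@dataclass
class PairTruth:
    pair_id: str
    d_r: float                 # true ancestral midpoint distance (bp)
    cls: str                   # contracted | conserved | expanded
    archetype: str
    tip_distance: dict         # species -> midpoint distance (bp, int)
    T_r: dict = dc_field(default_factory=dict)   # class -> ancestral length (bp)
    transposon_free: bool = False
    ortholog: dict = dc_field(default_factory=dict)  # species -> {L: (c,s,e), R: ...}


@dataclass
class GroundTruth:
    config_seed: int
    pairs: dict                 # pair_id -> PairTruth

    def to_json(self, path) -> None:
        blob = {
            "config_seed": self.config_seed,
            "pairs": {
                pid: {
                    "d_r": t.d_r, "class": t.cls, "archetype": t.archetype,
                    "tip_distance": t.tip_distance, "T_r": t.T_r,
                    "transposon_free": t.transposon_free,
                    "ortholog": t.ortholog,
                }
                for pid, t in self.pairs.items()
            },
        }
        Path(path).write_text(json.dumps(blob, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        blob = json.loads(Path(path).read_text())
        pairs = {
            pid: PairTruth(pid, d["d_r"], d["class"], d["archetype"],
                           d["tip_distance"], d["T_r"], d["transposon_free"],
                           d.get("ortholog", {}))
            for pid, d in blob["pairs"].items()
        }
        return cls(blob["config_seed"], pairs)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _tree_adjacency(tree):
    """Undirected adjacency {node: [(neighbor, branch_length), ...]}."""
    adj = {}
    for node in tree.preorder_node_iter():
        adj.setdefault(node, [])
        for child in node.child_nodes():
            L = child.edge.length or 0.0
            adj[node].append((child, L))
            adj.setdefault(child, []).append((node, L))
    return adj


def simulate_distances(config: SimConfig, rng=None):
    """Per-pair per-species tip distances plus ground truth.

    Ancestral distances are log-uniform on ``d_r_range``; tips evolve by
    Brownian motion (variance sigma2 * branch length) outward from the
    mammalian MRCA; the focal tip receives the class shift; everything is
    clipped at ``min_distance`` and rounded to integer bp.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_pairs
    tree = parse_newick_string(config.tree_newick)
    mammals_present = [s for s in MAMMALS if s in set(config.species)]
    mrca = tree.mrca(taxon_labels=mammals_present)

    lo, hi = config.d_r_range
    d_r = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    counts = {c: int(np.floor(config.class_fractions[c] * n)) for c in CLASSES}
    counts["conserved"] += n - sum(counts.values())
    labels = np.array(
        [c for c in CLASSES for _ in range(counts[c])], dtype=object)
    rng.shuffle(labels)

    # BM outward from the mammalian MRCA over the unrooted tree
    adj = _tree_adjacency(tree)
    values = {mrca: d_r.copy()}
    stack = [(mrca, None)]
    tip_values = {}
    while stack:
        node, parent = stack.pop()
        for nbr, L in sorted(adj[node], key=lambda t: _node_sort_key(t[0])):
            if nbr is parent:
                continue
            step = rng.normal(0.0, np.sqrt(config.sigma2 * L), size=n) if L > 0 else 0.0
            values[nbr] = values[node] + step
            if nbr.is_leaf():
                tip_values[nbr.taxon.label] = values[nbr]
            stack.append((nbr, node))

    shift = np.zeros(n)
    shift[labels == "contracted"] = config.contraction_shift
    shift[labels == "expanded"] = config.expansion_shift
    tip_values[config.focal] = tip_values[config.focal] + shift * d_r

    pair_ids = [f"p{i:05d}" for i in range(n)]
    distances = {}
    for sp in config.species:
        distances[sp] = np.maximum(
            np.rint(tip_values[sp]), config.min_distance).astype(np.int64)

    archetypes = _assign_archetypes(labels, config, rng)
    truth = GroundTruth(config.seed, {})
    for i, pid in enumerate(pair_ids):
        truth.pairs[pid] = PairTruth(
            pair_id=pid, d_r=float(d_r[i]), cls=str(labels[i]),
            archetype=archetypes[i],
            tip_distance={sp: int(distances[sp][i]) for sp in config.species},
        )
    import pandas as pd
    dist_df = pd.DataFrame(distances, index=pair_ids)
    return dist_df, truth


def _node_sort_key(node):
    if node.is_leaf():
        return (0, node.taxon.label)
    return (1, min(l.taxon.label for l in node.leaf_iter()))


def _assign_archetypes(labels, config, rng):
    out = []
    for cls in labels:
        mix = config.archetype_mix[cls]
        names = sorted(mix)
        out.append(str(rng.choice(names, p=[mix[k] for k in names])))
    return out


# ---------------------------------------------------------------------------
# element placement & hit tables
# ---------------------------------------------------------------------------

SEPARATOR_LEN = 2000     # coding separator element between consecutive pairs
PAIR_SPACER = 6000       # gap flanking each pair
MIN_CNE_LEN = 100
MAX_CNE_LEN = 1000
GAP_FLOOR = 100          # inter-CNE gap must survive the <100bp merge rule


@dataclass
class SpeciesLayout:
    chrom: str
    chrom_len: int
    elements: list          # (interval, name) CNEs in placement order
    separators: list        # separator intervals (focal species only)
    pair_region: dict       # pair_id -> (left_iv, right_iv)


def emit_elements_and_pairs(config: SimConfig, dist_df, truth: GroundTruth, rng=None):
    """Place CNEs so midpoint distances match the simulated values exactly.

    Returns {species: SpeciesLayout} plus forward/reverse hit tables (pandas
    DataFrames).  CNE lengths are shared across species (orthologs of the
    same element); a 2-kb coding separator element between consecutive focal
    pairs prevents spurious cross-pair adjacency.
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    pair_ids = list(dist_df.index)
    n = len(pair_ids)

    d_min = dist_df.min(axis=1).to_numpy()
    lengths = np.empty((n, 2), dtype=np.int64)
    for i in range(n):
        cap = min(MAX_CNE_LEN, int(d_min[i]) - 2 * GAP_FLOOR)
        if cap < MIN_CNE_LEN:
            lengths[i] = MIN_CNE_LEN
        else:
            lengths[i] = rng.integers(MIN_CNE_LEN, cap + 1, size=2)
        # guarantee gap >= GAP_FLOOR in every species
        while (lengths[i].sum() // 2) + GAP_FLOOR > d_min[i]:
            lengths[i] = np.maximum(MIN_CNE_LEN, lengths[i] // 2)

    layouts = {}
    for sp in config.species:
        chrom = "chr1"
        cursor = PAIR_SPACER
        elements = []
        separators = []
        pair_region = {}
        for i, pid in enumerate(pair_ids):
            d = int(dist_df.loc[pid, sp])
            L1, L2 = int(lengths[i, 0]), int(lengths[i, 1])
            left = GenomicInterval(chrom, cursor, cursor + L1)
            m1 = left.midpoint
            right_start = m1 + d - L2 // 2
            right = GenomicInterval(chrom, right_start, right_start + L2)
            assert right.midpoint - left.midpoint == d
            elements.append((left, f"{pid}_L"))
            elements.append((right, f"{pid}_R"))
            pair_region[pid] = (left, right)
            cursor = right.end + PAIR_SPACER
            if sp == config.focal and i < n - 1:
                sep = GenomicInterval(chrom, cursor, cursor + SEPARATOR_LEN)
                separators.append(sep)
                cursor = sep.end + PAIR_SPACER
        total_span = cursor
        layouts[sp] = SpeciesLayout(chrom, 3 * total_span, elements, separators, pair_region)
        for pid in pair_ids:
            left, right = pair_region[pid]
            truth.pairs[pid].ortholog[sp] = {
                "L": (left.chrom, left.start, left.end),
                "R": (right.chrom, right.start, right.end),
            }

    fwd_rows, rev_rows = [], []
    focal_layout = layouts[config.focal]
    focal_by_name = {name: iv for iv, name in focal_layout.elements}
    for sp in config.species:
        if sp == config.focal:
            continue
        sp_by_name = {name: iv for iv, name in layouts[sp].elements}
        for name, fiv in focal_by_name.items():
            qid = element_id(fiv)
            tiv = sp_by_name[name]
            fwd_rows.append([qid, sp, tiv.chrom, tiv.start, tiv.end, 100.0])
            violate = rng.random() < config.rbh_violation_fraction
            if rng.random() < config.decoy_fraction:
                dstart = int(rng.integers(0, layouts[sp].chrom_len - tiv.length))
                fwd_rows.append([qid, sp, tiv.chrom, dstart, dstart + tiv.length,
                                 round(float(rng.uniform(0.5, 0.95)) * 100.0, 3)])
            tkey = f"{sp}:{tiv.chrom}:{tiv.start}-{tiv.end}"
            if violate:
                # reverse best maps off the original locus -> RBH rejection
                back_start = fiv.end + 50_000
                rev_rows.append([tkey, "focal", fiv.chrom, back_start,
                                 back_start + fiv.length, 100.0])
            else:
                rev_rows.append([tkey, "focal", fiv.chrom, fiv.start, fiv.end, 100.0])

    hits_fwd = pd.DataFrame(fwd_rows, columns=["query", "species", "chrom", "start", "end", "score"])
    hits_rev = pd.DataFrame(rev_rows, columns=["query", "species", "chrom", "start", "end", "score"])
    return layouts, hits_fwd, hits_rev


# ---------------------------------------------------------------------------
# transposons
# ---------------------------------------------------------------------------

def emit_transposons(config: SimConfig, truth: GroundTruth,
                     layouts: dict, rng=None):
    """Class-labelled transposon intervals per species, plus ancestral truth.

    Each non-transposon-free pair gets ancestral per-class lengths T_r* =
    density * d_r*; species tips scale T with their own inter-CNE span.
    Focal-branch edits: contracted pairs lose everything (T_h = 0), expanded
    pairs gain SINEs/LINEs proportional to the added span.  Background
    transposons cover the remaining genome at the 0.46 expectation, masked
    out of every planted pair span.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)

    for pid, t in truth.pairs.items():
        if rng.random() < config.transposon_free_fraction:
            t.transposon_free = True
            t.T_r = {cls: 0.0 for cls in config.ancestral_te_density}
        else:
            t.T_r = {cls: float(np.rint(dens * t.d_r))
                     for cls, dens in config.ancestral_te_density.items()}

    records = {sp: [] for sp in config.species}
    for sp in config.species:
        layout = layouts[sp]
        for pid, t in truth.pairs.items():
            left, right = layout.pair_region[pid]
            span = right.midpoint - left.midpoint
            if t.transposon_free:
                continue
            T = {cls: int(np.rint(v * span / t.d_r)) for cls, v in t.T_r.items()}
            if sp == config.focal:
                if t.cls == "contracted":
                    T = {cls: 0 for cls in T}
                elif t.cls == "expanded":
                    gained = max(0, span - int(np.rint(t.d_r)))
                    T["SINE"] += int(0.4 * gained)
                    T["LINE"] += int(0.2 * gained)
            _place_in_region(records[sp], layout.chrom, left.end, right.start, T, rng)

    for sp in config.species:
        layout = layouts[sp]
        mask = sorted((lv.start - 200, rv.end + 200)
                      for lv, rv in layout.pair_region.values())
        _background_transposons(records[sp], layout.chrom, layout.chrom_len,
                                mask, config.background_te_density, rng)
    return records


def _place_in_region(records, chrom, start, end, T_by_class, rng):
    """Lay per-class blocks sequentially inside [start, end), 10-bp gaps."""
    avail = end - start
    total = sum(T_by_class.values())
    if total <= 0:
        return
    if total + 10 * len(T_by_class) > avail:
        scale = (avail - 10 * len(T_by_class)) / total
        T_by_class = {c: int(v * scale) for c, v in T_by_class.items()}
    cursor = start + 5
    for cls in sorted(T_by_class):
        L = T_by_class[cls]
        if L < 1:
            continue
        records.append((GenomicInterval(chrom, cursor, cursor + L), cls))
        cursor += L + 10


def _background_transposons(records, chrom, chrom_len, mask, density, rng,
                            mean_len: float = 300.0):
    """Random intervals at total covered fraction sum(density), outside mask."""
    rho = sum(density.values())
    mean_gap = mean_len * (1 - rho) / rho
    classes = sorted(density)
    probs = np.array([density[c] for c in classes]) / rho
    cursor = 0
    mi = 0
    while cursor < chrom_len:
        cursor += int(rng.exponential(mean_gap)) + 1
        L = max(30, int(rng.exponential(mean_len)))
        s, e = cursor, min(cursor + L, chrom_len)
        if e <= s:
            break
        while mi < len(mask) and mask[mi][1] <= s:
            mi += 1
        if mi < len(mask) and mask[mi][0] < e:  # overlaps a planted pair
            cursor = mask[mi][1]
            continue
        cls = classes[int(rng.choice(len(classes), p=probs))]
        records.append((GenomicInterval(chrom, s, e), cls))
        cursor = e


# ---------------------------------------------------------------------------
# epigenetic tracks
# ---------------------------------------------------------------------------

def emit_tracks(config: SimConfig, truth: GroundTruth,
                layout: SpeciesLayout, rng=None) -> dict:
    """Fold-enrichment tracks {(tissue, mark): SignalTrack} for the focal genome.

    Baseline fold-enrichment 1.0 over every pair span (plus margin), with
    archetype-specific signal of amplitude ``signal_amplitude`` and iid
    Gaussian bin noise (sd ``noise_sd``), clipped at 0.  Bins are
    ``bin_size``-aligned so strided window scans see exact block edges.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    b = config.bin_size
    amp = config.signal_amplitude

    # per pair: bin grid and per-mark signal profile (tissue-independent)
    pair_bins = {}
    for pid, t in truth.pairs.items():
        left, right = layout.pair_region[pid]
        # cover the pair span AND the 300-bp CNE windows, bin-aligned
        lo = (min(left.start, left.midpoint - 150) - 2 * b) // b * b
        hi = -(-(max(right.end, right.midpoint + 150) + 2 * b) // b) * b
        edges = np.arange(lo, hi + b, b, dtype=np.int64)
        starts = edges[:-1]
        profile = {mark: np.zeros(len(starts)) for mark in HISTONE_MARKS}

        def paint(marks, s, e, level):
            sel = (starts + b > s) & (starts < e)
            for m in marks:
                profile[m][sel] = np.maximum(profile[m][sel], level)

        wl = (left.midpoint - 150, left.midpoint + 150)
        wr = (right.midpoint - 150, right.midpoint + 150)
        if t.archetype == "CNE_active":
            paint(("H3K27ac", "H3K4me1", "H3K4me3"), wl[0], wr[1], amp)
        elif t.archetype == "CNE_poised":
            paint(("H3K27me3", "H3K4me1"), *wl, amp)
            paint(("H3K27me3", "H3K4me1"), *wr, amp)
        elif t.archetype == "interCNE_poised":
            inter_lo, inter_hi = left.end, right.start
            if inter_hi - inter_lo > 200:
                hs = int(rng.integers(inter_lo, inter_hi - 200))
            else:
                hs = inter_lo
            hs = hs // b * b  # align hotspot to the bin grid
            paint(("H3K4me1", "H3K27me3", "H3K9me3"), hs, min(hs + 200, inter_hi), amp)
        pair_bins[pid] = (starts, profile)

    tracks = {}
    for tissue in config.tissues:
        for mark in HISTONE_MARKS:
            all_starts, all_vals = [], []
            for pid in truth.pairs:
                starts, profile = pair_bins[pid]
                vals = 1.0 + profile[mark]
                if config.noise_sd > 0:
                    vals = vals + rng.normal(0.0, config.noise_sd, size=len(starts))
                all_starts.append(starts)
                all_vals.append(np.clip(vals, 0.0, None))
            starts = np.concatenate(all_starts)
            vals = np.concatenate(all_vals)
            tracks[(tissue, mark)] = SignalTrack.from_arrays(
                tissue, mark, layout.chrom, starts, starts + b, vals)
    return tracks


# ---------------------------------------------------------------------------
# GTF + full emission
# ---------------------------------------------------------------------------

def write_annotation_gtf(path, layout: SpeciesLayout) -> None:
    """Minimal protein-coding GTF: one gene per separator, exon = separator."""
    with open(path, "w") as fh:
        for i, sep in enumerate(layout.separators):
            gid = f"gene{i:05d}"
            strand = "+" if i % 2 == 0 else "-"
            gs, ge = sep.start - 500, sep.end + 500
            attrs = f'gene_id "{gid}"; gene_type "protein_coding";'
            for feature, s, e in (("gene", gs, ge), ("transcript", gs, ge),
                                  ("exon", sep.start, sep.end)):
                fh.write("\t".join([
                    layout.chrom, "sim", feature, str(s + 1), str(e), ".",
                    strand, ".", attrs]) + "\n")


def write_conservation_scores(path, layout: SpeciesLayout, rng) -> None:
    """Per-CNE constant phastCons-like scores in [0.6, 1.0]."""
    with open(path, "w") as fh:
        for iv, _name in layout.elements:
            score = rng.uniform(0.6, 1.0)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{score:.4f}\n")


def simulate_all(config: SimConfig, outdir) -> GroundTruth:
    """Generate and write the complete synthetic input directory tree."""
    outdir = Path(outdir)
    for sub in ("elements", "transposons", "tracks"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(config.seed)
    dist_df, truth = simulate_distances(config, rng)
    layouts, hits_fwd, hits_rev = emit_elements_and_pairs(config, dist_df, truth, rng)
    te_records = emit_transposons(config, truth, layouts, rng)
    tracks = emit_tracks(config, truth, layouts[config.focal], rng)

    for sp, layout in layouts.items():
        records = [(iv, name, None) for iv, name in layout.elements]
        # coding separator elements break cross-pair adjacency in the focal set
        records += [(iv, f"sep{i:05d}", None)
                    for i, iv in enumerate(layout.separators)]
        records.sort(key=lambda r: (r[0].chrom, r[0].start))
        write_bed(outdir / "elements" / f"{sp}.bed", records)
        write_bed(outdir / "transposons" / f"{sp}.bed",
                  [(iv, cls, None) for iv, cls in te_records[sp]])
    for (tissue, mark), track in tracks.items():
        write_track(outdir / "tracks" / f"{tissue}_{mark}.bedGraph", track)
    write_hits(outdir / "hits_forward.tsv", hits_fwd)
    write_hits(outdir / "hits_reverse.tsv", hits_rev)
    (outdir / "tree.nwk").write_text(config.tree_newick + "\n")
    write_annotation_gtf(outdir / "annotation.gtf", layouts[config.focal])
    write_conservation_scores(outdir / "scores.bedGraph", layouts[config.focal],
                              np.random.default_rng(config.seed + 4))
    with open(outdir / "genome.tsv", "w") as fh:
        fh.write("species\tchrom\tchrom_len\tgenome_size\n")
        for sp in config.species:
            fh.write(f"{sp}\t{layouts[sp].chrom}\t{layouts[sp].chrom_len}"
                     f"\t{config.genome_sizes[sp]}\n")
    truth.to_json(outdir / "truth.json")
    write_config(outdir / "config.yaml", _config_dict(config))
    return truth


def _config_dict(config: SimConfig) -> dict:
    d = {}
    for k, v in vars(config).items():
        if isinstance(v, tuple):
            v = list(v)
        d[k] = v
    return d
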