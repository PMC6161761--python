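"""Maximum-likelihood ancestral states for continuous traits under Brownian motion.

For a trait evolving by Brownian motion on a dated tree, the ML estimate of
the state at an internal node ``r`` is the generalized-least-squares mean of
the tip values,

    x_hat = (1' C^-1 x) / (1' C^-1 1),

where ``C`` is the tip covariance of the tree rerooted at ``r`` (entry ij =
shared path length from ``r`` to the divergence of tips i and j).  The BM
rate sigma^2 scales ``C`` uniformly, cancels in the ratio, and never needs to
be estimated.  The same machinery serves inter-CNE distances (``d_r``) and
per-class transposon lengths (``T_r``) at the common mammalian ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


@dataclass
class AncestralEstimate:
    pair_id: str
    node_label: str
    estimate: float
    n_tips: int
    flags: list[str] = field(default_factory=list)


class AncestorNotReconstructible(ValueError):
    """The requested ancestor is not an internal node of the pruned tree."""


def resolve_polytomies(tree: dendropy.Tree, seed: int = 0) -> dendropy.Tree:
    """Resolve polytomies by inserting zero-length internal branches.

    A zero-length arbitrary resolution leaves the BM likelihood unchanged, so
    the seed affects only node bookkeeping, never the estimates.
    """
    rng = np.random.default_rng(seed)
    tree.resolve_polytomies(rng=_RngAdapter(rng))
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return tree


class _RngAdapter:
    """Adapts numpy Generator to the random.Random subset dendropy uses."""

    def __init__(self, rng):
        self._rng = rng

    def sample(self, population, k):
        idx = self._rng.choice(len(population), size=k, replace=False)
        return [population[i] for i in sorted(int(i) for i in idx)]

    def shuffle(self, seq):
        self._rng.shuffle(seq)

    def randint(self, a, b):
        return int(self._rng.integers(a, b + 1))

    def choice(self, seq):
        return seq[int(self._rng.integers(len(seq)))]


class PhyloModel:
    """A fixed dated tree supporting ML ancestral estimation at a chosen node.

    Missing species are pruned per trait vector (pairwise deletion), and the
    GLS weights are cached per observed-species subset because hundreds of
    pairs typically share a handful of subsets.
    """

    def __init__(self, tree: dendropy.Tree, seed: int = 0):
        tree = tree.clone(depth=1)
        resolve_polytomies(tree, seed=seed)
        self.tree = tree
        self._labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        self._weights_cache: dict[tuple[frozenset, frozenset], tuple] = {}

    @property
    def tip_labels(self) -> list[str]:
        return list(self._labels)

    # -- geometry ----------------------------------------------------------

    def _node_depths(self):
        depths = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        return depths

    def _ancestor_sets(self):
        anc = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                anc[node] = (node,)
            else:
                anc[node] = anc[node.parent_node] + (node,)
        return anc

    def mrca(self, labels) -> dendropy.Node:
        taxa = set(labels)
        node = self.tree.mrca(taxon_labels=sorted(taxa))
        if node is None:
            raise ValueError(f"no MRCA for {sorted(taxa)}")
        return node

    def gls_weights(self, tip_labels: tuple[str, ...], node_labels: frozenset) -> np.ndarray:
        """GLS weights for the tips, for the ancestor = MRCA of node_labels.

        The target node is addressed by the tip-label set whose MRCA it is.
        """
        key = (frozenset(tip_labels), node_labels)
        if key in self._weights_cache:
            cached_order, w = self._weights_cache[key]
            return w[[cached_order.index(l) for l in tip_labels]]

        depths = self._node_depths()
        anc = self._ancestor_sets()
        node = self.mrca(node_labels)
        leaves = {leaf.taxon.label: leaf for leaf in self.tree.leaf_node_iter()}
        tips = [leaves[l] for l in tip_labels]

        def mrca2(a, b):
            sa = anc[a]
            sb = set(anc[b])
            for x in reversed(sa):
                if x in sb:
                    return x
            raise RuntimeError("disconnected tree")

        def pathlen(a, b):
            return depths[a] + depths[b] - 2 * depths[mrca2(a, b)]

        n = len(tips)
        C = np.empty((n, n))
        d_r = np.array([pathlen(node, t) for t in tips])
        for i in range(n):
            for j in range(i, n):
                d_ij = 0.0 if i == j else pathlen(tips[i], tips[j])
                C[i, j] = C[j, i] = 0.5 * (d_r[i] + d_r[j] - d_ij)
        ones = np.ones(n)
        try:
            Cinv1 = np.linalg.solve(C, ones)
        except np.linalg.LinAlgError as exc:
            # e.g. duplicated tips hanging on zero-length pendant branches
            raise AncestorNotReconstructible(
                f"singular BM covariance for tips {tip_labels}"
            ) from exc
        w = Cinv1 / Cinv1.sum()
        if not np.all(np.isfinite(w)):
            raise AncestorNotReconstructible(
                f"non-finite GLS weights for tips {tip_labels}"
            )
        self._weights_cache[key] = (tuple(tip_labels), w)
        return w

    # -- estimation --------------------------------------------------------

    def ml_ancestral_state(
        self,
        tip_values: dict[str, float],
        ancestor_of: set[str] | frozenset,
        require: set[str] | None = None,
    ) -> tuple[float, int]:
        """ML (GLS) estimate of the trait at the MRCA of ``ancestor_of``.

        ``tip_values`` maps species to observed values; species absent from
        the mapping are pruned.  ``require`` lists species that must be
        observed for the node to be reconstructible (e.g. the platypus rule
        for the common mammalian ancestor).  Returns (estimate, n_tips).
        """
        observed = {l: v for l, v in tip_values.items() if l in set(self._labels)}
        if len(observed) < 2:
            raise AncestorNotReconstructible(
                f"need >= 2 observed tips, got {len(observed)}"
            )
        if require is not None:
            missing = set(require) - set(observed)
            if missing:
                raise AncestorNotReconstructible(
                    f"ancestor not reconstructible: missing required tips {sorted(missing)}"
                )
        anchor = frozenset(l for l in ancestor_of if l in observed)
        if len(anchor) < 2:
            raise AncestorNotReconstructible(
                "ancestor not reconstructible: fewer than 2 observed descendants"
            )
        labels = tuple(sorted(observed))
        w = self.gls_weights(labels, anchor)
        x = np.array([observed[l] for l in labels])
        return float(w @ x), len(labels)


def reconstruct_pair_ancestors(
    distances,
    tree: dendropy.Tree,
    mammals: list[str],
    required: tuple[str, ...] = ("platypus",),
    seed: int = 0,
):
    """Estimate the ancestral inter-CNE distance ``d_r`` for each pair.

    ``distances`` is a mapping ``pair_id -> {species: distance}`` (or a pandas
    DataFrame with species columns).  The ancestor node is the MRCA of the
    mammals; pairs lacking a required species (platypus by default) are
    flagged ``no_platypus`` and skipped.  Only mammalian observations feed
    the estimate.
    """
    import pandas as pd

    if isinstance(distances, pd.DataFrame):
        distances = {
            idx: {sp: v for sp, v in row.items() if pd.notna(v)}
            for idx, row in distances.iterrows()
        }
    model = PhyloModel(tree, seed=seed)
    mammal_set = set(mammals) & set(model.tip_labels)
    rows = []
    for pair_id, tips in distances.items():
        obs = {sp: v for sp, v in tips.items() if sp in mammal_set}
        flags = []
        missing_required = set(required) - set(obs)
        if missing_required:
            flags.append("no_" + "_".join(sorted(missing_required)))
            rows.append(AncestralEstimate(pair_id, "mammal_ancestor", float("nan"), len(obs), flags))
            continue
        try:
            est, n = model.ml_ancestral_state(obs, ancestor_of=mammal_set)
        except AncestorNotReconstructible as exc:
            rows.append(AncestralEstimate(pair_id, "mammal_ancestor", float("nan"),
                                          len(obs), [f"skipped: {exc}"]))
            continue
        rows.append(AncestralEstimate(pair_id, "mammal_ancestor", est, n, flags))
    return rows


def reconstruct_transposon_ancestors(
    lengths_by_class,
    tree: dendropy.Tree,
    mammals: list[str],
    required: tuple[str, ...] = ("platypus",),
    seed: int = 0,
):
    """Ancestral transposon length ``T_r`` per pair per class, clamped at 0.

    ``lengths_by_class`` maps ``(pair_id, class) -> {species: length}``.
    Negative GLS outputs are floored to 0 and flagged ``clamped``.
    """
    model = PhyloModel(tree, seed=seed)
    mammal_set = set(mammals) & set(model.tip_labels)
    out = {}
    for (pair_id, cls), tips in lengths_by_class.items():
        obs = {sp: v for sp, v in tips.items() if sp in mammal_set}
        flags = []
        if set(required) - set(obs):
            out[(pair_id, cls)] = AncestralEstimate(
                pair_id, "mammal_ancestor", float("nan"), len(obs), ["no_platypus"])
            continue
        try:
            est, n = model.ml_ancestral_state(obs, ancestor_of=mammal_set)
        except AncestorNotReconstructible as exc:
            out[(pair_id, cls)] = AncestralEstimate(
                pair_id, "mammal_ancestor", float("nan"), len(obs), [f"skipped: {exc}"])
            continue
        if est < 0:
            est = 0.0
            flags.append("clamped")
        out[(pair_id, cls)] = AncestralEstimate(pair_id, "mammal_ancestor", est, n, flags)
    return out
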