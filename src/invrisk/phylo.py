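"""Dated-phylogeny handling.

Divergence time between two host species is the age (time before
present, in millions of years) of their most recent common ancestor on
an ultrametric, dated tree. The module also provides Blomberg's K, the
ratio of the observed to the Brownian-motion-expected phylogenetic
signal in a continuous (or integer-coded ordinal) trait, with a
permutation test shuffling trait values across tips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .exceptions import PhyloError

__all__ = [
    "DatedTree",
    "PhyloSignalResult",
    "parse_newick",
    "mrca_age",
    "closest_native_host",
    "blomberg_k",
    "k_randomization_test",
    "encode_ordinal",
]

#: Integer codes for the ordinal trait levels used in phylogenetic-signal
#: calculations ("medium" is an accepted synonym of "moderate").
ORDINAL_CODES = {"none": 0, "low": 1, "moderate": 2, "medium": 2, "high": 3}


def encode_ordinal(levels: Sequence[str]) -> np.ndarray:
    """Code ordinal levels none/low/moderate(medium)/high as 0..3."""
    out = np.empty(len(levels), dtype=float)
    for i, level in enumerate(levels):
        try:
            out[i] = ORDINAL_CODES[level]
        except KeyError:
            raise PhyloError(
                f"unknown ordinal level {level!r}; expected one of "
                f"{sorted(set(ORDINAL_CODES))}") from None
    return out


class DatedTree:
    """A rooted, (near-)ultrametric tree with branch lengths in my.

    Node ages are defined as the maximum distance from the node to any
    descendant tip, which on an exactly ultrametric tree is the usual
    time before present. Trees failing the relative ultrametricity check
    (root-to-tip spread > 1e-6 x root age) are accepted with a warning.
    """

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        self._tree = tree
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or leaf.taxon.label is None:
                raise PhyloError("tree has an unlabeled tip")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise PhyloError(f"duplicate tip labels: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise PhyloError("tree has an edge with no branch length")

        # node "age" = max distance to a descendant tip (postorder)
        self._age: dict[dendropy.Node, float] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self._age[node] = 0.0
            else:
                self._age[node] = max(
                    self._age[ch] + (ch.edge.length or 0.0)
                    for ch in node.child_nodes())
        self.root_age = self._age[tree.seed_node]

        # root-to-tip spread for the ultrametricity report
        depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
        tip_depths = []
        for node in tree.preorder_node_iter():
            if node is not tree.seed_node:
                depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
            if node.is_leaf():
                tip_depths.append(depth[node])
        spread = max(tip_depths) - min(tip_depths)
        self.is_ultrametric = spread <= 1e-6 * max(self.root_age, 1e-12)
        if not self.is_ultrametric:
            warnings.warn(
                f"tree is not ultrametric (root-to-tip spread {spread:.3g} my); "
                "MRCA ages use the maximum distance-to-tip convention",
                stacklevel=3)

        # ancestor paths (leaf -> root) for MRCA lookups
        self._leaf: dict[str, dendropy.Node] = {
            lf.taxon.label: lf for lf in tree.leaf_node_iter()}
        self._path: dict[str, list[dendropy.Node]] = {}
        for label, leaf in self._leaf.items():
            path = []
            node = leaf
            while node is not None:
                path.append(node)
                node = node.parent_node
            self._path[label] = path

    @property
    def tip_labels(self) -> list[str]:
        return sorted(self._leaf)

    def __len__(self) -> int:
        return len(self._leaf)

    def _mrca(self, tip_a: str, tip_b: str) -> dendropy.Node:
        for label in (tip_a, tip_b):
            if label not in self._leaf:
                raise PhyloError(f"unknown tip {label!r}")
        ancestors_b = set(map(id, self._path[tip_b]))
        for node in self._path[tip_a]:
            if id(node) in ancestors_b:
                return node
        raise PhyloError(f"no common ancestor of {tip_a!r} and {tip_b!r}")

    def mrca_age(self, tip_a: str, tip_b: str) -> float:
        """Age (my before present) of the MRCA of two tips."""
        return self._age[self._mrca(tip_a, tip_b)]

    def vcv(self, labels: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Brownian-motion covariance matrix: shared root-to-MRCA depth.

        C[i, j] = root_age - age(MRCA(i, j)); the diagonal holds each
        tip's total root-to-tip path under the same convention.
        """
        labels = list(labels) if labels is not None else self.tip_labels
        n = len(labels)
        C = np.empty((n, n))
        for i, a in enumerate(labels):
            C[i, i] = self.root_age
            for j in range(i + 1, n):
                C[i, j] = C[j, i] = self.root_age - self.mrca_age(a, labels[j])
        return C, labels

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        """The underlying dendropy tree (read-only use)."""
        return self._tree

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


def parse_newick(text: str) -> DatedTree:
    """Parse a Newick string (branch lengths in my) into a DatedTree."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parser error types
        raise PhyloError(f"malformed Newick: {exc}") from exc
    return DatedTree(tree)


def read_newick(path: str | Path) -> DatedTree:
    return parse_newick(Path(path).read_text())


def mrca_age(tree: DatedTree, tip_a: str, tip_b: str) -> float:
    return tree.mrca_age(tip_a, tip_b)


def closest_native_host(
    tree: DatedTree,
    novel_host: str,
    native_hosts: Sequence[str],
    overrides: Mapping[tuple[str, str], float] | None = None,
) -> tuple[str, float]:
    """Native host most recently diverged from the novel host.

    Returns ``(native_host, divergence_mya)`` minimizing the MRCA age;
    ties break lexicographically by species id. A conspecific match
    returns age 0.0 and is expected to be excluded downstream.
    ``overrides`` supplies pairwise ages for hosts placed from other
    published phylogenies; an override wins over the tree lookup.
    """
    if not native_hosts:
        raise PhyloError(
            f"insect has no native hosts: cannot compute divergence for "
            f"novel host {novel_host!r}")

    def age_of(native: str) -> float:
        if native == novel_host:
            return 0.0
        if overrides is not None:
            for key in ((novel_host, native), (native, novel_host)):
                if key in overrides:
                    return float(overrides[key])
        return tree.mrca_age(novel_host, native)

    best = min(sorted(set(native_hosts)), key=lambda nh: (age_of(nh), nh))
    return best, age_of(best)


def _signal_ratio(x: np.ndarray, Cinv: np.ndarray, ones: np.ndarray) -> float:
    """MSE0/MSE for trait vector x given the inverse BM covariance."""
    denom = ones @ Cinv @ ones
    a_hat = (ones @ Cinv @ x) / denom
    dev = x - a_hat
    n = len(x)
    mse0 = dev @ dev / (n - 1)
    mse = dev @ Cinv @ dev / (n - 1)
    return mse0 / mse


def _prepare_k(tree: DatedTree, trait_values: Mapping[str, float]):
    labels = tree.tip_labels
    missing = [l for l in labels if l not in trait_values]
    if missing:
        raise PhyloError(f"trait values missing for tips: {missing[:5]}")
    x = np.asarray([float(trait_values[l]) for l in labels])
    if len(labels) < 4:
        raise PhyloError("Blomberg's K needs at least 4 tips")
    if not np.all(np.isfinite(x)):
        raise PhyloError("non-finite trait value")
    if np.ptp(x) == 0:
        raise PhyloError("constant trait: phylogenetic signal undefined")
    C, _ = tree.vcv(labels)
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise PhyloError("singular phylogenetic covariance matrix") from exc
    n = len(x)
    ones = np.ones(n)
    expected = (np.trace(C) - n / np.sum(Cinv)) / (n - 1)
    return x, Cinv, ones, expected


def blomberg_k(tree: DatedTree, trait_values: Mapping[str, float]) -> float:
    """Blomberg's K phylogenetic-signal statistic.

    K = (MSE0/MSE) / E_BM[MSE0/MSE], where MSE0 is the ordinary mean
    squared deviation of tip values from the GLS (C^-1-weighted)
    phylogenetic mean, MSE the C^-1-weighted one, and the expectation
    (trace(C) - n / sum(C^-1)) / (n - 1) is the value under Brownian
    motion on the given tree. K = 1 for Brownian evolution, ~0 for trait
    values random with respect to the phylogeny.
    """
    x, Cinv, ones, expected = _prepare_k(tree, trait_values)
    return _signal_ratio(x, Cinv, ones) / expected


@dataclass(frozen=True)
class PhyloSignalResult:
    K_stat: float
    p_value: float
    n_randomizations: int


def k_randomization_test(
    tree: DatedTree,
    trait_values: Mapping[str, float],
    n_rand: int = 1000,
    seed: int | None = None,
) -> PhyloSignalResult:
    """Permutation test of K against random tip assignment.

    Trait values are shuffled across tips ``n_rand`` times;
    p = (1 + #{K_perm >= K_obs}) / (n_rand + 1).
    """
    if n_rand < 1:
        raise PhyloError("n_rand must be >= 1")
    x, Cinv, ones, expected = _prepare_k(tree, trait_values)
    observed = _signal_ratio(x, Cinv, ones) / expected
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rand):
        perm = rng.permutation(x)
        if _signal_ratio(perm, Cinv, ones) / expected >= observed:
            hits += 1
    return PhyloSignalResult(
        K_stat=observed,
        p_value=(1 + hits) / (n_rand + 1),
        n_randomizations=n_rand,
    )
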