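"""Projection of a phylogeny into the continuous niche plane.

Tip positions are the species' meta-ordination scores; internal-node
positions are estimated by squared-change parsimony — the configuration
minimizing the sum over edges of squared positional change, optionally
weighted by inverse branch length.  The minimizer satisfies a linear
system in which every internal node sits at the (weighted) mean of its
neighbours, solved here directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np


class PhylospaceError(ValueError):
    pass


@dataclass
class Phylogeny:
    """Rooted tree wrapper with stable node indexing (preorder)."""

    tree: dendropy.Tree

    def __post_init__(self):
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise PhylospaceError("duplicate tip labels")
        self._nodes = list(self.tree.preorder_node_iter())
        self._index = {id(nd): i for i, nd in enumerate(self._nodes)}

    @property
    def nodes(self):
        return self._nodes

    @property
    def tip_labels(self):
        return tuple(
            nd.taxon.label for nd in self._nodes if nd.is_leaf()
        )

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def node_index(self, nd) -> int:
        return self._index[id(nd)]

    def edges(self):
        """(parent index, child index, branch length or None) per edge."""
        out = []
        for nd in self._nodes:
            for child in nd.child_nodes():
                out.append((self._index[id(nd)], self._index[id(child)],
                            child.edge.length))
        return out

    def write_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def parse_newick(text: str, assemblage_species=None, prune: bool = False) -> Phylogeny:
    """Parse a newick string into a rooted tree (polytomies allowed).

    If ``assemblage_species`` is given, tips outside the assemblage
    trigger a warning, and are pruned when ``prune`` is set.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise PhylospaceError(f"newick parse error: {exc}") from None
    if assemblage_species is not None:
        known = set(assemblage_species)
        extra = [
            leaf.taxon for leaf in tree.leaf_node_iter()
            if leaf.taxon.label not in known
        ]
        if extra:
            names = sorted(t.label for t in extra)
            warnings.warn(
                f"{len(extra)} tip(s) absent from assemblage: {names}",
                stacklevel=2,
            )
            if prune:
                keep = [
                    leaf.taxon for leaf in tree.leaf_node_iter()
                    if leaf.taxon.label in known
                ]
                tree.retain_taxa(keep)
    return Phylogeny(tree)


def ancestral_scores(phylo: Phylogeny, tip_scores: dict,
                     weighted: bool = False) -> np.ndarray:
    """Squared-change parsimony positions for every node.

    Minimizes sum over edges of w_e * ||x_parent - x_child||^2 with
    tips fixed at their scores; w_e = 1/branch length when ``weighted``
    (lengths required > 0), else 1.  Solved per axis as one sparse-free
    linear system (the graph Laplacian restricted to internal nodes).

    Returns an (n_nodes, n_axes) array in the phylogeny's preorder node
    order.
    """
    nodes = phylo.nodes
    n = len(nodes)
    root = nodes[0]
    if len(root.child_nodes()) < 2:
        raise PhylospaceError("root must have >= 2 children")
    tips = [i for i, nd in enumerate(nodes) if nd.is_leaf()]
    internal = [i for i, nd in enumerate(nodes) if not nd.is_leaf()]
    missing = [nodes[i].taxon.label for i in tips if nodes[i].taxon.label not in tip_scores]
    if missing:
        raise PhylospaceError(f"no scores for tip(s): {missing}")
    n_axes = len(np.atleast_1d(next(iter(tip_scores.values()))))
    X = np.zeros((n, n_axes))
    for i in tips:
        X[i] = np.atleast_1d(tip_scores[nodes[i].taxon.label])

    edges = phylo.edges()
    weights = []
    for p, c, length in edges:
        if weighted:
            if length is None or length <= 0:
                raise PhylospaceError(
                    "weighted reconstruction requires positive branch lengths"
                )
            weights.append(1.0 / length)
        else:
            weights.append(1.0)

    pos = {i: k for k, i in enumerate(internal)}
    m = len(internal)
    A = np.zeros((m, m))
    b = np.zeros((m, n_axes))
    for (p, c, _), w in zip(edges, weights):
        for u, v in ((p, c), (c, p)):
            if u in pos:
                A[pos[u], pos[u]] += w
                if v in pos:
                    A[pos[u], pos[v]] -= w
                else:
                    b[pos[u]] += w * X[v]
    if m:
        X[internal] = np.linalg.solve(A, b)
    return X


def niche_branch_lengths(phylo: Phylogeny, node_scores: np.ndarray) -> dict:
    """Euclidean edge lengths in the projected plane.

    Keys are (parent index, child index) pairs in preorder indexing.
    """
    out = {}
    for p, c, _ in phylo.edges():
        out[(p, c)] = float(np.linalg.norm(node_scores[p] - node_scores[c]))
    return out


@dataclass(frozen=True)
class NicheSpaceProjection:
    phylogeny: Phylogeny
    node_scores: np.ndarray
    branch_lengths: dict

    @property
    def total_length(self) -> float:
        return float(sum(self.branch_lengths.values()))

    def to_newick(self) -> str:
        """Newick with branch lengths replaced by niche branch lengths."""
        tree = self.phylogeny.tree.clone(depth=1)
        clone_nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(clone_nodes)}
        for nd in clone_nodes:
            parent = nd.parent_node
            if parent is not None:
                nd.edge.length = self.branch_lengths[(index[id(parent)], index[id(nd)])]
        return tree.as_string(schema="newick").strip()


def project_phylogeny(phylo: Phylogeny, species_ids, scores: np.ndarray,
                      axes=(0, 1), weighted: bool = False) -> NicheSpaceProjection:
    """Project tips at their ordination scores and reconstruct ancestors.

    ``scores`` rows follow ``species_ids``; the projection plane is the
    pair of score columns in ``axes``.
    """
    axes = tuple(axes)
    tip_scores = {
        sp: np.asarray(scores[i, list(axes)], dtype=float)
        for i, sp in enumerate(species_ids)
    }
    node_scores = ancestral_scores(phylo, tip_scores, weighted=weighted)
    lengths = niche_branch_lengths(phylo, node_scores)
    return NicheSpaceProjection(phylo, node_scores, lengths)
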