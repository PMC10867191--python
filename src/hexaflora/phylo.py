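"""Tree handling and the phylogenetic covariance matrix.

Trees come in as Newick with branch lengths; polytomies are kept as-is
because shared-path covariances are well defined on unresolved trees (no
random resolution is ever performed).  The among-species covariance under
Brownian motion is C[i, j] = shared root-to-MRCA path length, and Pagel's λ
rescales its off-diagonal part:

    C(λ) = λ·C + (1 − λ)·diag(C)

``lambda_max`` is the largest λ keeping C(λ) positive definite; on a
perfectly ultrametric tree it exceeds 1, which is why single-trait λ
estimates slightly above 1 can occur.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np


class TreeFormatError(ValueError):
    pass


class LabelMatchError(KeyError):
    pass


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    ``source`` may be a path or a Newick string.  Missing branch lengths on
    non-root edges raise an error naming the node; zero-length terminal
    branches are tolerated but flagged via a ``zero_length_tips`` annotation.
    """
    text = str(source)
    if "(" not in text:
        p = Path(source)
        if not p.exists():
            raise FileNotFoundError(source)
        text = p.read_text()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise TreeFormatError(f"unparseable Newick: {exc}") from exc
    zero_tips = []
    for node in tree:
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            name = node.taxon.label if node.taxon else "<internal>"
            raise TreeFormatError(f"missing branch length above node {name!r}")
        if node.edge.length < 0:
            name = node.taxon.label if node.taxon else "<internal>"
            raise TreeFormatError(f"negative branch length above node {name!r}")
        if node.is_leaf() and node.edge.length == 0:
            zero_tips.append(node.taxon.label)
    tree.zero_length_tips = zero_tips
    return tree


_RANK_MARKERS = re.compile(r"\s+(var|subsp|ssp|f|cv)\.?\s+\S+$", re.IGNORECASE)


def normalize_label(label: str) -> str:
    return label.strip().casefold().replace(" ", "_")


def _strip_rank(label: str) -> str:
    return normalize_label(_RANK_MARKERS.sub("", label.replace("_", " ")))


def match_labels(tree_labels: Iterable[str], wanted: Iterable[str]) -> dict[str, str]:
    """Map requested names onto tree tip labels.

    Exact (case/space-insensitive) matches first; infraspecific rank markers
    (var., subsp., ...) are stripped only for names that failed to match.
    Returns ``wanted_name -> tree_label``; unmatched names are absent.
    """
    tree_labels = list(tree_labels)
    norm = {normalize_label(t): t for t in tree_labels}
    out: dict[str, str] = {}
    missing = []
    for w in wanted:
        hit = norm.get(normalize_label(w))
        if hit is not None:
            out[w] = hit
        else:
            missing.append(w)
    if missing:
        stripped = {_strip_rank(t): t for t in tree_labels}
        for w in missing:
            hit = stripped.get(_strip_rank(w))
            if hit is not None:
                out[w] = hit
    return out


def prune_to(tree: dendropy.Tree, taxa: Sequence[str]) -> dendropy.Tree:
    """Induced subtree on ``taxa``: unifurcations collapsed, paths preserved."""
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    mapping = match_labels(tips, taxa)
    unmatched = sorted(set(taxa) - set(mapping))
    if not mapping:
        raise LabelMatchError(f"no requested taxa found in tree: {unmatched[:5]}...")
    if unmatched:
        raise LabelMatchError(f"taxa absent from tree: {unmatched}")
    sub = tree.clone(depth=1)
    sub.retain_taxa_with_labels(list(mapping.values()))
    sub.zero_length_tips = getattr(tree, "zero_length_tips", [])
    return sub


@dataclass
class PhyloCov:
    """Among-species Brownian covariance derived from a tree."""

    taxa: list[str]
    C: np.ndarray
    lambda_max: float = field(default=np.inf)

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("covariance shape does not match taxa")
        if not np.allclose(C, C.T):
            raise ValueError("covariance not symmetric")
        self.C = C
        if not np.isfinite(self.lambda_max) and len(self.taxa) > 1:
            self.lambda_max = _lambda_max(C)

    def decomposition(self):
        """Cached pieces for λ-profile likelihoods: with D = diag(C) and
        M = D^-½ C D^-½ − I, returns (s=D^-½, eigenvalues of M,
        eigenvectors of M, ln|D|).  C(λ) = D^½ Q (I + λ·diag(μ)) Qᵀ D^½."""
        if not hasattr(self, "_decomp"):
            d = np.diag(self.C)
            s = 1.0 / np.sqrt(d)
            M = self.C * np.outer(s, s)
            np.fill_diagonal(M, 0.0)
            mu, Q = np.linalg.eigh(M)
            self._decomp = (s, mu, Q, float(np.sum(np.log(d))))
        return self._decomp

    def with_lambda(self, lam: float) -> np.ndarray:
        """C(λ): off-diagonals scaled by λ, diagonal unchanged."""
        out = lam * self.C
        np.fill_diagonal(out, np.diag(self.C))
        return out

    def subset(self, taxa: Sequence[str]) -> "PhyloCov":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCov(list(taxa), self.C[np.ix_(idx, idx)])


def _lambda_max(C: np.ndarray, cap: float = 10.0) -> float:
    """Largest λ keeping C(λ) positive definite.

    With D = diag(C), C(λ) = D^½ (I + λ M) D^½ where
    M = D^-½ (C − D) D^-½; positive definiteness fails when
    1 + λ·min_eig(M) reaches 0.
    """
    d = np.diag(C)
    if np.any(d <= 0):
        raise ValueError("non-positive diagonal in covariance")
    s = 1.0 / np.sqrt(d)
    M = (C * np.outer(s, s))
    np.fill_diagonal(M, 0.0)
    mu_min = float(np.linalg.eigvalsh(M).min())
    if mu_min >= 0:
        return cap
    return min(cap, -1.0 / mu_min)


def phylo_cov(tree: dendropy.Tree) -> PhyloCov:
    """Shared-path covariance matrix for the tips of a rooted tree.

    C[i, i] is the root-to-tip depth; C[i, j] the depth of the MRCA of i and
    j, computed by a single preorder traversal (polytomies handled natively).
    """
    leaves = list(tree.leaf_node_iter())
    taxa = [lf.taxon.label for lf in leaves]
    index = {id(lf): k for k, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))

    # depth of every node, then: for each internal node, tips in different
    # child subtrees share exactly that node's depth
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depth[id(parent)] + (node.edge.length or 0.0)
        depth[id(node)] = d

    tipsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            k = index[id(node)]
            tipsets[id(node)] = [k]
            C[k, k] = depth[id(node)]
            continue
        children = [tipsets.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                ia = np.asarray(children[a])
                ib = np.asarray(children[b])
                C[np.ix_(ia, ib)] = d
                C[np.ix_(ib, ia)] = d
        tipsets[id(node)] = [k for ch in children for k in ch]

    if np.any(C < 0):
        raise TreeFormatError("negative branch lengths produce invalid covariance")
    return PhyloCov(taxa, C)
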