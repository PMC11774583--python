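"""Rooted, branch-length-bearing trees and patristic distances.

Trees are represented as :class:`skbio.TreeNode` throughout the package.  The
helpers here enforce the invariants the downstream scan relies on (unique tip
labels, every non-root edge carrying a non-negative length) and provide the
clade geometry used by the distal-tenth node enumeration: per-node tip-to-tip
diameters, clade branch lengths and stable node identifiers.
"""

from __future__ import annotations

import hashlib
import io
import re
from typing import Iterable, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode


class TreeValidationError(ValueError):
    """A tree violates a structural invariant (labels, branch lengths)."""


_COMMENT_RE = re.compile(r"\[[^\]\[]*\]")


def _strip_newick_comments(text: str) -> str:
    """Remove square-bracket comments outside of quoted labels."""
    out: list[str] = []
    in_quote = False
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "'":
            in_quote = not in_quote
            out.append(ch)
            i += 1
        elif ch == "[" and not in_quote:
            depth = 1
            i += 1
            while i < len(text) and depth:
                if text[i] == "[":
                    depth += 1
                elif text[i] == "]":
                    depth -= 1
                i += 1
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def read_newick(path, assume_zero_lengths: bool = False) -> TreeNode:
    """Read a rooted tree from a Newick file.

    Quoted labels and internal support labels are accepted; square-bracket
    comments are ignored.  Missing branch lengths raise
    :class:`TreeValidationError` unless ``assume_zero_lengths`` is set, in
    which case they are mapped to 0.  Duplicate tip labels always raise.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    text = _strip_newick_comments(text)
    tree = TreeNode.read(io.StringIO(text), format="newick", convert_underscores=False)
    validate_tree(tree, assume_zero_lengths=assume_zero_lengths)
    return tree


def parse_newick(text: str, assume_zero_lengths: bool = False) -> TreeNode:
    """Parse a Newick string (convenience wrapper around :func:`read_newick`)."""
    return read_newick(io.StringIO(text), assume_zero_lengths=assume_zero_lengths)


def write_newick(tree: TreeNode, path) -> None:
    """Write a tree to Newick with 10 significant digits on branch lengths."""
    if hasattr(path, "write"):
        tree.write(path, format="newick")
    else:
        with open(path, "w", encoding="utf-8") as fh:
            tree.write(fh, format="newick")


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def validate_tree(tree: TreeNode, assume_zero_lengths: bool = False) -> None:
    """Check tip-label uniqueness and branch-length presence/positivity."""
    seen: set[str] = set()
    for tip in tree.tips():
        if tip.name is None:
            raise TreeValidationError("tree contains an unlabeled tip")
        if tip.name in seen:
            raise TreeValidationError(f"duplicate tip label: {tip.name!r}")
        seen.add(tip.name)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if assume_zero_lengths:
                node.length = 0.0
            else:
                raise TreeValidationError(
                    f"missing branch length on node {node.name!r}; "
                    "pass assume_zero_lengths=True to map them to 0"
                )
        if node.length < 0:
            raise TreeValidationError(
                f"negative branch length {node.length} on node {node.name!r}"
            )
    if tree.length is None:
        tree.length = 0.0


def total_branch_length(tree: TreeNode) -> float:
    """Sum of all edge lengths (the root's stem, if any, is excluded)."""
    return float(sum(n.length or 0.0 for n in tree.traverse(include_self=False)))


def patristic_distances(tree: TreeNode, tips: Sequence[str] | None = None) -> DistanceMatrix:
    """Tip-to-tip path-length distances.

    Parameters
    ----------
    tree : TreeNode
    tips : sequence of tip labels, optional
        Restrict the matrix to these tips (order preserved).  Unknown labels
        raise ``KeyError``.

    Returns
    -------
    skbio.DistanceMatrix
    """
    if tips is None:
        return tree.tip_tip_distances()
    available = {t.name for t in tree.tips()}
    missing = [t for t in tips if t not in available]
    if missing:
        raise KeyError(f"tip label(s) not in tree: {missing}")
    dm = tree.tip_tip_distances(endpoints=list(tips))
    # enforce requested ordering
    return dm.filter(list(tips))


def node_id(node: TreeNode) -> str:
    """Stable identifier for an internal node: hash of its sorted tip set.

    Independent of node iteration order and of the file layout of the input
    tree, so per-node RNG streams and cross-stage joins are reproducible.
    """
    tips = sorted(t.name for t in node.tips())
    digest = hashlib.sha1("\x00".join(tips).encode("utf-8")).hexdigest()
    return f"node_{digest[:12]}"


def node_id_for_tips(tip_labels: Iterable[str]) -> str:
    """The :func:`node_id` a node with exactly these tips would carry."""
    tips = sorted(tip_labels)
    digest = hashlib.sha1("\x00".join(tips).encode("utf-8")).hexdigest()
    return f"node_{digest[:12]}"


def clade_diameters(tree: TreeNode) -> dict[int, float]:
    """Maximum within-clade tip-to-tip distance for every node.

    Returns a mapping ``id(node) -> diameter`` computed in one postorder pass
    (tips have diameter 0).  ``id()`` keys avoid requiring unique internal
    names.
    """
    diam: dict[int, float] = {}
    depth: dict[int, float] = {}  # max distance from node down to any tip
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            diam[id(node)] = 0.0
            depth[id(node)] = 0.0
            continue
        child_depths = [depth[id(c)] + (c.length or 0.0) for c in node.children]
        child_diams = [diam[id(c)] for c in node.children]
        depth[id(node)] = max(child_depths)
        through = 0.0
        if len(child_depths) >= 2:
            top2 = sorted(child_depths, reverse=True)[:2]
            through = top2[0] + top2[1]
        diam[id(node)] = max(child_diams + [through])
    return diam


def tree_diameter(tree: TreeNode) -> float:
    """Maximum tip-to-tip patristic distance of the whole tree."""
    return clade_diameters(tree)[id(tree)]


def clade_branch_length(node: TreeNode, include_subtending: bool = True) -> float:
    """Total branch length of the clade rooted at ``node``.

    ``include_subtending`` counts the edge above ``node`` (absent for the
    root), treating the clade's stem as part of its diversification history.
    """
    total = sum(n.length or 0.0 for n in node.traverse(include_self=False))
    if include_subtending and node.parent is not None:
        total += node.length or 0.0
    return float(total)


def check_distance_matrix(dm: DistanceMatrix) -> None:
    """Assert symmetry, zero diagonal and non-negativity (defensive check)."""
    a = dm.data
    if not np.allclose(a, a.T):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(a), 0.0):
        raise ValueError("distance matrix has a non-zero diagonal")
    if (a < 0).any():
        raise ValueError("distance matrix has negative entries")
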