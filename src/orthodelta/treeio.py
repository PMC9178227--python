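"""Phylogenetic tree I/O and elementary manipulations.

Trees are represented as :class:`skbio.TreeNode` objects throughout the
package.  This module wraps Newick parsing/writing with stricter validation
(unique leaf labels, balanced parentheses), and provides the tree operations
the decomposition and concordance machinery is built from: midpoint rooting,
collapsing of short internal branches, pruning to a leaf subset, bipartition
enumeration, Robinson–Foulds distances and patristic distances.

Branch lengths are in whatever units the input trees carry (substitutions
per site for ML trees, change counts for parsimony trees, coalescent units
for simulated trees); nothing here converts between unit systems.
"""

from __future__ import annotations

import io
import warnings
from pathlib import Path
from typing import Iterable, Sequence

from skbio import TreeNode

__all__ = [
    "NewickParseError",
    "TreeError",
    "UnmappedLabelError",
    "SpeciesMap",
    "parse_newick",
    "write_newick",
    "read_trees",
    "midpoint_root",
    "collapse_short_branches",
    "prune_to",
    "bipartitions",
    "rf_distance",
    "patristic_distance",
    "tip_names",
]

Tree = TreeNode  # public alias: the package's tree container


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed or violates invariants."""


class TreeError(ValueError):
    """Raised when a tree operation's preconditions are violated."""


class UnmappedLabelError(KeyError):
    """Raised when a gene-copy label cannot be resolved to a species."""


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _check_balanced(text: str) -> None:
    depth = 0
    in_quote = False
    for pos, ch in enumerate(text):
        if ch == "'":
            in_quote = not in_quote
        elif not in_quote:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise NewickParseError(
                        f"unbalanced parentheses: unmatched ')' at position {pos}"
                    )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced parentheses: {depth} '(' left open"
        )
    if in_quote:
        raise NewickParseError("unterminated quoted label")


def parse_newick(text: str) -> TreeNode:
    """Parse a single Newick statement into a tree.

    Quoted labels, internal-node labels (kept as annotations), missing branch
    lengths and scientific-notation lengths are all accepted.  Leaf labels
    must be unique; duplicates, unbalanced parentheses and empty input raise
    :class:`NewickParseError`.
    """
    stripped = text.strip()
    if not stripped:
        raise NewickParseError("empty Newick input")
    if not stripped.endswith(";"):
        raise NewickParseError("Newick statement must end with ';'")
    _check_balanced(stripped)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree = TreeNode.read(io.StringIO(stripped), format="newick")
    except Exception as exc:  # skbio raises NewickFormatError subclasses
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    seen: set[str] = set()
    leaves = [tree] if tree.is_tip() else list(tree.tips())
    for tip in leaves:
        if tip.name is None:
            raise NewickParseError("unlabeled leaf in Newick input")
        if tip.name in seen:
            raise NewickParseError(f"duplicate leaf label {tip.name!r}")
        seen.add(tip.name)
    if not seen:
        raise NewickParseError("tree has no leaves")
    return tree


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_trees(path: str | Path) -> list[TreeNode]:
    """Read trees from a file with one Newick statement per line.

    A file containing a single tree is the one-line special case, so the same
    reader serves both "one per file" and "treelist" layouts.
    """
    trees = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        try:
            trees.append(parse_newick(line))
        except NewickParseError as exc:
            raise NewickParseError(f"{path}:{lineno}: {exc}") from exc
    if not trees:
        raise NewickParseError(f"{path}: no trees found")
    return trees


def tip_names(tree: TreeNode) -> list[str]:
    if tree.is_tip():
        return [tree.name]
    return [t.name for t in tree.tips()]


# ---------------------------------------------------------------------------
# Species mapping
# ---------------------------------------------------------------------------

class SpeciesMap:
    """Resolve gene-copy labels to species identifiers.

    Two construction modes:

    * **delimiter rule** (default): the species is the label prefix before
      the first occurrence of ``sep`` (default ``"|"``).  A label without the
      separator is taken to be a bare species name, so single-copy species
      trees resolve transparently.
    * **explicit table**: a ``copy_id -> species_id`` mapping; labels absent
      from the table raise :class:`UnmappedLabelError` rather than being
      silently dropped, since silent drops corrupt occupancy counts.
    """

    def __init__(self, table: dict[str, str] | None = None, sep: str = "|"):
        self.table = dict(table) if table is not None else None
        self.sep = sep

    @classmethod
    def from_delimiter(cls, sep: str = "|") -> "SpeciesMap":
        return cls(table=None, sep=sep)

    @classmethod
    def from_table(cls, path: str | Path) -> "SpeciesMap":
        """Load a 2-column tab-separated file (copy_id, species_id).

        A header line is detected (and skipped) when its first field is
        literally ``copy_id``.
        """
        table: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            if lineno == 1 and parts[0].lower() == "copy_id":
                continue
            table[parts[0]] = parts[1]
        return cls(table=table)

    def __call__(self, label: str) -> str:
        if self.table is not None:
            try:
                return self.table[label]
            except KeyError:
                raise UnmappedLabelError(
                    f"copy label {label!r} not present in the species map"
                ) from None
        return label.split(self.sep, 1)[0]

    def species_of(self, tree: TreeNode) -> dict[str, str]:
        """Map every leaf of *tree* to its species (errors propagate)."""
        return {t.name: self(t.name) for t in tree.tips()}


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def _require_lengths(tree: TreeNode) -> None:
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise TreeError("operation requires branch lengths on every branch")


def _path(a: TreeNode, b: TreeNode) -> list[TreeNode]:
    """Node path from leaf *a* to leaf *b* through their LCA."""
    anc_a = [a] + list(a.ancestors())
    anc_b = [b] + list(b.ancestors())
    set_a = set(map(id, anc_a))
    lca = next(n for n in anc_b if id(n) in set_a)
    up = []
    for n in anc_a:
        up.append(n)
        if n is lca:
            break
    down = []
    for n in anc_b:
        if n is lca:
            break
        down.append(n)
    return up + list(reversed(down))


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    When several leaf pairs attain the maximum path length, the
    lexicographically smallest (leafA, leafB) name pair is used, which makes
    the operation deterministic.  If every branch has zero length there is no
    midpoint; the tree is then rooted on the first internal edge in preorder
    and a warning is emitted.

    Raises :class:`TreeError` when branch lengths are missing or the tree has
    fewer than two leaves.
    """
    tree = tree.copy()
    tips = sorted(tree.tips(), key=lambda t: t.name)
    if len(tips) < 2:
        raise TreeError("midpoint rooting requires at least 2 leaves")
    _require_lengths(tree)

    dm = tree.tip_tip_distances()
    best: tuple[str, str] | None = None
    best_d = -1.0
    names = sorted(dm.ids)
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            d = dm[na, nb]
            if d > best_d:
                best_d = d
                best = (na, nb)
    assert best is not None

    if best_d <= 0.0:
        warnings.warn(
            "all path lengths are zero; rooting on the first internal edge",
            stacklevel=2,
        )
        for node in tree.preorder(include_self=False):
            if not node.is_tip():
                return tree.root_at(node, above=0.0, reset=True)
        # no internal edge at all (star of 2 leaves): root above first tip
        return tree.root_at(tree.find(names[0]), above=0.0, reset=True)

    a = tree.find(best[0])
    b = tree.find(best[1])
    target = best_d / 2.0
    path = _path(a, b)
    cum = 0.0
    for u, v in zip(path, path[1:]):
        child = u if u.parent is v else v
        length = child.length or 0.0
        if cum + length >= target - 1e-12:
            rem = min(max(target - cum, 0.0), length)
            above = rem if child is u else length - rem
            return tree.root_at(child, above=above, reset=True)
        cum += length
    # numerically the midpoint is at the far end of the path
    return tree.root_at(path[-1], above=path[-1].length, reset=True)


# ---------------------------------------------------------------------------
# Editing
# ---------------------------------------------------------------------------

def collapse_short_branches(tree: TreeNode, tol: float = 0.0) -> TreeNode:
    """Contract internal branches with length <= *tol* into polytomies.

    Terminal branches are never collapsed (leaves must survive), and the
    default tolerance of 0 contracts exactly the zero-length branches.
    Branches with no recorded length are left alone.
    """
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    tree = tree.copy()
    doomed = [
        node
        for node in tree.postorder(include_self=False)
        if not node.is_tip()
        and node.length is not None
        and node.length <= tol
    ]
    for node in doomed:
        node.unpack()
    return tree


def prune_to(tree: TreeNode, keep: Iterable[str]) -> TreeNode:
    """Restrict a tree to a subset of its leaves.

    Degree-2 nodes left by the pruning are suppressed with their branch
    lengths summed, so patristic distances among kept leaves are conserved.
    """
    keep = set(keep)
    if not keep:
        raise TreeError("keep set must contain at least one leaf")
    have = set(tip_names(tree))
    unknown = keep - have
    if unknown:
        raise TreeError(f"labels not in tree: {sorted(unknown)}")
    return tree.shear(keep)


# ---------------------------------------------------------------------------
# Bipartitions and distances
# ---------------------------------------------------------------------------

def bipartitions(tree: TreeNode) -> frozenset[frozenset[str]]:
    """The non-trivial bipartitions (splits) of a tree, viewed unrooted.

    Each split is canonicalized as the side *not* containing the
    lexicographically smallest leaf, so rooted and unrooted encodings of the
    same topology yield identical sets.
    """
    all_tips = frozenset(tip_names(tree))
    n = len(all_tips)
    if n < 4:
        return frozenset()
    ref = min(all_tips)
    splits: set[frozenset[str]] = set()
    cache: dict[int, frozenset[str]] = {}
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            cache[id(node)] = frozenset([node.name])
            continue
        side = frozenset().union(*(cache[id(c)] for c in node.children))
        cache[id(node)] = side
        if ref in side:
            side = all_tips - side
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return frozenset(splits)


def rf_distance(t1: TreeNode, t2: TreeNode) -> tuple[int, float]:
    """Robinson–Foulds distance between two trees on the same leaf set.

    Returns ``(raw, normalized)`` where *raw* is the size of the symmetric
    difference of the two non-trivial split sets, and *normalized* divides by
    the total number of non-trivial splits present in both trees — which is
    ``2(n-3)`` for two binary trees and smaller when polytomies are present.
    """
    l1, l2 = set(tip_names(t1)), set(tip_names(t2))
    if l1 != l2:
        raise TreeError(
            "leaf sets differ: only in first "
            f"{sorted(l1 - l2)}, only in second {sorted(l2 - l1)}"
        )
    s1, s2 = bipartitions(t1), bipartitions(t2)
    raw = len(s1 ^ s2)
    denom = len(s1) + len(s2)
    return raw, (raw / denom if denom else 0.0)


def patristic_distance(tree: TreeNode, a: str, b: str) -> float:
    """Sum of branch lengths along the unique path between leaves *a*, *b*."""
    if a == b:
        return 0.0
    na = tree.find(a)
    nb = tree.find(b)
    total = 0.0
    path = _path(na, nb)
    for u, v in zip(path, path[1:]):
        child = u if u.parent is v else v
        if child.length is None:
            raise TreeError("patristic distance requires branch lengths")
        total += child.length
    return total
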