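"""Gene concordance factors: branch-wise gene-tree classification.

Every internal branch of a rooted binary species tree defines a
quadripartition of the species set: the two clades below the branch (A, B),
the sibling clade (C) and everything else (D).  A single-copy gene tree is
*decisive* for the branch when it samples at least one species from each
group; a decisive tree is then classified by which of the three possible
resolutions of the induced quartet it contains:

* ``CONCORDANT``    — the split (A∪B | C∪D), i.e. the species-tree branch;
* ``ALT1`` / ``ALT2`` — the two nearest-neighbour-interchange alternatives
  (A∪C | B∪D) and (B∪C | A∪D), the "minor" topologies;
* ``PARAPHYLETIC``  — none of the three splits is present (possible when the
  gene tree resolves the four groups non-monophyletically or a polytomy
  hides the resolution).

The gene concordance factor (gCF) of a branch is the percentage of decisive
gene trees that are concordant.  Splits are tested on the gene tree viewed
unrooted, so the classification is invariant to gene-tree rooting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd
from skbio import TreeNode

from .treeio import SpeciesMap, TreeError, tip_names

__all__ = [
    "Classification",
    "Quadripartition",
    "BranchConcordance",
    "internal_branches",
    "quadripartition",
    "classify",
    "classification_matrix",
    "concordance_table",
    "discordant_fraction",
    "table_to_dataframe",
]


class Classification(enum.Enum):
    CONCORDANT = "concordant"
    ALT1 = "alt1"
    ALT2 = "alt2"
    PARAPHYLETIC = "paraphyletic"
    NOT_DECISIVE = "not_decisive"


@dataclass(frozen=True)
class Quadripartition:
    """The four disjoint species groups around an internal branch."""

    branch_id: str
    a: frozenset[str]
    b: frozenset[str]
    c: frozenset[str]
    d: frozenset[str]

    @property
    def groups(self) -> tuple[frozenset[str], ...]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class BranchConcordance:
    """Per-branch gene-tree tallies and the gene concordance factor."""

    branch_id: str
    quad: Quadripartition
    n_concordant: int = 0
    n_alt1: int = 0
    n_alt2: int = 0
    n_paraphyletic: int = 0

    @property
    def n_decisive(self) -> int:
        return (
            self.n_concordant + self.n_alt1 + self.n_alt2 + self.n_paraphyletic
        )

    @property
    def gcf(self) -> float | None:
        """Gene concordance factor, in percent; None when no tree decides."""
        if self.n_decisive == 0:
            return None
        return 100.0 * self.n_concordant / self.n_decisive


# ---------------------------------------------------------------------------
# Species-tree branch enumeration
# ---------------------------------------------------------------------------

def _validate_species_tree(stree: TreeNode) -> None:
    names = tip_names(stree)
    if len(names) != len(set(names)):
        raise TreeError("species tree has duplicate leaf labels")
    if len(names) < 4:
        raise TreeError("concordance analysis needs >= 4 species")
    for node in stree.non_tips(include_self=True):
        if len(node.children) != 2:
            raise TreeError("species tree must be rooted and strictly binary")


def internal_branches(stree: TreeNode) -> list[Quadripartition]:
    """Quadripartitions for every internal branch, in preorder.

    The two rooted edges adjacent to the root correspond to a single unrooted
    internal branch and are emitted once (with C and D taken from the sibling
    clade's two children).  Branch ids ``b1, b2, ...`` follow preorder and
    are stable for a fixed species tree.
    """
    _validate_species_tree(stree)
    leafset = frozenset(tip_names(stree))
    quads: list[Quadripartition] = []
    seen_root_edge = False
    counter = 0
    for node in stree.preorder(include_self=False):
        if node.is_tip():
            continue
        parent = node.parent
        ab = [frozenset(t.name for t in c.tips()) | (
            frozenset([c.name]) if c.is_tip() else frozenset()
        ) for c in node.children]
        a, b = ab
        if parent.is_root():
            sibling = next(c for c in parent.children if c is not node)
            if sibling.is_tip():
                continue  # unrooted endpoint is a leaf: terminal branch
            if seen_root_edge:
                continue  # same unrooted branch as the other root child
            seen_root_edge = True
            cs = [frozenset(t.name for t in c.tips()) | (
                frozenset([c.name]) if c.is_tip() else frozenset()
            ) for c in sibling.children]
            c_grp, d_grp = cs
        else:
            sibling = next(c for c in parent.children if c is not node)
            c_grp = frozenset(
                [sibling.name]
            ) if sibling.is_tip() else frozenset(t.name for t in sibling.tips())
            d_grp = leafset - a - b - c_grp
        counter += 1
        quads.append(
            Quadripartition(f"b{counter}", a, b, c_grp, d_grp)
        )
    return quads


def quadripartition(stree: TreeNode, branch_id: str) -> Quadripartition:
    """Look up one branch's quadripartition by its stable id."""
    for quad in internal_branches(stree):
        if quad.branch_id == branch_id:
            return quad
    raise TreeError(f"no quadripartition for branch {branch_id!r}")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _species_splits(
    gtree: TreeNode, smap: SpeciesMap
) -> tuple[frozenset[str], set[frozenset[str]]]:
    """Present species and the gene tree's splits at species level.

    Raises when a species appears twice (decompose the family first).
    """
    leaf_species = {}
    for name in tip_names(gtree):
        sp = smap(name)
        if sp in leaf_species.values():
            raise TreeError(
                f"species {sp!r} has multiple copies in the gene tree; "
                "run a decomposition method first"
            )
        leaf_species[name] = sp
    present = frozenset(leaf_species.values())
    splits: set[frozenset[str]] = set()
    cache: dict[int, frozenset[str]] = {}
    for node in gtree.postorder(include_self=False):
        if node.is_tip():
            cache[id(node)] = frozenset([leaf_species[node.name]])
            continue
        side = frozenset().union(*(cache[id(c)] for c in node.children))
        cache[id(node)] = side
        if 2 <= len(side) <= len(present) - 2:
            splits.add(side)
    return present, splits


def _classify_splits(
    present: frozenset[str],
    splits: set[frozenset[str]],
    quad: Quadripartition,
) -> Classification:
    groups = [g & present for g in quad.groups]
    if any(not g for g in groups):
        return Classification.NOT_DECISIVE
    a, b, c, d = groups
    kept = a | b | c | d
    candidates = {
        Classification.CONCORDANT: frozenset(a | b),
        Classification.ALT1: frozenset(a | c),
        Classification.ALT2: frozenset(b | c),
    }
    hits = []
    for split in splits:
        x = split & kept
        if not x or x == kept:
            continue
        y = kept - x
        for label, side in candidates.items():
            if x == side or y == side:
                hits.append(label)
    hits = sorted(set(hits), key=lambda h: h.value)
    assert len(hits) <= 1, "conflicting splits cannot coexist in one tree"
    return hits[0] if hits else Classification.PARAPHYLETIC


def classify(
    gtree: TreeNode, smap: SpeciesMap, quad: Quadripartition
) -> Classification:
    """Classify one single-copy gene tree against one species-tree branch."""
    present, splits = _species_splits(gtree, smap)
    return _classify_splits(present, splits, quad)


def classification_matrix(
    gtrees: list[TreeNode], smap: SpeciesMap, stree: TreeNode
) -> tuple[list[Quadripartition], list[list[Classification]]]:
    """Classify every gene tree at every internal branch.

    Returns the branch quadripartitions and, per branch, the list of labels
    across gene trees (in input order).  Gene-tree splits are computed once
    per tree, so the cost is linear in #trees x #branches.
    """
    if not gtrees:
        raise ValueError("at least one gene tree is required")
    quads = internal_branches(stree)
    prepared = [_species_splits(g, smap) for g in gtrees]
    labels = [
        [_classify_splits(present, splits, quad) for present, splits in prepared]
        for quad in quads
    ]
    return quads, labels


def concordance_table(
    gtrees: list[TreeNode], smap: SpeciesMap, stree: TreeNode
) -> list[BranchConcordance]:
    """Branch-wise concordance tallies over a collection of gene trees."""
    quads, labels = classification_matrix(gtrees, smap, stree)
    out = []
    for quad, row in zip(quads, labels):
        bc = BranchConcordance(branch_id=quad.branch_id, quad=quad)
        for lab in row:
            if lab is Classification.CONCORDANT:
                bc.n_concordant += 1
            elif lab is Classification.ALT1:
                bc.n_alt1 += 1
            elif lab is Classification.ALT2:
                bc.n_alt2 += 1
            elif lab is Classification.PARAPHYLETIC:
                bc.n_paraphyletic += 1
        out.append(bc)
    return out


def discordant_fraction(
    bc: BranchConcordance, include_paraphyletic: bool = False
) -> float:
    """Fraction of decisive trees that are discordant at the branch.

    By default only the two minor topologies count as discordant (they are
    what the introgression test consumes); with ``include_paraphyletic`` the
    complement of the concordant fraction is returned instead.
    """
    if bc.n_decisive == 0:
        raise ValueError(
            f"{bc.branch_id}: discordant fraction undefined (no decisive trees)"
        )
    if include_paraphyletic:
        return 1.0 - bc.n_concordant / bc.n_decisive
    return (bc.n_alt1 + bc.n_alt2) / bc.n_decisive


def table_to_dataframe(table: list[BranchConcordance]) -> pd.DataFrame:
    """Tabular export: one row per internal branch."""
    rows = []
    for bc in table:
        q = bc.quad
        rows.append(
            {
                "branch_id": bc.branch_id,
                "groups": ";".join(
                    ",".join(sorted(g)) for g in (q.a, q.b, q.c, q.d)
                ),
                "n_decisive": bc.n_decisive,
                "n_concordant": bc.n_concordant,
                "n_alt1": bc.n_alt1,
                "n_alt2": bc.n_alt2,
                "n_paraphyletic": bc.n_paraphyletic,
                "gCF": bc.gcf,
            }
        )
    return pd.DataFrame(rows)
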