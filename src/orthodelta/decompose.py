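"""Decomposition of multi-copy gene families into ortholog sets.

A gene family is a gene tree whose leaves are gene copies, several of which
may belong to the same species.  Orthologs (copies diverging at speciations)
are what species-tree and introgression analyses need; paralogs (copies
diverging at duplications) must be filtered out.  This module implements the
tree-based decomposition toolbox:

* ``filter_scc``        — keep only families that are already single-copy;
* ``trim_lsd``          — collapse lineage-specific duplications to one copy;
* ``trim_tsd``          — collapse duplications private to a species pair;
* ``extract_se``        — subtree extraction: all maximal duplicate-free
  rooted subtrees after midpoint rooting and LSD/TSD trimming;
* ``extract_mi``        — maximum inclusion: iteratively cut the branch that
  frees the largest duplicate-free subtree, after removing branches longer
  than a cutoff (paralog/long-branch guard);
* ``extract_mo``        — monophyletic outgroups: root on a single-copy
  monophyletic outgroup and prune the smaller side of every duplication node
  from the root toward the tips;
* ``sample_one_paralog``— random single copy per species, orthology ignored;
* ``family_stats``      — family/copy accounting and per-species occupancy.

Every method applies a MIN-k occupancy threshold (``FilterConfig.min_taxa``)
after extraction, counting distinct species.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from skbio import TreeNode

from ._util import clean, derive_rng, detach, tips_of
from .treeio import SpeciesMap, TreeError, midpoint_root, prune_to, tip_names

__all__ = [
    "GeneFamily",
    "OrthologSet",
    "FilterConfig",
    "MIConfig",
    "FamilyStats",
    "filter_scc",
    "trim_lsd",
    "trim_tsd",
    "extract_se",
    "extract_mi",
    "extract_mo",
    "sample_one_paralog",
    "family_stats",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class GeneFamily:
    """A multi-copy gene tree plus its copy-to-species mapping.

    ``lengths`` optionally maps copy ids to ungapped sequence lengths
    (residues); it drives the survivor choice when collapsing
    lineage-specific duplicates.  ``removed`` accumulates copies pruned by
    the trimming operations applied so far.
    """

    tree: TreeNode
    smap: SpeciesMap
    lengths: dict[str, int] | None = None
    family_id: str = "family"
    removed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in tip_names(self.tree):
            self.smap(name)  # raises UnmappedLabelError on failure
            if self.lengths is not None and name not in self.lengths:
                raise ValueError(
                    f"{self.family_id}: no sequence length for copy {name!r}"
                )

    def copies(self) -> list[str]:
        return tip_names(self.tree)

    def species_counts(self) -> Counter:
        return Counter(self.smap(n) for n in self.copies())


@dataclass
class OrthologSet:
    """A single-copy-per-species tree extracted from a gene family."""

    tree: TreeNode
    members: list[str]
    method: str  # SCC, LSD, TSD, MI, MO, SE or ONE
    source_family: str
    removed: list[str] = field(default_factory=list)

    @property
    def n_taxa(self) -> int:
        return len(self.members)


@dataclass
class FilterConfig:
    """Occupancy threshold: keep sets sampling at least ``min_taxa`` species."""

    min_taxa: int = 4

    def __post_init__(self) -> None:
        if self.min_taxa < 2:
            raise ValueError("min_taxa must be >= 2")


@dataclass
class MIConfig(FilterConfig):
    """Maximum-inclusion parameters.

    ``long_branch_cutoff`` is in the tree's branch-length units (e.g. 0.4
    substitutions/site for ML trees, 500 changes for parsimony trees);
    ``None`` disables the long-branch cut.
    """

    long_branch_cutoff: float | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.long_branch_cutoff is not None and self.long_branch_cutoff <= 0:
            raise ValueError("long_branch_cutoff must be positive")


# ---------------------------------------------------------------------------
# Internal helpers
# ---------------------------------------------------------------------------

def _species_counter(node: TreeNode, smap: SpeciesMap) -> Counter:
    return Counter(smap(t.name) for t in tips_of(node))


def _duplicate_free(counter: Counter) -> bool:
    return all(v == 1 for v in counter.values())


def _remove_tips(tree: TreeNode, names: set[str]) -> TreeNode:
    for tip in [t for t in tips_of(tree) if t.name in names]:
        if tip.parent is None:
            raise TreeError("cannot remove the only leaf of a tree")
        node = tip
        while node.parent is not None:
            parent = node.parent
            parent.remove(node)
            if parent.children:
                break
            node = parent  # ancestor emptied out: cascade the removal
    return clean(tree)


def _rooted(family: GeneFamily) -> TreeNode:
    """A working copy, midpoint-rooted if the stored tree is unrooted."""
    tree = family.tree.copy()
    if len(tree.children) > 2:
        tree = midpoint_root(tree)
    return tree


def _root_to_tip(tree: TreeNode, tip: TreeNode) -> float:
    d = 0.0
    node = tip
    while node.parent is not None:
        d += node.length or 0.0
        node = node.parent
    return d


# ---------------------------------------------------------------------------
# Single-copy clusters
# ---------------------------------------------------------------------------

def filter_scc(family: GeneFamily, cfg: FilterConfig) -> OrthologSet | None:
    """Keep the family iff it is single-copy in every represented species."""
    counts = family.species_counts()
    if any(v > 1 for v in counts.values()) or len(counts) < cfg.min_taxa:
        return None
    return OrthologSet(
        tree=family.tree.copy(),
        members=family.copies(),
        method="SCC",
        source_family=family.family_id,
        removed=[],
    )


# ---------------------------------------------------------------------------
# Lineage-specific duplicates
# ---------------------------------------------------------------------------

def _maximal_single_species_clades(
    tree: TreeNode, smap: SpeciesMap
) -> list[TreeNode]:
    out = []
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            continue
        cnt = _species_counter(node, smap)
        if len(cnt) == 1 and sum(cnt.values()) >= 2:
            parent = node.parent
            if parent is None or len(_species_counter(parent, smap)) > 1:
                out.append(node)
    return out


def trim_lsd(family: GeneFamily) -> GeneFamily:
    """Reduce every lineage-specific duplication to a single surviving copy.

    Each maximal clade whose leaves all belong to one species (and holds at
    least two copies) is replaced by one copy.  With a sequence-length table
    the survivor is the copy closest in length to the median length over all
    sequences of the family (lower median for even counts; ties broken by
    tree order).  Without lengths the survivor is the copy with the smallest
    root-to-tip distance, ties broken lexicographically.
    """
    tree = _rooted(family)
    removed: list[str] = []
    med = None
    if family.lengths is not None:
        vals = sorted(family.lengths[n] for n in tip_names(tree))
        med = vals[(len(vals) - 1) // 2]
    clades = _maximal_single_species_clades(tree, family.smap)
    doomed: set[str] = set()
    for clade in clades:
        tips = tips_of(clade)
        if med is not None:
            best = min(tips, key=lambda t: abs(family.lengths[t.name] - med))
        else:
            best = min(tips, key=lambda t: (_root_to_tip(tree, t), t.name))
        doomed.update(t.name for t in tips if t is not best)
    if doomed:
        tree = _remove_tips(tree, doomed)
        removed = sorted(doomed)
    lengths = None
    if family.lengths is not None:
        lengths = {n: family.lengths[n] for n in tip_names(tree)}
    return GeneFamily(
        tree=tree,
        smap=family.smap,
        lengths=lengths,
        family_id=family.family_id,
        removed=family.removed + removed,
    )


# ---------------------------------------------------------------------------
# Two-species duplicates
# ---------------------------------------------------------------------------

def _maximal_two_species_clades(tree: TreeNode, smap: SpeciesMap) -> list[TreeNode]:
    out = []
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            continue
        cnt = _species_counter(node, smap)
        if len(cnt) == 2 and sum(cnt.values()) >= 3:
            parent = node.parent
            if parent is None or len(_species_counter(parent, smap)) != 2:
                out.append(node)
    return out


def trim_tsd(family: GeneFamily) -> GeneFamily:
    """Reduce every two-species duplication clade to its closest cross pair.

    Lineage-specific duplicates are trimmed first.  In each maximal clade
    whose copies come from exactly two species (with at least one species
    duplicated), the cross-species pair with the minimum patristic distance
    survives; equal distances are broken by the lexicographically smallest
    (copy, copy) pair.  Branch lengths are required.
    """
    family = trim_lsd(family)
    tree = family.tree
    doomed: set[str] = set()
    from .treeio import patristic_distance

    for clade in _maximal_two_species_clades(tree, family.smap):
        tips = tips_of(clade)
        by_sp: dict[str, list[TreeNode]] = {}
        for t in tips:
            by_sp.setdefault(family.smap(t.name), []).append(t)
        sp_a, sp_b = sorted(by_sp)
        best_pair = None
        best_key = None
        for ta in by_sp[sp_a]:
            for tb in by_sp[sp_b]:
                d = patristic_distance(tree, ta.name, tb.name)
                names = tuple(sorted((ta.name, tb.name)))
                key = (d, names)
                if best_key is None or key < best_key:
                    best_key = key
                    best_pair = {ta.name, tb.name}
        doomed.update(t.name for t in tips if t.name not in best_pair)
    if doomed:
        tree = _remove_tips(tree, doomed)
    lengths = None
    if family.lengths is not None:
        lengths = {n: family.lengths[n] for n in tip_names(tree)}
    return GeneFamily(
        tree=tree,
        smap=family.smap,
        lengths=lengths,
        family_id=family.family_id,
        removed=family.removed + sorted(doomed),
    )


# ---------------------------------------------------------------------------
# Subtree extraction (SE)
# ---------------------------------------------------------------------------

def extract_se(family: GeneFamily, cfg: FilterConfig) -> list[OrthologSet]:
    """All maximal duplicate-free rooted subtrees of the trimmed family.

    The family is midpoint-rooted (if needed) and LSD/TSD-trimmed, then every
    node whose subtree contains no species twice — but whose parent's subtree
    does — is extracted in a single pass (the root qualifies when the whole
    tree is duplicate-free).  The extracted subtrees are leaf-disjoint and
    jointly cover all post-trim leaves; the occupancy threshold is applied
    last.
    """
    trimmed = trim_tsd(family)
    tree = trimmed.tree
    all_names = set(tip_names(tree))
    dupfree: dict[int, bool] = {}
    counters: dict[int, Counter] = {}
    for node in tree.postorder(include_self=True):
        cnt = (
            Counter([family.smap(node.name)])
            if node.is_tip()
            else sum((counters[id(c)] for c in node.children), Counter())
        )
        counters[id(node)] = cnt
        dupfree[id(node)] = all(v == 1 for v in cnt.values())
    out: list[OrthologSet] = []
    for node in tree.postorder(include_self=True):
        if not dupfree[id(node)]:
            continue
        parent = node.parent
        if parent is not None and dupfree[id(parent)]:
            continue  # not maximal
        if len(counters[id(node)]) < cfg.min_taxa:
            continue
        members = [t.name for t in tips_of(node)]
        sub = node.copy()
        sub.length = None
        out.append(
            OrthologSet(
                tree=sub,
                members=members,
                method="SE",
                source_family=family.family_id,
                removed=sorted(
                    set(family.copies()) - set(members)
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Maximum inclusion (MI)
# ---------------------------------------------------------------------------

def _cut_long_branches(tree: TreeNode, cutoff: float) -> list[TreeNode]:
    comps: list[TreeNode] = []
    queue = [tree]
    while queue:
        t = queue.pop()
        found = None
        for node in t.traverse(include_self=False):
            if node.length is None:
                raise TreeError(
                    "long-branch cutoff requires branch lengths everywhere"
                )
            if node.length > cutoff:
                found = node
                break
        if found is None:
            comps.append(t)
            continue
        sub, rest = detach(t, found)
        queue.append(rest)
        queue.append(sub)
    return comps


def _mi_component(
    comp: TreeNode, smap: SpeciesMap, min_taxa: int, family: GeneFamily
) -> list[OrthologSet]:
    out: list[OrthologSet] = []
    stack = [comp]
    while stack:
        t = stack.pop()
        total_cnt = _species_counter(t, smap)
        if _duplicate_free(total_cnt):
            if len(total_cnt) >= min_taxa:
                out.append(_mi_set(t, family))
            continue
        nodes = [n for n in t.postorder(include_self=False)]
        counters: dict[int, Counter] = {}
        lsums: dict[int, float] = {}
        for node in nodes:
            if node.is_tip():
                counters[id(node)] = Counter([smap(node.name)])
                lsums[id(node)] = 0.0
            else:
                counters[id(node)] = sum(
                    (counters[id(c)] for c in node.children), Counter()
                )
                lsums[id(node)] = sum(
                    lsums[id(c)] + (c.length or 0.0) for c in node.children
                )
        best_key = None
        best_node = None
        for idx, node in enumerate(nodes):
            cnt = counters[id(node)]
            if not _duplicate_free(cnt):
                continue
            key = (-len(cnt), lsums[id(node)], idx)
            if best_key is None or key < best_key:
                best_key = key
                best_node = node
        if best_node is None or -best_key[0] < min_taxa:
            continue  # nothing extractable above the occupancy threshold
        sub, rest = detach(t, best_node)
        out.append(_mi_set(sub, family))
        stack.append(rest)  # remainder is re-analyzed as a whole tree
    return out


def _mi_set(tree: TreeNode, family: GeneFamily) -> OrthologSet:
    members = [t.name for t in tips_of(tree)]
    return OrthologSet(
        tree=tree.copy(),
        members=members,
        method="MI",
        source_family=family.family_id,
        removed=sorted(set(family.copies()) - set(members)),
    )


def extract_mi(family: GeneFamily, cfg: MIConfig) -> list[OrthologSet]:
    """Maximum inclusion: iterative extraction of duplicate-free subtrees.

    Branches longer than ``cfg.long_branch_cutoff`` are first cut and the
    tree decomposed into the resulting components (guarding against
    pseudoorthologs on long branches).  Each component is then processed
    iteratively: a duplicate-free tree is emitted whole (if it meets the
    occupancy threshold); otherwise the duplicate-free clade with the most
    species is cut off and emitted, and the remainder is pushed back for
    re-analysis as a whole tree.  Extraction stops when no duplicate-free
    clade with at least ``min_taxa`` species remains.  Ties prefer the clade
    with smaller total branch length, then postorder position.
    """
    tree = family.tree.copy()
    if cfg.long_branch_cutoff is not None:
        comps = _cut_long_branches(tree, cfg.long_branch_cutoff)
    else:
        comps = [tree]
    out: list[OrthologSet] = []
    for comp in comps:
        out.extend(_mi_component(comp, family.smap, cfg.min_taxa, family))
    return out


# ---------------------------------------------------------------------------
# Monophyletic outgroups (MO)
# ---------------------------------------------------------------------------

def extract_mo(
    family: GeneFamily, outgroups: set[str], cfg: FilterConfig
) -> OrthologSet | None:
    """Root on a monophyletic outgroup and prune duplications root-to-tip.

    Returns ``None`` when no outgroup species is present, when any outgroup
    species is multi-copy, or when the outgroup copies are not monophyletic.
    Otherwise the tree is rooted on the outgroup clade and traversed from the
    root toward the tips: at every node whose child subtrees share at least
    one species (a duplication), the child with more species is kept (ties:
    fewer gene copies, then tree order) and the other pruned.  The ingroup
    tree is returned if at least ``min_taxa`` species survive.
    """
    import warnings

    import skbio.tree as _sk

    smap = family.smap
    tree = family.tree.copy()
    og_tips = [t for t in tips_of(tree) if smap(t.name) in outgroups]
    if not og_tips:
        return None
    og_counts = Counter(smap(t.name) for t in og_tips)
    if any(v > 1 for v in og_counts.values()):
        return None
    og_names = {t.name for t in og_tips}
    if og_names == set(tip_names(tree)):
        return None  # no ingroup at all
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree = tree.root_by_outgroup(sorted(og_names))
    except _sk.TreeError:
        return None  # outgroup not monophyletic
    ingroup = next(
        c
        for c in tree.children
        if {t.name for t in tips_of(c)} != og_names
    )
    _mo_resolve(ingroup, smap)
    ingroup.parent = None
    ingroup.length = None
    ingroup = clean(ingroup)
    cnt = _species_counter(ingroup, smap)
    if len(cnt) < cfg.min_taxa:
        return None
    members = [t.name for t in tips_of(ingroup)]
    return OrthologSet(
        tree=ingroup,
        members=members,
        method="MO",
        source_family=family.family_id,
        removed=sorted(set(family.copies()) - set(members)),
    )


def _mo_resolve(node: TreeNode, smap: SpeciesMap) -> None:
    if node.is_tip():
        return
    while True:
        counters = [_species_counter(c, smap) for c in node.children]
        pair = None
        for i in range(len(counters)):
            for j in range(i + 1, len(counters)):
                if counters[i] & counters[j]:
                    pair = (i, j)
                    break
            if pair:
                break
        if pair is None:
            break
        i, j = pair
        key_i = (-len(counters[i]), sum(counters[i].values()), i)
        key_j = (-len(counters[j]), sum(counters[j].values()), j)
        drop = node.children[j] if key_i <= key_j else node.children[i]
        node.remove(drop)
    for child in list(node.children):
        _mo_resolve(child, smap)


# ---------------------------------------------------------------------------
# One paralog per species
# ---------------------------------------------------------------------------

def sample_one_paralog(
    family: GeneFamily, cfg: FilterConfig, seed: int
) -> OrthologSet | None:
    """Uniformly sample one copy per species, without regard to orthology.

    The RNG stream is derived from (seed, family id), so the draw for a
    family does not depend on how many other families were processed before
    it.  Returns ``None`` when fewer than ``min_taxa`` species are present.
    """
    by_sp: dict[str, list[str]] = {}
    for name in family.copies():
        by_sp.setdefault(family.smap(name), []).append(name)
    if len(by_sp) < cfg.min_taxa:
        return None
    rng = derive_rng(seed, "one-paralog", family.family_id)
    members = []
    for sp in sorted(by_sp):
        copies = by_sp[sp]
        members.append(copies[int(rng.integers(len(copies)))])
    tree = prune_to(family.tree, members)
    return OrthologSet(
        tree=tree,
        members=sorted(members),
        method="ONE",
        source_family=family.family_id,
        removed=sorted(set(family.copies()) - set(members)),
    )


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------

@dataclass
class FamilyStats:
    n_families: int
    n_copies: int
    mean_copies: float
    mean_copies_rounded: int
    occupancy: dict[str, int]  # species -> number of families containing it


def family_stats(families: list[GeneFamily]) -> FamilyStats:
    """Copy counts and per-species occupancy over a family collection."""
    if not families:
        raise ValueError("family_stats requires at least one family")
    n_copies = 0
    occupancy: Counter = Counter()
    for fam in families:
        copies = fam.copies()
        n_copies += len(copies)
        occupancy.update(set(fam.smap(c) for c in copies))
    mean = n_copies / len(families)
    return FamilyStats(
        n_families=len(families),
        n_copies=n_copies,
        mean_copies=mean,
        mean_copies_rounded=int(round(mean)),
        occupancy=dict(occupancy),
    )
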