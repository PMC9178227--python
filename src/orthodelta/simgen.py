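"""Synthetic data: species trees, coalescent gene trees, duplication–loss
gene families with truth labels, and triplet-count draws with introgression.

All generators are deterministic given (seed, configuration).  Time and
branch lengths are in coalescent units (2N generations) throughout, and the
duplication/loss rates are interpreted per copy per coalescent unit, so a
single unit system runs through the whole test bed.

The duplication–loss model is a locus-tree-style birth–death process hung on
the species tree: one ancestral copy enters at the root; along each branch
every extant copy duplicates at rate λ (spawning an independent subtree) and
is lost at rate μ; surviving copies speciate at species-tree nodes.  Each
internal node of the resulting gene tree carries a truth label — ``D`` for
duplication, ``S`` for speciation — from which true ortholog groups are
derivable.  Gene trees equal locus trees here (no within-locus coalescence),
which is the structure the decomposition methods consume.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from ._util import derive_rng, tips_of
from .decompose import GeneFamily
from .treeio import SpeciesMap

__all__ = [
    "SimConfig",
    "SimFamily",
    "sim_species_tree",
    "sim_msc_gene_trees",
    "sim_dl_family",
    "sim_dl_families",
    "sim_triplet_counts",
    "triplet_probabilities",
    "true_ortholog_sets",
]


@dataclass
class SimConfig:
    """Study conditions for the simulators.

    ``n_species``        species-tree size (>= 4).
    ``speciation_rate``  pure-birth rate per lineage per coalescent unit.
    ``dup_rate``/``loss_rate``  λ and μ of the duplication–loss process,
                         per copy per coalescent unit.
    ``t_internal``       internal branch length for triplet draws
                         (coalescent units).
    ``gamma``            introgression fraction in [0, 1].
    ``t_prime``          post-introgression internal branch length.
    ``n_loci``           number of gene trees / triplet draws.
    ``seed``             master seed.
    """

    n_species: int = 12
    speciation_rate: float = 1.0
    dup_rate: float = 0.3
    loss_rate: float = 0.3
    t_internal: float = 1.0
    gamma: float = 0.0
    t_prime: float = 0.5
    n_loci: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        for name in ("speciation_rate", "dup_rate", "loss_rate",
                     "t_internal", "t_prime"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.gamma <= 1:
            raise ValueError("gamma must be in [0, 1]")


@dataclass
class SimFamily:
    """A simulated gene family with truth labels on its internal nodes."""

    family: GeneFamily | None  # None when every copy was lost
    n_duplications: int  # duplication nodes surviving in the tree
    n_losses: int  # loss events drawn

    @property
    def empty(self) -> bool:
        return self.family is None


# ---------------------------------------------------------------------------
# Species trees
# ---------------------------------------------------------------------------

def sim_species_tree(
    n_species: int, speciation_rate: float = 1.0, seed: int = 0
) -> TreeNode:
    """A pure-birth (Yule) rooted binary ultrametric species tree.

    Lineages split at ``speciation_rate`` each; the simulation stops when
    ``n_species`` tips exist and the tips are extended by one further
    exponential waiting time so terminal branches are positive.  Species are
    named ``s01, s02, ...`` in tip order.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = derive_rng(seed, "species-tree", n_species)
    root = TreeNode()
    birth = {id(root): 0.0}
    active = [root]
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * speciation_rate))
        idx = int(rng.integers(k))
        node = active.pop(idx)
        node.length = t - birth[id(node)] if node.parent is not None else None
        node._split_time = t
        kids = [TreeNode(), TreeNode()]
        for kid in kids:
            birth[id(kid)] = t
            node.append(kid)
        active.extend(kids)
    t_end = t + rng.exponential(1.0 / (n_species * speciation_rate))
    for i, node in enumerate(active, 1):
        node.length = t_end - birth[id(node)]
        node.name = f"s{i:02d}"
    return root


def node_ages(stree: TreeNode) -> dict[int, float]:
    """Node ages (time before present) of an ultrametric tree."""
    ages: dict[int, float] = {}
    for node in stree.postorder(include_self=True):
        if node.is_tip():
            ages[id(node)] = 0.0
        else:
            child = node.children[0]
            ages[id(node)] = ages[id(child)] + (child.length or 0.0)
    return ages


# ---------------------------------------------------------------------------
# Multispecies coalescent
# ---------------------------------------------------------------------------

def _coalesce(
    lineages: list[tuple[TreeNode, float]],
    t_start: float,
    t_end: float,
    rng: np.random.Generator,
) -> list[tuple[TreeNode, float]]:
    """Coalesce (node, birth-age) lineages within [t_start, t_end]."""
    t = t_start
    lineages = list(lineages)
    while len(lineages) > 1:
        k = len(lineages)
        rate = k * (k - 1) / 2.0
        t = t + rng.exponential(1.0 / rate)
        if t >= t_end:
            break
        i, j = sorted(rng.choice(k, size=2, replace=False).tolist())
        node_j, birth_j = lineages.pop(j)
        node_i, birth_i = lineages.pop(i)
        parent = TreeNode()
        node_i.length = t - birth_i
        node_j.length = t - birth_j
        parent.append(node_i)
        parent.append(node_j)
        lineages.append((parent, t))
    return lineages


def sim_msc_gene_trees(
    stree: TreeNode, n_loci: int, seed: int = 0
) -> list[TreeNode]:
    """Single-copy gene trees under the multispecies coalescent.

    One lineage enters per species; within each species-tree branch, each
    lineage pair coalesces at rate 1 (branch lengths in coalescent units);
    remaining lineages coalesce above the root.  Loci are independent.
    """
    ages = node_ages(stree)
    order = list(stree.postorder(include_self=True))
    rng = derive_rng(seed, "msc", n_loci)
    trees: list[TreeNode] = []
    for _ in range(n_loci):
        pool: dict[int, list[tuple[TreeNode, float]]] = {}
        for node in order:
            if node.is_tip():
                pool[id(node)] = [(TreeNode(name=node.name), 0.0)]
            else:
                incoming: list[tuple[TreeNode, float]] = []
                for child in node.children:
                    incoming.extend(
                        _coalesce(
                            pool[id(child)],
                            ages[id(child)],
                            ages[id(node)],
                            rng,
                        )
                    )
                pool[id(node)] = incoming
        final = _coalesce(pool[id(stree)], ages[id(stree)], math.inf, rng)
        (gtree, _birth), = final
        gtree.length = None
        trees.append(gtree)
    return trees


# ---------------------------------------------------------------------------
# Duplication–loss families
# ---------------------------------------------------------------------------

def sim_dl_family(
    stree: TreeNode,
    cfg: SimConfig,
    family_id: str = "fam",
) -> SimFamily:
    """One gene family evolved by duplication and loss along *stree*.

    A single copy enters at the root.  λ = μ = 0 reproduces the species tree
    exactly with all-``S`` labels.  Families whose copies are all lost are
    returned empty.
    """
    rng = derive_rng(cfg.seed, "dl-family", family_id)
    lam, mu = cfg.dup_rate, cfg.loss_rate
    total = lam + mu
    counters: Counter = Counter()
    tally = {"dup": 0, "loss": 0}

    def evolve(snode: TreeNode, remaining: float) -> TreeNode | None:
        elapsed = 0.0
        while True:
            dt = rng.exponential(1.0 / total) if total > 0 else math.inf
            if dt >= remaining - elapsed:
                break
            elapsed += dt
            if rng.random() < (mu / total):
                tally["loss"] += 1
                return None
            # duplication: two independent copies continue from here
            left = evolve(snode, remaining - elapsed)
            right = evolve(snode, remaining - elapsed)
            if left is None and right is None:
                return None
            if left is None or right is None:
                survivor = left if left is not None else right
                survivor.length += elapsed
                return survivor
            node = TreeNode(name="D", length=elapsed)
            node.event = "D"
            tally["dup"] += 1
            node.append(left)
            node.append(right)
            return node
        # reached the bottom of the species-tree branch
        if snode.is_tip():
            counters[snode.name] += 1
            leaf = TreeNode(
                name=f"{snode.name}|g{counters[snode.name]}", length=remaining
            )
            return leaf
        kids = [evolve(c, c.length or 0.0) for c in snode.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length += remaining
            return kids[0]
        node = TreeNode(name="S", length=remaining)
        node.event = "S"
        for k in kids:
            node.append(k)
        return node

    gtree = evolve(stree, 0.0)
    if gtree is None or gtree.is_tip():
        # empty, or a single surviving copy (no tree structure to decompose)
        if gtree is None:
            return SimFamily(None, tally["dup"], tally["loss"])
    gtree.length = None
    fam = GeneFamily(
        tree=gtree,
        smap=SpeciesMap.from_delimiter("|"),
        family_id=family_id,
    )
    return SimFamily(fam, tally["dup"], tally["loss"])


def sim_dl_families(
    stree: TreeNode, cfg: SimConfig, n_families: int, prefix: str = "fam"
) -> list[SimFamily]:
    """A collection of independent duplication–loss families (may be empty)."""
    return [
        sim_dl_family(stree, cfg, family_id=f"{prefix}{i:05d}")
        for i in range(n_families)
    ]


# ---------------------------------------------------------------------------
# Triplet counts under MSC + introgression
# ---------------------------------------------------------------------------

def triplet_probabilities(
    t_internal: float, t_prime: float, gamma: float
) -> np.ndarray:
    """(concordant, alt1, alt2) probabilities for one rooted triplet.

    With probability 1 − γ the gene follows the species history: the
    concordant topology has probability 1 − (2/3)e^{−T} and each minor
    topology (1/3)e^{−T}, where T is the internal branch length in
    coalescent units.  With probability γ it follows the introgressed
    history, whose own major topology is the alt1 class: alt1 receives
    1 − (2/3)e^{−T′} while concordant and alt2 each receive (1/3)e^{−T′}.
    """
    def split(t: float) -> tuple[float, float]:
        minor = math.exp(-t) / 3.0
        return 1.0 - 2.0 * minor, minor

    maj_s, min_s = split(t_internal)
    maj_i, min_i = split(t_prime)
    p = np.array(
        [
            (1 - gamma) * maj_s + gamma * min_i,   # concordant
            (1 - gamma) * min_s + gamma * maj_i,   # alt1
            (1 - gamma) * min_s + gamma * min_i,   # alt2
        ]
    )
    assert abs(p.sum() - 1.0) < 1e-12
    return p


def sim_triplet_counts(cfg: SimConfig) -> tuple[int, int, int]:
    """Multinomial draw of ``n_loci`` triplet topologies."""
    rng = derive_rng(cfg.seed, "triplets", cfg.n_loci)
    p = triplet_probabilities(cfg.t_internal, cfg.t_prime, cfg.gamma)
    counts = rng.multinomial(cfg.n_loci, p)
    return int(counts[0]), int(counts[1]), int(counts[2])


# ---------------------------------------------------------------------------
# Truth extraction
# ---------------------------------------------------------------------------

def true_ortholog_sets(
    fam: SimFamily, min_taxa: int = 2
) -> list[frozenset[str]]:
    """True ortholog groups: copies descending from a duplication-free history.

    A group is the leaf set of a maximal clade containing no ``D``-labeled
    node, i.e. all copies descending from a single ancestral copy with no
    duplication among them (the root qualifies when the family never
    duplicated; the two child subtrees of a root duplication are two
    groups).  Groups are disjoint; those sampling fewer than ``min_taxa``
    species are dropped.
    """
    if fam.empty:
        return []
    tree = fam.family.tree
    smap = fam.family.smap
    dfree: dict[int, bool] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            dfree[id(node)] = True
        else:
            dfree[id(node)] = getattr(node, "event", None) != "D" and all(
                dfree[id(c)] for c in node.children
            )
    out = []
    for node in tree.preorder(include_self=True):
        if not dfree[id(node)]:
            continue
        parent = node.parent
        if parent is not None and dfree[id(parent)]:
            continue  # not maximal
        leaves = [t.name for t in tips_of(node)]
        if len({smap(n) for n in leaves}) >= min_taxa:
            out.append(frozenset(leaves))
    return sorted(out, key=lambda s: sorted(s))
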