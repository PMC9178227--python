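"""Shared internal helpers: deterministic RNG substreams and tree surgery."""

from __future__ import annotations

import hashlib

import numpy as np
from skbio import TreeNode


def derive_rng(seed: int, *tokens: object) -> np.random.Generator:
    """A reproducible RNG substream keyed by (seed, tokens).

    Tokens (family ids, branch ids, replicate indices, ...) are hashed into
    the seed sequence so that streams for different keys are independent and
    insensitive to processing order.
    """
    digest = hashlib.sha256(
        "\x1f".join(str(t) for t in tokens).encode()
    ).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *words])
    )


def tips_of(node: TreeNode) -> list[TreeNode]:
    """Leaves below *node*, or the node itself if it is a leaf."""
    return [node] if node.is_tip() else list(node.tips())


def clean(tree: TreeNode) -> TreeNode:
    """Normalize a tree after leaf removal.

    Drops childless internal nodes, suppresses unifurcations (summing branch
    lengths, preserving child order), and collapses a single-child root.
    Returns the possibly new root; the input is modified in place.
    """
    for node in list(tree.postorder(include_self=False)):
        if not node.is_tip() and len(node.children) == 1:
            child = node.children[0]
            if node.length is not None:
                child.length = (child.length or 0.0) + node.length
            parent = node.parent
            i = parent.children.index(node)
            node.parent = None
            child.parent = parent
            parent.children[i] = child
    while not tree.is_tip() and len(tree.children) == 1:
        tree = tree.children[0]
        tree.parent = None
        tree.length = None
    tree.clear_caches(attr=False)
    return tree


def detach(tree: TreeNode, node: TreeNode) -> tuple[TreeNode, TreeNode]:
    """Cut the branch above *node*: return (subtree, remainder), both cleaned."""
    parent = node.parent
    parent.remove(node)
    node.parent = None
    node.length = None
    return clean(node), clean(tree)
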