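"""Independent brute-force oracles for the parsimony reconstructions.

These enumerate every possible internal-node assignment on small trees and
are deliberately written without reference to the package's reconstruction
code: they only use the tree structure (ids, parents, leaves).
"""
from itertools import product

from domevol import PhyloTree


def enumerate_topologies(labels):
    """All distinct rooted binary topologies over the given leaf labels,
    as nested tuples (1, 3, 15, 105, 945 topologies for 2..6 leaves)."""
    labels = list(labels)
    if len(labels) == 1:
        return [labels[0]]
    first, rest = labels[0], labels[1:]
    out = []
    for mask in range(1, 2 ** len(rest)):
        side2 = [rest[i] for i in range(len(rest)) if mask >> i & 1]
        side1 = [first] + [x for x in rest if x not in side2]
        for left in enumerate_topologies(side1):
            for right in enumerate_topologies(side2):
                out.append((left, right))
    return out


def _assignments(tree: PhyloTree, leaf_state):
    internals = [n for n in tree.preorder() if not n.is_leaf]
    fixed = {leaf.id: leaf_state[leaf.label] for leaf in tree.leaves()}
    for combo in product((0, 1), repeat=len(internals)):
        state = dict(fixed)
        state.update({n.id: s for n, s in zip(internals, combo)})
        yield state


def count_changes(tree: PhyloTree, state) -> int:
    return sum(
        1
        for n in tree.preorder()
        if n.parent is not None and state[n.id] != state[n.parent.id]
    )


def fitch_min_changes(tree: PhyloTree, leaf_state) -> int:
    """Minimum number of parent->child state changes over all assignments."""
    return min(count_changes(tree, st) for st in _assignments(tree, leaf_state))


def gains_and_losses(tree: PhyloTree, state):
    gains = sum(
        1
        for n in tree.preorder()
        if state[n.id] == 1 and (n.parent is None or state[n.parent.id] == 0)
    )
    losses = sum(
        1
        for n in tree.preorder()
        if n.parent is not None and state[n.id] == 0 and state[n.parent.id] == 1
    )
    return gains, losses


def dollo_min_losses(tree: PhyloTree, leaf_state):
    """Minimum number of losses over assignments with at most one gain.

    Returns ``None`` if no valid single-gain assignment exists (never the
    case for binary characters on a tree).
    """
    best = None
    for st in _assignments(tree, leaf_state):
        gains, losses = gains_and_losses(tree, st)
        if gains > 1:
            continue
        if best is None or losses < best:
            best = losses
    return best
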