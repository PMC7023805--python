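"""Ancestral presence/absence reconstruction on the species tree.

The repertoire history is reconstructed twice, over two character sets:

* **Fitch parsimony**, one binary character per domain *arrangement*
  (including single-domain arrangements).  Arrangements are modular and may
  be formed and broken repeatedly, so minimum-change reconstruction with
  free gains and losses is appropriate.  The up-pass uses the three-valued
  (present / absent / unknown) rule table; the down-pass resolves the root
  (configurable, default absent) and copies the finalized parental state
  into every remaining unknown.  The result attains the parsimony minimum
  number of state changes.

* **Dollo parsimony**, one binary character per single *domain* occurring in
  any arrangement.  A novel domain is assumed to be gained exactly once; the
  gain is placed at the most recent common ancestor of all leaves carrying
  the domain and losses fall out wherever a present node has an all-absent
  child subtree.  This minimizes losses subject to the single-gain
  constraint.  The Dollo layer is used to vet emergence and single-domain
  loss events inferred from the Fitch layer.

Both reconstructions are vectorized across characters with numpy.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Dict, Hashable, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

from .arrangements import ArrangementSet
from .errors import ValidationError
from .io_formats import SpeciesAnnotation
from .tree import PhyloTree


class TriState(IntEnum):
    ABSENT = 0
    PRESENT = 1
    UNKNOWN = 2


ARRANGEMENT = "arrangement"
DOMAIN = "domain"

_ROOT_RULE = {"absent": TriState.ABSENT, "present": TriState.PRESENT}


@dataclass(frozen=True)
class CharacterMatrix:
    """Finalized per-node states for one character set (no unknowns left)."""

    character_kind: str
    characters: Tuple[Hashable, ...]
    node_ids: Tuple[str, ...]
    states: np.ndarray  # shape (n_nodes, n_characters), int8 TriState values

    def __post_init__(self) -> None:
        object.__setattr__(self, "_char_index",
                           {c: i for i, c in enumerate(self.characters)})
        object.__setattr__(self, "_node_index",
                           {n: i for i, n in enumerate(self.node_ids)})

    def state(self, node_id: str, character: Hashable) -> TriState:
        return TriState(self.states[self._node_index[node_id],
                                    self._char_index[character]])

    def present_characters(self, node_id: str) -> frozenset:
        row = self.states[self._node_index[node_id]]
        return frozenset(self.characters[i]
                         for i in np.flatnonzero(row == TriState.PRESENT))

    def changes(self, tree: PhyloTree) -> int:
        """Total number of parent->child state changes over all characters."""
        total = 0
        for node in tree.preorder():
            if node.parent is None:
                continue
            a = self.states[self._node_index[node.id]]
            b = self.states[self._node_index[node.parent.id]]
            total += int(np.sum(a != b))
        return total


def _leaf_state_matrix(
    tree: PhyloTree,
    leaf_states: Mapping[str, Iterable[Hashable]],
    characters: Sequence[Hashable],
) -> Dict[str, np.ndarray]:
    char_index = {c: i for i, c in enumerate(characters)}
    missing = [leaf.label for leaf in tree.leaves() if leaf.label not in leaf_states]
    if missing:
        raise ValidationError(
            f"no leaf states supplied for: {', '.join(sorted(missing))}"
        )
    rows: Dict[str, np.ndarray] = {}
    for leaf in tree.leaves():
        row = np.zeros(len(characters), dtype=np.int8)
        for char in leaf_states[leaf.label]:
            idx = char_index.get(char)
            if idx is None:
                raise ValidationError(
                    f"leaf {leaf.label!r} carries unknown character {char!r}"
                )
            row[idx] = TriState.PRESENT
        rows[leaf.label] = row
    return rows


def fitch_reconstruct(
    tree: PhyloTree,
    leaf_states: Mapping[str, Iterable[Hashable]],
    characters: Optional[Sequence[Hashable]] = None,
    root_unknown: str = "absent",
    character_kind: str = ARRANGEMENT,
) -> CharacterMatrix:
    """Fitch (minimum-change) reconstruction of all characters at once.

    ``leaf_states`` maps each leaf label to the collection of characters
    present at that leaf; everything else is absent.  ``root_unknown``
    selects how an ambiguous root state is finalized.
    """
    if root_unknown not in _ROOT_RULE:
        raise ValidationError(f"root_unknown must be 'absent' or 'present', got {root_unknown!r}")
    if characters is None:
        characters = sorted({c for states in leaf_states.values() for c in states},
                            key=str)
    characters = tuple(characters)
    leaf_rows = _leaf_state_matrix(tree, leaf_states, characters)

    n_nodes = tree.n_nodes
    states = np.empty((n_nodes, len(characters)), dtype=np.int8)
    node_ids = tuple(n.id for n in tree.preorder())
    index = {nid: i for i, nid in enumerate(node_ids)}

    # up-pass (leaves -> root): three-valued combination of the children
    for node in tree.postorder():
        i = index[node.id]
        if node.is_leaf:
            states[i] = leaf_rows[node.label]
            continue
        acc = states[index[node.children[0].id]]
        for child in node.children[1:]:
            acc = _fitch_combine(acc, states[index[child.id]])
        states[i] = acc

    # down-pass (root -> leaves): resolve root, then copy parent into unknowns
    root_row = states[index[tree.root.id]]
    root_row[root_row == TriState.UNKNOWN] = _ROOT_RULE[root_unknown]
    for node in tree.preorder():
        if node.parent is None:
            continue
        i, p = index[node.id], index[node.parent.id]
        mask = states[i] == TriState.UNKNOWN
        states[i, mask] = states[p, mask]

    return CharacterMatrix(character_kind, characters, node_ids, states)


def _fitch_combine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise rule: equal -> that state; one unknown -> the known state;
    present vs absent -> unknown."""
    out = np.full_like(a, TriState.UNKNOWN)
    same = a == b
    out[same] = a[same]
    a_unknown = (a == TriState.UNKNOWN) & (b != TriState.UNKNOWN)
    out[a_unknown] = b[a_unknown]
    b_unknown = (b == TriState.UNKNOWN) & (a != TriState.UNKNOWN)
    out[b_unknown] = a[b_unknown]
    return out


def dollo_reconstruct(
    tree: PhyloTree,
    leaf_states: Mapping[str, Iterable[Hashable]],
    characters: Optional[Sequence[Hashable]] = None,
    character_kind: str = DOMAIN,
) -> Tuple[CharacterMatrix, Dict[Hashable, Optional[str]]]:
    """Single-gain / minimum-loss reconstruction of all characters.

    Returns the finalized matrix and a mapping character -> id of its unique
    gain node (``None`` for characters absent from every leaf).
    """
    if characters is None:
        characters = sorted({c for states in leaf_states.values() for c in states},
                            key=str)
    characters = tuple(characters)
    leaf_rows = _leaf_state_matrix(tree, leaf_states, characters)

    n_nodes, n_chars = tree.n_nodes, len(characters)
    node_ids = tuple(n.id for n in tree.preorder())
    index = {nid: i for i, nid in enumerate(node_ids)}

    counts = np.zeros((n_nodes, n_chars), dtype=np.int32)
    for node in tree.postorder():
        i = index[node.id]
        if node.is_leaf:
            counts[i] = leaf_rows[node.label]
        else:
            for child in node.children:
                counts[i] += counts[index[child.id]]
    total = counts[index[tree.root.id]]

    # gain node: deepest node whose subtree holds all present leaves = the
    # first such node in postorder (children precede parents).
    post_indices = np.array([index[n.id] for n in tree.postorder()])
    hits = counts[post_indices] == total[None, :]
    first_hit = np.argmax(hits, axis=0)
    gain_idx = post_indices[first_hit]  # meaningful only where total > 0

    gains: Dict[Hashable, Optional[str]] = {}
    for j, char in enumerate(characters):
        gains[char] = node_ids[gain_idx[j]] if total[j] > 0 else None

    # present iff inside the gain subtree and some present leaf below
    below = np.zeros((n_nodes, n_chars), dtype=bool)
    for node in tree.preorder():
        i = index[node.id]
        row = (gain_idx == i) & (total > 0)
        if node.parent is not None:
            row = row | below[index[node.parent.id]]
        below[i] = row
    present = below & (counts > 0)

    states = np.where(present, np.int8(TriState.PRESENT),
                      np.int8(TriState.ABSENT)).astype(np.int8)
    return CharacterMatrix(character_kind, characters, node_ids, states), gains


@dataclass(frozen=True)
class Reconstruction:
    """Finalized dual reconstruction over one tree.

    ``fitch`` holds arrangement characters, ``dollo`` single-domain
    characters, ``dollo_gains`` each domain's unique gain node id.
    """

    tree: PhyloTree
    fitch: CharacterMatrix
    dollo: CharacterMatrix
    dollo_gains: Mapping[str, Optional[str]]

    def arrangement_set(self, node_id: str) -> ArrangementSet:
        return ArrangementSet(self.fitch.present_characters(node_id))


def reconstruct_all(
    tree: PhyloTree,
    annotations: Sequence[SpeciesAnnotation],
    root_unknown: str = "absent",
) -> Reconstruction:
    """Run both reconstructions for a tree plus per-species repertoires.

    Arrangement characters are the union of all leaf repertoires; domain
    characters the union of all domains occurring in any arrangement.
    """
    by_species = {ann.species_id: ann for ann in annotations}
    if len(by_species) != len(annotations):
        raise ValidationError("duplicate species ids among annotations")
    leaves = tree.leaf_labels
    missing = sorted(leaves - by_species.keys())
    extra = sorted(by_species.keys() - leaves)
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"leaves without annotation: {', '.join(missing)}")
        if extra:
            parts.append(f"annotations without leaf: {', '.join(extra)}")
        raise ValidationError("; ".join(parts))

    arr_states = {sp: frozenset(ann.repertoire.arrangements)
                  for sp, ann in by_species.items()}
    dom_states = {sp: ann.repertoire.domain_content
                  for sp, ann in by_species.items()}
    arr_chars = sorted({a for s in arr_states.values() for a in s}, key=str)
    dom_chars = sorted({d for s in dom_states.values() for d in s})

    fitch = fitch_reconstruct(tree, arr_states, arr_chars,
                              root_unknown=root_unknown,
                              character_kind=ARRANGEMENT)
    dollo, gains = dollo_reconstruct(tree, dom_states, dom_chars,
                                     character_kind=DOMAIN)
    return Reconstruction(tree=tree, fitch=fitch, dollo=dollo, dollo_gains=gains)
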