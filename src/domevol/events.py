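"""Single-step rearrangement events and solution-type classification.

For every node (except the root and any excluded nodes) the finalized
arrangement set is compared with its parent's.  Each gained or lost
arrangement becomes one change record; all single-step explanations are
enumerated against the parent's full set and the record is classified:

* ``exact`` — exactly one candidate event;
* ``non_ambiguous`` — several candidates, all of the same event type;
* ``ambiguous`` — candidates of more than one event type;
* ``complex`` — no single-step candidate (would need a chain of events).

Exact and non-ambiguous records are the *unique solutions* counted by the
rates layer.

The six event types, in terms of a gained arrangement N and the parental
set P:

* **fusion** — N is the concatenation of two arrangements of P (including
  single-domain ones, which amounts to gene fusion);
* **fission** — N is a proper terminal fragment of some P-arrangement whose
  complementary fragment also persists in the child set (one arrangement
  split into two, both retained);
* **terminal loss** — N is a single-terminus truncation of some
  P-arrangement and the removed block leaves no trace (its complementary
  fragment is absent from the child set); one event may drop several
  contiguous domains, as a premature stop codon would;
* **terminal emergence** — N is a P-arrangement with exactly one *novel*
  domain appended at one terminus, where novel means the domain's unique
  Dollo gain sits at this very node;
* **single emergence** — N is a single novel domain appearing as a discrete
  arrangement (Dollo gain at this node);
* **single loss** — a lost single-domain arrangement whose domain vanishes
  completely from the child repertoire (Dollo-consistent).

Lost multi-domain arrangements, and single-domain losses whose domain
persists inside other arrangements, are outside the six types: they are
recorded as unclassified ``complex`` losses so that the solution-type
counts always partition the observed changes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

from .arrangements import ArrangementSet, DomainArrangement
from .errors import ValidationError
from .parsimony import CharacterMatrix, Reconstruction, TriState

logger = logging.getLogger(__name__)


class EventType(str, Enum):
    FUSION = "fusion"
    FISSION = "fission"
    TERMINAL_LOSS = "terminal_loss"
    TERMINAL_EMERGENCE = "terminal_emergence"
    SINGLE_LOSS = "single_loss"
    SINGLE_EMERGENCE = "single_emergence"


class SolutionType(str, Enum):
    EXACT = "exact"
    NON_AMBIGUOUS = "non_ambiguous"
    AMBIGUOUS = "ambiguous"
    COMPLEX = "complex"


#: solution types counted by the rates layer
UNIQUE_SOLUTIONS = frozenset({SolutionType.EXACT, SolutionType.NON_AMBIGUOUS})


class ChangeKind(str, Enum):
    GAINED = "gained"
    LOST = "lost"


@dataclass(frozen=True)
class CandidateEvent:
    """One single-step explanation of one arrangement change."""

    event_type: EventType
    precursors: Tuple[DomainArrangement, ...]
    product: DomainArrangement
    detail: str


@dataclass(frozen=True)
class EventRecord:
    """One arrangement change at one node, with its classification."""

    node_id: str
    change_kind: ChangeKind
    arrangement: DomainArrangement
    candidates: Tuple[CandidateEvent, ...]
    solution: SolutionType
    resolved_type: Optional[EventType]


def node_changes(
    parent_set: ArrangementSet, child_set: ArrangementSet
) -> Tuple[FrozenSet[DomainArrangement], FrozenSet[DomainArrangement]]:
    """Arrangements gained and lost at a node relative to its parent."""
    gained = child_set.arrangements - parent_set.arrangements
    lost = parent_set.arrangements - child_set.arrangements
    return gained, lost


class _ParentIndex:
    """Index of a parent set by first and last domain, to find all
    arrangements having a given fragment as terminal prefix/suffix."""

    __slots__ = ("by_first", "by_last")

    def __init__(self, parent_set: ArrangementSet) -> None:
        self.by_first: Dict[str, List[DomainArrangement]] = {}
        self.by_last: Dict[str, List[DomainArrangement]] = {}
        for arr in parent_set:
            self.by_first.setdefault(arr[0], []).append(arr)
            self.by_last.setdefault(arr[-1], []).append(arr)


def explain_gain(
    new_arr: DomainArrangement,
    parent_set: ArrangementSet,
    child_set: ArrangementSet,
    dollo_gains: Mapping[str, Optional[str]],
    node_id: str,
    junction_merge: bool = False,
    _index: Optional[_ParentIndex] = None,
) -> List[CandidateEvent]:
    """Enumerate all single-step explanations for a gained arrangement.

    ``junction_merge=True`` additionally admits fusion splits whose junction
    domains merge under repeat collapse (X ending in d with Y starting in d,
    so X + Y collapses to the product); the default enumerates plain
    concatenation splits only, matching the event model's worked examples.
    """
    if new_arr in parent_set:
        raise ValidationError(f"{new_arr} is present in the parent set, not a gain")
    index = _index if _index is not None else _ParentIndex(parent_set)
    n = len(new_arr)
    candidates: Dict[tuple, CandidateEvent] = {}

    # (a) fusion: every ordered pair of parent arrangements concatenating to
    # the product.  Splits at every boundary; symmetric orders are distinct
    # candidates only when both concatenations really yield the product.
    for i in range(1, n):
        x, y = new_arr[:i], new_arr[i:]
        if x in parent_set and y in parent_set:
            xa, ya = DomainArrangement(x), DomainArrangement(y)
            candidates.setdefault(
                (EventType.FUSION, xa, ya),
                CandidateEvent(EventType.FUSION, (xa, ya), new_arr, f"{xa}+{ya}"),
            )
    if junction_merge:
        for i in range(2, n):
            x, y = new_arr[:i], new_arr[i - 1:]
            if len(y) < n and x in parent_set and y in parent_set:
                xa, ya = DomainArrangement(x), DomainArrangement(y)
                candidates.setdefault(
                    (EventType.FUSION, xa, ya),
                    CandidateEvent(EventType.FUSION, (xa, ya), new_arr,
                                   f"{xa}+{ya} (shared {x[-1]})"),
                )

    # (b)+(c) fission vs terminal loss: scan parent arrangements carrying the
    # product as a proper terminal fragment; the complementary fragment
    # decides which event it is (persists in the child -> fission; no trace
    # -> terminal loss).  A precursor yielding a fission candidate never also
    # yields a terminal-loss candidate.
    target = tuple(new_arr)
    fission_parents = set()
    tloss: Dict[tuple, CandidateEvent] = {}
    sources = []
    for p in index.by_first.get(new_arr[0], ()):
        if len(p) > n and p[:n] == target:
            sources.append((p, "prefix", n))
    for p in index.by_last.get(new_arr[-1], ()):
        if len(p) > n and p[len(p) - n:] == target:
            sources.append((p, "suffix", len(p) - n))
    for p, side, split in sources:
        comp = DomainArrangement(p[split:] if side == "prefix" else p[:split])
        if comp in child_set:
            fission_parents.add(p)
            candidates.setdefault(
                (EventType.FISSION, p, split),
                CandidateEvent(EventType.FISSION, (p,), new_arr,
                               f"{p} -> {new_arr} + {comp}"),
            )
        else:
            tloss.setdefault(
                (EventType.TERMINAL_LOSS, p, side, comp),
                CandidateEvent(EventType.TERMINAL_LOSS, (p,), new_arr,
                               f"{p} minus {side=='prefix' and 'C' or 'N'}-terminal {comp}"),
            )
    for key, cand in tloss.items():
        if cand.precursors[0] not in fission_parents:
            candidates[key] = cand

    # (d) terminal emergence: one novel domain (Dollo gain at this node)
    # appended at exactly one terminus of a parent arrangement.
    if n >= 2:
        first, last = new_arr[0], new_arr[-1]
        if dollo_gains.get(first) == node_id:
            rest = DomainArrangement(new_arr[1:])
            if rest in parent_set:
                key = (EventType.TERMINAL_EMERGENCE, first, "N")
                candidates[key] = CandidateEvent(
                    EventType.TERMINAL_EMERGENCE, (rest,), new_arr,
                    f"novel {first} at N-terminus of {rest}")
        if dollo_gains.get(last) == node_id:
            rest = DomainArrangement(new_arr[:-1])
            if rest in parent_set:
                key = (EventType.TERMINAL_EMERGENCE, last, "C")
                candidates[key] = CandidateEvent(
                    EventType.TERMINAL_EMERGENCE, (rest,), new_arr,
                    f"novel {last} at C-terminus of {rest}")

    # (e) single emergence: a novel domain appearing as a discrete arrangement
    if n == 1 and dollo_gains.get(new_arr[0]) == node_id:
        candidates[(EventType.SINGLE_EMERGENCE, new_arr[0])] = CandidateEvent(
            EventType.SINGLE_EMERGENCE, (), new_arr,
            f"first emergence of {new_arr[0]} as a single-domain arrangement")

    return sorted(candidates.values(), key=lambda c: (c.event_type.value, c.detail))


def explain_loss(
    lost_arr: DomainArrangement,
    parent_set: ArrangementSet,
    child_set: ArrangementSet,
    dollo: Optional[CharacterMatrix] = None,
    node_id: Optional[str] = None,
    parent_id: Optional[str] = None,
) -> List[CandidateEvent]:
    """Explanations for a lost arrangement.

    Only the complete loss of a single-domain arrangement (the domain occurs
    in no arrangement of the child set, and — when the Dollo matrix is given
    — is reconstructed absent here and present at the parent) is a
    single-step event.  Everything else yields no candidate and will be
    classified complex.
    """
    if lost_arr not in parent_set:
        raise ValidationError(f"{lost_arr} is not in the parent set")
    if lost_arr in child_set:
        raise ValidationError(f"{lost_arr} is present in the child set, not a loss")
    if len(lost_arr) != 1:
        return []
    domain = lost_arr[0]
    if domain in child_set.domain_content:
        return []
    if dollo is not None and node_id is not None:
        if dollo.state(node_id, domain) != TriState.ABSENT:
            return []
        if parent_id is not None and dollo.state(parent_id, domain) != TriState.PRESENT:
            return []
    return [CandidateEvent(EventType.SINGLE_LOSS, (lost_arr,), lost_arr,
                           f"complete loss of domain {domain}")]


def classify(candidates: Iterable[CandidateEvent]) -> SolutionType:
    cands = list(candidates)
    if not cands:
        return SolutionType.COMPLEX
    if len(cands) == 1:
        return SolutionType.EXACT
    types = {c.event_type for c in cands}
    return SolutionType.NON_AMBIGUOUS if len(types) == 1 else SolutionType.AMBIGUOUS


def _make_record(node_id: str, kind: ChangeKind, arr: DomainArrangement,
                 candidates: List[CandidateEvent]) -> EventRecord:
    solution = classify(candidates)
    resolved = candidates[0].event_type if solution in UNIQUE_SOLUTIONS else None
    return EventRecord(node_id, kind, arr, tuple(candidates), solution, resolved)


def infer_events(
    recon: Reconstruction,
    excluded_nodes: FrozenSet[str] = frozenset(),
    junction_merge: bool = False,
) -> List[EventRecord]:
    """One record per (node, changed arrangement) for every non-root,
    non-excluded node, in deterministic preorder / lexicographic order.

    Candidates are always evaluated against the parent's full finalized set;
    changes at a node are never applied incrementally within that node.
    """
    records: List[EventRecord] = []
    set_cache: Dict[str, ArrangementSet] = {}

    def node_set(node_id: str) -> ArrangementSet:
        if node_id not in set_cache:
            set_cache[node_id] = recon.arrangement_set(node_id)
        return set_cache[node_id]

    for node in recon.tree.preorder():
        if node.parent is None or node.id in excluded_nodes:
            continue
        parent_set = node_set(node.parent.id)
        child_set = node_set(node.id)
        gained, lost = node_changes(parent_set, child_set)
        if not gained and not lost:
            continue
        index = _ParentIndex(parent_set)
        for arr in sorted(gained, key=str):
            cands = explain_gain(arr, parent_set, child_set, recon.dollo_gains,
                                 node.id, junction_merge=junction_merge,
                                 _index=index)
            records.append(_make_record(node.id, ChangeKind.GAINED, arr, cands))
        for arr in sorted(lost, key=str):
            cands = explain_loss(arr, parent_set, child_set, recon.dollo,
                                 node.id, node.parent.id)
            records.append(_make_record(node.id, ChangeKind.LOST, arr, cands))
    return records


def write_events_tsv(records: Iterable[EventRecord], path) -> None:
    """Events table: node, change kind, arrangement, classification and the
    semicolon-joined candidate derivations."""
    with open(path, "w") as fh:
        fh.write("node_id\tchange_kind\tarrangement\tsolution_type\t"
                 "resolved_event_type\tn_candidates\tcandidates\n")
        for r in records:
            resolved = r.resolved_type.value if r.resolved_type else ""
            details = ";".join(c.detail for c in r.candidates)
            fh.write(f"{r.node_id}\t{r.change_kind.value}\t{r.arrangement}\t"
                     f"{r.solution.value}\t{resolved}\t{len(r.candidates)}\t{details}\n")
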