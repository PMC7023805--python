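"""Forward simulator of domain-arrangement evolution along a tree.

The simulator is the validation harness for the inference pipeline: it
evolves a presence/absence repertoire from a root set down the tree,
applying the six single-step event types with configurable weights, and
records the ground-truth event log and every ancestral set.  The generated
data satisfy the inference model's assumptions by construction — emergence
events always introduce globally fresh domains (so the Dollo single-gain
assumption holds in truth), fission retains both fragments and drops the
precursor, and terminal loss adds the truncated form while the precursor
persists (presence/absence semantics: other gene copies keep the full
arrangement).

Event counting note: a fission produces two gained fragments, hence two
change records on inference, while every other event type maps to exactly
one record.  :func:`recover_rates` therefore reports ground-truth
frequencies in *record equivalents* (fission counts twice) so that truth
and inference are measured on the same scale.
"""
from __future__ import annotations

import logging
from bisect import insort
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd

from .arrangements import ArrangementSet, DomainArrangement, concat_collapse
from .errors import ValidationError
from .events import ChangeKind, EventType, UNIQUE_SOLUTIONS
from .io_formats import SpeciesAnnotation
from .rates import EVENT_ORDER, RateTable, run_pipeline
from .tree import PhyloTree

logger = logging.getLogger(__name__)

#: Default event-type weights: the mixed-regime study condition.
DEFAULT_WEIGHTS: Dict[EventType, float] = {
    EventType.FUSION: 0.45,
    EventType.FISSION: 0.15,
    EventType.TERMINAL_LOSS: 0.20,
    EventType.TERMINAL_EMERGENCE: 0.01,
    EventType.SINGLE_LOSS: 0.17,
    EventType.SINGLE_EMERGENCE: 0.02,
}

#: Truncated geometric-like distribution over initial arrangement lengths
#: (mean about 2 domains, as short arrangements dominate real proteomes).
DEFAULT_LENGTH_DISTRIBUTION: Tuple[Tuple[int, float], ...] = (
    (1, 0.50), (2, 0.25), (3, 0.125), (4, 0.0625), (5, 0.03125), (6, 0.03125),
)

_MAX_RETRIES = 30


@dataclass
class SimulationConfig:
    """Study conditions for one simulation run.

    ``events_per_branch`` may be an integer (fixed count per branch) or a
    float (Poisson mean).  ``domain_alphabet_size`` is the size of the root
    domain pool and defaults to the scale of the Pfam vocabulary (~18k
    domain models), so that unrelated arrangements rarely share domains —
    the regime the inference model assumes; emergence events always use
    fresh domains outside the pool.
    """

    tree: PhyloTree
    root_repertoire_size: int = 500
    length_distribution: Tuple[Tuple[int, float], ...] = DEFAULT_LENGTH_DISTRIBUTION
    domain_alphabet_size: int = 18000
    events_per_branch: float = 5
    event_type_weights: Mapping[EventType, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_repertoire_size < 1:
            raise ValidationError("root repertoire must be non-empty")
        weights = [float(self.event_type_weights.get(et, 0.0)) for et in EVENT_ORDER]
        if any(w < 0 for w in weights):
            raise ValidationError("event-type weights must be non-negative")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValidationError("event-type weights must sum to 1")
        total_p = sum(p for _, p in self.length_distribution)
        if abs(total_p - 1.0) > 1e-9:
            raise ValidationError("length distribution must sum to 1")
        if self.domain_alphabet_size < 4:
            raise ValidationError("domain alphabet too small")


@dataclass(frozen=True)
class TrueEvent:
    """One executed ground-truth event."""

    node_id: str
    event_type: EventType
    precursors: Tuple[DomainArrangement, ...]
    products: Tuple[DomainArrangement, ...]


@dataclass
class SimulationResult:
    tree: PhyloTree
    config: SimulationConfig
    leaf_annotations: List[SpeciesAnnotation]
    true_events: List[TrueEvent]
    true_ancestral_sets: Dict[str, ArrangementSet]
    skipped: Counter = field(default_factory=Counter)


class _Branch:
    """Mutable repertoire on one branch, tracking which arrangements are
    still inherited from the parent (valid single-step precursors)."""

    def __init__(self, parent_set: frozenset) -> None:
        self.current = set(parent_set)
        self.snapshot = parent_set
        self._pool = sorted(parent_set, key=str)
        self._poolset = set(parent_set)

    @property
    def pool(self) -> List[DomainArrangement]:
        return self._pool

    def add(self, arr: DomainArrangement) -> None:
        self.current.add(arr)
        if arr in self.snapshot and arr not in self._poolset:
            self._poolset.add(arr)
            insort(self._pool, arr, key=str)

    def remove(self, arr: DomainArrangement) -> None:
        self.current.remove(arr)
        if arr in self._poolset:
            self._poolset.remove(arr)
            self._pool.remove(arr)


def simulate(config: SimulationConfig) -> SimulationResult:
    """Evolve a repertoire along the tree under the configured event mix.

    Infeasible or colliding draws (e.g. a fusion product already present, or
    no eligible single-domain arrangement for a single loss) are re-sampled
    a bounded number of times and then skipped with a log message — never an
    exception mid-simulation.
    """
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    weights = np.array([float(config.event_type_weights.get(et, 0.0))
                        for et in EVENT_ORDER])
    weights = weights / weights.sum()

    fresh_counter = [0]

    def fresh_domain() -> str:
        fresh_counter[0] += 1
        return f"x{fresh_counter[0]:05d}"

    root_set = _draw_root_repertoire(config, rng)
    sets: Dict[str, frozenset] = {tree.root.id: root_set}
    true_events: List[TrueEvent] = []
    skipped: Counter = Counter()

    for node in tree.preorder():
        if node.parent is None:
            continue
        branch = _Branch(sets[node.parent.id])
        n_events = _draw_event_count(config.events_per_branch, rng)
        for _ in range(n_events):
            etype = EVENT_ORDER[int(rng.choice(len(EVENT_ORDER), p=weights))]
            event = _execute(etype, branch, rng, fresh_domain)
            if event is None:
                skipped[etype] += 1
                logger.debug("skipped infeasible %s at node %s", etype.value, node.id)
            else:
                true_events.append(TrueEvent(node.id, etype, *event))
        sets[node.id] = frozenset(branch.current)

    leaf_annotations = []
    for leaf in tree.leaves():
        arrs = sorted(sets[leaf.id], key=str)
        proteins = {f"{leaf.label}_p{i:05d}": arr for i, arr in enumerate(arrs)}
        leaf_annotations.append(SpeciesAnnotation(leaf.label, proteins))

    if skipped:
        logger.info("skipped infeasible events: %s",
                    {et.value: n for et, n in skipped.items()})
    return SimulationResult(tree=tree, config=config,
                            leaf_annotations=leaf_annotations,
                            true_events=true_events,
                            true_ancestral_sets={k: ArrangementSet(v)
                                                 for k, v in sets.items()},
                            skipped=skipped)


def _draw_root_repertoire(config: SimulationConfig, rng) -> frozenset:
    pool = [f"d{i:04d}" for i in range(config.domain_alphabet_size)]
    lengths, probs = zip(*config.length_distribution)
    repertoire: set = set()
    attempts = 0
    while len(repertoire) < config.root_repertoire_size:
        attempts += 1
        if attempts > 50 * config.root_repertoire_size:
            raise ValidationError(
                "could not draw the requested number of distinct root arrangements; "
                "increase domain_alphabet_size or relax the length distribution")
        k = int(rng.choice(lengths, p=probs))
        doms: List[str] = []
        while len(doms) < k:
            d = pool[int(rng.integers(len(pool)))]
            if doms and doms[-1] == d:
                continue
            doms.append(d)
        repertoire.add(DomainArrangement(doms))
    return frozenset(repertoire)


def _draw_event_count(events_per_branch: float, rng) -> int:
    if float(events_per_branch).is_integer():
        return int(events_per_branch)
    return int(rng.poisson(events_per_branch))


def _execute(etype: EventType, branch: _Branch, rng, fresh_domain):
    """Try to apply one event; returns (precursors, products) or None."""
    for _ in range(_MAX_RETRIES):
        pool = branch.pool
        if etype is EventType.FUSION:
            if len(pool) < 2:
                return None
            i, j = rng.choice(len(pool), size=2, replace=False)
            x, y = pool[int(i)], pool[int(j)]
            product = concat_collapse(x, y)
            if product in branch.current:
                continue
            branch.add(product)
            return (x, y), (product,)

        if etype is EventType.FISSION:
            eligible = [a for a in pool if len(a) >= 2]
            if not eligible:
                return None
            p = eligible[int(rng.integers(len(eligible)))]
            split = int(rng.integers(1, len(p)))
            f1 = DomainArrangement(p[:split])
            f2 = DomainArrangement(p[split:])
            if f1 in branch.current or f2 in branch.current:
                continue
            branch.remove(p)
            branch.add(f1)
            branch.add(f2)
            return (p,), (f1, f2)

        if etype is EventType.TERMINAL_LOSS:
            eligible = [a for a in pool if len(a) >= 2]
            if not eligible:
                return None
            p = eligible[int(rng.integers(len(eligible)))]
            k = int(rng.integers(1, len(p)))
            if int(rng.integers(2)):
                truncated = DomainArrangement(p[k:])   # N-terminal block lost
            else:
                truncated = DomainArrangement(p[:len(p) - k])
            if truncated in branch.current:
                continue
            branch.add(truncated)
            return (p,), (truncated,)

        if etype is EventType.TERMINAL_EMERGENCE:
            if not pool:
                return None
            p = pool[int(rng.integers(len(pool)))]
            d = fresh_domain()
            if int(rng.integers(2)):
                product = DomainArrangement((d,) + tuple(p))
            else:
                product = DomainArrangement(tuple(p) + (d,))
            branch.add(product)
            return (p,), (product,)

        if etype is EventType.SINGLE_LOSS:
            counts = Counter(d for arr in branch.current for d in arr)
            eligible = [a for a in pool if len(a) == 1 and counts[a[0]] == 1]
            if not eligible:
                return None
            a = eligible[int(rng.integers(len(eligible)))]
            branch.remove(a)
            return (a,), ()

        if etype is EventType.SINGLE_EMERGENCE:
            product = DomainArrangement((fresh_domain(),))
            branch.add(product)
            return (), (product,)

    return None


def replay_events(result: SimulationResult) -> Dict[str, ArrangementSet]:
    """Reapply the true event log from the root repertoire along the tree.

    Independent of the simulator's internal bookkeeping; used to check the
    replay invariant (reproduces every recorded ancestral set exactly).
    """
    events_by_node: Dict[str, List[TrueEvent]] = {}
    for ev in result.true_events:
        events_by_node.setdefault(ev.node_id, []).append(ev)
    sets: Dict[str, ArrangementSet] = {
        result.tree.root.id: result.true_ancestral_sets[result.tree.root.id]}
    for node in result.tree.preorder():
        if node.parent is None:
            continue
        current = set(sets[node.parent.id].arrangements)
        for ev in events_by_node.get(node.id, ()):
            if ev.event_type in (EventType.FISSION, EventType.SINGLE_LOSS):
                for pre in ev.precursors:
                    current.discard(pre)
            current.update(ev.products)
        sets[node.id] = ArrangementSet(current)
    return sets


@dataclass
class RecoveryReport:
    """True vs inferred event frequencies, plus the truth/solution confusion."""

    true_counts: Counter  # record equivalents per EventType, included nodes
    true_frequencies: Dict[EventType, float]  # percent
    inferred: RateTable
    records: list
    confusion: Dict[EventType, Counter]
    excluded: frozenset

    @property
    def unique_fraction(self) -> float:
        """Unique solutions as a fraction of all change records."""
        total = sum(self.inferred.solution_breakdown.values())
        if not total:
            return float("nan")
        unique = sum(self.inferred.solution_breakdown.get(st, 0)
                     for st in UNIQUE_SOLUTIONS)
        return unique / total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for et in EVENT_ORDER:
            rows.append({
                "event_type": et.value,
                "true_pct": round(self.true_frequencies.get(et, 0.0), 2),
                "inferred_pct": round(self.inferred.frequencies.get(et, float("nan")), 2),
            })
        return pd.DataFrame(rows)


def recover_rates(result: SimulationResult, root_unknown: str = "absent",
                  junction_merge: bool = False) -> RecoveryReport:
    """Close the validation loop: run the full inference pipeline on the
    simulated leaf repertoires and compare against the ground truth.

    True frequencies are in record equivalents (one per gained fragment, so
    fission counts twice; one per single loss), restricted to the same
    non-excluded nodes the rate calculation uses.
    """
    recon, records, table, excluded = run_pipeline(
        result.tree, result.leaf_annotations, root_unknown=root_unknown,
        junction_merge=junction_merge)

    true_counts: Counter = Counter()
    for ev in result.true_events:
        if ev.node_id in excluded:
            continue
        true_counts[ev.event_type] += len(ev.products) if ev.products else 1
    total_true = sum(true_counts.values())
    true_freq = {et: 100.0 * true_counts.get(et, 0) / total_true
                 for et in EVENT_ORDER} if total_true else {}

    by_key = {(r.node_id, r.arrangement, r.change_kind): r for r in records}
    confusion: Dict[EventType, Counter] = {et: Counter() for et in EVENT_ORDER}
    for ev in result.true_events:
        if ev.node_id in excluded:
            continue
        targets = [(arr, ChangeKind.GAINED) for arr in ev.products]
        if ev.event_type is EventType.SINGLE_LOSS:
            targets = [(ev.precursors[0], ChangeKind.LOST)]
        for arr, kind in targets:
            record = by_key.get((ev.node_id, arr, kind))
            if record is None:
                label = "not_observed"
            elif record.solution in UNIQUE_SOLUTIONS:
                label = record.resolved_type.value
            else:
                label = record.solution.value
            confusion[ev.event_type][label] += 1

    return RecoveryReport(true_counts=true_counts, true_frequencies=true_freq,
                          inferred=table, records=records, confusion=confusion,
                          excluded=excluded)
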