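"""Clade-wide rearrangement rates and the jackknife robustness test.

Only unique solutions (exact + non-ambiguous records) enter the rate
calculation; ambiguous and complex records are tallied in the solution-type
breakdown but ignored for frequencies.  To avoid polarization artifacts,
events at the outgroup (its leaves and exclusively-outgroup ancestors), at
the root of the whole tree, and at the clade root (the first ingroup node
below the root) are excluded.

The jackknife removes a fixed number of randomly chosen ingroup species per
replicate, prunes the tree (suppressing the resulting degree-2 nodes),
reruns the entire pipeline from the remaining leaf repertoires, and reports
the per-event mean and standard deviation of the frequencies over
replicates.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .events import (EventRecord, EventType, SolutionType, UNIQUE_SOLUTIONS,
                     infer_events)
from .io_formats import SpeciesAnnotation
from .parsimony import reconstruct_all
from .tree import PhyloTree

logger = logging.getLogger(__name__)

EVENT_ORDER = tuple(EventType)


def excluded_nodes(tree: PhyloTree) -> FrozenSet[str]:
    """Node ids excluded from rate calculation.

    All outgroup leaves and their exclusively-outgroup ancestors, the root,
    and every root child that is not purely outgroup (the clade root).  With
    no designated outgroup only the root and its first canonical child are
    excluded (a documented convention; logged).
    """
    excluded = {tree.root.id}
    og = tree.outgroup_leaves
    if og:
        for node in tree.preorder():
            if tree.subtree_leaves(node.id) <= og:
                excluded.add(node.id)
        for child in tree.root.children:
            if not (tree.subtree_leaves(child.id) <= og):
                excluded.add(child.id)
    else:
        logger.warning("no outgroup designated: excluding only the root and "
                       "its first child from rate calculation")
        excluded.add(tree.root.children[0].id)
    return frozenset(excluded)


@dataclass
class RateTable:
    """Per-node and aggregate counts/frequencies of the six event types."""

    per_node: Dict[str, Counter]
    totals: Counter
    frequencies: Dict[EventType, float]  # percent; empty if no unique solution
    solution_breakdown: Counter  # over SolutionType, all non-excluded records

    @property
    def total_unique(self) -> int:
        return sum(self.totals.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "event_type": et.value,
                "count": self.totals.get(et, 0),
                "frequency_pct": round(self.frequencies.get(et, float("nan")), 2),
            }
            for et in EVENT_ORDER
        ]
        return pd.DataFrame(rows)

    def node_counts_frame(self) -> pd.DataFrame:
        rows = []
        for node_id in sorted(self.per_node):
            row = {"node_id": node_id}
            for et in EVENT_ORDER:
                row[et.value] = self.per_node[node_id].get(et, 0)
            rows.append(row)
        return pd.DataFrame(rows, columns=["node_id"] + [et.value for et in EVENT_ORDER])

    def to_dict(self) -> dict:
        return {
            "totals": {et.value: self.totals.get(et, 0) for et in EVENT_ORDER},
            "frequencies_pct": {et.value: round(f, 2)
                                for et, f in self.frequencies.items()},
            "solution_breakdown": {st.value: self.solution_breakdown.get(st, 0)
                                   for st in SolutionType},
            "total_unique": self.total_unique,
        }


def compute_rates(
    records: Iterable[EventRecord],
    excluded: FrozenSet[str] = frozenset(),
) -> RateTable:
    """Aggregate unique-solution records at non-excluded nodes.

    Frequencies are percentages of the total number of unique solutions; if
    there is none they are reported empty, with a warning.
    """
    per_node: Dict[str, Counter] = defaultdict(Counter)
    totals: Counter = Counter()
    breakdown: Counter = Counter()
    for record in records:
        if record.node_id in excluded:
            continue
        breakdown[record.solution] += 1
        if record.solution in UNIQUE_SOLUTIONS:
            assert record.resolved_type is not None
            per_node[record.node_id][record.resolved_type] += 1
            totals[record.resolved_type] += 1
    total = sum(totals.values())
    if total == 0:
        logger.warning("no unique solutions: event-type frequencies are undefined")
        frequencies: Dict[EventType, float] = {}
    else:
        frequencies = {et: 100.0 * totals.get(et, 0) / total for et in EVENT_ORDER}
    return RateTable(per_node=dict(per_node), totals=totals,
                     frequencies=frequencies, solution_breakdown=breakdown)


def run_pipeline(
    tree: PhyloTree,
    annotations: Sequence[SpeciesAnnotation],
    root_unknown: str = "absent",
    junction_merge: bool = False,
):
    """Reconstruct, infer events, and aggregate rates in one call.

    Returns ``(reconstruction, records, rate_table, excluded)``.
    """
    recon = reconstruct_all(tree, annotations, root_unknown=root_unknown)
    excluded = excluded_nodes(tree)
    records = infer_events(recon, excluded, junction_merge=junction_merge)
    table = compute_rates(records, excluded)
    return recon, records, table, excluded


@dataclass
class JackknifeResult:
    """Mean/sd of event-type frequencies over leaf-removal replicates."""

    replicates: int
    removed_per_clade: int
    seed: int
    means: Dict[EventType, float]
    sds: Dict[EventType, float]
    per_replicate: np.ndarray  # shape (replicates, 6), percent
    removed: List[List[str]] = field(default_factory=list)
    full_frequencies: Dict[EventType, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"event_type": et.value,
              "mean_pct": round(self.means[et], 2),
              "sd_pct": round(self.sds[et], 2)} for et in EVENT_ORDER]
        )


def jackknife(
    tree: PhyloTree,
    annotations: Sequence[SpeciesAnnotation],
    n_remove: int = 3,
    reps: int = 100,
    seed: int = 0,
    root_unknown: str = "absent",
    junction_merge: bool = False,
) -> JackknifeResult:
    """Jackknife over random removal of ingroup species.

    Per replicate, ``n_remove`` ingroup leaves are removed uniformly at
    random (outgroup species are never removed), the tree is pruned and the
    whole pipeline rerun.  Fully reproducible from ``seed``.
    """
    if reps <= 0:
        raise ValidationError("reps must be positive")
    if n_remove < 0:
        raise ValidationError("n_remove must be non-negative")
    ingroup = sorted(tree.leaf_labels - tree.outgroup_leaves)
    if len(ingroup) - n_remove < 4:
        raise ValidationError(
            f"clade would retain {len(ingroup) - n_remove} leaves after removal; "
            "at least 4 are required"
        )
    by_species = {ann.species_id: ann for ann in annotations}
    rng = np.random.default_rng(seed)
    freq = np.zeros((reps, len(EVENT_ORDER)))
    removed_log: List[List[str]] = []
    for r in range(reps):
        removed = sorted(rng.choice(ingroup, size=n_remove, replace=False).tolist()) \
            if n_remove else []
        removed_log.append(removed)
        sub_tree = tree.prune(removed) if removed else tree
        sub_ann = [by_species[sp] for sp in sorted(sub_tree.leaf_labels)]
        _, _, table, _ = run_pipeline(sub_tree, sub_ann,
                                      root_unknown=root_unknown,
                                      junction_merge=junction_merge)
        for j, et in enumerate(EVENT_ORDER):
            freq[r, j] = table.frequencies.get(et, np.nan)
    means = {et: float(np.nanmean(freq[:, j])) for j, et in enumerate(EVENT_ORDER)}
    # identical replicate values have exactly zero spread (nanstd would leave
    # ~1e-16 round-off from the mean)
    sds = {
        et: (0.0 if np.all(freq[:, j] == freq[0, j])
             else float(np.nanstd(freq[:, j], ddof=0)))
        for j, et in enumerate(EVENT_ORDER)
    }
    _, _, full_table, _ = run_pipeline(tree, list(annotations),
                                       root_unknown=root_unknown,
                                       junction_merge=junction_merge)
    return JackknifeResult(replicates=reps, removed_per_clade=n_remove, seed=seed,
                           means=means, sds=sds, per_replicate=freq,
                           removed=removed_log,
                           full_frequencies=dict(full_table.frequencies))
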