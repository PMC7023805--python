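# Methods

## Model

The unit of observation is the *domain arrangement*: the ordered sequence of
domain identifiers annotated on one protein, canonicalized by collapsing
consecutive repeats of the same domain (`A-B-B-B-C → A-B-C`). Repeat
collapse absorbs both the high natural volatility of tandem-repeat copy
number and split-domain annotation artifacts. A species (or ancestral node)
is represented by the presence/absence *set* of its arrangements; copy
number is never modelled, so expansion or contraction of an existing
arrangement is invisible by design — emergence and loss are functional
(repertoire-level) notions here.

Ancestral repertoires on a rooted bifurcating species tree are
reconstructed with two parsimony schemes over two character sets:

* **Arrangements → Fitch parsimony.** Each arrangement is a binary
  character that may be gained and lost repeatedly. The up-pass combines
  the two children of each node with three-valued rules (equal states pass
  through; one unknown defers to the known state; present-vs-absent gives
  unknown, i.e. the ambiguous set {present, absent}); the down-pass first
  resolves an unknown root by the root rule and then sets every remaining
  unknown to its finalized parent state. This refinement is an arbitrary
  minimum-change assignment — the test suite verifies optimality against
  exhaustive enumeration on all rooted binary topologies with ≤ 6 leaves.
* **Single domains → Dollo parsimony.** Each domain occurring in any
  arrangement is a binary character that is gained exactly once. The gain
  is placed at the most recent common ancestor of all leaves carrying the
  domain; a node is present iff it lies on a path from the gain node to a
  carrying leaf. This closed form is provably the minimum-loss assignment
  under the single-gain constraint (also oracle-verified); it involves no
  unknown states, so the root rule below only concerns Fitch characters.

Changed arrangements at each node (vs its parent) are explained by
enumerating all *single-step* candidates among six event types. For a
gained arrangement N against the parental set P:

* **fusion** — N splits at some boundary into two arrangements both in P.
* **fission** — N is a proper terminal fragment (prefix or suffix) of some
  arrangement in P *and* the complementary fragment is present in the child
  set: the precursor split into two parts, both retained.
* **terminal loss** — N is a terminal fragment of some arrangement in P and
  the complementary block left *no trace* (no child arrangement equals it).
  A single event may remove several contiguous domains from one terminus —
  the natural consequence of a premature stop codon — but never from both
  termini at once.
* **terminal emergence** — N is an arrangement of P with exactly one novel
  domain appended at one terminus, where "novel" is gated by the Dollo
  layer: the domain's unique gain must sit at this very node.
* **single emergence** — N is a single novel domain (Dollo gain here)
  appearing as a discrete arrangement.

A lost arrangement has exactly one possible single-step explanation,
**single loss**: it is a single-domain arrangement whose domain disappears
completely from the child repertoire (and is Dollo-reconstructed absent at
the node, present at the parent). Lost multi-domain arrangements and
single-domain losses whose domain persists inside other arrangements are
recorded as unclassified complex losses — the six types do not cover them,
and dropping them silently would break the books (solution-type counts
always partition the observed changes).

Records with one candidate are *exact*; several candidates of one type,
*non-ambiguous*; several types, *ambiguous*; none, *complex*. Rates count
only exact + non-ambiguous ("unique") records, as percentages of their
total. Events at the outgroup leaves and their exclusively-outgroup
ancestors, at the tree root, and at the clade root (the first ingroup node
below the root) are excluded from rates, because changes there cannot be
polarized reliably.

## Design choices that were genuinely open

* **Fusion enumeration and repeat collapse.** Stored arrangements are
  canonical, so a biologically real fusion of `A-B` and `B-C` would be
  observed as `A-B-C`. By default the candidate enumeration nevertheless
  uses plain concatenation splits only, keeping the candidate set aligned
  with the event model's worked examples (gaining `A-B-C` over
  `{A, A-B, B-C, C}` yields exactly the two routes `A+B-C` and `A-B+C`).
  Passing `junction_merge=True` to `explain_gain`/`infer_events` adds the
  collapse-aware shared-boundary routes (`A-B ⊕ B-C`). The fusion product
  helper `concat_collapse` always re-collapses, and the simulator uses it,
  so the two conventions can be compared on the same data.
* **Fission vs terminal loss.** The two tests are formally identical except
  for the fate of the complementary fragment; the presence/absence of that
  fragment in the child set is the discriminator. It is enforced per
  precursor: an arrangement that supports a fission candidate (either
  complement persisting) never also contributes a terminal-loss candidate
  for the same gain, so the two types cannot co-occur on one precursor.
* **Fission record counting.** When both fragments of a fission are new at
  a node, each gained fragment is its own record (two records, each with
  its own candidate set). This affects absolute counts, not the soundness
  of classification; the simulator's recovery report therefore states true
  frequencies in the same record-equivalents (a fission event counts
  twice).
* **Terminal loss in the simulator retains the precursor.** Under
  presence/absence semantics the truncation of one gene copy leaves other
  copies of the full arrangement intact, so the child set holds both the
  precursor and the truncated form — exactly the inference signature of a
  terminal loss. Fission, by contrast, removes the precursor and keeps both
  fragments, so each simulated fission also produces one unclassified
  multi-domain loss record.
* **Root rule.** An unknown Fitch root state resolves to *absent* by
  default (`root_unknown="present"` is available). Resolving absent pushes
  gains toward the leaves and is conservative about deep ancestral
  repertoires; any residual bias sits at the root/clade-root nodes, which
  the rate calculation excludes anyway.
* **No-outgroup trees.** "Clade root" presumes the root separates outgroup
  from ingroup. Without a designated outgroup the package excludes the root
  and its first child in canonical order (children are sorted by smallest
  leaf label) and logs a warning; this is a convention, not a modelling
  claim.
* **Isoform filter tie-break.** Equal-length isoforms of one gene keep the
  lexicographically smallest protein id, for determinism.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `root_unknown` | `absent` | Resolution of an ambiguous Fitch root state. |
| `junction_merge` | `False` | Admit collapse-aware fusion routes. |
| jackknife `n_remove` | 3 | Ingroup species removed per replicate (outgroup never removed; the clade must retain ≥ 4 leaves). |
| jackknife `reps` | 100 | Replicates; mean and sd (population, ddof=0) per event type. |
| `root_repertoire_size` | 500 | Arrangements in the simulated root repertoire. |
| length distribution | geometric-like, mean ≈ 2 | Initial arrangement lengths 1–6 (halving probabilities); short arrangements dominate real proteomes. |
| `domain_alphabet_size` | 18000 | Root domain pool, at the scale of the Pfam vocabulary, so unrelated arrangements rarely share domains — the regime in which the single-gain assumption and the fragment-trace discriminator are clean. |
| `events_per_branch` | 5 | Integer = fixed count per branch; non-integer = Poisson mean. The default keeps events sparse relative to the repertoire (a few per branch), where single-step explanations are identifiable. |
| `event_type_weights` | .45/.15/.20/.01/.17/.02 | Fusion / fission / terminal loss / terminal emergence / single loss / single emergence: a mixed regime dominated by fusion and losses with rare emergences. |

## What the simulator emulates — and what it does not

The generator evolves a repertoire forward along the tree under exactly the
six event types, with ground truth recorded per branch: emergence events
always introduce globally fresh domains (so Dollo's single-gain assumption
holds *in truth*), single losses only remove a domain's last appearance,
and each event's precursors are arrangements inherited from the branch's
parent node, making every event a single step relative to the parent.
Colliding or infeasible draws are re-sampled a bounded number of times and
then skipped with a log entry. Replaying the event log from the root set
reproduces every recorded ancestral set exactly (a tested invariant).

This is the model's own best-case world. Passing recovery tests therefore
show that the inference machinery is correct and well-calibrated *under the
model's assumptions*; they do not show that real proteomes satisfy those
assumptions. Real data differ in ways the generator deliberately omits:
domains re-emerge by annotation noise, arrangements share promiscuous
domains far more often than a uniform draw over a Pfam-scale alphabet,
repertoires are 20–50× larger, gene models are wrong in correlated ways,
and event density varies strongly across branches. At higher simulated
densities the same machinery degrades honestly: parallel identical events
in different lineages get merged rootward by parsimony and fission becomes
undercounted — the recovery report's truth/inference confusion table makes
this visible rather than hiding it.

## Numerical and determinism notes

* Reconstruction is vectorized with int8 numpy matrices (nodes ×
  characters); both traversals are exact integer logic, no floating point.
* All iteration over arrangement sets is in lexicographic order of the
  textual form, children are in canonical order, and internal node ids are
  assigned in preorder — identical inputs give identical outputs regardless
  of input file order or set iteration order.
* Jackknife frequencies are percentages (they sum to 100 within float
  round-off); when all replicate values of an event type coincide the sd is
  reported as exactly 0.0 instead of the ~1e-16 round-off `nanstd` yields.
* Degenerate inputs: a zero-unique-solution run reports empty frequencies
  with a warning rather than NaNs; a character absent from every leaf is
  all-absent with no Dollo gain; pruning suppresses degree-2 nodes and
  re-roots if the root is left with one child.

## Known limitations

* Single-step explanations only: chains of two or more events are reported
  as complex, never searched.
* Rates are raw per-node event frequencies — not normalized by proteome
  size, duplication activity, or branch time (branch lengths are read and
  ignored), so cross-clade comparisons should hold annotation depth and
  sampling comparable.
* Ambiguous records are reported but not adjudicated (e.g. no domain-tree
  evidence is consulted).
* Multifurcations must be resolved upstream, except a root trifurcation
  that the designated outgroup can split.
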