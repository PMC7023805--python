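# domevol

Protein domains are reusable structural and functional modules, and much of
protein innovation happens not by point mutation but by *rearranging* them:
two proteins fuse, one protein splits in two, terminal domains are clipped
off by a premature stop codon, and whole domains emerge or disappear.
`domevol` infers these events — and their clade-wide rates — from a rooted
species tree plus per-species domain annotations, for people studying
genome/proteome evolution who want event counts and frequencies rather than
sequence-level alignments.

## Method

A *domain arrangement* is the ordered sequence of domains in one protein,
with consecutive repeats collapsed (`A-B-B-B-C → A-B-C`); each species
contributes the presence/absence **set** of its arrangements (copy number is
deliberately ignored). Ancestral repertoires are reconstructed twice:

* **Fitch parsimony**, one binary character per arrangement — arrangements
  are modular and may be formed and broken repeatedly, so minimum-change
  reconstruction with free gains and losses fits. An up-pass applies the
  three-valued (present/absent/unknown) rules; a down-pass resolves the root
  (default: absent) and copies the finalized parent state into remaining
  unknowns. The result provably attains the parsimony minimum.
* **Dollo parsimony**, one binary character per single domain — a novel
  domain is gained exactly once, at the most recent common ancestor of the
  leaves carrying it, with losses wherever a present node has an all-absent
  subtree. The Dollo layer vets every emergence and single-domain loss call.

Every arrangement gained or lost at a node (relative to its parent) is then
given all single-step explanations among six event types — **fusion**,
**fission**, **terminal loss**, **terminal emergence**, **single-domain
loss**, **single-domain emergence** — and classified as an *exact* solution
(one candidate), *non-ambiguous* (several candidates, one type),
*ambiguous* (several types), or *complex* (no single-step explanation).
Only exact + non-ambiguous ("unique") solutions enter the rate table, and
events at the outgroup, the root, and the clade root are excluded to avoid
polarization artifacts. Robustness is assessed by a jackknife that removes
random ingroup species and reruns everything. A forward simulator generates
repertoires evolving under the same six event types with a ground-truth log,
closing the validation loop (`recover_rates`).

See `docs/methods.md` for assumptions, parameters, and limitations.

## Worked example

Simulate a small dataset (8 species, two of them outgroup), estimate rates,
and compare against the simulation's ground truth:

```bash
cat > sim.yaml <<'YAML'
tree: "((og1,og2),((a,b),((c,d),(e,f))));"
outgroup: [og1, og2]
root_repertoire_size: 120
events_per_branch: 4
seed: 11
YAML

domevol simulate --config sim.yaml --out sim_out
domevol rates --tree sim_out/tree.nwk --manifest sim_out/manifest.tsv \
              --outgroup og1,og2 --out rates_out
domevol recover --sim sim_out --out rec_out
```

which prints

```
simulated 56 events over 8 species -> sim_out
wrote results to rates_out
                fusion:  53.49 %
               fission:  18.60 %
         terminal_loss:   6.98 %
    terminal_emergence:   2.33 %
           single_loss:  18.60 %
      single_emergence:   0.00 %
        event_type  true_pct  inferred_pct
            fusion     51.11         53.49
           fission     22.22         18.60
     terminal_loss      6.67          6.98
terminal_emergence      2.22          2.33
       single_loss     17.78         18.60
  single_emergence      0.00          0.00
unique solutions: 86.0 % of records
```

The first block is the estimated event-type frequency table (percent of all
unique solutions at non-excluded nodes; `rates_out/` also contains the
events table, per-node counts, and the solution-type breakdown). The second
block shows that rerunning inference on the simulated data recovers the
ground-truth event mix to within a few percentage points — the residual gap
is the price of parsimony reconstruction plus the genuinely ambiguous and
complex cases, which are reported but never counted.

Real data go in the same way: a Newick tree, plus either `pfam_scan.pl`
output (`--format pfamscan`) or two-column arrangement TSVs per species,
listed in a manifest or a directory. `domevol inspect-node --node N7 ...`
dumps one node's reconstructed changes and candidate events for debugging.

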