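# Methods

## Model and procedure

The central computation is minimum-change (parsimony) ancestral-state
reconstruction of categorical characters on a rooted phylogeny, together
with exact bookkeeping over the full set of optima.

Given a rooted tree (polytomies allowed) and, per tip, an allowed state
set — a single observed state, a polymorphic set, or the full state space
for missing data — an ancestral assignment gives every node one state. Its
cost is the sum of per-edge costs `c(parent_state, child_state)` under
either the unordered model (every change costs 1) or a custom
non-negative, zero-diagonal cost matrix. A most-parsimonious
reconstruction (MPR) is an assignment of minimum total cost.

* **Minimum cost** is computed by Sankoff dynamic programming: an upward
  pass computes, per node and state, the optimal subtree cost; polytomies
  are handled natively because the recursion sums over all children. No
  prior is placed on the root: the optimum is the minimum over root
  states. Under unit costs the result is cross-checked at run time against
  a Hartigan-style generalization of the Fitch set algorithm (at each
  node, keep the states carried by the largest number of children; the
  count increases by the number of children minus that multiplicity).
* **Per-node state sets** (the states a node takes in at least one MPR)
  come from a second, downward pass: a state is optimal at a node iff its
  upward cost plus the cost of the rest of the tree equals the global
  minimum. At tips the reported set is the observed set (full space when
  missing) — the constraint, not its MPR-restriction.
* **MPR enumeration** backtracks over the DP tables in a fixed preorder
  with states tried in the character's declared order, so the stream is
  deterministic and lexicographic. A configurable cap (default 10,000)
  bounds the enumeration; truncation is flagged on the result rather than
  silently ignored. Intervals are then exact counts over the enumerated
  set: for transitions, the number of edges whose parent/child states
  match the queried ordered pair; for independent origins, the number of
  maximal connected regions carrying the state whose parent does not (a
  root assigned the state counts as one origin). Reporting `[min, max]`
  rather than a single optimum is deliberate: genuinely ambiguous
  histories ("five or six independent occurrences") stay ambiguous.

Conventions for degenerate inputs: a missing tip costs zero for every
state, inherits its parent's state in every enumerated MPR, and therefore
never contributes transitions or origins; a polymorphic tip behaves
exactly as a tip allowed any of its states (it may contribute an origin if
its optimal state differs from its parent's). Ties between states are
never broken arbitrarily — they propagate into the state sets and
intervals. Costs are compared with a 1e-9 absolute tolerance so that
integer-valued unit-cost arithmetic is exact.

## Habitat and ecozone analysis

Salinity (‰) maps to habitat classes on the half-open bins [0,5)
freshwater, [5,25) brackish, [25,35] marine, (35,∞) hypersaline.
Boundaries resolve upward; the choice is anchored by a 25‰ site described
as marine in the source material, while the 5‰ boundary is genuinely
ambiguous there (both "0–5" and "5–25" are printed) and half-open
assignment to brackish is this package's convention. The classifier is a
total monotone step function. Subclade habitat consensus is strict
majority (>50% of non-missing values; polymorphic members contribute each
of their states once); anything less is an explicit tie. Invasion counting
is exactly independent-origin counting on the habitat character. "Soil"
records are folded into freshwater, since the habitat scheme carries no
separate soil class.

## Identification key

Species profiles hold, per trait of a fixed nine-trait schema, a numeric
interval or a categorical state set. Approximate literature values ("~30
membranelles", "85 µm") are expanded to ±10% intervals so that point
estimates participate in overlap logic; broad polymorphic species are
simply wide intervals, with no special-casing. Compatibility is inclusive
interval membership / set membership, with missing data compatible by
convention. Identification ranks species by the number of incompatible
traits (ties broken alphabetically for determinism) and reports an
identification only for a unique conflict-free candidate.
`discriminating_characters` returns traits whose ranges are disjoint —
intervals meeting at a single shared endpoint count as overlapping, which
is the conservative reading of "unambiguously different". Qualitative
notes that do not fit the schema (peristome width, apical notches, cirral
vestiges) are outside the key's scope; the packaged comparative table
therefore expresses a superset-of-bold-cells guarantee only for
schema-expressible characters.

## Alignment curation and identity

End-trimming scans inward from each alignment end and removes columns
while the missing-data fraction (gaps and N) strictly exceeds the
threshold (default 0.6), stopping at the first compliant column per end;
interior columns are never removed, and a column at exactly the threshold
is retained. The operation is idempotent. Percent identity is reported
either over the columns of an existing alignment (gap–gap columns
excluded) or after a BLAST-like local alignment (match +2, mismatch −3,
gap open −5, extend −2); local-alignment identity is comparable to, but
not bit-identical with, any particular BLAST build, so cross-database
comparisons should use a tolerance of a few tenths of a percentage point.

## Synthetic data

The generators emulate the shape of the study data, not its content:
Yule trees (uniform lineage splitting, exponential waiting times),
per-edge Markov character evolution (with probability *p* per edge the
state switches to a uniformly chosen different state; the latent event
list is returned alongside the tips), and specimens drawn uniformly from
a profile's intervals with optional relative Gaussian jitter. Defaults —
16 tips, 2–3 states, p = 0.1 for general checks and p = 0.02 (expected
<1 change per 16-tip tree) for root-recovery checks — are chosen to match
the regimes the properties address: the true event count must dominate
the parsimony minimum on every replicate, and at low rates the true root
state should sit in the reconstructed root set in ≥95% of replicates.
What the simulations do **not** emulate: rate heterogeneity across
lineages, correlated characters, branch-length-dependent change
probabilities, or measurement error structure beyond i.i.d. jitter — so
passing these checks validates the algorithms, not any claim about real
*Euplotes* evolution. All generators are pure functions of (config, seed);
replicate seeds derive from a master seed by fixed arithmetic
(`(master * 1000003 + index) mod 2^31`) so other implementations can match
the replicate structure without matching the RNG stream.

## The packaged dataset

The fixture encodes the genus-level dataset: a 46-tip species tree
(outgroup omitted; *E. charon* excluded as unplaceable), five major clades
A–E and fifteen monophyletic subclades, a species × character matrix
(dargyrome type, FVC count, habitat, ecozone) and the six-species
comparative trait table. Every matrix cell carries a provenance tag:
`text` and `table` cells restate printed statements; `figure-transcription`
cells are read off published figures and cannot be re-verified against
printed text, so downstream claims that depend on them (e.g. ecozone
origin counts) are treated as bounds rather than equalities. The
15-subclade synopsis tree and its habitat states are a *computed view* —
subclades collapsed from the species tree, habitats by majority-rule
consensus — never an independent input. Checksums of the shipped files are
exposed via a manifest. Where figures and text could disagree, text wins
and the discrepancy would be logged in the fixture's annotation file.

## Problem sizes and numerical choices

The oracle-equivalence check compares minimum cost, node state sets, the
complete MPR set, and transition/origin intervals against exhaustive
enumeration on 1,000 random instances of up to 8 tips (≤7 internal nodes
after random polytomy creation) and 3 states, including missing and
polymorphic tips; simulation bounds use 500 seeded replicates. These sizes
make the exhaustive oracle exact while keeping the default test run fast.
The MPR cap (10,000) is far above the optimum counts seen on the packaged
data (≤4 for the dargyrome character); analyses that hit the cap report
`complete: false` instead of pretending exactness.

## Known limitations

* Parsimony only: no likelihood or Bayesian reconstruction, no
  branch-length awareness, no stochastic character mapping — minimum
  counts are lower bounds on the true number of events by construction.
* Interval endpoints are computed by enumeration; pathological characters
  with astronomically many MPRs would be truncated (and flagged).
* The identification key is a deterministic range check, not a
  statistical species-delimitation method.
* The figure-transcribed fixture cells are a reconstruction consistent
  with all printed statements, not a digitization of the original files.
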