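# euplotia

Character evolution, biogeography and morphospecies identification for the
ciliate genus *Euplotes* (Spirotrichea, Euplotia).

*Euplotes* is one of the best-defined ciliate genera: over 70 morphospecies
delimited by a small set of quantifiable cortical characters — the dorsal
argyrome ("dargyrome") pattern, the number of frontoventral cirri (FVC),
dorsolateral kinety counts, body size, adoral membranelle counts. Mapped
onto the genus SSU rRNA phylogeny, these characters evolve convergently:
the same cirri are lost and the same dargyrome shifts recur in unrelated
lineages, and marine ancestors repeatedly invaded freshwater, hypersaline
and polar habitats. This package implements the desk side of that
analysis, for taxonomists describing new *Euplotes* populations and for
anyone doing discrete-character work on small phylogenies:

* **Parsimony ancestral-state reconstruction** on rooted, possibly
  multifurcating trees: generalized Fitch (Hartigan) set logic under unit
  costs, Sankoff dynamic programming under arbitrary cost matrices
  (e.g. a loss-only model for cirri counts), full enumeration of
  most-parsimonious reconstructions (MPRs), and exact `[min, max]`
  intervals over all MPRs for the number of specific transitions
  (`double-eurystomus → double-patella`) and of independent origins of a
  state (freshwater invasions, polar colonizations).
* **Habitat analysis**: the salinity classification (freshwater 0–5‰,
  brackish 5–25‰, marine 25–35‰, hypersaline >35‰), majority-rule subclade
  consensus, and invasion counting.
* **A trait-range identification key** reproducing the comparative-table
  logic of species descriptions: interval/state-set compatibility,
  ranked identification, and "unambiguously different" (disjoint-range)
  character detection.
* **Alignment curation**: end-column trimming at a strict >60% missing-data
  threshold, and pairwise percent identity (aligned-columns or BLAST-like
  local mode).
* **Seeded synthetic data** (Yule trees, Markov-evolved characters with
  known true histories, specimens drawn from trait ranges) so every stage
  is testable without downloads, plus a packaged, provenance-tagged
  encoding of the 46-taxon genus dataset.

The parsimony criterion: for character state assignments $x_v$ on tree
nodes, minimize $\sum_{(u,v)\in E} c(x_u, x_v)$ subject to tips matching
their observed state sets, with $c$ the unit or a custom cost matrix; the
package reports the minimum, the per-node sets of states realized in at
least one optimum, and count intervals across the complete optimum set.

## Worked example

Reconstruct dargyrome-type evolution on the packaged genus tree:

```bash
euplotia events --char dargyrome_type
```

prints (abridged):

```json
{
 "results": {
  "character": "dargyrome_type",
  "complete": true,
  "n_mprs": 4,
  "total_changes": 9,
  "transitions": {
   "double-eurystomus -> double-patella": [5, 6]
  },
  "origins": {
   "double-patella": [6, 6],
   "single": [1, 1],
   "multiple": [1, 1],
   "complex": [1, 1]
  }
 }
}
```

Read: at least **9** dargyrome-type changes occurred in the genus; the
shift from double-*eurystomus* to double-*patella* happened **5 or 6**
independent times depending on how the ambiguous root (the early-branching
*E. petzi* + *E. sinicus* lineage is double-*patella*) is resolved; the
single, multiple and complex types each arose once. The same command with
`--char FVC_count` gives **7** cirri-loss events with root state **10** —
the genus ancestor had the full set of ten frontoventral cirri:

```bash
euplotia reconstruct --char FVC_count   # min_changes: 7, root_states: ["10"]
euplotia invasions --state freshwater   # origins: [5, 5] (>= 2 radiations)
```

Identify a specimen against the packaged comparative table:

```bash
echo '{"size_length_um": 55, "shape": "oval", "peristome_extent_pct": 70,
       "AZM_membranelles": 30, "dorsal_ridges": "inconspicuous",
       "dargyrome_type": "double-eurystomus", "FVC_count": 10,
       "dorsolateral_kineties": 7, "middorsal_dikinetids": 11}' > s.json
euplotia identify --specimen s.json     # identification: Euplotes_curdsi
```

All subcommands (`reconstruct`, `events`, `invasions`, `identify`, `trim`,
`simulate`, `fixtures`, `pipeline`) emit one versioned JSON envelope and
are byte-deterministic given the same inputs and seed. The same
functionality is available as a library (`euplotia.parsimony`,
`euplotia.biogeography`, `euplotia.morphokey`, `euplotia.alignqc`,
`euplotia.synthdata`, `euplotia.fixtures`).

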