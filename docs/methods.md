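# Methods

## The model

`egotroph` treats a trophic dataset as a directed multigraph over taxa:
each record is a consumer → resource link annotated with the habitat in
which the interaction occurs (land / tidal / sea, an ordinal series) and
its interaction type (detritivory / herbivory / predation / parasitism, a
nominal set).  Interaction strength is deliberately ignored: all links are
unweighted and trophically "negative" from the resource's side.  Loops
(cannibalism) are excluded, and a duplicate of the 4-tuple
(consumer, resource, habitat, type) is collapsed with a warning, so the
link count E always counts distinct records.

The ego net of a focal taxon contains the taxa sharing a link with it
(the alters), the ego–alter links, and every link between two alters.
Taxa linked only to alters lie outside the ego net and are dropped,
together with their links, during construction.  N denotes the number of
alters (the ego's degree centrality) and E the total number of links.

### Descriptor conventions

Where a formula admits more than one reading, the package follows the
convention that reproduces the published worked arithmetic; the
alternative is available as an explicit option, never the default.

* **Role census.**  An alter is a consumer (resource) if it is the
  consumer (resource) end of at least one link *inside the net*; declared
  table flags are only a fallback for degenerate inputs.  The ego is
  excluded.  The identity `n_consumers + n_resources − n_both = N` holds
  by construction.
* **d₂ forbidden links.**  The denominator `n_c·n_r − n_b` counts the
  trophically allowed directed alter pairs: resource-only taxa cannot
  consume, and each dual-role taxon contributes one impossible self-pair,
  which the `− n_b` term removes.  A vanishing denominator makes d₂
  undefined; it is reported as an explicit marker, never 0.
* **Effective size.**  `N_eff = N − A/N` with A the number of alter–alter
  links counted once (A = E − N).  The social-network textbook variant
  sums alter degrees and so counts each link twice; it is exposed as
  `mode="degree_sum"` but is not the default, because the reference
  arithmetic divides the single count.
* **Ego betweenness.**  Link direction is ignored; path length counts
  links.  For each unordered alter pair, the fraction of its shortest
  paths passing through the ego is accumulated (a pair with one two-link
  path through ego and one around it contributes ½) and the sum is
  divided by the star-net maximum N(N−1)/2.  Implemented via Brandes
  betweenness (networkx) on the collapsed simple graph; the test suite
  checks it against exhaustive shortest-path enumeration.
* **Fragmentation.**  F = 1 − Σ s(s−1)/[N(N−1)] over the connected
  components of the alter–alter subgraph (ego and its links removed),
  which is equivalent to the pairwise reachability-matrix definition; the
  equivalence is test-verified against an explicit N×N matrix.
* **Layer diversity.**  Blau H = 1 − Σ p_k² with p_k the proportion of
  the net's *links* (ego–alter and alter–alter alike) in layer k.  The
  alternative alter-proportion reading (`proportions="alters"`) is
  available, but only link proportions reproduce the reference values.
  IQV divides H by 1 − 1/n where n is the number of layers *defined* for
  the dimension (3 habitats, 4 interaction types), occupied or not.  A
  one-layer dimension makes IQV undefined (explicit marker).
* **Densities** are reported on the 0–100 percent scale.  Printed-value
  comparisons round half away from zero (`utils.round_half_away`), the
  spreadsheet convention, not banker's rounding.

### Module detection

Modules are detected on the undirected alter–alter subgraph only.  The
ego is linked to every alter, so any partition would place it in every
module; clustering without it and re-attaching it for reporting gives
non-overlapping modules plus an omnipresent ego.  Alters with no
alter–alter links are singleton modules by definition (each pairs with
the ego alone).  `N_m = n_multi + n_singleton` counts both kinds, and
`M_ratio = (N_m − 1)/(N − 1)` uses the original alter count even when the
net has been layer-expanded.

The optimizer is a greedy Louvain-style modularity maximization written
in-package because reproducibility requirements pin details a library
leaves unspecified: the reference pass sweeps nodes in ascending id order
with deterministic tie-breaking (ties keep the current community, then
prefer the smallest community label), followed by seeded random-restart
passes (16 by default) whose node orders reshuffle each sweep; the
best-Q partition wins, earliest restart on ties.  Q is always evaluated
with `networkx.community.modularity` on the original subgraph, and
`networkx.community.louvain_communities` serves as an independent quality
cross-check in the tests.  On subgraphs small enough for exhaustive
partition search the returned Q matches the global optimum (test-verified
to 1e−9 on nets with up to 8 non-isolated alters).  An edgeless
alter–alter subgraph gets Q = 0 by convention, with a warning.  The
resolution parameter defaults to 1 (classic modularity) and is
configurable but non-default.  Greedy maximization on larger dense graphs
can return a local optimum; restarts make this rare but not impossible.

### Dimension-layer expansion

`expand_layers` replicates each taxon into one copy per
(habitat, interaction-type) context in which it has at least one link; a
seabird eaten as carrion on land, preyed upon on land and hunting at sea
gets three copies.  Each original link maps to exactly one layered link,
so the layered link count equals E, and copies of one taxon are *not*
linked to each other — the expansion adds information, never links.
Whether cross-layer self-links should exist is genuinely open; linking
copies would merge layer modules that the expansion is meant to separate,
so the package does not.  Single-level partitions only: nested or
submodular structure inside modules is out of scope.

### Time slices and scenarios

Presence intervals are closed on the arrival year and open after the
departure year — a predator present 1949–1991 is in the 1975 slice and
out of the 1995 slice.  A missing arrival means "baseline" (present from
the earliest slice); a missing departure is open-ended.  Links obey a
persistence rule: once first observed, a link stays as long as both
species are present; `first_observed = baseline` links exist from the
start.  Scenario branches live only on the final slice: an interval
tagged with a branch applies only under that branch, untagged intervals
under every branch, which makes all branches agree on every pre-branch
slice by construction.

Turnover records classify alters entering/leaving between consecutive
slices by native/exotic origin and satisfy the ledger identity
N(t) = N(t−1) + in − out identically.  Descriptor correlations
(Pearson or Spearman, via scipy.stats) are computed over the ten
descriptors (N, E, d₁, d₂, b_ego, N_eff, M_ratio, F, H_h, H_i —
efficiency and the IQVs are normalizations of other rows and excluded),
giving 45 unordered pairs; constant columns and pairs with fewer than
three defined points are undefined markers.  Grouping descriptors into
covarying families is interpretive and left to the user.

## The synthetic generator

The generator emulates the statistical shape of a seabird-island ego-net
baseline, not any real species list.  Defaults (changeable via
`GeneratorParams` or YAML):

| parameter | default | rationale |
|---|---|---|
| `n_alters` | 50 | baseline net size |
| role fractions (consumer-only / resource-only / both) | 0.08 / 0.50 / 0.42 | reproduces a (25, 46, 21) role census |
| `alter_link_prob` | 0.048 | ≈ 54 alter–alter links over the 25·46 − 21 = 1129 allowed pairs |
| `habitat_weights` | 39:32:33 /104 | baseline per-habitat link counts |
| `type_weights` | 16:6:78:4 /104 | baseline per-type link counts (predation-dominated) |

Every alter gets exactly one ego link (consumer-only alters consume the
ego; all others are consumed by it), then alter–alter links are
independent Bernoulli draws over trophically allowed consumer→resource
pairs — mirroring the d₂ forbidden-link logic, so generated nets are
always consistent with the bipartite denominator.  Node habitat sets are
the union of their links' habitats.  Optional planted groups replace the
background draws with high within-group / low between-group link
probabilities for module-recovery experiments.  The timeline generator
scripts presence gaps, departures, exotic arrivals (each arrival brings
an ego link and a few alter links first observed that year), one keystone
exotic that persists only in one terminal branch, and cascade natives
that persist only in the other.

What the generator does **not** emulate: correlated layer structure
(real habitats and interaction types covary), body-size or abundance
effects, multi-layer repeated links, taxonomic aggregation artifacts, or
empirically scripted event magnitudes.  Passing tests therefore show the
machinery is correct on nets of realistic size and shape, not that any
ecological conclusion about a real island transfers.

## Numerical choices and degenerate inputs

* Undefined descriptors (empty slice, vanishing d₂ denominator, N < 2
  for betweenness/fragmentation, one-layer IQV) surface as NaN plus a
  note in `DescriptorRecord.notes`, serialized as the string
  `undefined` in CSV output — never silently 0.
* Oracle comparisons in the tests use 1e−9 (path counting, modularity
  optima) or 1e−12 (algebraic identities).
* Module labels are assigned by each module's smallest member id, making
  partition exports byte-stable across runs and platforms.
* Seeds: one user seed drives a whole trajectory (module detection per
  slice re-uses it), and generator seeds fully determine the emitted
  tables, byte for byte.

## Problem sizes in the test suite

Exhaustive oracles bound the sizes they can check: betweenness and
fragmentation are verified on 200 random nets of up to 12 nodes,
modularity optimality on 50+ subgraphs of up to 8 non-isolated alters
(set-partition enumeration grows as the Bell numbers), planted-module
recovery on 100 replicates of the 50-alter configuration, and the
uniform-habitat diversity calibration on 200 replicates.  These sizes
keep the full suite under a couple of minutes while leaving the checked
properties size-independent.

## Known limitations

* Greedy modularity maximization is heuristic above exhaustively
  checkable sizes; different algorithms (or resolutions) can place module
  boundaries differently.
* Marine alter–alter links, indirect/apparent-competition links, and
  interaction strengths are not inferred — absent records stay absent.
* The layered expansion has no M_ratio/F analogue for nested submodular
  structure; it reports the flat partition only.
* Scenario branching supports terminal branches only; mid-timeline
  branching would require a tree of scenario tags.
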