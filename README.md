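# egotroph

Ego-network analysis of trophic interaction records, for ecologists who
want to quantify how a single focal species is embedded in its web of
feeding interactions.

A complete food web describes everything at once; an *ego net* recedes
focus to one species — the **ego** — its directly interacting partners —
the **alters** — the ego–alter links, and the alter–alter links among
those alters.  `egotroph` builds the ego net of any focal taxon from a
pair of delimited tables (taxa and directed consumer → resource records,
each link carrying a habitat layer and an interaction-type layer),
computes ten structural descriptors, detects modules with or without
dimension-layer expansion, and tracks the descriptors across time slices
and branching invasion scenarios.

## The descriptors

With *N* alters and *E* links in total (ego–alter plus alter–alter):

| descriptor | definition |
|---|---|
| size | *N*, *E* |
| total link density | *d*₁ = 100·*E* / [*N*(*N*+1)] (%) |
| alter link density | *d*₂ = 100·(*E*−*N*) / (*N*_c·*N*_r − *N*_c=r) (%) |
| effective size | *N*_eff = *N* − *A*/*N*, with *A* = *E*−*N* alter–alter links; efficiency = *N*_eff/*N* |
| ego betweenness | *b*_ego = fraction of shortest alter–alter paths through ego, normalized by *N*(*N*−1)/2 |
| module ratio | *M*_ratio = (*N*_m−1)/(*N*−1), *N*_m modules from greedy modularity maximization on the alter–alter subgraph |
| fragmentation | *F* = 1 − Σ*r*ᵢⱼ/[*N*(*N*−1)], over pairwise alter reachability avoiding ego |
| layer diversity | Blau *H* = 1 − Σ*p*ₖ² and IQV = *H*/(1 − 1/*n*) per dimension (habitat: 3 layers; interaction type: 4) |

*d*₂ treats the alters as a two-mode consumer/resource set, so trophically
forbidden pairs (and the self-loops of dual-role taxa) are excluded from
its denominator.  Betweenness and reachability ignore link direction.
Module detection runs on the alter–alter subgraph only — the ego, linked
to everything, belongs to every module and is re-attached afterwards;
alters with no alter–alter links each form a singleton module with the
ego.  Full definitions, conventions and edge cases are in
[docs/methods.md](docs/methods.md).

## Worked example

The bundled teaching fixture is an ego with six alters and 14 links
(four alters consumed by the ego, two consuming it, and eight
alter–alter links), plus three outside taxa that touch only alters and
are therefore excluded during construction:

```python
import egotroph as et

nodes, links = et.make_toy_net()
net = et.build_ego_net(nodes, links, "ego")
record = et.descriptor_suite(net, seed=1)
print(record.to_dict(include_counts=False))
```

prints (rounded):

```
n_alters         6        # N: six alters; the three outside taxa dropped
n_links          14       # E: 6 ego links + 8 alter-alter links
d1               33.333   # 100*14/(6*7): a third of possible links realized
d2               47.059   # 100*8/(5*4-3): census (5 consumers, 4 resources, 3 both)
b_ego            0.267    # most alter pairs already reach each other off-ego
n_eff            4.667    # 6 - 8/6: alter-alter redundancy discounts the star
efficiency       0.778
m_ratio          0.2      # 2 modules among 6 alters
n_modules        2
fragmentation    0.0      # every alter reaches every other without the ego
h_habitat        0.622    # link spread over land/tidal/sea
iqv_habitat      0.934
h_interaction    0.582    # link spread over the four interaction types
iqv_interaction  0.776
```

The same pipeline is exposed on the command line:

```sh
egotroph generate --kind timeline --seed 1 --out data/
egotroph trajectory --nodes data/nodes.csv --links data/links.csv \
    --ego ego --timeline data/timeline.yaml --seed 1 --out results/
```

which writes a descriptor-by-slice table (six shared time slices plus two
terminal scenario branches), per-slice species turnover counts split by
native/exotic origin, and the 45-pair descriptor correlation matrix.

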