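# phosphowalk

Phosphorylation-chain inference for treated-vs-control antibody microarrays.

Phospho-antibody arrays (e.g. Kinexus KAM-1325 / KAM-2000 designs, with
1,325 and 2,000 pan- and phosphosite-specific antibodies) report, per probe,
a treatment fluorescence signal and a control signal with error estimates.
The interesting biology is usually not the single largest fold change but
*chains* of phosphorylation events — a root kinase activating a cascade of
substrates. `phosphowalk` reconstructs such chains by mapping the measured
percent changes from control onto a signed kinase–substrate prior network
and running seeded random walks against a permutation null, separately for
up- and down-regulated events, then assembling the surviving chains into a
comparative pathway map.

## Method in brief

For each probe, the percent change from control is
`%CFC = 100 · (S_T − S_C) / S_C` and the fold change `log2(S_T / S_C)`.
Probes are filtered by three rules before mapping: low signal (either
channel strictly below the array design's cutoff — 1,000 units for
KAM-1325, 500 for KAM-2000), high error relative to signal change
(`(e_T + e_C)/|S_T − S_C| > 1`), and higher total treatment-channel error
than control-channel error across all replicate arrays.

The prior network is a directed multigraph of relations *kinase → substrate
@ site* with an activating or inhibitory effect; relations of unknown effect
are treated as activating. Nodes with no incoming edge (root kinases) are
the only permitted walk start points. A walk starts at a uniformly chosen
root and steps along an untraversed outgoing edge with probability
proportional to `|%CFC| + ε`; it stops when the last phosphorylation is
inhibitory, when no untraversed edge remains, or at a length cap. Where a
node has exactly one unmeasured downstream option, a fold change is imputed
for the single path (uniform in [0, 20]% for the experimental dataset, 20%
exactly for a control). A chain's *enrichment* is its observed walk
frequency divided by its mean frequency when the measured CFC values are
reassigned to random network edges; chains occurring much more or much less
often than expected are kept, resolved for parallel phosphorylation (the
delivering edge with the greater magnitude wins), and selected when they
have more than 2 intermediates and every edge exceeds 5% CFC. A *hit* (or
lead) is a measured phosphosite appearing in at least one selected chain.

## Worked example

The package bundles a small curated two-arm signalling network (a
growth/survival AKT arm and a cell-cycle CDK1 arm) with synthetic,
sign-consistent measurements:

```python
from phosphowalk import PhosphoChainModel, fixtures

model = PhosphoChainModel(
    fixtures.load_demo_probes(),
    fixtures.load_demo_relations(),
    config=fixtures.demo_config(),
)
results = model.fit(seed=1)
print(results.summary())
```

```
                 Phosphorylation chain inference
==================================================================
array design:      KAM-1325 (low-signal cutoff 1000 units)
probes:            14 in, 14 retained (low-signal 0, relative-error 0, total-error 0)
network:           15 proteins, 17 site edges, 16 measured; roots: CDK7, CHEK1, MAPK14, PDK1, PIK3CA, SRC
walks:             4000 walks x 20 permutations, seed 1
------------------------------------------------------------------
selected chains:   8 up, 11 down
hits:              11 measured phosphosites in selected chains
  [  up] MAPK14->AKT@S473-|BAD@S75  (score 15.0, inhibition)
  [  up] MAPK14->AKT@S473->EZR@T567  (score 15.0, sink)
  [  up] PDK1->AKT@S473-|BAD@S75  (score 15.0, inhibition)
  ...
  [down] CHEK1->CDK1@Y15->JUN@S73  (score 18.0, sink)
  [down] SRC->CDK1@Y15->JUN@S73  (score 18.0, sink)
==================================================================
```

The up-direction chains recover AKT activation at S473 terminating at the
inhibitory AKT ⊣ BAD@S75 edge (walks never continue past an inhibitory
phosphorylation); the down-direction chains recover the CDK1@Y15 →
JUN@S73 cell-cycle arm. `results.hits_frame()`, `results.lead_frame()` and
`results.to_pathway_map()` expose the hit list, the lead table and the
styled comparative map (GraphML/DOT/JSON export; arrow width scales with
|log2 fold change|, color encodes direction).

The same pipeline is available from the shell:

```sh
phosphowalk simulate --out sim --seed 7            # synthetic planted-cascade arrays
phosphowalk infer --probes sim/probes_rep1.tsv --probes sim/probes_rep2.tsv \
    --probes sim/probes_rep3.tsv --relations sim/relations.tsv \
    --out run --seed 7                             # chains, leads, provenance
phosphowalk map --chains run/chains.json --out run/map.dot --format dot
```

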