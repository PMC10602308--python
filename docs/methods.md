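# Methods

This note documents the model behind `phosphowalk`, the choices made where
the procedure was genuinely open, the synthetic benchmark it is validated
on, and the limits of that validation.

## Data model

A probe measurement is a paired observation `(S_T ± e_T, S_C ± e_C)` of one
antibody under treatment and control. Phosphosite-specific probes measure
one phosphorylated residue (site grammar: one of S/T/Y plus a 1-based
position, e.g. `S473`); pan-specific probes measure total protein
expression and are tagged with the sentinel site `pan`. Derived quantities:
`%CFC = 100·(S_T − S_C)/S_C` and `log2fc = log2(S_T/S_C)`; the two are
monotone transforms of each other and always agree in sign.

## Preprocessing filters

Applied in order; each removal is attributed to exactly one rule, so the
filter report conserves counts exactly.

1. **Low signal.** A probe is removed when `min(S_T, S_C)` is strictly
   below the array design's cutoff (KAM-1325: 1,000 units; KAM-2000: 500).
   Equality retains (a literal reading of "below"). Using the minimum of
   the two channels means a quantifiable change cannot be computed against
   an unquantifiable denominator.
2. **Relative error.** Removed when `(e_T + e_C)/|S_T − S_C| > r`, default
   `r = 1` — i.e. the signal change is within the summed error. A zero
   change with nonzero error is an infinite ratio (removed); zero change
   with zero error is retained. The threshold is configurable
   (`relative_error_threshold`).
3. **Total error.** With replicate tables, a probe is blacklisted when its
   summed treatment-channel error across all tables strictly exceeds its
   summed control-channel error. Equal totals retain.

With replicates, signals and errors are averaged channel-wise before rules
1–2 and fold-change computation; rule 3 sees the per-table totals. The
pipeline is idempotent.

## Network model

Prior knowledge enters as site-resolved signed relations `kinase →
substrate @ site, effect ∈ {activation, inhibition, unknown}` held in a
directed multigraph keyed by site, so AKT activated via S473 and via Y326
are distinct edges. `unknown` effects are coerced to `activation` at build
time: absent curated evidence, a phosphorylation is assumed activating for
the purposes of chain tracing. Because array data cannot attribute a
measured phosphosite to one specific upstream kinase, a probe's CFC is
attached to *every* edge delivering its (substrate, site); nodes without
incoming edges (root kinases) are the only permitted chain origins. Pan
probes annotate nodes with an expression log2fc but never weight walks —
chains are defined over phosphorylation events, not expression.

The analysis runs independently for up- and down-regulated events: the up
(down) subnetwork keeps edges with positive (negative) CFC plus all
unmeasured edges; an exactly-zero CFC is neither an up- nor a
down-regulated event and joins neither side.

## Walk process

A walk starts at a root chosen uniformly at random and repeatedly steps
along an untraversed outgoing edge of the current node with probability
proportional to `w + ε`, where `w` is the edge's measured `|%CFC|` (or an
imputed value, below; 0 if neither) and `ε = 1` percent-point keeps
unmeasured edges reachable. Termination:

1. no untraversed outgoing edge at the current node (**sink**);
2. the last traversed phosphorylation is inhibitory (**inhibition**) — an
   inhibited substrate does not propagate the cascade;
3. a hard cap of 25 edges (**max_length**), relevant only on cyclic input;
   walks are self-avoiding on edges, so on acyclic networks every walk
   terminates by rules 1–2.

**Single-path imputation.** When a node has exactly one downstream option
and that edge carries no measurement, a percent fold change is imputed for
the single path: drawn uniformly in [0, 20] for an experimental dataset
(seeded; `impute_mode: fixed` substitutes the midpoint 10), exactly 20 for
a control dataset. Draws are made once per run per edge and flagged as
imputed in every output. Since imputation only ever applies where the walk
has no choice, it never changes transition probabilities — only the
recorded per-edge CFC used by the selection rules.

On acyclic networks the sampler runs all walks in lock-step with vectorised
per-node multinomial draws; on cyclic networks it falls back to a per-walk
loop with an explicit traversed-edge set. `enumerate_chains` computes the
exact distribution of the same process by exhaustive DFS and serves as the
sampler's independent oracle in the tests.

## Null model and enrichment

"Chains occurring more or less frequently than expected" requires a null
for *expected*. The package defines it as a placement permutation on the
full measurement-attached network: the multiset of measured signed CFC
values is reassigned to a uniformly random subset of all edges, the
up/down split and single-path imputation are recomputed, and the walks
rerun. This preserves the network topology and the measured value
distribution while destroying the association between values and edges, so
a chain's expected frequency means "how often would this chain be walked if
the measurements had landed anywhere". A permutation confined to the
originally-measured edge positions would be degenerate precisely in the
cases of interest — when the measured edges are few and concentrated on a
real cascade, permuting among them reproduces the observed walk and every
enrichment collapses to 1 — so the placement null is used instead.

Expected frequency is the mean over `n_permutations` reruns of `n_walks`
walks; chains never seen under the null receive the pseudo-floor
`1/(n_walks · n_permutations)`. Enrichment = observed/expected; chains with
enrichment ≥ 1.5 or ≤ 0.67 (both tails; reciprocal symmetry) pass the gate.
Defaults `n_walks = 2000`, `n_permutations = 50` make the permutation mean
stable to well under the gate width at the network sizes the package
targets (hundreds of edges) while keeping a 50-scenario benchmark suite in
minutes on one core; both are configurable.

## Chain post-processing

1. **Trailing trim.** A complete walk routinely overshoots the measured
   part of a cascade into unmeasured (~0% change) territory. Trailing
   edges whose effective `|CFC|` (measured or imputed; unmeasured counts
   as 0) does not exceed the CFC bound are trimmed before filtering; an
   *interior* failing edge still rejects the chain (the cascade is broken,
   not merely overshot).
2. **Parallel resolution.** When two or more chains deliver the same
   (substrate, site) via different immediate kinases, only chains whose
   delivering edge has the greatest magnitude keep that event; exact ties
   keep all (dropping one would be arbitrary), with deterministic ordering.
   Different sites on one substrate never compete.
3. **Selection.** A chain is kept when it has strictly more than 2
   intermediates (internal nodes between root and terminus) and every edge
   exceeds 5% CFC (`cfc_mode="mean"` switches to an aggregate-mean test).
   Output is deduplicated and sorted by score (minimum edge |CFC|)
   descending.

A **hit** (lead) is a measured phosphosite appearing in at least one
selected chain of a direction; the lead table reports it with its
direction, CFC and chain membership count.

## Pathway map

Selected chains of both directions merge into one comparative map: edge
union keyed by (kinase, substrate, site); an edge claimed by both
directions keeps the version with the greater |log2fc| (the same magnitude
precedence as parallel resolution). Styling is deterministic: arrow width
interpolates |log2fc| linearly into a configurable range (default 0.5–4.0
drawing units) and color classes encode direction. Exports: GraphML and
JSON (lossless round trip) and a minimal DOT serialisation for external
layout engines; no fixed visual layout is attempted.

## Synthetic benchmark

Because no raw probe-level dataset is publicly deposited for this setting,
end-to-end validation uses a generator that emulates the *structure* of an
array experiment:

- **Network**: a random DAG over synthetic symbols (default 100 nodes,
  mean out-degree 2, inhibitory fraction 0.1) with random per-edge sites.
- **Planted cascades**: root-anchored activation paths (default one
  6-edge "up" cascade) whose sites carry a known signed effect (default
  +30% CFC). Only activation edges are eligible — an interior inhibitory
  edge would terminate every walk mid-cascade by rule 2, making the plant
  unrecoverable by construction. A few percent of random networks contain
  no admissible path; the scenario builder then regenerates the network
  from a derived seed, since a scenario's planted paths must be valid
  chains of its own network.
- **Signals**: per-probe lognormal baselines (geometric sd 1.5 around
  3,000 units) span a realistic dynamic range and leave a small tail below
  the low-signal cutoff so that filter is exercised; planted-site baselines
  are kept at or above the nominal baseline, because a planted effect is by
  definition a quantifiable event. Treated = control × (1 + CFC/100), with
  multiplicative Gaussian noise (default sd 5%) on both channels.
- **Errors**: the reported error is modelled as the antibody's technical
  variability — one half-normal draw per probe per replicate (sd = 10% of
  the probe baseline, the default stand-in for unknown real magnitudes),
  reported identically for the two channels of a paired comparison. This
  mirrors per-antibody error-range reporting; channel-independent error
  draws would make the total-error filter a fair coin on every probe,
  which no meaningful quality rule can be.
- **Replicates**: 3 arrays per condition, the standard minimal replication
  in this field; the error filters are defined over totals across arrays.

`recovery_metrics` scores a run against the plant: edge precision/recall
over the union of selected chain edges, and site hit recall over planted
sites appearing as measured hits.

What passing these benchmarks shows: the filters, mapping, walk, null,
and selection rules interlock correctly, recover a known cascade through
realistic noise without hallucinating chains from pure noise, and are
exactly reproducible. What it does not show: performance on real arrays,
whose error structure, antibody cross-reactivity, and prior-network
incompleteness the generator deliberately does not model.

## Numerical and degenerate-input choices

- All randomness flows from one integer seed through stable SHA-256-derived
  stage seeds (each < 2^31), so stages are individually reproducible and
  outputs are byte-identical across reruns.
- Walks on a rootless network (e.g. a pure cycle) raise a rootless-network
  error at walk time; root *finding* on such a network simply returns the
  empty set. A null permutation draw that admits no walks contributes zero
  counts rather than failing the run.
- An empty direction subnetwork yields zero chains and zero hits.
- Ties in parallel resolution and map merging are kept and ordered
  deterministically; selection bounds are strict inequalities.
- The bundled two-arm demonstration network runs with the enrichment gate
  and the intermediate bound disabled (`fixtures.demo_config()`): its arms
  are only 2–3 edges long and a permutation null over ~17 edges carries no
  information, so the demo exercises direction recovery, termination and
  parallel resolution rather than enrichment statistics. Sites the curation
  could not source from literature (IRS1 S636, ESR1 S118, the CDK7→CDK1
  T161 upstream assignment) are synthetic placeholders and marked as such
  in the data file.

## Known limitations

- The transition rule (`∝ |CFC| + ε`) and the placement null are explicit
  formalisations of a procedure whose published description specifies
  neither; both are isolated behind configuration and documented here.
- The 0–20% single-path imputation injects sub-threshold-to-threshold
  weight into unmeasured linear stretches; selected chains always flag
  which edges were imputed, but downstream consumers should treat
  imputed-heavy chains with care.
- Hits are defined at chain-membership granularity; alternative hit
  definitions (filtered probes, network nodes) would give different counts
  on the same data.
- Real kinase–substrate priors are user-supplied; the package bundles only
  the small demonstration curation.
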