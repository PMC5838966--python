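# Methods

## Model

`phosphopetri` implements a discrete, token-based Petri net specialised
for phosphorylation signalling. Proteins are places; the token count of a
place is an integer phosphate load. Typed transitions connect an enzyme
place to a substrate place: phosphorylation transitions (from kinases) add
one token to the substrate per firing, de-phosphorylation transitions
(from phosphatases) remove one, clamped at zero because a substrate cannot
hold negative phosphate. Firing never alters the enzyme's own tokens — an
enzyme catalyses without consuming itself.

Enabling couples the enzyme's token count to its *activation condition*.
Most kinases and phosphatases are activated by being phosphorylated, so
their transitions are enabled when their tokens strictly exceed the
enabling threshold τ. A small minority are activated without
phosphorylation (phosphorylation inhibits them); their transitions are
enabled when their tokens are strictly *below* τ. Counts exactly at τ
enable nothing under either regime — the inequalities are taken literally.

Execution is organised in blocks. Per block: draw a fresh random
permutation of the full transition list; for each transition in that
order, re-impose the state perturbation, skip the transition if its enzyme
is inhibited, check enabling, and fire if enabled; after the pass,
re-impose the perturbation once more and degrade every place by the
degradation rate, rounding down. A single simulation initialises every
place with an independent uniform integer on [0, init_max] and runs a
fixed number of blocks. The *phosphorylation status* of a state is the
per-place mean of the final-block markings over `iterations` independently
seeded simulations.

### Perturbation semantics

- **Reference**: no perturbation.
- **Stimulated (atrophic)**: the stimulus molecule is typically absent
  from the network (e.g. a circulating ligand), so its direct-target
  places are clamped to high activity — `2τ` tokens — before every
  transition check.
- **Gene-inhibited**: layered on the stimulated state; the inhibited place
  is pinned to zero tokens *and* every transition it catalyses is
  suppressed. The explicit suppression matters: zero tokens would
  otherwise count as *active* for a without-phosphorylation enzyme, which
  cannot be the meaning of "zero activity". This dual clamp+suppress rule
  is one reading of an underdetermined convention and is flagged as a
  design choice, not the only possible semantics.

The perturbation is also re-applied once at the end of the block, before
degradation, so the *recorded* marking of each block honours the state: an
inhibited place reads exactly zero in every block even if a late
transition in the pass phosphorylated it.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `threshold` (τ) | 35 | enabling threshold, in tokens |
| `blocks` | 100 | shuffled-list passes per simulation; saturation horizon |
| `degradation_rate` | 0.10 | fraction of tokens removed per place per block |
| `iterations` | 10 | simulations averaged into a status |
| `init_max` | 2τ = 70 | inclusive upper bound of the random initial marking |
| `replicates` | 3 | independent inhibited-state screens per candidate |
| `min_recovered` | 4 | markers (of 5) that every replicate must recover |

The defaults are the standard operating point for this model family; the
threshold value is itself selectable by the robustness scan (below).
Degradation uses `floor((1 − rate)·n)`, which keeps counts integral and
strictly decreases every positive count, so an unfed place always reaches
zero — "reducing 10 %" must terminate absent any firing.

A useful consequence of floor degradation: a place receiving a constant
gain of g tokens per block has absorbing fixed points exactly on the band
[9g − 9, 9g] (for rate 0.10). A place fed by a single active enzyme
therefore saturates at ≤ 9 tokens, far below τ = 35; crossing the
threshold requires either the stimulus clamp or a confluence of ≥ 5
simultaneously active upstream enzymes. This is the quantitative reason
several design choices below look the way they do.

## Screening and statistics

**Direction calls.** Only directions of change are compared, never
magnitudes. The change from status a to status b is `up`/`down` by strict
sign; an exact zero difference is `none`. A configurable epsilon band
(default 0) can widen the `none` zone; with statuses that are means of 10
integers, exact ties are uncommon but possible, and a tie is evidence of
nothing. A marker is *recovered* when the reference→diseased and
diseased→inhibited directions are both non-none and opposite; a candidate
is *selected* when every replicate recovers at least `min_recovered`
markers. Replicate seeds derive from the master seed and the candidate's
identifier (CRC-32 chain), so candidate order and count cannot change any
result.

**Candidate population.** An enzyme is a candidate when a directed
enzyme→substrate path links it to at least one panel marker ("linked" is
read as directed reachability; an undirected mode is provided, since the
convention is genuinely ambiguous).

**Threshold robustness scan.** For each candidate τ (grid
1, 5, 10, …, 50), `iterations` simulations per state (reference and
stimulated) are run; each run's places are ranked by final-block marking;
all pairwise Spearman ρ (average-rank ties; 10 runs → 45 pairs) are
averaged per state, and the two state scores are averaged for selection,
ties to the smallest τ. How the two states' scores should combine is not
fixed by convention; the plain mean is used and per-state scores are
always reported alongside. Spearman ρ comes from `scipy.stats.spearmanr`;
a constant ranking (no ordering information) yields NaN rather than a
fabricated score.

**Overlap test.** The hypergeometric upper tail P(X ≥ k) is computed by
exact summation of the probability mass in arbitrary-precision integer
arithmetic (`math.comb`); the only rounding is the final division. At the
population sizes involved (hundreds) this is fast and strictly more
accurate than log-gamma or normal approximations. The test suite checks it
independently against `scipy.stats.hypergeom` and against brute-force
enumeration of all draws for small populations.

**Proximity baseline.** Average unweighted shortest-path length from a
gene to the panel (breadth-first, via networkx), undirected by default as
is usual for proximity baselines, with a directed mode. Markers
unreachable from the gene are excluded from the average (and counted); if
none is reachable the result is NaN and the gene is never selected by the
top-k cut. Top-k selection expands to the entire tie class at the cutoff
length, so a requested k may return more than k genes.

## Synthetic data

The generator emulates the *structure* of a curated phosphorylation
network: kinases emit only phosphorylation edges, phosphatases only
de-phosphorylation edges, most nodes are substrate-only, and a small
fraction of enzymes (default 25/526 ≈ 4.8 %, matching the observed
minority in curated human networks) is activated without phosphorylation.
Edge endpoints are drawn uniformly at random — no degree heterogeneity —
because no degree distribution is canonical here and uniform wiring keeps
the planted-scenario guarantees provable. A virtual stimulus has a set of
direct-target kinases, and every panel marker is guaranteed reachable from
the stimulus (asserted at generation time).

With `plant_relay=True` the scenario contains a known ground truth: a
relay kinase R that is one of the stimulus's direct targets and the *only*
conduit from stimulus to markers — the remaining direct targets feed only
R, and the markers receive edges only from R, with the random background
quarantined from the planted machinery. Under the default dynamics every
marker is then exactly zero in the reference state (unfed places decay to
zero within ~70 blocks), saturates near the gain-1 band (≤ 9 tokens) in
the stimulated state, and collapses back to zero when R is inhibited — so
the screen must select R, and inhibiting anything off the stimulus→marker
paths leaves marker statuses changed only by seed noise.

All planted markers are *up* markers. This is forced by the dynamics, not
a convenience: by the fixed-point-band argument above, a graph-exclusive
single relay can never push a downstream enzyme across τ, so a
"down"-marker mechanism routed through a relay-activated phosphatase would
be dynamically inert and the marker's first-leg direction would be `none`.
The panel directions recorded in the scenario are derived from the wiring
that is actually effective, never asserted blindly.

What the generator does **not** emulate: hub-dominated degree
distributions, feedback loops curated from real pathways, realistic
enzyme/substrate ratios at scale, or biological noise models. Passing the
planted-relay recovery test therefore demonstrates that the screen's
machinery (simulation, direction calls, replicate rule, seeding) is
correct, not that the method's biological error rates on a real curated
network are characterised.

## Numerical and reproducibility choices

- Token counts are plain Python integers; degradation is the only
  non-integer operation and floors immediately.
- All randomness flows from one master seed through a CRC-32 chain over
  labelled derivation paths (`("iteration", i)`, `("inhibit", gene, r)`,
  `("scan", τ, state, i)`, …), masked to 31 bits. CRC-32 is
  platform-stable, unlike Python's salted `hash`. Iteration sub-seeds do
  not depend on the iteration count, so extending a campaign preserves the
  prefix.
- `simulate_state` is bit-reproducible: identical inputs give identical
  floats.
- Conflicting edge pairs (same ordered pair annotated with both types) are
  dropped wholesale unless an explicit resolution table names the type to
  keep; counts are logged. Orphan nodes are removed after tissue
  filtering.
- An enzyme with both qualifying and non-qualifying upstream annotations
  is classified `without_phosphorylation` — the rule is an evidence-based
  override of the default assumption.
- Identifiers are opaque strings; no identifier-namespace validation is
  performed.

## Known limitations

- The unit-firing/threshold dynamics make single-edge influence saturate
  at 9 tokens (see the band argument), so sparse synthetic networks
  exhibit threshold crossings only at stimulus targets or high-confluence
  nodes; real curated networks, with much higher in-degrees, behave more
  gradually.
- The selection rule is binary and can reject genes that recover markers
  in most but not all replicates — near-miss triples such as (4, 5, 3)
  are rejected by construction, a known conservatism of the
  all-replicates criterion.
- The proximity baseline treats all edges equally; no weighting by
  interaction type or confidence.
- Simulations are sequential and pure Python; the intended scale is
  desk-sized networks (tens to a few thousand transitions), not
  proteome-scale screens.
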