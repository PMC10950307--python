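# Methods

## The model

A pyramidal cell (PC) is reduced to a binary-output unit with two input
routes. Its **basal dendritic tree** is a collection of synaptic clusters:
each cluster is a set of `C` distinct presynaptic sources with a
non-negative weight, abstracting a group of co-located basal synapses whose
coincident activation fires a local NMDA spike. Its **apical route** is a
"guess" selection input: during training, exactly one minicolumn per
episode is fired apically, standing in for the dendritic Ca²⁺ spike / burst
firing that accompanies top-down selection. No membrane potentials, spike
times, or Ca²⁺ dynamics are simulated; cells, inputs, and rewards operate
in an on/off regime.

**Plasticity.** After each episode, every cluster of a fired cell whose
active-source count reaches the threshold `G` (default `G = C`, i.e. all
synapses active) is updated by the reward-gated rule:

- *positive or insignificant reward*: weight ← weight + `increment` (default
  1, scaled linearly by the reward magnitude when it exceeds 1);
- *negative reward*: weight ← 0 (default, "enhancement removed if present"),
  or weight ← max(0, weight − `decrement_step` · magnitude) in the graded
  decrement mode.

Non-fired cells never change. The behavioural-timescale eligibility window
of the underlying biology collapses to same-episode coincidence because a
pattern is static within an episode. Weights are therefore non-negative
always, and under a positive-only schedule the final weights of one epoch
are independent of presentation order (each update is an independent
increment gated only by the pattern–cell pair). Homeostatic weight
renormalisation is not implemented; weights stay bounded in one-epoch
experiments.

An insignificant (zero-magnitude) reward strengthens by one full increment,
exactly like a unit positive reward: the rule groups "positive or
insignificant" on one branch, and scaling strictly by magnitude would
abolish zero-reward learning. How much *weaker* an insignificant reward
ought to be is genuinely open; we chose equality, the reading under which
the rule has no free parameter.

**Readout.** At test time each pattern is presented once, read-only. Every
minicolumn's L5 sums the weights of its fully active clusters; the
minicolumn with the largest sum fires (winner-take-all), ties broken
uniformly at random. In the internal-representation configuration the L2/3
learners run a second, independent competition, and a pattern is
*simultaneously correct* when both layer winners equal the assigned
minicolumn. Whether the original L2/3 test competed across minicolumns or
was thresholded per cell is not documented; we implement the competition
reading, the minimal symmetric extension of the explicit L5 rule.

## Network configurations

Ten minicolumns, each owning one L5 learner with `floor(S_max / C)`
clusters (`S_max` = 20,000 basal synapses).

- **Hierarchical**: two prewired L2/3 detector cells per minicolumn respond
  to the presence of an `XXXXX` (any 5 adjacent active inputs) or `XXOXX`
  (two active pairs separated by one inactive input) motif anywhere in the
  raw pattern. Their outputs join the L5 sampling space with `F` slots each
  (externals have 1), so a single synapse draw lands on a detector with
  probability `2F / (I + 2F)`; `F = 0` reproduces "no L2/3→L5
  connectivity". Detector responses are pure functions of the pattern —
  their own acquisition is taken as given and not simulated.
- **Internal representation**: one plastic L2/3 learner per minicolumn,
  built exactly like the L5 (same `S_max`, same `C`, no detector sources),
  not connected to it basally. Apical cross-induction within the dendritic
  bundle makes it fire, and therefore learn, in exactly the episodes its
  L5 fires.

**Cluster sampling.** "Sampling-space size" is realised as categorical
sampling with slot counts (1 per external input, `F` per detector; `F` may
be non-integer, in which case slots become weights). Duplicates within a
cluster are rejected and redrawn, which is weighted sampling without
replacement; we vectorise it with exponential sorting keys
(key = Exp(1)/weight, keep the `C` smallest — the Efraimidis–Spirakis
scheme, distributionally identical to successive draws with rejection).
Clusters own disjoint physical synapses (so `C × n_clusters ≤ S_max`), but
identical source compositions may recur across clusters.

## Synthetic input patterns

Patterns live on a 1-D line of `I = 100` external inputs and are unions of
5-wide objects (`XXXXX` activates all five positions; `XXOXX` leaves the
middle inactive). Objects may neither overlap nor touch — at least one
inactive input between footprints — and do not wrap around the ends.
Placement sets are sampled *exactly* uniformly over all valid
configurations via a stars-and-bars bijection with combinations (no
rejection sampling, hence no pathological rejection rates at high
density). Distinctness of the 100 activity vectors is enforced by bounded
redraw (collisions are vanishingly rare at `I = 100` but the loop must
terminate).

The hierarchical experiment uses 50 random `XXXXX` patterns plus 50
location-matched `XXOXX` twins that copy the exact object start positions —
"same object locations" is read as exact start copying, so twin vectors
differ exactly at the objects' middle positions. Twins are assigned to
different minicolumns under a balanced 10-patterns-per-minicolumn
assignment (uniform shuffle, redrawn while any twin pair collides).

One boundary subtlety: two `XXXXX` objects at the minimum spacing of one
inactive input create a `1,1,0,1,1` window at the junction, so the `XXOXX`
detector — which sees raw activity, not placements — responds to such
patterns. This is a property of the stated detector definitions, not a
bug; the tests pin it down explicitly.

The object count per hierarchical pattern is not fixed by the source
experiments; the default is 5 (25% active density for `XXXXX`), consistent
with the observation that cluster sizes ≥ 4 need input density above
roughly 20% to work well, and it is exposed as a configuration knob.

## What the generator emulates — and what it does not

Random placement of rigid, identical motifs on a line emulates the *sparse
combinatorial structure* of feedforward input, not real receptive fields:
real inputs have correlated, graded, possibly topographic statistics, and
real synapse placement may itself be correlated with input statistics.
Passing results therefore show that the learning rule and readout work
under the stated idealised conditions; they do not calibrate performance on
biological data.

## Experiments and their scales

- *Hierarchical F sweep*: default grid `0, 1, 2, 5, 10, 20, 50, 100`
  (the original x-axis values are not printed anywhere; the grid spans "no
  connectivity" to detector-dominated sampling), 50 runs per cell. Run `r`
  of every `F` cell reuses the same pattern-set stream, so `F` comparisons
  are paired; the direction claim (accuracy improves with `F`) is tested as
  a paired sign test between `F = 10` and `F = 0`.
- *Internal-representation object sweep*: default grid 1–8 objects, 10 runs
  per cell; the headline quantity is the mean simultaneous accuracy at
  `C = 4`, 5 objects (≥ 98%).
- *Concept-extraction demo*: a 4-input cell with all six 2-synapse clusters
  and binary enhancement replays a trial-and-error sequence; the canonical
  3-step sequence (`{2,3,4}+`, `{2,4}−`, `{3,4}−`) leaves exactly the pair
  `{2,3}` enhanced — the extracted abstract concept.
- *Addressing capacity*: `C(I, G)` as an exact arbitrary-precision integer —
  the number of cells individually selectable when each cell's tuft cluster
  is a distinct `G`-subset of `I` selection inputs. The count is purely
  combinatorial; crosstalk between overlapping clusters is deliberately not
  modelled.

## Numerical and reproducibility choices

- Weights are stored as float64 arrays for vectorised updates, but every
  default increment is an integer, so all arithmetic (and every tie
  comparison in the readout) is exact.
- All randomness flows from one master seed through a documented ladder:
  `SeedSequence(master, crc32(label)…)` with separate purpose labels for
  trees, patterns, and tie-breaks per (configuration cell, run). Tie-break
  draws consume their stream only on actual ties, in fixed order (pattern
  order, L5 before L2/3). A full sweep is bit-reproducible from
  `(master seed, config)`.
- Degenerate inputs fail loudly: infeasible object packings, cluster sizes
  exceeding the source pool, unknown source codes, and empty score lists
  raise instead of truncating.
- Test scale: the unit suite runs scaled-down trees (a few hundred
  synapses) since every property holds at any scale; the end-to-end checks
  run the full 20,000-synapse, 100-pattern experiments (sub-second per run
  with vectorised scoring).

## Known limitations

- Binary activity and rewards; no graded firing, inhibition, or attention
  dynamics — these are modelled only through their abstract consequences
  (apical selection, WTA readout).
- The prewired detectors' own learning history is not simulated.
- One training epoch per experiment; long-horizon weight dynamics (and any
  homeostatic regulation they would need) are out of scope.
- The capacity count assumes one NMDA spike suffices to select a cell and
  ignores cluster overlap.
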