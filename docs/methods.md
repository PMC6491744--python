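# Methods

## Model overview and assumptions

The package simulates a discrete-time, two-layer network. Each timestep
processes one (movement, feature) pair through four stages: (1) movement
path-integrates every activity bump in every location module; (2) the updated
location activity drives dendritic predictions in the sensory layer; (3) the
sensed feature activates its mini-columns, gated by those predictions; (4)
the sensory activity recalls location cells and each module's bump set is
replaced by bumps centered on the recalled cells. No recurrent settling is
simulated after stage 4; the network simply advances to the next timestep.
Neurons are binary, synapses are binary and only ever grow (bitwise OR), and
each cell carries any number of independent dendritic segments that act as
sparse-pattern detectors.

Grid modules are treated as black boxes with known properties: each module
maintains an explicit list of bump phases on the unit rhombus rather than
simulating attractor dynamics. This is deliberate — the model requires
modules to carry *unions* of bumps, which standard continuous-attractor
implementations collapse. Heading retrieval and orientation are not modeled:
movements arrive already expressed in the object's reference frame, so
objects are only recognized at their learned orientation. Location codes are
2D; 3D objects are out of scope.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n` (modules) | 10 | number of grid modules; orientations evenly spaced at i·60/n degrees, all scales equal |
| `w` (cells per axis) | 10 | each module has w² cells at the centers of a w×w partition of the phase square |
| `scale` | 1.5 length units | lattice period; by default half the object width (4×4 unit-spaced grid spans 3 units) |
| `σ` (bump width) | 0.18172·6/w | Gaussian bump width in phase units; the w=6 value mimics rat entorhinal module sparsity |
| `δφ` (readout resolution) | (1/3)·6/w | diameter of the phase range one bump's active set encodes |
| mini-columns × cells | 150 × 16 | sensory layer size |
| feature sparsity | 10 columns | fixed random 10-of-150 code per feature |
| `θ^loc` | 8 | location-segment threshold, against the 10-cell sensory learning code |
| `θ^in` | ⌈0.8·n⌉ | sensory-segment threshold, against the n-cell location winner code |
| pass limit | 4 | an episode fails if no convergence after 4 complete passes over the object |

σ and δφ shrink together as w grows so that a bump stays a fixed size
relative to the cells: a single bump always activates 4–7 cells regardless of
module size, and adding cells only adds cells the bump does *not* activate.

## Numerical choices

- **Readout threshold.** A cell is active when its scalar activation reaches
  `Gaussian((δφ/2)·(2/√3))`. The factor 2/√3 ≈ 1.1547 is the hexagonal
  covering/packing radius ratio: it expands the readout discs so that discs
  packed hexagonally overlap and leave no uncovered phase. A dense sweep
  confirms every bump position activates ≥ 4 cells (coverage with margin)
  and ≤ 7. Shrinking the discs instead (a factor < 1) produces single-cell
  minima and readout gaps, contradicting both stated bounds, which is why the
  expanding factor is used.
- **Rhombus metric.** Distances between phases are computed in the physical
  60°-sheared basis, minimized over the 3×3 grid of integer wrap offsets.
  A property test confirms a 5×5 offset search never finds shorter distances.
- **Winner cells and learning resolution.** During learning only the single
  most-active cell per module (ties break to the lowest index, for
  determinism) is associated with the feature. The learning resolution (one
  cell, spacing 1/w) is therefore twice as fine as the readout resolution
  (δφ = 2/w), which bounds the quantization drift introduced when a sensed
  feature re-anchors a bump on a cell center.
- **Bump deduplication.** Sense-driven resets can center bumps on adjacent
  cells recalling the same location; bumps closer than δφ/4 on the rhombus
  are merged (first kept) so union sizes are not inflated. At the default
  scaling δφ/4 = 1/(2w) is below the cell spacing, so distinct recalled
  cells are never merged.
- **Segment growth.** A learning cell extends an existing segment when that
  segment already overlaps the presynaptic active set at threshold, and grows
  a new segment otherwise; distinct contexts therefore land on distinct
  segments, and re-learning a known (feature, location) pair is a no-op.
  Segments per cell are uncapped: at these workloads the capacity limit comes
  from union density, not segment exhaustion.
- **Phases** are double precision; mod-1 arithmetic is clamped so phases
  always lie in [0, 1).

## Training, recognition, and failure criteria

Training visits each point of each object exactly once. A new object starts
with one uniform-random phase per module (its private location space; origins
are stored so retraining is idempotent). At each point, reciprocal
OR-connections form between the n location winner cells and one learning cell
per active column (the predicted cells if any, else one uniformly random cell
per column), and the winner-cell code is stored in a classifier keyed by
(object, point).

Inference starts stateless and traverses the points in fresh random order
each pass, with movements equal to coordinate differences of consecutive
points (continuing across pass boundaries). After each sensation, if every
module holds exactly one bump, the winner-cell code is compared with the
stored code for the current point of the true object: a match unique to the
object counts as *recognized*; a match shared with other objects is
*converged-nonunique* (the location is real but not object-specific, as with
a single module); a mismatch is *wrong-location*. Four complete passes
without convergence is *no-convergence*. On ensembles with the study's
statistics only recognized / no-convergence occur; the other two outcomes are
tracked and asserted against.

## What the synthetic generator emulates — and what it does not

Objects are 10 distinct points on a 4×4 unit grid with features drawn with
replacement from a fixed pool (uniform by default), so features repeat within
and across objects and objects can share entire feature multisets. Feature →
mini-column codes are fixed random 10-of-150 draws, stable across train and
test. Two skewed samplers ("zipf": p ∝ 1/rank, and "two_tier": a fifth of the
pool carries 80% of the mass) are representative stand-ins for alternate
feature statistics — they are not fitted to any empirical distribution. The
generator does not model sensory noise, feature extraction, partial
observability, movement error, or object orientation; passing tests therefore
demonstrate the localization-and-association machinery under clean,
object-frame input, not robustness of a perception pipeline on real data.

## Experiment harness and problem sizes

All experiments are deterministic functions of (config, seed); every random
draw descends from the seed. The activation-density metric is the fraction of
active location-layer cells after stage 4, averaged over modules. Capacity is
found by doubling then bisection on the object count, with the ≥90% accuracy
threshold inclusive, and is reported as 5th/50th/95th percentiles over
object-set seeds.

The shipped defaults are desk-scale choices: ≤10×10 to 30×30 cells per
module, tens to ~130 objects, single-seed 3-point sweeps for the monotone
trends (capacity vs. cells at w ∈ {6, 8, 10} with pool 30; capacity vs. pool
at {15, 30, 60} with w = 10; the cells/pool compensation check at 10×10/pool
30 vs. 14×14/pool 15; union-size analysis at 80 objects, pool 30, zipf
features, which straddles this model size's breaking point near k ≈ 10–16).
Larger, figure-scale sweeps run through the same entry points by raising the
config values. The ideal-observer-equivalence check uses 25 objects from a
10-feature pool with 30×30 cells per module, where the network's
sensations-to-recognition match the exhaustive localizer episode-for-episode.

## Known limitations

- Union semantics make recognition sensitive to δφ/σ miscalibration: wider
  bumps raise interstitial activations and can cause spurious cell recruitment
  near capacity. The defaults keep the single-bump readout in the verified
  4–7 cell band at every supported w.
- Capacity's linear laws in cells and pool size carry a small-module offset;
  compensation between the two holds in the linear regime (≥ ~100 cells per
  module) and degrades for very small modules.
- The classifier-based recognition criterion requires exact winner-code
  equality; it does not award partial credit for near-miss codes, matching
  the strict convergence definition used throughout.
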