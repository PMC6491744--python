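# gridcolumn

A two-layer neural network model of sensorimotor object recognition built on
cortical grid-cell modules, for computational neuroscientists studying how a
single patch of cortex could learn and recognize objects from sequences of
sensations and movements.

## The model

A *location layer* of `n` grid-cell-like modules represents where a sensor is
in the reference frame of an object. Each module `i` has `w × w` cells on a
unit phase rhombus (basis vectors 60° apart) and maintains an explicit set of
activity-bump phases Φᵗᵢ. A movement `d` of the sensor shifts every bump
through the module's transform

    Mᵢ = [sᵢ·(cos θᵢ, sin θᵢ) ; sᵢ·(cos(θᵢ+60°), sin(θᵢ+60°))]⁻¹,
    φ ← (φ + Mᵢ·d) mod 1,

so path integration is exact and order-independent. A Gaussian readout
(width σ) turns bumps into scalar cell activations; multiple bumps combine as
a probabilistic OR, `a_c = 1 − Π_b (1 − a_{c,b})`, and cells above a threshold
set by the readout resolution δφ form the module's binary output. Several
simultaneous bumps per module — a *union* — encode a set of candidate
locations under ambiguity.

A *sensory layer* of mini-columns (150 columns × 16 cells at baseline)
receives a sparse 10-column code per sensed feature. Location input arrives on
modulatory dendritic segments with binary synapses: predicted cells in a
sensed column fire and inhibit their neighbors; a sensed column with no
prediction bursts, encoding feature-at-unknown-location. The sensory activity
in turn drives dendritic segments of location cells, re-anchoring each
module's bumps on the recalled cells. Learning simply forms reciprocal
OR-connections between the per-module winner cells and one learning cell per
active column.

Recognition works like Markov localization: the first feature invokes the
union of all its learned locations, movement path-integrates the union, and
each further sensation prunes inconsistent candidates until one bump per
module remains. The package also implements the two reference detectors the
model is judged against — an exhaustive candidate-tracking **ideal observer**
and a **bag-of-features** detector — plus experiment harnesses for
convergence curves, object capacity (max objects at ≥90% recognition), and
the union-size statistic *k* (occurrence count of an object's rarest
feature), with synthetic objects drawn as 10 feature-bearing points on a 4×4
grid.

## Worked example

```python
import numpy as np
from gridcolumn import *

rng = np.random.default_rng(0)
objects = generate_objects(10, pool_size=40, rng=rng)   # 10 objects, 4x4 grid
encoding = make_feature_encoding(40, rng=rng)           # 10-of-150 column codes
net = Network(NetworkConfig.default(), encoding)        # 10 modules, 10x10 cells
net.train(objects, rng)

for obj in objects[:3]:
    out = net.infer(obj, rng, record_density=True)
    print(f"object {obj.id}: {out.status.value} after "
          f"{out.sensations_to_recognition} sensations; "
          f"densities {[round(d, 3) for d in out.densities]}")
```

prints

```
object 0: recognized after 2 sensations; densities [0.264, 0.07]
object 1: recognized after 2 sensations; densities [0.196, 0.07]
object 2: recognized after 1 sensations; densities [0.07]
```

The first sensation activates a dense union (26% of location cells for object
0 — every learned location of that feature); the second sensation prunes it to
a single location per module (7 of 100 cells ≈ one bump), the stored code is
unique to the object, and recognition is declared. Objects whose first sensed
feature is globally unique are recognized immediately.

The same functionality is available from the shell:

```
gridcolumn generate --seed 1 --out objects.json
gridcolumn infer --seed 0 --object 0
gridcolumn convergence --seed 0 --out results/convergence
gridcolumn capacity --param pool_size --values 15,30,60 --seed 0 --out results/cap
gridcolumn unionsize --seed 0 --out results/union.csv
gridcolumn selftest
```

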