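# molfm

Multi-modal flow matching for all-atom 3D *de novo* small-molecule
generation, with a quality-metric suite for generated molecules.

## The problem

A 3D molecular generative model must jointly sample four coupled data
types: atom coordinates **X** ∈ ℝ^(N×3), atom types **A**, formal charges
**C**, and a bond order for every atom pair **E** — and the result must be a
chemically valid, geometrically sensible molecule. `molfm` implements this
as a single denoiser trained under two flow-matching regimes at once:

* **coordinates** follow continuous flow matching on the straight-line
  interpolant `x_t = (1−t)x₀ + t·x₁`, with an equivariant-optimal-transport
  style coupling (Kabsch alignment + optimal assignment) between the
  Gaussian prior and the conformer, endpoint parameterization (the network
  predicts X̂₁, the field is `(X̂₁ − x)/(1−t)`), and the clamped loss
  weighting `w(t) = min((1−t)⁻², 100)`;
* **atom types, charges, bonds** follow masking discrete flow matching:
  every token starts as a MASK state and is unmasked by a continuous-time
  Markov chain whose per-step kernel is `Δt·(1+ηt)/(1−t)·p̂(j)` for masked
  tokens and remask rate `ηΔt` otherwise, trained with cross-entropy on
  masked tokens.

The denoiser is an SE(3)-equivariant graph network built from geometric
vector perceptrons extended with cross-product channels, so mirror-image
inputs (stereoisomers) get different outputs. Three train-time
self-correction features — self-conditioning, fake atoms, and geometry
distortion — teach the model to detect and repair its own sampling drift;
all three are single-switch configurable.

The metric suite runs on molecules alone (no model needed): RDKit
sanitization validity, functional-group deviation
`Σ_f |ω_f^ref − ω_f^gen|` over an alert-group SMARTS set, the
out-of-distribution ring-system rate against a reference ring catalog,
optional PoseBusters/GFN2-xTB wrappers, subset-based confidence intervals,
and a linear additive-effects analysis of denoiser-endpoint movement.

## Worked example

Train on the bundled synthetic fixture set (small H/C/N/O/F molecules,
generated by seeded distance geometry — no downloads), sample, and evaluate:

```python
import numpy as np
from molfm import (TrainConfig, SamplerConfig, AugmentConfig, fit,
                   sample_molecules, dataset_stats, validity_rate)
from molfm.network import NetworkConfig
from molfm.toydata import ToyDatasetConfig, TRAIN_CATALOG, generate_fixtures

fx = generate_fixtures(ToyDatasetConfig(smiles_catalog=TRAIN_CATALOG, seed=0))
cfg = TrainConfig(batch_size=10, learning_rate=2e-3, n_steps=8000, seed=0,
                  min_lr_factor=0.02, network=NetworkConfig.toy())
model, log = fit(fx.graphs, cfg, fx.vocab)
print(f"loss {log[0]['loss']:.2f} -> {log[-1]['loss']:.2f}")

mols, _ = sample_molecules(model, 200, dataset_stats(fx.graphs, fx.vocab),
                           SamplerConfig(n_steps=250, seed=1, eta=1.5),
                           AugmentConfig())
pct, _ = validity_rate(mols, fx.vocab)
print(f"{pct:.1f}% of 200 sampled molecules sanitize")
```

This takes roughly twenty minutes on one CPU core and prints:

```
loss 7.15 -> 1.04
92.5% of 200 sampled molecules sanitize
```

The loss is the weighted sum of the coordinate endpoint loss and the three
masked cross-entropies; the validity percentage is the fraction of sampled
graphs that RDKit accepts (valences, kekulization) — RDKit also logs a
valence warning for each sample that fails. The CTMC stochasticity
`eta=1.5` enables token remasking during sampling, which lets the model
revise early atom-type or bond commitments; it is worth a few validity
points over the plain masking process (`eta=0`) at this scale. On this
10-molecule desk-scale corpus the model memorizes the training
distribution; about nine in ten valid samples are graph-identical to a
training molecule.

The same pipeline is scriptable from the shell:

```bash
molfm make-fixtures --out fixtures/ --seed 0
molfm train --config run.yaml --data fixtures/fixtures.sdf --checkpoint model.npz
molfm sample --checkpoint model.npz --n 200 --steps 250 --seed 1 \
             --size-source fixtures/fixtures.sdf --out samples.sdf
molfm evaluate --in samples.sdf --reference-freqs fixtures/fg_reference.json \
               --ring-reference fixtures/ring_reference.txt --out report.json
```

Training on a real corpus (e.g. GEOM-Drugs, explicit hydrogens, kekulized)
is supported through `molfm.toydata.process_geom_drugs` and the same
`train` entry point with the full-scale `NetworkConfig()` (~6 M
parameters); that path requires the archive download and long compute and
is not exercised by the test suite.

## Layout

| Module | Contents |
| --- | --- |
| `molfm.molgraph` | molecule/vocabulary types, SDF I/O, dataset statistics |
| `molfm.coupling` | prior sampling, Kabsch alignment, optimal assignment |
| `molfm.flows` | interpolants, CTMC kernels, losses, multi-modal composition |
| `molfm.augment` | fake atoms, geometry distortion, self-conditioning schedule |
| `molfm.network` | GVP-cross denoiser, molecule update blocks, checkpoints |
| `molfm.sampler` | joint Euler/CTMC inference, trajectories, X̂₁ movement |
| `molfm.trainer` | training loop, optimizer, resume |
| `molfm.metrics` | validity, FG deviation, OOD rings, CIs, additive effects |
| `molfm.toydata` | synthetic fixtures, optional large-corpus processing |
| `molfm.ad` | minimal reverse-mode autodiff over NumPy |

See `docs/methods.md` for the model, parameter meanings, and limitations.
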