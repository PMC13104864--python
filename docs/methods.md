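# Methods

## Model

`molfm` generates all-atom 3D molecules `g = (X, A, C, E)`: Cartesian
coordinates X (Å), atom types A, formal charges C, and a bond order for
every unordered atom pair E (NONE / SINGLE / DOUBLE / TRIPLE; aromatic
systems are kekulized so no aromatic category exists). One SE(3)-equivariant
network is trained to predict the clean endpoint ĝ₁ from a noisy state g_t,
and sampling runs all modalities jointly.

**Coordinates — continuous flow matching.** The conditional path is the
straight line `x_t = (1−t)x₀ + t·x₁` between a centered Gaussian prior draw
and the target conformer. The network predicts the endpoint X̂₁, from which
the sampling field `(X̂₁ − x)/(1−t)` follows. The regression loss is mean
squared error weighted by `w(t) = min((1−t)⁻², w_clamp)`; the weighting
compensates the shrinking distance-to-endpoint, and the clamp (default 100,
i.e. frozen past t = 0.9) keeps it finite at t → 1.

**Coupling.** Before interpolation, the prior draw is coupled to the target:
alternating proper-rotation Kabsch alignment (scipy `align_vectors`,
det = +1 only — reflections would silently invert stereocenters) and an
exact squared-distance-minimizing assignment (Hungarian algorithm), with a
stability stopping rule capped at 10 rounds. Each half-step solves its
subproblem exactly, so the paired cost is non-increasing; tests check
monotonicity, rotation invariance of the final cost, and agreement with
brute-force assignment for N ≤ 6.

**Categorical modalities — masking discrete flow matching.** Each token
evolves by a CTMC on [0, 1] from an all-MASK prior. Along the conditional
path a token is its final category with probability t, else MASK. One Euler
step uses, for a masked token, jump probability `Δt·(1+ηt)/(1−t)·p̂(j)`
toward category j under the denoiser distribution p̂, and for an unmasked
token, remask probability `ηΔt`. Near t → 1 the off-diagonal mass can exceed
1; the row is then renormalized (unmask with certainty), and any token still
masked after the final step resolves to the denoiser argmax, so outputs are
mask-free by construction. The training loss is cross-entropy on tokens that
are currently masked, averaged over masked tokens only. The stochasticity η
defaults to 0 and is config-exposed.

**Multi-modal composition.** Modalities are conditionally independent given
(g₀, g₁): training states are assembled by sampling each modality's path
independently; the total loss is a weighted sum of the four per-modality
losses (all weights default 1.0).

## Self-correction features

Three train-time features teach the denoiser to detect and undo its own
sampling drift; all are cleanly disabled by zeroing their parameters, which
reproduces the vanilla wiring exactly (tested at the RNG-stream level).

* **Fake atoms** (`p_fake = 0.3`, `σ_fake = 1.0` Å): the target is padded
  with `n ~ U{0, …, ⌈p_fake·N⌉}` atoms of a dedicated FAKE type placed at a
  uniformly chosen real anchor plus an isotropic Gaussian offset; charge 0,
  all bonds NONE. Fake atoms receive coordinate and categorical losses like
  real atoms — the model must learn to place and to recognise them. At
  inference the same allowance of extra slots is added to the drawn size and
  atoms predicted FAKE are stripped, so atom counts seen by the network
  match training.
* **Geometry distortion** (`p_distort = 0.7`, `t_distort = 0.25`,
  `σ_distort = 0.5` Å): past the onset time, a Bernoulli subset of atoms is
  displaced on top of the interpolant. Applied to real and fake atoms alike,
  after the categorical draws (so a shared RNG stream cannot leak distortion
  choices into token draws).
* **Self-conditioning** (rate 0.5): on a random half of training steps the
  denoiser first runs gradient-free, and its prediction is fed back through
  a residual module before the loss pass. The residual embeds the
  displacement X̂₁ − x_t into equivariant vector channels and the previous
  categorical probabilities into invariant node/edge channels; with no
  previous prediction the increments are exactly zero. At inference the
  previous step's output is always passed.

## Network

Nodes carry invariant scalar features, equivariant geometric vector
features, and positions; directed edges carry invariant scalars. Stacked
Molecule Update Blocks each run a node feature update (message passing with
3-GVP chains for messages and updates, mean aggregation, residual + scalar
layer norm), a node position update (a 3-GVP chain emitting one vector,
identity final gate, zero-initialized final weights so initial updates
vanish), and an edge feature update (shallow MLP on endpoint scalars and the
post-update distance, residual + layer norm). Distances enter through a
16-center Gaussian radial basis on [0, 10] Å.

The GVP primitive is extended with cross-product channels: two learned
vector projections are crossed, and their scalar triple products with a
third projection — pseudo-scalars that flip sign under reflection — join the
invariant pathway. This makes the network SE(3)- rather than
E(3)-equivariant, i.e. stereochemistry-aware. Because a molecule's vector
features at the first block would otherwise all be parallel to the single
edge direction (making every cross product vanish at initialization), the
message inputs also include each endpoint's position relative to its
molecule centroid — translation-invariant, equivariant, and linearly
independent of the edge direction.

Numerical stabilization choices: vector features are RMS-normalized per node
after each residual update, and the message function consumes the *unit*
edge direction (the magnitude enters through the radial basis). Both were
adopted after unnormalized variants diverged at desk scale; neither affects
equivariance, which is tested end to end (rotation 1e−4, translation exact,
permutation, reflection sensitivity on a chiral fixture).

Bond logits are decoded per directed edge and averaged over the two
directions of each pair, producing a single order per unordered pair.
The full-scale default configuration (5 blocks, 280 scalar / 16 vector /
160 edge channels) has ≈ 6.0 M parameters; the desk-scale `toy`
configuration (4 blocks, 64/8/32) has ≈ 0.31 M. The desk depth was chosen
by comparing 3-, 4-, and 5-block variants at matched CPU budget: the
4-block model reached a clearly lower training loss and better sample
validity than the 3-block one, while 5 blocks brought no further gain.

## Training and sampling

Per molecule and step: center, pad with fake atoms, draw `t ~ U[0, 1)`,
couple the prior, sample the multi-modal path with distortion, run the
denoiser (two-pass on self-conditioning steps), and accumulate the weighted
loss. Optimization is Adam with cosine learning-rate decay (defaults
2·10⁻³ → 10% of that); these optimizer settings are the package's own
choices and fully config-driven. Every random draw in a step is independent
of the network weights, so checkpoint resume replays the RNG stream exactly
and continues the uninterrupted trajectory bit-for-bit (with a flat
learning rate; the cosine schedule is a function of a run's total length).
Datasets with several conformers per molecule contribute one randomly
chosen conformer per step.

Sampling uses 250 evenly spaced Euler steps by default. The final
coordinate update sets `x ← X̂₁` (the limit of the Euler step as t → 1).

The CTMC stochasticity η trades extra unmasking pressure against random
remasking of already-committed tokens, giving the model second chances to
re-draw tokens whose early commitment turned out inconsistent — the
dominant failure mode of desk-scale samples is exactly an early atom-type
or bond commitment that later conditionals cannot complete into a valid
molecule. A sweep on the desk-scale model (η ∈ {0, 0.1, 0.4, 0.5, 0.6,
0.7, 1, 1.5, 2}) found validity improving from η = 0 through a broad
optimum near η ≈ 1.5, worth several points over the plain masking process;
the end-to-end evaluation samples at η = 1.5. The library default remains
η = 0, and the best η is expected to be model- and scale-dependent.

## Synthetic data

The fixture generator embeds a catalog of ~30 small kekulizable structures
over {H, C, N, O, F} (4–20 atoms with explicit hydrogens) with seeded
ETKDG distance geometry plus MMFF cleanup: realistic bond lengths and
angles, zero downloads, byte-identical SDF output under a fixed seed. The
catalog covers rings (including fused aromatic chemistry via benzene,
pyridine, pyrrole, furan), charges −1/0/+1, all three bond orders, one
chiral center (alanine), and exactly one instance of a rare alert group
(an epoxide) to exercise skewed functional-group frequencies. The
10-molecule training subset used in end-to-end tests contains the smallest
acyclic members (4–9 atoms).

What the fixtures do *not* emulate: drug-like size (tens of heavy atoms),
conformer ensembles, the heteroatom richness of real training corpora, or
their ring-system diversity. Desk-scale results therefore demonstrate that
the machinery — flows, network, trainer, sampler, metrics — is correct and
can memorize and re-generate a small distribution; they say nothing about
generation quality at full scale, which requires training on a corpus such
as GEOM-Drugs (supported via `process_geom_drugs`, optional and

not exercised by tests).

## Metrics

* **Validity**: fraction of molecules whose graph sanitizes in RDKit.
* **Functional-group deviation**: Σ_f |ω_f^ref − ω_f^gen| where ω is
  instances of alert group f per molecule (may exceed 1). The bundled
  default alert list is a curated set of ~40 classic structural alerts;
  published alert collections (Dundee, Glaxo Wellcome) drop into the same
  loader as SMARTS files.
* **OOD ring rate**: ring systems are connected components of fused rings
  extended by exocyclic double-bonded atoms, canonicalized to a fragment
  SMILES key after making hydrogens implicit; the rate is occurrences of
  keys absent from a reference catalog per molecule (per-ring-system
  normalization available by flag). A toy reference of common small rings is
  bundled; large-scale references (e.g. ring systems of a compound database)
  are user-supplied files.
* **Plausibility / relaxation**: thin wrappers over PoseBusters and GFN2-xTB
  that detect tool absence and omit their fields with a warning.
* **Subset confidence intervals**: molecules are split into k = 5 random
  subsets; the 95% interval is 1.96·sd/√k over subset statistics under a
  normal approximation of the subset mean.
* **Endpoint-movement analysis**: X̂₁ movement (mean per-atom displacement of
  the predicted endpoint between consecutive steps) is regressed per time
  step on binary feature indicators by OLS; a feature's relative effect is
  its coefficient over the fitted baseline with that feature off. Features
  that do not vary across runs are dropped (NaN coefficients) rather than
  fitted; a rank-deficient design over the varying features is an error
  naming the missing combinations.

## Problem sizes used in tests

Monte-Carlo statistics use 10 000 draws (3σ binomial bands, 5% relative
tolerance on standard deviations). The end-to-end run trains the toy
configuration for 8 000 Adam steps on the 10-molecule fixture catalog and
samples 200 molecules at 250 Euler steps — sizes chosen so the whole suite
runs on a single CPU in tens of minutes while still exercising every
component at its defaults.

## Known limitations

* The desk-scale generation test is a memorization surrogate; distributional
  fidelity at realistic scale is not measured by the suite.
* The autodiff engine is minimal by design (dense NumPy ops, no fusion);
  full-scale training is supported in principle but is orders of magnitude
  slower than a GPU tensor framework.
* η (CTMC stochasticity) defaults to 0; its desk-scale operating point was
  selected on a memorization task and need not transfer to full scale.
* PoseBusters and xtb wrappers are exercised only on their absence path in
  CI-like environments without those tools.
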