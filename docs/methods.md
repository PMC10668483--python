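# Methods

## Differential reaction fingerprint with fragment maps

A reaction SMILES `reactants>agents>products` is split into molecules;
agents are merged into the reactant side, since the differential fingerprint
is defined on exactly two sides and public enzymatic datasets rarely use the
agent field. For every atom of every molecule (hydrogens made explicit
first, by default) the circular environment at each bond radius 0..r
(default r = 2) is serialised with RDKit as one canonical fragment SMILES —
non-rooted, so a fragment has a single string form regardless of which atom
it was grown from, e.g. `[H]C([H])([H])OC([H])([H])[H]` for dimethyl ether.
An environment that contains no bond beyond the previous radius is not
re-emitted; rare fragments that fail sanitisation are skipped with a
warning. Ring-system shingles are available behind the `include_rings` flag
(default off) for compatibility with encoders that emit them.

The reaction's fragment set is the symmetric difference of the two sides'
fragment-SMILES sets: shared chemistry cancels, so the vector describes the
transformation rather than the participants. Each surviving fragment is
hashed and folded to bit `crc32(smiles) mod d` (default d = 10,240). CRC-32
of the UTF-8 bytes is used as the 32-bit hash because it is deterministic
across platforms and Python versions and exactly fills the 2³² space the
collision analysis assumes. Duplicate occurrences of a fragment set no
extra bits — this is a set fingerprint, and multiplicity is discarded.

Every bit stores the fragment SMILES that set it, and every fragment stores
its occurrences: (molecule index, covered atom set, side). Atom indices are
projected onto heavy atoms of the input molecule (an explicit hydrogen maps
to the heavy atom carrying it), so the maps remain valid for 2D depictions
drawn without explicit hydrogens. Identity reactions legally encode to the
all-zero vector with empty maps; Jaccard similarity against an all-zero
vector is defined as 0.

## Classifier

One independently trained MLP per EC level: linear input (d), one ReLU
hidden layer (default 1664 units), linear output over the level-truncated
label vocabulary. Cross-entropy loss; Adam with learning rate 0.001;
exponential learning-rate decay, γ = 0.9 per epoch; early stopping when
`mean(last 5 validation losses) − current validation loss < 0.001`, never
before epoch 5 (the window-mean is undefined earlier). Other readings of
the stopping rule (window-mean vs previous window-mean) change stopping
epochs by 1–2 on our corpora without changing the fitted accuracy; the
current-vs-window-mean form is the simplest consistent one. The hidden
activation is ReLU — the standard choice for this architecture family and
the activation the attribution engine's Rescale rule is written for; the
bundle records the activation id and attribution refuses anything else.

The network is implemented directly on numpy (forward, backward, Adam,
scheduler) so the attribution engine has first-class access to weights and
training is reproducible from one master seed, which expands via
`SeedSequence` into separate fold-construction, weight-initialisation and
batch-shuffle streams. Weights are float32; probabilities are computed with
a float64 softmax so they normalise to ~1e-16. Default batch size is 256
and max 100 epochs. With very small corpora (tens of reactions) a 256-batch
gives one optimiser step per epoch and the decaying schedule runs out of
steps before convergence, so small-corpus runs (tests, the synthetic
pipeline) use batch 8 and a 256-unit hidden layer — the recipe is
unchanged, only the step granularity and capacity are matched to the data.

Cross-validation is stratified on the level-truncated label: labels with ≥ k
members are dealt round-robin across the k test folds, smaller labels are
scattered randomly; 10% of each training portion (at least one record per
label with ≥ 2 training members) is held out, stratified, as the validation
split that drives early stopping. Evaluation reports accuracy, macro F1
(unweighted per-class mean — macro because class imbalance is the concern
being measured; a weighted mean would hide exactly the small classes of
interest) and the full confusion matrix via scikit-learn.

The label-shuffle ablation re-trains each fold after permuting ⌈p·n⌉
training labels uniformly among themselves (test labels untouched), for a
list of fractions p; the permutation preserves the label multiset. The
three level models are trained independently, so their predictions need not
agree on shared EC prefixes; `hierarchy_inconsistency_rate` (and the
`predict` CLI warning) reports how often they disagree rather than forcing
consistency.

## Attribution

DeepLIFT with the Rescale rule, specialised to the two-linear-layer ReLU
network. Against a reference input, multipliers pass through linear layers
as the weight matrices; the hidden ReLU contributes
`m = (relu(z) − relu(z_ref)) / (z − z_ref)`, falling back to the gradient
`1[z > 0]` when `|z − z_ref| < 1e-7`. Contributions are computed in float64
and satisfy completeness — they sum to `score(x) − score(ref)` — to ~1e-7
even through float32 weights (the acceptance script records the worst
residual observed). The explained quantity is the pre-softmax class score:
this makes completeness exact and is common DeepLIFT practice; an
`explain_probability` flag rescales contributions so they sum to the
probability difference instead (an approximation, since softmax couples
classes — rankings are unaffected in practice).

DeepSHAP-style averaging: contributions are averaged over a background set,
by default 100 reactions sampled uniformly without replacement from the
training fold with a fixed seed, and the baseline (`expected_value`) is the
mean class score over that set.

Per-bit contributions split into present fragments (every on bit, carrying
the reaction's own fragment set for the bit) and absent fragments (off bits
ranked by |contribution|, top 10 by default, annotated with the corpus-wide
fragments that fold to the bit). When several of a reaction's fragments
share one bit, the bit's single weight is assigned to each colliding
fragment without splitting and the collision is flagged — collisions are
surfaced, not resolved. Atom weights sum each present bit's weight once per
atom in the union of its fragments' occurrence atom sets, which keeps the
identity `Σ_a w_a = Σ_bits w_bit · |atoms(bit)|` testable by brute force.

## Depiction

2D coordinates come from RDKit's coordinate generator per molecule;
molecules are arranged left-to-right (reactants, arrow, products) with
fixed gaps. Atom weights are normalised by the maximum |w| across the whole
reaction — across molecules, not per molecule, so relative contribution
sizes are comparable, and max-abs (rather than sum) keeps the diverging
colour scale anchored at zero with full use of both hues. The heat field is
the sum of isotropic Gaussians at atom coordinates with a shared σ
(default 0.3 × median bond length, so lobes localise to atoms at any
drawing scale). The exponent uses the sum of squared coordinate
differences: a difference of squares is not a decaying radial kernel and
would diverge along one axis. Grid samples use a corner convention
(`x = xmin + i/ppu`) so integer coordinates land exactly on samples, which
makes the closed-form checks (`G(0,0) = 1`, `G(1,0) = e^{-1/2}` for unit
weight and σ) exact.

Rendering rasterises the field at `ppu` pixels per drawing unit (default
20), maps it through the green/magenta diverging scale with opacity
proportional to |G|/max|G| (all-zero fields are fully transparent, so the
output is byte-identical to the plain depiction), upscales
nearest-neighbour by an integer factor, and draws bonds, heteroatom labels
and the arrow on top with pillow. Output is PNG; SVG wraps the same raster.
All steps are deterministic, so identical inputs give identical bytes. The
absent-fragment report lists the top-k absent bits by |weight|, ties broken
by bit index.

## Collision accounting

Expected 32-bit hash collisions use the birthday-problem pair count
`n(n−1)/(2M)` with M = 2³² buckets; for n ~ 10⁴ this agrees with the exact
occupancy expectation `n − M(1 − (1 − 1/M)^n)` to relative order n/3M
(~7·10⁻⁷), and a Monte-Carlo test confirms the expectation to 3 SD.
Folding collisions are counted exactly: bits whose corpus-wide fragment set
has ≥ 2 members, and (reaction, bit) pairs where a single reaction's own
fragments co-occupy a bit, with the fraction of reactions affected.

## Synthetic corpus

The generator emits template reactions
`scaffold.cosubstrate >> scaffold.diagnostic.byproduct` for n_classes
pseudo-classes labelled `c.1.1`. The scaffold appears unchanged on both
sides and cancels in the symmetric difference; co-substrates and byproducts
are drawn from pools shared by all classes, contributing class-uninformative
difference fragments; the diagnostic molecule (chloroform,
1,2-dibromoethane, carbon disulfide, ... — pairwise substructure-disjoint,
validated at config time) appears only in its class's products. Each class
therefore carries guaranteed class-specific on bits amid shared noise bits,
making the corpus linearly separable by construction while leaving the
attribution task non-trivial: the engine must rank the diagnostic bits above
the noise bits, not merely find the only signal present.

What the fixtures emulate: the fingerprint geometry (sparse class-indicative
bits plus shared bits) and the end-to-end flow of real corpora. What they do
not: chemical diversity within a class, label noise, class imbalance, and
stereochemistry-dependent differences — so passing fixture tests shows the
machinery is correct, not that real-data accuracy will be high. Default
conditions for the synthetic study: 3 classes × 10 reactions, full
10,240-bit fingerprint, radius 2, explicit hydrogens, 4-fold CV, 256 hidden
units, batch 8, 100-reaction background. Published-corpus reproduction
(7010 Rhea reactions, accuracies 0.98/0.96/0.95) requires the deposited
CSV; the loaders, training recipe and collision counters run unchanged on
it via `data/rhea.csv`.

## Known limitations

- Attribution supports exactly the input–ReLU–output architecture; deeper
  nets would need a general multiplier backpropagation.
- Nearest-neighbour search is exact (O(n·d) per query); no approximate
  index.
- The probability-space attribution flag is a rescaling approximation, not
  a full DeepLIFT pass through softmax.
- Folded-bit collisions are reported, never resolved; an explanation for a
  collided bit is inherently ambiguous between the colliding fragments.
- Depictions are schematic (no stereo wedges, no aromatic circles); they
  locate attributions rather than replace a chemistry drawing tool.
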