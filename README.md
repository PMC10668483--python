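# rxnlift

Explainable EC-number classification of enzyme-catalysed reactions.

Enzyme-catalysed reactions are annotated with hierarchical Enzyme Commission
(EC) numbers `x.y.z.sn` — class, subclass, sub-subclass, serial number.
Curating these annotations is slow expert work, and the deep models proposed
to automate it are usually opaque. `rxnlift` is a toolkit for people building
or auditing reaction-based EC classifiers: database curators who want a
human-in-the-loop triage step, and cheminformaticians who want to see *why*
a model called a reaction a hydrolase.

The pipeline:

1. **Fragment-mapped differential reaction fingerprint.** Every molecule on
   each side of a reaction SMILES is decomposed into circular substructures
   (radii 0..2, hydrogens explicit, one canonical SMILES per fragment). The
   symmetric difference of the reactant-side and product-side fragment sets
   is hashed (CRC-32) and folded modulo the fingerprint length *d* (default
   10,240) into a binary vector `v`. Unlike an ordinary hashed fingerprint,
   each bit keeps the fragment SMILES that set it and the atoms each fragment
   covers.
2. **One-hidden-layer MLP per EC level** (ECX, ECXY, ECXYZ): input `d`,
   hidden 1664 ReLU units, softmax output over the level-truncated label
   vocabulary; cross-entropy, Adam (lr 0.001), exponential learning-rate
   decay (γ = 0.9/epoch), early stopping on the mean validation loss of the
   5 most recent epochs, 4-fold stratified cross-validation.
3. **DeepLIFT (Rescale rule) attributions**, averaged over a background set
   of 100 training reactions (DeepSHAP style). Contributions are complete:
   they sum to `score(x) − E[score]`. Per-fragment weights `w_f` aggregate to
   per-atom weights `w_a = Σ_i w_{f_i} [a ∈ f_i, v_i = 1]`, and attributions
   of *absent* fragments (off bits) are reported with their corpus-wide
   candidate fragments.
4. **Heat-map depictions.** Atom weights, max-abs-normalised across the
   reaction, become a summed-Gaussian pixel field
   `G(x,y) = Σ_j w_j exp(−((x−x_j)² + (y−y_j)²)/2σ²)` rendered on a diverging
   colour scale (green positive, magenta negative) under the 2D reaction
   drawing.
5. **Collision accounting.** Expected 32-bit hash collisions via the
   birthday-problem pair count `n(n−1)/2M`, plus exact counts of folded bits
   representing multiple fragments, corpus-wide and within single reactions.

A seeded synthetic-corpus generator builds template reactions whose class is
determined by a diagnostic fragment, giving a download-free, perfectly
separable testbed for the whole pipeline.

## Worked example

```python
import numpy as np
from rxnlift import (
    default_fixture_config, generate_fixture_corpus, encode_corpus,
    FingerprintParams, TrainConfig, run_cv, predict, sample_background,
    explain_reaction, expected_hash_collisions,
)

records = generate_fixture_corpus(default_fixture_config(3, 10, seed=7))
params = FingerprintParams(dim=2048, radius=2)
index = encode_corpus(records, params)

summary = run_cv(records, level=3, k=4, params=params,
                 config=TrainConfig(hidden_size=256, batch_size=8, seed=3),
                 X=index.matrix.astype(np.float32))
print(f"4-fold CV accuracy: {summary.mean_accuracy:.2f} +/- {summary.sd_accuracy:.2f}")

model = summary.models[0]
for label, p in predict(model, index.matrix[0].astype(float), top_k=3):
    print(f"  {label}: {p:.3f}")

background = sample_background(index.matrix.astype(float), 100, seed=1)
result = explain_reaction(model, records[0], background, corpus=index)[0]
top = max(result.present_fragments, key=lambda f: f.weight)
print(f"top positive fragment for {result.class_label}: "
      f"{top.fragments[0]} (w = {top.weight:+.3f})")
print(f"expected hash collisions, 9509 fragments in 2^32: "
      f"{expected_hash_collisions(9509, 2**32):.2f}")
```

prints

```
4-fold CV accuracy: 1.00 +/- 0.00
  1.1.1: 0.741
  2.1.1: 0.130
  3.1.1: 0.129
top positive fragment for 1.1.1: CCl (w = +0.230)
expected hash collisions, 9509 fragments in 2^32: 0.01
```

The synthetic corpus is perfectly separable, so cross-validated accuracy is
1.0; the top-ranked positive fragment `CCl` is a substructure of the
pseudo-class-1 diagnostic molecule (chloroform), i.e. the attribution engine
recovers the planted signal. The 0.01 is the expected number of colliding
fragment pairs when 9509 distinct fragment SMILES are hashed into 2³²
buckets — hash collisions are negligible; folding collisions (the modulo
step) are counted exactly by `rxnlift stats collisions`.

The same pipeline is available from the shell:

```bash
rxnlift fixture --classes 3 --per-class 10 --seed 7 --out fix.csv
rxnlift encode  --input fix.csv --dim 10240 --radius 2 --out corpus.npz
rxnlift train   --corpus corpus.npz --level subsubclass --folds 4 --seed 3 \
                --out-prefix run
rxnlift explain --model run.fold0.model.npz --corpus corpus.npz \
                --reaction "$(sed -n 2p fix.csv | cut -d, -f1)" --out exp.json
rxnlift render  --explanation exp.json --out exp.png
```

Real corpora load the same way with `rxnlift encode --input rhea.csv
--dialect rhea_csv` (columns `rxn_smiles`, `ec`) or `--dialect ecreact_csv`
(EC tokens embedded as `|x.y.z.sn` inside the SMILES are stripped). EC class
7 (translocases) is excluded on load: translocation encodes no chemical
transformation for a reaction fingerprint to see.

## Layout

| module | contents |
| --- | --- |
| `rxnlift.chem_io` | reaction/EC parsing, dataset dialects, stratified CV folds, fixture corpus |
| `rxnlift.drfp` | fragment-mapped fingerprint, hashing, corpus index, exact Jaccard search |
| `rxnlift.classifier` | MLP training recipe, evaluation, cross-validation, label-shuffle ablation |
| `rxnlift.attribution` | DeepLIFT Rescale engine, background averaging, fragment/atom mapping |
| `rxnlift.collision_stats` | analytic and empirical collision accounting |
| `rxnlift.depiction` | 2D layout, Gaussian heat-map grids, PNG/SVG rendering |
| `rxnlift.cli` | `rxnlift` command group tying the pipeline together |

See `docs/methods.md` for the model details, parameter choices and
limitations.
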