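# multispot

Emitter counting and nanometer-precision localization for
**sub-diffraction-limited spots** in single-molecule localization microscopy
(SMLM/STORM).

## The problem

When two or more fluorophores closer together than the diffraction limit
(~240 nm for AF647 at NA 1.4, since the Abbe limit is λ/2NA) emit in the
same camera frame, they produce a single apparent spot that is
morphologically indistinguishable from a single-molecule spot — its fitted
size (2σ<sub>x</sub> × 2σ<sub>y</sub>) and ellipticity (σ<sub>x</sub>/σ<sub>y</sub>)
distributions overlap heavily with those of true singles. Classical
single-Gaussian fitting therefore under-counts molecules and mislocates
them toward spot centroids, which distorts quantification of dense
sub-diffraction structures (receptor clusters, molecular complexes).

`multispot` addresses this with a **two-stage classify-then-localize
pipeline**:

1. a *classification network* predicts the emitter count *I* of each
   15×15-pixel spot crop (cross-entropy loss
   L<sub>class</sub> = −Σ p(x<sub>i</sub>) log q(x<sub>i</sub>));
2. a count-specific *localization network* regresses the 2*I* coordinates
   (mean-square loss
   L<sub>position</sub> = 1/(2I) Σ<sub>i</sub> [(x<sub>i</sub>−x̄<sub>i</sub>)² + (y<sub>i</sub>−ȳ<sub>i</sub>)²]).

Training data with exact ground truth are constructed **without any extra
information**: single-emitter library spots (7×7-pixel crops with
Gaussian-fitted emitter positions) are translated sub-pixel so their fitted
anchors land on coordinates drawn inside a 240 nm disk, then summed. The
anchor coordinates become the labels.

Quality is measured with the confusion-matrix metrics
(Recall = TP/(TP+FN), Precision = TP/(TP+FP), Accuracy = (TP+TN)/total)
and the per-spot localization error

RMS = √( Σ<sub>i</sub> [(x<sub>i</sub>−x̄<sub>i</sub>)² + (y<sub>i</sub>−ȳ<sub>i</sub>)²] / 2I ),

with predicted and true emitters paired by minimum-cost (Hungarian)
assignment. A spike-rendering + Gaussian-convolution + SSIM harness
compares coordinate predictions with image-generating reconstruction
methods, and a STORM simulator of dense, center-weighted ultrastructures
(50–550 molecules per 240 nm disk) exercises the full frame-level pipeline
against the classical one-localization-per-spot baseline.

Because no deep-learning framework is assumed, the networks are compact
fully-connected residual models written in pure numpy (Adam, cosine
annealing, L2 weight penalty), sized for 15×15 single-channel crops; see
`docs/methods.md` for the architecture and its relation to the full-scale
residual-CNN recipe.

## Worked example

```python
import numpy as np
import multispot as ms

# generate a synthetic single-emitter spot library (AF647-like statistics)
library = ms.build_synthetic_library(n_molecules=600, rng=0)

# derive labeled one- and two-emitter spots and train the two-stage pipeline
dataset = ms.build_dataset(library, n_per_class=3000, classes=(1, 2), rng=1)
bundle = ms.train_bundle(dataset, ms.TrainConfig(epochs=30, seed=2))

# held-out counting quality (two-emitter class as positive)
test = dataset.test()
pred = bundle.classifier.predict_count(test.images)
cm = ms.ConfusionMatrix.from_labels(test.counts, pred, positive=2)
precision, recall, accuracy = ms.classification_metrics(cm)
print(f"counting: accuracy={accuracy:.3f} precision={precision:.3f} recall={recall:.3f}")

# held-out two-emitter localization error (Hungarian-matched RMS, nm)
pairs = test.subset(test.counts == 2)
center = np.array([7.5 * 160, 7.5 * 160])
coords = bundle.localizers[2].predict_coords(pairs.images) + center
rms = [ms.rms_error(coords[i], pairs.coords_nm[i]) for i in range(len(pairs))]
print(f"localization: mean RMS = {np.mean(rms):.1f} nm over {len(pairs)} spots")
```

Output:

```
counting: accuracy=1.000 precision=1.000 recall=1.000
localization: mean RMS = 12.9 nm over 300 spots
```

The counting metrics say every held-out spot's emitter count was predicted
correctly at this (small) problem size; the 12.9 nm mean RMS is the
Hungarian-matched localization error over two-emitter spots whose true
separations are drawn uniformly inside the 240 nm disk — already well below
the pixel size (160 nm) and the diffraction limit. Larger libraries and
longer training (see `multispot.benchmarks`) push the RMS below 10 nm.

The same pipeline is available from the shell:

```sh
multispot --seed 1 simulate-library --out lib/
multispot --seed 1 train --out bundle/
multispot --seed 1 simulate-storm --n-molecules 350 --out sim/
multispot --seed 1 predict --stack sim/stack.tiff --bundle bundle/ --out locs.csv
multispot --seed 1 evaluate --pred locs.csv --truth sim/ground_truth.csv --out report/
```

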