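# normsar

Norm-index molecular descriptors and a random-forest structure–activity
model for the cellular uptake of surface-modified nanoparticles.

## The problem

Libraries of magneto-fluorescent nanoparticles share one metal-oxide core
and differ only in the small organic molecule decorating the surface; their
uptake by pancreatic-cancer (PaCa2) cells spans two orders of magnitude and
is strongly determined by that surface modifier.  `normsar` is for
computational toxicologists and nano-QSAR modellers who want to classify
whether a candidate modifier gives high uptake (> 5000 particles per cell)
before synthesizing it.

## The model

Each all-atom structure is reduced to 72 scalar descriptors.  With the
step matrix **DM1** (graph shortest-path lengths in bonds), the Euclidean
distance matrix **DM2** (Å), and the per-atom property matrix

    PM = [ SN  EN  Ei  tanh(ac) ]

(electron shell number, Pauling electronegativity, first ionization energy
in eV, and tanh of the partial atomic charge), three extended-matrix
families combine a distance matrix with one property column *p* = PM(:, n):

    EM1 = [ DM  p ]          (column appended)
    EM2 = p pᵀ + DM
    EM3 = p pᵀ ∘ DM          (elementwise)

Each of the 24 extended matrices is summarized by three matrix norms —
maximum absolute column sum ‖·‖₁, spectral norm ‖·‖₂ (largest singular
value) and Frobenius norm ‖·‖F — giving 72 nonnegative descriptors that are
invariant to atom relabeling and rigid motions.

The endpoint, log₁₀ particles per cell, is binarized at log₁₀ 5000 ≈ 3.699.
A stratified random split (89 train / 20 test on 109 samples) feeds
recursive feature elimination driven by random-forest importances (drop the
least important descriptor, refit, record the cross-validated accuracy of
every subset size); the smallest subset within one standard error of the
best accuracy is kept.  The final forest is validated with sensitivity,
specificity, accuracy and the Matthews correlation coefficient, k-fold
cross-validation, and a per-class leverage applicability domain
h = xᵀ(XᵀX)⁻¹x (a test prediction is trusted only when its leverage lies
within the training range of its class).

## Worked example

```python
from normsar import CellularUptakeSAR, PipelineConfig, emulate_study_shape

study = emulate_study_shape(seed=7)          # 109 molecules, 59/50 classes
model = CellularUptakeSAR(study.dataset, PipelineConfig(n_trees=40, cv_folds=3))
res = model.fit(pre_split=study.split)
print(res.summary())
```

prints:

```
Cellular-uptake nano-SAR (random forest on norm-index descriptors)
selected descriptors (3): EM3_DM1_P4_norm1, EM3_DM2_P2_norm1, EM3_DM2_P4_norm3
3-fold CV accuracy (training set): 0.933
test samples in applicability domain: 13 / 20

Sub-Set           n         SE         SP        ACC        MCC
---------------------------------------------------------------
Training set     89      1.000      1.000      1.000      1.000
Test set         20      0.818      1.000      0.900      0.818
Complete        109      0.966      1.000      0.982      0.964
```

The summary mirrors the standard nano-SAR report: per-subset confusion
statistics (training accuracy 1.000 here reflects the forest's in-sample
fit; the test row is the honest estimate), the cross-validated accuracy of
the selected-descriptor model, and how many test structures fall inside the
leverage applicability domain — predictions for the others should be
discarded.

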