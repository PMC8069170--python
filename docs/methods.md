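# Methods

## Descriptors

A molecule enters the descriptor stage as an all-atom graph (hydrogens
included) with 3D coordinates in Å and per-atom partial charges.  Two
distance matrices are formed: the step matrix `DM1` of graph shortest-path
lengths in bonds (Dijkstra on the unweighted bond graph) and the Euclidean
matrix `DM2`.  The property matrix `PM` holds, per atom, the period number
SN, the Pauling electronegativity EN, the first ionization energy Ei in eV
(NIST values, frozen in `normsar/data/atomic_properties.json`), and
tanh of the partial charge.  The first three columns are used unscaled; no
normalization is applied.  Charges enter only through tanh, which bounds
their column to (−1, 1).

Each distance matrix is combined with each property column three ways —
appended column (`EM1`, N×(N+1)), plus the property outer product (`EM2`),
times the outer product (`EM3`) — and each combination is summarized by the
maximum absolute column sum, the spectral norm and the Frobenius norm.
The product in `EM3` is elementwise by default, which preserves symmetry
and the zero diagonal so that the matrix remains a property-weighted
distance matrix; the matrix-product reading is available via
`em3_product="matmul"` since the defining convention is ambiguous.  The
spectral norm is computed by SVD, which is valid for the non-square `EM1`.
Canonical order — family, distance matrix, property column, norm — fixes
the 72 descriptor names and every downstream column order.

## Partial charges

Reference charges for this descriptor family come from quantum chemistry,
which is outside this package's scope.  The default stand-in is a damped
electronegativity-equalization scheme on the bond graph: charge flows along
each bond proportionally to the difference in effective electronegativity
χ_i + η_i q_i (Pauling χ, chemical hardness η), damped by 2^(−sweep), for
12 sweeps.  The scheme is deterministic, permutation-equivariant, exactly
charge-conserving, and gives chemically sensible signs (O negative against
C, symmetric atoms equal).  Magnitudes are plausible rather than accurate;
file-supplied charges (SDF `<PARTIAL_CHARGES>` field, XYZ fifth column)
always take precedence.  Hydrogens are included in all matrices; a
`heavy_atoms_only` reading can be obtained by stripping hydrogens upstream.

## Classification pipeline

The uptake endpoint (log₁₀ particles per cell) is binarized at 5000
particles per cell; the comparison is strict (`> log₁₀ 5000`).  Splitting
is random, stratified by class, reproducible by seed; 109 samples at test
fraction 20/109 give the 89/20 split with an 11/9 test class balance.

The forest uses 500 trees, √p features per split, unlimited depth and
impurity-based importances (defaults exposed in `PipelineConfig`; the
hyperparameters are not dictated by the problem, and recovery experiments
in the test suite use 30–40 trees and 3 CV folds — at ~100 samples the
extra trees change accuracy by well under one test-set count, and the
smaller forest keeps the multi-seed experiments cheap).  RFE drops exactly
one descriptor per iteration (the least important; ties broken by dropping
the later name in canonical order so the procedure is deterministic),
recording the stratified-CV accuracy of every subset size.  The selected
subset is the smallest whose CV accuracy is within one standard error of
the curve maximum — parsimony is preferred because descriptor sets this
collinear offer many near-equivalent optima.

Metrics follow the standard confusion-matrix definitions with positive
class 1.  A statistic with a zero denominator (e.g. MCC when a predicted
class is empty) is reported as undefined (`None`) rather than 0, because
specificity exactly 1 occurs in realistic runs and silently substituting 0
would corrupt averages.

## Applicability domain

Leverage h = xᵀ(XᵀX)⁻¹x is evaluated per class against that class's
training submatrix, in the space of the *selected* descriptors — with ~45
training samples per class, the full 72-column XᵀX is singular, and the
model's predictions live in the selected subspace anyway.  A rank-deficient
XᵀX falls back to the pseudo-inverse with a warning.  No intercept column
is added by default (the defining quadratic form has none; `add_intercept`
is available).  The default `range` policy trusts a query when its leverage
does not exceed the class's maximum training leverage; the classical
warning leverage h* = 3p′/n is available as `warning_leverage`.  "Within
the range of the training set" admits several readings (maximum leverage,
convex hull); the maximum-leverage reading is used because it is the one
the quadratic form supports directly.

## Synthetic data

The generator emulates small organic surface modifiers: 5–30 heavy atoms
drawn as C 0.60 / N 0.15 / O 0.15 / S 0.10, grown as a random tree by
uniform attachment respecting standard valences (C4, N3, O2, S2), with one
optional ring closure (probability 0.3) between atoms at graph distance
≥ 3; hydrogens fill remaining valences.  Coordinates come from a
deterministic tree-walk placement at standard single-bond lengths (C–C
1.54 Å, C–N 1.47 Å, C–O 1.43 Å, C–S 1.81 Å, X–H 1.09 Å) with Gaussian
jitter (σ = 0.05 Å) and directions rejected within ~60° of an existing
bond at the same atom.  The geometry is physically plausible, not relaxed:
ring-closing bonds do not constrain the embedding, there are no torsional
preferences, and charges are the equalization stand-in.  Consequently the
descriptors are realistic in scale and correlation structure but not
DFT-accurate, and all quantitative claims the tests make on synthetic data
are relative to the planted ground truth, not to laboratory uptake data.

Labels are planted through a logistic model on standardized values of
three named descriptors (defaults `EM3_DM1_P4_norm1`, `EM3_DM2_P1_norm1`,
`EM3_DM1_P1_norm1` with coefficients 6, 4, 4), then flipped with
probability 0.05.  The coefficients are large so the Bernoulli draw is
near-deterministic and the flip noise dominates, putting the Bayes accuracy
near 0.95 — the performance regime of real uptake models.  The
study-shaped dataset (`emulate_study_shape`) labels the 59 largest planted
scores positive — the exact realization of tuning the logistic intercept to
a 59/50 balance — and applies the label noise as matched positive/negative
flip pairs so the balance stays exactly 59/50; a continuous uptake value is
emitted by affinely mapping each class's scores into the observed
2.23–4.44 range on its side of the 5000-particle threshold, so binarization
round-trips.

A structural property of the 72 norm descriptors matters for recovery
experiments: they are strongly mutually correlated (pairwise |r| ≳ 0.8 on
generator output, dominated by molecular size).  Any planted triple is
therefore partly redundant, and an importance-based elimination that prunes
redundant twins is behaving correctly when it retains one of several
near-equivalent descriptors.  Recovery of the full planted identity is
accordingly tested on planted datasets with independent features (where the
ground truth is identifiable), while the molecular end-to-end experiments
assert what is identifiable there: held-out accuracy and a non-empty
intersection between the selected set and the planted set.

## Experiment sizes

Multi-seed experiments in the tests and acceptance script use: 50 seeds for
the RFE ranking recovery (120 samples, 20 independent features, 3
informative), 20 seeds for the end-to-end study-shaped recovery (109
molecules each), forests of 30–40 trees with 3-fold selection CV in those
loops, and a 200-tree forest with 5-fold CV for the single acceptance run.

## Known limitations

- Descriptor values depend on the charge stand-in; models trained on
  DFT-charged structures are not interchangeable with equalization-charged
  ones.
- Single conformer per molecule; conformational flexibility is ignored.
- Bond perception for XYZ input is a covalent-radius cutoff (factor 1.2)
  and can mis-bond unusual geometries; SDF bond blocks are authoritative.
- The leverage domain is a convexity-free ellipsoidal criterion; structures
  inside the leverage range can still be chemically dissimilar to the
  training set.
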