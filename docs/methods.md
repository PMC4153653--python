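# Methods

## Model

A protein `P = R1 R2 ... RL` over the 20 standard amino acids is
mapped to a fixed-length vector so that variable-length sequences can
feed a kernel classifier without discarding all order information. The
vector has three ingredients:

1. **Reduced alphabet.** An ordered partition of the 20 residues into
   `n_c` clusters. Treating clusters as letters shrinks the ordered
   pair space from `400·d` to `n_c²·d`, which cuts computation and
   overfitting risk. Only the identity partition `cp(20)` is built in;
   published multi-cluster profiles must be supplied as profile files
   (one line, clusters separated by `;`). We deliberately do not
   hard-code any published 13/14/15/19-cluster memberships: the
   sources that report results under those names do not print the
   memberships, and guessing them would silently change every feature.
2. **Composition block.** The `n_c` cluster occurrence frequencies
   (counts / L).
3. **Distance-pair blocks.** For each distance `d' = 1..d_max`, an
   `n_c × n_c` matrix of ordered pair counts: entry `(a, b)` counts
   positions `p` with cluster `a` at `p` and cluster `b` at `p + d'`.
   **Distance convention:** `d'` is the index offset, so `d' = 3`
   means two residues separated by two others, and `d' = 1` means
   adjacent. This is the single most error-prone convention in this
   feature family; it is frozen here and pinned by tests.

Total dimension `Λ = n_c + n_c²·d_max`. Layout (frozen, relied on by
the discriminant code): composition at indices `0..n_c-1`; the block
for `d'` starts at `n_c + (d'-1)·n_c²`, row-major, `(a, b)` at offset
`a·n_c + b`. Pairs are ordered (`A→K ≠ K→A`).

**Normalization.** The literature this feature family comes from says
"occurrence frequency" without fixing a denominator. Our default
`per_stratum` divides the composition block by `L` and each distance
block by its own pair count `L − d'`, so every defined block is a
probability distribution and sequence length is factored out
consistently. `raw_counts` mode keeps integer counts; it is what the
brute-force oracle checks exactly and what the occurrence-localization
cross-check uses. A sequence with `L ≤ d'` has no pairs at that
distance: the block is all zeros and a warning is logged — short but
valid proteins stay encodable.

## Classifier

An RBF-kernel SVM (scikit-learn's libsvm binding; the quadratic
program is not re-implemented). Conventions fixed by this package:

* labels: +1 DNA-binding, −1 non-binding; decision value exactly 0
  maps to +1;
* no feature scaling: per-stratum features already lie in [0, 1];
* solver tolerance pinned at 1e-3 and stored in the model file —
  retraining on identical input reproduces identical predictions, and
  symmetry properties (e.g. label-flip antisymmetry of decision
  values) hold to this tolerance, not exactly;
* grid search: exhaustive over exponential ladders
  `C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}`, `γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}` by stratified
  k-fold CV accuracy, deterministic given the fold seed; ties break to
  the highest accuracy, then smallest C, then smallest γ, so reports
  are reproducible.

Model files are joblib archives carrying a format version, the solver
parameters, the fitted support data and the full encoding
configuration (alphabet profile string, d_max, normalization), so a
loaded model re-encodes queries consistently.

## Evaluation

Sn, Sp, Acc in the error-count form (`Sn = 1 − FN/N⁺`,
`Sp = 1 − FP/N⁻`), MCC by the standard Matthews formula. A vanishing
MCC denominator is reported as *undefined* with the raw counts
attached, never coerced to 0. ROC is a threshold sweep over decision
values with one vertex per distinct value; tied scores get half
credit, making the trapezoid AUC equal to the normalized Mann–Whitney
statistic (property-tested against exhaustive pair comparison and
against scikit-learn).

Protocols: jackknife (leave-one-out; N training rounds, metrics pooled
over held-out predictions), stratified k-fold (deterministic given the
seed; `k = n` degenerates to leave-one-out splits since stratification
is impossible there), a sweep over `d_max` that runs one k-fold per
value and reports the argmax, and a single-train independent test that
warns when train/test ids overlap. Hyperparameters are fixed once and
reused in every jackknife round — the convention in this literature —
but this lets selection information leak; `jackknife(...,
nested_grid=...)` re-selects (C, γ) inside every round for a
leakage-free estimate.

## Discriminant interpretation

From the fitted model, `W_j = Σᵢ aᵢ·M{i,j}` with `aᵢ` the label-signed
dual coefficients and `M` the training feature matrix. For the RBF
kernel this is an interpretive linear approximation of feature
importance (it is the exact primal weight only for a linear kernel);
outputs are labelled as such. The pair-score matrix sums `max(W_j, 0)`
over the distances of each ordered pair, excluding the composition
block; its large cells name the discriminative pairs.

`locate_pair_occurrences` lists every occurrence of a chosen pair at
chosen distances (1-based positions); its totals equal the raw-count
encoder entries (cross-module test). `region_overlap` counts hits
inside 1-based inclusive regions; because a distance-pair spans
residues `p..p+d'`, membership is ambiguous at region edges, so both
rules are implemented: `intersect` (default — the span touches a
region) and `strict` (the span lies entirely inside one region). Case
studies should be run under both and the rule recorded.

## Synthetic data generator

Emulates the one property the method exploits: class-specific
enrichment of an ordered residue pair at short distances. Negatives
are i.i.d. draws from a background composition; positives additionally
get planted `(a, b)` pairs written in at the requested distances.
Defaults (the generator's stated world, fixed before the acceptance
thresholds were tested): 100 positives vs 100 negatives, lengths
uniform in 80–200, uniform background, pair (R, R) at distances 1–3,
enrichment 10 (the planted count per stratum is
`round((enrichment−1)·(L−d)·p_a·p_b)`, so enrichment 1 plants nothing
and the classes are exchangeable). Planting overwrites positions
rather than inserting, keeping length uninformative. The optional
`balance_composition` mode scatters the same number of single planted
residues into the negatives so that composition is also uninformative
and any signal must be carried by the pair features; it is off by
default (negatives are pure background). A SwissProt-like composition
preset is included as versioned data.

What a green synthetic test establishes: the pipeline can learn and
re-identify a planted pair signal well above chance, and collapses to
chance when no signal is planted. What it does not establish:
performance on real PDB-derived benchmarks, which have homology
structure, composition biases and length/label correlations the
generator does not simulate; real-data accuracy claims require the
real benchmark FASTA.

## Numerical and design choices

* Benchmark cleaning drops chains shorter than 50 residues (fragments)
  and chains containing 'X' or other ambiguity/unusual codes
  ('B', 'Z', 'U', 'O', 'J', '*', '-'); the encoder separately refuses
  them with a positional error rather than skipping, because skipping
  silently changes frequencies. Sequence-identity redundancy reduction
  is out of scope (use PISCES/CD-HIT upstream).
* Lowercase FASTA letters are uppercased, not rejected.
* `feature_dimension` validates `1 ≤ n_c ≤ 20`, `d_max ≥ 0`.
* Test/CLI hyperparameters `C = 32`, `γ = 2` are ladder values chosen
  once on the generator's stated world; per-stratum features are
  small, so informative RBF widths sit at γ ≥ 1.
* Heatmap export puts the first residue of the pair on the horizontal
  axis, clusters labelled by member letters, standard alphabetical
  order.

## Known limitations

* Only the identity alphabet ships; results under reduced profiles
  depend entirely on user-supplied memberships.
* The discriminant weights are a linear read-out of a nonlinear model;
  ranks are meaningful, magnitudes are not calibrated.
* Jackknife is O(N) SVM fits and is meant for benchmark-sized sets
  (~10³ sequences), not proteome scans.
* The PDB 1HLV chain-A case study needs the real sequence supplied by
  the user (`data/1HLV_A.fasta`); it is not redistributable here.
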