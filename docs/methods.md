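# Methods

## Model and procedure

A PSM table carries one best-ranked peptide-spectrum match per spectrum
with six quality features: Xcorr, ΔCn, ΔM (signed precursor mass deviation,
ppm), SpRank, the fraction of matched fragment ions, and a retention-time
p-value. Decoy status is derived from the protein accession (configurable
prefix, default `REV_`); the phosphopeptide flag from `S[p]`/`T[p]`/`Y[p]`
annotations in the peptide string. Records are split into strata by
phospho-status × precursor charge; only charges +2 and +3 are kept (others
are counted and dropped), because score distributions differ strongly
across these cells and each stratum is calibrated on its own decoys.

**Estimator.** For an acceptance rule passing N_T PSMs of which D_T are
decoys, the false discovery rate of the N_T − D_T accepted targets is
estimated as FDR̂ = D_T/(N_T − D_T). This is valid exactly when wrong
matches hit targets and decoys with equal probability. The FDR of an empty
selection is defined as 0; a selection containing only decoys has no
defined FDR and is treated as infeasible.

**Discriminator.** Per stratum, a feed-forward network with one hidden
layer and two sigmoid output nodes (one per class) is trained to separate
decoy (0) from non-decoy (1) hits by classical stochastic backpropagation:
squared-error loss against one-hot targets, per-example updates
Δw = η·δ·x + μ·Δw_prev, momentum μ = 0.2, initial weights uniform on
[−0.5, 0.5], example order reshuffled every epoch from the run's seeded
generator. Six runs per stratum use
(hidden, η, epochs) = (4, 0.1, 1000), (4, 0.2, 1000), (4, 0.3, 1000),
(5, 0.1, 2000), (5, 0.2, 2000), (5, 0.3, 2000); run *i* uses seed
base_seed + i. Training is bit-deterministic given data and seed. The
discriminant probability of a PSM being genuine is P = o₁/(o₀ + o₁), the
normalised pair of output activations — the simplest convention that keeps
P ∈ [0, 1] with P = 0.5 when the two nodes tie. The model is deliberately
applied to its own training data: the goal is to separate correct from
incorrect hits in *this* dataset, not to generalise, so no cross-validation
is performed (see Limitations).

Features are standardised per stratum to zero mean and unit variance;
SpRank is log(1+rank)-transformed first because its raw scale is
heavy-tailed; constant columns map to zeros. No class rebalancing is
applied despite decoy/target imbalance.

**Calibration.** Candidate cutoffs are the distinct probabilities plus a
sentinel below all of them; acceptance is strict (P > θ). The chosen cutoff
maximises accepted targets subject to FDR̂ ≤ ε globally (the estimate is
not monotone in θ, so first-crossing search would be wrong); ties break
toward smaller FDR̂, then higher θ. An infeasible ε yields an empty
acceptance with θ = 1 rather than an error, which the ε = 0 first pass
relies on. The ROC curve (decoys negative, trapezoidal AUC) is computed for
diagnostics only; selection uses decoy counts, since the decoy-based FPR
and the FDR of the accepted set are different quantities. Among the six
runs the most sensitive result is reported (ties: smaller FDR̂, then lower
run index). Optionally the runs are merged: targets accepted by any run and
decoys above any run's cutoff are pooled by spectrum id with their maximum
per-run probability, FDR̂ is re-estimated on the pool, and while it exceeds
ε the pooled record with the lowest maximum probability is removed
(dropping low-probability decoys is what restores the bound; removal order
is deterministic, ties by spectrum id).

**Retention time.** A first pass at ε = 0 on the five search-engine
features yields near-certain identifications. Their unmodified sequences
(duplicates collapsed to the mean observed RT) train a linear model of RT
on the twenty amino-acid counts plus sequence length. Length equals the sum
of the counts, so the design is rank-deficient by construction; the fit
therefore applies a minimal ridge penalty (1e-6) to all non-intercept
coefficients, and the identifiable quantities are the per-residue effective
coefficients (count + length) and the predictions. The residual scale is
√(SSR/(n − rank)). Each PSM's sixth feature is the two-sided Gaussian tail
probability of its studentised residual, p = erfc(|z|/√2), floored at
1e-300; a zero residual scale degenerates to p = 1 at zero deviation and
the floor otherwise. Strata whose first pass yields fewer than 10 unique
peptides degrade to the five-feature path with a warning — mirroring the
practice of discarding datasets with fewer than 10 correct assignments —
rather than aborting. RT prediction is a pluggable component behind this
module boundary; any sequence-to-seconds regressor (e.g. a kernel SVR)
could be substituted, as only the deviation p-value is consumed
downstream.

**BIDE baseline.** The classical uni/bivariate decoy analysis is provided
for comparison: exhaustive search over all observed cutoffs of one or two
features, maximising accepted targets under FDR̂ ≤ ε. Cutoff direction per
feature: lower bounds on Xcorr, ΔCn, matched-ion fraction and RT p-value
(small p = suspicious deviation); upper bounds on SpRank and |ΔM|.
Restricting candidates to observed values loses no optima because the
accepted set is constant between them. Ties break toward fewer accepted
decoys, then the stricter primary-feature cutoff.

## Synthetic data

The generator produces the statistical structure the estimator assumes,
with ground-truth labels that never enter the written table. Each stratum
is a three-part mixture: correct targets from a "good-score" multivariate
Gaussian; incorrect targets and decoys drawn i.i.d. from a shared
"bad-score" Gaussian (this shared draw *is* the exchangeability assumption,
and the suite verifies it by two-sample KS tests); latent features
(xcorr, ΔCn, ion fraction, ΔM, log SpRank) are clipped/rounded into their
legal ranges. Defaults, chosen once to mimic a typical phosphoproteomics
search: 18% of target PSMs correct ("usually less than 20%"), 45% of rows
decoys (so decoy and incorrect-target counts nearly coincide, the regime
the estimator assumes), moderate signal on every feature with no single
feature separating on its own, correlation 0.3 among the three ion-quality
scores. Phospho strata shift the correct component's score means down by
0.5 component standard deviations (phosphopeptide spectra score lower).
Peptides are tryptic-like (7–25 residues, C-terminal K/R, ≥ 1 annotated
phospho-site in phospho strata). Correct hits elute at a linear
composition model (hydrophobicity-like per-residue seconds, length
coefficient 12 s, intercept 400 s) plus Gaussian noise (σ = 60 s) inside a
3600 s run; wrong hits elute uniformly. Decoy counts per stratum are fixed
at round(n × fraction) for reproducible arithmetic.

What the generator does **not** emulate: discrete/heteroscedastic score
artefacts of real search engines, charge-dependent feature shifts beyond
stratum separation, shared peptides between spectra, correlated wrongness
(e.g. near-miss sequences), or chromatographic drift. Passing tests
therefore show the machinery is correct under the model's own assumptions,
not that real SEQUEST output will behave identically.

## Validation design and problem sizes

Deterministic components are tested against independent brute-force
oracles: exhaustive enumeration for the FDR arithmetic (all 0 ≤ d < n ≤
200), per-record re-checks for threshold filtering, full cutoff-grid
enumeration for the BIDE search (n ≤ 30) and the probability sweep
(n ≤ 100). The twelve-PSM worked example fixes the 3-vs-5 filtering
counts. Network capacity is checked on separable and XOR-arranged Gaussian
clusters (a linear boundary cannot exceed chance on the latter); a scorer
trained on pure noise must rank *held-out* draws at chance AUC.
End-to-end FDR calibration is measured on two charge strata of 5000 PSMs
across ten seeds at ε = 0.01 and 0.05 in the five-feature mode, pooling
accepted counts over seeds and comparing realized wrong-hit fractions with
ε at three binomial standard errors; the sensitivity comparisons
(six-run protocol vs BIDE; six vs five features) use single strata of
1000 PSMs, ten seeds, medians at ε = 0.01. The acceptance script uses a
2000-PSM stratum.

## Known limitations

* **The decoy estimate of the self-scored network is anti-conservative.**
  Because each run scores the very PSMs it was trained on, training nudges
  individual decoys (label 0) below incorrect targets (label 1) even though
  the two are statistically identical; the decoy count above the chosen
  cutoff then undercounts wrong target hits exactly where calibration
  happens. The included calibration check measures realized FDRs of
  roughly three to four times the nominal ε = 0.01 (and ~2.5× at ε = 0.05)
  under the default generator, while a label-blind score passes the same
  check — so the bias is attributable to self-scoring, not to the sweep.
  Training accuracy stays near 56–60%, i.e. this is margin-level
  displacement, not gross overfitting; min-max input scaling and the
  pooled-decoy merge shrink but do not remove it. The standard remedy —
  cross-fitting, scoring each PSM with a model trained on the other folds —
  contradicts this method's deliberate train-on-self design and is not
  applied; treat reported FDR̂ as optimistic by a small integer factor at
  tight ε, or rerun with a stricter ε.
* Sensitivity claims are medians over synthetic replicates; single-seed
  comparisons can go either way.
* The RT model is composition-only (no positional or modification effects)
  and the p-value assumes Gaussian residuals; modified residues are
  stripped before prediction.
* Only the single reported best hit per spectrum is handled; protein-level
  inference, q-values per PSM and search-engine file formats are out of
  scope.

## Numerical conventions

Empty-selection FDR = 0. Accept-all calibration threshold reported as −1
(any value below the minimum probability); infeasible ε reported as
threshold 1 with empty acceptance. ε = 0 means exactly zero decoys above
threshold. Ridge penalty 1e-6 on the RT fit's non-intercept coefficients,
solved as an augmented least-squares system for numerical stability;
p-value floor 1e-300. Stratum seeds advance in steps of 101 from the base
seed so no two strata share run seeds; all seeds are reduced mod 2³¹. The
training inner loop is JIT-compiled (numba) with a pure-Python fallback
exercised in the test suite.
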