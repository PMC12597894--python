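# Methods

## Scope and model

`tdbench` benchmarks the machine-learning stage of target–decoy peptide
identification: given a table of precursor rows with numeric sub-scores and
target/decoy labels, a *discriminator* is trained and its scores are turned
into decoy-based q-values. The package implements three training frameworks
× four classifier families, two error estimates (reported, i.e. decoy-based,
and external, i.e. entrapment-based), a mutation-based decoy sequence
generator, and a synthetic table generator with known ground truth.

## Error estimation

**Reported FDR / q-values.** At threshold *s*, `FDR̂(s) = D(s) / max(1, T(s))`
with `D`/`T` the decoy/target counts at or above *s*; a target's q-value is
the minimum `FDR̂` over all thresholds that accept it. The plain ratio (no +1
pseudo-count, no π₀ correction) is the estimator appropriate to the 1:1
target:decoy design; a `pseudocount` option exists, default off. Thresholds
run over distinct score values, so tied rows are accepted as blocks and
decoys tied with targets count against them. The implementation is exact:
it is tested for bit-identical agreement with an O(n²) brute-force double
loop on random instances, ties included.

**External FDR.** Among accepted targets, the fraction flagged as entrapment
(a foreign-proteome peptide searched as a target). No database-size scaling
is applied by default — the plain ratio is a lower bound on the FDP whenever
entrapment hits behave like the other false hits; a `scale` factor is
available. An empty accepted set yields 0 (logged). Identification counts
exclude entrapment hits (an entrapment hit is not a desired identification);
the calibration curve reports the non-entrapment count per grid point.

**Calibration curve.** Reported-FDR grid 1%–5% in 0.5% steps (9 points) by
default; each point records the external FDR of the accepted set and the
identification count. `ids_at_external_fdr` instead sweeps raw score
thresholds and returns the best identification count whose accepted set
keeps the entrapment ratio under the level (default 1%).

## Classifier families

All families standardize features with training-set mean/sd; the scaler is
stored in the model, so no test statistics leak in. Downstream q-values
depend only on score *rank order*, so each family may emit its natural link
(signed distance, margin, probability).

| family | implementation | defaults |
|---|---|---|
| `lda` | pooled-covariance LDA, eigen solver | shrinkage 1e-6 (rank safety) |
| `svm` | linear hinge-loss SVM | C = 1 |
| `gbt` | XGBoost, margin output | 100 rounds, depth 6, lr 0.1, subsample 1.0 |
| `mlp_ensemble` | bagged sklearn MLPs | 12 members, hidden 25-20-15-5, logistic, each on a per-class random half, mean member probability |

The MLP ensemble follows the DIA-NN-style design (many small networks,
averaged); its exact production settings are not public, so every number
here is an explicit, configurable default of this package. `epochs` counts
Adam passes for MLP members and is noted-and-ignored by the closed-form /
convex / fixed-schedule families. GBT margins (not probabilities) are used
as scores because heavily overfit probabilities saturate at 1.0 and would
create artificial ties. `gbt` and `mlp_ensemble` are seeded and reproducible
(bit-for-bit for trees, to numerical tolerance for the ensemble).

## Training frameworks

**Semi-supervised** (`n_iterations=10`, `q_init=0.15`, `q_learn=0.02`):
initialization picks the single (column, sign) maximizing targets at
q ≤ `q_init`; each iteration refits from scratch on targets with current
q ≤ `q_learn` vs all decoys, rescores everything, recomputes q. The loop
constants follow the established semi-supervised rescoring convention; all
are config keys. An empty positive set raises a collapse error with the
iteration index. Note that once the positive set saturates near the true
target count it can jitter by a few rows between refits; growth, not strict
monotonicity, is the expected behaviour.

**Fully supervised** (`epochs=1`): one fit, all targets positive, scores
everything. The single-epoch default is part of the design (the conventional
guard against full train/test overlap); overriding it is allowed and logged.

**K-fold** (`n_folds=5`): rows — targets *and* decoys — are split by a
seeded label-stratified shuffle; each row is scored only by the model that
never saw it. With 5 folds each training partition holds exactly 80% of the
targets. Decoys are scored out-of-fold by default; `decoy_scoring=
"ensemble_mean"` instead averages all K models on decoy rows (a reading in
which every model may score every decoy). Because the K models emit
discriminants on slightly different scales, each fold's scores are
standardized on that fold's decoy distribution before pooling
(`fold_normalization="decoy_zscore"`); this affine map preserves within-fold
ranks and aligns the null across folds — without it, fold-to-fold offset
noise mixes the acceptance boundary and costs recovery. `"none"` restores
raw pooling. The fitted rescorer exposes `fold_assignment_`, `scored_by_`
and `leakage_pairs()` for an explicit audit that no row was scored by a
model trained on it.

Seed derivation is shared across frameworks (`SeedSequence([seed, k])`), so
one semi-supervised iteration with every target confidently positive
reproduces the fully supervised fit exactly — a reduction the tests exploit.
Epochs default to 10 for the semi-supervised and K-fold frameworks (their
multi-epoch capability is the point of comparing them) and 1 for fully
supervised.

## Synthetic data

One generated table holds `n_targets` targets and as many decoys. Each
target is genuine with probability `pi_true`; genuine rows add
`effect_size` (default 3) null standard deviations to the first
`n_informative` (default 10) of `n_features` (default 50) coordinates. All
null rows — decoys, false targets, entrapment targets — share an
equicorrelated Gaussian (one-factor construction, ρ = `feature_correlation`,
default 0.2; Student-t tails via `tail_df` for robustness checks, rescaled
to unit variance). A fraction `entrap_frac` (default 0.45, mirroring the
typical size ratio of an entrapment library to a human target library) of
the *false* target population carries the entrapment flag. Because
entrapment rows and false targets are drawn from the same null, the
entrapment FDR estimates `entrap_frac × FDP` — a faithful lower bound, as
in real entrapment experiments. Sequences, when requested, are
uniform-random peptides of length 7–30 with mutation-scheme decoys.

Presets fix the scale/signal regimes: `qc_like` (20 000 targets,
π = 0.6), `highthroughput_like` (10 000, 0.4), `plasma_like` (3 000, 0.2),
`singlecell_like` (2 000, 0.15). Small, null-heavy tables are the regime
where train-on-test frameworks overfit most visibly.

**What the generator does not emulate:** real sub-scores are non-Gaussian,
heteroscedastic, and nonlinearly dependent; decoy score vectors are only
approximately exchangeable with false targets; retention-time and
deep-learning similarity scores have bounded supports. Passing tests
therefore certify the *logic* of the frameworks and estimators (leakage
freedom, calibration, the overfitting mechanism), not engine performance on
real data. In particular, on Gaussian nulls with a mean-shift signal the LDA
direction is Bayes-optimal, so the classifier-family *ranking* observed on
real data (MLP > GBT > SVM/LDA) is not reproducible here by construction;
the package asserts comparable recovery across families under K-fold
instead of an ordering.

## Problem sizes and numerical choices

The test suite and the acceptance script run the overfitting contrast on
ten replicate `singlecell_like` tables (2 000 targets, π = 0.15, 50
features) — small enough to finish in minutes on one CPU while keeping
hundreds of accepted rows per replicate; the contrast is asserted
directionally (calibrated in ≥ 9/10 for K-fold+MLP, overfit in ≥ 5/10 for
fully-supervised+GBT), never by magnitude, since the external FDR at a 1%
acceptance involves single-digit entrapment counts and is Poisson-noisy.
Ties in q-value computation are handled as blocks; ties in
`select_initial_direction` break toward the lowest column index, +1 before
−1. Non-finite score cells are imputed with the column median of finite
values (deterministic and scale-robust); all-missing columns are dropped
with a warning. TSV floats are written at `repr` precision and parsed with
correctly-rounded conversion, so write→read round-trips are exact.

## Known limitations

* Real engine reports with per-run score scales, missing-value structure or
  PSM-level redundancy need upstream normalization beyond the column map.
* The semi-supervised loop retrains from scratch each iteration; warm-start
  variants are not implemented.
* No protein-level inference, PEP/local FDR, or π₀ estimation.
* Runtime is recorded per benchmark cell as a diagnostic only.
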