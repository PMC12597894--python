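# tdbench

Benchmarking machine-learning discriminators for target–decoy peptide
identification.

## The problem

Peptide-centric identification engines (DIA and DDA alike) end with a
machine-learning step: a binary classifier — the *discriminator* — is trained
to separate target from decoy score vectors, its discriminant score re-ranks
every precursor, and decoy counts turn the ranking into q-values that drive
FDR control. Engines disagree on two design axes:

* **Training framework** — *semi-supervised* (iteratively expand a
  high-confidence positive set, predict everything), *fully supervised*
  (all targets positive, single epoch, predict everything), or *K-fold*
  (each row scored only by a model trained on the other folds).
* **Classifier family** — linear discriminant analysis (LDA), linear SVM,
  gradient-boosted trees (GBT/XGBoost), or an ensemble of small multilayer
  perceptrons (MLPs).

The first two frameworks train and test on the same rows. If the classifier
is expressive enough to memorize, the decoys it trained on score low, the
reported (decoy-based) FDR collapses, and error control silently fails —
*overfitting*. Too-weak training costs identifications — *underfitting*.
`tdbench` measures both on any score table, real or synthetic.

## Core statistics

With a 1:1 target:decoy design, at score threshold *s*

```
reported FDR(s) = #decoys >= s / max(1, #targets >= s)
q(target) = min over thresholds t <= score(target) of reported FDR(t)
```

The *external* (actual) FDR uses entrapment targets — peptides from a foreign
proteome searched as targets, which can only be false hits:

```
external FDR = #entrapment hits / #all hits   (a lower bound on the FDP)
```

Plotting external vs reported FDR over a 1%–5% grid exposes overfitting
(points above the identity line) and underfitting (depressed identification
counts at matching calibration). Decoys are generated 1:1 from targets by
mutating the two terminal-adjacent residues (positions 2 and L−1) with the
fixed pattern `GAVLIFMPWSCTYHKRQEND → LLLVVLLLLTSSSSLLNDQE`.

## Worked example

```python
import tdbench as tb

config = tb.dataset_presets("singlecell_like", seed=11)
table, truth = tb.generate_table(config)
print(f"{len(table)} rows: {table.n_targets} targets "
      f"({truth.is_true_target.sum()} true, {table.entrapment.sum()} entrapment), "
      f"{table.n_decoys} decoys")

for name, rescorer in {
    "kfold + mlp_ensemble": tb.KFoldRescorer("mlp_ensemble", seed=5),
    "fully_supervised + gbt": tb.FullySupervisedRescorer("gbt", seed=5),
}.items():
    rescorer.fit_table(table)
    reported, external, n_ids = tb.calibration_curve(rescorer.qvalues_, table).at(0.01)
    accepted = table.is_target & (rescorer.qvalues_ <= 0.01)
    print(f"{name}: at reported FDR {reported:.0%} -> external FDR {external:.2%}, "
          f"{n_ids} identifications (true FDP {truth.fdp(accepted):.2%})")
```

prints

```
4000 rows: 2000 targets (314 true, 756 entrapment), 2000 decoys
kfold + mlp_ensemble: at reported FDR 1% -> external FDR 0.93%, 319 identifications (true FDP 2.48%)
fully_supervised + gbt: at reported FDR 1% -> external FDR 37.48%, 1221 identifications (true FDP 83.92%)
```

The K-fold MLP ensemble stays calibrated (external 0.93% at reported 1%) and
recovers essentially all 314 true targets. The fully supervised GBT memorizes
its decoys: the reported 1% threshold actually admits 84% false discoveries,
which the entrapment lower bound flags at 37%.

The rescorers are scikit-learn estimators (`fit(X, y)` with a boolean target
mask, fitted `scores_`/`qvalues_` attributes), so they compose with sklearn
tooling; `fit_table` is a convenience for `ScoreTable` objects, and the
functional wrappers `run_semi_supervised` / `run_fully_supervised` /
`run_kfold` mirror them.

## Command line

```sh
tdbench simulate --preset singlecell_like --seed 1 --out table.tsv
tdbench decoys --in peptides.txt --out pairs.tsv
tdbench bench --input demo=table.tsv --frameworks kfold,fully_supervised \
              --classifiers lda,svm,gbt,mlp_ensemble --seed 42 --out results/
```

`bench` writes a long-format `calibration.tsv` (one row per cell × grid
point), a `benchmark.json` summary, and optional calibration plots. Real
engine reports load through a YAML column map (`--column-map`) naming the
id/label/entrapment columns and the label vocabulary; all other columns are
treated as sub-scores.

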