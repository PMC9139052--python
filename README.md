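# ppidht

Sequence-based prediction of protein–protein interactions (PPIs) from
evolutionary conservation profiles.

Experimental PPI screens (yeast two-hybrid, tandem affinity purification,
mass spectrometry) are costly and noisy, so computational predictors that
need nothing but the two amino-acid sequences are widely used as a triage
tool. `ppidht` implements one such predictor end to end:

1. **Profile representation.** Each protein is an L×20 position-specific
   scoring matrix (PSSM): per-position log-odds scores over the 20 amino
   acids, as produced by PSI-BLAST. A substitution-matrix *pseudo-PSSM*
   (BLOSUM62 or PAM250 rows) is built in for running without PSI-BLAST.
2. **Hilbert-transform featurization.** The 2-D discrete Hilbert transform
   (DHT) — the linear filter with frequency response −j·sgn(Ω), applied
   separably along both PSSM axes — phase-shifts the conservation profile;
   the magnitudes of its 10 lowest sequence-frequency bins × 20 channel
   bins give a 200-value descriptor per protein, position-robust by
   construction. A pair descriptor is the concatenation: **400 features**.
3. **Rotation forest classification.** An ensemble of L CART trees, each
   trained on the data rotated by its own orthogonal block-diagonal matrix:
   the features are randomly split into K subsets, and each block is the
   full PCA basis of a 75% bootstrap of the training objects restricted to
   that subset. Class confidences are the mean of the tree posteriors,

   λ(x) = (1/L) Σᵢ dᵢ(x Rᵢ).

4. **Evaluation.** Stratified five-fold cross-validation reporting ACC,
   sensitivity, specificity, precision, MCC (per-fold and mean ± sd) and
   ROC/AUC.

A planted-signal synthetic-data generator makes every stage testable with
no downloads: positive pairs share a conservation motif injected into both
members' PSSMs at random positions, giving a known, tunable effect size.

## Worked example

```python
from ppidht import SyntheticDatasetSpec, gen_ppi_dataset, kfold_cv
from ppidht.dht_features import feature_matrix

spec = SyntheticDatasetSpec(n_pos=100, n_neg=100, signal_strength=1.0,
                            noise_sd=1.0, seed=42)
pssms, pairs = gen_ppi_dataset(spec)
X = feature_matrix(pssms, zip(pairs["id_a"], pairs["id_b"]))
y = pairs["label"].to_numpy()
report = kfold_cv(X, y, k=5, n_estimators=30, n_subsets=20, random_state=42)
print(report.to_table())
```

prints

```
Fold	ACC	Sen	Spec	PR	MCC	AUC
1	97.50	95.00	100.00	100.00	95.12	0.9950
2	95.00	95.00	95.00	95.00	90.00	0.9938
3	95.00	95.00	95.00	95.00	90.00	0.9762
4	97.50	100.00	95.00	95.24	95.12	0.9962
5	97.50	95.00	100.00	100.00	95.12	0.9988
Average	96.50 ± 1.37	96.00 ± 2.24	97.00 ± 2.74	97.05 ± 2.70	93.07 ± 2.80	0.9920 ± 0.0090
```

Reading: 200 balanced pairs with a weak planted conservation shift (1 score
unit against unit noise) are still almost perfectly separated — each fold
row gives the held-out accuracy, sensitivity, specificity, precision and
MCC as percentages (MCC on the ×100 convention) and AUC as a fraction; the
Average row is mean ± sample standard deviation across the five folds.

The same classifier composes with scikit-learn directly:

```python
from ppidht import RotationForestClassifier
from sklearn.model_selection import cross_val_score
cross_val_score(RotationForestClassifier(random_state=0), X, y, cv=5)
```

## Command line

```sh
ppidht synth   --out data/ --n-pos 500 --n-neg 500 --seed 1   # FASTA + PSSMs + pairs.tsv
ppidht extract --pssm-dir data/pssms --pairs data/pairs.tsv --out features.tsv
ppidht train   --features features.tsv --out model.joblib -L 30 -K 20 --seed 1
ppidht predict --model model.joblib --features features.tsv --out preds.tsv
ppidht cv      --features features.tsv --out-dir cv/ --seed 1
```

`extract` also accepts `--fasta` to fall back to pseudo-PSSMs for proteins
without a PSI-BLAST profile. Every output embeds the seed and a hash of the
effective configuration, and identical invocations produce byte-identical
artifacts.

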