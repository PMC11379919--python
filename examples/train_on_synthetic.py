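"""Train and evaluate the full pipeline on synthetic data with a planted motif.

Generates a balanced two-class set (motif GACU planted at position 19 of every
positive), runs 10-fold cross-validation of the complete pipeline (propensity
fitting, encoding, SHAP top-64 selection and the gradient-boosted classifier
are all refit inside each fold), then fits a final model on an 80% partition
and scores the held-out 20%. High accuracy/MCC here means the pipeline
recovers a position-specific signal; on a motif_prob=0 null the same numbers
sit at chance.
"""

import hmckit as hk

pos, neg = hk.generate(
    hk.SyntheticConfig(n_pos=200, n_neg=200, L=41, motif="GACU",
                       motif_position=19, motif_prob=1.0, seed=1)
)

report = hk.run_cv(pos, neg, cv_cfg=hk.CvConfig(n_folds=10, seed=1))
print("10-fold cross-validation (mean row = averaged over folds):")
print(report.to_dataframe().round(4).to_string())

(train_pos, train_neg), (test_pos, test_neg) = hk.stratified_split(pos, neg)
model = hk.train_final(train_pos, train_neg)
df_pos, df_neg = hk.predict(model, test_pos), hk.predict(model, test_neg)
acc = ((df_pos.label == 1).sum() + (df_neg.label == 0).sum()) / (len(df_pos) + len(df_neg))
print(f"\nindependent 20% test accuracy: {acc:.4f} "
      f"({len(df_pos)}+{len(df_neg)} held-out sequences)")
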