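"""Reproduce the published 5hmC benchmark protocol on user-supplied FASTA files.

The balanced 1324-sequence benchmark (662 positives / 662 negatives,
pre-deduplicated) must be downloaded separately:
https://github.com/salman-khan-mrd/5HMC-2

Given the two FASTA files, this script runs the full published protocol:
an 80/20 stratified split, 10-fold cross-validation of the pipeline on the
training partition, a final model fit, and independent-test metrics, plus the
baseline-classifier comparison on identical folds. Published headline numbers
are at the ~90% accuracy level; exact agreement is not expected because the
original encoder parameters (mismatch k/m, DAC index set and lags) are not
fully specified.

Usage: python examples/reproduce_benchmark.py 5hmC.fasta non5hmC.fasta
"""

import sys

import numpy as np

import hmckit as hk


def main(pos_path: str, neg_path: str, seed: int = 42) -> None:
    pos = hk.validate_set(hk.read_fasta(pos_path, "positive", ambiguity_policy="drop"))
    neg = hk.validate_set(hk.read_fasta(neg_path, "negative", ambiguity_policy="drop"))
    print(f"loaded {len(pos)} positives, {len(neg)} negatives, L={pos.length}")

    (tr_pos, tr_neg), (te_pos, te_neg) = hk.stratified_split(
        pos, neg, hk.SplitConfig(seed=seed)
    )
    report = hk.run_cv(tr_pos, tr_neg, cv_cfg=hk.CvConfig(n_folds=10, seed=seed))
    print("\n10-fold CV on the training partition:")
    print(report.to_dataframe().round(4).to_string())

    model = hk.train_final(tr_pos, tr_neg)
    df_p, df_n = hk.predict(model, te_pos), hk.predict(model, te_neg)
    y = np.concatenate([np.ones(len(df_p), int), np.zeros(len(df_n), int)])
    prob = np.concatenate([df_p.probability, df_n.probability])
    rep = hk.metrics(
        hk.confusion(y, (prob >= 0.5).astype(int)), auc=hk.roc_auc(y, prob)
    )
    print("\nindependent test:", {k: round(v, 4) for k, v in rep.as_dict().items()})

    print("\nbaseline comparison (10-fold, shared folds and selected features):")
    baselines = hk.run_baselines(tr_pos, tr_neg, cv_cfg=hk.CvConfig(n_folds=10, seed=seed))
    for name, rep in baselines.items():
        print(f"  {name:8s}", {k: round(v, 4) for k, v in rep.mean.as_dict().items()})


if __name__ == "__main__":
    if len(sys.argv) < 3:
        sys.exit(__doc__)
    main(sys.argv[1], sys.argv[2])
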