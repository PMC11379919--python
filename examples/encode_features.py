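"""Encode a tiny RNA sequence set with all five feature blocks and fuse them.

Builds a 10+10 synthetic pair, fits the position-specific trinucleotide
propensity table on it, and prints the shape and first labels of every block.
The fused width is 64 (mismatch k-mer profile) + 16 (skip-dinucleotide
composition) + 6 (auto-covariance: 3 thermodynamic indices x 2 lags) + L
(accumulated frequencies) + L-2 (propensity lookups).
"""

import hmckit as hk

pos, neg = hk.generate(hk.SyntheticConfig(n_pos=10, n_neg=10, L=41, seed=0))
model = hk.fit_pstnpss(pos, neg)

blocks = [
    hk.encode_mismatch(pos),
    hk.encode_asdc(pos),
    hk.encode_dac(pos),
    hk.encode_anf(pos),
    hk.transform_pstnpss(model, pos),
]
for b in blocks:
    print(f"{b.name:6s} {b.matrix.shape}  first labels: {b.column_labels[:3]}")

hybrid = hk.fuse(blocks)
print(f"fused  {hybrid.matrix.shape}  ({hybrid.n_features} columns in MisM|ASDC|DAC|ANF|PSTNP order)")
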