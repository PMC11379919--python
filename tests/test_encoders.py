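import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_set
from hmckit.encoders import (
    DINUCLEOTIDES,
    TRINUCLEOTIDES,
    DacConfig,
    FeatureBlock,
    MismatchConfig,
    PhysicochemicalTable,
    PstnpssModel,
    encode_anf,
    encode_asdc,
    encode_dac,
    encode_mismatch,
    fit_pstnpss,
    fuse,
    load_default_index_table,
    transform_pstnpss,
)
from hmckit.sequence_io import SequenceRecord, SequenceSet

rna_seq = st.text(alphabet="ACGU", min_size=5, max_size=30)


def sset(*seqs: str) -> SequenceSet:
    return SequenceSet([SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)])


# ---------------------------------------------------------------------------
# Mismatch profile
# ---------------------------------------------------------------------------

def mismatch_oracle(seq: str, k: int, m: int) -> np.ndarray:
    """Brute force: for each k-mer, count windows within Hamming distance m."""
    kmers = ["".join(p) for p in itertools.product("ACGU", repeat=k)]
    windows = [seq[i : i + k] for i in range(len(seq) - k + 1)]
    out = np.zeros(4**k)
    for t, kmer in enumerate(kmers):
        out[t] = sum(
            1 for w in windows if sum(a != b for a, b in zip(w, kmer)) <= m
        )
    return out


class TestMismatch:
    def test_exact_counting_homopolymer(self):
        block = encode_mismatch(sset("AAAA"), MismatchConfig(k=3, m=0))
        vec = dict(zip(block.column_labels, block.matrix[0]))
        assert vec["MisM:AAA"] == 2
        assert sum(vec.values()) == 2

    def test_one_mismatch_homopolymer_mass(self):
        block = encode_mismatch(sset("AAAA"), MismatchConfig(k=3, m=1))
        vec = block.matrix[0]
        # every k-mer within Hamming 1 of AAA is hit by both windows
        labels = block.column_labels
        for t, lab in enumerate(labels):
            kmer = lab.split(":")[1]
            dist = sum(c != "A" for c in kmer)
            assert vec[t] == (2 if dist <= 1 else 0)
        assert vec.sum() == 2 * (1 + comb(3, 1) * 3)  # 20

    def test_m0_equals_exact_spectrum(self, rng):
        s = random_set(rng, 5, 20)
        block = encode_mismatch(s, MismatchConfig(k=3, m=0))
        for r, rec in enumerate(s.records):
            assert np.array_equal(block.matrix[r], mismatch_oracle(rec.sequence, 3, 0))
            assert block.matrix[r].sum() == 20 - 3 + 1

    @given(rna_seq, st.integers(2, 4), st.integers(0, 2))
    def test_matches_bruteforce_oracle(self, seq, k, m):
        if m >= k or k > len(seq):
            return
        block = encode_mismatch(sset(seq), MismatchConfig(k=k, m=m))
        assert np.array_equal(block.matrix[0], mismatch_oracle(seq, k, m))

    @given(rna_seq)
    def test_mass_conservation_and_monotonicity(self, seq):
        k = 3
        if len(seq) < k:
            return
        prev = None
        n_win = len(seq) - k + 1
        for m in range(k):
            vec = encode_mismatch(sset(seq), MismatchConfig(k=k, m=m)).matrix[0]
            expected_mass = n_win * sum(comb(k, j) * 3**j for j in range(m + 1))
            assert vec.sum() == expected_mass
            if prev is not None:
                assert np.all(vec >= prev)
            prev = vec

    def test_k_exceeding_length_rejected(self):
        with pytest.raises(ValueError):
            encode_mismatch(sset("ACG"), MismatchConfig(k=4, m=0))

    def test_invalid_budget_rejected(self):
        with pytest.raises(ValueError):
            MismatchConfig(k=3, m=3)

    def test_normalize_flag_divides_by_windows(self):
        raw = encode_mismatch(sset("ACGUACGU"), MismatchConfig(k=3, m=1))
        frac = encode_mismatch(sset("ACGUACGU"), MismatchConfig(k=3, m=1, normalize=True))
        assert np.allclose(frac.matrix, raw.matrix / 6)


# ---------------------------------------------------------------------------
# ANF
# ---------------------------------------------------------------------------

class TestAnf:
    def test_worked_example(self):
        vec = encode_anf(sset("UCGUUCAUGG")).matrix[0]
        assert np.allclose(
            np.round(vec, 2), [1, 0.5, 0.33, 0.5, 0.6, 0.33, 0.14, 0.5, 0.22, 0.3]
        )

    def test_homopolymer_density_one(self):
        assert np.array_equal(encode_anf(sset("AAAA")).matrix[0], [1, 1, 1, 1])

    def test_all_distinct_gives_reciprocal(self):
        assert np.allclose(encode_anf(sset("ACGU")).matrix[0], [1, 1 / 2, 1 / 3, 1 / 4])

    @given(rna_seq)
    def test_exactness_and_range(self, seq):
        vec = encode_anf(sset(seq)).matrix[0]
        assert vec[0] == 1.0
        assert np.all((vec > 0) & (vec <= 1))
        # d at the n-th occurrence position p of residue q equals n/p
        seen: dict[str, int] = {}
        for p, q in enumerate(seq, start=1):
            seen[q] = seen.get(q, 0) + 1
            assert vec[p - 1] == pytest.approx(seen[q] / p)


# ---------------------------------------------------------------------------
# PSTNPss
# ---------------------------------------------------------------------------

class TestPstnpss:
    def test_identical_classes_zero(self, rng):
        s = random_set(rng, 10, 9)
        model = fit_pstnpss(s, s)
        assert np.array_equal(model.z, np.zeros((64, 7)))

    def test_single_sequence_classes(self):
        model = fit_pstnpss(sset("AAA"), sset("CCC"))
        z = model.z
        assert z.shape == (64, 1)
        i_aaa = TRINUCLEOTIDES.index("AAA")
        i_ccc = TRINUCLEOTIDES.index("CCC")
        assert z[i_aaa, 0] == 1 and z[i_ccc, 0] == -1
        mask = np.ones(64, bool)
        mask[[i_aaa, i_ccc]] = False
        assert np.all(z[mask] == 0)

    def test_transform_lookup(self):
        model = fit_pstnpss(sset("AAA"), sset("CCC"))
        assert transform_pstnpss(model, sset("AAA")).matrix[0] == [1.0]
        assert transform_pstnpss(model, sset("CCC")).matrix[0] == [-1.0]

    def test_zero_model_zero_features(self, rng):
        s = random_set(rng, 8, 9)
        model = PstnpssModel(z=np.zeros((64, 7)), L=9)
        assert not transform_pstnpss(model, s).matrix.any()

    def test_column_sums_zero_and_range(self, rng):
        pos, neg = random_set(rng, 15, 12), random_set(rng, 11, 12)
        z = fit_pstnpss(pos, neg).z
        assert np.allclose(z.sum(axis=0), 0, atol=1e-9)
        assert np.all((z >= -1) & (z <= 1))

    def test_antisymmetry(self, rng):
        pos, neg = random_set(rng, 15, 12), random_set(rng, 11, 12)
        assert np.array_equal(fit_pstnpss(pos, neg).z, -fit_pstnpss(neg, pos).z)

    def test_transformed_training_values_in_range(self, rng):
        pos, neg = random_set(rng, 15, 12), random_set(rng, 11, 12)
        model = fit_pstnpss(pos, neg)
        feats = transform_pstnpss(model, pos).matrix
        assert np.all((feats >= -1) & (feats <= 1))

    def test_errors(self, rng):
        pos = random_set(rng, 5, 9)
        with pytest.raises(ValueError):
            fit_pstnpss(pos, SequenceSet([]))
        with pytest.raises(ValueError):
            fit_pstnpss(pos, random_set(rng, 5, 10))
        model = fit_pstnpss(pos, random_set(rng, 5, 9))
        with pytest.raises(ValueError):
            transform_pstnpss(model, random_set(rng, 3, 8))


# ---------------------------------------------------------------------------
# ASDC
# ---------------------------------------------------------------------------

def asdc_oracle(seq: str) -> np.ndarray:
    out = np.zeros(16)
    L = len(seq)
    for p in range(L):
        for q in range(p + 1, L):
            out[DINUCLEOTIDES.index(seq[p] + seq[q])] += 1
    return out / (L * (L - 1) / 2)


class TestAsdc:
    def test_single_pair(self):
        vec = dict(zip(*(lambda b: (b.column_labels, b.matrix[0]))(encode_asdc(sset("AA")))))
        assert vec["ASDC:AA"] == 1 and sum(vec.values()) == 1

    def test_three_residues(self):
        block = encode_asdc(sset("ACG"))
        vec = dict(zip(block.column_labels, block.matrix[0]))
        assert vec["ASDC:AC"] == vec["ASDC:CG"] == vec["ASDC:AG"] == pytest.approx(1 / 3)

    @given(rna_seq)
    def test_simplex_and_oracle(self, seq):
        vec = encode_asdc(sset(seq)).matrix[0]
        assert np.all(vec >= 0)
        assert vec.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(vec, asdc_oracle(seq), atol=1e-12)


# ---------------------------------------------------------------------------
# DAC
# ---------------------------------------------------------------------------

def dac_oracle(seq: str, table: PhysicochemicalTable, lag_max: int) -> np.ndarray:
    """Direct double-loop evaluation of the lagged auto-covariance."""
    L = len(seq)
    out = []
    for u in range(len(table.indices)):
        vals = np.array(
            [table.values[u, DINUCLEOTIDES.index(seq[i : i + 2])] for i in range(L - 1)]
        )
        mean = vals.mean()
        for lag in range(1, lag_max + 1):
            total = 0.0
            for i in range(L - 1 - lag):
                total += (vals[i] - mean) * (vals[i + lag] - mean)
            out.append(total / (L - lag - 1))
    return np.array(out)


class TestDac:
    def test_constant_index_vanishes(self):
        table = PhysicochemicalTable(indices=["const"], values=np.full((1, 16), 3.7))
        block = encode_dac(sset("ACGUACGUA"), DacConfig(lag_max=2, table=table))
        assert np.allclose(block.matrix, 0)

    def test_homopolymer_vanishes(self):
        block = encode_dac(sset("A" * 12), DacConfig(lag_max=2))
        assert np.allclose(block.matrix, 0)

    def test_hand_worked_toy(self):
        values = np.zeros((1, 16))
        values[0, DINUCLEOTIDES.index("AC")] = 1
        values[0, DINUCLEOTIDES.index("CG")] = 2
        values[0, DINUCLEOTIDES.index("GU")] = 3
        table = PhysicochemicalTable(indices=["toy"], values=values)
        block = encode_dac(sset("ACGU"), DacConfig(lag_max=1, table=table))
        # mean = 2; [(1-2)(2-2) + (2-2)(3-2)] / (4-1-1) = 0
        assert block.matrix[0, 0] == 0.0

    def test_matches_double_loop_oracle(self, rng):
        table = load_default_index_table()
        s = random_set(rng, 10, 20)
        block = encode_dac(s, DacConfig(lag_max=3, table=table))
        for r, rec in enumerate(s.records):
            assert np.allclose(
                block.matrix[r], dac_oracle(rec.sequence, table, 3), atol=1e-12
            )

    def test_lag_too_large_rejected(self):
        with pytest.raises(ValueError):
            encode_dac(sset("ACGU"), DacConfig(lag_max=3))

    def test_default_table_standardized(self):
        table = load_default_index_table()
        assert table.standardized
        assert np.allclose(table.values.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(table.values.std(axis=1), 1, atol=1e-9)


# ---------------------------------------------------------------------------
# Fusion / determinism
# ---------------------------------------------------------------------------

class TestFuse:
    def _blocks(self, rng, L=41):
        pos, neg = random_set(rng, 12, L, "positive"), random_set(rng, 12, L, "negative")
        model = fit_pstnpss(pos, neg)
        return [
            encode_mismatch(pos),
            encode_asdc(pos),
            encode_dac(pos),
            encode_anf(pos),
            transform_pstnpss(model, pos),
        ]

    def test_default_widths_at_L41(self, rng):
        hybrid = fuse(self._blocks(rng))
        # 64 (MisM) + 16 (ASDC) + 3*2 (DAC) + 41 (ANF) + 39 (PSTNP)
        assert hybrid.n_features == 64 + 16 + 6 + 41 + 39
        assert hybrid.column_labels[0].startswith("MisM:")
        assert hybrid.column_labels[-1].startswith("PSTNP:")

    def test_single_block_identity(self, rng):
        block = encode_mismatch(random_set(rng, 5, 10))
        hybrid = fuse([block])
        assert np.array_equal(hybrid.matrix, block.matrix)

    def test_permuted_order_rejected(self, rng):
        blocks = self._blocks(rng)
        with pytest.raises(ValueError):
            fuse(blocks[::-1])

    def test_row_mismatch_rejected(self, rng):
        blocks = self._blocks(rng)
        blocks[1] = FeatureBlock(
            "ASDC", blocks[1].matrix[:-1], blocks[1].column_labels
        )
        with pytest.raises(ValueError):
            fuse(blocks)

    def test_encoders_deterministic(self, rng):
        s = random_set(rng, 6, 15)
        for enc in (encode_mismatch, encode_asdc, encode_dac, encode_anf):
            a, b = enc(s).matrix, enc(s).matrix
            assert np.array_equal(a, b)
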