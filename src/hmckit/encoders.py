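"""Residue-based feature encoders and their serial fusion.

Five encoders turn a validated :class:`~hmckit.sequence_io.SequenceSet` into
column-labeled numeric blocks:

* **MisM** — k-mer mismatch profile: for every one of the 4^k k-mers, the
  number of length-k windows of the sequence within Hamming distance m of it
  (raw counts; m < k).
* **ANF** — accumulated nucleotide frequency: at each position i, the
  frequency of the residue s_i within the prefix s_1..s_i, divided by i.
* **PSTNPss** — position-specific trinucleotide propensity (single strand):
  the only *trained* encoder. Fitting builds a 64 x (L-2) matrix
  z[i, j] = F+(3mer_i | j) - F-(3mer_i | j) of per-position trinucleotide
  frequency differences between the positive and negative class; transforming
  a sequence looks up z at its own trinucleotide at each position.
* **ASDC** — adaptive skip dinucleotide composition: frequencies of the 16
  ordered residue pairs over *all* gaps 1..L-1, normalized to a probability
  vector over L(L-1)/2 position pairs.
* **DAC** — dinucleotide auto-covariance of physicochemical indices: for each
  index u and lag, the covariance of the per-dinucleotide index values at
  positions i and i+lag, centered on the sequence's own mean index value.

Fusion concatenates the blocks column-wise in the fixed order
MisM, ASDC, DAC, ANF, PSTNP.

Positions in column labels are 1-based. Trinucleotide and dinucleotide
orderings are lexicographic with A < C < G < U and are fixed, so column
labels are stable across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .sequence_io import ALPHABET, SequenceSet

FUSION_ORDER = ("MisM", "ASDC", "DAC", "ANF", "PSTNP")

DINUCLEOTIDES = ["".join(p) for p in itertools.product(ALPHABET, repeat=2)]
TRINUCLEOTIDES = ["".join(p) for p in itertools.product(ALPHABET, repeat=3)]

_CODE = {c: i for i, c in enumerate(ALPHABET)}


def _encode_codes(sset: SequenceSet) -> np.ndarray:
    """(n, L) int8 matrix of residue codes A=0, C=1, G=2, U=3."""
    n, L = len(sset), sset.length
    out = np.empty((n, L), dtype=np.int8)
    for r, rec in enumerate(sset.records):
        out[r] = [_CODE[c] for c in rec.sequence]
    return out


@dataclass
class FeatureBlock:
    """A named n_samples x d feature matrix with unique column labels."""

    name: str
    matrix: np.ndarray
    column_labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.matrix.shape[1] != len(self.column_labels):
            raise ValueError("column_labels length != matrix width")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"non-finite values in feature block {self.name!r}")
        if len(set(self.column_labels)) != len(self.column_labels):
            raise ValueError(f"duplicate column labels in block {self.name!r}")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]


@dataclass
class HybridMatrix:
    """The fused feature matrix with globally unique, block-prefixed labels."""

    matrix: np.ndarray
    column_labels: list[str]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# Mismatch profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MismatchConfig:
    """k-mer length and mismatch budget; m must be strictly less than k."""

    k: int = 3
    m: int = 1
    normalize: bool = False  # divide counts by the L-k+1 windows

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0 <= self.m < self.k):
            raise ValueError("mismatch budget requires 0 <= m < k")


def _kmer_digit_table(k: int) -> np.ndarray:
    """(4^k, k) base-4 digit expansion of every k-mer index."""
    idx = np.arange(4**k)
    digits = np.empty((4**k, k), dtype=np.int8)
    for pos in range(k - 1, -1, -1):
        digits[:, pos] = idx % 4
        idx = idx // 4
    return digits


def _mismatch_membership(k: int, m: int) -> np.ndarray:
    """Boolean (4^k, 4^k) matrix: Hamming(kmer_w, kmer_t) <= m."""
    digits = _kmer_digit_table(k)
    ham = (digits[:, None, :] != digits[None, :, :]).sum(axis=2)
    return ham <= m


def encode_mismatch(sset: SequenceSet, cfg: MismatchConfig | None = None) -> FeatureBlock:
    """Mismatch profile: per sequence, a 4^k vector of window counts.

    Entry t counts the windows (all L-k+1 of them) whose Hamming distance to
    k-mer t is at most m. With m=0 this is the exact k-mer spectrum. Counts
    are raw unless ``cfg.normalize``.
    """
    cfg = cfg or MismatchConfig()
    L = sset.length
    if cfg.k > L:
        raise ValueError(f"k={cfg.k} exceeds sequence length {L}")
    codes = _encode_codes(sset)
    n = len(sset)
    n_kmers = 4**cfg.k
    # window codes via positional weights
    weights = 4 ** np.arange(cfg.k - 1, -1, -1)
    n_win = L - cfg.k + 1
    win = np.zeros((n, n_win), dtype=np.int64)
    for j in range(cfg.k):
        win += codes[:, j : j + n_win].astype(np.int64) * weights[j]
    exact = np.zeros((n, n_kmers))
    for r in range(n):
        exact[r] = np.bincount(win[r], minlength=n_kmers)
    member = _mismatch_membership(cfg.k, cfg.m)
    counts = exact @ member  # symmetric membership: window w credits kmer t
    if cfg.normalize:
        counts = counts / n_win
    labels = ["".join(km) for km in itertools.product(ALPHABET, repeat=cfg.k)]
    labels = [f"MisM:{km}" for km in labels]
    return FeatureBlock(name="MisM", matrix=counts, column_labels=labels)


# ---------------------------------------------------------------------------
# Accumulated nucleotide frequency
# ---------------------------------------------------------------------------

def encode_anf(sset: SequenceSet) -> FeatureBlock:
    """ANF: d_i = (# occurrences of residue s_i in s_1..s_i) / i, for each i."""
    codes = _encode_codes(sset)
    n, L = codes.shape
    out = np.empty((n, L))
    for r in range(n):
        counts = np.zeros(4)
        for i in range(L):
            counts[codes[r, i]] += 1
            out[r, i] = counts[codes[r, i]] / (i + 1)
    labels = [f"ANF:pos{i}" for i in range(1, L + 1)]
    return FeatureBlock(name="ANF", matrix=out, column_labels=labels)


# ---------------------------------------------------------------------------
# Position-specific trinucleotide propensity (single strand)
# ---------------------------------------------------------------------------

@dataclass
class PstnpssModel:
    """Fitted 64 x (L-2) propensity matrix z (positive minus negative freq)."""

    z: np.ndarray
    L: int
    trinucleotide_order: tuple[str, ...] = tuple(TRINUCLEOTIDES)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (64, self.L - 2):
            raise ValueError("z must be 64 x (L-2)")


def _trinuc_codes(codes: np.ndarray) -> np.ndarray:
    """(n, L-2) trinucleotide indices (16*a + 4*b + c) at each start position."""
    return (
        codes[:, :-2].astype(np.int64) * 16
        + codes[:, 1:-1].astype(np.int64) * 4
        + codes[:, 2:].astype(np.int64)
    )


def _position_frequencies(sset: SequenceSet) -> np.ndarray:
    """(64, L-2) per-position trinucleotide frequencies within one class."""
    tri = _trinuc_codes(_encode_codes(sset))
    n, ncols = tri.shape
    freq = np.zeros((64, ncols))
    for j in range(ncols):
        freq[:, j] = np.bincount(tri[:, j], minlength=64) / n
    return freq


def fit_pstnpss(pos: SequenceSet, neg: SequenceSet) -> PstnpssModel:
    """Fit z[i, j] = F+(3mer_i | j) - F-(3mer_i | j) from the two classes."""
    if not len(pos) or not len(neg):
        raise ValueError("both classes must be non-empty to fit PSTNPss")
    if pos.length != neg.length:
        raise ValueError(
            f"class length mismatch: positives L={pos.length}, negatives L={neg.length}"
        )
    z = _position_frequencies(pos) - _position_frequencies(neg)
    return PstnpssModel(z=z, L=pos.length)


def transform_pstnpss(model: PstnpssModel, sset: SequenceSet) -> FeatureBlock:
    """Per sequence, the length-(L-2) vector of z looked up at its own 3-mers."""
    if sset.length != model.L:
        raise ValueError(
            f"sequence length {sset.length} != model training length {model.L}"
        )
    tri = _trinuc_codes(_encode_codes(sset))
    cols = np.arange(model.L - 2)
    out = model.z[tri, cols[None, :]]
    labels = [f"PSTNP:pos{j}" for j in range(1, model.L - 1)]
    return FeatureBlock(name="PSTNP", matrix=out, column_labels=labels)


# ---------------------------------------------------------------------------
# Adaptive skip dinucleotide composition
# ---------------------------------------------------------------------------

def encode_asdc(sset: SequenceSet) -> FeatureBlock:
    """ASDC: frequency of each ordered residue pair over all gaps.

    Every ordered position pair (p, p+g), g = 1..L-1, contributes one count to
    the pair (s_p, s_{p+g}); the 16 counts are divided by the total number of
    pairs L(L-1)/2, so the vector sums to 1.
    """
    codes = _encode_codes(sset)
    n, L = codes.shape
    if L < 2:
        raise ValueError("ASDC needs L >= 2")
    out = np.zeros((n, 16))
    total = L * (L - 1) // 2
    for r in range(n):
        # suffix residue counts: after position p, how many of each residue
        suffix = np.zeros(4, dtype=np.int64)
        acc = np.zeros((4, 4), dtype=np.int64)
        for p in range(L - 1, -1, -1):
            acc[codes[r, p]] += suffix
            suffix[codes[r, p]] += 1
        out[r] = acc.reshape(16) / total
    labels = [f"ASDC:{d}" for d in DINUCLEOTIDES]
    return FeatureBlock(name="ASDC", matrix=out, column_labels=labels)


# ---------------------------------------------------------------------------
# Dinucleotide auto-covariance
# ---------------------------------------------------------------------------

@dataclass
class PhysicochemicalTable:
    """Named physicochemical indices over the 16 RNA dinucleotides (AA..UU)."""

    indices: list[str]
    values: np.ndarray  # (N, 16), columns in lexicographic dinucleotide order
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.indices), 16):
            raise ValueError("values must be N x 16 in AA..UU order")

    def standardize(self) -> "PhysicochemicalTable":
        """Zero-mean, unit-SD each index row across the 16 dinucleotides."""
        mu = self.values.mean(axis=1, keepdims=True)
        sd = self.values.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("cannot standardize a constant index row")
        return PhysicochemicalTable(
            indices=list(self.indices),
            values=(self.values - mu) / sd,
            standardized=True,
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhysicochemicalTable":
        """Load a TSV whose header lists the 16 dinucleotides AA..UU."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        cols = [c.upper().replace("T", "U") for c in df.columns]
        if sorted(cols) != sorted(DINUCLEOTIDES):
            raise ValueError("index table must have exactly the 16 dinucleotide columns")
        df.columns = cols
        df = df[DINUCLEOTIDES]
        return cls(indices=[str(i) for i in df.index], values=df.to_numpy(float))


def load_default_index_table(standardize: bool = True) -> PhysicochemicalTable:
    """Packaged default: Turner nearest-neighbor stacking thermodynamics
    (dG37, dH, dS) per dinucleotide step, standardized across the 16 steps."""
    ref = resources.files("hmckit.data") / "rna_dinucleotide_indices.tsv"
    with resources.as_file(ref) as path:
        table = PhysicochemicalTable.from_tsv(path)
    return table.standardize() if standardize else table


@dataclass
class DacConfig:
    """Maximum lag and index table for the auto-covariance encoder."""

    lag_max: int = 2
    table: PhysicochemicalTable = field(default_factory=load_default_index_table)

    def __post_init__(self) -> None:
        if self.lag_max < 1:
            raise ValueError("lag_max must be >= 1")


def encode_dac(sset: SequenceSet, cfg: DacConfig | None = None) -> FeatureBlock:
    """DAC(u, lag) = mean over i of [P_u(di_i) - mean_u][P_u(di_{i+lag}) - mean_u].

    mean_u is the per-sequence average of index u over its own L-1
    dinucleotides; the sum over the L-1-lag valid pairs is divided by
    L-lag-1. Columns are index-major, lag-minor.
    """
    cfg = cfg or DacConfig()
    L = sset.length
    if cfg.lag_max > L - 2:
        raise ValueError(f"lag_max={cfg.lag_max} too large for L={L} (need lag_max <= L-2)")
    codes = _encode_codes(sset)
    di = codes[:, :-1].astype(np.int64) * 4 + codes[:, 1:].astype(np.int64)  # (n, L-1)
    vals = cfg.table.values[:, di]  # (N, n, L-1)
    mean = vals.mean(axis=2, keepdims=True)
    centered = vals - mean
    n = len(sset)
    N = len(cfg.table.indices)
    out = np.empty((n, N * cfg.lag_max))
    for u in range(N):
        for lag in range(1, cfg.lag_max + 1):
            prod = centered[u, :, : L - 1 - lag] * centered[u, :, lag:]
            out[:, u * cfg.lag_max + lag - 1] = prod.sum(axis=1) / (L - lag - 1)
    labels = [
        f"DAC:{cfg.table.indices[u]}:lag{lag}"
        for u in range(N)
        for lag in range(1, cfg.lag_max + 1)
    ]
    return FeatureBlock(name="DAC", matrix=out, column_labels=labels)


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def fuse(blocks: list[FeatureBlock]) -> HybridMatrix:
    """Serially concatenate blocks in the fixed order MisM, ASDC, DAC, ANF, PSTNP."""
    names = tuple(b.name for b in blocks)
    if names != FUSION_ORDER[: len(blocks)] and names != FUSION_ORDER:
        raise ValueError(
            f"blocks must be supplied in order {FUSION_ORDER}, got {names}"
        )
    if len(blocks) == 0:
        raise ValueError("no blocks to fuse")
    n = blocks[0].n_samples
    for b in blocks:
        if b.n_samples != n:
            raise ValueError(
                f"row-count mismatch: block {b.name!r} has {b.n_samples} rows, expected {n}"
            )
    matrix = np.hstack([b.matrix for b in blocks])
    labels = [lab for b in blocks for lab in b.column_labels]
    if len(set(labels)) != len(labels):
        raise ValueError("column labels collide across blocks")
    return HybridMatrix(matrix=matrix, column_labels=labels)


def encode_all(
    sset: SequenceSet,
    pstnp_model: PstnpssModel,
    mismatch_cfg: MismatchConfig | None = None,
    dac_cfg: DacConfig | None = None,
) -> HybridMatrix:
    """Run all five encoders on a validated set and fuse the blocks."""
    blocks = [
        encode_mismatch(sset, mismatch_cfg),
        encode_asdc(sset),
        encode_dac(sset, dac_cfg),
        encode_anf(sset),
        transform_pstnpss(pstnp_model, sset),
    ]
    return fuse(blocks)
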