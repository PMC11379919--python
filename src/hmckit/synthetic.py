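"""Synthetic two-class RNA sequence sets with controllable, encoder-visible signal.

The generator emulates the structure of balanced 5hmC benchmark sets:
fixed-length windows (default L=41, a typical modification-site window; 662
sequences per class, the benchmark's class size), with two independent signal
dials:

* a **motif** overwritten at a fixed 1-based position in each positive with
  probability ``motif_prob`` — visible to the position-specific encoders
  (PSTNPss, ANF) and, through its k-mers, to the mismatch profile;
* a **composition shift** between the per-class nucleotide probability
  vectors — visible to the composition encoders (ASDC, ANF, DAC).

With ``motif_prob=0`` and equal compositions the classes are exchangeable and
the pipeline should perform at chance. Positives and negatives are drawn from
deterministic per-class substreams of one seed, so enlarging one class never
changes the other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .sequence_io import ALPHABET, SequenceRecord, SequenceSet

UNIFORM = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class SyntheticConfig:
    n_pos: int = 662
    n_neg: int = 662
    L: int = 41
    motif: str = "GACU"
    motif_position: int = 19  # 1-based start of the planted motif
    motif_prob: float = 1.0
    pos_composition: tuple[float, float, float, float] = UNIFORM
    neg_composition: tuple[float, float, float, float] = UNIFORM
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class sizes must be positive")
        if self.L < 3:
            raise ValueError("L must be >= 3")
        if self.motif and any(c not in ALPHABET for c in self.motif):
            raise ValueError(f"motif {self.motif!r} must be over {{A,C,G,U}}")
        if self.motif and not (
            1 <= self.motif_position
            and self.motif_position + len(self.motif) - 1 <= self.L
        ):
            raise ValueError("motif does not fit within L at motif_position")
        if not (0 <= self.motif_prob <= 1):
            raise ValueError("motif_prob must be in [0, 1]")
        for comp in (self.pos_composition, self.neg_composition):
            if len(comp) != 4 or abs(sum(comp) - 1) > 1e-9 or min(comp) < 0:
                raise ValueError("compositions must be 4 non-negative probs summing to 1")


def _draw_class(
    rng: np.random.Generator, n: int, L: int, comp, prefix: str
) -> list[str]:
    codes = rng.choice(4, size=(n, L), p=np.asarray(comp, float))
    return ["".join(ALPHABET[c] for c in row) for row in codes]


def generate(cfg: SyntheticConfig | None = None) -> tuple[SequenceSet, SequenceSet]:
    """Draw (positive, negative) sets per the config; deterministic given seed."""
    cfg = cfg or SyntheticConfig()
    pos_rng, neg_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(2)
    )
    pos_seqs = _draw_class(pos_rng, cfg.n_pos, cfg.L, cfg.pos_composition, "pos")
    if cfg.motif:
        start = cfg.motif_position - 1
        plant = pos_rng.random(cfg.n_pos) < cfg.motif_prob
        pos_seqs = [
            s[:start] + cfg.motif + s[start + len(cfg.motif):] if keep else s
            for s, keep in zip(pos_seqs, plant)
        ]
    neg_seqs = _draw_class(neg_rng, cfg.n_neg, cfg.L, cfg.neg_composition, "neg")
    pos = SequenceSet(
        [SequenceRecord(f"pos_{i+1:04d}", s, "positive") for i, s in enumerate(pos_seqs)]
    )
    neg = SequenceSet(
        [SequenceRecord(f"neg_{i+1:04d}", s, "negative") for i, s in enumerate(neg_seqs)]
    )
    return pos, neg


def write_manifest(cfg: SyntheticConfig, path: str | Path) -> None:
    """JSON manifest sufficient to regenerate the exact same sets."""
    Path(path).write_text(json.dumps(asdict(cfg), indent=2))
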