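"""Reading, validating and writing labeled fixed-length RNA sequence sets.

All downstream encoders are position-indexed, so the central contract here is
that every record in a :class:`SequenceSet` has the same length ``L`` and an
alphabet of exactly {A, C, G, U}. DNA-convention input (T, lowercase) is
normalized silently; anything else is an error unless the caller opts into
dropping ambiguous records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = "ACGU"
Label = Literal["positive", "negative", "unknown"]
AmbiguityPolicy = Literal["error", "drop"]

_NORMALIZE = str.maketrans("acgutT", "ACGUUU")


class SequenceError(ValueError):
    """Base class for sequence-input failures."""


class AmbiguousResidueError(SequenceError):
    """A residue outside {A,C,G,U,T} (either case) was encountered."""

    def __init__(self, residue: str, position: int, record_id: str | None = None):
        self.residue = residue
        self.position = position  # 1-based, matching user-facing coordinates
        self.record_id = record_id
        where = f" in record {record_id!r}" if record_id else ""
        super().__init__(
            f"ambiguous residue {residue!r} at position {position}{where}"
        )


class LengthMismatchError(SequenceError):
    """Records in a set do not share a common length, or L < 3."""


class DuplicateIdError(SequenceError):
    """Two records in one set share an identifier."""


@dataclass(frozen=True)
class SequenceRecord:
    """One labeled RNA sequence window."""

    id: str
    sequence: str
    label: Label = "unknown"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceSet:
    """A collection of equal-length records; the universal pipeline input."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def length(self) -> int:
        """Common sequence length L (0 for an empty set)."""
        return len(self.records[0].sequence) if self.records else 0

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def normalize_sequence(
    raw: str,
    ambiguity_policy: AmbiguityPolicy = "error",
    record_id: str | None = None,
) -> str | None:
    """Uppercase ``raw`` and map T to U.

    Returns the normalized string, or ``None`` under ``ambiguity_policy="drop"``
    when a residue outside the DNA/RNA alphabet is found (the caller discards
    the record). Under the default ``"error"`` policy such a residue raises
    :class:`AmbiguousResidueError` naming the character and 1-based position.
    """
    if not raw:
        raise SequenceError("empty sequence")
    out = raw.translate(_NORMALIZE)
    for pos, ch in enumerate(out, start=1):
        if ch not in ALPHABET:
            if ambiguity_policy == "drop":
                return None
            raise AmbiguousResidueError(raw[pos - 1], pos, record_id)
    if "t" in raw or "T" in raw:
        logger.info("normalized T->U in %s", record_id or "<sequence>")
    return out


def read_fasta(
    path: str | Path,
    label: Label = "unknown",
    ambiguity_policy: AmbiguityPolicy = "error",
) -> SequenceSet:
    """Parse a FASTA file into a :class:`SequenceSet` with one label per file.

    Line-wrapped bodies are concatenated (standard FASTA semantics). Length
    validation is deferred to :func:`validate_set` so callers can give a
    better combined error. Duplicate ids and empty files are errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    dropped = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise DuplicateIdError(f"duplicate id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = normalize_sequence(str(entry.seq), ambiguity_policy, entry.id)
        if seq is None:
            dropped += 1
            continue
        records.append(SequenceRecord(id=entry.id, sequence=seq, label=label))
    if not seen:
        raise SequenceError(f"no FASTA records found in {path}")
    if dropped:
        logger.info("dropped %d ambiguous record(s) from %s", dropped, path)
    return SequenceSet(records=records)


def write_fasta(sset: SequenceSet, path: str | Path, width: int = 60) -> None:
    """Write the set as FASTA with bodies wrapped at ``width`` columns."""
    bio = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in sset.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def validate_set(sset: SequenceSet) -> SequenceSet:
    """Enforce the equal-length (and L >= 3) invariant, listing offenders."""
    if not sset.records:
        raise SequenceError("empty sequence set")
    L = len(sset.records[0].sequence)
    bad = [(r.id, len(r.sequence)) for r in sset.records if len(r.sequence) != L]
    if bad:
        shown = ", ".join(f"{rid}(len {n})" for rid, n in bad[:10])
        raise LengthMismatchError(
            f"records differ from common length {L}: {shown}"
            + (" ..." if len(bad) > 10 else "")
        )
    if L < 3:
        raise LengthMismatchError(
            f"sequence length {L} < 3; position-specific trinucleotide "
            "features need at least one trinucleotide window"
        )
    return sset
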