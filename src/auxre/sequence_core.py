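"""Sequence primitives: IUPAC consensus matching and strand-aware scanning.

Coordinates are 0-based half-open throughout. A minus-strand hit is
recorded at the plus-strand start offset of the matched window (its
leftmost base), so all downstream distance arithmetic lives in a single
coordinate system. ``N`` in a genome sequence matches only an ``N``
pattern position — masked bases never produce hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = frozenset("ACGTN")


class InvalidPatternError(ValueError):
    """Raised for a consensus pattern containing a non-IUPAC character."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named uppercase DNA sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ConsensusMatcher:
    """Per-position allowed-letter sets compiled from an IUPAC pattern."""

    pattern: str
    allowed: tuple[frozenset[str], ...]

    @property
    def width(self) -> int:
        return len(self.allowed)

    def matches(self, window: str) -> bool:
        """True iff ``window`` matches position-by-position.

        ``N`` in the window matches only an ``N`` pattern position
        (i.e. positions whose allowed set is the full alphabet).
        """
        if len(window) != self.width:
            return False
        for ch, ok, pat in zip(window, self.allowed, self.pattern):
            if ch == "N":
                if pat != "N":
                    return False
            elif ch not in ok:
                return False
        return True


@dataclass(frozen=True, order=True)
class SiteHit:
    """One predicted motif occurrence on a sequence.

    ``start`` is the 0-based plus-strand offset of the window's leftmost
    base regardless of strand; ``score`` is 1.0 for consensus hits.
    """

    seq_id: str = field(compare=False)
    start: int
    width: int = field(compare=False)
    strand: str = field(compare=False)
    score: float = field(compare=False, default=1.0)
    model_id: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0:
            raise ValueError("start must be non-negative")

    @property
    def end(self) -> int:
        return self.start + self.width

    @property
    def center(self) -> float:
        """Real-valued center coordinate (half-integral for even widths)."""
        return self.start + (self.width - 1) / 2


def parse_iupac(pattern: str) -> ConsensusMatcher:
    """Compile an IUPAC degenerate pattern into a matcher.

    >>> parse_iupac("TGTCNN").width
    6
    """
    if not pattern:
        raise InvalidPatternError("empty pattern")
    pattern = pattern.upper()
    allowed = []
    for ch in pattern:
        try:
            allowed.append(IUPAC_CODES[ch])
        except KeyError:
            raise InvalidPatternError(
                f"invalid IUPAC character {ch!r} in pattern {pattern!r}"
            ) from None
    return ConsensusMatcher(pattern=pattern, allowed=tuple(allowed))


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def scan_consensus(
    record: SequenceRecord,
    matcher: ConsensusMatcher,
    strands: Iterable[str] = ("+", "-"),
    model_id: str | None = None,
) -> list[SiteHit]:
    """Exhaustively scan a sequence for consensus matches on chosen strands.

    Every matching start offset is reported once per (start, strand);
    overlapping occurrences are counted separately. Minus-strand hits test
    the reverse complement of the window and are reported at the window's
    plus-strand start. Hits are sorted by start, '+' before '-' at ties.
    """
    strands = tuple(strands)
    if not strands:
        raise ValueError("empty strand set")
    for s in strands:
        if s not in ("+", "-"):
            raise ValueError(f"invalid strand {s!r}")
    mid = model_id if model_id is not None else matcher.pattern
    w = matcher.width
    seq = record.seq
    hits: list[SiteHit] = []
    for start in range(len(seq) - w + 1):
        window = seq[start : start + w]
        if "+" in strands and matcher.matches(window):
            hits.append(SiteHit(record.id, start, w, "+", 1.0, mid))
        if "-" in strands and matcher.matches(reverse_complement(window)):
            hits.append(SiteHit(record.id, start, w, "-", 1.0, mid))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# FASTA / BED I/O


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into uppercase SequenceRecords."""
    return [
        SequenceRecord(id=rec.id, seq=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def hits_to_bed(hits: Sequence[SiteHit]) -> str:
    """Render hits as 6-column BED (score = score*1000 truncated)."""
    lines = []
    for h in hits:
        lines.append(
            f"{h.seq_id}\t{h.start}\t{h.end}\t{h.model_id}\t"
            f"{int(h.score * 1000)}\t{h.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def write_bed(hits: Sequence[SiteHit], path) -> None:
    with open(path, "w") as fh:
        fh.write(hits_to_bed(hits))
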