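"""Strand-aware scanning of DNA for degenerate consensus motifs.

Forkhead-box (FOX) transcription factors recognise the degenerate binding
element 5'-RYAAAYA-3' (R = A/G, Y = C/T).  This module provides the small
amount of sequence machinery the rest of the package needs: validated DNA
sequences with promoter coordinates, IUPAC consensus patterns, exhaustive
both-strand window scanning, and annotation of homotypic site pairs — a
primary element plus an adjacent (possibly overlapping) secondary element,
the FBE1/FBE2 architecture of the TP53 promoter probe.

Coordinates are 0-based, half-open, always on the plus strand.  Promoter
coordinates (e.g. -558..-552) are obtained by adding the sequence ``offset``
at the reporting layer only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "IUPAC_CODES",
    "DnaSequence",
    "ConsensusPattern",
    "MotifMatch",
    "SitePair",
    "reverse_complement",
    "iupac_matches",
    "scan",
    "annotate_homotypic_pairs",
    "read_fasta",
]

#: Degeneracy sets for every IUPAC nucleotide code (patterns may use all of
#: them; sequences are restricted to A/C/G/T/N).
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
_SEQUENCE_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class DnaSequence:
    """A validated DNA sequence with an optional promoter-coordinate offset.

    ``offset`` is the plus-strand coordinate of the first base, so a promoter
    fragment cloned from -1800 carries ``offset=-1800``.
    """

    id: str
    bases: str
    offset: int = 0

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "bases", self.bases.upper())
        for pos, base in enumerate(self.bases):
            if base not in _SEQUENCE_ALPHABET:
                raise ValueError(
                    f"sequence {self.id!r}: invalid base {base!r} at position {pos} "
                    "(only A/C/G/T/N allowed in sequences; degeneracy codes belong "
                    "in patterns)"
                )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ConsensusPattern:
    """A degenerate consensus motif over the IUPAC alphabet, e.g. RYAAAYA."""

    pattern: str
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", self.pattern.upper())
        if not self.name:
            object.__setattr__(self, "name", self.pattern)
        if len(self.pattern) < 4:
            raise ValueError(f"pattern {self.pattern!r} shorter than 4")
        for pos, code in enumerate(self.pattern):
            if code not in IUPAC_CODES:
                raise ValueError(
                    f"pattern {self.pattern!r}: {code!r} at position {pos} is not "
                    "an IUPAC nucleotide code"
                )

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifMatch:
    """A consensus hit reported in plus-strand, 0-based half-open coordinates.

    ``site`` is always the plus-strand slice ``sequence[start:end]``; a
    minus-strand hit means the reverse complement of ``site`` matches the
    pattern.
    """

    start: int
    end: int
    strand: str
    site: str
    pattern_name: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def promoter_interval(self, seq: DnaSequence) -> tuple[int, int]:
        """Map to promoter coordinates using the sequence offset."""
        return self.start + seq.offset, self.end + seq.offset


@dataclass(frozen=True)
class SitePair:
    """A homotypic pair: primary match plus an adjacent secondary match.

    ``overlap`` is the number of shared plus-strand bases; a negative value
    is a gap of ``-overlap`` bases between the two sites.
    """

    primary: MotifMatch
    secondary: MotifMatch
    overlap: int


def reverse_complement(seq: DnaSequence | str) -> DnaSequence | str:
    """Watson–Crick reverse complement; an involution on valid sequences."""
    if isinstance(seq, DnaSequence):
        return DnaSequence(seq.id, _rc_string(seq.bases), offset=seq.offset)
    return _rc_string(seq.upper())


def _rc_string(bases: str) -> str:
    for pos, base in enumerate(bases):
        if base not in _SEQUENCE_ALPHABET:
            raise ValueError(f"invalid base {base!r} at position {pos}")
    return bases.translate(_COMPLEMENT)[::-1]


def iupac_matches(site: str, pattern: ConsensusPattern | str) -> bool:
    """True iff every base of ``site`` is in the degeneracy set of the
    corresponding pattern code.  ``N`` in the *site* matches nothing
    (masked sequence is treated conservatively)."""
    pat = pattern.pattern if isinstance(pattern, ConsensusPattern) else pattern.upper()
    if len(site) != len(pat):
        raise ValueError(f"site length {len(site)} != pattern length {len(pat)}")
    site = site.upper()
    for base, code in zip(site, pat):
        allowed = IUPAC_CODES.get(code)
        if allowed is None:
            raise ValueError(f"{code!r} is not an IUPAC code")
        if base not in allowed:
            return False
    return True


def scan(
    seq: DnaSequence,
    pattern: ConsensusPattern,
    both_strands: bool = True,
) -> list[MotifMatch]:
    """Exhaustively test every window of ``seq`` against ``pattern``.

    Minus-strand hits are tested against the reverse complement of the window
    and reported in plus-strand coordinates.  Results are sorted by start,
    plus strand before minus at equal start.  Overlapping hits are all
    reported; deduplication is the caller's concern.
    """
    if len(pattern) > len(seq):
        raise ValueError(
            f"pattern length {len(pattern)} exceeds sequence length {len(seq)}"
        )
    hits: list[MotifMatch] = []
    width = len(pattern)
    for start in range(len(seq) - width + 1):
        window = seq.bases[start : start + width]
        if iupac_matches(window, pattern):
            hits.append(MotifMatch(start, start + width, "+", window, pattern.name))
        if both_strands and iupac_matches(_rc_string(window), pattern):
            hits.append(MotifMatch(start, start + width, "-", window, pattern.name))
    hits.sort(key=lambda m: (m.start, m.strand))  # '+' < '-' in ASCII
    return hits


def annotate_homotypic_pairs(
    matches: Sequence[MotifMatch],
    secondary: ConsensusPattern,
    seq: DnaSequence,
    max_overlap: int = 2,
    max_gap: int = 0,
) -> list[SitePair]:
    """Pair each primary match with adjacent secondary-pattern hits.

    A secondary hit qualifies when it overlaps the primary by at most
    ``max_overlap`` bases, or is separated from it by at most ``max_gap``
    bases.  A hit identical in coordinates and strand to the primary is
    never paired with itself.
    """
    secondary_hits = scan(seq, secondary, both_strands=True)
    pairs: list[SitePair] = []
    for primary in matches:
        for sec in secondary_hits:
            if (
                sec.start == primary.start
                and sec.end == primary.end
                and sec.strand == primary.strand
            ):
                continue
            ov = min(primary.end, sec.end) - max(primary.start, sec.start)
            if (0 < ov <= max_overlap) or (ov <= 0 and -ov <= max_gap):
                pairs.append(SitePair(primary, sec, ov))
    pairs.sort(key=lambda p: (p.primary.start, p.secondary.start))
    return pairs


def read_fasta(path: str | Path, offset: int = 0) -> list[DnaSequence]:
    """Read a (possibly multi-record, wrapped) FASTA file into DnaSequences."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [DnaSequence(rec.id, str(rec.seq), offset=offset) for rec in records]
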