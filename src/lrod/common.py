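"""Common-k-mer set construction for a read pair.

An *anchor* (common k-mer) is a solid k-mer occurring in both reads of
a pair, recorded as a four-tuple of start positions and orientations.
Anchors whose orientations agree are *positive*, otherwise *opposite*;
a majority vote over the two classes fixes the pair's relative strand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import TYPE_CHECKING, List, Optional

from .spectrum import SolidKmerIndex

if TYPE_CHECKING:  # pragma: no cover
    from .driver_io import ReadRecord

# Relative strand of a read pair.
POSITIVE = "+"
OPPOSITE = "-"


@dataclass(frozen=True)
class CommonKmer:
    """One anchor: positions (0-based starts) and orientations in both reads."""

    P1: int
    O1: str
    P2: int
    O2: str
    kmer: str

    @property
    def positive(self) -> bool:
        return self.O1 == self.O2


@dataclass
class CommonKmerSet:
    """Strand-classified anchor list for a pair, sorted ascending by P1.

    ``M`` and ``N`` are the positive/opposite anchor counts *before*
    the vote discarded the minority class.
    """

    anchors: List[CommonKmer]
    strand: str
    M: int
    N: int


def find_common_kmers(
    r1: "ReadRecord", r2: "ReadRecord", index: SolidKmerIndex, s: int = 1
) -> List[CommonKmer]:
    """Raw anchor list between two reads via the solid-k-mer index.

    K-mers are taken from ``r1`` at every ``s``-th start position (only
    solid occurrences exist in the index, so non-solid starts contribute
    nothing) and matched against ``r2``'s solid occurrences.  One anchor
    is produced per (position-in-r1, position-in-r2) combination.
    """
    anchors: List[CommonKmer] = []
    r2_map = index.kmer_positions(r2.id)
    if not r2_map:
        return anchors
    for p1, kmer, o1 in index.occurrences(r1.id):
        if s > 1 and p1 % s != 0:
            continue
        hits = r2_map.get(kmer)
        if not hits:
            continue
        for p2, o2 in hits:
            anchors.append(CommonKmer(P1=p1, O1=o1, P2=p2, O2=o2, kmer=kmer))
    return anchors


def remove_nonunique(anchors: List[CommonKmer]) -> List[CommonKmer]:
    """Drop every anchor whose k-mer value participates in more than one anchor.

    A k-mer occurring at several positions in either read produces
    several anchors with contradictory coordinates; all of them are
    removed (symmetric reading of the repeat rule).
    """
    counts = Counter(a.kmer for a in anchors)
    return [a for a in anchors if counts[a.kmer] == 1]


def classify_strand(
    anchors: List[CommonKmer], count: int
) -> Optional[CommonKmerSet]:
    """Majority vote on anchor orientation classes.

    Keeps the positive anchors when M > N and M > count, the opposite
    anchors when N > M and N > count, and returns ``None`` (no overlap)
    otherwise — including the tie M == N.  Survivors are sorted
    ascending by P1 (ties broken by P2 for determinism).
    """
    M = sum(1 for a in anchors if a.positive)
    N = len(anchors) - M
    if M > N and M > count:
        kept = [a for a in anchors if a.positive]
        strand = POSITIVE
    elif N > M and N > count:
        kept = [a for a in anchors if not a.positive]
        strand = OPPOSITE
    else:
        return None
    kept.sort(key=lambda a: (a.P1, a.P2))
    return CommonKmerSet(anchors=kept, strand=strand, M=M, N=N)
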