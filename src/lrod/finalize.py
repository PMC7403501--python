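"""Overlap revision and acceptance.

The chain spans only part of the true overlap; revision extends its
draft interval to the read boundaries according to which read sticks
out on each side (four geometric cases covering dovetail and
containment layouts).  The revised overlap is then accepted only when
the chain explains almost all of it on both reads, it is long enough,
and its two per-read lengths agree within gamma.

All arithmetic in this module follows the 1-based inclusive convention
of the revision formulas; 0-based chain coordinates are shifted on
entry, and opposite-strand chains are first mapped into the frame where
R2 is reverse-complemented (so Q increases along the chain).  Reported
coordinates are mapped back to the original R2 strand at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Optional, Tuple

from .chaining import Chain
from .common import OPPOSITE, POSITIVE
from .spectrum import Parameters

if TYPE_CHECKING:  # pragma: no cover
    from .driver_io import ReadRecord


@dataclass(frozen=True)
class Overlap:
    """Final per-pair overlap, 1-based inclusive coordinates.

    For opposite-strand overlaps the stored SP2/EP2 are on the original
    R2 sequence; the strand flag records the relative orientation.
    """

    id1: str
    id2: str
    strand: str
    SP1: int
    EP1: int
    SP2: int
    EP2: int
    Len1: int
    Len2: int
    support: int

    @property
    def overlap_len1(self) -> int:
        return self.EP1 - self.SP1

    @property
    def overlap_len2(self) -> int:
        return self.EP2 - self.SP2

    @property
    def max_overlap_len(self) -> int:
        return max(self.overlap_len1, self.overlap_len2)

    @property
    def min_overlap_len(self) -> int:
        return min(self.overlap_len1, self.overlap_len2)


def chain_endpoints(chain: Chain, len2: int, k: int) -> Tuple[int, int, int, int]:
    """1-based (P1, Pn, Q1, Qn) with R2 in the strand-normalized frame.

    For opposite chains Q decreases along the chain on the original R2;
    mapping q -> len2 - q - k (0-based) into the reverse-complement
    frame makes Q increase with P.
    """
    first, last = chain.anchors[0], chain.anchors[-1]
    p1, pn = first.P1 + 1, last.P1 + 1
    if chain.strand == POSITIVE:
        q1, qn = first.P2 + 1, last.P2 + 1
    else:
        q1 = len2 - first.P2 - k + 1
        qn = len2 - last.P2 - k + 1
    return p1, pn, q1, qn


def revise_coords(
    p1: int, q1: int, pn: int, qn: int, len1: int, len2: int
) -> Tuple[int, int, int, int]:
    """Four-case boundary extension of the draft overlap (1-based inclusive).

    The left edge is set by whichever read has more sequence before the
    first anchor; the right edge by whichever has less sequence after
    the last.  Equal left margins fold into the clamped-to-1 branch.
    """
    if len1 - pn <= len2 - qn:
        ep1 = len1
        ep2 = qn + (len1 - pn)
    else:
        ep1 = pn + (len2 - qn)
        ep2 = len2
    if p1 > q1:
        sp1 = p1 - q1
        sp2 = 1
    else:
        sp1 = 1
        sp2 = max(1, q1 - p1)
    return sp1, ep1, sp2, ep2


def revise_overlap(
    chain: Chain, len1: int, len2: int, k: int
) -> Tuple[int, int, int, int]:
    """Revised (SP1, EP1, SP2, EP2) for a chain, R2 strand-normalized."""
    p1, pn, q1, qn = chain_endpoints(chain, len2, k)
    return revise_coords(p1, q1, pn, qn, len1, len2)


def evaluate_overlap(ov: Overlap, chain: Chain, params: Parameters) -> bool:
    """Acceptance test; ``ov`` must be in the strand-normalized frame.

    Conditions: the chain span falls short of the revised overlap by
    less than alpha on both reads; the shorter overlap side exceeds
    epsilon; and the two overlap lengths differ by less than a fraction
    gamma.
    """
    p1, pn, q1, qn = chain_endpoints(chain, ov.Len2, params.k)
    k = params.k
    if (ov.EP1 - ov.SP1) - (pn + k - p1) >= params.alpha:
        return False
    if (ov.EP2 - ov.SP2) - (qn + k - q1) >= params.alpha:
        return False
    if ov.min_overlap_len <= params.epsilon:
        return False
    if ov.max_overlap_len == 0:
        return False
    diff = ov.max_overlap_len - ov.min_overlap_len
    return diff / ov.max_overlap_len < params.gamma


def finalize_pair(
    chain: Chain, r1: "ReadRecord", r2: "ReadRecord", params: Parameters
) -> Optional[Overlap]:
    """Revise the chain's draft overlap and accept or reject it.

    Returns the accepted overlap with coordinates on the original
    strands, or ``None``.
    """
    len1, len2 = len(r1.seq), len(r2.seq)
    sp1, ep1, sp2, ep2 = revise_overlap(chain, len1, len2, params.k)
    ov = Overlap(
        id1=r1.id,
        id2=r2.id,
        strand=chain.strand,
        SP1=sp1,
        EP1=ep1,
        SP2=sp2,
        EP2=ep2,
        Len1=len1,
        Len2=len2,
        support=len(chain.anchors),
    )
    if not evaluate_overlap(ov, chain, params):
        return None
    if ov.strand == OPPOSITE:
        # Map [SP2, EP2] from the reverse-complement frame back to the
        # original R2 coordinates.
        ov = replace(ov, SP2=len2 - ep2 + 1, EP2=len2 - sp2 + 1)
    return ov
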