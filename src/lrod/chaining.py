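"""Greedy anchor chaining with a two-stage consistency test.

Two anchors are *consistent* when they advance in the same direction on
both reads (C1 for positive pairs, C2 for opposite), both inter-anchor
distances stay below a bound (C3), and the two distances do not differ
by more than a fraction gamma (C4).  Stage 1 applies C1-C4 with a tight
bound alpha; when it fails, stage 2 retries with a loose bound beta and
demands a path of small k_s-mer matches through the inter-anchor gap —
indels widen anchor spacing, and the rescue accepts a wide gap only
when its interior still aligns at k_s resolution.

The chain itself is built greedily: starting from one anchor, repeatedly
append the first subsequent anchor (in P1 order) consistent with the
current tail.  Because the greedy state is fully determined by the tail
anchor, chains from all possible starts share suffixes; the best-start
search memoizes the successor of each anchor and so costs little more
than a single pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Dict, List, Optional, Tuple

from .common import POSITIVE, CommonKmer, CommonKmerSet
from .spectrum import Parameters, revcomp

if TYPE_CHECKING:  # pragma: no cover
    from .driver_io import ReadRecord


@dataclass
class Chain:
    """Ordered run of pairwise-consistent anchors."""

    anchors: List[CommonKmer]
    strand: str

    def __len__(self) -> int:
        return len(self.anchors)

    @property
    def p_first(self) -> int:
        return self.anchors[0].P1

    @property
    def p_last(self) -> int:
        return self.anchors[-1].P1

    @property
    def q_first(self) -> int:
        return self.anchors[0].P2

    @property
    def q_last(self) -> int:
        return self.anchors[-1].P2


def _orientation_ok(a: CommonKmer, b: CommonKmer, strand: str) -> bool:
    # C1 (positive): both coordinates advance; C2 (opposite): P2 retreats.
    if a.P1 >= b.P1:
        return False
    if strand == POSITIVE:
        return b.P2 > a.P2
    return b.P2 < a.P2


def _ratio_ok(d1: int, d2: int, gamma: float) -> bool:
    # C4; guard the degenerate d1 == d2 == 0 case (cannot arise on a
    # passing path because C1/C2 are strict, but keep the division safe).
    m = d1 if d1 >= d2 else d2
    if m == 0:
        return False
    return (m - min(d1, d2)) / m < gamma


def consistent_stage1(
    a: CommonKmer, b: CommonKmer, strand: str, alpha: int, gamma: float
) -> bool:
    """C1/C2 + C3 (both distances < alpha) + C4 (relative difference < gamma)."""
    if not _orientation_ok(a, b, strand):
        return False
    d1 = b.P1 - a.P1
    d2 = abs(b.P2 - a.P2)
    if d1 >= alpha or d2 >= alpha:
        return False
    return _ratio_ok(d1, d2, gamma)


def _link(d1: int, d2: int, alpha: int, gamma: float) -> bool:
    """Edge test of the stage-2 path graph: monotone advance + C3 + C4."""
    if d1 <= 0 or d2 <= 0 or d1 >= alpha or d2 >= alpha:
        return False
    return _ratio_ok(d1, d2, gamma)


def _unique_kmer_positions(seq: str, k: int) -> Dict[str, int]:
    """Positions of k-mers occurring exactly once in ``seq`` (N-free)."""
    pos: Dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        pos[km] = -1 if km in pos else i
    return {km: i for km, i in pos.items() if i >= 0 and "N" not in km}


def _gap_path_exists(
    g1: str, g2: str, d1: int, d2: int, k: int, k_s: int, alpha: int, gamma: float
) -> bool:
    """Path search through common k_s-mers of the two gap regions.

    Nodes are k_s-mers unique within both regions, matched literally
    (g2 has already been strand-normalized).  A virtual start node
    stands for anchor ``a`` (distance k + offset to a node) and a
    virtual end node for anchor ``b``; edges use the C3/C4 test at the
    alpha scale.  Nodes are processed in ascending position so each node
    only looks back at earlier ones; the backward scan stops as soon as
    the gap on g1 reaches alpha.
    """
    if len(g1) < k_s or len(g2) < k_s:
        return False
    pos2 = _unique_kmer_positions(g2, k_s)
    if not pos2:
        return False
    pos1 = _unique_kmer_positions(g1, k_s)
    nodes: List[Tuple[int, int]] = sorted(
        (x, pos2[km]) for km, x in pos1.items() if km in pos2
    )
    if not nodes:
        return False
    reach = [False] * len(nodes)
    for i, (x, y) in enumerate(nodes):
        if _link(k + x, k + y, alpha, gamma):
            reach[i] = True
        else:
            for j in range(i - 1, -1, -1):
                xj, yj = nodes[j]
                if x - xj >= alpha:
                    break
                if reach[j] and _link(x - xj, y - yj, alpha, gamma):
                    reach[i] = True
                    break
        if reach[i] and _link(d1 - k - x, d2 - k - y, alpha, gamma):
            return True
    return False


def consistent_stage2(
    a: CommonKmer,
    b: CommonKmer,
    r1: "ReadRecord",
    r2: "ReadRecord",
    strand: str,
    params: Parameters,
) -> bool:
    """Rescue test for anchor pairs that fail stage 1.

    Requires the orientation condition and both distances < beta, then
    demands a k_s-mer path through the inter-anchor regions.  The R2
    region is reverse-complemented for opposite-strand pairs so both
    regions read in the same direction.
    """
    if not _orientation_ok(a, b, strand):
        return False
    k = params.k
    d1 = b.P1 - a.P1
    d2 = abs(b.P2 - a.P2)
    if d1 >= params.beta or d2 >= params.beta:
        return False
    if d1 - k < params.k_s or d2 - k < params.k_s:
        return False  # gaps too short to host any k_s-mer path
    g1 = r1.seq[a.P1 + k : b.P1]
    if strand == POSITIVE:
        g2 = r2.seq[a.P2 + k : b.P2]
    else:
        g2 = revcomp(r2.seq[b.P2 + k : a.P2])
    return _gap_path_exists(g1, g2, d1, d2, k, params.k_s, params.alpha, params.gamma)


def determine_consistent(
    a: CommonKmer,
    b: CommonKmer,
    r1: "ReadRecord",
    r2: "ReadRecord",
    strand: str,
    params: Parameters,
) -> bool:
    """Two-stage consistency: stage 1, and on failure the stage-2 rescue."""
    if consistent_stage1(a, b, strand, params.alpha, params.gamma):
        return True
    return consistent_stage2(a, b, r1, r2, strand, params)


def chain_from_start(
    cks: CommonKmerSet,
    start: int,
    r1: "ReadRecord",
    r2: "ReadRecord",
    params: Parameters,
) -> Chain:
    """Greedy chain beginning at ``cks.anchors[start]``.

    Scans subsequent anchors in P1 order and appends the first one
    consistent with the current tail, repeating until all anchors have
    been visited.
    """
    anchors = cks.anchors
    if not 0 <= start < len(anchors):
        raise IndexError(f"start {start} out of range for {len(anchors)} anchors")
    chain = [anchors[start]]
    tail = anchors[start]
    for j in range(start + 1, len(anchors)):
        b = anchors[j]
        if determine_consistent(tail, b, r1, r2, cks.strand, params):
            chain.append(b)
            tail = b
    return Chain(anchors=chain, strand=cks.strand)


def find_candidate_chain(
    cks: CommonKmerSet,
    r1: "ReadRecord",
    r2: "ReadRecord",
    params: Parameters,
) -> Optional[Chain]:
    """Best greedy chain over all start anchors; None when it has <= 2 anchors.

    Equivalent to running :func:`chain_from_start` from every start and
    keeping the largest chain (first found wins ties), but computed via
    memoized successor links: the greedy continuation depends only on
    the current tail anchor.
    """
    anchors = cks.anchors
    n = len(anchors)
    if n == 0:
        return None
    nxt: List[int] = [-1] * n
    size: List[int] = [1] * n
    for t in range(n - 2, -1, -1):
        a = anchors[t]
        for j in range(t + 1, n):
            if determine_consistent(a, anchors[j], r1, r2, cks.strand, params):
                nxt[t] = j
                size[t] = 1 + size[j]
                break
    best = 0
    for t in range(1, n):
        if size[t] > size[best]:
            best = t
    if size[best] <= 2:
        return None
    chain: List[CommonKmer] = []
    t = best
    while t != -1:
        chain.append(anchors[t])
        t = nxt[t]
    return Chain(anchors=chain, strand=cks.strand)


def dump_anchors_tsv(
    cks: CommonKmerSet, chain: Optional[Chain], path: str
) -> None:
    """Debug dump: one row per anchor with an in_chain flag (dot-plot aid)."""
    in_chain = set(id(a) for a in chain.anchors) if chain else set()
    with open(path, "w") as fh:
        fh.write("P1\tP2\tstrand\tin_chain\n")
        for a in cks.anchors:
            fh.write(f"{a.P1}\t{a.P2}\t{cks.strand}\t{int(id(a) in in_chain)}\n")
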