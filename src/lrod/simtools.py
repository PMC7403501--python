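"""Synthetic long-read simulation with ground-truth overlaps, and scoring.

The simulator draws a uniform-random genome, samples reads at recorded
positions and strands, and corrupts them with independent per-base
substitution/insertion/deletion errors — the error regime of
third-generation sequencing (10-20% mixed errors).  Because sampling
coordinates are known, every pair of reads whose genome intervals
intersect yields a ground-truth overlap with intervals projected into
each read's error-free coordinate frame.

Scoring follows the precision/recall/F1 protocol: a detected pair is a
true positive when the unordered pair appears in the truth table with
matching relative strand and the detected interval on each read covers
at least half of the shorter of (detected, true) interval on that read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .driver_io import PafRow, ReadRecord
from .spectrum import revcomp

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Simulation settings; error fractions are fractions *of* ``error_rate``.

    ``sub_frac + ins_frac + del_frac`` must equal 1, so the per-base
    substitution/insertion/deletion rates sum to ``error_rate``.
    """

    genome_length: int = 100_000
    n_reads: int = 100
    read_length_mean: float = 8000.0
    read_length_sd: float = 1000.0
    error_rate: float = 0.10
    sub_frac: float = 0.5
    ins_frac: float = 0.25
    del_frac: float = 0.25
    seed: int = 0
    revcomp_prob: float = 0.0
    min_truth_overlap: int = 1
    min_read_length: int = 100

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.n_reads <= 0:
            raise ValueError("genome_length and n_reads must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        fracs = self.sub_frac + self.ins_frac + self.del_frac
        if abs(fracs - 1.0) > 1e-9:
            raise ValueError("sub_frac + ins_frac + del_frac must equal 1")
        if not 0 <= self.revcomp_prob <= 1:
            raise ValueError("revcomp_prob must be in [0, 1]")

    @property
    def sub_rate(self) -> float:
        return self.error_rate * self.sub_frac

    @property
    def ins_rate(self) -> float:
        return self.error_rate * self.ins_frac

    @property
    def del_rate(self) -> float:
        return self.error_rate * self.del_frac


@dataclass(frozen=True)
class TruthOverlap:
    """Ground-truth overlap between two reads (error-free read frames).

    Intervals are 0-based half-open.  ``strand`` is '+' when both reads
    were sampled from the same genome strand, '-' otherwise.
    """

    id1: str
    id2: str
    strand: str
    s1: int
    e1: int
    s2: int
    e2: int

    @property
    def min_len(self) -> int:
        return min(self.e1 - self.s1, self.e2 - self.s2)


@dataclass
class SimStats:
    n_bases: int = 0
    n_sub: int = 0
    n_ins: int = 0
    n_del: int = 0

    @property
    def realized_error_rate(self) -> float:
        return (self.n_sub + self.n_ins + self.n_del) / max(1, self.n_bases)


@dataclass
class Placement:
    """Where a read was sampled on the genome (before errors)."""

    read_id: str
    start: int
    end: int
    strand: str  # '+' forward, '-' reverse complement


def mutate_sequence(
    seq: str,
    rng: np.random.Generator,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    stats: Optional[SimStats] = None,
) -> str:
    """Apply independent per-base substitution/insertion/deletion errors.

    The random draw sequence depends only on the sequence length, never
    on base identity, so simulations with the same seed stay aligned
    across strand choices.
    """
    out: List[str] = []
    for ch in seq:
        r = rng.random()
        if r < del_rate:
            if stats:
                stats.n_del += 1
        elif r < del_rate + sub_rate:
            # one draw picks among the three non-original bases
            offset = 1 + int(rng.integers(0, 3))
            out.append(_BASES[(_BASES.index(ch) + offset) % 4])
            if stats:
                stats.n_sub += 1
        else:
            out.append(ch)
        if rng.random() < ins_rate:
            out.append(_BASES[rng.integers(0, 4)])
            if stats:
                stats.n_ins += 1
    if stats:
        stats.n_bases += len(seq)
    return "".join(out)


def random_genome(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=length)])


def truth_from_placements(
    placements: Sequence[Placement], min_overlap: int = 1
) -> List[TruthOverlap]:
    """All read pairs whose genome intervals intersect by >= ``min_overlap``.

    Overlap intervals are projected into each read's error-free frame:
    position 0 of a forward read maps to its genome start, position 0 of
    a reverse read maps to its genome end.
    """
    truths: List[TruthOverlap] = []
    for i in range(len(placements)):
        a = placements[i]
        for j in range(i + 1, len(placements)):
            b = placements[j]
            os_, oe = max(a.start, b.start), min(a.end, b.end)
            if oe - os_ < min_overlap:
                continue
            if a.strand == "+":
                s1, e1 = os_ - a.start, oe - a.start
            else:
                s1, e1 = a.end - oe, a.end - os_
            if b.strand == "+":
                s2, e2 = os_ - b.start, oe - b.start
            else:
                s2, e2 = b.end - oe, b.end - os_
            strand = "+" if a.strand == b.strand else "-"
            truths.append(
                TruthOverlap(a.read_id, b.read_id, strand, s1, e1, s2, e2)
            )
    return truths


def simulate_full(
    config: SimConfig, stats: Optional[SimStats] = None
) -> Tuple[List[ReadRecord], List[TruthOverlap], str, List[Placement]]:
    """Like :func:`simulate` but also returns the genome and read placements."""
    rng = np.random.default_rng(config.seed)
    genome = random_genome(config.genome_length, rng)
    reads: List[ReadRecord] = []
    placements: List[Placement] = []
    width = len(str(config.n_reads - 1))
    for i in range(config.n_reads):
        length = int(round(rng.normal(config.read_length_mean, config.read_length_sd)))
        length = max(config.min_read_length, min(length, config.genome_length))
        start = int(rng.integers(0, config.genome_length - length + 1))
        end = start + length
        strand = "-" if rng.random() < config.revcomp_prob else "+"
        segment = genome[start:end]
        if strand == "-":
            segment = revcomp(segment)
        seq = mutate_sequence(
            segment, rng, config.sub_rate, config.ins_rate, config.del_rate, stats
        )
        read_id = f"read{i:0{width}d}"
        reads.append(ReadRecord(id=read_id, seq=seq))
        placements.append(Placement(read_id, start, end, strand))
    truth = truth_from_placements(placements, config.min_truth_overlap)
    logger.info("simulated %d reads, %d true overlaps", len(reads), len(truth))
    return reads, truth, genome, placements


def simulate(
    config: SimConfig, stats: Optional[SimStats] = None
) -> Tuple[List[ReadRecord], List[TruthOverlap]]:
    """Generate reads plus the ground-truth overlap table; seeded and exact.

    Reads are sampled uniformly on a random genome; a read drawn from
    the reverse strand is reverse-complemented before errors are
    applied.
    """
    reads, truth, _genome, _placements = simulate_full(config, stats)
    return reads, truth


def write_reads_fasta(reads: Iterable[ReadRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.seq}\n")


def write_truth_tsv(truths: Iterable[TruthOverlap], path: str) -> None:
    """TSV: id1, id2, strand, s1, e1, s2, e2 (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("#id1\tid2\tstrand\ts1\te1\ts2\te2\n")
        for t in truths:
            fh.write(f"{t.id1}\t{t.id2}\t{t.strand}\t{t.s1}\t{t.e1}\t{t.s2}\t{t.e2}\n")


def read_truth_tsv(path: str) -> List[TruthOverlap]:
    truths: List[TruthOverlap] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            truths.append(
                TruthOverlap(f[0], f[1], f[2], int(f[3]), int(f[4]), int(f[5]), int(f[6]))
            )
    return truths


def _interval_match(ds: int, de: int, ts: int, te: int, min_frac: float) -> bool:
    inter = min(de, te) - max(ds, ts)
    shorter = min(de - ds, te - ts)
    if shorter <= 0:
        return False
    return inter >= min_frac * shorter


def score(
    detected: Sequence[PafRow],
    truth: Sequence[TruthOverlap],
    min_len: int = 1,
    min_frac: float = 0.5,
    known_ids: Optional[set] = None,
) -> Tuple[float, float, float]:
    """Precision, recall and F1 of a detected overlap set against truth.

    A detected pair is a true positive iff the unordered pair is in the
    truth table with the same relative strand and the detected interval
    on each read intersects the true interval by >= ``min_frac`` of the
    shorter of the two.  Recall is measured against truth pairs whose
    shorter true interval is at least ``min_len``; precision counts a
    match against any truth pair.  An empty detected set scores
    precision 0 by convention.
    """
    truth_map: Dict[Tuple[str, str], TruthOverlap] = {}
    for t in truth:
        truth_map[(t.id1, t.id2)] = t
    if known_ids is not None:
        for row in detected:
            for rid in (row.qname, row.tname):
                if rid not in known_ids:
                    raise ValueError(f"detected read id {rid!r} not in truth read set")
    tp = 0
    matched: set = set()
    for row in detected:
        key, swapped = (row.qname, row.tname), False
        if key not in truth_map:
            key, swapped = (row.tname, row.qname), True
            if key not in truth_map:
                continue
        t = truth_map[key]
        if row.strand != t.strand:
            continue
        if swapped:
            q_iv, t_iv = (t.s2, t.e2), (t.s1, t.e1)
        else:
            q_iv, t_iv = (t.s1, t.e1), (t.s2, t.e2)
        if _interval_match(row.qstart, row.qend, *q_iv, min_frac) and _interval_match(
            row.tstart, row.tend, *t_iv, min_frac
        ):
            tp += 1
            matched.add(key)
    eligible = {(t.id1, t.id2) for t in truth if t.min_len >= min_len}
    precision = tp / len(detected) if detected else 0.0
    recall = len(matched & eligible) / len(eligible) if eligible else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1
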