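"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
import pytest

from lrod.common import OPPOSITE, POSITIVE, CommonKmer, CommonKmerSet
from lrod.driver_io import ReadRecord
from lrod.spectrum import (
    KmerSpectrum,
    Parameters,
    SolidKmerIndex,
    build_histogram,
    build_solid_index,
    count_kmers,
)

BASES = "ACGT"


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def toy_params(k: int = 15, **kwargs) -> Parameters:
    """Parameters with a consistent small-seed default for toy k values."""
    kwargs.setdefault("k_s", min(9, k - 1))
    kwargs.setdefault("min_read_len", 1)
    return Parameters(k=k, **kwargs)


def index_for(
    reads: List[ReadRecord], k: int, f_min: int = 2, f_max: Optional[int] = None
) -> Tuple[KmerSpectrum, SolidKmerIndex]:
    """Build a solid index over a small read set with an explicit f_max.

    When ``f_max`` is None every frequency >= f_min counts as solid,
    which is the convenient setting for hand-built pairs.
    """
    spec = count_kmers(reads, k)
    build_histogram(spec)
    spec.f_max = f_max if f_max is not None else max(spec.h, f_min)
    params = toy_params(k=k, f_min=f_min)
    return spec, build_solid_index(reads, spec, params)


def diagonal_anchors(
    positions: List[int], offset: int = 0, strand: str = POSITIVE
) -> List[CommonKmer]:
    """Positive anchors on the diagonal P2 = P1 + offset (distinct dummy k-mers)."""
    return [
        CommonKmer(P1=p, O1="+", P2=p + offset, O2="+" if strand == POSITIVE else "-", kmer=f"km{i}")
        for i, p in enumerate(positions)
    ]


def make_cks(anchors: List[CommonKmer], strand: str = POSITIVE) -> CommonKmerSet:
    anchors = sorted(anchors, key=lambda a: (a.P1, a.P2))
    m = sum(1 for a in anchors if a.positive)
    return CommonKmerSet(anchors=anchors, strand=strand, M=m, N=len(anchors) - m)


def random_cks(
    rng: np.random.Generator,
    n_anchors: int,
    read_len: int = 4000,
    strand: str = POSITIVE,
    noise: float = 0.3,
) -> Tuple[CommonKmerSet, ReadRecord, ReadRecord]:
    """Random anchor set: a noisy diagonal plus a fraction of outliers.

    Reads are random sequences long enough to contain every anchor, so
    stage-2 gap extraction always has material to work on.
    """
    span = read_len - 200
    p1s = np.sort(rng.choice(span, size=n_anchors, replace=False))
    anchors = []
    for i, p1 in enumerate(p1s):
        if rng.random() < noise:
            p2 = int(rng.integers(0, span))
        else:
            p2 = int(p1 + rng.integers(-40, 41))
            p2 = max(0, min(span, p2))
        if strand == OPPOSITE:
            p2 = span - p2
            o2 = "-"
        else:
            o2 = "+"
        anchors.append(CommonKmer(P1=int(p1), O1="+", P2=p2, O2=o2, kmer=f"km{i}"))
    r1 = ReadRecord(id="r1", seq=random_seq(rng, read_len))
    r2 = ReadRecord(id="r2", seq=random_seq(rng, read_len))
    return make_cks(anchors, strand), r1, r2
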