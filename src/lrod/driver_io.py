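"""End-to-end orchestration: input, pair enumeration, detection, PAF output."""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass
from typing import Dict, Iterable, List, NamedTuple, Optional, Tuple

from Bio import SeqIO

from . import chaining, common, finalize, spectrum
from .spectrum import Parameters, SolidKmerIndex

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


class ParseError(ValueError):
    """Malformed or invalid input data."""


@dataclass(frozen=True)
class ReadRecord:
    """One input read: unique identifier plus uppercase ACGTN sequence."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


def _open_text(path: str):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "r")


def _sniff_format(path: str) -> str:
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("@"):
                return "fastq"
            raise ParseError(f"{path}: unrecognized sequence format (first record line {line[:30]!r})")
    return "empty"


def load_reads(path: str, min_read_len: int = 0) -> List[ReadRecord]:
    """Load FASTA/FASTQ (optionally gzipped), dropping reads below the cutoff.

    Sequences are uppercased and must contain only A/C/G/T/N.  Duplicate
    identifiers and malformed records fail with a :class:`ParseError`.
    """
    fmt = _sniff_format(path)
    if fmt == "empty":
        logger.warning("%s: empty input file, no reads loaded", path)
        return []
    reads: List[ReadRecord] = []
    seen: set = set()
    dropped = 0
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, fmt):
                seq = str(rec.seq).upper()
                if rec.id in seen:
                    raise ParseError(f"{path}: duplicate read id {rec.id!r}")
                seen.add(rec.id)
                bad = set(seq) - _VALID_BASES
                if bad:
                    raise ParseError(
                        f"{path}: read {rec.id!r} contains invalid characters {sorted(bad)}"
                    )
                if len(seq) < min_read_len:
                    dropped += 1
                    continue
                reads.append(ReadRecord(id=rec.id, seq=seq))
        except ValueError as exc:
            if isinstance(exc, ParseError):
                raise
            raise ParseError(f"{path}: malformed {fmt} record: {exc}") from exc
    logger.info(
        "%s: kept %d reads, dropped %d shorter than %d bp",
        path, len(reads), dropped, min_read_len,
    )
    return reads


def build_index(
    reads: List[ReadRecord], params: Parameters
) -> Tuple[spectrum.KmerSpectrum, SolidKmerIndex]:
    """Count k-mers, derive the solid interval, and build the positional index."""
    spec = spectrum.count_kmers(reads, params.k)
    spectrum.build_histogram(spec)
    spec.f_max = spectrum.derive_fmax(spec.F, params.f_min, params.theta)
    logger.info(
        "spectrum: %d distinct k-mers, h=%d, solid interval [%d, %d]",
        len(spec.freq), spec.h, params.f_min, spec.f_max,
    )
    index = spectrum.build_solid_index(reads, spec, params)
    logger.info("index: %d solid k-mer postings", index.n_postings())
    return spec, index


def enumerate_pairs(index: SolidKmerIndex) -> List[Tuple[str, str]]:
    """Unordered read-id pairs sharing at least one solid k-mer.

    Pairs are oriented (i, j) with i before j in input order, each
    yielded exactly once, self-pairs excluded, sorted by input order for
    deterministic downstream processing.
    """
    order = index.read_order
    pairs: set = set()
    for posts in index.postings.values():
        if len(posts) < 2:
            continue
        rids = sorted({rid for rid, _pos, _orient in posts}, key=order.__getitem__)
        for i in range(len(rids)):
            for j in range(i + 1, len(rids)):
                pairs.add((rids[i], rids[j]))
    return sorted(pairs, key=lambda p: (order[p[0]], order[p[1]]))


def detect_pair(
    r1: ReadRecord,
    r2: ReadRecord,
    index: SolidKmerIndex,
    params: Parameters,
) -> Optional[finalize.Overlap]:
    """Full per-pair pipeline: anchors -> strand vote -> chain -> revision."""
    anchors = common.find_common_kmers(r1, r2, index, params.s)
    anchors = common.remove_nonunique(anchors)
    cks = common.classify_strand(anchors, params.count)
    if cks is None:
        return None
    chain = chaining.find_candidate_chain(cks, r1, r2, params)
    if chain is None:
        return None
    return finalize.finalize_pair(chain, r1, r2, params)


def detect_all(
    reads: List[ReadRecord],
    params: Parameters,
    progress: bool = False,
    debug_dir: Optional[str] = None,
) -> List[finalize.Overlap]:
    """Detect overlaps among all candidate pairs of the read set.

    Deterministic given the input order and parameters; output is sorted
    by (query, target) input order.  ``debug_dir``, when set, receives a
    per-pair anchor TSV for every classified pair.
    """
    if not reads:
        return []
    try:
        _spec, index = build_index(reads, params)
    except spectrum.DegenerateSpectrumError as exc:
        # No k-mer reaches f_min: nothing is solid, hence no overlaps.
        logger.warning("degenerate spectrum: %s; reporting no overlaps", exc)
        return []
    by_id: Dict[str, ReadRecord] = {r.id: r for r in reads}
    pairs = enumerate_pairs(index)
    logger.info("%d candidate pairs", len(pairs))
    if progress:
        from tqdm import tqdm

        pairs_iter: Iterable[Tuple[str, str]] = tqdm(pairs, unit="pair")
    else:
        pairs_iter = pairs
    overlaps: List[finalize.Overlap] = []
    for id1, id2 in pairs_iter:
        r1, r2 = by_id[id1], by_id[id2]
        if debug_dir is not None:
            ov = _detect_pair_debug(r1, r2, index, params, debug_dir)
        else:
            ov = detect_pair(r1, r2, index, params)
        if ov is not None:
            overlaps.append(ov)
    logger.info("%d overlaps accepted", len(overlaps))
    return overlaps


def _detect_pair_debug(
    r1: ReadRecord,
    r2: ReadRecord,
    index: SolidKmerIndex,
    params: Parameters,
    debug_dir: str,
) -> Optional[finalize.Overlap]:
    anchors = common.remove_nonunique(common.find_common_kmers(r1, r2, index, params.s))
    cks = common.classify_strand(anchors, params.count)
    if cks is None:
        return None
    chain = chaining.find_candidate_chain(cks, r1, r2, params)
    os.makedirs(debug_dir, exist_ok=True)
    chaining.dump_anchors_tsv(
        cks, chain, os.path.join(debug_dir, f"{r1.id}__{r2.id}.tsv")
    )
    if chain is None:
        return None
    return finalize.finalize_pair(chain, r1, r2, params)


class PafRow(NamedTuple):
    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    blocklen: int
    mapq: int


def overlap_to_paf(ov: finalize.Overlap, k: int) -> PafRow:
    """12-column PAF row; 1-based inclusive coordinates become 0-based half-open.

    Residue matches are approximated as anchor support times k; mapping
    quality is the conventional 255 placeholder.
    """
    span1 = ov.EP1 - ov.SP1 + 1
    span2 = ov.EP2 - ov.SP2 + 1
    return PafRow(
        qname=ov.id1,
        qlen=ov.Len1,
        qstart=ov.SP1 - 1,
        qend=ov.EP1,
        strand=ov.strand,
        tname=ov.id2,
        tlen=ov.Len2,
        tstart=ov.SP2 - 1,
        tend=ov.EP2,
        nmatch=ov.support * k,
        blocklen=max(span1, span2),
        mapq=255,
    )


def write_paf(overlaps: List[finalize.Overlap], path: str, k: int) -> None:
    """Write accepted overlaps as 12-column tab-separated PAF."""
    try:
        with open(path, "w") as fh:
            for ov in overlaps:
                fh.write("\t".join(str(f) for f in overlap_to_paf(ov, k)) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write PAF to {path}: {exc}") from exc


def read_paf(path: str) -> List[PafRow]:
    """Parse a 12-column PAF file back into rows."""
    rows: List[PafRow] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 PAF columns, got {len(fields)}")
            rows.append(
                PafRow(
                    qname=fields[0],
                    qlen=int(fields[1]),
                    qstart=int(fields[2]),
                    qend=int(fields[3]),
                    strand=fields[4],
                    tname=fields[5],
                    tlen=int(fields[6]),
                    tstart=int(fields[7]),
                    tend=int(fields[8]),
                    nmatch=int(fields[9]),
                    blocklen=int(fields[10]),
                    mapq=int(fields[11]),
                )
            )
    return rows
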