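"""Dataset-wide k-mer statistics and the solid-k-mer index.

A *solid* k-mer is one whose dataset-wide frequency lies in an interval
``[f_min, f_max]``: frequent enough that it is unlikely to contain a
sequencing error, rare enough that it is unlikely to come from a
repetitive region.  ``f_min`` is a fixed threshold (2 by default);
``f_max`` is derived from the k-mer frequency histogram as the smallest
frequency at which the cumulative histogram mass exceeds a quantile
``theta`` of the total mass at frequencies >= ``f_min``.

Counting is done on *canonical* k-mers (the lexicographic minimum of a
k-mer and its reverse complement) so that reads sequenced from opposite
strands still share k-mers.  K-mers containing a non-ACGT base are
skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, Iterable, Iterator, List, Tuple

if TYPE_CHECKING:  # pragma: no cover
    from .driver_io import ReadRecord

# Orientation of a k-mer occurrence relative to its canonical form.
FORWARD = "+"
REVERSE = "-"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class DegenerateSpectrumError(ValueError):
    """Raised when no k-mer reaches frequency ``f_min`` (nothing is solid)."""


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Canonical form: lexicographic min of the k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def iter_canonical_kmers(seq: str, k: int) -> Iterator[Tuple[int, str, str]]:
    """Yield ``(position, canonical_kmer, orientation)`` over every k-mer start.

    Positions are 0-based.  K-mers containing ``N`` are skipped.  The
    orientation is FORWARD when the literal k-mer equals its canonical
    form, REVERSE otherwise (palindromes, only possible for even k,
    report FORWARD).
    """
    n = len(seq)
    if n < k:
        return
    rc = revcomp(seq)
    for pos in range(n - k + 1):
        km = seq[pos : pos + k]
        if "N" in km:
            continue
        rk = rc[n - pos - k : n - pos]
        if km <= rk:
            yield pos, km, FORWARD
        else:
            yield pos, rk, REVERSE


@dataclass(frozen=True)
class Parameters:
    """All tunables of the detection pipeline, validated on construction.

    Attributes
    ----------
    k : seed length in bases.
    k_s : small seed length used by the stage-2 rescue, ``k_s < k``.
    s : extraction step on the first read of a pair.
    f_min : minimum solid k-mer frequency.
    theta : cumulative-mass quantile in (0, 1] used to derive ``f_max``.
    alpha : stage-1 distance bound between consecutive anchors (bases).
    beta : stage-2 distance bound (bases), ``alpha < beta``.
    gamma : maximum relative difference between the two anchor distances.
    epsilon : minimum accepted overlap length (bases).
    count : strand-vote threshold on the majority anchor class.
    min_read_len : reads shorter than this are dropped on input.
    """

    k: int = 15
    k_s: int = 9
    s: int = 1
    f_min: int = 2
    theta: float = 0.9
    alpha: int = 400
    beta: int = 1500
    gamma: float = 0.3
    epsilon: int = 500
    count: int = 5
    min_read_len: int = 2000

    def __post_init__(self) -> None:
        for name in ("k", "k_s", "s", "alpha", "beta", "epsilon", "min_read_len"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.k_s >= self.k:
            raise ValueError(f"k_s ({self.k_s}) must be smaller than k ({self.k})")
        if not 0 < self.theta <= 1:
            raise ValueError(f"theta must be in (0, 1], got {self.theta}")
        if not 0 <= self.gamma < 1:
            raise ValueError(f"gamma must be in [0, 1), got {self.gamma}")
        if self.alpha >= self.beta:
            raise ValueError(f"alpha ({self.alpha}) must be < beta ({self.beta})")
        if self.f_min < 2:
            raise ValueError(f"f_min must be >= 2, got {self.f_min}")
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")


@dataclass
class KmerSpectrum:
    """Frequency map of canonical k-mers plus its derived histogram.

    ``F[x]`` is the number of distinct k-mers with frequency exactly x;
    ``h`` is the maximum observed frequency; ``f_max`` is filled in by
    :func:`derive_fmax`.  ``skipped`` counts k-mer occurrences dropped
    because they contained an N.
    """

    k: int = 0
    freq: Dict[str, int] = field(default_factory=dict)
    F: Dict[int, int] = field(default_factory=dict)
    h: int = 0
    f_max: int | None = None
    skipped: int = 0

    def total_occurrences(self) -> int:
        return sum(self.freq.values())


def count_kmers(reads: Iterable["ReadRecord"], k: int) -> KmerSpectrum:
    """Count canonical k-mers across all reads.

    Each read of length L contributes max(0, L-k+1) k-mer occurrences,
    minus occurrences skipped because they contain an N.  Characters
    other than A/C/G/T/N must have been rejected upstream.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    freq: Dict[str, int] = {}
    skipped = 0
    for read in reads:
        n = len(read.seq)
        seen = 0
        for _pos, km, _orient in iter_canonical_kmers(read.seq, k):
            freq[km] = freq.get(km, 0) + 1
            seen += 1
        skipped += max(0, n - k + 1) - seen
    return KmerSpectrum(k=k, freq=freq, skipped=skipped)


def build_histogram(spectrum: KmerSpectrum) -> Tuple[Dict[int, int], int]:
    """Fill in and return the frequency histogram F and max frequency h.

    ``F[x]`` counts distinct k-mers whose frequency is exactly ``x``;
    frequencies with no k-mers are simply absent (``F.get(x, 0) == 0``).
    An empty spectrum yields an empty F and ``h == 0``.
    """
    F: Dict[int, int] = {}
    for f in spectrum.freq.values():
        F[f] = F.get(f, 0) + 1
    spectrum.F = F
    spectrum.h = max(F) if F else 0
    return F, spectrum.h


def derive_fmax(F: Dict[int, int], f_min: int, theta: float) -> int:
    """Smallest f with cumulative mass S(f) = sum_{x=f_min..f} F(x) > theta*S(h).

    S(h) is the total number of distinct k-mers with frequency >= f_min.
    For theta == 1 the strict inequality can never hold and the maximum
    frequency h is returned.

    Raises
    ------
    DegenerateSpectrumError
        If no k-mer has frequency >= f_min.
    """
    xs = sorted(x for x in F if x >= f_min and F[x] > 0)
    if not xs:
        raise DegenerateSpectrumError(
            f"no k-mer has frequency >= f_min={f_min}; cannot derive f_max"
        )
    total = sum(F[x] for x in xs)
    threshold = theta * total
    cum = 0
    for x in xs:
        cum += F[x]
        if cum > threshold:
            return x
    return xs[-1]  # theta == 1 (or floating-point edge): all mass needed


class SolidKmerIndex:
    """Postings from canonical solid k-mer to its occurrences in the reads.

    Each posting is ``(read_id, start, orientation)`` with a 0-based
    start.  Per-read views (used to intersect two reads quickly) are
    built lazily on first access.
    """

    def __init__(self, k: int, read_order: Dict[str, int]):
        self.k = k
        self.postings: Dict[str, List[Tuple[str, int, str]]] = {}
        self.read_order = read_order
        self._by_read: Dict[str, Dict[str, List[Tuple[int, str]]]] | None = None

    def add(self, kmer: str, read_id: str, pos: int, orient: str) -> None:
        self.postings.setdefault(kmer, []).append((read_id, pos, orient))
        self._by_read = None

    def _build_by_read(self) -> Dict[str, Dict[str, List[Tuple[int, str]]]]:
        if self._by_read is None:
            by_read: Dict[str, Dict[str, List[Tuple[int, str]]]] = {}
            for kmer, posts in self.postings.items():
                for read_id, pos, orient in posts:
                    by_read.setdefault(read_id, {}).setdefault(kmer, []).append(
                        (pos, orient)
                    )
            self._by_read = by_read
        return self._by_read

    def kmer_positions(self, read_id: str) -> Dict[str, List[Tuple[int, str]]]:
        """Map canonical solid k-mer -> [(pos, orientation)] within one read."""
        return self._build_by_read().get(read_id, {})

    def occurrences(self, read_id: str) -> List[Tuple[int, str, str]]:
        """All solid occurrences in one read as (pos, kmer, orientation), sorted."""
        occ = [
            (pos, kmer, orient)
            for kmer, positions in self.kmer_positions(read_id).items()
            for pos, orient in positions
        ]
        occ.sort()
        return occ

    def n_postings(self) -> int:
        return sum(len(p) for p in self.postings.values())


def build_solid_index(
    reads: Iterable["ReadRecord"], spectrum: KmerSpectrum, params: Parameters
) -> SolidKmerIndex:
    """Index every occurrence of a solid k-mer (frequency in [f_min, f_max])."""
    if spectrum.f_max is None:
        raise ValueError("spectrum.f_max not derived; call derive_fmax first")
    f_min, f_max = params.f_min, spectrum.f_max
    freq = spectrum.freq
    reads = list(reads)
    read_order = {r.id: i for i, r in enumerate(reads)}
    index = SolidKmerIndex(spectrum.k, read_order)
    for read in reads:
        for pos, km, orient in iter_canonical_kmers(read.seq, spectrum.k):
            f = freq.get(km, 0)
            if f_min <= f <= f_max:
                index.add(km, read.id, pos, orient)
    return index


def dump_spectrum_tsv(spectrum: KmerSpectrum, path: str) -> None:
    """Write the histogram as two-column TSV ``frequency<TAB>F(frequency)``."""
    with open(path, "w") as fh:
        for x in sorted(spectrum.F):
            fh.write(f"{x}\t{spectrum.F[x]}\n")
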