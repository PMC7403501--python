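# lrod — long-read overlap detection from the k-mer frequency distribution

`lrod` detects pairwise overlaps in an error-prone long-read set
(PacBio/ONT-style, 10–20% mixed indel/substitution errors) and reports
them as 12-column PAF. The pipeline:

1. **Solid k-mer selection** (`lrod.spectrum`) — canonical k-mers are
   counted across the whole dataset; k-mers with frequency in
   `[f_min, f_max]` are *solid* (frequent enough not to be an error,
   rare enough not to be repeat-derived). `f_max` is the smallest
   frequency at which the cumulative histogram mass exceeds a quantile
   `theta` of the mass at frequencies ≥ `f_min`. Solid occurrences are
   indexed by read, position and orientation.
2. **Common k-mer set** (`lrod.common`) — for each candidate pair, solid
   k-mers shared by both reads become anchors (position + orientation in
   each read). Anchors from repeated k-mers are dropped, and a majority
   vote over same-/opposite-orientation anchors fixes the pair's
   relative strand (ties or weak majorities ⇒ no overlap).
3. **Chaining** (`lrod.chaining`) — a greedy chain of pairwise
   *consistent* anchors. Consistency is two-staged: a fast test
   (monotone advance, both inter-anchor distances < `alpha`, relative
   distance difference < `gamma`), rescued on failure by a looser bound
   `beta` plus a path of small `k_s`-mer matches through the
   inter-anchor gap. All start anchors are tried (memoized); the largest
   chain wins and must have more than 2 anchors.
4. **Revision & acceptance** (`lrod.finalize`) — the chain's draft
   interval is extended to the read boundaries (four dovetail/containment
   cases); the result is accepted when the chain spans it to within
   `alpha` on both reads, the shorter side exceeds `epsilon`, and the
   two per-read lengths agree within `gamma`.

`lrod.simtools` simulates reads from a random genome with configurable
substitution/insertion/deletion errors and known sampling coordinates,
emits a ground-truth overlap table, and scores PAF output
(precision/recall/F1 with a reciprocal 50% interval-intersection match
criterion).

## CLI

```sh
# detect overlaps (FASTA/FASTQ, optionally gzipped) -> PAF
lrod detect reads.fasta -o out.paf \
    [--k 15 --ks 9 --step 1 --fmin 2 --theta 0.9 --alpha 400 --beta 1500 \
     --gamma 0.3 --epsilon 500 --count 5 --min-read-len 2000 \
     --config params.yaml --dump-spectrum spec.tsv --debug-anchors DIR]

# simulate a read set with ground truth
lrod simulate --genome-length 200000 --n-reads 250 --error-rate 0.1 \
    --revcomp-prob 0.5 --seed 7 -o sim
# -> sim.fasta, sim.truth.tsv

# score a PAF against the truth table
lrod score --paf out.paf --truth sim.truth.tsv --min-len 500
```

A YAML config file may set any parameter (`k: 15`, `epsilon: 500`, …);
explicit CLI flags override it. Exit codes: 0 success (including zero
overlaps), 1 usage error, 2 input parse error.

## Library

```python
from lrod import Parameters, detect_all, load_reads, write_paf

params = Parameters()                       # validated defaults
reads = load_reads("reads.fasta", params.min_read_len)
overlaps = detect_all(reads, params)        # list of Overlap records
write_paf(overlaps, "out.paf", params.k)
```

## Notes

- Counting is canonical (min of k-mer and reverse complement); k-mers
  containing `N` are skipped.
- Internal coordinates are 0-based half-open; PAF output is 0-based
  half-open on the original strands, with strand `-` for
  opposite-orientation overlaps.
- Detection is deterministic for a given input order and parameter set;
  output is sorted by input order of (query, target).
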