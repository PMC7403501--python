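"""I/O, pair enumeration, end-to-end detection, PAF round trips, CLI."""

import gzip

import pytest

from lrod.cli import main as cli_main
from lrod.common import OPPOSITE, POSITIVE
from lrod.driver_io import (
    ParseError,
    ReadRecord,
    build_index,
    detect_all,
    detect_pair,
    enumerate_pairs,
    load_reads,
    overlap_to_paf,
    read_paf,
    write_paf,
)
from lrod.spectrum import canonical, revcomp

from conftest import index_for, random_seq, toy_params

PARAMS = toy_params()

def run_cli(args):
    """Invoke the CLI entry point and normalize its exit code."""
    try:
        return cli_main(args) or 0
    except SystemExit as exc:
        return exc.code or 0



class TestLoadReads:
    def test_length_filter(self, tmp_path, rng):
        p = tmp_path / "in.fasta"
        p.write_text(f">short\n{random_seq(rng, 1500)}\n>long\n{random_seq(rng, 2500)}\n")
        reads = load_reads(str(p), min_read_len=2000)
        assert [r.id for r in reads] == ["long"]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        assert load_reads(str(p), 2000) == []

    def test_fastq_roundtrip(self, tmp_path, rng):
        seqs = {f"q{i}": random_seq(rng, 50) for i in range(5)}
        p = tmp_path / "in.fastq"
        p.write_text("".join(f"@{n}\n{s}\n+\n{'I' * len(s)}\n" for n, s in seqs.items()))
        reads = load_reads(str(p), 0)
        assert {r.id: r.seq for r in reads} == seqs

    def test_gzipped_fasta(self, tmp_path, rng):
        seq = random_seq(rng, 60)
        p = tmp_path / "in.fasta.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(f">a\n{seq}\n")
        reads = load_reads(str(p), 0)
        assert reads == [ReadRecord("a", seq)]

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">a\nacgtn\n")
        assert load_reads(str(p), 0)[0].seq == "ACGTN"

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">a\nACGT\n>a\nACGT\n")
        with pytest.raises(ParseError, match="duplicate"):
            load_reads(str(p), 0)

    def test_invalid_character_rejected(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">a\nACRT\n")
        with pytest.raises(ParseError, match="invalid characters"):
            load_reads(str(p), 0)

    def test_unrecognized_format(self, tmp_path):
        p = tmp_path / "in.txt"
        p.write_text("not sequence data\n")
        with pytest.raises(ParseError):
            load_reads(str(p), 0)


class TestEnumeratePairs:
    def test_three_reads_sharing_kmer(self, rng):
        shared = random_seq(rng, 15)
        reads = [
            ReadRecord(f"r{i}", random_seq(rng, 40) + shared + random_seq(rng, 40))
            for i in range(3)
        ]
        _spec, index = index_for(reads, k=15)
        pairs = enumerate_pairs(index)
        assert set(pairs) == {("r0", "r1"), ("r0", "r2"), ("r1", "r2")}

    def test_disjoint_reads(self, rng):
        reads = [ReadRecord(f"r{i}", random_seq(rng, 100)) for i in range(4)]
        _spec, index = index_for(reads, k=15, f_max=50)
        assert enumerate_pairs(index) == []

    def test_matches_bruteforce_intersection(self, rng):
        reads = []
        shared_a, shared_b = random_seq(rng, 15), random_seq(rng, 15)
        for i in range(8):
            seq = random_seq(rng, 60)
            if i % 2 == 0:
                seq += shared_a
            if i % 3 == 0:
                seq += shared_b
            reads.append(ReadRecord(f"r{i}", seq + random_seq(rng, 20)))
        _spec, index = index_for(reads, k=15)
        got = set(enumerate_pairs(index))
        solid = set(index.postings)
        kmer_sets = {
            r.id: {
                canonical(r.seq[i : i + 15])
                for i in range(len(r.seq) - 14)
            }
            & solid
            for r in reads
        }
        expect = {
            (reads[i].id, reads[j].id)
            for i in range(len(reads))
            for j in range(i + 1, len(reads))
            if kmer_sets[reads[i].id] & kmer_sets[reads[j].id]
        }
        assert got == expect

    def test_no_self_pairs_no_duplicates(self, rng):
        shared = random_seq(rng, 15)
        reads = [
            ReadRecord(f"r{i}", shared + random_seq(rng, 30) + shared)
            for i in range(3)
        ]
        _spec, index = index_for(reads, k=15)
        pairs = enumerate_pairs(index)
        assert len(pairs) == len(set(pairs))
        assert all(a != b for a, b in pairs)


@pytest.fixture
def dovetail(rng):
    """Two error-free reads overlapping by an exact 3 kb suffix/prefix."""
    genome = random_seq(rng, 9000)
    r1 = ReadRecord("r1", genome[:6000])
    r2 = ReadRecord("r2", genome[3000:])
    return r1, r2


class TestDetection:
    def test_dovetail_positive_overlap(self, dovetail):
        r1, r2 = dovetail
        overlaps = detect_all([r1, r2], PARAMS)
        assert len(overlaps) == 1
        ov = overlaps[0]
        assert (ov.id1, ov.id2, ov.strand) == ("r1", "r2", POSITIVE)
        # true overlap: r1[3000:6000] vs r2[0:3000] (0-based)
        assert abs((ov.SP1 - 1) - 3000) <= PARAMS.k
        assert ov.EP1 == 6000
        assert ov.SP2 == 1
        assert abs(ov.EP2 - 3000) <= PARAMS.k

    def test_dovetail_length_within_k_of_truth(self, dovetail):
        r1, r2 = dovetail
        ov = detect_all([r1, r2], PARAMS)[0]
        assert abs(ov.overlap_len1 - 3000) <= PARAMS.k
        assert abs(ov.overlap_len2 - 3000) <= PARAMS.k

    def test_reverse_strand_overlap(self, dovetail):
        r1, (_, tail) = dovetail[0], ("", dovetail[1].seq)
        r2 = ReadRecord("r2", revcomp(tail))
        overlaps = detect_all([r1, r2], PARAMS)
        assert len(overlaps) == 1
        ov = overlaps[0]
        assert ov.strand == OPPOSITE
        # overlapping genome segment sits at the far end of the flipped r2
        assert abs((ov.SP2 - 1) - 3000) <= PARAMS.k
        assert ov.EP2 == 6000
        row = overlap_to_paf(ov, PARAMS.k)
        assert row.strand == "-"

    def test_unrelated_reads_no_overlap(self, rng):
        reads = [ReadRecord("a", random_seq(rng, 10000)), ReadRecord("b", random_seq(rng, 10000))]
        assert detect_all(reads, PARAMS) == []

    def test_detect_pair_no_common(self, rng):
        reads = [ReadRecord("a", random_seq(rng, 3000)), ReadRecord("b", random_seq(rng, 3000))]
        _spec, index = index_for(reads, k=15, f_max=50)
        assert detect_pair(reads[0], reads[1], index, PARAMS) is None

    def test_empty_read_set(self):
        assert detect_all([], PARAMS) == []

    def test_determinism_byte_identical(self, dovetail, tmp_path):
        r1, r2 = dovetail
        out1, out2 = tmp_path / "a.paf", tmp_path / "b.paf"
        write_paf(detect_all([r1, r2], PARAMS), str(out1), PARAMS.k)
        write_paf(detect_all([r1, r2], PARAMS), str(out2), PARAMS.k)
        assert out1.read_bytes() == out2.read_bytes()


class TestPaf:
    def test_single_overlap_twelve_fields(self, dovetail, tmp_path):
        r1, r2 = dovetail
        overlaps = detect_all([r1, r2], PARAMS)
        out = tmp_path / "out.paf"
        write_paf(overlaps, str(out), PARAMS.k)
        lines = out.read_text().splitlines()
        assert len(lines) == 1
        assert len(lines[0].split("\t")) == 12

    def test_roundtrip(self, dovetail, tmp_path):
        r1, r2 = dovetail
        overlaps = detect_all([r1, r2], PARAMS)
        out = tmp_path / "out.paf"
        write_paf(overlaps, str(out), PARAMS.k)
        rows = read_paf(str(out))
        assert len(rows) == 1
        row, ov = rows[0], overlaps[0]
        assert row.qname == ov.id1 and row.tname == ov.id2
        assert (row.qstart, row.qend) == (ov.SP1 - 1, ov.EP1)
        assert (row.tstart, row.tend) == (ov.SP2 - 1, ov.EP2)
        assert (row.qlen, row.tlen) == (ov.Len1, ov.Len2)
        assert row.mapq == 255

    def test_empty_overlap_list(self, tmp_path):
        out = tmp_path / "out.paf"
        write_paf([], str(out), 15)
        assert out.read_text() == ""
        assert read_paf(str(out)) == []

    def test_malformed_paf_rejected(self, tmp_path):
        p = tmp_path / "bad.paf"
        p.write_text("a\tb\tc\n")
        with pytest.raises(ParseError):
            read_paf(str(p))


class TestCli:
    def test_detect_end_to_end(self, dovetail, tmp_path):
        r1, r2 = dovetail
        reads = tmp_path / "reads.fasta"
        reads.write_text(f">{r1.id}\n{r1.seq}\n>{r2.id}\n{r2.seq}\n")
        out = tmp_path / "out.paf"
        spectrum_tsv = tmp_path / "spectrum.tsv"
        code = run_cli([
                "detect", str(reads), "-o", str(out),
                "--dump-spectrum", str(spectrum_tsv),
            ])
        assert code == 0
        assert len(read_paf(str(out))) == 1
        assert spectrum_tsv.exists()

    def test_usage_error_exit_code_1(self, tmp_path):
        code = run_cli(["detect", "--bogus-flag"])
        assert code == 1

    def test_parse_error_exit_code_2(self, tmp_path):
        bad = tmp_path / "bad.fasta"
        bad.write_text(">a\nACRT\n")
        code = run_cli(["detect", str(bad), "-o", str(tmp_path / "o.paf"), "--min-read-len", "1"])
        assert code == 2

    def test_config_file_overridden_by_flags(self, dovetail, tmp_path):
        r1, r2 = dovetail
        reads = tmp_path / "reads.fasta"
        reads.write_text(f">{r1.id}\n{r1.seq}\n>{r2.id}\n{r2.seq}\n")
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("epsilon: 100000\nmin_read_len: 100\n")  # would reject everything
        out = tmp_path / "out.paf"
        code = run_cli([
                "detect", str(reads), "-o", str(out),
                "--config", str(cfg), "--epsilon", "500",
            ])
        assert code == 0
        assert len(read_paf(str(out))) == 1  # CLI flag restored a sane epsilon

    def test_simulate_and_score_commands(self, tmp_path):
        prefix = tmp_path / "sim"
        code = run_cli([
                "simulate", "--genome-length", "20000", "--n-reads", "12",
                "--read-length-mean", "4000", "--read-length-sd", "300",
                "--error-rate", "0.03", "--seed", "5", "-o", str(prefix),
            ])
        assert code == 0
        reads_fa = f"{prefix}.fasta"
        truth_tsv = f"{prefix}.truth.tsv"
        out = tmp_path / "out.paf"
        code = run_cli(["detect", reads_fa, "-o", str(out), "--min-read-len", "1000"])
        assert code == 0
        code = run_cli(["score", "--paf", str(out), "--truth", truth_tsv, "--min-len", "500"])
        assert code == 0


def test_cli_help_exits_zero():
    code = run_cli(["--help"])
    assert code == 0
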