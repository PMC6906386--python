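"""Read processing against a naive per-read oracle, SAM round-trips, and
GFF3 3'-UTR extraction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from crossmir import smallrna_io as sio
from crossmir import synthetic_data as syn
from crossmir.source_attribution import Library, match_read

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def make_read(rid, seq, quals):
    return sio.SmallRNARead(rid, seq, tuple(quals))


# ---------------------------------------------------------------------------
# process_reads
# ---------------------------------------------------------------------------

def naive_filter(read, adapter, min_phred, window, mode="trim"):
    """Independent per-read reference filter: returns the retained sequence
    or None, applying the same documented rules one read at a time."""
    seq, qual = read.sequence, list(read.quality or [])
    if adapter:
        for i in range(len(seq)):
            m = min(len(adapter), len(seq) - i)
            if m >= 8 and seq[i:i + m] == adapter[:m]:
                seq, qual = seq[:i], qual[:i]
                break
    if read.quality is not None:
        if mode == "drop":
            if any(q < min_phred for q in qual):
                return None
        else:
            keep = len(seq)
            for i, q in enumerate(qual):
                if q < min_phred:
                    keep = i
                    break
            seq = seq[:keep]
    if window[0] <= len(seq) <= window[1]:
        return seq
    return None


class TestProcessReads:
    def test_adapter_clipped_read_retained(self):
        seq = "A" * 30 + ADAPTER[:12]
        rs = sio.ReadSet("s", reads=[make_read("r1", seq, [40] * len(seq))])
        out, stats = sio.process_reads(rs, ADAPTER, 28, (17, 35))
        assert [r.sequence for r in out.reads] == ["A" * 30]
        assert stats.n_adapter_clipped == 1 and stats.n_retained == 1

    def test_short_read_dropped_at_window_boundary(self):
        rs = sio.ReadSet("s", reads=[make_read("r1", "A" * 16, [40] * 16),
                                     make_read("r2", "C" * 17, [40] * 17)])
        out, stats = sio.process_reads(rs, "", 28, (17, 35))
        assert [r.id for r in out.reads] == ["r2"]
        assert stats.dropped_length == 1

    def test_quality_trim_vs_drop_modes(self):
        quals = [40] * 20 + [10] + [40] * 9
        rs = sio.ReadSet("s", reads=[make_read("r1", "A" * 30, quals)])
        trimmed, _ = sio.process_reads(rs, "", 28, (17, 35), "trim")
        assert len(trimmed.reads[0].sequence) == 20
        dropped, stats = sio.process_reads(rs, "", 28, (17, 35), "drop")
        assert len(dropped.reads) == 0 and stats.dropped_quality == 1

    def test_thousand_reads_match_naive_oracle(self, rng):
        reads = []
        for i in range(1000):
            n = int(rng.integers(12, 45))
            seq = "".join(rng.choice(list("ACGT"), n))
            if rng.random() < 0.5:  # plant an adapter suffix
                seq = seq[:int(rng.integers(0, n))] + ADAPTER[:int(rng.integers(8, 21))]
            quals = rng.choice([40, 35, 30, 20, 10], size=len(seq),
                               p=[0.6, 0.2, 0.1, 0.05, 0.05]).tolist()
            reads.append(make_read(f"r{i}", seq, quals))
        rs = sio.ReadSet("s", reads=reads)
        for mode in ("trim", "drop"):
            out, stats = sio.process_reads(rs, ADAPTER, 28, (17, 35), mode)
            expected = {r.id: naive_filter(r, ADAPTER, 28, (17, 35), mode)
                        for r in reads}
            expected = {k: v for k, v in expected.items() if v is not None}
            assert {r.id: r.sequence for r in out.reads} == expected
            assert stats.n_retained + stats.n_dropped == stats.n_input == 1000

    def test_idempotent(self, rng):
        reads = [make_read(f"r{i}",
                           "".join(rng.choice(list("ACGT"), 30)) + ADAPTER[:10],
                           [40] * 40) for i in range(50)]
        rs = sio.ReadSet("s", reads=reads)
        once, _ = sio.process_reads(rs, ADAPTER, 28, (17, 35))
        twice, stats = sio.process_reads(once, ADAPTER, 28, (17, 35))
        assert [r.sequence for r in twice.reads] == [r.sequence for r in once.reads]
        assert stats.n_dropped == 0 and stats.n_adapter_clipped == 0

    @given(st.lists(st.tuples(
        st.text(alphabet="ACGT", min_size=1, max_size=45),
        st.integers(min_value=0, max_value=41)), min_size=1, max_size=20))
    def test_conservation_property(self, raw):
        reads = [make_read(f"r{i}", seq, [q] * len(seq))
                 for i, (seq, q) in enumerate(raw)]
        rs = sio.ReadSet("s", reads=reads)
        out, stats = sio.process_reads(rs, ADAPTER, 28, (17, 35))
        assert stats.n_retained + stats.n_dropped == len(reads)
        assert len(out.reads) == stats.n_retained

    def test_empty_adapter_warns_and_skips(self, caplog):
        rs = sio.ReadSet("s", reads=[make_read("r", "A" * 20, [40] * 20)])
        with caplog.at_level("WARNING"):
            out, _ = sio.process_reads(rs, "", 28, (17, 35))
        assert "adapter" in caplog.text
        assert out.reads[0].sequence == "A" * 20


# ---------------------------------------------------------------------------
# FASTQ / FASTA round trips
# ---------------------------------------------------------------------------

def test_fastq_round_trip(tmp_path):
    reads = [make_read("a", "ACGTACGTACGTACGTA", [38] * 17),
             make_read("b", "TTTTACGTACGTACGTACGT", [40] * 20)]
    path = tmp_path / "x.fastq"
    sio.write_fastq(reads, path)
    back = sio.read_fastq(path)
    assert back == reads


def test_malformed_fastq_names_record_index(tmp_path):
    path = tmp_path / "bad.fastq"
    path.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGTACGT\n+\nII\n")
    with pytest.raises(sio.FastqParseError, match="#1"):
        sio.read_fastq(path)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:ref1\tLN:1000\n"


def test_parse_alignments_nm_and_gaps(tmp_path):
    sam = SAM_HEADER + "\n".join([
        "r0\t0\tref1\t1\t255\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\tNM:i:0",
        "r1\t0\tref1\t5\t255\t10M1I10M\t*\t0\t0\t" + "A" * 21 + "\t*\tNM:i:1",
        "r2\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 20 + "\t*",          # unmapped
        "r3\t0\tref1\t9\t255\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\tMD:Z:5A14",
        "r4\t0\tref1\t9\t255\t20M\t*\t0\t0\t" + "A" * 20 + "\t*",   # no NM/MD
    ]) + "\n"
    path = tmp_path / "x.sam"
    path.write_text(sam)
    records, rejected = sio.parse_alignments(path, "lib")
    by_id = {r.read_id: r for r in records}
    assert rejected == 1 and "r2" not in by_id and "r4" not in by_id
    assert by_id["r0"].mismatches == 0 and not by_id["r0"].gapped
    assert by_id["r1"].gapped
    assert by_id["r3"].mismatches == 1  # reconstructed from MD
    assert by_id["r3"].start == 8       # SAM is 1-based, records are 0-based


@pytest.mark.parametrize("md,expected", [
    ("20", 0), ("5A14", 1), ("0A0C18", 2), ("10^ACG10", 0), ("3T2^AC4G1", 2)])
def test_md_mismatch_reconstruction(md, expected):
    assert sio._mismatches_from_md(md) == expected


def test_internal_matcher_sam_round_trip(tmp_path, genome_set):
    """Matcher hits -> SAM -> parse: identical AlignmentRecords."""
    plant = genome_set.sequences["plant"]
    lib = Library("plant", "host_plant", plant)
    rng = np.random.default_rng(0)
    reads, records = {}, []
    for i in range(50):
        start = int(rng.integers(0, len(plant) - 22))
        seq = plant[start:start + 22]
        if rng.random() < 0.5:
            seq = syn.revcomp(seq)
        rid = f"r{i}"
        reads[rid] = seq
        records.extend(match_read(seq, lib, k_max=1, read_id=rid))
    path = tmp_path / "hits.sam"
    sio.write_alignments_sam(records, reads, {"plant": len(plant)}, path)
    back, rejected = sio.parse_alignments(path, "plant")
    assert rejected == 0
    assert sorted(back, key=lambda r: (r.read_id, r.start, r.strand)) == \
           sorted(records, key=lambda r: (r.read_id, r.start, r.strand))


# ---------------------------------------------------------------------------
# GFF3 3' UTRs
# ---------------------------------------------------------------------------

def gff_text(genes):
    """genes: list of (gene_id, [(tx_id, utr_start, utr_end)])  (1-based)."""
    lines = ["##gff-version 3"]
    for gid, txs in genes:
        lo = min(s for _, s, _ in txs)
        hi = max(e for _, _, e in txs)
        lines.append(f"chr1\tsrc\tgene\t{lo}\t{hi}\t.\t+\t.\tID={gid}")
        for tid, s, e in txs:
            lines.append(f"chr1\tsrc\tmRNA\t{lo}\t{hi}\t.\t+\t.\tID={tid};Parent={gid}")
            lines.append(f"chr1\tsrc\tthree_prime_UTR\t{s}\t{e}\t.\t+\t.\tParent={tid}")
    return "\n".join(lines) + "\n"


def test_shared_utr_merges_isoforms(tmp_path):
    path = tmp_path / "a.gff3"
    path.write_text(gff_text([("g1", [("t1", 100, 200), ("t2", 100, 200)])]))
    df, skipped = sio.extract_three_prime_utrs(path)
    assert skipped == 0 and len(df) == 1
    assert df.iloc[0].transcripts == ("t1", "t2")
    assert df.iloc[0].n_transcripts == 2
    assert df.iloc[0].gene_id == "g1"


def test_distinct_utrs_stay_separate(tmp_path):
    path = tmp_path / "b.gff3"
    path.write_text(gff_text([("g1", [("t1", 100, 200), ("t2", 150, 250)])]))
    df, _ = sio.extract_three_prime_utrs(path)
    assert len(df) == 2 and set(df.n_transcripts) == {1}


def test_multiplicity_matches_parent_attribute_count(tmp_path, rng):
    genes = []
    for g in range(100):
        n_tx = int(rng.integers(1, 4))
        base = 1000 * g + 100
        shared = rng.random() < 0.5
        txs = [(f"g{g}.t{t}", base, base + 100) if shared or t == 0
               else (f"g{g}.t{t}", base + 10 * t, base + 100 + 10 * t)
               for t in range(n_tx)]
        genes.append((f"g{g}", txs))
    path = tmp_path / "c.gff3"
    text = gff_text(genes)
    path.write_text(text)
    df, _ = sio.extract_three_prime_utrs(path)
    # brute-force oracle: count Parent attributes on three_prime_UTR lines
    expected = sum(line.count("Parent=") for line in text.splitlines()
                   if "\tthree_prime_UTR\t" in line)
    assert int(df.n_transcripts.sum()) == expected


def test_utr_without_parent_skipped_and_counted(tmp_path):
    path = tmp_path / "d.gff3"
    path.write_text("##gff-version 3\n"
                    "chr1\tsrc\tthree_prime_UTR\t10\t50\t.\t+\t.\tID=orphan\n")
    df, skipped = sio.extract_three_prime_utrs(path)
    assert skipped == 1 and len(df) == 0
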