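"""Read processing and parsers/writers for the standard formats the pipeline touches.

Small RNA reads arrive as FASTQ (phred-33) or FASTA; alignments as SAM;
gene models as GFF3; homology evidence as BLAST tabular (outfmt 6 with a
qcovs column).  All internal coordinates are 0-based half-open; written
reports use 1-based closed coordinates and say so in their headers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

TISSUES = ("gut", "bacteriome", "other")

#: Length windows used for insect-tissue mapping and for plant miRNA
#: precursor annotation, respectively (nucleotides, inclusive).
INSECT_WINDOW = (17, 35)
PLANT_ANNOTATION_WINDOW = (17, 25)


@dataclass(frozen=True)
class SmallRNARead:
    """A single small RNA read; quality is per-base phred scores or None."""

    id: str
    sequence: str
    quality: tuple | None = None

    def __post_init__(self):
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id}: quality length != sequence length")


@dataclass
class ReadSet:
    """A sample's reads plus tissue/line metadata and processing provenance."""

    sample_id: str
    tissue: str = "other"
    line: str = ""
    reads: list = field(default_factory=list)
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")

    def __len__(self):
        return len(self.reads)


@dataclass(frozen=True)
class AlignmentRecord:
    """One ungapped-or-gapped alignment of a read to a library reference."""

    read_id: str
    library: str
    reference: str
    start: int  # 0-based
    strand: str  # '+' or '-'
    mismatches: int
    gapped: bool = False

    def __post_init__(self):
        if self.start < 0:
            raise ValueError("alignment start must be >= 0")
        if self.mismatches < 0:
            raise ValueError("mismatch count must be >= 0")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class HomologyRecord:
    """One homology-search hit (BLAST-style), e-value plus query coverage."""

    query_id: str
    subject_id: str
    evalue: float
    query_coverage: float  # fraction in [0, 1]
    kind: str = "precursor_blast"  # or "short_blast"

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValueError("query coverage must be a fraction in [0, 1]")
        if self.kind not in ("precursor_blast", "short_blast"):
            raise ValueError(f"unknown search kind {self.kind!r}")


@dataclass
class ProcessingStats:
    """Per-reason accounting for process_reads; retained + dropped = input."""

    n_input: int = 0
    n_retained: int = 0
    dropped_quality: int = 0
    dropped_length: int = 0
    n_adapter_clipped: int = 0
    n_quality_trimmed: int = 0

    @property
    def n_dropped(self):
        return self.dropped_quality + self.dropped_length

    def as_dict(self):
        return {
            "input": self.n_input,
            "retained": self.n_retained,
            "dropped_quality": self.dropped_quality,
            "dropped_length": self.dropped_length,
            "adapter_clipped": self.n_adapter_clipped,
            "quality_trimmed": self.n_quality_trimmed,
        }


class FastqParseError(ValueError):
    """Malformed FASTQ record, carrying the 0-based record index."""

    def __init__(self, index, message):
        self.index = index
        super().__init__(f"malformed FASTQ record #{index}: {message}")


# ---------------------------------------------------------------------------
# read processing
# ---------------------------------------------------------------------------

MIN_ADAPTER_MATCH = 8


def _clip_adapter(seq, adapter, min_match=MIN_ADAPTER_MATCH):
    """Return the clip point: the leftmost i where seq[i:] is a prefix of the
    adapter (or the adapter plus arbitrary trailing bases), with at least
    ``min_match`` adapter bases matching exactly.  len(seq) means no clip."""
    n = len(seq)
    for i in range(0, n - min_match + 1):
        m = min(len(adapter), n - i)
        if m >= min_match and seq[i:i + m] == adapter[:m]:
            return i
    return n


def _quality_keep_length(quality, min_phred):
    """Length of the longest prefix whose bases are all >= min_phred."""
    for i, q in enumerate(quality):
        if q < min_phred:
            return i
    return len(quality)


def process_reads(readset, adapter, min_phred=28, window=INSECT_WINDOW,
                  quality_mode="trim"):
    """Adapter-clip, quality-filter and length-select a read set.

    Steps per read: (1) clip at the leftmost exact match of >=8 adapter
    bases; (2) quality: in ``trim`` mode 3'-trim to the longest prefix with
    all bases >= ``min_phred``, in ``drop`` mode discard reads with any base
    below it; (3) keep reads whose final length falls in ``window``
    (inclusive).  Reads without qualities (FASTA input) skip step 2.

    Returns ``(ReadSet, ProcessingStats)``; retained + dropped equals the
    input count.
    """
    if quality_mode not in ("trim", "drop"):
        raise ValueError("quality_mode must be 'trim' or 'drop'")
    lo, hi = window
    if lo < 1 or hi < lo:
        raise ValueError(f"bad length window {window}")
    if adapter == "":
        logger.warning("empty adapter sequence: adapter clipping skipped")

    stats = ProcessingStats(n_input=len(readset.reads))
    kept = []
    for read in readset.reads:
        seq, qual = read.sequence, read.quality
        if adapter:
            cut = _clip_adapter(seq, adapter)
            if cut < len(seq):
                stats.n_adapter_clipped += 1
                seq = seq[:cut]
                qual = qual[:cut] if qual is not None else None
        if qual is not None:
            if quality_mode == "drop":
                if any(q < min_phred for q in qual):
                    stats.dropped_quality += 1
                    continue
            else:
                keep = _quality_keep_length(qual, min_phred)
                if keep < len(seq):
                    stats.n_quality_trimmed += 1
                    seq, qual = seq[:keep], qual[:keep]
        if lo <= len(seq) <= hi:
            kept.append(SmallRNARead(read.id, seq, tuple(qual) if qual is not None else None))
            stats.n_retained += 1
        else:
            stats.dropped_length += 1

    step = (f"process_reads(adapter={adapter!r}, min_phred={min_phred}, "
            f"window={window}, quality_mode={quality_mode})")
    out = ReadSet(readset.sample_id, readset.tissue, readset.line, kept,
                  readset.provenance + [step])
    return out, stats


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def read_fastq(path):
    """Parse phred-33 FASTQ into SmallRNARead objects; errors name the record."""
    reads = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            reads.append(SmallRNARead(rec.id, str(rec.seq).upper(),
                                      tuple(rec.letter_annotations["phred_quality"])))
    except ValueError as exc:
        raise FastqParseError(len(reads), str(exc)) from exc
    return reads


def read_fasta(path):
    """Parse FASTA into (id -> sequence), uppercased."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads, path, default_quality=40):
    records = []
    for r in reads:
        qual = list(r.quality) if r.quality is not None else [default_quality] * len(r.sequence)
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = qual
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_fasta(sequences, path):
    """Write an (id -> sequence) mapping or an iterable of (id, seq) pairs."""
    items = sequences.items() if hasattr(sequences, "items") else sequences
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_MD_MISMATCH = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def _mismatches_from_md(md):
    """Count substituted bases in an MD tag (deletion runs excluded)."""
    n = 0
    for num, deletion, letter in _MD_MISMATCH.findall(md):
        if letter:
            n += 1
    return n


def parse_alignments(path, library_name):
    """Parse a SAM file into AlignmentRecords for one library.

    Unmapped records are excluded; the gapped flag is set when the CIGAR
    contains I, D or N operations.  Mismatch counts come from the NM tag or,
    failing that, are reconstructed from MD; records with neither are
    rejected.  Returns ``(records, n_rejected)``.
    """
    records, rejected = [], 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            gapped = any(op in (1, 2, 3) for op, _ in (aln.cigartuples or []))
            if aln.has_tag("NM"):
                nm = aln.get_tag("NM")
            elif aln.has_tag("MD"):
                nm = _mismatches_from_md(aln.get_tag("MD"))
            else:
                rejected += 1
                continue
            records.append(AlignmentRecord(
                read_id=aln.query_name,
                library=library_name,
                reference=aln.reference_name,
                start=aln.reference_start,
                strand="-" if aln.is_reverse else "+",
                mismatches=int(nm),
                gapped=gapped,
            ))
    if rejected:
        logger.warning("parse_alignments: %d mapped records lacked NM and MD tags", rejected)
    return records, rejected


def write_alignments_sam(records, read_sequences, reference_lengths, path):
    """Write ungapped AlignmentRecords as SAM (full-length M CIGAR, NM tag).

    ``read_sequences`` maps read id -> forward-orientation read sequence;
    minus-strand records are stored reverse-complemented per SAM convention.
    """
    refs = sorted(reference_lengths)
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": r, "LN": int(reference_lengths[r])} for r in refs]}
    ref_index = {r: i for i, r in enumerate(refs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seq = read_sequences[rec.read_id]
            if rec.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.query_sequence = seq
            a.flag = 16 if rec.strand == "-" else 0
            a.reference_id = ref_index[rec.reference]
            a.reference_start = rec.start
            a.mapping_quality = 255
            a.cigartuples = [(0, len(seq))]
            a.set_tag("NM", rec.mismatches)
            out.write(a)


# ---------------------------------------------------------------------------
# GFF3: 3' UTR -> isoform table
# ---------------------------------------------------------------------------

def extract_three_prime_utrs(gff_path):
    """Tabulate three_prime_UTR features, merging identical coordinates.

    UTRs sharing (seqid, start, end, strand) across isoforms collapse into a
    single UTR id listing every parent transcript; features without a Parent
    attribute are skipped and counted.  Returns ``(DataFrame, n_skipped)``
    with columns utr_id, seqid, start, end, strand, transcripts (tuple),
    gene_id, n_transcripts.  Coordinates in the frame are 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    # transcript id -> gene id, from mRNA/transcript Parent attributes
    tx_gene = {}
    for ftype in ("mRNA", "transcript"):
        for feat in db.features_of_type(ftype):
            parents = feat.attributes.get("Parent", [])
            tx_gene[feat.id] = parents[0] if parents else ""

    groups = {}
    skipped = 0
    for feat in db.features_of_type("three_prime_UTR"):
        parents = feat.attributes.get("Parent")
        if not parents:
            skipped += 1
            continue
        key = (feat.seqid, feat.start - 1, feat.end, feat.strand)
        groups.setdefault(key, set()).update(parents)
    if skipped:
        logger.warning("extract_three_prime_utrs: %d three_prime_UTR features "
                       "lacked a Parent attribute", skipped)

    rows = []
    for (seqid, start, end, strand), txs in sorted(groups.items()):
        txs = tuple(sorted(txs))
        genes = sorted({tx_gene.get(t, "") for t in txs} - {""})
        rows.append({
            "utr_id": f"{seqid}:{start}-{end}({strand})",
            "seqid": seqid, "start": start, "end": end, "strand": strand,
            "transcripts": txs,
            "gene_id": ",".join(genes),
            "n_transcripts": len(txs),
        })
    return pd.DataFrame(rows), skipped


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6 + qcovs)
# ---------------------------------------------------------------------------

#: outfmt "6 std qcovs"
BLAST6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                  "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qcovs"]


def parse_blast_tabular(path, kind="precursor_blast"):
    """Parse BLAST outfmt-6 (std + qcovs) into HomologyRecords."""
    df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")
    return [
        HomologyRecord(row.qseqid, row.sseqid, float(row.evalue),
                       float(row.qcovs) / 100.0, kind)
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# TSV output with commented headers
# ---------------------------------------------------------------------------

def write_tsv(df, path, header_lines=()):
    """Write a DataFrame as TSV preceded by '#'-commented header lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path):
    return pd.read_csv(path, sep="\t", comment="#")
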