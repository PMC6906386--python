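"""Post-processing of miRNA precursor calls.

Takes hairpin loci called on plant small RNA data (one set per source
dataset), collapses duplicate loci across datasets, designates mature vs
star arms by read support, enumerates the unique mature/star products, and
classifies every precursor as known or novel from tiered homology evidence
against a reference miRNA database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

MAX_PRECURSOR_LEN = 300
ARM_LEN_RANGE = (20, 24)

# homology decision-tree thresholds
KNOWN_EVALUE = 1e-10       # precursor e < this  -> known outright
NOVEL_EVALUE = 1e-3        # precursor e >= this -> novel outright
COVERAGE_KNOWN = 0.60      # middle tier: coverage >= this -> known
SHORT_KNOWN_EVALUE = 1e-10 # middle tier fallback: min arm-level e < this -> known


@dataclass
class MiRNAPrecursor:
    """A hairpin locus with its mature/star duplex and read support.

    ``mature`` / ``star`` are 0-based half-open intervals in precursor
    coordinates; the mature/star designation reflects read support, not the
    5'/3' naming convention.
    """

    id: str
    reference: str
    start: int
    end: int
    strand: str
    sequence: str
    mature: tuple  # (start, end) within the precursor
    star: tuple
    mature_count: int = 0
    star_count: int = 0
    dataset_id: str = ""
    dot_bracket: str | None = None

    def __post_init__(self):
        n = len(self.sequence)
        if n > MAX_PRECURSOR_LEN:
            raise ValueError(f"precursor {self.id}: length {n} > {MAX_PRECURSOR_LEN}")
        for name, (a, b) in (("mature", self.mature), ("star", self.star)):
            if not (0 <= a < b <= n):
                raise ValueError(f"precursor {self.id}: {name} interval {a, b} outside [0, {n})")
            if not ARM_LEN_RANGE[0] <= b - a <= ARM_LEN_RANGE[1]:
                raise ValueError(
                    f"precursor {self.id}: {name} arm length {b - a} outside {ARM_LEN_RANGE}")
        if min(self.mature[1], self.star[1]) > max(self.mature[0], self.star[0]):
            raise ValueError(f"precursor {self.id}: mature and star intervals overlap")

    @property
    def mature_sequence(self):
        return self.sequence[self.mature[0]:self.mature[1]]

    @property
    def star_sequence(self):
        return self.sequence[self.star[0]:self.star[1]]

    @property
    def locus_length(self):
        return self.end - self.start


@dataclass
class MiRNA:
    """One unique mature/star product and the precursors that encode it."""

    sequence: str
    arm: str  # "first" (5'-proximal arm) or "second"
    precursor_ids: list = field(default_factory=list)
    status: str = "unset"  # known / novel / unset


@dataclass(frozen=True)
class ClassificationEvidence:
    """Homology evidence feeding the known/novel decision tree."""

    precursor_evalue: float
    precursor_coverage: float | None = None
    short_evalues: tuple = ()  # arm-level e-values (mature, star) when searched

    def __post_init__(self):
        if self.precursor_evalue < 0:
            raise ValueError("precursor e-value must be >= 0")
        if self.precursor_coverage is not None and not 0 <= self.precursor_coverage <= 1:
            raise ValueError("coverage must be a fraction in [0, 1]")
        if any(e < 0 for e in self.short_evalues):
            raise ValueError("short-search e-values must be >= 0")


@dataclass(frozen=True)
class Classification:
    status: str  # known / novel / unset
    branch: str  # which tier of the tree decided
    note: str = ""


def classify_precursor(evidence):
    """Known/novel decision for one precursor from tiered homology evidence.

    Tree: precursor e-value < 1e-10 -> known; >= 1e-3 -> novel; in between,
    query coverage >= 60% -> known, otherwise the mature/star sequences are
    searched with a short-sequence strategy and min arm e-value < 1e-10 ->
    known, else novel.  A precursor reaching the short-search branch without
    arm-level evidence is left ``unset`` with an explicit note.  Boundary
    semantics: e exactly 1e-10 lands in the middle tier; coverage exactly
    0.60 is known; short e exactly 1e-10 is novel.
    """
    e = evidence.precursor_evalue
    if e < KNOWN_EVALUE:
        return Classification("known", "precursor_evalue")
    if e >= NOVEL_EVALUE:
        return Classification("novel", "precursor_evalue")
    cov = evidence.precursor_coverage
    if cov is None:
        return Classification("unset", "coverage",
                              "middle-tier precursor lacks query coverage")
    if cov >= COVERAGE_KNOWN:
        return Classification("known", "coverage")
    if not evidence.short_evalues:
        return Classification("unset", "short_blast",
                              "middle-tier low-coverage precursor lacks "
                              "arm-level short-search evidence")
    if min(evidence.short_evalues) < SHORT_KNOWN_EVALUE:
        return Classification("known", "short_blast")
    return Classification("novel", "short_blast")


def evidence_from_homology(precursor, records):
    """Assemble ClassificationEvidence for one precursor from homology hits.

    ``records`` are HomologyRecords; precursor-level hits are matched on the
    precursor id, arm-level (short-search) hits on ``<id>.mature`` /
    ``<id>.star`` query ids.  The best (lowest-e) precursor hit supplies the
    e-value and coverage; absent precursor hits mean no detectable homology
    and classify as novel via a sentinel e-value of infinity.
    """
    prec_hits = [r for r in records
                 if r.kind == "precursor_blast" and r.query_id == precursor.id]
    short_es = tuple(r.evalue for r in records
                     if r.kind == "short_blast"
                     and r.query_id in (f"{precursor.id}.mature", f"{precursor.id}.star"))
    if not prec_hits:
        return ClassificationEvidence(float("inf"), None, short_es)
    best = min(prec_hits, key=lambda r: r.evalue)
    return ClassificationEvidence(best.evalue, best.query_coverage, short_es)


# ---------------------------------------------------------------------------
# duplicate collapse across datasets
# ---------------------------------------------------------------------------

def _reciprocal_overlap(a, b, threshold):
    """True when two same-strand loci overlap >= threshold of each length."""
    if a.reference != b.reference or a.strand != b.strand:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    return (ov >= threshold * a.locus_length) and (ov >= threshold * b.locus_length)


def collapse_duplicates(precursors, overlap_threshold=0.5):
    """Collapse duplicate loci called independently in several datasets.

    Precursors whose loci reciprocally overlap by >= ``overlap_threshold``
    on the same strand form a duplicate group (transitively); the member
    with the most reads on its mature arm is retained.  Ties retain the
    member from the lexicographically smallest dataset id, with a warning.

    Returns ``(retained, groups)`` where groups maps each retained id to the
    full member id list.
    """
    n = len(precursors)
    # union-find over pairwise reciprocal overlaps
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _reciprocal_overlap(precursors[i], precursors[j], overlap_threshold):
                parent[find(i)] = find(j)

    components = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)

    retained, groups = [], {}
    for members in components.values():
        group = [precursors[i] for i in members]
        best = max(group, key=lambda p: (p.mature_count, ), default=None)
        ties = [p for p in group if p.mature_count == best.mature_count]
        if len(ties) > 1:
            best = min(ties, key=lambda p: p.dataset_id)
            logger.warning("collapse_duplicates: mature-count tie in group %s; "
                           "retaining %s from dataset %r",
                           [p.id for p in group], best.id, best.dataset_id)
        retained.append(best)
        groups[best.id] = sorted(p.id for p in group)
    retained.sort(key=lambda p: (p.reference, p.start, p.strand, p.id))
    return retained, groups


def assign_mature_star(first_arm_count, second_arm_count):
    """Designate the arm with more mapped reads as mature, the other as star.

    Equal counts fall back to the first (5'-proximal) arm with a warning.
    Returns ``(mature_arm, warned)`` with mature_arm in {"first", "second"}.
    """
    if first_arm_count < 0 or second_arm_count < 0:
        raise ValueError("arm read counts must be >= 0")
    if first_arm_count == second_arm_count:
        logger.warning("assign_mature_star: tied arm counts (%d); "
                       "designating the first arm mature", first_arm_count)
        return "first", True
    return ("first", False) if first_arm_count > second_arm_count else ("second", False)


def enumerate_mirnas(precursors):
    """Enumerate the unique mature/star sequences across collapsed precursors.

    One MiRNA per unique arm sequence; duplicated loci encoding the same
    sequence contribute one entry listing every precursor.  At most
    2 x len(precursors) unique products are possible.
    """
    by_seq = {}
    for prec in precursors:
        n = len(prec.sequence)
        for interval in (prec.mature, prec.star):
            seq = prec.sequence[interval[0]:interval[1]]
            # arm index: which side of the hairpin the product comes from
            arm = "first" if interval[0] + (interval[1] - interval[0]) // 2 < n // 2 else "second"
            entry = by_seq.get(seq)
            if entry is None:
                by_seq[seq] = MiRNA(seq, arm, [prec.id])
            elif prec.id not in entry.precursor_ids:
                entry.precursor_ids.append(prec.id)
    return sorted(by_seq.values(), key=lambda m: m.sequence)


# ---------------------------------------------------------------------------
# structural validation
# ---------------------------------------------------------------------------

def pair_table(dot_bracket):
    """Map each paired position to its partner (dict); errors on imbalance."""
    stack, pairs = [], {}
    for i, c in enumerate(dot_bracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket: ')' at {i} with no open '('")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
        elif c != ".":
            raise ValueError(f"dot-bracket contains {c!r} at {i}")
    if stack:
        raise ValueError(f"unbalanced dot-bracket: {len(stack)} unclosed '('")
    return pairs


def duplex_pairing_fraction(precursor, dot_bracket):
    """Fraction of mature-arm positions paired with star-arm positions."""
    pairs = pair_table(dot_bracket)
    m0, m1 = precursor.mature
    s0, s1 = precursor.star
    paired = sum(1 for i in range(m0, m1) if s0 <= pairs.get(i, -1) < s1)
    return paired / (m1 - m0)


def validate_precursor(precursor, dot_bracket, min_duplex_fraction=0.75):
    """Structural sanity check of a precursor against its secondary structure.

    Fails when the hairpin exceeds 300 nt, an arm falls outside 20-24 nt, or
    fewer than ``min_duplex_fraction`` of mature positions pair with star
    positions.  Returns ``(passed, reasons)``.
    """
    if len(dot_bracket) != len(precursor.sequence):
        raise ValueError("dot-bracket length != precursor length")
    reasons = []
    if len(precursor.sequence) > MAX_PRECURSOR_LEN:
        reasons.append("length")
    for name, (a, b) in (("mature", precursor.mature), ("star", precursor.star)):
        if not ARM_LEN_RANGE[0] <= b - a <= ARM_LEN_RANGE[1]:
            reasons.append(f"{name}_arm_length")
    frac = duplex_pairing_fraction(precursor, dot_bracket)
    if frac < min_duplex_fraction:
        reasons.append("duplex_pairing")
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# tabular I/O (ShortStack-results dialect)
# ---------------------------------------------------------------------------

def read_precursor_table(path, sequences, dataset_id=""):
    """Read a precursor-call table (ShortStack Results dialect) plus FASTA.

    Expected columns: Locus (ref:start-end, 1-based closed), Strand, Name,
    MajorRNA (mature sequence), Star, MajorRNAReads, StarReads.  Sequences
    come from ``sequences`` (id -> hairpin sequence); mature/star intervals
    are located by exact substring search within the hairpin.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for row in df.itertuples():
        ref, span = row.Locus.split(":")
        start, end = (int(x) for x in span.split("-"))
        seq = sequences[row.Name]
        m = seq.find(row.MajorRNA)
        s = seq.find(row.Star)
        if m < 0 or s < 0:
            raise ValueError(f"{row.Name}: mature/star sequence not found in hairpin")
        out.append(MiRNAPrecursor(
            id=row.Name, reference=ref, start=start - 1, end=end, strand=row.Strand,
            sequence=seq, mature=(m, m + len(row.MajorRNA)), star=(s, s + len(row.Star)),
            mature_count=int(row.MajorRNAReads), star_count=int(row.StarReads),
            dataset_id=dataset_id))
    return out


def precursor_table(precursors, classifications=None):
    """Collapsed-precursor report; locus coordinates are 1-based closed."""
    rows = []
    for p in precursors:
        cls = classifications.get(p.id) if classifications else None
        rows.append({
            "precursor_id": p.id,
            "locus": f"{p.reference}:{p.start + 1}-{p.end}",
            "strand": p.strand,
            "length": len(p.sequence),
            "mature_seq": p.mature_sequence,
            "star_seq": p.star_sequence,
            "mature_reads": p.mature_count,
            "star_reads": p.star_count,
            "dataset": p.dataset_id,
            "status": cls.status if cls else "unset",
            "status_branch": cls.branch if cls else "",
        })
    return pd.DataFrame(rows)


def read_precursor_fasta(path, dataset_id=""):
    """Read precursors from FASTA whose headers annotate the arm intervals.

    Header dialect: ``>id mature=START-END star=START-END [reads=M,S]
    [locus=ref:START-END] [strand=+/-]`` with 1-based closed coordinates;
    the hairpin sequence is the record body.
    """
    from Bio import SeqIO

    def span(text):
        a, b = text.split("-")
        return int(a) - 1, int(b)

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(part.split("=", 1) for part in rec.description.split()[1:]
                      if "=" in part)
        if "mature" not in fields or "star" not in fields:
            raise ValueError(f"{rec.id}: header lacks mature=/star= intervals")
        counts = fields.get("reads", "0,0").split(",")
        ref, locus_span = (fields["locus"].split(":")
                           if "locus" in fields else (rec.id, None))
        start, end = span(locus_span) if locus_span else (0, len(rec.seq))
        out.append(MiRNAPrecursor(
            id=rec.id, reference=ref, start=start, end=end,
            strand=fields.get("strand", "+"), sequence=str(rec.seq).upper(),
            mature=span(fields["mature"]), star=span(fields["star"]),
            mature_count=int(counts[0]), star_count=int(counts[1]),
            dataset_id=dataset_id))
    return out


def write_precursor_fasta(precursors, path):
    """Inverse of read_precursor_fasta (1-based closed header intervals)."""
    with open(path, "w") as fh:
        for p in precursors:
            fh.write(f">{p.id} mature={p.mature[0] + 1}-{p.mature[1]} "
                     f"star={p.star[0] + 1}-{p.star[1]} "
                     f"reads={p.mature_count},{p.star_count} "
                     f"locus={p.reference}:{p.start + 1}-{p.end} "
                     f"strand={p.strand}\n{p.sequence}\n")


def mirna_fasta_records(mirnas):
    """(header, sequence) pairs for the unique-miRNA FASTA; headers carry
    status and the encoding precursor list."""
    out = []
    for i, m in enumerate(mirnas, 1):
        header = f"mir{i:04d}|{m.status}|arm={m.arm}|precursors={','.join(m.precursor_ids)}"
        out.append((header, m.sequence))
    return out
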