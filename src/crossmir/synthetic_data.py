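"""Ground-truth simulators for every stage of the pipeline.

The generators emulate the data the analysis was designed for: a set of
source genomes (host insect, its obligate symbiont, the host plant, and
bacterial/viral contaminant libraries), plant hairpin precursors with
labelled mature/star/loop/end regions, small RNA reads drawn from those
sources at configurable proportions and substitution-error rates,
multi-tool target-prediction tables with controllable seed overlap, and a
COG-annotated reference "proteome" with one-to-many UTR-to-isoform
structure.  Every read carries a TruthLabel, so downstream attribution,
detection and profiling can be scored exactly.

Mutations are substitutions only: gapped alignments are excluded
downstream anyway, so indels could never survive, and substitution-only
truth keeps the oracles simple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .precursor_annotation import (ARM_LEN_RANGE, MAX_PRECURSOR_LEN,
                                   ClassificationEvidence, MiRNAPrecursor)
from .smallrna_io import ReadSet, SmallRNARead

logger = logging.getLogger(__name__)

CATEGORIES = ("host_insect", "obligate_symbiont", "host_plant", "bacterial", "viral")
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PROVENANCE_KMER = 17  # shared k-mers of this size would make provenance ambiguous


def revcomp(seq):
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibrarySpec:
    name: str
    category: str
    length: int = 10_000
    gc: float = 0.40

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.length < 100:
            raise ValueError("library length must be >= 100")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("GC content must be in (0, 1)")


@dataclass
class TruthGenomeSet:
    """Named source libraries with category labels; provenance-unambiguous."""

    libraries: list  # of (name, category, sequence)
    seed: int

    @property
    def sequences(self):
        return {name: seq for name, _, seq in self.libraries}

    @property
    def categories(self):
        return {name: cat for name, cat, _ in self.libraries}


def _random_sequence(rng, length, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(_BASES))[rng.choice(4, size=length, p=p)])


def _kmers(seq, k):
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def count_shared_kmers(a, b, k=PROVENANCE_KMER):
    """Number of exact k-mers (forward or reverse-complement) shared by two
    sequences — the quantity the disjointness guarantee bounds."""
    return len(_kmers(a, k) & (_kmers(b, k) | _kmers(revcomp(b), k)))


def generate_genome_set(specs, seed, k=PROVENANCE_KMER, max_shared=0,
                        max_retries=100):
    """Generate source libraries with a cap on cross-library shared k-mers.

    Disjointness (including reverse complements) is enforced by rejection
    sampling: a library sharing more than ``max_shared`` exact k-mers with
    any earlier library is redrawn, up to ``max_retries`` times.
    Deterministic for a fixed seed.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("generate_genome_set: empty library list")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("library names must be unique")
    rng = np.random.default_rng(seed)
    libraries, seen = [], []
    for spec in specs:
        for attempt in range(max_retries + 1):
            seq = _random_sequence(rng, spec.length, spec.gc)
            ks = _kmers(seq, k) | _kmers(revcomp(seq), k)
            if all(len(ks & prev) <= max_shared for prev in seen):
                if attempt:
                    logger.info("generate_genome_set: %s accepted after %d "
                                "rejections", spec.name, attempt)
                break
        else:
            raise RuntimeError(f"could not draw library {spec.name!r} with "
                               f"<= {max_shared} shared {k}-mers in {max_retries} retries")
        seen.append(ks)
        libraries.append((spec.name, spec.category, seq))
    return TruthGenomeSet(libraries, seed)


# ---------------------------------------------------------------------------
# hairpin precursors
# ---------------------------------------------------------------------------

REGION_ORDER = ("five_prime_end", "first_arm", "loop", "second_arm", "three_prime_end")


@dataclass
class TruthPrecursor:
    """A simulated hairpin with its exact region map and duplex structure."""

    id: str
    sequence: str
    regions: dict  # region name -> (start, end), contiguous, covering [0, len)
    mature_arm: str  # "first" or "second"
    dot_bracket: str
    mismatch_positions: tuple = ()  # first-arm offsets where the duplex is broken
    planted_counts: dict = field(default_factory=dict)

    @property
    def mature(self):
        return self.regions["first_arm" if self.mature_arm == "first" else "second_arm"]

    @property
    def star(self):
        return self.regions["second_arm" if self.mature_arm == "first" else "first_arm"]

    @property
    def mature_sequence(self):
        a, b = self.mature
        return self.sequence[a:b]

    @property
    def star_sequence(self):
        a, b = self.star
        return self.sequence[a:b]


def generate_precursor(arm_len, loop_len, end_lens=(10, 10), n_mismatches=0,
                       seed=0, mature_arm="first", prec_id="prec1"):
    """Build a hairpin: 5' end + arm + loop + reverse-complement arm + 3' end.

    The second arm is the reverse complement of the first except at
    ``n_mismatches`` injected duplex positions.  Arms must be 20-24 nt and
    the total length at most 300 nt.  The dot-bracket pairs the arms except
    at the injected mismatches.
    """
    lo, hi = ARM_LEN_RANGE
    if not lo <= arm_len <= hi:
        raise ValueError(f"arm length must be in [{lo}, {hi}], got {arm_len}")
    if loop_len < 3:
        raise ValueError("loop must be >= 3 nt")
    end5, end3 = end_lens
    total = end5 + arm_len + loop_len + arm_len + end3
    if total > MAX_PRECURSOR_LEN:
        raise ValueError(f"total precursor length {total} > {MAX_PRECURSOR_LEN}")
    if not 0 <= n_mismatches <= arm_len:
        raise ValueError("n_mismatches must be in [0, arm_len]")
    if mature_arm not in ("first", "second"):
        raise ValueError("mature_arm must be 'first' or 'second'")

    rng = np.random.default_rng(seed)
    arm1 = _random_sequence(rng, arm_len, 0.5)
    arm2 = list(revcomp(arm1))
    mm_pos = tuple(sorted(rng.choice(arm_len, size=n_mismatches, replace=False)))
    for j in mm_pos:  # j indexes arm1; the partner sits mirrored in arm2
        partner = arm_len - 1 - j
        complement = arm2[partner]
        choices = [b for b in _BASES if b != complement]
        arm2[partner] = choices[rng.integers(len(choices))]
    arm2 = "".join(arm2)

    seq = (_random_sequence(rng, end5, 0.5) + arm1 + _random_sequence(rng, loop_len, 0.5)
           + arm2 + _random_sequence(rng, end3, 0.5))
    regions = {
        "five_prime_end": (0, end5),
        "first_arm": (end5, end5 + arm_len),
        "loop": (end5 + arm_len, end5 + arm_len + loop_len),
        "second_arm": (end5 + arm_len + loop_len, end5 + arm_len + loop_len + arm_len),
        "three_prime_end": (end5 + 2 * arm_len + loop_len, total),
    }
    db = ["."] * total
    a1, l1 = regions["first_arm"][0], regions["second_arm"][0]
    for j in range(arm_len):
        if j not in mm_pos:
            db[a1 + j] = "("
            db[l1 + arm_len - 1 - j] = ")"
    return TruthPrecursor(prec_id, seq, regions, mature_arm, "".join(db), mm_pos)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthLabel:
    """Ground truth for one generated read."""

    read_id: str
    origin: str           # source library / precursor name
    region: str | None    # precursor region label, when applicable
    n_mismatches: int
    reverse_complemented: bool = False


def _mutate(rng, seq, n):
    if n == 0:
        return seq
    if n > len(seq):
        raise ValueError("cannot inject more mismatches than read length")
    pos = rng.choice(len(seq), size=n, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = _BASES[(("ACGT".index(out[p]) + 1 + rng.integers(3)) % 4)] \
            if out[p] in _BASES else "A"
    # ensure a real substitution at every chosen position
    for p in pos:
        if out[p] == seq[p]:
            out[p] = next(b for b in _BASES if b != seq[p])
    return "".join(out)


def sample_reads(sources, n, length_range=(17, 28), n_mismatches=0, seed=0,
                 revcomp_fraction=0.0, sample_id="synthetic", tissue="other",
                 line="", id_prefix="read"):
    """Draw reads from named source sequences at stated proportions.

    ``sources`` is a list of (name, sequence, proportion); proportions must
    sum to 1 (tolerance 1e-9).  Per-origin counts are the exact multinomial
    draw for the seed.  Each read is a uniformly placed substring of its
    origin with ``n_mismatches`` injected substitutions, reverse-complemented
    with probability ``revcomp_fraction``.  Returns (ReadSet, labels).
    """
    lo, hi = length_range
    if not (17 <= lo <= hi <= 35):
        raise ValueError("read length range must lie within [17, 35]")
    if n == 0:
        return ReadSet(sample_id, tissue, line, [], ["sample_reads(n=0)"]), []
    props = np.array([p for _, _, p in sources], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"source proportions sum to {props.sum()}, not 1")
    for name, seq, _ in sources:
        if len(seq) < hi:
            raise ValueError(f"source {name!r} shorter than the max read length")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, props)
    reads, labels = [], []
    i = 0
    for (name, seq, _), count in zip(sources, counts):
        for _ in range(count):
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, len(seq) - length + 1))
            sub = _mutate(rng, seq[start:start + length], n_mismatches)
            rc = bool(rng.random() < revcomp_fraction)
            if rc:
                sub = revcomp(sub)
            rid = f"{id_prefix}{i:06d}"
            reads.append(SmallRNARead(rid, sub, tuple([40] * length)))
            labels.append(TruthLabel(rid, name, None, n_mismatches, rc))
            i += 1
    readset = ReadSet(sample_id, tissue, line, reads,
                      [f"sample_reads(n={n}, mismatches={n_mismatches}, seed={seed})"])
    return readset, labels


#: labels sample_precursor_reads can plant, and how they are realized
PROFILE_LABELS = ("mature", "star", "loop", "five_prime_end", "three_prime_end", "fragment")


def sample_precursor_reads(precursor, proportions, n, seed=0, length_range=(17, 24),
                           sample_id="profile", id_prefix="pread"):
    """Draw reads lying cleanly inside labelled precursor regions.

    ``proportions`` maps labels from PROFILE_LABELS to fractions summing to
    1.  Region reads are substrings fully inside the region (no overlap into
    neighbours); ``fragment`` reads straddle a region boundary by at least
    2 nt on each side, which the 1-nt-overlap rule must call a fragment.
    Regions too short for the read length window are rejected.
    """
    props = {k: v for k, v in proportions.items() if v > 0}
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    unknown = set(props) - set(PROFILE_LABELS)
    if unknown:
        raise ValueError(f"unknown region labels: {sorted(unknown)}")
    lo, hi = length_range

    region_for = {"mature": precursor.mature, "star": precursor.star,
                  "five_prime_end": precursor.regions["five_prime_end"],
                  "three_prime_end": precursor.regions["three_prime_end"],
                  "loop": precursor.regions["loop"]}
    for label in props:
        if label != "fragment":
            a, b = region_for[label]
            if b - a < lo:
                raise ValueError(f"region {label} ({b - a} nt) shorter than "
                                 f"minimum read length {lo}")
    # interior boundaries usable for fragments (need >= 2 nt on both sides)
    bounds = []
    order = [precursor.regions[r] for r in REGION_ORDER]
    for (a0, b0), (a1, b1) in zip(order, order[1:]):
        if b0 - a0 >= 2 and b1 - a1 >= 2:
            bounds.append(b0)
    if "fragment" in props and not bounds:
        raise ValueError("no interior boundary wide enough for fragment reads")

    rng = np.random.default_rng(seed)
    labels_order = sorted(props)
    counts = rng.multinomial(n, [props[k] for k in labels_order])
    reads, labels = [], []
    i = 0
    for label, count in zip(labels_order, counts):
        for _ in range(count):
            if label == "fragment":
                cut = int(bounds[rng.integers(len(bounds))])
                left_max = min(cut, hi - 2)
                right_max = min(len(precursor.sequence) - cut, hi - 2)
                left = int(rng.integers(2, max(2, min(left_max, hi - 2)) + 1))
                right_lo = max(2, lo - left)
                right_hi = min(right_max, hi - left)
                if right_hi < right_lo:
                    left = max(2, lo - 2)
                    right_lo, right_hi = max(2, lo - left), min(right_max, hi - left)
                right = int(rng.integers(right_lo, right_hi + 1))
                start, end = cut - left, cut + right
            else:
                a, b = region_for[label]
                length = int(rng.integers(lo, min(hi, b - a) + 1))
                start = int(rng.integers(a, b - length + 1))
                end = start + length
            rid = f"{id_prefix}{i:06d}"
            reads.append(SmallRNARead(rid, precursor.sequence[start:end],
                                      tuple([40] * (end - start))))
            labels.append(TruthLabel(rid, precursor.id, label, 0))
            i += 1
    readset = ReadSet(sample_id, "gut", "", reads,
                      [f"sample_precursor_reads(n={n}, seed={seed})"])
    return readset, labels


# ---------------------------------------------------------------------------
# truth mirnome + homology evidence
# ---------------------------------------------------------------------------

#: evidence templates cycling through every branch of the known/novel tree
_KNOWN_BRANCHES = (
    dict(precursor_evalue=1e-12),                                      # e < 1e-10
    dict(precursor_evalue=1e-5, precursor_coverage=0.72),              # coverage >= 0.6
    dict(precursor_evalue=1e-5, precursor_coverage=0.40,
         short_evalues=(1e-12, 0.5)),                                  # short e < 1e-10
)
_NOVEL_BRANCHES = (
    dict(precursor_evalue=0.01),                                       # e >= 1e-3
    dict(precursor_evalue=1e-5, precursor_coverage=0.40,
         short_evalues=(1e-8, 0.2)),                                   # short e >= 1e-10
)


def make_truth_mirnome(n_loci, n_duplicated_loci=0, n_known=None, seed=0,
                       reference="chr_sim"):
    """Generate a collapsed-ready precursor set plus homology evidence.

    ``n_duplicated_loci`` of the ``n_loci`` total are exact sequence copies
    of earlier loci placed at distinct coordinates, so they encode identical
    mature miRNAs.  The first ``n_known`` loci receive evidence cycling
    through every known branch of the classification tree; the rest cycle
    through the novel branches.  Returns ``(precursors, evidence, truth)``
    where evidence maps precursor id -> ClassificationEvidence and truth
    maps precursor id -> expected status.
    """
    if n_duplicated_loci > n_loci:
        raise ValueError("n_duplicated_loci must be <= n_loci")
    if n_known is None:
        n_known = n_loci
    if n_known > n_loci:
        raise ValueError("n_known must be <= n_loci")
    rng = np.random.default_rng(seed)
    n_base = n_loci - n_duplicated_loci
    truth_precs = []
    for i in range(n_base):
        arm = int(rng.integers(ARM_LEN_RANGE[0], ARM_LEN_RANGE[1] + 1))
        loop = int(rng.integers(18, 30))
        ends = (int(rng.integers(17, 25)), int(rng.integers(17, 25)))
        truth_precs.append(generate_precursor(
            arm, loop, ends, n_mismatches=int(rng.integers(0, 3)),
            seed=int(rng.integers(2**31)), prec_id=f"prec{i + 1:03d}"))

    precursors, pos = [], 1000
    sources = truth_precs + [truth_precs[int(rng.integers(n_base))]
                             for _ in range(n_duplicated_loci)]
    for i, tp in enumerate(sources):
        mature_count = int(rng.integers(50, 500))
        star_count = int(rng.integers(1, mature_count))  # mature strictly higher
        length = len(tp.sequence)
        precursors.append(MiRNAPrecursor(
            id=f"locus{i + 1:03d}", reference=reference, start=pos, end=pos + length,
            strand="+", sequence=tp.sequence, mature=tp.mature, star=tp.star,
            mature_count=mature_count, star_count=star_count,
            dataset_id=f"ds{1 + i % 2}", dot_bracket=tp.dot_bracket))
        pos += length + 200  # non-overlapping loci

    evidence, truth = {}, {}
    for i, prec in enumerate(precursors):
        if i < n_known:
            kw = _KNOWN_BRANCHES[i % len(_KNOWN_BRANCHES)]
            truth[prec.id] = "known"
        else:
            kw = _NOVEL_BRANCHES[i % len(_NOVEL_BRANCHES)]
            truth[prec.id] = "novel"
        evidence[prec.id] = ClassificationEvidence(**kw)
    return precursors, evidence, truth


# ---------------------------------------------------------------------------
# multi-tool target tables
# ---------------------------------------------------------------------------

def make_tool_tables(mirna_lengths, target_ids, tools, n_consensus, n_partial,
                     n_nonoverlap, seed=0, site_region=(100, 400)):
    """Synthesize per-tool target predictions with planted overlap structure.

    Plants three kinds of (miRNA, target) pairs: ``n_consensus`` predicted by
    every tool with mutually overlapping seed images; ``n_partial`` predicted
    by a strict subset of tools; ``n_nonoverlap`` predicted by all tools but
    with at least one seed image disjoint from the rest.  Returns
    ``(rows, truth)`` where rows are dicts (tool, mirna_id, target_id, start,
    end, score) and truth maps (mirna_id, target_id) -> planted kind.
    """
    if len(tools) < 2:
        raise ValueError("need at least 2 tools")
    rng = np.random.default_rng(seed)
    mirnas = sorted(mirna_lengths)
    pairs = [(m, t) for m in mirnas for t in target_ids]
    need = n_consensus + n_partial + n_nonoverlap
    if need > len(pairs):
        raise ValueError("not enough (miRNA, target) pairs for the requested structure")
    chosen = [pairs[j] for j in rng.choice(len(pairs), size=need, replace=False)]
    rows, truth = [], {}

    def site(mirna, anchor):
        length = mirna_lengths[mirna]
        return anchor, anchor + length

    for idx, (mirna, target) in enumerate(chosen):
        anchor = int(rng.integers(*site_region))
        if idx < n_consensus:
            truth[(mirna, target)] = "consensus"
            for tool in tools:
                # jitter < 4 keeps the 7-nt seed images mutually overlapping
                s, e = site(mirna, anchor + int(rng.integers(-3, 4)))
                rows.append(dict(tool=tool, mirna_id=mirna, target_id=target,
                                 start=s, end=e, score=float(rng.uniform(50, 100))))
        elif idx < n_consensus + n_partial:
            truth[(mirna, target)] = "partial"
            subset = rng.choice(len(tools), size=int(rng.integers(1, len(tools))),
                                replace=False)
            for j in subset:
                s, e = site(mirna, anchor + int(rng.integers(-3, 4)))
                rows.append(dict(tool=tools[j], mirna_id=mirna, target_id=target,
                                 start=s, end=e, score=float(rng.uniform(50, 100))))
        else:
            truth[(mirna, target)] = "nonoverlap"
            for j, tool in enumerate(tools):
                offset = 0 if j else 40  # push one tool's seed image clear away
                s, e = site(mirna, anchor + offset)
                rows.append(dict(tool=tool, mirna_id=mirna, target_id=target,
                                 start=s, end=e, score=float(rng.uniform(50, 100))))
    return rows, truth


# ---------------------------------------------------------------------------
# COG-annotated reference "proteome"
# ---------------------------------------------------------------------------

def make_cog_universe(n_utrs, categories=("J", "K", "L", "E", "G"), seed=0,
                      max_isoforms=3, unannotated_fraction=0.1):
    """Build a UTR universe with one-to-many isoform expansion and COG labels.

    Each UTR carries 1..``max_isoforms`` isoforms; each isoform is assigned
    one COG letter uniformly from ``categories``, or none with probability
    ``unannotated_fraction``.  Returns ``(utr_ids, expansion, cog_table)``:
    expansion maps UTR id -> isoform id tuple, cog_table maps isoform id ->
    COG letter string ("" when unannotated).
    """
    rng = np.random.default_rng(seed)
    utr_ids, expansion, cog_table = [], {}, {}
    for i in range(n_utrs):
        utr = f"utr{i + 1:05d}"
        utr_ids.append(utr)
        k = int(rng.integers(1, max_isoforms + 1))
        isos = tuple(f"{utr}.iso{j + 1}" for j in range(k))
        expansion[utr] = isos
        for iso in isos:
            if rng.random() < unannotated_fraction:
                cog_table[iso] = ""
            else:
                cog_table[iso] = categories[int(rng.integers(len(categories)))]
    return utr_ids, expansion, cog_table
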