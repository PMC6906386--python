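"""Profile reads over miRNA precursor regions.

Reads aligning exactly (no mismatches, no gaps) to a precursor are assigned
to one of five regions — mature, star, loop, 5' end, 3' end — when the
alignment lies within the region allowing at most one nucleotide of overlap
into each adjacent region; anything overlapping a neighbouring region by
more than one nucleotide is a precursor fragment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

REGION_LABELS = ("mature", "star", "loop", "five_prime_end", "three_prime_end")
FRAGMENT = "fragment"

#: specificity rank used when several occurrences of one read must be reduced
#: to a single assignment (higher = more specific)
_SPECIFICITY = {"mature": 3, "star": 3, "loop": 2,
                "five_prime_end": 2, "three_prime_end": 2, FRAGMENT: 1}


@dataclass(frozen=True)
class RegionMap:
    """Five labelled, contiguous intervals covering a precursor.

    ``intervals`` is a tuple of (label, start, end) in 5'->3' order with
    labels from REGION_LABELS; whether mature precedes star depends on which
    arm carries the mature product.
    """

    precursor_id: str
    intervals: tuple

    def __post_init__(self):
        labels = [lab for lab, _, _ in self.intervals]
        if sorted(labels) != sorted(REGION_LABELS):
            raise ValueError(f"region map must carry exactly {REGION_LABELS}")
        pos = 0
        for lab, a, b in self.intervals:
            if a != pos or b < a:
                raise ValueError("region intervals must be contiguous, "
                                 "non-overlapping and cover [0, len)")
            pos = b

    @property
    def length(self):
        return self.intervals[-1][2]

    @classmethod
    def from_precursor(cls, precursor):
        """Derive the map from a precursor's arm coordinates.

        Works for both TruthPrecursor (region dict + mature_arm) and
        MiRNAPrecursor (explicit mature/star intervals): the two arms are
        labelled mature/star, whatever lies between them is the loop, and
        the flanks are the 5'/3' ends.
        """
        m, s = tuple(precursor.mature), tuple(precursor.star)
        first, second = (m, s) if m[0] < s[0] else (s, m)
        first_label = "mature" if first == m else "star"
        second_label = "star" if first == m else "mature"
        n = len(precursor.sequence)
        intervals = (
            ("five_prime_end", 0, first[0]),
            (first_label, first[0], first[1]),
            ("loop", first[1], second[0]),
            (second_label, second[0], second[1]),
            ("three_prime_end", second[1], n),
        )
        return cls(getattr(precursor, "id", "precursor"), intervals)


@dataclass(frozen=True)
class RegionAssignment:
    read_id: str
    precursor_id: str
    start: int
    end: int
    label: str


def align_to_precursor(read_seq, precursor_seq):
    """All exact, ungapped occurrences of the read in the precursor
    (forward strand), as 0-based half-open intervals."""
    hits, pos = [], precursor_seq.find(read_seq)
    while pos >= 0:
        hits.append((pos, pos + len(read_seq)))
        pos = precursor_seq.find(read_seq, pos + 1)
    return hits


def classify_read_region(interval, region_map, max_overlap=1):
    """Label one exact alignment interval against a precursor region map.

    The interval gets a region's label when it lies within that region
    extended by ``max_overlap`` nucleotides into each adjacent region
    (extensions are clipped at the precursor boundaries).  If the
    extensions make more than one region eligible, mature/star win over
    loop/ends, then the region containing the majority of the interval,
    then 5'->3' order.  An interval eligible for no region is a fragment.
    """
    start, end = interval
    if not (0 <= start < end <= region_map.length):
        raise ValueError(f"interval {interval} outside precursor "
                         f"[0, {region_map.length})")
    eligible = []
    for idx, (label, a, b) in enumerate(region_map.intervals):
        if b <= a:
            continue  # empty region (e.g. zero-length end) can hold nothing
        lo = a - max_overlap if a > 0 else 0
        hi = b + max_overlap if b < region_map.length else region_map.length
        if start >= lo and end <= hi:
            overlap = min(end, b) - max(start, a)
            eligible.append((label, idx, overlap))
    if not eligible:
        return FRAGMENT
    arm = [e for e in eligible if e[0] in ("mature", "star")]
    pool = arm if arm else eligible
    pool.sort(key=lambda e: (-e[2], e[1]))  # majority overlap, then 5'->3'
    return pool[0][0]


def profile_reads(readset, precursors, multi="best", max_overlap=1):
    """Assign every precursor-aligned read a region label.

    ``precursors`` is an iterable of precursor objects (sequence + mature/
    star intervals).  A read aligning nowhere contributes nothing.  With
    ``multi='best'`` (default) a read occurring at several intervals or in
    several precursors yields one assignment — the most specific label
    (mature/star > loop/ends > fragment), ties to the leftmost interval of
    the first precursor; ``multi='all'`` keeps every occurrence.
    """
    if multi not in ("best", "all"):
        raise ValueError("multi must be 'best' or 'all'")
    precs = [(p, RegionMap.from_precursor(p)) for p in precursors]
    assignments = []
    for read in readset.reads:
        hits = []
        for order, (prec, rmap) in enumerate(precs):
            for iv in align_to_precursor(read.sequence, prec.sequence):
                label = classify_read_region(iv, rmap, max_overlap)
                hits.append((label, order, iv, rmap.precursor_id))
        if not hits:
            continue
        if multi == "best":
            hits.sort(key=lambda h: (-_SPECIFICITY[h[0]], h[1], h[2][0]))
            hits = hits[:1]
        for label, _, (a, b), pid in hits:
            assignments.append(RegionAssignment(read.id, pid, a, b, label))
    return assignments


def summarize_profile(assignments):
    """Percentage of precursor-aligned reads per label; sums to 100.

    Accepts assignments pooled over any number of samples (summarizing a
    concatenation equals summarizing the pool).  Zero assignments yield an
    empty table rather than a division error.
    """
    order = list(REGION_LABELS) + [FRAGMENT]
    if not assignments:
        return pd.DataFrame(columns=["label", "count", "percent"])
    counts = {}
    for a in assignments:
        counts[a.label] = counts.get(a.label, 0) + 1
    total = sum(counts.values())
    rows = [{"label": lab, "count": counts.get(lab, 0),
             "percent": 100.0 * counts.get(lab, 0) / total}
            for lab in order]
    return pd.DataFrame(rows)
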