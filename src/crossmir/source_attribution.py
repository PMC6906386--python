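"""Assign each small RNA read a set of source libraries.

A read belongs to a library when it has an ungapped occurrence with at most
``k_max`` substitutions (default 1 — the "fewer than two mismatches" rule)
on either strand.  Reads are then partitioned into exclusive category
combinations (e.g. exclusively host-plant, insect+symbiont, unmapped) and
summarized per sample group with means and n-1 standard deviations.

The default cascade interrogates the host insect and obligate symbiont
genomes first and sends only the reads those fail to explain against the
plant/bacterial/viral libraries; an all-vs-all mode matches every read
against every library, which is required to observe joint categories such
as insect+plant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .smallrna_io import AlignmentRecord
from .synthetic_data import CATEGORIES, revcomp

logger = logging.getLogger(__name__)

#: categories interrogated first in the cascade
FIRST_STAGE = ("host_insect", "obligate_symbiont")


@dataclass(frozen=True)
class Library:
    name: str
    category: str
    sequence: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class SourcePartition:
    """Per-read library-membership sets and the per-sample category table."""

    sample_id: str
    membership: dict            # read id -> frozenset of category names
    total: int                  # filtered reads interrogated
    mode: str = "cascade"
    k_max: int = 1

    @property
    def category_counts(self):
        """Counts per exclusive membership combination ('unmapped' for none)."""
        counts = {}
        for cats in self.membership.values():
            key = "unmapped" if not cats else "+".join(sorted(cats))
            counts[key] = counts.get(key, 0) + 1
        return counts

    @property
    def n_unmapped(self):
        return sum(1 for cats in self.membership.values() if not cats)


def _encode(seq):
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def match_read(read_seq, library, k_max=1, read_id="read", both_strands=True):
    """All ungapped occurrences of a read in a library with <= k_max mismatches.

    Scans every alignment position of both strands (a minus-strand hit means
    the reverse complement of the read matches the forward reference) and
    counts substitutions per window; ``N`` never matches and so counts as a
    mismatch.  Hits are ordered by (reference, position, strand).
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    if len(read_seq) < 17:
        raise ValueError(f"read shorter than 17 nt ({len(read_seq)})")
    lib_arr = _encode(library.sequence)
    hits = []
    queries = [("+", read_seq)]
    if both_strands:
        queries.append(("-", revcomp(read_seq)))
    for strand, q in queries:
        if len(q) > len(lib_arr):
            continue
        windows = sliding_window_view(lib_arr, len(q))
        mm = (windows != _encode(q)).sum(axis=1)
        for pos in np.nonzero(mm <= k_max)[0]:
            hits.append(AlignmentRecord(read_id, library.name, library.name,
                                        int(pos), strand, int(mm[pos])))
    hits.sort(key=lambda h: (h.reference, h.start, h.strand))
    return hits


def _matches_anywhere(read_arr, rc_arr, lib_arr, k_max):
    """True when either orientation occurs in the library with <= k_max
    substitutions (membership only; positions not needed)."""
    m = len(read_arr)
    if m > len(lib_arr):
        return False
    windows = sliding_window_view(lib_arr, m)
    if ((windows != read_arr).sum(axis=1) <= k_max).any():
        return True
    return bool(((windows != rc_arr).sum(axis=1) <= k_max).any())


def partition_reads(readset, libraries, k_max=1, mode="cascade"):
    """Compute per-read category-membership sets for a sample.

    In ``cascade`` mode reads are first matched against the host-insect and
    obligate-symbiont libraries; only reads with no first-stage membership
    are interrogated against the remaining libraries.  In ``all`` mode every
    read is matched against every library.  Membership is at the category
    level: matching any library of a category once suffices.
    """
    if mode not in ("cascade", "all"):
        raise ValueError("mode must be 'cascade' or 'all'")
    names = [lib.name for lib in libraries]
    if len(set(names)) != len(names):
        raise ValueError("duplicate library names")
    logger.info("partition_reads: sample=%s mode=%s k_max=%d libraries=%s",
                readset.sample_id, mode, k_max, names)

    stage1 = [lib for lib in libraries if lib.category in FIRST_STAGE]
    stage2 = [lib for lib in libraries if lib.category not in FIRST_STAGE]
    lib_arrays = {lib.name: _encode(lib.sequence) for lib in libraries}

    membership = {}
    for read in readset.reads:
        arr, rc = _encode(read.sequence), _encode(revcomp(read.sequence))
        cats = set()
        for lib in stage1:
            if _matches_anywhere(arr, rc, lib_arrays[lib.name], k_max):
                cats.add(lib.category)
        if mode == "all" or not cats:
            for lib in stage2:
                if _matches_anywhere(arr, rc, lib_arrays[lib.name], k_max):
                    cats.add(lib.category)
        membership[read.id] = frozenset(cats)
    return SourcePartition(readset.sample_id, membership, len(readset.reads),
                           mode=mode, k_max=k_max)


def partition_from_alignments(sample_id, read_ids, records_by_library, categories):
    """Build a SourcePartition from externally produced SAM records.

    Gapped records are excluded from membership (the internal contract is
    ungapped) and counted separately; the returned tuple is
    ``(partition, n_gapped_excluded)``.
    """
    membership = {rid: set() for rid in read_ids}
    n_gapped = 0
    for library, records in records_by_library.items():
        cat = categories[library]
        for rec in records:
            if rec.gapped:
                n_gapped += 1
                continue
            if rec.read_id in membership:
                membership[rec.read_id].add(cat)
    membership = {rid: frozenset(c) for rid, c in membership.items()}
    return SourcePartition(sample_id, membership, len(read_ids)), n_gapped


def partition_table(partition):
    """Per-read membership table (TSV-ready)."""
    rows = [{"read_id": rid,
             "categories": "+".join(sorted(cats)) if cats else "unmapped"}
            for rid, cats in sorted(partition.membership.items())]
    return pd.DataFrame(rows)


def summarize_partitions(partitions_by_group, include_categories=()):
    """Mean and n-1 SD of per-category proportions across a group's samples.

    ``partitions_by_group`` maps a group label (e.g. tissue) to its samples'
    SourcePartitions.  The table carries every exclusive membership
    combination observed in any sample (absent combinations count 0) plus
    'any:<category>' roll-ups (proportion of reads whose membership contains
    the category, however many others it also matches).
    ``include_categories`` forces rows for combinations absent from every
    sample (reported as 0).  Groups of one sample report SD as NaN
    (undefined), not zero.
    """
    rows = []
    for group, partitions in partitions_by_group.items():
        if not partitions:
            raise ValueError(f"group {group!r} has no samples")
        per_sample = []
        combos, categories = set(include_categories), set()
        for part in partitions:
            counts = part.category_counts
            combos.update(counts)
            for cats in part.membership.values():
                categories.update(cats)
            per_sample.append((part, counts))
        for combo in sorted(combos):
            props = [counts.get(combo, 0) / part.total for part, counts in per_sample]
            rows.append(_summary_row(group, combo, props))
        for cat in sorted(categories):
            props = []
            for part, _ in per_sample:
                n = sum(1 for cats in part.membership.values() if cat in cats)
                props.append(n / part.total)
            rows.append(_summary_row(group, f"any:{cat}", props))
    return pd.DataFrame(rows)


def _summary_row(group, category, props):
    arr = np.asarray(props, dtype=float)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else float("nan")
    return {"group": group, "category": category, "n_samples": len(arr),
            "mean_proportion": float(arr.mean()), "sd_proportion": sd}
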