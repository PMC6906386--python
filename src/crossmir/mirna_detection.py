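"""Detect annotated plant miRNAs in insect small RNA read sets.

A miRNA is observed in a sample when a processed read is exactly identical
to the mature/star sequence, full length, forward orientation — a 22-nt
miRNA contained inside a 30-nt read is a precursor fragment, not a mature
observation.  A substring mode exists for sensitivity analysis, and a
reverse-complement mode for unstranded libraries.
"""

from __future__ import annotations

import logging
from collections import Counter

import pandas as pd

from .synthetic_data import revcomp

logger = logging.getLogger(__name__)


def detect_mirnas(mirnas, readset, mode="exact", orientation="forward"):
    """Count perfect-match observations of each miRNA in a read set.

    ``mirnas`` maps miRNA id -> sequence (sequences must be unique, so each
    read counts toward at most one miRNA).  Returns a DataFrame with columns
    (mirna_id, sample_id, count); a miRNA is "detected" iff count >= 1.
    """
    if mode not in ("exact", "substring"):
        raise ValueError("mode must be 'exact' or 'substring'")
    if orientation not in ("forward", "both"):
        raise ValueError("orientation must be 'forward' or 'both'")
    if not mirnas:
        logger.warning("detect_mirnas: empty miRNA set")
        return pd.DataFrame(columns=["mirna_id", "sample_id", "count"])
    seqs = list(mirnas.values())
    if len(set(seqs)) != len(seqs):
        raise ValueError("miRNA sequences must be unique")

    rows = []
    if mode == "exact":
        counter = Counter(r.sequence for r in readset.reads)
        for mid, seq in sorted(mirnas.items()):
            count = counter[seq]
            if orientation == "both":
                count += counter[revcomp(seq)]
            rows.append({"mirna_id": mid, "sample_id": readset.sample_id,
                         "count": count})
    else:
        for mid, seq in sorted(mirnas.items()):
            queries = [seq] if orientation == "forward" else [seq, revcomp(seq)]
            count = sum(1 for r in readset.reads
                        if any(q in r.sequence for q in queries))
            rows.append({"mirna_id": mid, "sample_id": readset.sample_id,
                         "count": count})
    return pd.DataFrame(rows)


def detected_set(detections):
    """miRNA ids with count >= 1 in a detection table."""
    return set(detections.loc[detections["count"] >= 1, "mirna_id"])


def intersect_across_samples(detections_by_sample, samples=None):
    """miRNAs detected (count >= 1) in every sample of a group."""
    if samples is None:
        samples = list(detections_by_sample)
    if not samples:
        raise ValueError("sample group must be nonempty")
    sets = [detected_set(detections_by_sample[s]) for s in samples]
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


def map_to_precursors(mirnas, detected_ids):
    """Union of encoding precursors over a detected miRNA set.

    ``mirnas`` maps miRNA id -> MiRNA (with ``precursor_ids``).  Returns
    ``(precursor_ids, per_mirna, flagged)`` where per_mirna gives each
    detected miRNA's own precursor list and flagged collects detected
    miRNAs with an empty precursor list.  Duplicated loci mean the union
    can exceed the number of miRNAs.
    """
    per_mirna, union, flagged = {}, set(), []
    for mid in sorted(detected_ids):
        precs = list(mirnas[mid].precursor_ids)
        per_mirna[mid] = precs
        if not precs:
            flagged.append(mid)
        union.update(precs)
    if flagged:
        logger.warning("map_to_precursors: %d detected miRNAs have no "
                       "precursor list: %s", len(flagged), flagged)
    return sorted(union), per_mirna, flagged
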