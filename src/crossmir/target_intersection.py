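"""Intersect per-tool miRNA target predictions in the seed region.

Target-prediction tools disagree wildly; the consensus filter keeps a
(miRNA, target) pair only when every required tool reports a site and the
target-side images of the miRNA seed (positions 2-8 from the 5' end,
configurable) mutually overlap by at least one nucleotide.  Venn counts per
tool combination and UTR-to-isoform expansion of the consensus set are
provided alongside.

Coordinates are 0-based half-open on the target; per-tool ingestion
converts each tool's native convention (1-based closed) at parse time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SEED = (2, 8)  # miRNA positions, 1-based inclusive from the 5' end


@dataclass(frozen=True)
class TargetPrediction:
    """One predicted binding site of a miRNA on a target (UTR/transcript)."""

    tool: str
    mirna_id: str
    target_id: str
    start: int  # 0-based half-open site interval on the target
    end: int
    score: float | None = None

    def __post_init__(self):
        if self.end - self.start < 6:
            raise ValueError(f"site interval shorter than 6 nt: {self.start, self.end}")


@dataclass(frozen=True)
class ConsensusTarget:
    mirna_id: str
    target_id: str
    tools: tuple
    seed_start: int  # consensus seed-image interval on the target
    seed_end: int


def seed_interval(mirna_length, site, seed=DEFAULT_SEED):
    """Target-side image of the miRNA seed for one predicted site.

    With antiparallel pairing, miRNA position p (1-based from the miRNA 5'
    end) pairs with target position site_end - p; seed positions a..b
    therefore map to the half-open target interval
    [site_end - b, site_end - a + 1).  Returns None (excluded) when the site
    is too short to contain the image.
    """
    a, b = seed
    if not 1 <= a <= b:
        raise ValueError(f"bad seed definition {seed}")
    start, end = site
    if end - start < mirna_length - 4:
        raise ValueError(f"site {site} shorter than miRNA length - 4")
    img = (end - b, end - a + 1)
    if img[0] < start:
        return None  # site too short to contain the seed image
    return img


def _overlap(x, y):
    return min(x[1], y[1]) - max(x[0], y[0])


def _seed_images(predictions, mirna_lengths, seed):
    """(miRNA, target) -> tool -> list of seed images; logs exclusions."""
    images = {}
    excluded = 0
    for p in predictions:
        img = seed_interval(mirna_lengths[p.mirna_id], (p.start, p.end), seed)
        if img is None:
            excluded += 1
            continue
        images.setdefault((p.mirna_id, p.target_id), {}).setdefault(p.tool, []).append(img)
    if excluded:
        logger.info("seed images: %d sites too short to contain a seed image "
                    "were excluded", excluded)
    return images


def intersect_predictions(predictions, required_tools, mirna_lengths,
                          seed=DEFAULT_SEED):
    """Consensus (miRNA, target) pairs with seed-region agreement.

    A pair is consensus iff every required tool reports at least one site
    such that the chosen sites' seed images mutually overlap by >= 1 nt
    (pairwise overlap of intervals implies a common intersection).  The
    consensus interval is the intersection of those images; when several
    site combinations qualify, the lexicographically first combination (by
    tool order, then image position) is reported.
    """
    required = tuple(required_tools)
    images = _seed_images(predictions, mirna_lengths, seed)
    out = []
    for (mirna, target), by_tool in sorted(images.items()):
        if any(t not in by_tool for t in required):
            continue
        options = [sorted(by_tool[t]) for t in required]
        for combo in product(*options):
            if all(_overlap(x, y) >= 1
                   for i, x in enumerate(combo) for y in combo[i + 1:]):
                lo = max(c[0] for c in combo)
                hi = min(c[1] for c in combo)
                out.append(ConsensusTarget(mirna, target, required, lo, hi))
                break
    return out


def venn_counts(predictions, tools, mirna_lengths=None):
    """Exclusive tool-combination counts of (miRNA, target) pairs.

    Tallies, for every nonempty subset of ``tools``, the pairs predicted by
    exactly that subset (site anywhere; no seed requirement — this mirrors
    per-tool prediction overlap, the consensus filter is separate).  The
    disjoint-region counts partition the distinct pairs.
    """
    tools = tuple(tools)
    if len(tools) < 2:
        raise ValueError("venn_counts needs >= 2 tools")
    by_pair = {}
    for p in predictions:
        if p.tool in tools:
            by_pair.setdefault((p.mirna_id, p.target_id), set()).add(p.tool)
    counts = {}
    for subset in by_pair.values():
        key = tuple(t for t in tools if t in subset)
        counts[key] = counts.get(key, 0) + 1
    return counts


def venn_table(counts, tools):
    rows = [{"tools": "+".join(key), "n_tools": len(key), "count": n}
            for key, n in sorted(counts.items(), key=lambda kv: (-len(kv[0]), kv[0]))]
    return pd.DataFrame(rows)


def expand_utrs(consensus_targets, utr_to_isoforms):
    """Expand UTR-level consensus targets to their mRNA isoforms.

    ``utr_to_isoforms`` maps UTR id -> iterable of transcript ids (every
    isoform sharing the UTR is a potential target).  Unknown UTR ids raise,
    listing them.  Returns ``(isoforms, per_utr)`` with duplicates removed;
    the isoform list can exceed the UTR count.
    """
    utr_ids = sorted({c.target_id for c in consensus_targets})
    missing = [u for u in utr_ids if u not in utr_to_isoforms]
    if missing:
        raise KeyError(f"UTR ids absent from the isoform table: {missing}")
    per_utr = {u: sorted(set(utr_to_isoforms[u])) for u in utr_ids}
    isoforms = sorted({iso for isos in per_utr.values() for iso in isos})
    return isoforms, per_utr


def consensus_table(consensus_targets, seed=DEFAULT_SEED):
    """Consensus report; seed-image coordinates are 1-based closed."""
    rows = [{"mirna_id": c.mirna_id, "target_id": c.target_id,
             "tools": "+".join(c.tools),
             "seed_start": c.seed_start + 1, "seed_end": c.seed_end}
            for c in consensus_targets]
    df = pd.DataFrame(rows, columns=["mirna_id", "target_id", "tools",
                                     "seed_start", "seed_end"])
    df.attrs["seed_definition"] = f"miRNA positions {seed[0]}-{seed[1]} (1-based, 5'->3')"
    return df


# ---------------------------------------------------------------------------
# tool-table ingestion
# ---------------------------------------------------------------------------

def parse_tool_table(path, tool, one_based=True):
    """Read a tool's tabular predictions into TargetPredictions.

    Expects TSV columns (mirna_id, target_id, start, end[, score]); most
    tool exports use 1-based closed site coordinates (the default), which
    are converted to the internal 0-based half-open convention.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    preds = []
    for row in df.itertuples():
        start = int(row.start) - 1 if one_based else int(row.start)
        end = int(row.end) if one_based else int(row.end)
        score = float(row.score) if hasattr(row, "score") else None
        preds.append(TargetPrediction(tool, str(row.mirna_id), str(row.target_id),
                                      start, end, score))
    return preds
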