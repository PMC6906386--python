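"""Resampling-based COG enrichment of miRNA target sets.

The observed statistic is the per-COG count of target proteins; the null is
built by repeatedly drawing the same number of 3' UTRs uniformly with
replacement from the reference universe, expanding each draw into every
isoform sharing the UTR (so a replicate can contain more proteins than
UTRs), and tallying COG letters.  Significance is the empirical two-tailed
p-value: twice the smaller tail proportion, capped at 1; an observed value
outside every replicate is reported as the bound p < 1/R rather than 0.

Multi-letter COG assignments count once in every assigned category, and the
reference composition is computed identically, so observed and null are
commensurable.  A single-primary-letter mode and a protein-level sampling
mode exist behind flags.  No multiple-testing correction is applied to the
significance flags; a Bonferroni column is emitted for reference only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the 26 single-letter COG functional categories
COG_LETTERS = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ")

UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class PValue:
    """Empirical p-value; ``bound`` means "p < value" (zero-tail case)."""

    value: float
    bound: bool = False

    def __str__(self):
        return f"< {self.value:g}" if self.bound else f"{self.value:g}"


@dataclass
class NullDistributions:
    """Per-COG replicate counts from the resampling null.

    ``counts`` is an (R x C) matrix over ``letters``; ``totals`` holds each
    replicate's annotated-protein total (needed to express thresholds on the
    percentage/enrichment scale).
    """

    letters: tuple
    counts: np.ndarray
    totals: np.ndarray
    n_draws: int
    n_replicates: int
    seed: int

    def replicates(self, letter):
        return self.counts[:, self.letters.index(letter)]


def _letters_of(annotation, multi_letter=True):
    letters = [c for c in str(annotation) if c in set(COG_LETTERS)]
    if not letters:
        return ()
    return tuple(letters) if multi_letter else (letters[0],)


def observed_cog_counts(target_ids, expansion, cog_table, multi_letter=True):
    """Per-COG counts of a target set, after isoform expansion.

    ``target_ids`` are UTR ids when ``expansion`` (UTR -> isoform ids) is
    given, otherwise protein/transcript ids used directly.  Ids outside the
    annotation universe raise, listing them.  Proteins without a COG letter
    are tallied under ``unannotated``.
    """
    if expansion is not None:
        missing = sorted(t for t in target_ids if t not in expansion)
        if missing:
            raise KeyError(f"target ids absent from the expansion table: {missing[:10]}")
        proteins = [iso for t in target_ids for iso in expansion[t]]
    else:
        proteins = list(target_ids)
    missing = sorted(p for p in proteins if p not in cog_table)
    if missing:
        raise KeyError(f"protein ids absent from the COG table: {missing[:10]}")

    counts = {}
    unannotated = 0
    for p in proteins:
        letters = _letters_of(cog_table[p], multi_letter)
        if not letters:
            unannotated += 1
        for letter in letters:
            counts[letter] = counts.get(letter, 0) + 1
    return counts, unannotated


def _expansion_matrix(universe, expansion, cog_table, multi_letter=True):
    """Per-UTR COG-count rows: M[u, c] = how many of UTR u's isoforms carry
    letter c; also per-UTR annotated totals and isoform counts."""
    letters = sorted({letter
                      for p in cog_table
                      for letter in _letters_of(cog_table[p], multi_letter)})
    index = {c: i for i, c in enumerate(letters)}
    M = np.zeros((len(universe), len(letters)), dtype=np.int64)
    n_isoforms = np.zeros(len(universe), dtype=np.int64)
    for u, utr in enumerate(universe):
        isos = expansion[utr] if expansion is not None else (utr,)
        n_isoforms[u] = len(isos)
        for iso in isos:
            for letter in _letters_of(cog_table[iso], multi_letter):
                M[u, index[letter]] += 1
    return tuple(letters), M, n_isoforms


def monte_carlo_null(universe, expansion, cog_table, n_draws, n_replicates,
                     seed, multi_letter=True, chunk=20_000):
    """Resampling null: R replicates of n UTR draws (uniform, with
    replacement), isoform-expanded and tallied per COG.

    Deterministic for a fixed seed; replicates are generated in chunks so
    R = 10^6 stays within memory.  ``universe`` lists the reference UTR ids
    (or protein ids, with ``expansion=None`` for protein-level sampling).
    """
    if n_draws < 1 or n_replicates < 1:
        raise ValueError("n_draws and n_replicates must be >= 1")
    universe = list(universe)
    if not universe:
        raise ValueError("reference universe is empty")
    letters, M, _ = _expansion_matrix(universe, expansion, cog_table, multi_letter)
    rng = np.random.default_rng(seed)
    counts = np.empty((n_replicates, len(letters)), dtype=np.int64)
    done = 0
    while done < n_replicates:
        r = min(chunk, n_replicates - done)
        idx = rng.integers(0, len(universe), size=(r, n_draws))
        counts[done:done + r] = M[idx].sum(axis=1)
        done += r
    return NullDistributions(letters, counts, counts.sum(axis=1),
                             n_draws, n_replicates, seed)


def empirical_two_tailed_p(observed, replicates):
    """Tail-doubled empirical p of an observed count against null replicates.

    p = min(1, 2 * min(P_hat(X >= obs), P_hat(X <= obs))), ties counted in
    both tails.  When the smaller tail holds zero replicates the result is
    the bound p < 1/R (PValue with ``bound=True``).
    """
    replicates = np.asarray(replicates)
    R = len(replicates)
    if R < 1:
        raise ValueError("need at least one replicate")
    hi = int((replicates >= observed).sum())
    lo = int((replicates <= observed).sum())
    m = min(hi, lo)
    if m == 0:
        return PValue(1.0 / R, bound=True)
    return PValue(min(1.0, 2.0 * m / R))


def empirical_two_tailed_p_deviation(observed, replicates):
    """Variant two-tailed rule: proportion of replicates at least as far
    from the null mean as the observed count (absolute deviation)."""
    replicates = np.asarray(replicates, dtype=float)
    R = len(replicates)
    dev = abs(observed - replicates.mean())
    m = int((np.abs(replicates - replicates.mean()) >= dev).sum())
    if m == 0:
        return PValue(1.0 / R, bound=True)
    return PValue(min(1.0, m / R))


def reference_composition(universe, expansion, cog_table, multi_letter=True):
    """Whole-reference per-COG counts (same counting rule as observed)."""
    letters, M, _ = _expansion_matrix(universe, expansion, cog_table, multi_letter)
    totals = M.sum(axis=0)
    return dict(zip(letters, (int(t) for t in totals)))


def enrichment_report(observed_counts, nulls, reference_counts, alpha=0.05,
                      p_rule="tail_doubling"):
    """Per-COG enrichment table in the style of the percent-difference plots.

    percent enrichment = (observed% - reference%) / reference% * 100, with
    percentages over annotated assignments.  Significance thresholds give
    the minimum |enrichment| reaching p < alpha on each side, from the
    alpha/2 and 1 - alpha/2 empirical quantiles of the null's per-replicate
    percentages.  A COG observed but absent from the reference is flagged
    ``undefined-positive``.  Rows are sorted by observed percentage,
    ascending.
    """
    if p_rule not in ("tail_doubling", "deviation"):
        raise ValueError("p_rule must be 'tail_doubling' or 'deviation'")
    p_func = (empirical_two_tailed_p if p_rule == "tail_doubling"
              else empirical_two_tailed_p_deviation)
    letters = nulls.letters
    for letter in observed_counts:
        if letter not in reference_counts and observed_counts[letter] > 0:
            logger.warning("COG %s observed but absent from the reference; "
                           "enrichment undefined", letter)
    obs_total = sum(observed_counts.values())
    ref_total = sum(reference_counts.values())
    if obs_total == 0 or ref_total == 0:
        raise ValueError("observed and reference compositions must be nonempty")

    with np.errstate(invalid="ignore", divide="ignore"):
        null_pct = 100.0 * nulls.counts / nulls.totals[:, None]

    rows = []
    for j, letter in enumerate(letters):
        obs = observed_counts.get(letter, 0)
        ref = reference_counts.get(letter, 0)
        obs_pct = 100.0 * obs / obs_total
        ref_pct = 100.0 * ref / ref_total
        if ref == 0:
            enrich = float("inf") if obs > 0 else 0.0
            flag = "undefined-positive" if obs > 0 else ""
        else:
            enrich = (obs_pct - ref_pct) / ref_pct * 100.0
            flag = ""
        reps = nulls.counts[:, j]
        pval = p_func(obs, reps)
        median = float(np.median(reps))
        q_lo, q_hi = np.quantile(null_pct[:, j], [alpha / 2, 1 - alpha / 2])
        if ref > 0:
            thr_under = (q_lo - ref_pct) / ref_pct * 100.0
            thr_over = (q_hi - ref_pct) / ref_pct * 100.0
        else:
            thr_under = thr_over = float("nan")
        significant = (pval.bound or pval.value < alpha)
        rows.append({
            "cog": letter,
            "observed_count": obs,
            "observed_pct": obs_pct,
            "reference_pct": ref_pct,
            "pct_enrichment": enrich,
            "direction": "over" if obs > median else ("under" if obs < median else "none"),
            "p_value": pval.value,
            "p_is_bound": pval.bound,
            "significant": significant,
            "threshold_over_pct": thr_over,
            "threshold_under_pct": thr_under,
            "bonferroni_p": min(1.0, pval.value * len(letters)),
            "flag": flag,
        })
    df = pd.DataFrame(rows).sort_values("observed_pct", kind="stable",
                                        ignore_index=True)
    df.attrs["alpha"] = alpha
    df.attrs["n_replicates"] = nulls.n_replicates
    df.attrs["n_draws"] = nulls.n_draws
    return df


# ---------------------------------------------------------------------------
# annotation-table ingestion (eggnog-mapper dialect)
# ---------------------------------------------------------------------------

def parse_cog_annotations(path, id_column="query", cog_column="COG_category"):
    """Read an eggnog-mapper-style TSV into an id -> COG-letters mapping.

    Lines starting with '#' are ignored except the first one naming the
    columns; ids absent a recognizable letter map to "" (unannotated).
    """
    df = pd.read_csv(path, sep="\t", comment=None, skip_blank_lines=True)
    if df.columns[0].startswith("#"):
        df = df.rename(columns={df.columns[0]: df.columns[0].lstrip("#")})
    if id_column not in df.columns or cog_column not in df.columns:
        raise ValueError(f"annotation table must carry {id_column!r} and "
                         f"{cog_column!r} columns; got {list(df.columns)}")
    table = {}
    for row in df.itertuples(index=False):
        raw = getattr(row, cog_column)
        letters = "".join(c for c in str(raw) if c in set(COG_LETTERS))
        table[str(getattr(row, id_column))] = letters
    return table


def read_expansion_table(path):
    """Read the UTR -> isoform TSV (columns utr_id, transcripts comma-joined)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return {row.utr_id: tuple(str(row.transcripts).split(","))
            for row in df.itertuples(index=False)}
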