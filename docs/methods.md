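# Methods

This note records the models and procedures `crossmir` implements, the
defaults and why, what the synthetic generator does and does not emulate,
and the numerical choices made where the underlying analysis left the
design open.

## Read processing

Reads are adapter-clipped at the leftmost position where at least 8 bases
of the adapter match exactly and the match extends to the end of the read
(or the end of the adapter). Quality filtering interprets "phred < 28" as
3′-end trimming to the longest prefix whose bases are all ≥ 28; a
`drop`-whole-read mode exists because published pipelines differ and the
choice is rarely stated. Both modes are logged, and processing is
idempotent. Length windows: 17–35 nt for insect-tissue mapping, 17–25 nt
for plant miRNA precursor annotation. Accounting is strict: retained +
dropped-with-reason = input, per sample.

## Source attribution

The matcher reports every ungapped occurrence of a read (either strand)
with at most `k_max` substitutions; `k_max = 1` encodes the "fewer than two
mismatches" rule. `N` never matches and therefore costs a mismatch. The
implementation is a vectorized sliding-window Hamming count, verified
exhaustively against an independent position-by-position scan.

Membership is **set-valued and category-level**: a read "exclusive" to the
host plant has membership exactly `{host_plant}`; multi-mapping within a
library counts once, and no best-hit resolution is attempted, because the
downstream quantities are category proportions, not placements. Two
interrogation orders are provided:

- `cascade` (default): host-insect and obligate-symbiont genomes first;
  only reads those fail to explain are matched against the plant,
  bacterial, and viral libraries. This mirrors the two-stage design of the
  original mapping.
- `all`: every read against every library — required to observe joint
  categories such as insect+plant, since the cascade never aligns an
  insect-mapped read to the plant library. Which order produced the
  published per-sample tables is not decidable from the text; both are
  first-class and the mode is logged and recorded in output headers.

Group summaries report the mean and the sample (n−1) standard deviation of
per-category proportions; single-sample groups report SD as undefined
(NaN), never 0. Gapped records ingested from external SAM files are
excluded from membership (the internal contract is ungapped) and counted
separately.

## Precursor collapse, mature/star, known/novel

Duplicate loci called independently in several datasets are grouped by
transitive ≥ 50 % reciprocal overlap on the same strand (the threshold is a
package choice — the source analysis says only that duplicates were
removed — and is configurable and logged). Within a group the member with
the most mature-arm reads is retained; ties go to the lexicographically
smallest dataset id, with a warning. The arm with more mapped reads is
mature, the other star; this deliberately does **not** encode the 5p/3p
naming convention, so arms are recorded as first/second. Equal counts
designate the first arm, with a warning.

The known/novel decision tree, with exact boundary semantics:

| precursor e-value | coverage | min arm (short-search) e | status |
|---|---|---|---|
| e < 1e-10 | — | — | known |
| e ≥ 1e-3 | — | — | novel |
| 1e-10 ≤ e < 1e-3 | ≥ 0.60 | — | known |
| 1e-10 ≤ e < 1e-3 | < 0.60 | < 1e-10 | known |
| 1e-10 ≤ e < 1e-3 | < 0.60 | ≥ 1e-10 | novel |

e exactly 1e-10 lands in the middle tier; coverage exactly 0.60 is known;
a short-search e exactly 1e-10 is novel. The minimum over the mature and
star arm e-values decides the short-search branch: strong homology of
either arm suffices for family membership. A precursor reaching a branch
without the needed evidence is left `unset` with an explicit note rather
than guessed. Query coverage is consumed as supplied by the evidence table
and never recomputed, since homology tools define it differently.
Expert-criteria overrides of novel calls are representable as an input
exception list, not inferred.

Structural validation fails a precursor when it exceeds 300 nt, an arm
falls outside 20–24 nt, or fewer than 75 % (configurable) of mature
positions pair with star positions in the supplied dot-bracket structure.

## Detection and profiling

"Perfect match" means **full-length string equality** in forward
orientation: a 22-nt miRNA inside a 30-nt read is a precursor fragment,
not a mature observation, and the discrete per-miRNA copy counts the
analysis reports only make sense under equality. A substring mode and a
reverse-complement mode exist behind flags for sensitivity analysis.

For profiling, a read must occur in the precursor exactly (no mismatches
or gaps). It takes a region's label when its interval lies within the
region extended by exactly one nucleotide into each adjacent region
(extensions clipped at the precursor ends); wider straddles are fragments.
When the 1-nt extensions make several regions eligible (possible only for
intervals ≤ 2 nt), mature/star outrank loop/ends, then the region holding
the majority of the interval, then 5′→3′ order. Reads occurring at several
intervals or precursors are counted once at their most specific label
(mature/star > loop/ends > fragment, ties leftmost) by default; a
count-all mode exists because the original tally rule is unstated.

## Target intersection

The seed is miRNA positions 2–8 from the 5′ end — the canonical animal-side
choice; the width is configurable (plant-side tools weight a longer
region, e.g. 2–13) and recorded in output headers. With antiparallel
pairing, miRNA position p pairs with target position `site_end − p`, so the
seed images to the half-open target interval
`[site_end − 8, site_end − 1)`. A (miRNA, target) pair is consensus iff
every required tool has a site whose seed images mutually overlap by
≥ 1 nt (pairwise interval overlap implies a common point); the consensus
interval is their intersection. Venn counts tally pairs per exact tool
subset without the seed requirement, mirroring raw per-tool overlap.
UTR-level targets expand to every isoform sharing the UTR; both the
distinct-UTR and distinct-pair tallies are emitted because published
target counts are ambiguous between the two.

## COG enrichment

The sampling unit is the 3′ UTR: each null replicate draws n UTRs
uniformly **with replacement** from the reference universe (n = the
observed target count), expands each to all isoforms sharing the UTR — so
replicates may contain more proteins than UTRs — and tallies COG letters.
Multi-letter assignments count once per letter, in the observed set, the
null, and the reference composition alike, keeping all three
commensurable; a single-primary-letter mode and a protein-level sampling
mode are available but off by default.

The empirical two-tailed p is tail-doubling with ties in both tails,
capped at 1; a zero minimum tail is reported as the bound `p < 1/R`, never
as 0. An alternative |deviation-from-mean| rule is available behind a
flag. No multiple-testing correction feeds the significance flags (the
analysis style is per-COG); a Bonferroni column is emitted for reference.
Significance thresholds on the percent-enrichment scale come from the
α/2 and 1−α/2 empirical quantiles of the null's per-replicate COG
percentages (each replicate normalized by its own annotated total),
converted with the reference percentage; this per-replicate normalization
is the package's choice, made so the threshold scale matches the reported
enrichment scale.

Replicate counts: 10⁶ matches the original analysis; the pipeline default
is 2×10⁴ so a desk run finishes in seconds. Calibration is tested at 10⁵
replicates against exact binomial computations, and the type-I error rate
of the whole construction is checked at ~0.05 on null-drawn targets.

## Synthetic data: what a green test establishes

The generator emulates *structure*, not biology: uniform-composition
source genomes at configurable GC, rejection-sampled so that no 17-mer
(forward or reverse-complement) is shared across libraries (ground-truth
provenance is then unambiguous, and zero-noise attribution must be
perfect); hairpins built as 5′ flank + arm + loop + reverse-complement arm
+ 3′ flank with a chosen number of broken duplex positions; reads drawn as
exact multinomial mixtures of substrings with substitution-only errors
(indels are excluded by design: gapped alignments are filtered downstream,
so indel truth would be untestable); tool tables with planted
consensus/partial/disjoint overlap structure; and a COG universe with 1–3
isoforms per UTR and ~10 % unannotated proteins.

It does **not** mimic real plant sequence composition, miRNA family
sequences, expression skew, or phloem small RNA profiles. A green
end-to-end test therefore establishes algorithmic correctness against
planted truth — not that the pipeline reproduces accession-dependent
headline numbers, which require the original sequencing data and genomes.

Defaults the demo world states: five libraries (3–6 kb), three 800-read
gut samples with a 35/5/40/15/5 % insect/symbiont/plant/bacterial/viral
mixture, eight precursor loci of which two are duplicated and five known,
a 300-UTR reference, and a region-read split of 85.7/5.7/1.8/6.8 %
mature/star/loop/fragment (the published profile puts 91.4 % of
precursor-aligned reads on mature+star, 1.8 % on loops and 6.8 % on
fragments; the mature-vs-star subdivision is the generator's own, chosen
mature-dominant).

## Numerical and engineering choices

- Coordinates are 0-based half-open internally, 1-based closed in every
  written report (stated in each header).
- All randomness flows from `numpy.random.default_rng` seeds; the pipeline
  derives per-stage child seeds (< 2³¹) from the run seed, and manifests
  record sha256 checksums so determinism is verifiable bit-for-bit.
- Mismatch counts from SAM prefer the NM tag and fall back to MD
  reconstruction; records with neither are rejected and counted.
- The k-mer disjointness rejection sampler retries up to 100 times per
  library and logs when it has to retry.

## Known limitations

- The internal matcher is a full scan — exact and fast enough for
  libraries up to ~10⁵–10⁶ bases, but not a replacement for an indexed
  aligner on real genomes; real-data runs ingest external SAM instead.
- Homology searching, precursor discovery, secondary-structure prediction,
  and the five target-prediction tools are deliberately out of scope:
  their outputs are inputs here.
- Empirical p-values are bounded below by 1/R; claims beyond that
  resolution require more replicates, not extrapolation.
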