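"""End-to-end orchestration: config validation, staged runs, manifest.

``run`` executes the stages against a YAML config; ``demo_config`` builds an
all-synthetic configuration so the whole pipeline exercises itself with no
external data.  Every stochastic stage derives its seed from the single run
seed, every output lands inside the run directory, and the manifest records
a sha256 checksum per output so reruns are verifiable bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cog_enrichment as cog
from . import mirna_detection as det
from . import precursor_annotation as ann
from . import precursor_profiling as prof
from . import smallrna_io as sio
from . import source_attribution as attr
from . import synthetic_data as syn
from . import target_intersection as tgt

logger = logging.getLogger(__name__)

STAGES = ("simulate", "trim", "attribute", "annotate", "detect", "profile",
          "targets", "enrich")

DEFAULTS = {
    "seed": 0,
    "stages": list(STAGES),
    "k_max": 1,
    "attribution_mode": "cascade",
    "length_window": [17, 35],
    "min_phred": 28,
    "adapter": "TGGAATTCTCGGGTGCCAAGG",
    "duplicate_overlap": 0.5,
    "seed_region": [2, 8],
    "tools": ["miRanda", "PITA", "RNAhybrid"],
    "n_replicates": 20_000,
    "alpha": 0.05,
    "simulate": {
        "n_samples": 3,
        "reads_per_sample": 800,
        "library_length": 6000,
        "n_loci": 8,
        "n_duplicated_loci": 2,
        "n_known": 5,
        "n_utrs": 300,
        "profile_reads": 2000,
        # stated-world region proportions for the profiling stage
        "region_split": {"mature": 0.857, "star": 0.057, "loop": 0.018,
                         "fragment": 0.068},
    },
}


class ConfigError(ValueError):
    pass


def load_config(source):
    """Merge a YAML config (path, mapping or None) over the defaults."""
    if source is None:
        cfg = {}
    elif isinstance(source, dict):
        cfg = dict(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh) or {}
    merged = json.loads(json.dumps(DEFAULTS))  # deep copy
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def validate_config(cfg):
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    lo, hi = cfg["length_window"]
    if not (1 <= lo <= hi):
        raise ConfigError(f"bad length window {cfg['length_window']}")
    if cfg["attribution_mode"] not in ("cascade", "all"):
        raise ConfigError("attribution_mode must be 'cascade' or 'all'")
    if "simulate" not in cfg["stages"]:
        for key in ("reads_fastq", "libraries_fasta"):
            path = cfg.get(key)
            if path and not Path(path).exists():
                raise ConfigError(f"configured input {key}={path} does not exist")
    return cfg


def demo_config(seed=0, **overrides):
    cfg = load_config(overrides or None)
    cfg["seed"] = seed
    return cfg


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _child_seeds(seed, n):
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31, size=n)]


def run(config, outdir):
    """Execute the configured stages into ``outdir``; returns the manifest.

    The demo (all-synthetic) configuration generates genomes, a truth
    mirnome, reads and annotation universes, then runs trimming, source
    attribution, precursor annotation, plant-miRNA detection, precursor
    profiling, target intersection and COG enrichment, writing one or more
    TSV/FASTA/FASTQ outputs per stage plus ``manifest.json``.
    """
    cfg = validate_config(load_config(config))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    seeds = dict(zip(STAGES, _child_seeds(seed, len(STAGES))))
    header = [f"crossmir {__version__}", f"run seed: {seed}",
              "coordinates in this report are 1-based closed"]
    outputs = {}
    state = {}

    def emit(name, writer):
        path = outdir / name
        writer(path)
        outputs[name] = _sha256(path)

    stages = cfg["stages"]
    if "simulate" in stages:
        _stage_simulate(cfg, seeds["simulate"], state, emit)
    if "trim" in stages:
        _stage_trim(cfg, state, emit, header)
    if "attribute" in stages:
        _require(state, "samples", "attribute", "trim")
        _stage_attribute(cfg, state, emit, header)
    if "annotate" in stages:
        _require(state, "precursors", "annotate", "simulate")
        _stage_annotate(cfg, state, emit, header)
    if "detect" in stages:
        _require(state, "mirnas", "detect", "annotate")
        _stage_detect(cfg, state, emit, header)
    if "profile" in stages:
        _require(state, "collapsed", "profile", "annotate")
        _stage_profile(cfg, seeds["profile"], state, emit, header)
    if "targets" in stages:
        _require(state, "detected_mirnas", "targets", "detect")
        _stage_targets(cfg, seeds["targets"], state, emit, header)
    if "enrich" in stages:
        _require(state, "consensus", "enrich", "targets")
        _stage_enrich(cfg, seeds["enrich"], state, emit, header)

    manifest = {
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "parameters": {k: cfg[k] for k in
                       ("k_max", "attribution_mode", "length_window", "min_phred",
                        "adapter", "duplicate_overlap", "seed_region", "tools",
                        "n_replicates", "alpha")},
        "outputs": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _require(state, key, stage, upstream):
    if key not in state:
        raise ConfigError(f"stage {stage!r} requires output of stage "
                          f"{upstream!r}, which did not run")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg, seed, state, emit):
    sim = cfg["simulate"]
    seeds = _child_seeds(seed, 4 + sim["n_samples"])
    genome_specs = [
        syn.LibrarySpec("aphid", "host_insect", sim["library_length"], 0.35),
        syn.LibrarySpec("buchnera", "obligate_symbiont", sim["library_length"], 0.30),
        syn.LibrarySpec("plant", "host_plant", sim["library_length"], 0.40),
        syn.LibrarySpec("bacteria", "bacterial", sim["library_length"], 0.45),
        syn.LibrarySpec("virus", "viral", max(1000, sim["library_length"] // 4), 0.45),
    ]
    genomes = syn.generate_genome_set(genome_specs, seeds[0])
    emit("libraries.fasta", lambda p: sio.write_fasta(genomes.sequences, p))

    precursors, evidence, truth = syn.make_truth_mirnome(
        sim["n_loci"], sim["n_duplicated_loci"], sim["n_known"], seeds[1])
    state.update(genomes=genomes, precursors=precursors, evidence=evidence,
                 truth_status=truth)
    emit("precursors.fasta",
         lambda p: sio.write_fasta({x.id: x.sequence for x in precursors}, p))

    def write_db(path):
        with open(path, "w") as fh:
            for x in precursors:
                fh.write(f">{x.id}\n{x.sequence}\n{x.dot_bracket}\n")
    emit("precursors.dotbracket.txt", write_db)

    # per-sample read sets: a gut-like mixture over the source libraries
    mix = [("aphid", 0.35), ("buchnera", 0.05), ("plant", 0.40),
           ("bacteria", 0.15), ("virus", 0.05)]
    sources = [(name, genomes.sequences[name], p) for name, p in mix]
    samples, labels = [], {}
    lines = ["G006", "G002", "USDA"]
    for i in range(sim["n_samples"]):
        sid = f"gut_{lines[i % len(lines)]}"
        rs, lab = syn.sample_reads(sources, sim["reads_per_sample"],
                                   seed=seeds[4 + i], sample_id=sid,
                                   tissue="gut", line=lines[i % len(lines)],
                                   id_prefix=f"s{i}_")
        samples.append(rs)
        labels[sid] = lab
        emit(f"reads_{sid}.fastq",
             lambda p, rs=rs: sio.write_fastq(rs.reads, p))
    state.update(samples=samples, truth_labels=labels)

    utrs, expansion, cog_table = syn.make_cog_universe(sim["n_utrs"], seed=seeds[2])
    state.update(utrs=utrs, expansion=expansion, cog_table=cog_table)

    def write_labels(path):
        rows = [{"read_id": l.read_id, "origin": l.origin,
                 "region": l.region or "", "mismatches": l.n_mismatches}
                for labs in labels.values() for l in labs]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    emit("truth_labels.tsv", write_labels)


def _stage_trim(cfg, state, emit, header):
    window = tuple(cfg["length_window"])
    trimmed, rows = [], []
    for rs in state["samples"]:
        out, stats = sio.process_reads(rs, cfg["adapter"], cfg["min_phred"], window)
        trimmed.append(out)
        rows.append({"sample_id": rs.sample_id, **stats.as_dict()})
        emit(f"trimmed_{rs.sample_id}.fastq",
             lambda p, out=out: sio.write_fastq(out.reads, p))
    state["samples"] = trimmed
    emit("trim_stats.tsv",
         lambda p: sio.write_tsv(pd.DataFrame(rows), p, header))


def _stage_attribute(cfg, state, emit, header):
    genomes = state["genomes"]
    libraries = [attr.Library(name, cat, seq)
                 for name, cat, seq in genomes.libraries]
    partitions = []
    for rs in state["samples"]:
        part = attr.partition_reads(rs, libraries, cfg["k_max"],
                                    cfg["attribution_mode"])
        partitions.append(part)
        emit(f"membership_{rs.sample_id}.tsv",
             lambda p, part=part: sio.write_tsv(attr.partition_table(part), p, header))
    state["partitions"] = partitions
    summary = attr.summarize_partitions({"gut": partitions})
    emit("attribution_summary.tsv", lambda p: sio.write_tsv(summary, p, header))


def _stage_annotate(cfg, state, emit, header):
    collapsed, groups = ann.collapse_duplicates(state["precursors"],
                                                cfg["duplicate_overlap"])
    classifications = {p.id: ann.classify_precursor(state["evidence"][p.id])
                       for p in collapsed}
    mirnas = ann.enumerate_mirnas(collapsed)
    for m in mirnas:
        statuses = {classifications[pid].status for pid in m.precursor_ids
                    if pid in classifications}
        m.status = "known" if "known" in statuses else next(iter(statuses), "unset")
    state.update(collapsed=collapsed, duplicate_groups=groups,
                 classifications=classifications, mirna_list=mirnas)
    state["mirnas"] = {f"mir{i + 1:04d}": m for i, m in enumerate(mirnas)}
    emit("precursors_collapsed.tsv",
         lambda p: sio.write_tsv(ann.precursor_table(collapsed, classifications),
                                 p, header))
    emit("mirnas.fasta",
         lambda p: sio.write_fasta(ann.mirna_fasta_records(mirnas), p))


def _stage_detect(cfg, state, emit, header):
    mirna_seqs = {mid: m.sequence for mid, m in state["mirnas"].items()}
    detections = {}
    frames = []
    for rs in state["samples"]:
        d = det.detect_mirnas(mirna_seqs, rs)
        detections[rs.sample_id] = d
        frames.append(d)
    table = pd.concat(frames, ignore_index=True)
    emit("detections.tsv", lambda p: sio.write_tsv(table, p, header))
    shared = det.intersect_across_samples(detections)
    detected_any = sorted(set().union(*(det.detected_set(d)
                                        for d in detections.values())))
    state.update(detections=detections, shared_mirnas=shared,
                 detected_mirnas=detected_any)
    union, per_mirna, _ = det.map_to_precursors(state["mirnas"], detected_any)
    rows = [{"mirna_id": mid, "precursors": ",".join(per_mirna[mid])}
            for mid in sorted(per_mirna)]
    rows.append({"mirna_id": "ALL_SHARED",
                 "precursors": ",".join(sorted(shared))})
    emit("detection_intersection.tsv",
         lambda p: sio.write_tsv(pd.DataFrame(rows), p, header))


def _stage_profile(cfg, seed, state, emit, header):
    sim = cfg["simulate"]
    split = dict(sim["region_split"])
    collapsed = state["collapsed"]
    seeds = _child_seeds(seed, len(collapsed))
    per = max(1, sim["profile_reads"] // len(collapsed))
    assignments = []
    for child, prec in zip(seeds, collapsed):
        rs, _ = syn.sample_precursor_reads(_as_truth(prec), split, per, seed=child)
        assignments.extend(prof.profile_reads(rs, [prec]))
    state["profile_assignments"] = assignments
    rows = [{"read_id": a.read_id, "precursor_id": a.precursor_id,
             "start": a.start + 1, "end": a.end, "label": a.label}
            for a in assignments]
    emit("profile_assignments.tsv",
         lambda p: sio.write_tsv(pd.DataFrame(rows), p, header))
    emit("profile_summary.tsv",
         lambda p: sio.write_tsv(prof.summarize_profile(assignments), p, header))


def _as_truth(prec):
    """View a MiRNAPrecursor as the region-labelled object the precursor-read
    sampler expects (mature/star + flanks + loop)."""
    rmap = prof.RegionMap.from_precursor(prec)
    regions = {}
    arm_labels = {}
    for label, a, b in rmap.intervals:
        if label in ("mature", "star"):
            key = "first_arm" if not arm_labels else "second_arm"
            arm_labels[key] = label
            regions[key] = (a, b)
        else:
            regions[label] = (a, b)
    mature_arm = "first" if arm_labels.get("first_arm") == "mature" else "second"
    return syn.TruthPrecursor(prec.id, prec.sequence, regions, mature_arm,
                              prec.dot_bracket or "." * len(prec.sequence))


def _stage_targets(cfg, seed, state, emit, header):
    tools = list(cfg["tools"])
    mirnas = state["mirnas"]
    detected = state["detected_mirnas"] or list(mirnas)
    mirna_lengths = {mid: len(mirnas[mid].sequence) for mid in detected}
    utr_ids = state["utrs"][:60]
    n = len(mirna_lengths) * len(utr_ids)
    rows, truth = syn.make_tool_tables(
        mirna_lengths, utr_ids, tools,
        n_consensus=min(25, n // 3), n_partial=min(25, n // 3),
        n_nonoverlap=min(10, n // 3), seed=seed)
    preds = [tgt.TargetPrediction(**r) for r in rows]
    state["target_truth"] = truth
    seed_region = tuple(cfg["seed_region"])
    consensus = tgt.intersect_predictions(preds, tools, mirna_lengths, seed_region)
    state["consensus"] = consensus
    counts = tgt.venn_counts(preds, tools)
    isoforms, per_utr = tgt.expand_utrs(consensus, state["expansion"])
    state["target_isoforms"] = isoforms
    hdr = header + [f"seed region: miRNA positions {seed_region[0]}-{seed_region[1]}"]
    emit("targets_consensus.tsv",
         lambda p: sio.write_tsv(tgt.consensus_table(consensus, seed_region), p, hdr))
    emit("targets_venn.tsv",
         lambda p: sio.write_tsv(tgt.venn_table(counts, tools), p, hdr))
    iso_rows = [{"utr_id": u, "isoforms": ",".join(per_utr[u])} for u in sorted(per_utr)]
    emit("targets_isoforms.tsv",
         lambda p: sio.write_tsv(pd.DataFrame(iso_rows), p, hdr))


def _stage_enrich(cfg, seed, state, emit, header):
    utrs, expansion, cog_table = (state["utrs"], state["expansion"],
                                  state["cog_table"])
    target_utrs = sorted({c.target_id for c in state["consensus"]})
    observed, unannotated = cog.observed_cog_counts(target_utrs, expansion, cog_table)
    n_draws = max(1, len(target_utrs))
    nulls = cog.monte_carlo_null(utrs, expansion, cog_table, n_draws,
                                 cfg["n_replicates"], seed)
    reference = cog.reference_composition(utrs, expansion, cog_table)
    report = cog.enrichment_report(observed, nulls, reference, cfg["alpha"])
    state["enrichment"] = report
    hdr = header + [f"null: {cfg['n_replicates']} replicates of {n_draws} UTR "
                    f"draws with replacement, isoform-expanded",
                    f"unannotated target proteins: {unannotated}"]
    emit("enrichment.tsv", lambda p: sio.write_tsv(report, p, hdr))
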