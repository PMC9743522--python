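"""End-to-end orchestration: simulate → balance → compartments → virtual-4C →
SV consensus → report, driven by one YAML config with a single seed.

Every run writes its outputs under one directory, stamped with a hash
of the canonicalized config and the seed; rerunning the same config and
seed reproduces every output byte-for-byte.  A stage failure aborts the
downstream stages and leaves a report marked invalid.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import yaml

from . import compartments as comp
from . import contact, simulate, sv_consensus, virtual4c
from .genome import GenomicInterval, SVEvent, build_derived_genome

logger = logging.getLogger("fusion4c")

DEFAULT_THRESHOLDS = {
    "tolerance": 1000,
    "min_size": 10_000,
    "min_callers": 2,
    "z_threshold": 4.0,
    "exclusion_flank": 1_000_000,
}

DEFAULT_RESOLUTIONS = {"fine": 10_000, "coarse": 50_000, "report": 500_000}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    raw: dict
    seed: int
    outdir: str
    resolutions: dict
    thresholds: dict
    anchors: virtual4c.AnchorSet
    simulate: dict | None
    genes: list | None
    fusion_callsets: dict | None = None

    @property
    def coarse_factor(self) -> int:
        return self.resolutions["coarse"] // self.resolutions["fine"]

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(source, outdir=None, seed=None) -> RunConfig:
    """Load and validate a YAML config (path or dict)."""
    base_dir = "."
    if isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
        base_dir = os.path.dirname(os.path.abspath(source))

    def _resolve(path):
        return path if os.path.isabs(path) else os.path.join(base_dir, path)
    resolutions = {**DEFAULT_RESOLUTIONS, **raw.get("resolutions", {})}
    if resolutions["coarse"] % resolutions["fine"]:
        raise ValueError(
            f"coarse resolution {resolutions['coarse']} is not divisible by "
            f"fine resolution {resolutions['fine']}"
        )
    if resolutions["report"] % resolutions["coarse"]:
        raise ValueError("report resolution must be divisible by coarse")
    thresholds = {**DEFAULT_THRESHOLDS, **raw.get("thresholds", {})}
    anchors = virtual4c.AnchorSet.from_dict(raw["anchors"])
    genes = None
    if raw.get("genes"):
        genes = sv_consensus.read_gene_bed(_resolve(raw["genes"]))
    fusion_callsets = None
    fus = raw.get("fusions")
    if fus and "callsets" in fus:
        fusion_callsets = {c: _resolve(p) for c, p in fus["callsets"].items()}
    return RunConfig(
        raw=raw,
        fusion_callsets=fusion_callsets,
        seed=int(seed if seed is not None else raw.get("seed", 0)),
        outdir=str(outdir or raw.get("outdir", "fusion4c_run")),
        resolutions=resolutions,
        thresholds=thresholds,
        anchors=anchors,
        simulate=raw.get("simulate"),
        genes=genes,
    )


def _parse_event(spec: dict) -> SVEvent:
    kind = spec["type"]
    if kind in ("tandem_duplication", "deletion"):
        ivs = (GenomicInterval(spec["chrom"], spec["start"], spec["end"]),)
    else:
        ivs = (
            GenomicInterval(
                spec["target"]["chrom"], spec["target"]["start"], spec["target"]["end"]
            ),
            GenomicInterval(
                spec["source"]["chrom"], spec["source"]["start"], spec["source"]["end"]
            ),
        )
    return SVEvent(kind, ivs, spec.get("orientation", "forward"), spec.get("name", ""))


def _simulate_cohort(cfg: RunConfig, outdir: str):
    """Generate the cohort's matrices, call sets and ground truth."""
    sim = cfg.simulate
    reference = [(str(c), int(s)) for c, s in sim["reference"]]
    fine = cfg.resolutions["fine"]
    n_samples = int(sim.get("n_samples", 6))
    rng = np.random.default_rng(cfg.seed)

    labels = None
    comp_cfg = sim.get("compartments")
    n_ref_bins = sum(-(-s // fine) for _, s in reference)
    if comp_cfg:
        labels = simulate.checkerboard_labels(
            n_ref_bins, block=int(comp_cfg.get("block", 10))
        )
    fusion_cfg = sim.get("fusion") or {}
    fusion_idx = int(fusion_cfg.get("sample_index", 0)) if fusion_cfg else None
    event = _parse_event(fusion_cfg["event"]) if fusion_cfg else None

    matrices, truths, names = [], [], []
    os.makedirs(os.path.join(outdir, "matrices"), exist_ok=True)
    for s in range(n_samples):
        name = f"sample{s + 1}"
        events = [event] if (event is not None and s == fusion_idx) else []
        scfg = simulate.SimulationConfig(
            bin_size=fine,
            decay_exponent=float(sim.get("decay_exponent", 1.0)),
            trans_rate=float(sim.get("trans_rate", 0.01)),
            depth=float(sim.get("depth", 1_000_000)),
            compartment_labels=labels,
            boost=float(comp_cfg.get("boost", 1.5)) if comp_cfg else 1.0,
            seed=int(rng.integers(2**31)),
        )
        matrix, truth = simulate.simulate_sample(reference, events, scfg, sample=name)
        contact.write_matrix(matrix, os.path.join(outdir, "matrices", f"{name}.coo"))
        matrices.append(matrix)
        truths.append(truth)
        names.append(name)
        logger.info("simulated %s (%d contacts)", name, int(matrix.total()))

    if event is not None:
        simulate.write_truth_bedpe([event], os.path.join(outdir, "truth.bedpe"))
    if labels is not None:
        bins = contact.BinTable(reference, fine)
        simulate.write_labels_bedgraph(
            bins, labels, os.path.join(outdir, "truth_compartments.bedGraph")
        )

    callsets = {}
    caller_cfg = sim.get("callers")
    if caller_cfg and event is not None:
        callsets[names[fusion_idx]] = simulate.simulate_callsets(
            [event],
            n_callers=int(caller_cfg.get("n", 4)),
            jitter_sd=float(caller_cfg.get("jitter_sd", 300)),
            dropout=float(caller_cfg.get("dropout", 0.0)),
            fp_per_caller=int(caller_cfg.get("fp_per_caller", 0)),
            seed=int(rng.integers(2**31)),
            reference=reference,
            sample=names[fusion_idx],
        )
    return reference, labels, names, matrices, truths, callsets, event, fusion_idx


def run_pipeline(source, outdir=None, seed=None) -> dict:
    """Run every stage and return (and write) the structured report."""
    cfg = load_config(source, outdir=outdir, seed=seed)
    os.makedirs(cfg.outdir, exist_ok=True)
    report: dict = {
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "status": "invalid",
        "stages": [],
    }
    report_path = os.path.join(cfg.outdir, "report.json")
    try:
        _run_stages(cfg, report)
        report["status"] = "ok"
    finally:
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report


def _run_stages(cfg: RunConfig, report: dict) -> None:
    if cfg.simulate is None:
        raise ValueError("config has no 'simulate' block; file-driven runs "
                         "use the per-stage CLI commands")
    (reference, labels, names, matrices, truths, callsets, event, fusion_idx
     ) = _simulate_cohort(cfg, cfg.outdir)
    report["stages"].append("simulate")
    report["samples"] = names
    fine = cfg.resolutions["fine"]

    # --- balancing
    for name, m in zip(names, matrices):
        res = contact.balance(m)
        contact.write_bedgraph(
            m.bins, res.weights, os.path.join(cfg.outdir, "matrices", f"{name}.weights.bedGraph")
        )
        logger.info("balanced %s in %d iterations (rel var %.2e)",
                    name, res.n_iter, res.rel_var)
    report["stages"].append("balance")

    # --- compartments (on the anchor chromosome, oriented by planted A-density)
    chrom = cfg.anchors.chrom
    comp_dir = os.path.join(cfg.outdir, "compartments")
    os.makedirs(comp_dir, exist_ok=True)
    tracks = []
    if labels is not None:
        fine_bins = matrices[0].bins
        sl = fine_bins.chrom_slice(chrom)
        a_fine = (np.asarray(labels)[sl] == "A").astype(float)
        # A-density per coarse bin orients the eigenvector sign
        coarse_size = cfg.resolutions["coarse"]
        pos = fine_bins.start[sl] // coarse_size
        n_coarse = int(pos.max()) + 1
        orientation = np.bincount(pos, weights=a_fine, minlength=n_coarse) / \
            np.bincount(pos, minlength=n_coarse)
        chrom_bins = contact.BinTable(
            [(chrom, dict(fine_bins.chromsizes)[chrom])], coarse_size
        )
        for name, m in zip(names, matrices):
            cm = contact.coarsen_anchored(m, cfg.coarse_factor)
            contact.balance(cm)
            track = comp.compartment_score(cm, chrom, orientation, sample=name)
            contact.write_bedgraph(
                chrom_bins, track.score, os.path.join(comp_dir, f"{name}.bedGraph")
            )
            tracks.append(track)
        sim = comp.compare_tracks(tracks)
        np.savetxt(
            os.path.join(comp_dir, "similarity.tsv"),
            sim.correlation, delimiter="\t", fmt="%.8g",
            header="\t".join(sim.samples), comments="",
        )
        with open(os.path.join(comp_dir, "linkage.nwk"), "w") as fh:
            fh.write(sim.to_newick() + "\n")
        report["compartments"] = {
            "chrom": chrom,
            "tracks": {t.sample: f"compartments/{t.sample}.bedGraph" for t in tracks},
            "mean_correlation": round(float(np.nanmean(
                sim.correlation[np.triu_indices(len(names), k=1)])), 6),
        }
    report["stages"].append("compartments")

    # --- virtual 4C
    v4c_dir = os.path.join(cfg.outdir, "virtual4c")
    os.makedirs(v4c_dir, exist_ok=True)
    profiles = []
    for name, m in zip(names, matrices):
        p = virtual4c.extract_profile(
            m, cfg.anchors, coarse_factor=cfg.coarse_factor, sample=name
        )
        p.write_tsv(os.path.join(v4c_dir, f"{name}.profile.tsv"))
        profiles.append(p)
    peaks = virtual4c.detect_partner_peaks(
        profiles,
        terminal="c",
        exclusion_flank=int(cfg.thresholds["exclusion_flank"]),
        z_threshold=float(cfg.thresholds["z_threshold"]),
    )
    with open(os.path.join(v4c_dir, "candidate_loci.bed"), "w") as fh:
        for name in names:
            for locus in peaks[name]:
                iv = locus.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t"
                    f"{locus.peak_z:.4g}\n"
                )
    candidates = {name: [
        {"chrom": l.interval.chrom, "start": l.interval.start,
         "end": l.interval.end, "peak_z": round(l.peak_z, 4)}
        for l in peaks[name]
    ] for name in names}
    called = sorted(n for n in names if candidates[n])
    report["virtual4c"] = {
        "candidate_loci": candidates,
        "samples_with_candidates": called,
    }
    if event is not None and fusion_idx is not None:
        fusion_name = names[fusion_idx]
        partner_chrom, partner_pos = event.breakpoint_pair()[1] \
            if event.event_type != "tandem_duplication" else event.breakpoint_pair()[0]
        hit = any(
            l["chrom"] == partner_chrom and l["start"] <= partner_pos < l["end"]
            for l in candidates.get(fusion_name, [])
        )
        report["virtual4c"]["fusion_sample"] = fusion_name
        report["virtual4c"]["partner_breakpoint"] = [partner_chrom, partner_pos]
        report["virtual4c"]["partner_locus_recovered"] = bool(hit)
    report["stages"].append("virtual4c")

    # --- SV consensus (simulated call sets, matched-normal empty)
    sv_dir = os.path.join(cfg.outdir, "sv")
    os.makedirs(sv_dir, exist_ok=True)
    sv_report = {}
    for name, sets in callsets.items():
        groups = sv_consensus.match_calls(sets, tolerance=int(cfg.thresholds["tolerance"]))
        kept = sv_consensus.filter_consensus(
            groups,
            min_size=int(cfg.thresholds["min_size"]),
            min_callers=int(cfg.thresholds["min_callers"]),
        )
        kept = sv_consensus.subtract_normal(kept, [], tolerance=int(cfg.thresholds["tolerance"]))
        sv_consensus.write_bedpe(kept, os.path.join(sv_dir, f"{name}.consensus.bedpe"))
        entry = []
        for g in kept:
            rec = {
                "chrom1": g.representative.chrom1, "pos1": g.representative.pos1,
                "chrom2": g.representative.chrom2, "pos2": g.representative.pos2,
                "sv_type": g.representative.sv_type,
                "callers": list(g.callers), "somatic": g.somatic,
            }
            if cfg.genes:
                ann = sv_consensus.annotate_breakpoints(g, cfg.genes)
                rec["gene5"], rec["gene3"] = ann.gene5, ann.gene3
            entry.append(rec)
        sv_report[name] = entry
    report["sv_consensus"] = sv_report
    report["stages"].append("sv_consensus")

    # --- RNA fusion aggregation (file-driven call sets, union by gene pair)
    if cfg.fusion_callsets:
        priority = cfg.raw.get("fusions", {}).get("priority_genes")
        fusions, skipped = sv_consensus.aggregate_fusions(
            cfg.fusion_callsets,
            priority_genes=set(priority) if priority else None,
        )
        report["fusions"] = {
            "calls": [
                {
                    "gene5": fc.gene5, "gene3": fc.gene3,
                    "n_callers": fc.n_callers,
                    "callers": sorted(set(fc.callers)),
                }
                for fc in fusions
            ],
            "malformed_rows_skipped": skipped,
        }
        report["stages"].append("fusions")


def main_report_summary(report: dict) -> str:
    """One-paragraph human summary of a run report."""
    lines = [f"run {report['config_hash']} seed {report['seed']}: {report['status']}"]
    v4c = report.get("virtual4c", {})
    if "fusion_sample" in v4c:
        lines.append(
            f"fusion sample {v4c['fusion_sample']} "
            f"{'recovered' if v4c['partner_locus_recovered'] else 'NOT recovered'} "
            f"at partner breakpoint {v4c['partner_breakpoint']}"
        )
    if v4c.get("samples_with_candidates") is not None:
        lines.append(
            "samples with exclusive loci: "
            + (", ".join(v4c["samples_with_candidates"]) or "none")
        )
    return "\n".join(lines)
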