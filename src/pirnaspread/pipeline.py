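"""End-to-end orchestration: simulate -> place reads -> profile -> cluster
-> scan targets -> test, from a single validated config, with deterministic
file outputs and a markdown report.
"""

from __future__ import annotations

import hashlib
import json
from collections import defaultdict
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import clustering, plotting, profiles, simulate, stats, targets
from .reads import (ANTISENSE, SENSE, AlignmentHit, ReadSet, align_exact,
                    filter_hits, normalization_factors)
from .reference import TranscriptModel
from .simulate import SimConfig


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, echoed verbatim into output manifests."""

    analysis: str = "sensor"            # sensor | panel
    genotypes: tuple[str, ...] = ("wild_type", "hrde-1", "nrde-4", "prg-1",
                                  "mut-16")
    seed: int = 1
    depth: int = 100_000
    panel_depth: int = 300_000
    normalization: str = "per_his58"
    proximal_window: int = 200
    n_bins: int = 10
    k_min: int = 2
    k_max: int = 8
    max_mm: int = 3
    spreading_threshold: float = 0.5
    pseudocount: float = 1.0
    min_reads: float = 1.0
    with_ip: bool = True
    ip_fold: float = 10.0
    n_genes: int = 300
    fraction_cluster6_like: float = 0.5
    fraction_cluster1_like: float = 0.2

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        if "genotypes" in d:
            d["genotypes"] = tuple(d["genotypes"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def sim_config(self, seed_offset: int = 0,
                   panel: bool = False) -> SimConfig:
        return SimConfig(
            seed=self.seed + seed_offset,
            depth=self.panel_depth if panel else self.depth,
            proximal_window=self.proximal_window, ip_fold=self.ip_fold,
            n_genes=self.n_genes,
            fraction_cluster6_like=self.fraction_cluster6_like,
            fraction_cluster1_like=self.fraction_cluster1_like)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    return obj


def group_hits(hits: Sequence[AlignmentHit]) -> dict[str, list[AlignmentHit]]:
    by_tid: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_tid[h.transcript_id].append(h)
    return by_tid


# ---------------------------------------------------------------------------
# Sensor analysis

@dataclass
class SensorBundle:
    config: PipelineConfig
    profiles: dict[str, profiles.PositionalProfile]
    summaries: dict[str, profiles.RegionSummary]
    raw_totals: dict[str, float]
    ip_folds: dict[str, float] | None
    logs: dict[str, dict]
    construct_id: str
    site_interval: tuple[int, int]


def run_sensor_analysis(config: PipelineConfig,
                        outdir: str | Path | None = None) -> SensorBundle:
    """Per-genotype normalized sensor profiles and proximal/distal summaries.

    Each genotype gets its own simulated library (seeds offset from the
    base seed), exact antisense placement, unique/antisense/22G filtering,
    normalization and a proximal/distal split around the target-site
    segment; optionally an IP/control pair from the wild-type library.
    """
    construct = simulate.make_sensor_construct()
    refs = simulate.sensor_reference_set(construct)
    transcript = refs[0]
    site = construct.target_site_interval
    his58 = construct.segment_interval("his-58")

    out_profiles: dict[str, profiles.PositionalProfile] = {}
    summaries: dict[str, profiles.RegionSummary] = {}
    raw_totals: dict[str, float] = {}
    logs: dict[str, dict] = {}

    for i, gname in enumerate(config.genotypes):
        readset, truth = simulate.simulate_sensor_scenario(
            config.sim_config(seed_offset=1000 * i), gname, construct)
        hits = align_exact(readset, refs)
        flog: dict = {}
        kept = filter_hits(hits, log=flog)
        norm = normalization_factors(
            hits, library_total=len(readset),
            normalizer=(transcript.id, his58), mode=config.normalization)
        prof = profiles.positional_profile(kept, transcript, norm)
        raw = profiles.positional_profile(kept, transcript, None)
        out_profiles[gname] = prof
        raw_totals[gname] = raw.total
        summaries[gname] = profiles.proximal_distal(
            prof, site, window=config.proximal_window)
        flog["his58_total"] = norm.his58_total
        flog["library_total"] = norm.library_total
        logs[gname] = flog

    ip_folds = None
    if config.with_ip:
        base_cfg = config.sim_config(seed_offset=0)
        base, _ = simulate.simulate_sensor_scenario(base_cfg, "wild_type",
                                                    construct)
        _, ip_set = simulate.simulate_ip_pair(base_cfg, base, control=False)
        _, ctrl_set = simulate.simulate_ip_pair(base_cfg, base, control=True)
        ip_folds = {}
        pm_profiles = []
        for rs in (ip_set, ctrl_set):
            hits = align_exact(rs, refs)
            kept = filter_hits(hits)
            norm = normalization_factors(hits, library_total=len(rs),
                                         mode="per_million")
            pm_profiles.append(
                profiles.positional_profile(kept, transcript, norm))
        # measure fold outside the normalizer segment, where the enriched
        # antisense population is not diluted by normalizer reads
        regions = {
            "upstream_of_normalizer": (0, his58[0]),
            "site_and_downstream": (his58[1], transcript.spliced_length),
        }
        folds = profiles.ip_enrichment(pm_profiles[0], pm_profiles[1],
                                       pseudocount=config.pseudocount,
                                       regions=regions)
        ip_folds.update(folds)
        # single summary value over both regions combined
        mask_sum = lambda p: sum(
            float(p.values[s:e].sum()) for s, e in regions.values())
        ip_folds["combined"] = ((mask_sum(pm_profiles[0]) + config.pseudocount)
                                / (mask_sum(pm_profiles[1]) + config.pseudocount))

    bundle = SensorBundle(config, out_profiles, summaries, raw_totals,
                          ip_folds, logs, construct.id, site)
    if outdir is not None:
        _write_sensor_outputs(bundle, Path(outdir))
    return bundle


def _write_sensor_outputs(bundle: SensorBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for gname, prof in bundle.profiles.items():
        safe = gname.replace(";", "_")
        p1 = outdir / f"profile_{safe}.tsv"
        profiles.write_profile_tsv(prof, p1)
        p2 = outdir / f"profile_{safe}.bedgraph"
        profiles.write_bedgraph(prof, p2)
        files += [p1, p2]
    summary = outdir / "proximal_distal.tsv"
    with open(summary, "w") as fh:
        fh.write("genotype\tproximal\tdistal\ttotal\traw_total"
                 "\tdistal_proximal_ratio\n")
        for gname, s in bundle.summaries.items():
            ratio = s.distal / s.proximal if s.proximal else float("nan")
            fh.write(f"{gname}\t{s.proximal:.6g}\t{s.distal:.6g}"
                     f"\t{s.total:.6g}\t{bundle.raw_totals[gname]:.6g}"
                     f"\t{ratio:.6g}\n")
    files.append(summary)
    if bundle.ip_folds is not None:
        p = outdir / "ip_enrichment.json"
        p.write_text(json.dumps(_jsonable(bundle.ip_folds), indent=2,
                                sort_keys=True))
        files.append(p)
        plotting.plot_ip_folds(bundle.ip_folds, outdir / "ip_enrichment.png")
    construct = simulate.make_sensor_construct()
    plotting.plot_profiles(bundle.profiles, construct,
                           outdir / "profiles.png")
    _write_manifest(outdir, files, bundle.config, bundle.logs)


# ---------------------------------------------------------------------------
# Genome-panel analysis

@dataclass
class PanelBundle:
    config: PipelineConfig
    bin_matrices: dict[str, pd.DataFrame]       # raw counts, gene x bins
    library_sizes: dict[str, int]
    k_chosen: int
    k_report: pd.DataFrame
    cluster_result: clustering.ClusterResult
    curves: list[clustering.RatioCurve]
    calls: list[clustering.SpreadingCall]
    predictions: list[targets.TargetSitePrediction]
    enrichments: dict[int, dict]
    level_changes: dict[int, targets.LevelChangeResult]
    truth: simulate.TruthTable
    summary: dict


def bin_matrix_for_readset(readset: ReadSet, refs: Sequence[TranscriptModel],
                           n_bins: int = 10) -> pd.DataFrame:
    """Raw antisense-22G 10-bin count matrix (every reference gene a row)."""
    hits = filter_hits(align_exact(readset, refs))
    by_tid = group_hits(hits)
    rows = {}
    for t in refs:
        prof = profiles.positional_profile(by_tid.get(t.id, []), t, None)
        rows[t.id] = profiles.bin_profile(prof, n_bins).bins
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"bin_{i + 1}" for i in range(n_bins)])
    df.index.name = "gene"
    return df


def run_genome_analysis(config: PipelineConfig,
                        outdir: str | Path | None = None,
                        mutant: str = "nrde-4",
                        wildtype: str = "wild_type",
                        loss_condition: str = "prg-1") -> PanelBundle:
    """Cluster genes by mutant 22G shape and characterize each cluster.

    The clustering condition is the nuclear-RNAi mutant (its bin shapes
    separate sites-proximal from spread patterns); ratio curves compare it
    to wild type; per-gene level changes compare the piRNA-pathway-null
    condition to wild type; each cluster is tested for 3'-half target-site
    bias against the remaining clustered genes.
    """
    panel = simulate.simulate_genome_panel(
        config.sim_config(panel=True),
        genotypes=(wildtype, mutant, loss_condition))
    refs = panel.references

    bin_matrices = {g: bin_matrix_for_readset(rs, refs, config.n_bins)
                    for g, rs in panel.readsets.items()}
    library_sizes = {g: len(rs) for g, rs in panel.readsets.items()}
    if len(bin_matrices) < 2:
        raise ValueError("panel needs read sets for at least two conditions")

    # genes with 22G signal in the clustering condition, shape-normalized
    clustered = clustering.filter_targeted(bin_matrices[mutant],
                                           min_reads=config.min_reads)
    shapes = clustering.to_proportions(clustered)
    k_chosen, k_report, results = clustering.select_k(
        shapes, k_range=range(config.k_min, config.k_max + 1),
        seed=config.seed)
    result = results[k_chosen]

    curves = clustering.ratio_curves(
        result, bin_matrices[mutant], bin_matrices[wildtype],
        (library_sizes[mutant], library_sizes[wildtype]),
        pseudocount=config.pseudocount)
    calls = clustering.call_spreading(curves,
                                      threshold=config.spreading_threshold)

    predictions = targets.predict_sites(panel.pirnas, refs,
                                        max_mm=config.max_mm)

    clustered_genes = set(result.assignments)
    enrichments: dict[int, dict] = {}
    level_changes: dict[int, targets.LevelChangeResult] = {}
    loss_totals = bin_matrices[loss_condition].sum(axis=1)
    wt_totals = bin_matrices[wildtype].sum(axis=1)
    for cid in sorted({c for c in result.assignments.values()}):
        members = result.genes_in(cid)
        background = sorted(clustered_genes - set(members))
        enr3 = targets.half_enrichment(predictions, members, background,
                                       cluster_id=cid,
                                       alternative=stats.GREATER)
        enr5 = targets.half_enrichment(predictions, members, background,
                                       cluster_id=cid,
                                       alternative=stats.LESS)
        enrichments[cid] = {
            "table": [enr3.a, enr3.b, enr3.c, enr3.d],
            "log2_enrichment": enr3.log2_enrichment,
            "p_3prime_bias": enr3.p,
            "p_5prime_bias": enr5.p,
            "p_binomial": enr3.p_binomial,
        }
        level_changes[cid] = targets.per_gene_level_change(
            {g: float(loss_totals[g]) for g in members},
            {g: float(wt_totals[g]) for g in members},
            (library_sizes[loss_condition], library_sizes[wildtype]),
            pseudocount=config.pseudocount)

    summary = {
        "k_chosen": k_chosen,
        "n_genes_clustered": len(clustered_genes),
        "clusters": {
            str(call.cluster_id): {
                "n_genes": next(c.n_genes for c in curves
                                if c.cluster_id == call.cluster_id),
                "spreading_index": call.index,
                "spreading_label": call.label,
                "ratio_curve": list(next(c.values for c in curves
                                         if c.cluster_id == call.cluster_id)),
                "half_enrichment": enrichments[call.cluster_id],
                "level_change_median_log2": level_changes[
                    call.cluster_id].median_log2_ratio,
                "level_change_p": level_changes[call.cluster_id].wilcoxon.p,
            } for call in calls
        },
    }

    bundle = PanelBundle(config, bin_matrices, library_sizes, k_chosen,
                         k_report, result, curves, calls, predictions,
                         enrichments, level_changes, panel.truth, summary)
    if outdir is not None:
        _write_panel_outputs(bundle, Path(outdir))
    return bundle


def _write_panel_outputs(bundle: PanelBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for gname, mat in bundle.bin_matrices.items():
        p = outdir / f"bins_{gname.replace(';', '_')}.tsv"
        mat.to_csv(p, sep="\t")
        files.append(p)
    assign = outdir / "cluster_assignments.tsv"
    with open(assign, "w") as fh:
        fh.write("gene\tcluster\n")
        for g in sorted(bundle.cluster_result.assignments):
            fh.write(f"{g}\t{bundle.cluster_result.assignments[g]}\n")
    files.append(assign)
    curves = outdir / "ratio_curves.tsv"
    with open(curves, "w") as fh:
        fh.write("cluster\tn_genes\t" + "\t".join(
            f"bin_{i + 1}" for i in range(bundle.config.n_bins)) + "\n")
        for c in bundle.curves:
            fh.write(f"{c.cluster_id}\t{c.n_genes}\t"
                     + "\t".join(f"{v:.6g}" for v in c.values) + "\n")
    files.append(curves)
    pred = outdir / "target_predictions.tsv"
    targets.write_predictions_tsv(bundle.predictions, pred)
    files.append(pred)
    summ = outdir / "panel_summary.json"
    summ.write_text(json.dumps(_jsonable(bundle.summary), indent=2,
                               sort_keys=True))
    files.append(summ)
    plotting.plot_ratio_curves(bundle.curves, outdir / "ratio_curves.png")
    _write_manifest(outdir, files, bundle.config,
                    {"k_report": bundle.k_report.to_dict(orient="records")})


def _write_manifest(outdir: Path, files: list[Path], config: PipelineConfig,
                    logs: dict) -> None:
    manifest = {
        "config": _jsonable(asdict(config)),
        "logs": _jsonable(logs),
        "files": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest()
            for f in sorted(files, key=lambda p: p.name)
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Exon/intron demonstration (spliced endogenous-like gene)

def exon_intron_demo(config: PipelineConfig) -> pd.DataFrame:
    """Simulate a spliced endogenous-like target and partition reads by feature.

    The simulator emits reads from the spliced transcript only, so after
    mapping read 5' ends back to genomic coordinates every intron count is
    zero; the function returns the per-feature table.
    """
    rng = np.random.default_rng(config.seed)
    exon_seqs = [simulate._random_seq(rng, n) for n in (400, 500, 400)]
    intron_seqs = [simulate._random_seq(rng, n) for n in (150, 200)]
    genomic = (exon_seqs[0] + intron_seqs[0] + exon_seqs[1]
               + intron_seqs[1] + exon_seqs[2])
    exons = [(0, 400), (550, 1050), (1250, 1650)]
    t = TranscriptModel(id="endogenous_target", strand="+", exons=exons,
                        sequence="".join(exon_seqs), genomic_sequence=genomic)

    cfg = config.sim_config()
    records: list = []
    rows: list = []
    n = int(rng.poisson(cfg.lambda_distal * t.spliced_length * cfg.depth))
    simulate._emit_antisense(rng, t.sequence, [(0, t.spliced_length)],
                             max(n, 50), cfg, t.id, "distal", "endo",
                             records, rows)
    readset = ReadSet(records, provenance=simulate._provenance(rows))
    hits = filter_hits(align_exact(readset, [t]))
    genomic_hits = []
    for h in hits:
        g5 = t.spliced_to_genomic(h.five_prime_position)
        genomic_hits.append(AlignmentHit(
            read_id=h.read_id, transcript_id=t.id, start=g5, end=g5 + 1,
            orientation=SENSE, n_loci=1, read_first_nt=h.read_first_nt))
    return profiles.exon_intron_counts(genomic_hits, t,
                                       library_total=len(readset))


# ---------------------------------------------------------------------------
# Report

def make_report(sensor: SensorBundle | None = None,
                panel: PanelBundle | None = None,
                exon_intron: pd.DataFrame | None = None,
                path: str | Path | None = None) -> str:
    """Render a markdown report with one section per analysis stage."""
    if sensor is None and panel is None and exon_intron is None:
        raise ValueError("empty bundle: nothing to report")
    lines = ["# Small-RNA spreading analysis report", ""]

    def section(title: str) -> None:
        lines.extend([f"## {title}", ""])

    section("Sensor antisense profiles per genotype")
    if sensor is not None:
        lines.append("| genotype | proximal | distal | distal/proximal |")
        lines.append("|---|---|---|---|")
        for g, s in sensor.summaries.items():
            ratio = s.distal / s.proximal if s.proximal else float("nan")
            lines.append(f"| {g} | {s.proximal:.4g} | {s.distal:.4g} "
                         f"| {ratio:.4g} |")
        lines.append("")
        lines.append(f"Normalization: {sensor.config.normalization}; "
                     f"proximal window {sensor.config.proximal_window} nt "
                     f"around site {sensor.site_interval}.")
    else:
        lines.append("_skipped (no sensor inputs)_")
    lines.append("")

    section("Argonaute IP enrichment")
    if sensor is not None and sensor.ip_folds is not None:
        for k, v in sorted(sensor.ip_folds.items()):
            lines.append(f"- {k}: fold {v:.3g}")
    else:
        lines.append("_skipped (no IP inputs)_")
    lines.append("")

    section("Endogenous-gene profile (reads per million)")
    if panel is not None:
        lines.append(f"Panel of {panel.config.n_genes} genes; library sizes: "
                     + ", ".join(f"{g}={n}" for g, n
                                 in sorted(panel.library_sizes.items())))
    else:
        lines.append("_skipped_")
    lines.append("")

    section("Gene bin matrix and k-means clustering")
    if panel is not None:
        lines.append(f"k chosen: {panel.k_chosen} "
                     f"(range {panel.config.k_min}-{panel.config.k_max})")
        lines.append("")
        lines.append(panel.k_report.to_markdown(index=False))
    else:
        lines.append("_skipped_")
    lines.append("")

    section("Per-cluster mutant/WT ratio curves and spreading calls")
    if panel is not None:
        for call in panel.calls:
            lines.append(f"- cluster {call.cluster_id}: index "
                         f"{call.index:.3f} -> {call.label}")
    else:
        lines.append("_skipped_")
    lines.append("")

    section("piRNA target-site predictions and half enrichment")
    if panel is not None:
        lines.append(f"{len(panel.predictions)} predicted sites "
                     f"(<= {panel.config.max_mm} mismatches)")
        for cid, enr in sorted(panel.enrichments.items()):
            lines.append(f"- cluster {cid}: table {enr['table']}, "
                         f"log2 {enr['log2_enrichment']:.3f}, "
                         f"p(3') {enr['p_3prime_bias']:.3g}, "
                         f"p(5') {enr['p_5prime_bias']:.3g}")
    else:
        lines.append("_skipped_")
    lines.append("")

    section("Per-gene 22G level change")
    if panel is not None:
        for cid, lc in sorted(panel.level_changes.items()):
            lines.append(f"- cluster {cid}: median log2 ratio "
                         f"{lc.median_log2_ratio:.3f}, Wilcoxon p "
                         f"{lc.wilcoxon.p:.3g} ({lc.wilcoxon.method})")
    else:
        lines.append("_skipped_")
    lines.append("")

    section("Exon/intron read partition")
    if exon_intron is not None:
        lines.append(exon_intron.to_markdown(index=False))
    else:
        lines.append("_skipped_")
    lines.append("")

    report = "\n".join(lines)
    if path is not None:
        Path(path).write_text(report)
    return report
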