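"""End-to-end orchestration: simulate -> count -> de -> pidshift -> snv ->
cluster -> biomarker -> report, from one JSON config.

Every stage reads its inputs from, and writes plain-text outputs to, the run
directory, so any stage can be re-run or inspected independently. A manifest
records checksums of all outputs; deterministic stages reproduce identical
checksums on re-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from . import __version__
from .biomarker import index_frame, indices_for_groups
from .clustering import (
    SimilarityGraph,
    cluster_de,
    cluster_frame,
    kmer_similarity_graph,
    mcl,
    translate_orfs,
)
from .config import ConfigError, SampleSheet, SimConfig
from .expression import CountMatrix, count_reads, differential_expression
from .formats import read_fasta, read_sam, write_vcf
from .popshift import conserved_shift_table, pid_histogram, shift_table_frame
from .snv import (
    allele_trajectories,
    build_pileup,
    call_snvs_per_sample,
    density_frame,
    snv_density,
    trajectory_frame,
)
from .simulate import generate_references, write_bundle

log = logging.getLogger(__name__)

STAGES = ("simulate", "count", "de", "pidshift", "snv", "cluster", "biomarker", "report")


class StageError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    simulation: SimConfig
    de: dict[str, Any] = field(default_factory=dict)
    pidshift: dict[str, Any] = field(default_factory=dict)
    snv: dict[str, Any] = field(default_factory=dict)
    cluster: dict[str, Any] = field(default_factory=dict)
    biomarker: dict[str, Any] = field(default_factory=dict)
    contrasts: dict[str, dict[str, list[str]]] | None = None

    def validate(self) -> None:
        self.simulation.validate()
        known = {s.name for s in self.simulation.samples}
        if self.contrasts:
            for exp, sides in self.contrasts.items():
                for side in ("depleted", "replete"):
                    for s in sides.get(side, []):
                        if s not in known:
                            raise ConfigError(
                                f"contrast {exp!r}: unknown sample {s!r} in {side} set"
                            )

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {"simulation", "de", "pidshift", "snv", "cluster", "biomarker", "contrasts"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        if "simulation" not in d:
            raise ConfigError("config must contain a 'simulation' section")
        cfg = cls(
            simulation=SimConfig.from_dict(d["simulation"]),
            de=d.get("de", {}),
            pidshift=d.get("pidshift", {}),
            snv=d.get("snv", {}),
            cluster=d.get("cluster", {}),
            biomarker=d.get("biomarker", {}),
            contrasts=d.get("contrasts"),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict[str, Any]:
        return {
            "simulation": self.simulation.to_dict(),
            "de": self.de,
            "pidshift": self.pidshift,
            "snv": self.snv,
            "cluster": self.cluster,
            "biomarker": self.biomarker,
            "contrasts": self.contrasts,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Provenance record: config hash, version, per-stage output checksums."""

    def __init__(self, config: PipelineConfig, outdir: Path):
        self.path = outdir / "manifest.json"
        cfg_json = json.dumps(config.to_dict(), sort_keys=True)
        self.data: dict[str, Any] = {
            "tool_version": __version__,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": config.simulation.seed,
            "stages": {},
        }

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.data["stages"][stage] = {
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        }
        self.write()

    def record_failure(self, stage: str, error: str) -> None:
        self.data["stages"][stage] = {"failed": True, "error": error}
        self.write()

    def write(self) -> None:
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _load_inputs(outdir: Path):
    sheet = SampleSheet.read_tsv(outdir / "sample_sheet.tsv")
    annotation = pd.read_csv(outdir / "annotation.tsv", sep="\t").fillna({"functional_label": ""})
    annotation["functional_label"] = annotation["functional_label"].fillna("")
    references = read_fasta(outdir / "references.fasta")
    return sheet, annotation, references


def _load_alignments(outdir: Path, sheet: SampleSheet):
    return {s: read_sam(outdir / f"{s}.sam") for s in sheet.samples}


def _experiments(sheet: SampleSheet) -> list[str]:
    out = []
    for exp in sorted(sheet.df["experiment"].unique()):
        depleted, replete = sheet.contrast_samples(exp)
        if depleted and replete:
            out.append(exp)
        else:
            log.warning("experiment %s skipped: empty depleted or replete set", exp)
    return out


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    bundle = generate_references(cfg.simulation)
    paths = write_bundle(bundle, outdir, write_reads=True)
    log.info(
        "simulate: %d ORFs, %d samples, %d total reads",
        len(bundle.orf_ids),
        len(cfg.simulation.samples),
        sum(s.library_size for s in cfg.simulation.samples),
    )
    return list(paths.values())


def stage_count(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    sheet, annotation, _refs = _load_inputs(outdir)
    alignments = _load_alignments(outdir, sheet)
    matrix = count_reads(alignments, annotation, sheet)
    out = outdir / "counts.tsv"
    matrix.write_tsv(out)
    log.info("count: %d ORFs x %d samples", *matrix.counts.shape)
    return [out]


def _de_options(cfg: PipelineConfig) -> dict[str, Any]:
    opts = {"min_total": 5, "phi": None}
    opts.update({k: v for k, v in cfg.de.items() if k in opts})
    return opts


def stage_de(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    sheet, annotation, _refs = _load_inputs(outdir)
    matrix = CountMatrix.read_tsv(outdir / "counts.tsv", sheet, annotation)
    opts = _de_options(cfg)
    outputs = []
    for exp in _experiments(sheet):
        for mode in ("global", "groupwise", "taxon_proportion"):
            table = differential_expression(
                matrix, exp, mode=mode, phi=opts["phi"], min_total=opts["min_total"]
            )
            path = outdir / f"de_{mode}_{exp}.tsv"
            table.to_csv(path, sep="\t", index=False)
            n_sig = int((table["fdr"] < 0.05).sum()) if not table.empty else 0
            log.info("de %s/%s: %d tested, %d at FDR<0.05", exp, mode, len(table), n_sig)
            outputs.append(path)
    return outputs


def stage_pidshift(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    sheet, annotation, _refs = _load_inputs(outdir)
    alignments = _load_alignments(outdir, sheet)
    summary = pid_histogram(alignments, annotation)
    outputs = [outdir / "pid_histogram.tsv", outdir / "pid_per_orf.tsv"]
    summary.histogram.to_csv(outputs[0], sep="\t", index=False)
    summary.per_orf.to_csv(outputs[1], sep="\t", index=False)
    opts = {"min_identity": 60.0, "alpha": 0.05, "min_reads": 10}
    opts.update({k: v for k, v in cfg.pidshift.items() if k in opts})
    for exp in _experiments(sheet):
        pairs = sheet.replicate_pairs(exp)
        if not pairs:
            log.warning("pidshift %s: no complete replicate pairs", exp)
            continue
        de = pd.read_csv(outdir / f"de_global_{exp}.tsv", sep="\t")
        records = conserved_shift_table(summary, de, pairs, **opts)
        path = outdir / f"shift_table_{exp}.tsv"
        shift_table_frame(records, annotation).to_csv(path, sep="\t", index=False)
        log.info("pidshift %s: %d conserved-shift ORFs (pairs=%s)", exp, len(records), pairs)
        outputs.append(path)
    return outputs


def stage_snv(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    sheet, annotation, references = _load_inputs(outdir)
    alignments = _load_alignments(outdir, sheet)
    opts = {"min_depth": 4, "min_alt": 2, "min_af": 0.05}
    opts.update({k: v for k, v in cfg.snv.items() if k in opts})
    sweep_hi = cfg.snv.get("sweep_hi", 0.9)
    sweep_lo = cfg.snv.get("sweep_lo", 0.5)

    pileups = {s: build_pileup(alns, references) for s, alns in alignments.items()}
    calls = call_snvs_per_sample(pileups, references, **opts)
    log.info("snv: %d merged calls across %d samples", len(calls), len(pileups))

    vcf_path = outdir / "snv_calls.vcf"
    write_vcf(calls, references, vcf_path, sample_names=sheet.samples)
    density = density_frame(snv_density(calls, pileups, annotation, min_depth=opts["min_depth"]))
    density_path = outdir / "snv_density.tsv"
    density.to_csv(density_path, sep="\t", index=False)
    traj = trajectory_frame(
        allele_trajectories(calls, sheet, sweep_hi=sweep_hi, sweep_lo=sweep_lo)
    )
    traj_path = outdir / "snv_trajectories.tsv"
    traj.to_csv(traj_path, sep="\t", index=False)
    return [vcf_path, density_path, traj_path]


def stage_cluster(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    sheet, annotation, references = _load_inputs(outdir)
    edge_list = cfg.cluster.get("edge_list")
    if edge_list:
        graph = SimilarityGraph.from_edge_list(pd.read_csv(edge_list, sep="\t"))
    else:
        peptides = translate_orfs(references)
        graph = kmer_similarity_graph(
            peptides, k=cfg.cluster.get("k", 4), min_shared=cfg.cluster.get("min_shared", 3)
        )
    result = mcl(graph, inflation=cfg.cluster.get("inflation", 1.5))
    de_by_contrast = {}
    for exp in _experiments(sheet):
        path = outdir / f"de_groupwise_{exp}.tsv"
        if path.exists():
            de_by_contrast[exp] = pd.read_csv(path, sep="\t")
    records = cluster_de(
        result,
        de_by_contrast,
        annotation,
        min_members=cfg.cluster.get("min_members", 11),
        fc_threshold=cfg.cluster.get("fc_threshold", 2.5),
    )
    frame = cluster_frame(records)
    out = outdir / "clusters.tsv"
    frame.to_csv(out, sep="\t", index=False)
    edge_out = outdir / "similarity_edges.tsv"
    graph.to_edge_frame().to_csv(edge_out, sep="\t", index=False)
    log.info(
        "cluster: %d clusters (%d retained), converged=%s",
        len(records), int(frame["retained"].sum()), result.converged,
    )
    return [out, edge_out]


def stage_biomarker(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    sheet, annotation, _refs = _load_inputs(outdir)
    matrix = CountMatrix.read_tsv(outdir / "counts.tsv", sheet, annotation)
    indices = indices_for_groups(
        matrix,
        pseudocount=cfg.biomarker.get("pseudocount", 1.0),
        include_dinoflagellates=cfg.biomarker.get("include_dinoflagellates", False),
    )
    out = outdir / "biomarker_indices.tsv"
    index_frame(indices).to_csv(out, sep="\t", index=False)
    log.info("biomarker: %d index values", len(indices))
    return [out]


def stage_report(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    sheet, annotation, _refs = _load_inputs(outdir)
    report: dict[str, Any] = {"tool_version": __version__, "samples": sheet.samples}

    de_counts: dict[str, Any] = {}
    for exp in _experiments(sheet):
        path = outdir / f"de_global_{exp}.tsv"
        if not path.exists():
            continue
        de = pd.read_csv(path, sep="\t")
        group_of = annotation.set_index("orf_id")["taxon_group"]
        de["taxon_group"] = de["orf_id"].map(group_of)
        sig = de[de["fdr"] < 0.05]
        per_group = {}
        for group, grp in sig.groupby("taxon_group"):
            per_group[group] = {
                "up_depleted": int((grp["log2fc"] > 0).sum()),
                "down_depleted": int((grp["log2fc"] < 0).sum()),
            }
        de_counts[exp] = {"n_tested": len(de), "n_significant": len(sig), "by_taxon": per_group}
    report["differential_expression"] = de_counts

    shifts = {}
    for exp in _experiments(sheet):
        path = outdir / f"shift_table_{exp}.tsv"
        if path.exists():
            tab = pd.read_csv(path, sep="\t")
            shifts[exp] = {
                "n_conserved_shift_orfs": len(tab),
                "mean_delta_pid": float(tab["mean_delta_pid"].mean()) if len(tab) else None,
            }
    report["percent_identity_shift"] = shifts

    density_path = outdir / "snv_density.tsv"
    if density_path.exists():
        dens = pd.read_csv(density_path, sep="\t")
        report["snv_density"] = dens.to_dict(orient="records")
    traj_path = outdir / "snv_trajectories.tsv"
    if traj_path.exists():
        traj = pd.read_csv(traj_path, sep="\t")
        report["snv_sweeps"] = int(traj["sweep"].sum())

    cluster_path = outdir / "clusters.tsv"
    if cluster_path.exists():
        cl = pd.read_csv(cluster_path, sep="\t")
        report["clusters"] = {
            "n_clusters": len(cl),
            "n_retained": int(cl["retained"].sum()),
        }

    marker_path = outdir / "biomarker_indices.tsv"
    if marker_path.exists():
        ix = pd.read_csv(marker_path, sep="\t")
        report["biomarkers"] = ix[
            ["sample", "scope", "index_name", "log2_ratio"]
        ].to_dict(orient="records")

    out = outdir / "report.json"
    with open(out, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return [out]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        v = float(o)
        return None if np.isnan(v) else v
    raise TypeError(f"not JSON serializable: {type(o)}")


STAGE_FUNCS: dict[str, Callable[[PipelineConfig, Path], list[Path]]] = {
    "simulate": stage_simulate,
    "count": stage_count,
    "de": stage_de,
    "pidshift": stage_pidshift,
    "snv": stage_snv,
    "cluster": stage_cluster,
    "biomarker": stage_biomarker,
    "report": stage_report,
}


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    stages: list[str] | None = None,
) -> Manifest:
    """Run stages in dependency order; the manifest records partial state on failure."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config, outdir)
    todo = stages if stages is not None else list(STAGES)
    bad = set(todo) - set(STAGES)
    if bad:
        raise ConfigError(f"unknown stages: {sorted(bad)}")
    for stage in STAGES:
        if stage not in todo:
            continue
        try:
            outputs = STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:  # noqa: BLE001 - manifest must record partial state
            manifest.record_failure(stage, str(exc))
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, outputs)
    return manifest
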