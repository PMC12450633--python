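"""End-to-end orchestration: config, stage execution, run manifest.

Stages run in dependency order (subtype merge -> markers; peaks + histone ->
CRE calls -> peak statistics and networks). Every output is written in a
deterministic byte order and checksummed into ``manifest.json``, so two runs
with the same config and inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import cre, grn, markers, peakstats, subtypes
from .intervals import (
    HistoneTrack,
    read_bed,
    read_gene_annotation,
    read_narrowpeak,
)
from .synthetic import SyntheticConfig, write_bundle

log = logging.getLogger("hepacre.pipeline")

STAGES = ("subtypes", "markers", "cres", "peakstats", "grn")


class PipelineError(RuntimeError):
    """A stage cannot run; the message names the stage and the missing piece."""


@dataclasses.dataclass
class RunConfig:
    """Paths, thresholds and toggles for one pipeline run.

    ``inputs`` keys (all paths): cluster_degs, condition_degs, genes,
    pathways, motifs, links_inferred, links_curated, peaks_<condition>,
    histone_<condition>_<mark>.
    """

    inputs: dict[str, str]
    outdir: str
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    conditions: tuple[str, str] = ("HTN", "normal")
    disease_condition: str = "HTN"
    condition_contrast: str = "HTN_vs_normal"
    k_top: int = 20
    fc_min: float = 0.0
    p_max: float = 0.05
    min_bp: int = 1
    n_subtypes: int = 2
    promoter_window_bp: int = 2000
    enhancer_max_distance_bp: int = 100_000
    gene_window_bp: int = 50_000

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise PipelineError(f"unknown stages {unknown}; valid: {STAGES}")
        if not (0 <= self.p_max <= 1):
            raise PipelineError("p_max must lie in [0, 1]")
        if self.min_bp < 1 or self.k_top < 1 or self.n_subtypes < 1:
            raise PipelineError("min_bp, k_top and n_subtypes must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = [k for k in raw if k not in known]
        if bad:
            raise PipelineError(f"config schema error: unknown keys {bad}")
        for key in ("stages", "conditions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["conditions"] = list(self.conditions)
        return d


def _require(config: RunConfig, stage: str, key: str) -> str:
    path = config.inputs.get(key)
    if not path:
        raise PipelineError(f"stage {stage!r}: no input configured for {key!r}")
    if not Path(path).exists():
        raise PipelineError(f"stage {stage!r}: missing input file {key!r}: {path}")
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(payload, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_histone(config: RunConfig, stage: str, condition: str,
                  mark: str) -> HistoneTrack:
    path = _require(config, stage, f"histone_{condition}_{mark}")
    return HistoneTrack(mark, read_narrowpeak(path))


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_subtypes(config: RunConfig, outdir: Path) -> dict:
    degs = subtypes.read_deg_table(_require(config, "subtypes", "cluster_degs"))
    gene_sets = subtypes.cluster_gene_sets(
        degs, k=config.k_top, fc_min=config.fc_min, p_max=config.p_max)
    matrix = subtypes.jaccard_matrix(gene_sets)
    assignment = subtypes.merge_subtypes(matrix, n_subtypes=config.n_subtypes)
    matrix.to_frame().to_csv(outdir / "jaccard_matrix.tsv", sep="\t",
                             float_format="%.6g")
    assignment.to_frame().to_csv(outdir / "subtype_assignment.tsv", sep="\t",
                                 index=False)
    return {"assignment": assignment, "matrix": matrix}


def _stage_markers(config: RunConfig, outdir: Path) -> dict:
    degs = pd.read_csv(_require(config, "markers", "condition_degs"), sep="\t")
    pathways = markers.read_gmt(_require(config, "markers", "pathways"))
    upregulated = markers.upregulated_in_condition(
        degs, config.condition_contrast, fc_min=config.fc_min, p_max=config.p_max)
    marker_set, venn = markers.intersect_with_pathways(upregulated, pathways)
    pd.DataFrame({"gene": sorted(marker_set)}).to_csv(
        outdir / "markers.tsv", sep="\t", index=False)
    _write_json(venn, outdir / "marker_venn.json")
    return {"upregulated": upregulated, "markers": marker_set}


def _stage_cres(config: RunConfig, outdir: Path) -> dict:
    annotation = read_gene_annotation(_require(config, "cres", "genes"))
    calls_by_condition: dict[str, dict[str, list[cre.CRECall]]] = {}
    summary: dict[str, dict[str, int]] = {}
    for cond in config.conditions:
        peaks = read_bed(_require(config, "cres", f"peaks_{cond}"),
                         category_column=6)
        k4me3 = _load_histone(config, "cres", cond, "H3K4me3")
        k4me1 = _load_histone(config, "cres", cond, "H3K4me1")
        k27ac = _load_histone(config, "cres", cond, "H3K27ac")
        promoters = cre.assign_genes(
            cre.call_promoters(peaks, k4me3, min_bp=config.min_bp),
            annotation, config.promoter_window_bp,
            config.enhancer_max_distance_bp)
        enhancers = cre.assign_genes(
            cre.call_enhancers(peaks, k4me1, k27ac, min_bp=config.min_bp),
            annotation, config.promoter_window_bp,
            config.enhancer_max_distance_bp)
        cre.write_cre_calls(promoters + enhancers,
                            outdir / f"cre_calls_{cond}.tsv")
        calls_by_condition[cond] = {"promoter": promoters, "enhancer": enhancers}
        summary[cond] = {
            "n_peaks": len(peaks),
            "n_promoters": len(promoters),
            "n_enhancers": len(enhancers),
            "n_promoters_with_gene": sum(1 for c in promoters if c.gene),
            "n_enhancers_with_gene": sum(1 for c in enhancers if c.gene),
        }
    _write_json(summary, outdir / "cre_summary.json")
    return {"calls": calls_by_condition, "summary": summary}


def _stage_peakstats(config: RunConfig, outdir: Path) -> dict:
    annotation = read_gene_annotation(_require(config, "peakstats", "genes"))
    peaks_by_condition = {
        cond: read_bed(_require(config, "peakstats", f"peaks_{cond}"),
                       category_column=6)
        for cond in config.conditions
    }
    table = peakstats.category_table(peaks_by_condition)
    table.to_frame().to_csv(outdir / "category_table.tsv", sep="\t")
    chisq = peakstats.chisq_independence(table)
    _write_json(dataclasses.asdict(chisq), outdir / "chisq.json")

    match: dict[str, dict[str, dict]] = {}
    for cond in config.conditions:
        match[cond] = {}
        for mark in ("H3K4me1", "H3K4me3", "H3K27ac"):
            track = _load_histone(config, "peakstats", cond, mark)
            result = peakstats.histone_match_fraction(
                peaks_by_condition[cond], track, min_bp=config.min_bp)
            match[cond][mark] = dataclasses.asdict(result)
    _write_json(match, outdir / "histone_match.json")

    coverage_summary: dict[str, dict] = {}
    for cond in config.conditions:
        cov = peakstats.gene_coverage(peaks_by_condition[cond], annotation,
                                      gene_window_bp=config.gene_window_bp)
        cov.counts.to_csv(outdir / f"gene_coverage_{cond}.tsv", sep="\t")
        coverage_summary[cond] = {
            "venn": cov.venn,
            "max_peaks_per_category": cov.max_peaks_per_category,
            "n_genes_all_categories": len(cov.genes_all_categories),
        }
    _write_json(coverage_summary, outdir / "gene_coverage_summary.json")
    return {"table": table, "chisq": chisq, "histone_match": match,
            "coverage": coverage_summary}


def _stage_grn(config: RunConfig, outdir: Path,
               cre_calls: dict[str, dict[str, list[cre.CRECall]]]) -> dict:
    cond = config.disease_condition
    degs = pd.read_csv(_require(config, "grn", "condition_degs"), sep="\t")
    upregulated = markers.upregulated_in_condition(
        degs, config.condition_contrast, fc_min=config.fc_min, p_max=config.p_max)
    occurrences = grn.read_motif_occurrences(_require(config, "grn", "motifs"))
    peaks = read_bed(_require(config, "grn", f"peaks_{cond}"), category_column=6)
    background = {p.name for p in peaks}

    promoters = cre_calls[cond]["promoter"]
    enhancers = cre_calls[cond]["enhancer"]
    for label, calls in (("promoters", promoters), ("enhancers", enhancers)):
        enrich = grn.motif_enrichment({c.cre_id for c in calls}, background,
                                      occurrences)
        enrich.to_csv(outdir / f"motif_enrichment_{label}.tsv", sep="\t",
                      index=False, float_format="%.6g")

    tf_universe = set(occurrences["motif"])
    promoter_edges = grn.build_promoter_network(
        set(upregulated), promoters, occurrences, tf_universe)
    grn.write_edges(promoter_edges, outdir / "promoter_edges.tsv")

    inferred = grn.read_link_table(_require(config, "grn", "links_inferred"))
    curated = grn.read_link_table(_require(config, "grn", "links_curated"))
    result = grn.build_enhancer_network(inferred, curated, enhancers,
                                        min_bp=config.min_bp)
    grn.write_edges(result.edges, outdir / "enhancer_edges.tsv")
    _write_json({"links": result.venn_pairs, "regions": result.venn_regions},
                outdir / "enhancer_venn.json")
    grn.write_graph_json(promoter_edges + result.edges, outdir / "graph.json")
    return {"promoter_edges": promoter_edges, "enhancer_network": result}


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the in-memory stage results.

    Writes one subdirectory per stage plus ``manifest.json`` (config hash,
    seed, per-output sha256). Reruns with identical config and inputs are
    byte-identical.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        if stage == "grn" and "cres" not in config.stages:
            raise PipelineError("stage 'grn': requires stage 'cres' upstream")
        stage_dir = outdir / stage
        stage_dir.mkdir(exist_ok=True)
        t0 = time.perf_counter()
        if stage == "subtypes":
            results[stage] = _stage_subtypes(config, stage_dir)
        elif stage == "markers":
            results[stage] = _stage_markers(config, stage_dir)
        elif stage == "cres":
            results[stage] = _stage_cres(config, stage_dir)
        elif stage == "peakstats":
            results[stage] = _stage_peakstats(config, stage_dir)
        elif stage == "grn":
            results[stage] = _stage_grn(config, stage_dir,
                                        results["cres"]["calls"])
        log.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)

    # hash the analysis-relevant config only: where outputs land must not
    # change what they contain
    config_dict = config.to_dict()
    config_dict.pop("outdir")
    config_blob = json.dumps(config_dict, sort_keys=True).encode()
    manifest = {
        "config_sha256": hashlib.sha256(config_blob).hexdigest(),
        "seed": config.seed,
        "inputs": {k: _sha256(Path(v)) for k, v in sorted(config.inputs.items())
                   if Path(v).exists()},
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    _write_json(manifest, outdir / "manifest.json")
    results["manifest"] = manifest
    return results


def make_fixtures(config: SyntheticConfig, outdir) -> dict[str, str]:
    """Generate a complete fixture bundle consumable by :func:`run_pipeline`."""
    return write_bundle(config, outdir)


def bundle_run_config(bundle_paths: dict[str, str], outdir,
                      seed: int = 0, **overrides) -> RunConfig:
    """Build a RunConfig wired to a generated fixture bundle."""
    return RunConfig(inputs=dict(bundle_paths), outdir=str(outdir), seed=seed,
                     **overrides)
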