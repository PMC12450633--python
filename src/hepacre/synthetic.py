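"""Synthetic pipeline inputs with planted ground truth.

The generator emulates the *post-upstream* tables the analysis consumes —
per-cluster DEG tables, cell metadata, categorised accessible-chromatin
peaks, histone narrowPeak tracks, a gene annotation, TF motif occurrences,
pathway gene sets and two enhancer-gene link tables — never raw reads or
fragments. Every downstream answer is planted:

* clusters fall into two hepatocyte-subtype blocks sharing top genes, plus
  a zero-similarity outlier cluster (a mis-annotated cholangiocyte stand-in);
* the disease-skewed block's clusters are ~85.3% disease cells, the
  normal-skewed block's ~12%;
* planted promoters are Promoter-category peaks overlapped by H3K4me3;
  planted enhancers are non-Promoter peaks overlapped by both H3K4me1 and
  H3K27ac; decoys carry only partial evidence;
* five canonical marker genes sit in the intersection of the
  condition-upregulated set and the pathway union;
* the enhancer link tables realise a configurable inferred / curated /
  histone three-way overlap whose triple intersection is the edge truth.

Layout guarantees make truth exact rather than probabilistic: the genome is
divided into fixed-width slots; each peak (and its histone evidence) lives
in the first half of its own slot, while link decoy coordinates and
background gene TSSs occupy the second halves of dedicated peak-free slots,
so no unplanned overlap can occur.

A single integer seed drives everything through documented sub-streams
(``SeedSequence(seed, spawn_key=(stage,))``), making bundles byte-identical
across runs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import (
    GeneAnnotation,
    GenomicInterval,
    HistoneTrack,
    write_bed,
    write_gene_annotation,
    write_narrowpeak,
)
from .markers import PathwayGeneSet
from .grn import EnhancerLink, write_link_table

# sub-seed stage keys
_STAGE_DEGS = 0
_STAGE_CELLS = 1
_STAGE_PEAKS = {"HTN": 2, "normal": 3}
_STAGE_GENES = 4
_STAGE_MOTIFS = 5
_STAGE_LINKS = 6
_STAGE_CONDITION_DEGS = 7


class ConfigError(ValueError):
    """Invalid synthetic configuration."""


class GenerationError(RuntimeError):
    """Configuration valid but physically unsatisfiable (e.g. genome too small)."""


@dataclasses.dataclass
class SyntheticConfig:
    """Study-condition knobs for the generator. Defaults mirror the study's
    reported magnitudes at roughly 1/10 scale so the full pipeline runs in
    seconds."""

    seed: int = 0

    # --- clusters and cluster-vs-rest DEG tables -------------------------
    subtype_blocks: tuple[tuple[str, ...], ...] = (
        ("C0", "C3", "C8", "C11", "C12", "C13", "C15"),
        ("C1", "C4", "C7", "C14"),
    )
    outlier_clusters: tuple[str, ...] = ("C9",)
    k_top: int = 20
    within_block_shared_genes: int = 10
    n_filler_genes_per_cluster: int = 30

    # --- cell metadata ----------------------------------------------------
    cells_per_cluster: int = 200
    conditions: tuple[str, str] = ("HTN", "normal")
    disease_fraction_disease_block: float = 0.853
    disease_fraction_normal_block: float = 0.12
    disease_fraction_outlier: float = 0.5
    condition_fraction_per_cluster: dict[str, float] | None = None

    # --- genome / accessible peaks / histone tracks ----------------------
    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("chr1", 5_000_000), ("chr2", 5_000_000),
    )
    slot_bp: int = 2000
    peak_width_bp: int = 500
    n_atac_peaks: int = 2000
    category_probs: dict[str, tuple[float, float, float, float]] = dataclasses.field(
        default_factory=lambda: {
            # Promoter, Distal, Exonic, Intronic
            "HTN": (0.168, 0.180, 0.200, 0.452),
            "normal": (0.083, 0.250, 0.210, 0.457),
        }
    )
    planted_promoter_rate: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"HTN": 0.15, "normal": 0.06}
    )
    planted_enhancer_rate: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"HTN": 0.125, "normal": 0.012}
    )
    decoy_single_mark_rate: float = 0.20
    decoy_promoter_enhancer_marks_rate: float = 0.25
    decoy_k4me3_wrong_category_rate: float = 0.08

    # --- genes, condition contrast, markers, pathways ---------------------
    n_genes: int = 2000
    marker_genes: tuple[str, ...] = ("UPB1", "SDS", "PCCA", "CYP3A4", "PPARGC1A")
    extra_network_genes: tuple[str, ...] = ("SLC2A2",)
    n_condition_upregulated: int = 60
    n_condition_fillers: int = 60
    condition_contrast: str = "HTN_vs_normal"
    n_pathway_only_genes: int = 10

    # --- motifs -----------------------------------------------------------
    tf_names: tuple[str, ...] = (
        "NR1H4", "WT1", "GATA4", "TBX21", "HNF4A", "FOXA1", "FOXA2", "CEBPA",
        "NR2F2", "PPARA", "RXRA", "ONECUT1", "HNF1A", "NFIA", "ESRRA", "MLXIPL",
    )
    motif_density: float = 0.05

    # --- enhancer-gene link tables ----------------------------------------
    n_inferred_links: int = 100
    n_curated_supported: int = 60
    n_triple_supported: int = 40
    n_curated_only: int = 20

    # ----------------------------------------------------------------------
    @property
    def clusters(self) -> list[str]:
        return [c for block in self.subtype_blocks for c in block] + list(
            self.outlier_clusters
        )

    @property
    def network_genes(self) -> tuple[str, ...]:
        return self.marker_genes + self.extra_network_genes

    def validate(self) -> None:
        seen: set[str] = set()
        for block in self.subtype_blocks:
            for c in block:
                if c in seen:
                    raise ConfigError(f"cluster {c!r} appears in two blocks")
                seen.add(c)
        for c in self.outlier_clusters:
            if c in seen:
                raise ConfigError(f"outlier {c!r} also in a block")
        if self.within_block_shared_genes > self.k_top:
            raise ConfigError("within_block_shared_genes exceeds k_top")
        for frac in (self.disease_fraction_disease_block,
                     self.disease_fraction_normal_block,
                     self.disease_fraction_outlier, self.motif_density,
                     self.decoy_single_mark_rate):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"fraction {frac} outside [0, 1]")
        if self.n_atac_peaks <= 0:
            raise ConfigError("n_atac_peaks must be positive")
        for cond in self.conditions:
            for table in (self.category_probs, self.planted_promoter_rate,
                          self.planted_enhancer_rate):
                if cond not in table:
                    raise ConfigError(f"no entry for condition {cond!r}")
        if not (self.n_triple_supported <= self.n_curated_supported
                <= self.n_inferred_links):
            raise ConfigError(
                "link overlap must satisfy triple <= curated-supported <= inferred"
            )
        n_prom_disease = round(
            self.planted_promoter_rate[self.conditions[0]] * self.n_atac_peaks
        )
        if n_prom_disease < len(self.network_genes):
            raise ConfigError(
                f"{n_prom_disease} planted promoters cannot host "
                f"{len(self.network_genes)} network genes"
            )
        if self.n_genes < n_prom_disease + 1:
            raise ConfigError("n_genes too small for the planted promoters")
        if self.n_condition_upregulated < len(self.network_genes):
            raise ConfigError("n_condition_upregulated below network gene count")


@dataclasses.dataclass
class PeaksBundle:
    """One condition's peaks, histone tracks, and the planted CRE truth."""

    condition: str
    peaks: list[GenomicInterval]
    tracks: dict[str, HistoneTrack]
    true_promoters: set[str]
    true_enhancers: set[str]


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed,
                                                        spawn_key=(stage,)))


# ---------------------------------------------------------------------------
# Genome slot layout
# ---------------------------------------------------------------------------

def _slot_coords(config: SyntheticConfig, slot: int) -> tuple[str, int]:
    remaining = slot
    for chrom, length in config.chrom_lengths:
        capacity = length // config.slot_bp
        if remaining < capacity:
            return chrom, remaining * config.slot_bp
        remaining -= capacity
    raise GenerationError(
        "genome too small to place requested peaks without forbidden overlaps: "
        f"slot {slot} exceeds capacity "
        f"{sum(l // config.slot_bp for _, l in config.chrom_lengths)}"
    )


def _n_link_slots(config: SyntheticConfig) -> int:
    return (config.n_inferred_links - config.n_triple_supported
            + config.n_curated_only)


def _check_capacity(config: SyntheticConfig) -> None:
    needed = config.n_atac_peaks + _n_link_slots(config) + config.n_genes
    capacity = sum(l // config.slot_bp for _, l in config.chrom_lengths)
    if needed > capacity:
        raise GenerationError(
            "genome too small to place requested peaks without forbidden "
            f"overlaps: need {needed} slots, capacity {capacity}"
        )
    jitter_max = (config.slot_bp // 2 - config.peak_width_bp - 100 - 75)
    if jitter_max < 0:
        raise GenerationError(
            f"slot_bp {config.slot_bp} too small for peak width "
            f"{config.peak_width_bp} plus histone padding"
        )


def _free_zone(config: SyntheticConfig, slot: int, width: int = 400
               ) -> tuple[str, int, int]:
    """A guaranteed peak-free span in the second half of a slot."""
    chrom, start = _slot_coords(config, slot)
    lo = start + config.slot_bp // 2 + 100
    return chrom, lo, lo + width


# ---------------------------------------------------------------------------
# DEG tables and cells
# ---------------------------------------------------------------------------

def generate_deg_tables(config: SyntheticConfig
                        ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-cluster cluster-vs-rest DEG records plus the subtype truth.

    Clusters in the same block share exactly ``within_block_shared_genes``
    of their top-k genes; blocks share none; the outlier shares none with
    anyone. Filler genes fail exactly one of the two upregulation filters.
    """
    config.validate()
    rng = _rng(config, _STAGE_DEGS)
    k, shared = config.k_top, config.within_block_shared_genes
    rows = []

    def planted_row(gene, cluster):
        return (gene, cluster, float(rng.uniform(0.5, 3.0)),
                float(rng.uniform(1e-6, 0.01)), "cluster_vs_rest")

    def filler_rows(cluster):
        for i in range(config.n_filler_genes_per_cluster):
            gene = f"{cluster}F{i:03d}"
            if i % 2 == 0:  # fails the fold-change filter
                yield (gene, cluster, float(rng.uniform(-3.0, -0.1)),
                       float(rng.uniform(1e-6, 0.01)), "cluster_vs_rest")
            else:           # fails the p-value filter
                yield (gene, cluster, float(rng.uniform(0.5, 3.0)),
                       float(rng.uniform(0.06, 0.9)), "cluster_vs_rest")

    for b, block in enumerate(config.subtype_blocks):
        shared_pool = [f"B{b + 1}S{i:03d}" for i in range(shared)]
        for cluster in block:
            for gene in shared_pool:
                rows.append(planted_row(gene, cluster))
            for i in range(k - shared):
                rows.append(planted_row(f"{cluster}U{i:03d}", cluster))
            rows.extend(filler_rows(cluster))
    for cluster in config.outlier_clusters:
        for i in range(k):
            rows.append(planted_row(f"{cluster}U{i:03d}", cluster))
        rows.extend(filler_rows(cluster))

    degs = pd.DataFrame(rows, columns=["gene", "cluster", "avg_log2FC",
                                       "p_val", "contrast"])
    return degs, true_subtype_labels(config)


def true_subtype_labels(config: SyntheticConfig) -> dict[str, str]:
    """Planted cluster -> subtype mapping, labelled by descending block size."""
    order = sorted(
        range(len(config.subtype_blocks)),
        key=lambda b: (-len(config.subtype_blocks[b]),
                       min(config.subtype_blocks[b])),
    )
    mapping = {}
    for rank, b in enumerate(order, start=1):
        for cluster in config.subtype_blocks[b]:
            mapping[cluster] = f"Subtype_{rank}"
    for cluster in config.outlier_clusters:
        mapping[cluster] = "excluded"
    return mapping


def _disease_fraction(config: SyntheticConfig, cluster: str) -> float:
    overrides = config.condition_fraction_per_cluster or {}
    if cluster in overrides:
        return overrides[cluster]
    if cluster in config.subtype_blocks[0]:
        return config.disease_fraction_disease_block
    if len(config.subtype_blocks) > 1 and cluster in config.subtype_blocks[1]:
        return config.disease_fraction_normal_block
    return config.disease_fraction_outlier


def generate_cells(config: SyntheticConfig) -> pd.DataFrame:
    """Cell metadata with per-cluster condition composition as configured."""
    config.validate()
    rng = _rng(config, _STAGE_CELLS)
    disease, normal = config.conditions
    rows = []
    for cluster in config.clusters:
        frac = _disease_fraction(config, cluster)
        draws = rng.random(config.cells_per_cluster) < frac
        for j, is_disease in enumerate(draws):
            rows.append((f"{cluster}_cell{j:04d}", cluster,
                         disease if is_disease else normal))
    return pd.DataFrame(rows, columns=["cell_id", "cluster", "condition"])


# ---------------------------------------------------------------------------
# Peaks, histone tracks, genes, motifs
# ---------------------------------------------------------------------------

def generate_peaks_and_histone(config: SyntheticConfig,
                               condition: str = "HTN") -> PeaksBundle:
    """One condition's categorised peaks + three histone tracks + CRE truth.

    Planted promoters/enhancers carry full histone support; negatives carry
    none, a single enhancer mark, enhancer marks on a Promoter-category peak,
    or H3K4me3 on a non-Promoter peak — all of which must be rejected
    downstream.
    """
    config.validate()
    _check_capacity(config)
    if condition not in config.conditions:
        raise ConfigError(f"unknown condition {condition!r}")
    rng = _rng(config, _STAGE_PEAKS[condition])
    P = config.n_atac_peaks
    n_prom = round(config.planted_promoter_rate[condition] * P)
    n_enh = round(config.planted_enhancer_rate[condition] * P)
    chosen = rng.choice(P, size=n_prom + n_enh, replace=False)
    prom_slots = set(int(s) for s in chosen[:n_prom])
    enh_slots = set(int(s) for s in chosen[n_prom:])

    cat_probs = np.asarray(config.category_probs[condition], dtype=float)
    cat_probs = cat_probs / cat_probs.sum()
    nonprom = np.array(["Distal", "Exonic", "Intronic"])
    nonprom_probs = cat_probs[1:] / cat_probs[1:].sum()
    jitter_max = config.slot_bp // 2 - config.peak_width_bp - 100 - 75

    peaks: list[GenomicInterval] = []
    tracks: dict[str, list[GenomicInterval]] = {m: [] for m in
                                                ("H3K4me1", "H3K4me3", "H3K27ac")}
    true_promoters: set[str] = set()
    true_enhancers: set[str] = set()

    def add_mark(mark, chrom, lo, hi):
        tracks[mark].append(GenomicInterval(
            chrom, max(0, lo), hi, f"{condition}_{mark}_{len(tracks[mark])}"))

    for slot in range(P):
        chrom, slot_start = _slot_coords(config, slot)
        start = slot_start + 100 + int(rng.integers(0, jitter_max + 1))
        end = start + config.peak_width_bp
        name = f"{condition}_peak{slot:05d}"
        if slot in prom_slots:
            category = "Promoter"
        elif slot in enh_slots:
            category = str(rng.choice(nonprom, p=nonprom_probs))
        else:
            category = str(rng.choice(np.array(
                ["Promoter", "Distal", "Exonic", "Intronic"]), p=cat_probs))
        peaks.append(GenomicInterval(
            chrom, start, end, name, score=float(rng.integers(100, 1000)),
            peak_category=category, summit_offset=config.peak_width_bp // 2))

        if slot in prom_slots:
            add_mark("H3K4me3", chrom, start - 50, end + 50)
            true_promoters.add(name)
        elif slot in enh_slots:
            add_mark("H3K4me1", chrom, start - 60, end + 30)
            add_mark("H3K27ac", chrom, start - 30, end + 60)
            true_enhancers.add(name)
        else:
            u = float(rng.random())
            if category == "Promoter":
                # never H3K4me3 here, so the promoter rule stays unsatisfied
                if u < config.decoy_promoter_enhancer_marks_rate:
                    add_mark("H3K4me1", chrom, start - 60, end + 30)
                    add_mark("H3K27ac", chrom, start - 30, end + 60)
                elif u < config.decoy_promoter_enhancer_marks_rate + 0.2:
                    mark = "H3K4me1" if rng.random() < 0.5 else "H3K27ac"
                    add_mark(mark, chrom, start - 40, end + 40)
            else:
                if u < config.decoy_single_mark_rate:
                    mark = "H3K4me1" if rng.random() < 0.5 else "H3K27ac"
                    add_mark(mark, chrom, start - 40, end + 40)
                elif u < (config.decoy_single_mark_rate
                          + config.decoy_k4me3_wrong_category_rate):
                    add_mark("H3K4me3", chrom, start - 50, end + 50)

    return PeaksBundle(
        condition, peaks,
        {m: HistoneTrack(m, ivs) for m, ivs in tracks.items()},
        true_promoters, true_enhancers,
    )


def _network_gene_peaks(config: SyntheticConfig,
                        disease_bundle: PeaksBundle) -> dict[str, GenomicInterval]:
    """Map each network gene to its host promoter peak (first planted slots)."""
    planted = sorted(disease_bundle.true_promoters)
    by_name = {p.name: p for p in disease_bundle.peaks}
    return {gene: by_name[planted[i]]
            for i, gene in enumerate(config.network_genes)}


def generate_gene_annotation(config: SyntheticConfig) -> list[GeneAnnotation]:
    """TSS annotation: one gene inside every disease planted-promoter peak
    (the first few being the named network genes), plus background genes in
    dedicated peak-free slots."""
    config.validate()
    _check_capacity(config)
    rng = _rng(config, _STAGE_GENES)
    disease = config.conditions[0]
    bundle = generate_peaks_and_histone(config, disease)
    planted = sorted(bundle.true_promoters)
    by_name = {p.name: p for p in bundle.peaks}

    genes: list[GeneAnnotation] = []
    for i, peak_name in enumerate(planted):
        peak = by_name[peak_name]
        symbol = (config.network_genes[i] if i < len(config.network_genes)
                  else f"PRG{i:04d}")
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(symbol, peak.chrom, peak.midpoint, strand))

    n_bg = config.n_genes - len(planted)
    first_bg_slot = config.n_atac_peaks + _n_link_slots(config)
    for j in range(n_bg):
        chrom, lo, _hi = _free_zone(config, first_bg_slot + j)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(f"BGG{j:04d}", chrom, lo + 150, strand))
    return genes


def generate_motif_occurrences(config: SyntheticConfig
                               ) -> tuple[pd.DataFrame,
                                          list[tuple[str, str, str]]]:
    """Motif table for the disease peak set plus the planted promoter edges.

    Network-gene promoter peaks carry only planted motifs (CYP3A4's promoter
    gets exactly five TFs); every other peak receives independent
    Bernoulli(motif_density) occurrences per TF.
    """
    config.validate()
    rng = _rng(config, _STAGE_MOTIFS)
    disease = config.conditions[0]
    bundle = generate_peaks_and_histone(config, disease)
    network_peaks = _network_gene_peaks(config, bundle)
    peak_of_gene = {g: p.name for g, p in network_peaks.items()}
    network_peak_names = set(peak_of_gene.values())

    tf_arr = np.array(config.tf_names)
    rows: list[tuple[str, str]] = []
    true_edges: list[tuple[str, str, str]] = []
    for gene in config.network_genes:
        count = 5 if gene == "CYP3A4" else int(rng.integers(1, 4))
        count = min(count, len(tf_arr))
        for tf in sorted(rng.choice(tf_arr, size=count, replace=False)):
            rows.append((peak_of_gene[gene], str(tf)))
            true_edges.append((str(tf), peak_of_gene[gene], gene))
    for peak in bundle.peaks:
        if peak.name in network_peak_names:
            continue
        hits = rng.random(len(tf_arr)) < config.motif_density
        for tf in tf_arr[hits]:
            rows.append((peak.name, str(tf)))

    occ = pd.DataFrame(rows, columns=["peak_id", "motif"]).sort_values(
        ["peak_id", "motif"], ignore_index=True)
    return occ, sorted(true_edges)


# ---------------------------------------------------------------------------
# Condition contrast, pathways, link tables
# ---------------------------------------------------------------------------

def generate_condition_deg_table(config: SyntheticConfig) -> pd.DataFrame:
    """Disease-vs-normal DEG contrast within the disease-skewed subtype.

    Upregulated set = network genes (markers included) + filler upregulated
    genes that exist only in expression space (no genomic annotation), so
    they can never acquire promoter calls.
    """
    config.validate()
    rng = _rng(config, _STAGE_CONDITION_DEGS)
    contrast = config.condition_contrast
    upregulated = list(config.network_genes) + [
        f"UPG{i:03d}"
        for i in range(config.n_condition_upregulated - len(config.network_genes))
    ]
    rows = [
        (gene, "Hepatocytes_1", float(rng.uniform(0.5, 3.0)),
         float(rng.uniform(1e-6, 0.01)), contrast)
        for gene in upregulated
    ]
    for i in range(config.n_condition_fillers):
        gene = f"UPF{i:03d}"
        if i % 2 == 0:
            rows.append((gene, "Hepatocytes_1", float(rng.uniform(-3.0, -0.1)),
                         float(rng.uniform(1e-6, 0.01)), contrast))
        else:
            rows.append((gene, "Hepatocytes_1", float(rng.uniform(0.5, 3.0)),
                         float(rng.uniform(0.06, 0.9)), contrast))
    return pd.DataFrame(rows, columns=["gene", "cluster", "avg_log2FC",
                                       "p_val", "contrast"])


def generate_pathways(config: SyntheticConfig) -> list[PathwayGeneSet]:
    """Two GO-style pathway sets whose union meets the upregulated set in
    exactly the five marker genes."""
    config.validate()
    m = config.marker_genes
    pw_a = list(m[:3]) + [f"PWA{i:03d}" for i in range(config.n_pathway_only_genes)]
    pw_b = list(m[2:]) + [f"PWB{i:03d}" for i in range(config.n_pathway_only_genes)]
    return [
        PathwayGeneSet("GO:0006631", "fatty acid metabolic process",
                       frozenset(pw_a)),
        PathwayGeneSet("GO:0044282", "small-molecule catabolic process",
                       frozenset(pw_b)),
    ]


def generate_link_tables(config: SyntheticConfig
                         ) -> tuple[list[EnhancerLink], list[EnhancerLink],
                                    list[tuple[str, str, str]]]:
    """Inferred + curated enhancer-gene link tables and the triple truth.

    Of ``n_inferred_links`` inferred links, ``n_curated_supported`` get a
    coordinate-overlapping curated partner with the same target gene, and
    ``n_triple_supported`` of those sit on planted-enhancer coordinates
    (histone support). The truth edge set is exactly the triple overlap.
    """
    config.validate()
    _check_capacity(config)
    rng = _rng(config, _STAGE_LINKS)
    disease = config.conditions[0]
    bundle = generate_peaks_and_histone(config, disease)
    enh_names = sorted(bundle.true_enhancers)
    if config.n_triple_supported > 0 and not enh_names:
        raise GenerationError(
            "no planted enhancers available for histone-supported links"
        )
    by_name = {p.name: p for p in bundle.peaks}

    n_planted_prom = len(bundle.true_promoters)
    n_bg = config.n_genes - n_planted_prom
    if n_bg < config.n_inferred_links:
        raise ConfigError(
            f"need >= {config.n_inferred_links} background genes for distinct "
            f"link targets, have {n_bg}"
        )
    gene_pool = np.array([f"BGG{j:04d}" for j in range(n_bg)])
    link_genes = [str(g) for g in
                  rng.choice(gene_pool, size=config.n_inferred_links,
                             replace=False)]
    if config.n_triple_supported > 0:
        link_genes[0] = "UPB1"  # flavor: the canonical enhancer-regulated marker

    inferred: list[EnhancerLink] = []
    curated: list[EnhancerLink] = []
    truth: list[tuple[str, str, str]] = []
    free_slot = config.n_atac_peaks

    for i in range(config.n_inferred_links):
        gene = link_genes[i]
        tf = "NR1H4" if i == 0 else str(rng.choice(np.array(config.tf_names)))
        if i < config.n_triple_supported:
            peak = by_name[enh_names[i % len(enh_names)]]
            chrom, lo, hi = peak.chrom, peak.start, peak.end
        else:
            chrom, lo, hi = _free_zone(config, free_slot)
            free_slot += 1
        iv = GenomicInterval(chrom, lo, hi, f"inf_{i:03d}")
        inferred.append(EnhancerLink(iv, gene, tf=tf, source="inferred",
                                     score=float(rng.uniform(0.5, 1.0))))
        if i < config.n_curated_supported:
            shift = int(rng.integers(-20, 21))
            civ = GenomicInterval(chrom, max(0, lo + shift), hi + shift,
                                  f"cur_{i:03d}")
            curated.append(EnhancerLink(civ, gene, source="curated"))
        if i < config.n_triple_supported:
            truth.append((tf, f"{chrom}:{lo}-{hi}", gene))

    for j in range(config.n_curated_only):
        chrom, lo, hi = _free_zone(config, free_slot)
        free_slot += 1
        civ = GenomicInterval(chrom, lo, hi, f"curonly_{j:03d}")
        curated.append(EnhancerLink(civ, str(rng.choice(gene_pool)),
                                    source="curated"))

    order = rng.permutation(len(inferred))
    inferred = [inferred[int(i)] for i in order]
    return inferred, curated, sorted(truth)


# ---------------------------------------------------------------------------
# Truth + bundle writer
# ---------------------------------------------------------------------------

def planted_truth(config: SyntheticConfig) -> dict:
    """The full planted truth as a JSON-serialisable dict."""
    config.validate()
    truth: dict = {"true_subtype": true_subtype_labels(config)}
    truth["marker_genes"] = sorted(config.marker_genes)
    _, prom_edges = generate_motif_occurrences(config)
    truth["true_promoter_edges"] = [list(e) for e in prom_edges]
    _, _, enh_edges = generate_link_tables(config)
    truth["true_enhancer_edges"] = [list(e) for e in enh_edges]
    truth["true_promoters"] = {}
    truth["true_enhancers"] = {}
    for cond in config.conditions:
        bundle = generate_peaks_and_histone(config, cond)
        truth["true_promoters"][cond] = sorted(bundle.true_promoters)
        truth["true_enhancers"][cond] = sorted(bundle.true_enhancers)
    cond_degs = generate_condition_deg_table(config)
    up = cond_degs[(cond_degs["avg_log2FC"] > 0) & (cond_degs["p_val"] < 0.05)]
    truth["upregulated_condition"] = sorted(up["gene"])
    return truth


def write_bundle(config: SyntheticConfig, outdir) -> dict[str, str]:
    """Write the complete fixture bundle + truth.json; returns name -> path."""
    config.validate()
    _check_capacity(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def register(key, filename):
        paths[key] = str(outdir / filename)
        return paths[key]

    degs, _ = generate_deg_tables(config)
    degs.to_csv(register("cluster_degs", "cluster_degs.tsv"), sep="\t",
                index=False, float_format="%.6g")
    generate_condition_deg_table(config).to_csv(
        register("condition_degs", "condition_degs.tsv"), sep="\t",
        index=False, float_format="%.6g")
    generate_cells(config).to_csv(register("cells", "cells.tsv"), sep="\t",
                                  index=False)

    for cond in config.conditions:
        bundle = generate_peaks_and_histone(config, cond)
        write_bed(bundle.peaks, register(f"peaks_{cond}", f"peaks_{cond}.bed"),
                  include_category=True)
        for mark, track in bundle.tracks.items():
            write_narrowpeak(track.intervals, register(
                f"histone_{cond}_{mark}", f"histone_{cond}_{mark}.narrowPeak"))

    write_gene_annotation(generate_gene_annotation(config),
                          register("genes", "genes.tsv"))

    occ, _ = generate_motif_occurrences(config)
    occ.to_csv(register("motifs", "motifs.tsv"), sep="\t", index=False)

    with open(register("pathways", "pathways.gmt"), "w") as fh:
        for pw in generate_pathways(config):
            fh.write("\t".join([pw.pathway_id, pw.name, *sorted(pw.genes)]) + "\n")

    inferred, curated, _ = generate_link_tables(config)
    write_link_table(inferred, register("links_inferred", "links_inferred.tsv"))
    write_link_table(curated, register("links_curated", "links_curated.tsv"))

    with open(register("truth", "truth.json"), "w") as fh:
        json.dump(planted_truth(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
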