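"""End-to-end orchestration: simulate -> reads -> graph -> analyze -> layout.

Every stage draws its randomness from a seed derived as
hash(top seed, stage name), recorded in the run manifest, so stages
can be re-run individually, in any order, with identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError  # noqa: F401

from . import __version__
from .graph import (SizeThresholdError, build_graph, call_components,
                    count_matrix, filter_components, project_a_graph,
                    refine_components, size_threshold, tau_filter)
from .panel import PanelConfig, generate_panel
from .reads import process_fastq
from .simulate import (CellSpec, ErrorModel, SimTruth, colocalized,
                       default_cell_spec, polarized, render_fastq,
                       simulate_sample)
from .spatial import colocalization_scores, polarity_scores

log = logging.getLogger("mpxtools")


class RunConfig(BaseModel):
    """Parameters of one MPX pipeline run (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "mpx_out"
    log_level: str = "INFO"

    # simulate
    n_cells: int = 10
    n_markers: int = 80
    n_controls: int = 4
    total_molecules: int = 10_900
    n_pixels_a: int = 1737
    n_pixels_b: int = 1737
    pixel_radius: float = 0.083
    doublet_fraction: float = 0.0
    polarized_markers: list[str] = []
    colocalized_pairs: list[list[str]] = []
    kappa: float = 0.0

    # amplicon
    amplicon: bool = False
    substitution_rate: float = 0.005
    pcr_duplication: float = 3.0
    dropout_rate: float = 0.0
    umi_collapse_max_dist: int = 2

    # graph
    resolution: float = 1.0
    max_refine_iter: int = 3
    crossing_max: int = 10
    drop_top_k: int = 0
    manual_min: int = 0
    use_spline_threshold: bool = True

    # analyze
    polarity: bool = True
    colocalization: bool = True
    n_perm: int = 50
    min_marker: int = 10
    min_neighborhood: int = 5

    # layout
    layout: bool = False
    layout_max_cells: int = 2
    distance_cutoff: float = 0.3
    grid_points: int = 2000

    def params_hash(self) -> str:
        """Hash of the scientific parameters (paths/logging excluded)."""
        doc = self.model_dump()
        doc.pop("out_dir", None)
        doc.pop("log_level", None)
        payload = json.dumps(doc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def _write_table(df: pd.DataFrame, path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mpxtools {__version__} params={cfg.params_hash()}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.save(out / "run_config.yaml")
    panel = generate_panel(cfg.n_markers, stage_seed(cfg.seed, "panel"),
                           n_controls=cfg.n_controls)
    panel.to_yaml(out / "panel.yaml")
    patterns = {m: polarized(cfg.kappa) for m in cfg.polarized_markers}
    for pair in cfg.colocalized_pairs:
        a, b = pair
        patterns.setdefault(a, polarized(cfg.kappa))
        patterns[b] = colocalized(a, cfg.kappa)
    spec = default_cell_spec(
        panel, total_molecules=cfg.total_molecules,
        spatial_pattern=patterns,
        n_pixels_a=cfg.n_pixels_a, n_pixels_b=cfg.n_pixels_b,
        pixel_radius=cfg.pixel_radius,
    )
    truth, edges = simulate_sample(
        [(spec, cfg.n_cells)], doublet_fraction=cfg.doublet_fraction,
        seed=stage_seed(cfg.seed, "simulate"),
        umi_length=panel.umi_length, upi_length=panel.upi_length,
    )
    truth.save(out)
    edges.to_csv(out / "edge_list.tsv", sep="\t", index=False)
    log.info("simulate: %d cells, %d molecules", cfg.n_cells, len(edges))


def stage_amplicon(cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    _require(out / "truth_molecules.tsv", "simulate")
    truth = SimTruth.load(out)
    panel = PanelConfig.from_yaml(out / "panel.yaml")
    errors = ErrorModel(
        substitution_rate=cfg.substitution_rate,
        pcr_duplication=cfg.pcr_duplication,
        dropout_rate=cfg.dropout_rate,
    )
    n_reads = render_fastq(truth, panel, errors,
                           seed=stage_seed(cfg.seed, "amplicon"),
                           path=out / "reads.fastq")
    edges, qc = process_fastq(out / "reads.fastq", panel,
                              max_dist=cfg.umi_collapse_max_dist)
    edges.to_csv(out / "edge_parsed.tsv", sep="\t", index=False)
    qc.to_json(out / "qc.json")
    log.info("amplicon: %d reads -> %d unique molecules",
             n_reads, qc.unique_molecules)


def stage_graph(cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    source = (out / "edge_parsed.tsv" if (out / "edge_parsed.tsv").exists()
              else out / "edge_list.tsv")
    _require(source, "simulate (or amplicon)")
    edges = pd.read_csv(source, sep="\t")
    g = build_graph(edges)
    g = refine_components(g, resolution=cfg.resolution,
                          max_iter=cfg.max_refine_iter,
                          crossing_max=cfg.crossing_max,
                          seed=stage_seed(cfg.seed, "leiden"))
    labels = call_components(g)
    threshold = 0
    if cfg.use_spline_threshold:
        try:
            threshold = size_threshold(labels.value_counts().values)
        except SizeThresholdError as exc:
            log.info("graph: spline threshold unavailable (%s); "
                     "using manual_min=%d", exc, cfg.manual_min)
    retained, rank_table = filter_components(
        labels, threshold=threshold, manual_min=cfg.manual_min,
        drop_top_k=cfg.drop_top_k)
    panel = PanelConfig.from_yaml(out / "panel.yaml")
    cm = count_matrix(g.edges, retained, panel)
    taus = tau_filter(cm)

    g.edges.to_csv(out / "components.tsv", sep="\t", index=False)
    _write_table(rank_table, out / "edge_rank.csv", cfg)
    cm.write_mtx(out / "counts")
    cm.counts.reset_index().to_csv(out / "counts.csv", index=False)
    cm.clr.reset_index().to_csv(out / "counts_clr.csv", index=False)
    _write_table(taus, out / "tau.csv", cfg)
    log.info("graph: %d components retained (threshold=%d)",
             len(retained), threshold)


def _iter_retained_projections(out: Path):
    edges = pd.read_csv(out / "components.tsv", sep="\t")
    rank = read_table(out / "edge_rank.csv")
    panel = PanelConfig.from_yaml(out / "panel.yaml")
    retained = rank.loc[rank.retained, "component"].tolist()
    for comp in retained:
        sub = edges[edges.component == comp]
        yield project_a_graph(sub, markers=panel.marker_names,
                              component=comp)


def stage_analyze(cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    _require(out / "components.tsv", "graph")
    pol_frames, coloc_frames = [], []
    coloc_seed = stage_seed(cfg.seed, "colocalization")
    for g in _iter_retained_projections(out):
        if cfg.polarity:
            pol_frames.append(polarity_scores(g))
        if cfg.colocalization:
            coloc_frames.append(colocalization_scores(
                g, min_marker=cfg.min_marker,
                min_neighborhood=cfg.min_neighborhood,
                n_perm=cfg.n_perm, seed=coloc_seed + int(g.component)))
    if cfg.polarity:
        df = (pd.concat(pol_frames, ignore_index=True) if pol_frames
              else pd.DataFrame())
        _write_table(df, out / "polarity.csv", cfg)
    if cfg.colocalization:
        df = (pd.concat(coloc_frames, ignore_index=True) if coloc_frames
              else pd.DataFrame())
        _write_table(df, out / "colocalization.csv", cfg)
    log.info("analyze: %d components scored", len(pol_frames) or
             len(coloc_frames))


def stage_layout(cfg: RunConfig) -> None:
    from .layout import density_table, fibonacci_sphere, layout_table

    out = Path(cfg.out_dir)
    _require(out / "components.tsv", "graph")
    layout_dir = out / "layouts"
    layout_dir.mkdir(exist_ok=True)
    grid = fibonacci_sphere(cfg.grid_points)
    seed = stage_seed(cfg.seed, "layout")
    for i, g in enumerate(_iter_retained_projections(out)):
        if i >= cfg.layout_max_cells:
            break
        tab = layout_table(g, seed=seed)
        _write_table(tab, layout_dir / f"component_{g.component}_layout.csv",
                     cfg)
        dens = density_table(g, tab[["sx", "sy", "sz"]].to_numpy(),
                             distance_cutoff=cfg.distance_cutoff, grid=grid)
        _write_table(dens, layout_dir / f"component_{g.component}_density.csv",
                     cfg)


STAGES = [
    ("simulate", stage_simulate),
    ("amplicon", stage_amplicon),
    ("graph", stage_graph),
    ("analyze", stage_analyze),
    ("layout", stage_layout),
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _require(path: Path, producer: str) -> None:
    if not Path(path).exists():
        raise FileNotFoundError(
            f"missing {path}; run the {producer} stage first")


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; returns the manifest dict.

    On stage failure, partial outputs are kept and the manifest records
    the failure point before the exception is re-raised.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "params_hash": config.params_hash(),
        "config": config.model_dump(),
        "stage_seeds": {name: stage_seed(config.seed, name)
                        for name in ("panel", "simulate", "amplicon",
                                     "leiden", "colocalization", "layout")},
        "stages_completed": [],
        "failed_stage": None,
    }
    for name, fn in STAGES:
        if name == "amplicon" and not config.amplicon:
            continue
        if name == "layout" and not config.layout:
            continue
        try:
            fn(config)
        except Exception as exc:
            manifest["failed_stage"] = name
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2)
            raise StageError(name, exc) from exc
        manifest["stages_completed"].append(name)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
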