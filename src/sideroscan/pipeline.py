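"""Pipeline orchestration: simulate -> blank-filter -> screen -> annotate
-> network -> report.

Every stage is independently callable from its own module; this module
wires them together behind a single config object whose defaults are the
published method parameters (matching tolerance 5 ppm / 0.003 Da, cosine
threshold R >= 0.7, >= 5 matched fragment ions, <= 10 neighbours per
node, top 5 peaks per 50 Da window, 0.1% intensity floor, 0.01% blank
area rule, contaminant m/z 202.080, scan range m/z 80-1500).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import __version__
from .annotate import (
    annotate_spectrum,
    default_library,
    load_library,
    score_hydroxamate_evidence,
)
from .features import MS1Feature, read_feature_table, write_feature_table
from .network import build_network, export_edge_table, export_graphml, export_node_table
from .screen import ScreenConfig, SiderophoreCandidate, screen_siderophores
from .simulate import ScenarioConfig, generate_scenario
from .spectra import (
    CONTAMINANT_MZ,
    FragmentSpectrum,
    filter_peaks,
    read_mgf,
    remove_contaminant,
    write_mgf,
)

logger = logging.getLogger("sideroscan")

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tolerances and thresholds of the pipeline, with method defaults."""

    # inputs: either simulate, or read these paths
    simulate: bool = True
    seed: int = 1
    sample_csv: Optional[str] = None
    sample_envelopes_csv: Optional[str] = None
    control_csv: Optional[str] = None
    spectra_mgf: Optional[str] = None
    library_csv: Optional[str] = None
    # matching tolerances ('5 p.p.m. or 0.003 Da', whichever larger)
    tol_ppm: float = 5.0
    tol_da: float = 0.003
    # blank subtraction
    blank_fraction: float = 1e-4
    # MS/MS hygiene
    contaminant_mz: float = CONTAMINANT_MZ
    top_k: int = 5
    window_da: float = 50.0
    min_rel_intensity: float = 0.001
    # networking
    cosine_min: float = 0.7
    min_matched: int = 5
    max_neighbors: int = 10
    intensity_transform: str = "sqrt"
    # screen
    require_apo: bool = True
    fe_ratio_window: Tuple[float, float] = (0.02, 0.15)
    fe_spacing_tol_mda: float = 5.0
    pair_rt_window: float = 2.0
    scan_range: Tuple[float, float] = (80.0, 1500.0)
    min_evidence_blocks: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fe_ratio_window" in raw:
            raw["fe_ratio_window"] = tuple(raw["fe_ratio_window"])
        if "scan_range" in raw:
            raw["scan_range"] = tuple(raw["scan_range"])
        return cls(**raw)

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            blank_threshold_fraction=self.blank_fraction,
            match_mz_tol_ppm=self.tol_ppm,
            fe_spacing_tol_mda=self.fe_spacing_tol_mda,
            fe_ratio_window=self.fe_ratio_window,
            pair_mz_tol_ppm=self.tol_ppm,
            pair_mz_tol_da=self.tol_da,
            pair_rt_window=self.pair_rt_window,
            require_apo=self.require_apo,
            formula_tol_ppm=self.tol_ppm,
        )


@dataclass
class RunReport:
    """Per-stage counts and the candidate table of one pipeline run."""

    version: str
    seed: int
    parameters: dict
    n_sample_features: int = 0
    n_control_features: int = 0
    n_after_blank_filter: int = 0
    n_iron_hits: int = 0
    n_apo_holo_pairs: int = 0
    n_candidates: int = 0
    n_spectra: int = 0
    n_network_nodes: int = 0
    n_network_edges: int = 0
    candidates: List[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def validate_config(cfg: PipelineConfig) -> List[str]:
    """Sanity-check a config; returns human-readable 'error:'/'warning:' strings."""
    issues: List[str] = []
    if not (0.0 <= cfg.cosine_min <= 1.0):
        issues.append(f"error: cosine_min must lie in [0, 1], got {cfg.cosine_min}")
    if cfg.min_matched < 1:
        issues.append(f"error: min_matched must be >= 1, got {cfg.min_matched}")
    if cfg.max_neighbors < 1:
        issues.append(f"error: max_neighbors must be >= 1, got {cfg.max_neighbors}")
    if cfg.tol_ppm <= 0 or cfg.tol_da <= 0:
        issues.append("error: tolerances must be positive")
    if cfg.top_k < 1 or cfg.window_da <= 0:
        issues.append("error: top_k must be >= 1 and window_da positive")
    if not (0.0 <= cfg.min_rel_intensity < 1.0):
        issues.append("error: min_rel_intensity must lie in [0, 1)")
    if cfg.blank_fraction < 0:
        issues.append("error: blank_fraction must be non-negative")
    if cfg.scan_range[0] >= cfg.scan_range[1]:
        issues.append("error: scan_range must be (low, high)")
    # deviations from the published defaults are legal but worth flagging
    published = {
        "cosine_min": 0.7, "min_matched": 5, "max_neighbors": 10, "top_k": 5,
        "window_da": 50.0, "min_rel_intensity": 0.001, "blank_fraction": 1e-4,
        "tol_ppm": 5.0, "tol_da": 0.003, "contaminant_mz": CONTAMINANT_MZ,
    }
    for key, default in published.items():
        value = getattr(cfg, key)
        if value != default:
            issues.append(f"warning: {key}={value} overrides the method default {default}")
    return issues


def _candidate_row(c: SiderophoreCandidate) -> dict:
    return {
        "apo_feature_id": c.apo_feature_id,
        "holo_feature_id": c.holo_feature_id,
        "apo_mz": round(c.apo_mz, 5),
        "holo_mz": round(c.holo_mz, 5),
        "apo_neutral_mass": round(c.apo_neutral_mass, 5),
        "rt_shift": round(c.pair.rt_shift, 3) if c.pair else None,
        "apo_fraction": round(c.pair.apo_fraction, 4) if c.pair else None,
        "fe_ratio": round(c.iron_hit.abundance_ratio, 4),
        "fe_spacing_error_mda": round(c.iron_hit.spacing_error_mda, 3),
        "top_formula": c.formulas[0].formula.hill() if c.formulas else None,
        "top_formula_ppm": round(c.formulas[0].mass_error_ppm, 3) if c.formulas else None,
        "n_formulas": len(c.formulas),
        "family_links": ";".join(
            f"{l.apo_a}~{l.apo_b}:{l.kind}" for l in c.family_links
        ),
        "hydroxamate_consistent": (c.msms_evidence or {}).get("hydroxamate_consistent"),
        "blocks_hit": ";".join((c.msms_evidence or {}).get("blocks_hit", [])),
    }


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> RunReport:
    """Execute all stages and write candidates, spectra, network and report."""
    errors = [m for m in validate_config(cfg) if m.startswith("error")]
    if errors:
        raise ValueError("; ".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        version=__version__, seed=cfg.seed, parameters=dataclasses.asdict(cfg)
    )

    # --- stage 1: obtain inputs ------------------------------------------
    if cfg.simulate:
        scenario = generate_scenario(ScenarioConfig(seed=cfg.seed), outdir=outdir)
        sample, control, spectra = scenario.sample, scenario.control, scenario.spectra
    else:
        if not cfg.sample_csv or not cfg.control_csv:
            raise ValueError("sample_csv and control_csv required when simulate=false")
        sample = read_feature_table(
            cfg.sample_csv, cfg.sample_envelopes_csv, scan_range=cfg.scan_range
        )
        control = read_feature_table(cfg.control_csv, scan_range=cfg.scan_range)
        spectra = read_mgf(cfg.spectra_mgf) if cfg.spectra_mgf else []
    report.n_sample_features = len(sample)
    report.n_control_features = len(control)
    report.n_spectra = len(spectra)
    logger.info("inputs: %d sample features, %d control features, %d spectra",
                len(sample), len(control), len(spectra))

    # --- stage 2+3: screen (blank filter inside) --------------------------
    from .features import blank_filter
    from .screen import find_iron_pattern_hits, pair_apo_holo

    scfg = cfg.screen_config()
    retained = blank_filter(
        sample, control,
        threshold_fraction=scfg.blank_threshold_fraction,
        mz_tol_ppm=scfg.match_mz_tol_ppm, rt_tol=scfg.match_rt_tol,
    )
    report.n_after_blank_filter = len(retained)
    report.n_iron_hits = len(
        find_iron_pattern_hits(
            retained, spacing_tol_mda=scfg.fe_spacing_tol_mda,
            ratio_window=scfg.fe_ratio_window, coelute_rt_tol=scfg.coelute_rt_tol,
        )
    )
    report.n_apo_holo_pairs = len(
        pair_apo_holo(
            retained, mz_tol_ppm=scfg.pair_mz_tol_ppm,
            mz_tol_da=scfg.pair_mz_tol_da, rt_window=scfg.pair_rt_window,
        )
    )
    candidates = screen_siderophores(sample, control, scfg)
    logger.info("screen: %d retained, %d iron hits, %d pairs, %d candidates",
                len(retained), report.n_iron_hits, report.n_apo_holo_pairs,
                len(candidates))

    # --- stage 4: MS/MS hygiene + annotation ------------------------------
    library = load_library(cfg.library_csv) if cfg.library_csv else default_library()
    clean: List[FragmentSpectrum] = []
    for s in spectra:
        s2 = remove_contaminant(s, contaminant_mz=cfg.contaminant_mz, tol_da=cfg.tol_da)
        s2 = filter_peaks(
            s2, top_k=cfg.top_k, window_da=cfg.window_da,
            min_rel_intensity=cfg.min_rel_intensity,
        )
        clean.append(s2)
    by_feature = {s.feature_id: s for s in clean}
    for c in candidates:
        s = by_feature.get(c.apo_feature_id) or by_feature.get(c.holo_feature_id)
        if s is None:
            continue
        hits = annotate_spectrum(s, library, tol_ppm=cfg.tol_ppm, tol_da=cfg.tol_da)
        c.msms_evidence = score_hydroxamate_evidence(
            s, hits, min_distinct_blocks=cfg.min_evidence_blocks
        ).as_dict()
    report.n_candidates = len(candidates)

    # --- stage 5: molecular network ---------------------------------------
    sider_ids = {c.apo_feature_id for c in candidates} | {
        c.holo_feature_id for c in candidates
    }
    node_attrs: Dict[str, dict] = {}
    areas = {f.feature_id: f.area for f in sample}
    for s in clean:
        key = s.feature_id or s.spectrum_id
        node_attrs[key] = {
            "area": areas.get(key, 0.0),
            "siderophore": key in sider_ids,
        }
    graph = build_network(
        clean, score_min=cfg.cosine_min, min_matched=cfg.min_matched,
        max_neighbors=cfg.max_neighbors, tol_ppm=cfg.tol_ppm, tol_da=cfg.tol_da,
        transform=cfg.intensity_transform, node_attrs=node_attrs,
    )
    report.n_network_nodes = graph.number_of_nodes()
    report.n_network_edges = graph.number_of_edges()
    logger.info("network: %d nodes, %d edges",
                report.n_network_nodes, report.n_network_edges)

    # --- stage 6: outputs --------------------------------------------------
    import pandas as pd

    report.candidates = [_candidate_row(c) for c in candidates]
    pd.DataFrame(
        report.candidates,
        columns=list(_candidate_row(candidates[0]).keys()) if candidates else None,
    ).to_csv(outdir / "candidates.csv", index=False)
    write_feature_table(retained, outdir / "features_filtered.csv")
    if clean:
        write_mgf(clean, outdir / "spectra_filtered.mgf")
    export_graphml(graph, outdir / "network.graphml")
    export_edge_table(graph, outdir / "edges.csv")
    export_node_table(graph, outdir / "nodes.csv")
    report.to_json(outdir / "report.json")
    return report
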