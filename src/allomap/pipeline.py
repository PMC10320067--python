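"""End-to-end orchestration: structure in, full allostery map out.

Stage order: load -> (optional redundant-chain removal) -> orthosteric
ligand selection -> pocket detection -> apo/holo elastic networks ->
per-pocket RAE -> feature extraction -> classification -> top-RAE sinks
-> residue graph -> shortest pathways -> hierarchy -> coupling matrix.
Deterministic for a fixed (config, model, input) triple.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field

import networkx as nx
import numpy as np
import yaml

from . import __version__
from .enm_dynamics import (
    DEFAULT_CUTOFF,
    build_enm,
    cross_correlation,
    mean_square_fluctuation,
)
from .errors import AllomapError, ConfigError, PipelineError
from .pathway_coupling import (
    CouplingMatrix,
    RegulationPathway,
    build_hierarchy,
    build_residue_graph,
    coupling_matrix,
    export_coupling,
    export_pathways,
    hierarchy_to_graph,
)
from .pocket_finder import (
    PocketParams,
    compute_descriptors,
    detect_pockets,
    export_pockets,
    flag_orthosteric_overlap,
    viewer_selection,
)
from .rae_profile import (
    export_rae_table,
    interaction_matrix,
    residue_rae,
    top_rae_residue,
)
from .site_classifier import (
    extract_features,
    load_model,
    predict_sites,
)
from .structure_io import (
    DEFAULT_MAX_BYTES,
    load_structure,
    make_apo,
    remove_redundant_chains,
    select_orthosteric_ligand,
)


@dataclass
class RunConfig:
    input_path: str
    ligand_spec: str = ""
    model_path: str = ""
    output_dir: str = "allomap_out"
    remove_redundant: bool = False
    identity_threshold: float = 0.95
    enm_cutoff: float = DEFAULT_CUTOFF
    probe_min: float = 3.0
    probe_max: float = 6.0
    cluster_distance: float = 4.5
    lining_cutoff: float = 5.0
    min_lining: int = 4
    orthosteric_contact_cutoff: float = 4.5
    decision_threshold: float = 0.5
    max_size_bytes: int = DEFAULT_MAX_BYTES
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "input_path" not in data:
            raise ConfigError("config must set input_path")
        return cls(**data)

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    config: RunConfig
    structure_label: str
    chains_kept: list[str]
    ligand: str
    pockets: list
    descriptors: dict
    rae_profiles: dict
    features: list
    predictions: list
    pathways: list[RegulationPathway]
    hierarchy: object | None
    coupling: CouplingMatrix | None
    timings: dict = field(default_factory=dict)
    failure: str | None = None


def run_pipeline(cfg: RunConfig, model=None) -> RunReport:
    """Execute the full workflow; stage failures raise
    :class:`PipelineError` naming the stage."""
    t0 = time.perf_counter()
    timings = {}

    def stage(name, fn):
        t = time.perf_counter()
        try:
            out = fn()
        except AllomapError as exc:
            raise PipelineError(name, exc) from exc
        timings[name] = round(time.perf_counter() - t, 4)
        return out

    s = stage("load_structure", lambda: load_structure(
        cfg.input_path, max_size=cfg.max_size_bytes))
    if cfg.remove_redundant:
        s = stage("remove_redundant_chains", lambda: remove_redundant_chains(
            s, cfg.identity_threshold))
    lig = stage("select_ligand", lambda: select_orthosteric_ligand(
        s, cfg.ligand_spec))
    # the apo structure: same protein coordinates, orthosteric ligand removed
    apo = stage("make_apo", lambda: make_apo(s, lig))

    params = PocketParams(
        probe_min=cfg.probe_min, probe_max=cfg.probe_max,
        cluster_distance=cfg.cluster_distance, lining_cutoff=cfg.lining_cutoff,
        min_lining=cfg.min_lining,
    )
    pockets = stage("detect_pockets", lambda: detect_pockets(apo, params))
    pockets = stage("flag_orthosteric", lambda: flag_orthosteric_overlap(
        pockets, lig, cfg.orthosteric_contact_cutoff))

    # apo network: protein only; holo network: protein + ligand pseudo-node
    net_apo = stage("enm_apo", lambda: build_enm(apo, None, cfg.enm_cutoff))
    net_holo = stage("enm_holo", lambda: build_enm(apo, lig, cfg.enm_cutoff))
    c_apo = stage("correlation_apo", lambda: cross_correlation(net_apo))
    c_holo = stage("correlation_holo", lambda: cross_correlation(net_holo))
    msf = stage("fluctuations", lambda: mean_square_fluctuation(net_holo))
    flex = msf.msf[: apo.n_residues]

    descriptors, profiles, features = {}, {}, []
    for p in pockets:
        d = compute_descriptors(p, apo, flex)
        i_apo = interaction_matrix(c_apo, p, "apo")
        i_holo = interaction_matrix(c_holo, p, "holo")
        prof = residue_rae(i_apo, i_holo)
        descriptors[p.pocket_id] = d
        profiles[p.pocket_id] = prof
        if not p.overlaps_orthosteric:
            features.append(extract_features(p, d, prof))

    if model is None and cfg.model_path:
        model = load_model(cfg.model_path)
    if model is None:
        raise PipelineError("classify", ConfigError(
            "no trained model supplied (model_path empty)"))
    predictions = stage("classify", lambda: predict_sites(
        model, features, threshold=cfg.decision_threshold))

    positive = [pr for pr in predictions if pr.is_allosteric]
    pathways, hierarchy, coupling = [], None, None
    if positive:
        graph = stage("residue_graph", lambda: build_residue_graph(
            net_holo, c_holo))

        def make_pathways():
            out = []
            from .pathway_coupling import shortest_pathway
            for pr in positive:
                sink = top_rae_residue(profiles[pr.pocket_id])
                out.append(shortest_pathway(graph, sink, pr.pocket_id))
            return out

        pathways = stage("pathways", make_pathways)
        hierarchy = stage("hierarchy", lambda: build_hierarchy(pathways))
        coupling = stage("coupling", lambda: coupling_matrix(pathways))

    timings["total"] = round(time.perf_counter() - t0, 4)
    return RunReport(
        config=cfg,
        structure_label=s.source_label,
        chains_kept=sorted(s.chains),
        ligand=str(lig),
        pockets=pockets,
        descriptors=descriptors,
        rae_profiles=profiles,
        features=features,
        predictions=predictions,
        pathways=pathways,
        hierarchy=hierarchy,
        coupling=coupling,
        timings=timings,
    )


def write_report(report: RunReport, out_dir: str) -> dict:
    """Write the report files; returns a manifest {filename: sha256}."""
    os.makedirs(out_dir, exist_ok=True)
    pred_by_id = {p.pocket_id: p for p in report.predictions}

    lines = ["pocket_id\tconfidence\tis_allosteric\toverlaps_orthosteric"
             "\thydrophobicity\tflexibility\tpocket_rae\tn_lining\tlining_residues"]
    ordered = sorted(
        report.pockets,
        key=lambda p: -(pred_by_id[p.pocket_id].confidence
                        if p.pocket_id in pred_by_id else -1.0),
    )
    for p in ordered:
        d = report.descriptors[p.pocket_id]
        prof = report.rae_profiles[p.pocket_id]
        pr = pred_by_id.get(p.pocket_id)
        conf = f"{pr.confidence:.6f}" if pr else "NA"
        call = str(int(pr.is_allosteric)) if pr else "NA"
        lining = ",".join(str(r) for r in sorted(p.lining_residues))
        lines.append(
            f"{p.pocket_id}\t{conf}\t{call}\t{int(p.overlaps_orthosteric)}"
            f"\t{d.hydrophobicity:.4f}\t{d.flexibility:.4f}\t{prof.pocket_rae:.6f}"
            f"\t{len(p.lining_residues)}\t{lining}"
        )
    _write(out_dir, "sites.tsv", "\n".join(lines) + "\n")

    _write(out_dir, "rae_per_site.tsv",
           export_rae_table(list(report.rae_profiles.values())))
    _write(out_dir, "pathways.tsv", export_pathways(report.pathways))
    if report.hierarchy is not None:
        nx.write_graphml(hierarchy_to_graph(report.hierarchy),
                         os.path.join(out_dir, "hierarchy.graphml"))
    else:
        _write(out_dir, "hierarchy.graphml",
               '<?xml version="1.0"?><graphml/>\n')
    if report.coupling is not None:
        _write(out_dir, "coupling.tsv", export_coupling(report.coupling))
    else:
        _write(out_dir, "coupling.tsv", "site\n")
    _write(out_dir, "viewer_selections.txt", "".join(
        f"pocket_{p.pocket_id}\t{viewer_selection(p)}\n" for p in report.pockets))
    _write(out_dir, "pockets.tsv", export_pockets(report.pockets))

    provenance = {
        "version": __version__,
        "config": asdict(report.config),
        "config_digest": report.config.digest(),
        "structure": report.structure_label,
        "chains_kept": report.chains_kept,
        "orthosteric_ligand": report.ligand,
        "n_pockets": len(report.pockets),
        "n_predicted_sites": sum(p.is_allosteric for p in report.predictions),
        "timings_s": report.timings,
        "failure": report.failure,
    }
    _write(out_dir, "provenance.json", json.dumps(provenance, indent=1) + "\n")

    manifest = {}
    for name in sorted(os.listdir(out_dir)):
        if name == "manifest.json":
            continue
        with open(os.path.join(out_dir, name), "rb") as fh:
            manifest[name] = hashlib.sha256(fh.read()).hexdigest()
    _write(out_dir, "manifest.json", json.dumps(manifest, indent=1) + "\n")
    return manifest


def _write(out_dir: str, name: str, text: str) -> None:
    with open(os.path.join(out_dir, name), "w") as fh:
        fh.write(text)
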