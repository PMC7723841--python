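"""Config-driven end-to-end runner.

Stages run in a fixed order: read → consensus → network → library
annotation → curation → propagation → export. Library annotation runs
before curation because the artifact rule anchors on annotated standard
nodes. Every stage logs its input/output counts; all outputs record the
configuration hash; a manifest lists every file written. Runs are fully
deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional

import pandas as pd
import yaml

from . import annotation as ann
from .consensus import cluster_scans
from .curation import CurationParams, curate
from .library import load_standard_library
from .network import MolecularNetwork, NetworkParams, build_network, export_graphml, export_tables
from .similarity import SimilarityParams
from .spectra_io import Spectrum, assign_groups, read_mgf
from .synthetic import SimulationConfig, SimulationResult, simulate_run

log = logging.getLogger("molnet")


@dataclass(frozen=True)
class ConsensusParams:
    precursor_tol: float = 0.02
    rt_window: float = 30.0
    min_score: float = 0.7
    fragment_tol: float = 0.02


@dataclass(frozen=True)
class AnnotationParams:
    min_score: float = 0.7
    min_matched: int = 6
    precursor_tol: float = 0.02
    decomposition_tol: float = 0.005


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults are the workflow's stated values
    (0.02 Da tolerances, cosine 0.7, 6 matched ions, 1e7 intensity floor,
    1 % Rt window)."""

    scenario: str = "seizureB"
    seed: int = 0
    out_dir: str = "molnet_out"
    inputs: dict[str, str] = field(default_factory=dict)  # mgf path -> group
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    similarity: SimilarityParams = field(default_factory=SimilarityParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    curation: CurationParams = field(default_factory=CurationParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)

    def __post_init__(self) -> None:
        # the seed flows into the simulation block unless set there explicitly
        if self.simulation.seed != self.seed:
            self.simulation = dataclasses.replace(self.simulation, seed=self.seed)
        self.network = dataclasses.replace(self.network, similarity=self.similarity)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        sections = {
            "simulation": SimulationConfig,
            "consensus": ConsensusParams,
            "similarity": SimilarityParams,
            "network": NetworkParams,
            "curation": CurationParams,
            "annotation": AnnotationParams,
        }
        top_fields = {f.name for f in dataclasses.fields(cls)}
        for key, value in data.items():
            if key not in top_fields:
                raise KeyError(f"unknown config key {key!r}")
            if key in sections:
                sub = sections[key]
                sub_fields = {f.name for f in dataclasses.fields(sub)}
                for k in value:
                    if k not in sub_fields:
                        raise KeyError(f"unknown config key {key}.{k}")
                value = sub(**{k: _coerce(v) for k, v in value.items()})
            kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, (tuple, list)):
                return [enc(x) for x in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return enc(self)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so reruns of
        the same configuration hash identically wherever they write)."""
        data = self.to_dict()
        data.pop("out_dir", None)
        data.pop("inputs", None)
        blob = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _coerce(v):
    return tuple(v) if isinstance(v, list) else v


@dataclass
class PipelineResult:
    config: PipelineConfig
    network: MolecularNetwork  # full network, pre-curation
    cleaned: MolecularNetwork
    annotations: dict[int, str]
    hypotheses: list[ann.AnnotationHypothesis]
    removal_log: pd.DataFrame
    report: pd.DataFrame
    outputs: dict[str, str]  # name -> path
    truth: Optional[list] = None


def run_simulate(config: PipelineConfig) -> SimulationResult:
    """Generate the scenario's MGF fixture set under ``out_dir``/mgf."""
    mgf_dir = os.path.join(config.out_dir, "mgf")
    result = simulate_run(config.simulation, config.scenario, mgf_dir)
    log.info(
        "simulate: scenario=%s seed=%d -> %d files",
        config.scenario, config.simulation.seed, len(result.files),
    )
    return result


def run_network(
    config: PipelineConfig, inputs: Mapping[str, str] | None = None
) -> PipelineResult:
    """Run the full networking pipeline over labelled MGF inputs."""
    files = dict(inputs if inputs is not None else config.inputs)
    if not files:
        raise KeyError("config key 'inputs' is empty: provide mgf-path -> group entries")
    os.makedirs(config.out_dir, exist_ok=True)
    chash = config.config_hash()

    spectra: list[Spectrum] = []
    for path in sorted(files):
        spectra.extend(read_mgf(path))
    spectra = assign_groups(files, spectra)
    log.info("read: %d files -> %d scans", len(files), len(spectra))

    cp = config.consensus
    nodes = cluster_scans(
        spectra,
        precursor_tol=cp.precursor_tol,
        rt_window=cp.rt_window,
        min_score=cp.min_score,
        fragment_tol=cp.fragment_tol,
        sim_params=config.similarity,
    )
    log.info("consensus: %d scans -> %d nodes", len(spectra), len(nodes))

    net = build_network(nodes, config.network)
    log.info("network: %d nodes, %d edges", len(net.nodes), len(net.edges))

    ap = config.annotation
    library = ann.build_library(nodes, load_standard_library(), ap.precursor_tol)
    hits = ann.annotate_nodes(
        net, library, ap.min_score, ap.min_matched, ap.precursor_tol, config.similarity
    )
    ann.flag_all(net)
    log.info("annotate: %d library hits from %d entries", len(hits), len(library))

    cleaned, removal_log = curate(net, set(hits), config.curation)
    log.info(
        "curate: %d -> %d nodes (%d removed)",
        len(net.nodes), len(cleaned.nodes), len(removal_log),
    )

    hypotheses = ann.propagate_annotations(
        cleaned, cleaned.annotations, ap.decomposition_tol
    )
    log.info("propagate: %d hypotheses", len(hypotheses))

    out = {
        "graphml": os.path.join(config.out_dir, "network.graphml"),
        "nodes_tsv": os.path.join(config.out_dir, "nodes.tsv"),
        "edges_tsv": os.path.join(config.out_dir, "edges.tsv"),
        "report_tsv": os.path.join(config.out_dir, "report.tsv"),
        "removal_tsv": os.path.join(config.out_dir, "removed.tsv"),
    }
    export_graphml(cleaned, out["graphml"], config_hash=chash)
    export_tables(cleaned, out["nodes_tsv"], out["edges_tsv"], config_hash=chash)
    report_df = ann.report(cleaned, path=out["report_tsv"], hypotheses=hypotheses, config_hash=chash)
    with open(out["removal_tsv"], "w", newline="\n") as fh:
        fh.write(f"# config_hash={chash}\n")
        removal_log.to_csv(fh, sep="\t", index=False)

    return PipelineResult(
        config=config,
        network=net,
        cleaned=cleaned,
        annotations=dict(cleaned.annotations),
        hypotheses=hypotheses,
        removal_log=removal_log,
        report=report_df,
        outputs=out,
    )


def run_all(config: PipelineConfig) -> PipelineResult:
    """Simulate the scenario, run the network pipeline, write a manifest."""
    sim = run_simulate(config)
    result = run_network(config, inputs=sim.files)
    result.truth = sim.truth
    result.outputs["mgf"] = sim.out_dir
    manifest = {
        "config_hash": config.config_hash(),
        "scenario": config.scenario,
        "seed": config.seed,
        "outputs": sorted(list(sim.files) + [p for p in result.outputs.values()]),
    }
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    result.outputs["manifest"] = manifest_path
    return result
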