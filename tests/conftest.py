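from __future__ import annotations

import pytest

from molnet.network import NetworkParams
from molnet.pipeline import PipelineConfig, run_all

#: Pruning disabled so component-membership checks see the raw gated graph.
UNPRUNED = dict(top_k=None, max_component_size=None)


def run_scenario(scenario: str, seed: int, out_dir) -> "molnet.pipeline.PipelineResult":
    cfg = PipelineConfig(
        scenario=scenario,
        seed=seed,
        out_dir=str(out_dir),
        network=NetworkParams(**UNPRUNED),
    )
    return run_all(cfg)


@pytest.fixture(scope="session")
def standards_result(tmp_path_factory):
    """Standards-mixture scenario (G1 triplicates + in-source artifacts)."""
    return run_scenario("standards", 7, tmp_path_factory.mktemp("std"))


@pytest.fixture(scope="session")
def seizure_result(tmp_path_factory):
    """Full study: standards plus both seizure extracts (G1+G2+G3)."""
    return run_scenario("seizureB", 7, tmp_path_factory.mktemp("seizure"))


def node_by_precursor(net, mz, rt=None, tol=0.02):
    hits = [n for n in net.nodes if abs(n.precursor_mz - mz) <= tol]
    if rt is not None:
        hits = [n for n in hits if abs(n.rt - rt) <= 30.0]
    assert hits, f"no node at m/z {mz}"
    assert len(hits) == 1, f"ambiguous node at m/z {mz}"
    return hits[0]
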