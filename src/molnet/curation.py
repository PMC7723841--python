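"""Node-cleaning rules: intensity filtering and in-source artifact removal.

Untargeted networks of standard mixtures accumulate nodes that are not
distinct analytes: low-intensity features, adducts and in-source
fragments of the standards. Two rules remove them:

* a precursor-intensity floor (default 1e7, arbitrary units);
* an artifact rule anchored on annotated standards — an unannotated node
  is flagged when it co-elutes with a standard (mean Rt within 1 %) AND
  shows either an undetermined (0) precursor charge or a precursor mass
  at the standard's [M−1] (here [M+H]+ − 1.0078, the mass of a hydrogen
  atom; tolerance reuses the 0.02 Da precursor window).

Co-elution alone never flags: genuine compounds can share elution; the
mass/charge evidence must concur. Filters are idempotent and applied in
a fixed order (intensity first, then artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .network import MolecularNetwork


@dataclass(frozen=True)
class CurationParams:
    intensity_threshold: float = 1e7
    rt_fraction: float = 0.01
    m_minus_tol: float = 0.02
    hydrogen_mass: float = 1.0078
    exempt_annotated: bool = True  # annotated standards ignore the intensity floor

    def __post_init__(self) -> None:
        for name in ("intensity_threshold", "rt_fraction", "m_minus_tol", "hydrogen_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ArtifactFlag:
    node_id: int
    reasons: frozenset[str]  # subset of {rt_coelution, charge_zero, m_minus_one}
    parent_standard: Optional[int] = None


def filter_by_intensity(
    net: MolecularNetwork,
    threshold: float = 1e7,
    exempt: Iterable[int] = (),
) -> tuple[MolecularNetwork, list[int]]:
    """Drop nodes below the precursor-intensity floor (with their edges).

    ``exempt`` node ids (typically annotated standards) are always kept.
    Idempotent.
    """
    exempt = set(exempt)
    removed = [
        n.node_id
        for n in net.nodes
        if n.precursor_intensity < threshold and n.node_id not in exempt
    ]
    keep = {n.node_id for n in net.nodes} - set(removed)
    return net.subset(keep), removed


def flag_artifacts(
    net: MolecularNetwork,
    standards: Iterable[int],
    params: CurationParams = CurationParams(),
) -> list[ArtifactFlag]:
    """Flag unannotated nodes that look like in-source artifacts of a
    standard: Rt within ``rt_fraction`` of the standard AND (charge 0 OR
    precursor at the standard's [M−1]). With no standards, returns no
    flags."""
    standard_ids = set(standards)
    anchors = [n for n in net.nodes if n.node_id in standard_ids]
    flags: list[ArtifactFlag] = []
    for node in net.nodes:
        if node.node_id in standard_ids:
            continue
        best: Optional[ArtifactFlag] = None
        best_dt = None
        for std in anchors:
            if std.rt <= 0:
                continue
            dt = abs(node.rt - std.rt)
            if dt / std.rt > params.rt_fraction:
                continue
            reasons = {"rt_coelution"}
            if node.precursor_charge == 0:
                reasons.add("charge_zero")
            m_minus = std.precursor_mz - params.hydrogen_mass
            if abs(node.precursor_mz - m_minus) <= params.m_minus_tol:
                reasons.add("m_minus_one")
            if len(reasons) == 1:  # co-elution alone is not evidence
                continue
            if best is None or dt < best_dt:
                best = ArtifactFlag(
                    node_id=node.node_id,
                    reasons=frozenset(reasons),
                    parent_standard=std.node_id,
                )
                best_dt = dt
        if best is not None:
            flags.append(best)
    return flags


def clean_network(
    net: MolecularNetwork, flags: Sequence[ArtifactFlag]
) -> tuple[MolecularNetwork, pd.DataFrame]:
    """Remove flagged nodes and incident edges; return the removal log."""
    ids = {n.node_id for n in net.nodes}
    for f in flags:
        if f.node_id not in ids:
            raise KeyError(f"flag references unknown node {f.node_id}")
    drop = {f.node_id for f in flags}
    log = pd.DataFrame(
        [
            {
                "node_id": f.node_id,
                "reasons": ",".join(sorted(f.reasons)),
                "parent_standard": "" if f.parent_standard is None else f.parent_standard,
            }
            for f in sorted(flags, key=lambda f: f.node_id)
        ],
        columns=["node_id", "reasons", "parent_standard"],
    )
    return net.subset(ids - drop), log


def curate(
    net: MolecularNetwork,
    standards: Iterable[int],
    params: CurationParams = CurationParams(),
) -> tuple[MolecularNetwork, pd.DataFrame]:
    """Fixed-order curation: intensity floor, then artifact removal.

    Returns the cleaned network and a combined removal log with a
    ``stage`` column.
    """
    standards = set(standards)
    exempt = standards if params.exempt_annotated else set()
    net1, removed = filter_by_intensity(net, params.intensity_threshold, exempt)
    rows = [
        {"stage": "intensity", "node_id": i, "reasons": "low_intensity", "parent_standard": ""}
        for i in sorted(removed)
    ]
    flags = flag_artifacts(net1, standards, params)
    net2, log2 = clean_network(net1, flags)
    if not log2.empty:
        log2.insert(0, "stage", "artifact")
        rows.extend(log2.to_dict("records"))
    return net2, pd.DataFrame(rows, columns=["stage", "node_id", "reasons", "parent_standard"])
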