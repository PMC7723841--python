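"""Library matching, diagnostic class flags and delta-mass propagation.

The standards mixture acts as a self-anchored spectral library: each
library entry pairs a compound record with a reference spectrum taken
from the G1 consensus of the same run. Unknown nodes that fail library
matching but sit next to an annotated anchor inherit a structural
hypothesis: the signed precursor mass difference is decomposed into
candidate elemental changes and rendered as "<anchor> + C5H2O2"-style
labels — the reasoning that turns, e.g., a 94.005 Da gap from a
despropionyl para-fluorofentanyl anchor into a putative
para-fluorofuranylfentanyl.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .consensus import ConsensusSpectrum
from .library import DIAGNOSTIC_FRAGMENTS, CompoundRecord
from .masscalc import DecompositionCandidate, decompose_delta
from .network import MolecularNetwork
from .similarity import SimilarityParams, modified_cosine
from .spectra_io import Spectrum
from .synthetic import theoretical_peaks


@dataclass(frozen=True)
class LibraryEntry:
    record: CompoundRecord
    spectrum: ConsensusSpectrum | Spectrum

    def __post_init__(self) -> None:
        if len(self.spectrum.peaks) == 0:
            raise ValueError(f"{self.record.name}: empty reference spectrum")


@dataclass(frozen=True)
class LibraryHit:
    entry: LibraryEntry
    score: float
    n_matched: int


@dataclass
class AnnotationHypothesis:
    """Putative identity of an unknown node from an annotated anchor."""

    node_id: int
    anchor_node_id: int
    anchor_name: str
    delta_mass: float  # node precursor − anchor precursor, signed
    delta_formulas: list[DecompositionCandidate]
    class_flags: frozenset[str]
    proposed_label: str
    cosine_to_anchor: float


def library_from_records(records: Iterable[CompoundRecord]) -> list[LibraryEntry]:
    """Theoretical-spectrum library (noise-free peak lists); useful when no
    standards run is available."""
    entries = []
    for r in records:
        peaks = theoretical_peaks(r)
        spec = Spectrum(
            scan_id=f"library:{r.name}",
            precursor_mz=r.precursor_mz,
            peaks=peaks,
            precursor_charge=1,
            rt=r.rt,
        )
        entries.append(LibraryEntry(record=r, spectrum=spec))
    return entries


def build_library(
    nodes: Sequence[ConsensusSpectrum],
    records: Iterable[CompoundRecord],
    precursor_tol: float = 0.02,
    rt_window: float = 30.0,
    group: str = "G1",
) -> list[LibraryEntry]:
    """Self-anchored library: attach each standard record to its consensus
    node from the standards group (nearest Rt among precursor matches)."""
    entries = []
    for r in records:
        candidates = [
            n
            for n in nodes
            if group in n.groups
            and abs(n.precursor_mz - r.precursor_mz) <= precursor_tol
            and abs(n.rt - r.rt) <= rt_window
        ]
        if not candidates:
            continue
        node = min(candidates, key=lambda n: abs(n.rt - r.rt))
        entries.append(LibraryEntry(record=r, spectrum=node))
    return entries


def library_match(
    node: ConsensusSpectrum,
    library: Sequence[LibraryEntry],
    min_score: float = 0.7,
    min_matched: int = 6,
    precursor_tol: float = 0.02,
    sim_params: SimilarityParams | None = None,
) -> Optional[LibraryHit]:
    """Best library entry with a matching precursor that clears both the
    cosine and matched-ion gates; None when nothing qualifies."""
    if not library:
        raise ValueError("library is empty")
    params = sim_params or SimilarityParams()
    best: Optional[LibraryHit] = None
    for entry in library:
        if abs(entry.spectrum.precursor_mz - node.precursor_mz) > precursor_tol:
            continue
        res = modified_cosine(node, entry.spectrum, params)
        if res.score < min_score or res.n_matched < min_matched:
            continue
        if best is None or res.score > best.score:
            best = LibraryHit(entry=entry, score=res.score, n_matched=res.n_matched)
    return best


def annotate_nodes(
    net: MolecularNetwork,
    library: Sequence[LibraryEntry],
    min_score: float = 0.7,
    min_matched: int = 6,
    precursor_tol: float = 0.02,
    sim_params: SimilarityParams | None = None,
) -> dict[int, LibraryHit]:
    """Library-match every node; store names on the network and return
    the hits by node id."""
    hits: dict[int, LibraryHit] = {}
    for node in net.nodes:
        hit = library_match(node, library, min_score, min_matched, precursor_tol, sim_params)
        if hit is not None:
            hits[node.node_id] = hit
            net.annotations[node.node_id] = hit.entry.record.name
    return hits


def class_flags(
    node: ConsensusSpectrum,
    diagnostics: Mapping[str, Sequence[float]] = DIAGNOSTIC_FRAGMENTS,
    frag_tol: float = 0.01,
    require_all: bool = True,
) -> frozenset[str]:
    """Scaffold-class flags from diagnostic fragment ions.

    A class is flagged when all (default) or any of its diagnostic
    fragments are present within ``frag_tol``.
    """
    if not diagnostics:
        raise ValueError("diagnostics map is empty")
    mzs = [p.mz for p in node.peaks]
    out = set()
    for name, frags in diagnostics.items():
        present = [any(abs(mz - f) <= frag_tol for mz in mzs) for f in frags]
        if (all(present) if require_all else any(present)) and present:
            out.add(name)
    return frozenset(out)


def flag_all(
    net: MolecularNetwork,
    diagnostics: Mapping[str, Sequence[float]] = DIAGNOSTIC_FRAGMENTS,
    frag_tol: float = 0.01,
    require_all: bool = True,
) -> dict[int, frozenset[str]]:
    flags = {
        n.node_id: class_flags(n, diagnostics, frag_tol, require_all) for n in net.nodes
    }
    net.class_flags.update(flags)
    return flags


def _label(anchor: str, formulas: list[DecompositionCandidate]) -> str:
    if not formulas:
        return ""
    top = formulas[0].formula
    s = top.signed_string()
    if s.startswith("+") and "-" not in s:
        return f"{anchor} + {s[1:]}"
    if s.startswith("-") and "+" not in s:
        return f"{anchor} - {s[1:]}"
    return f"{anchor} {s}"


def propagate_annotations(
    net: MolecularNetwork,
    annotations: Mapping[int, str],
    decomposition_tol: float = 0.005,
    bounds: Mapping[str, tuple[int, int]] | None = None,
) -> list[AnnotationHypothesis]:
    """One hypothesis per (unannotated node, annotated neighbor) edge.

    The delta mass is taken from the consensus precursors; its elemental
    decompositions are ranked by mass error, and the rank-1 formula names
    the proposed label. Hypotheses are sorted by node id, then descending
    cosine to the anchor. The best label per node is stored on the
    network for reporting.
    """
    index = {n.node_id: n for n in net.nodes}
    hypotheses: list[AnnotationHypothesis] = []
    for edge in net.edges:
        for node_id, anchor_id in ((edge.node_a, edge.node_b), (edge.node_b, edge.node_a)):
            if node_id in annotations or anchor_id not in annotations:
                continue
            node, anchor = index[node_id], index[anchor_id]
            delta = node.precursor_mz - anchor.precursor_mz
            formulas = decompose_delta(delta, decomposition_tol, bounds)
            hypotheses.append(
                AnnotationHypothesis(
                    node_id=node_id,
                    anchor_node_id=anchor_id,
                    anchor_name=annotations[anchor_id],
                    delta_mass=delta,
                    delta_formulas=formulas,
                    class_flags=net.class_flags.get(node_id, frozenset()),
                    proposed_label=_label(annotations[anchor_id], formulas),
                    cosine_to_anchor=edge.cosine,
                )
            )
    hypotheses.sort(key=lambda h: (h.node_id, -h.cosine_to_anchor, h.anchor_node_id))
    for h in hypotheses:
        if h.proposed_label and h.node_id not in net.hypothesis_labels:
            net.hypothesis_labels[h.node_id] = h.proposed_label
    return hypotheses


def report(
    net: MolecularNetwork,
    annotations: Mapping[int, str] | None = None,
    hypotheses: Sequence[AnnotationHypothesis] = (),
    path: str | os.PathLike | None = None,
    config_hash: str = "",
) -> pd.DataFrame:
    """Node inventory: precursor m/z (3 d.p.), Rt, groups and the best
    available identity (library ID, propagated label, or "unknown")."""
    annotations = dict(annotations or net.annotations)
    best_label = dict(net.hypothesis_labels)
    for h in sorted(hypotheses, key=lambda h: (h.node_id, -h.cosine_to_anchor)):
        if h.proposed_label:
            best_label.setdefault(h.node_id, h.proposed_label)
    rows = []
    for n in sorted(net.nodes, key=lambda n: (n.precursor_mz, n.rt)):
        identity = annotations.get(n.node_id) or best_label.get(n.node_id) or "unknown"
        kind = (
            "library"
            if n.node_id in annotations
            else ("propagated" if n.node_id in best_label else "none")
        )
        rows.append(
            {
                "node_id": n.node_id,
                "precursor_mz": f"{n.precursor_mz:.3f}",
                "rt_s": f"{n.rt:.2f}",
                "groups": ",".join(sorted(n.groups)),
                "id": identity,
                "id_source": kind,
                "class_flags": ",".join(sorted(net.class_flags.get(n.node_id, ()))),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["node_id", "precursor_mz", "rt_s", "groups", "id", "id_source", "class_flags"],
    )
    if path is not None:
        with open(path, "w", newline="\n") as fh:
            if config_hash:
                fh.write(f"# config_hash={config_hash}\n")
            df.to_csv(fh, sep="\t", index=False)
    return df
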