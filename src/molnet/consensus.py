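"""Consensus spectra: merging repeated scans of the same precursor.

Replicate injections and collision-energy variants of one analyte are
clustered by single linkage — two scans link when their precursors agree
within tolerance, they co-elute within the retention-time window, AND
their spectra align with a modified cosine above the gate. The cosine
gate is what keeps isobaric, co-eluting-in-mass but chemically different
species apart when retention time alone cannot (two distinct compounds
can share a nominal precursor m/z). Each cluster becomes one consensus
spectrum — the node unit of the molecular network.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .similarity import SimilarityParams, modified_cosine
from .spectra_io import Peak, Spectrum


@dataclass
class ConsensusSpectrum:
    """Merged representative of the scans in one cluster."""

    node_id: int
    member_scan_ids: list[str]
    precursor_mz: float  # intensity-weighted mean over members
    rt: float  # mean seconds
    precursor_intensity: float  # maximum over members
    precursor_charge: int  # modal value
    peaks: list[Peak]
    groups: frozenset[str]

    @property
    def n_members(self) -> int:
        return len(self.member_scan_ids)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])


def merge_peaks(members: Sequence[Spectrum], fragment_tol: float = 0.02) -> list[Peak]:
    """Merge member peak lists into one consensus list.

    Peaks across members are grouped by single linkage within
    ``fragment_tol`` (1-D: split wherever the sorted m/z gap exceeds the
    tolerance). Merged m/z is the intensity-weighted mean; merged
    intensity is the mean over members with absent peaks counted as zero
    (a peak seen in 1 of 3 scans keeps a third of its intensity). The
    result is normalized to base peak 100.
    """
    if not members:
        raise ValueError("merge_peaks requires at least one member")
    all_peaks = sorted(p for s in members for p in s.peaks)
    if not all_peaks:
        return []
    n = len(members)
    merged: list[Peak] = []
    start = 0
    for k in range(1, len(all_peaks) + 1):
        if k == len(all_peaks) or all_peaks[k].mz - all_peaks[k - 1].mz > fragment_tol:
            grp = all_peaks[start:k]
            total = sum(p.intensity for p in grp)
            if total > 0:
                mz = sum(p.mz * p.intensity for p in grp) / total
            else:
                mz = sum(p.mz for p in grp) / len(grp)
            merged.append(Peak(mz, total / n))
            start = k
    base = max(p.intensity for p in merged)
    if base > 0:
        merged = [Peak(p.mz, 100.0 * p.intensity / base) for p in merged]
    # guard against coincident merged centroids
    out: list[Peak] = []
    last = -np.inf
    for p in merged:
        mz = p.mz if p.mz - last >= 1e-6 else last + 2e-6
        out.append(Peak(mz, p.intensity))
        last = mz
    return out


def _build_consensus(
    node_id: int, members: list[Spectrum], fragment_tol: float
) -> ConsensusSpectrum:
    weights = np.array([max(s.precursor_intensity, 0.0) for s in members])
    precs = np.array([s.precursor_mz for s in members])
    if weights.sum() > 0:
        prec = float(np.average(precs, weights=weights))
    else:
        prec = float(precs.mean())
    charge_counts = Counter(s.precursor_charge for s in members)
    top = max(charge_counts.values())
    charge = min(c for c, k in charge_counts.items() if k == top)
    return ConsensusSpectrum(
        node_id=node_id,
        member_scan_ids=[s.scan_id for s in members],
        precursor_mz=prec,
        rt=float(np.mean([s.rt for s in members])),
        precursor_intensity=float(max(s.precursor_intensity for s in members)),
        precursor_charge=charge,
        peaks=merge_peaks(members, fragment_tol),
        groups=frozenset(s.group for s in members if s.group),
    )


def cluster_scans(
    spectra: Sequence[Spectrum],
    precursor_tol: float = 0.02,
    rt_window: float = 30.0,
    min_score: float = 0.7,
    fragment_tol: float = 0.02,
    sim_params: SimilarityParams | None = None,
) -> list[ConsensusSpectrum]:
    """Single-linkage clustering of scans into consensus spectra.

    Scans link iff |Δprecursor| ≤ ``precursor_tol`` and |Δrt| ≤
    ``rt_window`` and modified cosine ≥ ``min_score``. The result is
    invariant to input order (scans are sorted before clustering); node
    ids are assigned by ascending (precursor m/z, rt).
    """
    if not spectra:
        raise ValueError("cluster_scans requires at least one spectrum")
    params = sim_params or SimilarityParams(fragment_tol=fragment_tol)
    ordered = sorted(spectra, key=lambda s: (s.precursor_mz, s.rt, s.scan_id))

    parent = list(range(len(ordered)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for i, a in enumerate(ordered):
        for j in range(i + 1, len(ordered)):
            b = ordered[j]
            if b.precursor_mz - a.precursor_mz > precursor_tol:
                break
            if abs(a.rt - b.rt) > rt_window:
                continue
            if find(i) == find(j):
                continue
            if modified_cosine(a, b, params).score >= min_score:
                union(i, j)

    clusters: dict[int, list[Spectrum]] = {}
    for i, s in enumerate(ordered):
        clusters.setdefault(find(i), []).append(s)

    members_sorted = sorted(
        clusters.values(),
        key=lambda ms: (
            float(np.mean([m.precursor_mz for m in ms])),
            float(np.mean([m.rt for m in ms])),
        ),
    )
    return [
        _build_consensus(node_id, ms, fragment_tol)
        for node_id, ms in enumerate(members_sorted)
    ]
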