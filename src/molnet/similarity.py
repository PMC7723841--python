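"""Shift-aware (modified) cosine similarity between MS/MS spectra.

Two fragment peaks may match either directly (|Δm/z| ≤ tol) or shifted by
the precursor mass difference — the modification-tolerant match that links
structural homologs such as fentanyl and α-methylfentanyl. The score is
the cosine between square-root-intensity-weighted peak vectors under a
one-to-one peak assignment, found greedily over candidate pairs sorted by
descending weight product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Protocol

import numpy as np


class _HasPeaks(Protocol):  # Spectrum or ConsensusSpectrum
    precursor_mz: float

    @property
    def mz(self) -> np.ndarray: ...

    @property
    def intensity(self) -> np.ndarray: ...


@dataclass(frozen=True)
class SimilarityParams:
    """Matching parameters; defaults follow the networking conventions
    (fragment tolerance 0.02 Da, at least 6 common fragment ions)."""

    fragment_tol: float = 0.02
    min_matched: int = 6
    use_shift: bool = True
    intensity_power: float = 0.5

    def __post_init__(self) -> None:
        if self.fragment_tol <= 0:
            raise ValueError("fragment_tol must be positive")
        if self.min_matched < 1:
            raise ValueError("min_matched must be >= 1")


class CandidatePair(NamedTuple):
    i: int  # peak index in a
    j: int  # peak index in b
    shifted: bool


@dataclass
class AlignmentResult:
    """Outcome of aligning two spectra."""

    score: float
    matched_pairs: list[CandidatePair] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs)


def candidate_pairs(
    a: _HasPeaks, b: _HasPeaks, params: SimilarityParams = SimilarityParams()
) -> list[CandidatePair]:
    """All peak pairs matchable directly or (optionally) precursor-shifted.

    A pair that satisfies both windows appears twice, once per mode; the
    assignment step counts it once.
    """
    mza, mzb = np.asarray(a.mz, float), np.asarray(b.mz, float)
    if mza.size == 0 or mzb.size == 0:
        return []
    diff = mza[:, None] - mzb[None, :]
    out = []
    for shifted, offset in ((False, 0.0), (True, a.precursor_mz - b.precursor_mz)):
        if shifted and not params.use_shift:
            continue
        ii, jj = np.nonzero(np.abs(diff - offset) <= params.fragment_tol)
        out.extend(CandidatePair(int(i), int(j), shifted) for i, j in zip(ii, jj))
    return out


def _weights(spectrum: _HasPeaks, power: float) -> np.ndarray:
    w = np.asarray(spectrum.intensity, float) ** power
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def modified_cosine(
    a: _HasPeaks, b: _HasPeaks, params: SimilarityParams = SimilarityParams()
) -> AlignmentResult:
    """Greedy shift-aware cosine between two spectra.

    Peak weights are ``intensity ** intensity_power`` normalized to unit
    length per spectrum; candidate pairs are taken greedily by descending
    weight product (ties: smaller |m/z error|, then lower indices), each
    peak used at most once. Empty spectra score 0. The score is symmetric
    and equals 1 for a spectrum against itself or an exactly precursor-
    shifted copy.
    """
    cands = candidate_pairs(a, b, params)
    if not cands:
        return AlignmentResult(score=0.0)

    wa = _weights(a, params.intensity_power)
    wb = _weights(b, params.intensity_power)
    mza, mzb = np.asarray(a.mz, float), np.asarray(b.mz, float)
    offset = a.precursor_mz - b.precursor_mz

    def sort_key(c: CandidatePair):
        err = abs(mza[c.i] - mzb[c.j] - (offset if c.shifted else 0.0))
        return (-wa[c.i] * wb[c.j], err, c.i, c.j)

    used_a: set[int] = set()
    used_b: set[int] = set()
    chosen: list[CandidatePair] = []
    score = 0.0
    for c in sorted(cands, key=sort_key):
        if c.i in used_a or c.j in used_b:
            continue
        used_a.add(c.i)
        used_b.add(c.j)
        chosen.append(c)
        score += float(wa[c.i] * wb[c.j])
    return AlignmentResult(score=min(score, 1.0), matched_pairs=chosen)
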