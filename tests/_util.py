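"""Shared test helpers: independent oracles and instance generators."""

from __future__ import annotations

import numpy as np

from molnet.similarity import SimilarityParams, candidate_pairs
from molnet.spectra_io import Peak, Spectrum


def _dedupe(mzs, ints):
    order = np.argsort(mzs)
    peaks = []
    last = -np.inf
    for k in order:
        mz = float(mzs[k])
        if mz - last < 1e-6:
            mz = last + 2e-6
        peaks.append(Peak(mz, float(ints[k])))
        last = mz
    return peaks


def aligned_pair(rng: np.random.Generator, max_peaks: int = 8):
    """Random spectrum pair with a known homology structure.

    Peaks of ``a`` sit on a 0.5 Th grid; the precursor delta (6.66 Th) is
    off-grid, so every candidate match is either the constructed direct or
    the constructed shifted partner and conflicts are confined to
    one-sided near-duplicates. On this family a greedy assignment by
    descending weight product is provably optimal, which makes exhaustive
    oracle comparisons exact.
    """
    n_a = int(rng.integers(4, max_peaks + 1))
    slots = rng.choice(np.arange(120), size=n_a, replace=False)
    mz_a = np.sort(100.0 + 0.5 * slots)
    int_a = rng.uniform(5.0, 100.0, n_a)
    delta = 6.66
    prec_a, prec_b = 500.0, 500.0 + delta

    mz_b, int_b = [], []
    for mz in mz_a:
        r = rng.random()
        if r < 0.30:  # direct partner
            mz_b.append(mz + rng.uniform(-0.015, 0.015))
            int_b.append(rng.uniform(5.0, 100.0))
        elif r < 0.60:  # precursor-shifted partner
            mz_b.append(mz + delta + rng.uniform(-0.015, 0.015))
            int_b.append(rng.uniform(5.0, 100.0))
        elif r < 0.75:  # near-duplicate pair competing for one a-peak
            for _ in range(2):
                mz_b.append(mz + rng.uniform(-0.015, 0.015))
                int_b.append(rng.uniform(5.0, 100.0))
        # else: no partner
    for _ in range(int(rng.integers(0, 3))):  # unmatched extras
        mz_b.append(float(rng.uniform(650.0, 680.0)))
        int_b.append(rng.uniform(5.0, 100.0))
    if not mz_b:
        mz_b, int_b = [float(mz_a[0]) + delta], [50.0]
    mz_b, int_b = np.array(mz_b[:max_peaks]), np.array(int_b[:max_peaks])

    a = Spectrum("a", prec_a, _dedupe(mz_a, int_a), precursor_charge=1)
    b = Spectrum("b", prec_b, _dedupe(mz_b, int_b), precursor_charge=1)
    return a, b


def exhaustive_best_score(a: Spectrum, b: Spectrum, params: SimilarityParams) -> float:
    """Brute-force maximum of the cosine over all one-to-one assignments
    of candidate peak pairs. Exponential; only for tiny spectra."""
    pairs = sorted({(c.i, c.j) for c in candidate_pairs(a, b, params)})
    wa = a.intensity ** params.intensity_power
    wb = b.intensity ** params.intensity_power
    na, nb = np.linalg.norm(wa), np.linalg.norm(wb)
    if na > 0:
        wa = wa / na
    if nb > 0:
        wb = wb / nb

    best = 0.0

    def rec(k: int, used_a: frozenset, used_b: frozenset, acc: float) -> None:
        nonlocal best
        if acc + sum(wa[i] * wb[j] for i, j in pairs[k:]) <= best:
            return
        if k == len(pairs):
            best = max(best, acc)
            return
        i, j = pairs[k]
        if i not in used_a and j not in used_b:
            rec(k + 1, used_a | {i}, used_b | {j}, acc + wa[i] * wb[j])
        rec(k + 1, used_a, used_b, acc)
        best = max(best, acc)

    rec(0, frozenset(), frozenset(), 0.0)
    return min(best, 1.0)


def brute_force_decompositions(delta, tol, bounds):
    """Nested-loop enumeration over the full (tiny) bound box, including
    an explicit hydrogen loop — independent of the solver under test."""
    from molnet.masscalc import ELEMENTS, MONOISOTOPIC_MASS, ElementalFormula

    out = []
    rng = {e: range(bounds[e][0], bounds[e][1] + 1) for e in ELEMENTS}
    for c in rng["C"]:
        for h in rng["H"]:
            for n in rng["N"]:
                for o in rng["O"]:
                    for f in rng["F"]:
                        for s in rng["S"]:
                            mass = (
                                c * MONOISOTOPIC_MASS["C"]
                                + h * MONOISOTOPIC_MASS["H"]
                                + n * MONOISOTOPIC_MASS["N"]
                                + o * MONOISOTOPIC_MASS["O"]
                                + f * MONOISOTOPIC_MASS["F"]
                                + s * MONOISOTOPIC_MASS["S"]
                            )
                            if abs(delta - mass) <= tol:
                                out.append(
                                    ElementalFormula.from_counts(
                                        {"C": c, "H": h, "N": n, "O": o, "F": f, "S": s}
                                    )
                                )
    return set(out)
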