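"""Elemental formula arithmetic for accurate-mass reasoning.

Monoisotopic masses, protonated/fragment ion m/z, and exhaustive
decomposition of precursor mass differences into candidate elemental
changes (e.g. a 94.005 Da gap read as C5H2O2, or 17.991 as +F −H).
The supported element set (C, H, N, O, F, S) covers synthetic
cannabinoids and fentanyl analogs; hydrogen counts may go negative to
express substitution deltas such as fluorine-for-hydrogen.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping

ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "F", "S")

#: Monoisotopic masses of the lightest isotope, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250,
    "N": 14.0030740,
    "O": 15.9949146,
    "F": 18.9984032,
    "S": 31.9720707,
}

#: Mass of a proton (H+ including the missing electron), Da.
PROTON_MASS = 1.0072765
#: Electron rest mass, Da.
ELECTRON_MASS = 0.0005486

#: Decomposition search space: generous enough for any delta between two
#: nodes of the networks handled here. Only H may go negative (floor −3),
#: which is what expresses substitutions like +F −H.
DEFAULT_BOUNDS: dict[str, tuple[int, int]] = {
    "C": (0, 30),
    "H": (-3, 60),
    "N": (0, 6),
    "O": (0, 10),
    "F": (0, 3),
    "S": (0, 2),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparseable or unsupported formulas."""


@dataclass(frozen=True)
class ElementalFormula:
    """Signed element-count vector over C, H, N, O, F, S.

    Compound formulas have nonnegative counts; delta formulas produced by
    :func:`decompose_delta` may carry signed counts (e.g. ``{F: 1, H: -1}``).
    The all-zero formula is the identity with mass 0.
    """

    counts: tuple[int, int, int, int, int, int]

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "ElementalFormula":
        unknown = set(counts) - set(ELEMENTS)
        if unknown:
            raise FormulaError(f"unsupported element(s): {sorted(unknown)}")
        return cls(tuple(int(counts.get(e, 0)) for e in ELEMENTS))

    def as_dict(self) -> dict[str, int]:
        return {e: c for e, c in zip(ELEMENTS, self.counts) if c != 0}

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    @property
    def total_atoms(self) -> int:
        return sum(abs(c) for c in self.counts)

    def __neg__(self) -> "ElementalFormula":
        return ElementalFormula(tuple(-c for c in self.counts))

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(tuple(a + b for a, b in zip(self.counts, other.counts)))

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        return self + (-other)

    def __bool__(self) -> bool:
        return any(self.counts)

    def hill(self) -> str:
        """Hill-order string (C, H, then alphabetical), nonneg counts only."""
        if any(c < 0 for c in self.counts):
            raise FormulaError("hill() requires a nonnegative formula; use signed_string()")
        parts = []
        order = ["C", "H"] + sorted(e for e in ELEMENTS if e not in ("C", "H"))
        d = self.as_dict()
        for e in order:
            n = d.get(e, 0)
            if n == 1:
                parts.append(e)
            elif n > 1:
                parts.append(f"{e}{n}")
        return "".join(parts)

    def signed_string(self) -> str:
        """Render gains and losses, e.g. ``+F -H`` or ``+C5H2O2``."""
        pos = ElementalFormula(tuple(max(c, 0) for c in self.counts))
        neg = ElementalFormula(tuple(max(-c, 0) for c in self.counts))
        out = []
        if pos:
            out.append(f"+{pos.hill()}")
        if neg:
            out.append(f"-{neg.hill()}")
        return " ".join(out) if out else "+0"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        try:
            return self.hill() or "(empty)"
        except FormulaError:
            return self.signed_string()


ZERO_FORMULA = ElementalFormula((0, 0, 0, 0, 0, 0))


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string like ``C22H28N2O``.

    The empty string parses to the zero formula. Unknown element symbols
    raise :class:`FormulaError`.
    """
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos or not m.group(1):
            break
        sym, num = m.group(1), m.group(2)
        if sym not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        pos = m.end()
        if pos == len(text):
            break
    if pos != len(text):
        raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
    return ElementalFormula.from_counts(counts)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass of the (possibly signed) formula, Da."""
    return sum(c * MONOISOTOPIC_MASS[e] for e, c in zip(ELEMENTS, f.counts))


def protonated_mz(f: ElementalFormula) -> float:
    """[M+H]+ m/z of a neutral formula: monoisotopic mass plus one proton."""
    return monoisotopic_mass(f) + PROTON_MASS


def fragment_mz(f: ElementalFormula) -> float:
    """m/z of an even-electron fragment cation whose atom counts are ``f``.

    The formula describes the cation itself, so the only correction is the
    missing electron (e.g. C13H18N -> 188.1434, C8H9 -> 105.0699).
    """
    return monoisotopic_mass(f) - ELECTRON_MASS


@dataclass(frozen=True)
class DecompositionCandidate:
    """One elemental explanation of an observed mass difference."""

    formula: ElementalFormula
    theoretical_mass: float
    error: float  # observed − theoretical, Da
    rank: int


def _iter_compositions(
    target: float, tol: float, bounds: Mapping[str, tuple[int, int]]
) -> Iterator[ElementalFormula]:
    """Enumerate all in-bounds compositions with |mass − target| ≤ tol.

    Loops over the heavy elements and solves the hydrogen count in closed
    form (at most one integer H fits a ≤0.5 Da window), which keeps the
    search exhaustive but cheap.
    """
    m = MONOISOTOPIC_MASS
    h_lo, h_hi = bounds["H"]
    h_slack = -h_lo * m["H"]  # how far below target the heavy sum may go
    for s in range(bounds["S"][0], bounds["S"][1] + 1):
        ms = s * m["S"]
        if ms > target + tol + h_slack:
            break
        for f in range(bounds["F"][0], bounds["F"][1] + 1):
            mf = ms + f * m["F"]
            if mf > target + tol + h_slack:
                break
            for o in range(bounds["O"][0], bounds["O"][1] + 1):
                mo = mf + o * m["O"]
                if mo > target + tol + h_slack:
                    break
                for n in range(bounds["N"][0], bounds["N"][1] + 1):
                    mn = mo + n * m["N"]
                    if mn > target + tol + h_slack:
                        break
                    for c in range(bounds["C"][0], bounds["C"][1] + 1):
                        mc = mn + c * m["C"]
                        if mc > target + tol + h_slack:
                            break
                        rem = target - mc
                        h_min = max(h_lo, int(-(-(rem - tol) // m["H"])))
                        h_max = min(h_hi, int((rem + tol) // m["H"]))
                        for h in range(h_min, h_max + 1):
                            if abs(rem - h * m["H"]) <= tol:
                                yield ElementalFormula.from_counts(
                                    {"C": c, "H": h, "N": n, "O": o, "F": f, "S": s}
                                )


def decompose_delta(
    delta: float,
    tol: float = 0.005,
    bounds: Mapping[str, tuple[int, int]] | None = None,
) -> list[DecompositionCandidate]:
    """Exhaustively decompose a mass difference into elemental changes.

    Candidates within ``tol`` Da are ranked by absolute mass error, then
    total atom count (parsimony), then lexicographic element order. A
    negative ``delta`` is decomposed as the negated composition, so all
    counts of the returned formulas flip sign.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update({k: (int(lo), int(hi)) for k, (lo, hi) in bounds.items()})
    for e, (lo, hi) in b.items():
        if hi < lo:
            raise ValueError(f"degenerate bounds for {e}: {lo}..{hi}")

    negate = delta < 0
    target = -delta if negate else delta

    found = []
    for formula in _iter_compositions(target, tol, b):
        if negate:
            formula = -formula
        theo = monoisotopic_mass(formula)
        found.append((formula, theo, delta - theo))

    found.sort(key=lambda t: (abs(t[2]), t[0].total_atoms, t[0].counts))
    return [
        DecompositionCandidate(formula=f, theoretical_mass=theo, error=err, rank=i + 1)
        for i, (f, theo, err) in enumerate(found)
    ]
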