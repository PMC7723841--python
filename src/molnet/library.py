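"""Packaged reference library of NPS standards.

Two standard mixtures: 16 synthetic cannabinoids (each with its two
characteristic fragment ions) and 14 fentanyl derivatives. Ten of the
fentanyls preserve the phenylethylpiperidine core and therefore show the
diagnostic m/z 188.1434 / 105.0699 fragments (α-methylfentanyl carries
202.1590 in place of 188.1434, from its methylated core); the other four
have unrelated scaffolds and fragment differently.

Seizure compounds observed only by their precursor m/z (putative analogs
and unknown impurities) are modelled from the fentanyl-core fragment
pattern plus their printed precursor mass and retention time.

Each compound also carries a class-shared neutral-loss offset series:
peaks at (precursor − offset) that shift along with the precursor. These
are what make precursor-shifted matches — and hence cross-subfamily
network edges — possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .masscalc import ElementalFormula, parse_formula, protonated_mz

#: Diagnostic fragment cations of the unmodified phenylethylpiperidine core.
FRAG_CORE_188 = 188.1434  # C13H18N+
FRAG_CORE_105 = 105.0699  # C8H9+
FRAG_CORE_202 = 202.1590  # C14H20N+, methylated core (α-methylfentanyl)

#: Class flags are granted only if ALL listed fragments are present.
DIAGNOSTIC_FRAGMENTS: dict[str, tuple[float, ...]] = {
    "fentanyl_core": (FRAG_CORE_188, FRAG_CORE_105),
}

# Shared neutral-loss offset series (Da) and relative intensities, one per
# class. Offsets are disjoint between classes (no two within 0.04 Da) so
# precursor-shifted matches never bridge the two networks. Cannabinoid
# spectra are dominated by the shared series (cross-subfamily pairs must
# clear the cosine gate on shifted matches alone); fentanyl spectra are
# dominated by the diagnostic core fragments, which is what separates the
# two isobaric 351.243 spectra.
CANNABINOID_OFFSETS: tuple[tuple[float, float], ...] = (
    (18.0106, 100.0),
    (42.0470, 85.0),
    (58.0419, 70.0),
    (68.0626, 55.0),
    (96.0575, 45.0),
    (112.0888, 35.0),
)
FENTANYL_OFFSETS: tuple[tuple[float, float], ...] = (
    (28.0313, 25.0),
    (44.0262, 20.0),
    (56.0626, 15.0),
    (72.0575, 12.0),
    (94.0419, 10.0),
    (104.0626, 8.0),
)

#: Intensity (relative to base 100) of the two table fragments per class.
_CANNABINOID_FRAG_INTENSITIES = (50.0, 40.0)
_FENTANYL_CORE_FRAGS = ((FRAG_CORE_188, 100.0), (FRAG_CORE_105, 60.0))
_FENTANYL_METHYLCORE_FRAGS = ((FRAG_CORE_202, 100.0), (FRAG_CORE_105, 60.0))


@dataclass(frozen=True)
class CompoundRecord:
    """One library compound (or precursor-only seizure unknown)."""

    name: str
    formula: Optional[ElementalFormula]
    precursor_mz: float  # [M+H]+, Th
    rt: float  # seconds
    class_tag: str  # fentanyl_core | fentanyl_noncore | cannabinoid:<sub> | unknown
    fragments: tuple[tuple[float, float], ...]  # (mz, relative intensity)
    offset_series: tuple[tuple[float, float], ...]  # (neutral loss Da, rel. int.)

    def __post_init__(self) -> None:
        if self.formula is not None:
            theo = protonated_mz(self.formula)
            if abs(theo - self.precursor_mz) > 0.0005:
                raise ValueError(
                    f"{self.name}: precursor {self.precursor_mz} inconsistent "
                    f"with formula ({theo:.4f})"
                )

    @property
    def is_cannabinoid(self) -> bool:
        return self.class_tag.startswith("cannabinoid")


def _cannabinoid(name, formula, rt, subfamily, frag1, frag2) -> CompoundRecord:
    f = parse_formula(formula)
    i1, i2 = _CANNABINOID_FRAG_INTENSITIES
    return CompoundRecord(
        name=name,
        formula=f,
        precursor_mz=protonated_mz(f),
        rt=rt,
        class_tag=f"cannabinoid:{subfamily}",
        fragments=((frag1, i1), (frag2, i2)),
        offset_series=CANNABINOID_OFFSETS,
    )


def _fentanyl(name, formula, rt, core=True, frags=None, offsets=None) -> CompoundRecord:
    f = parse_formula(formula)
    return CompoundRecord(
        name=name,
        formula=f,
        precursor_mz=protonated_mz(f),
        rt=rt,
        class_tag="fentanyl_core" if core else "fentanyl_noncore",
        fragments=tuple(frags) if frags is not None else _FENTANYL_CORE_FRAGS,
        offset_series=tuple(offsets) if offsets is not None else FENTANYL_OFFSETS,
    )


def load_standard_library() -> list[CompoundRecord]:
    """The 30 standards of the two reference mixtures.

    Cannabinoid fragment pairs are the published characteristic ions of
    each compound; retention times are deterministic plausible values on
    the 12.5 min gradient (compounds present in the seizure inventory use
    their reported node retention times).
    """
    cannabinoids = [
        _cannabinoid("UR-144", "C21H29NO", 240.0, "ur", 125.0960, 214.1219),
        _cannabinoid("JWH-073", "C23H21NO", 252.0, "jwh", 155.0488, 200.1065),
        _cannabinoid("UR-144 N(4-hydroxypentyl)", "C21H29NO2", 264.0, "ur", 125.0959, 230.1165),
        _cannabinoid("XLR-11", "C21H28FNO", 276.0, "ur", 125.0959, 232.1128),
        _cannabinoid("JWH-018", "C24H23NO", 288.0, "jwh", 155.0488, 214.1221),
        _cannabinoid("AB-005", "C23H32N2O", 300.0, "ab", 112.1121, 98.0966),
        _cannabinoid("JWH-122", "C25H25NO", 312.0, "jwh", 169.0644, 214.1221),
        _cannabinoid("N5-OH-JWH018", "C24H23NO2", 324.0, "jwh", 155.0488, 230.1178),
        _cannabinoid("N-COOH-JWH018", "C24H21NO3", 336.0, "jwh", 155.0488, 244.0959),
        _cannabinoid("JWH-081", "C25H25NO2", 348.0, "jwh", 185.0593, 214.1221),
        # 470 s keeps MAM2201 well clear of furanylfentanyl's elution: their
        # precursors sit within the 0.02 Da [M−1] window of each other.
        _cannabinoid("MAM2201", "C25H24FNO", 470.0, "jwh", 169.0644, 232.1126),
        _cannabinoid("AM-1220", "C26H26N2O", 372.0, "ab", 98.0966, 112.1120),
        _cannabinoid("JWH-200", "C25H24N2O2", 384.0, "jwh", 155.0488, 114.0913),
        _cannabinoid("N-COOH-MAM2201", "C25H23NO3", 396.0, "jwh", 169.0644, 244.0962),
        _cannabinoid("N5-OH-JWH-081", "C25H25NO3", 408.0, "jwh", 185.0593, 230.1169),
        _cannabinoid("WIN-55", "C27H26N2O3", 420.0, "win", 155.0488, 100.0758),
    ]
    fentanyls = [
        _fentanyl("4-ANPP", "C19H24N2", 180.26),
        _fentanyl("Despropionyl para-fluorofentanyl", "C19H23FN2", 143.84),
        _fentanyl("Acetyl fentanyl", "C21H26N2O", 170.0),
        _fentanyl("Acrylfentanyl", "C22H26N2O", 200.0),
        _fentanyl("Fentanyl", "C22H28N2O", 260.0),
        _fentanyl("alpha-Methylfentanyl", "C23H30N2O", 409.30, frags=_FENTANYL_METHYLCORE_FRAGS),
        _fentanyl("ortho-Fluorofentanyl", "C22H27FN2O", 285.0),
        _fentanyl(
            "cis-3-Methylthiofentanyl", "C21H28N2OS", 320.0, core=False,
            frags=((208.1154, 100.0), (134.0963, 70.0)),
            offsets=((47.9669, 30.0), (75.9977, 25.0), (89.9827, 20.0), (121.0112, 15.0)),
        ),
        _fentanyl("Ocfentanyl", "C22H27FN2O2", 335.0),
        _fentanyl("Furanylfentanyl", "C24H26N2O2", 142.75),
        _fentanyl(
            "Remifentanyl", "C20H28N2O5", 360.0, core=False,
            frags=((113.0709, 100.0), (227.1541, 70.0)),
            offsets=((32.0262, 30.0), (60.0211, 25.0), (100.0524, 20.0), (132.0786, 15.0)),
        ),
        _fentanyl("Butyryl-fentanyl-carboxy metabolite", "C23H28N2O3", 385.0),
        _fentanyl(
            "Sufentanyl", "C22H30N2O2S", 430.0, core=False,
            frags=((238.1685, 100.0), (111.0263, 70.0)),
            offsets=((49.9826, 30.0), (77.9932, 25.0), (111.0069, 20.0), (140.0475, 15.0)),
        ),
        _fentanyl(
            "Alfentanyl", "C21H32N6O3", 450.0, core=False,
            frags=((268.1768, 100.0), (197.1284, 70.0)),
            offsets=((39.0421, 30.0), (67.0371, 25.0), (95.0684, 20.0), (123.0997, 15.0)),
        ),
    ]
    return cannabinoids + fentanyls


#: The ten core-preserving fentanyl standards (those that belong to the
#: fentanyl training network).
FENTANYL_CORE_STANDARDS: tuple[str, ...] = (
    "4-ANPP",
    "Despropionyl para-fluorofentanyl",
    "Acetyl fentanyl",
    "Acrylfentanyl",
    "Fentanyl",
    "alpha-Methylfentanyl",
    "ortho-Fluorofentanyl",
    "Ocfentanyl",
    "Furanylfentanyl",
    "Butyryl-fentanyl-carboxy metabolite",
)


def _seizure_unknown(name, precursor_mz, rt) -> CompoundRecord:
    return CompoundRecord(
        name=name,
        formula=None,
        precursor_mz=precursor_mz,
        rt=rt,
        class_tag="fentanyl_core",
        fragments=_FENTANYL_CORE_FRAGS,
        offset_series=FENTANYL_OFFSETS,
    )


def load_seizure_compounds() -> dict[str, list[CompoundRecord]]:
    """Seizure constituents by group label.

    Seizure A (G2) contains two putative fentanyl analogs, three unknown
    minor impurities and four compounds shared with the standard mixture;
    seizure B (G3) holds the subset seen in both seizures. Unknowns are
    modelled from their precursor m/z and the core fragment pattern only.
    The butyryl-type 351.243 compound shows the unmodified core (188/105,
    no 202.159) and so is isobaric with — but spectrally distinct from —
    α-methylfentanyl.
    """
    std = {c.name: c for c in load_standard_library()}
    butyryl = _seizure_unknown("putative (iso)butyrylfentanyl", 351.243, 212.88)
    pf_furanyl = _seizure_unknown("putative para-fluorofuranylfentanyl", 393.197, 188.91)
    unknowns_a = [
        _seizure_unknown("unknown 403.238", 403.238, 230.90),
        _seizure_unknown("unknown 619.365", 619.365, 317.06),
        _seizure_unknown("unknown 437.280", 437.280, 242.78),
    ]
    shared = [
        std["Despropionyl para-fluorofentanyl"],
        std["Furanylfentanyl"],
    ]
    seizure_a = unknowns_a + [
        std["alpha-Methylfentanyl"],
        std["4-ANPP"],
        butyryl,
        pf_furanyl,
    ] + shared
    seizure_b = [butyryl, pf_furanyl] + shared
    return {"G2": seizure_a, "G3": seizure_b}


#: Compounds whose seizure intensity is 2–3 orders of magnitude below the
#: main seizure peaks (minor impurities / synthetic byproducts).
SEIZURE_IMPURITIES: tuple[str, ...] = (
    "unknown 403.238",
    "unknown 619.365",
    "unknown 437.280",
)
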