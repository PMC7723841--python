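"""Formula parsing, monoisotopic mass arithmetic and delta decomposition."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molnet.library import load_standard_library
from molnet.masscalc import (
    PROTON_MASS,
    ElementalFormula,
    FormulaError,
    ZERO_FORMULA,
    decompose_delta,
    fragment_mz,
    monoisotopic_mass,
    parse_formula,
    protonated_mz,
)

from _util import brute_force_decompositions


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C22H28N2O", {"C": 22, "H": 28, "N": 2, "O": 1}),
            ("C5H2O2", {"C": 5, "H": 2, "O": 2}),
            ("C19H23FN2", {"C": 19, "H": 23, "F": 1, "N": 2}),
            ("C21H28N2OS", {"C": 21, "H": 28, "N": 2, "O": 1, "S": 1}),
            ("", {}),
        ],
    )
    def test_examples(self, text, expected):
        assert parse_formula(text).as_dict() == expected

    @pytest.mark.parametrize("bad", ["C2X", "Si2O", "C-3", "22C", "CH3)2"])
    def test_rejects_garbage(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "F", "S"]),
            st.integers(min_value=1, max_value=40),
            min_size=1,
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_hill_round_trip(self, counts):
        f = ElementalFormula.from_counts(counts)
        assert parse_formula(f.hill()) == f


class TestMasses:
    def test_moiety_masses(self):
        assert monoisotopic_mass(parse_formula("C5H2O2")) == pytest.approx(94.0055, abs=5e-5)
        assert monoisotopic_mass(
            ElementalFormula.from_counts({"F": 1, "H": -1})
        ) == pytest.approx(17.9906, abs=5e-5)
        assert monoisotopic_mass(ZERO_FORMULA) == 0.0

    # printed [M+H]+ values of the full packaged library (4 d.p.)
    @pytest.mark.parametrize(
        "formula,printed",
        [
            ("C21H29NO", 312.2321), ("C23H21NO", 328.1695), ("C21H29NO2", 328.2271),
            ("C21H28FNO", 330.2227), ("C24H23NO", 342.1852), ("C23H32N2O", 353.2587),
            ("C25H25NO", 356.2008), ("C24H23NO2", 358.1801), ("C24H21NO3", 372.1594),
            ("C25H25NO2", 372.1958), ("C25H24FNO", 374.1914), ("C26H26N2O", 383.2117),
            ("C25H24N2O2", 385.1910), ("C25H23NO3", 386.1750), ("C25H25NO3", 388.1907),
            ("C27H26N2O3", 427.2016),
            ("C19H24N2", 281.2012), ("C19H23FN2", 299.1918), ("C21H26N2O", 323.2118),
            ("C22H26N2O", 335.2118), ("C22H28N2O", 337.2274), ("C23H30N2O", 351.2431),
            ("C22H27FN2O", 355.2180), ("C21H28N2OS", 357.1995), ("C22H27FN2O2", 371.2129),
            ("C24H26N2O2", 375.2067), ("C20H28N2O5", 377.2071), ("C23H28N2O3", 381.2173),
            ("C22H30N2O2S", 387.2101), ("C21H32N6O3", 417.2609),
        ],
    )
    def test_protonated_mz_reproduces_printed_values(self, formula, printed):
        assert protonated_mz(parse_formula(formula)) == pytest.approx(printed, abs=1e-4)

    @pytest.mark.parametrize(
        "cation,printed",
        [("C13H18N", 188.143), ("C8H9", 105.070), ("C14H20N", 202.159)],
    )
    def test_fragment_cations(self, cation, printed):
        assert round(fragment_mz(parse_formula(cation)), 3) == printed

    def test_protonation_offset_is_exact(self):
        for record in load_standard_library():
            if record.formula is None:
                continue
            assert protonated_mz(record.formula) - monoisotopic_mass(
                record.formula
            ) == pytest.approx(PROTON_MASS, abs=1e-12)


class TestDecomposeDelta:
    def test_printed_deltas_recover_printed_formulas(self):
        for delta, formula in [
            (94.005, "C5H2O2"),
            (28.032, "C2H4"),
            (51.995, "C3O"),
            (122.037, "C7H6O2"),
        ]:
            found = {c.formula for c in decompose_delta(delta, 0.005)}
            assert parse_formula(formula) in found

    def test_fluorine_for_hydrogen(self):
        found = {c.formula for c in decompose_delta(17.991, 0.005)}
        assert ElementalFormula.from_counts({"F": 1, "H": -1}) in found

    def test_rank1_on_exact_moiety_masses(self):
        # at the unrounded masses the chemically expected formula is rank 1
        for formula in ["C5H2O2", "C2H4", "C3O", "C7H6O2"]:
            f = parse_formula(formula)
            cands = decompose_delta(monoisotopic_mass(f), 0.005)
            assert cands[0].formula == f

    def test_zero_delta(self):
        cands = decompose_delta(0.0, 0.005)
        assert cands[0].formula == ZERO_FORMULA and cands[0].rank == 1

    def test_negative_delta_is_negated_composition(self):
        cands = decompose_delta(-monoisotopic_mass(parse_formula("C2H4")), 0.005)
        assert cands[0].formula == ElementalFormula.from_counts({"C": -2, "H": -4})
        assert cands[0].theoretical_mass < 0

    def test_errors_within_tolerance_and_ranked(self):
        cands = decompose_delta(94.005, 0.005)
        assert all(abs(c.error) <= 0.005 for c in cands)
        errors = [abs(c.error) for c in cands]
        assert errors == sorted(errors)
        assert [c.rank for c in cands] == list(range(1, len(cands) + 1))

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            decompose_delta(94.0, tol=0.0)
        with pytest.raises(ValueError):
            decompose_delta(94.0, bounds={"C": (5, 2)})
        assert decompose_delta(0.9, 0.005, bounds={"H": (0, 0)}) == []

    def test_matches_brute_force_oracle(self):
        bounds = {
            "C": (0, 8), "H": (-3, 16), "N": (0, 3),
            "O": (0, 4), "F": (0, 2), "S": (0, 1),
        }
        rng = np.random.default_rng(20260922)
        for delta in rng.uniform(0.0, 150.0, 25):
            expected = brute_force_decompositions(delta, 0.01, bounds)
            got = {c.formula for c in decompose_delta(float(delta), 0.01, bounds)}
            assert got == expected

    def test_library_formulas_round_trip(self):
        for record in load_standard_library():
            if record.formula is None:
                continue
            found = {c.formula for c in decompose_delta(record.formula.mass, 0.005)}
            assert record.formula in found, record.name
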