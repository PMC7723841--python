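"""Library matching, diagnostic flags and delta-mass propagation on the
simulated study."""

from __future__ import annotations

import pytest

from molnet.annotation import (
    class_flags,
    library_from_records,
    library_match,
    report,
)
from molnet.consensus import ConsensusSpectrum
from molnet.library import load_standard_library
from molnet.masscalc import ElementalFormula, parse_formula
from molnet.network import MolecularNetwork
from molnet.spectra_io import Peak

from conftest import node_by_precursor


@pytest.fixture(scope="module")
def theoretical_library():
    return library_from_records(load_standard_library())


class TestLibraryMatch:
    def test_reflexive_on_library(self, theoretical_library):
        for entry in theoretical_library:
            node = ConsensusSpectrum(
                node_id=0,
                member_scan_ids=["x"],
                precursor_mz=entry.spectrum.precursor_mz,
                rt=entry.record.rt,
                precursor_intensity=1e8,
                precursor_charge=1,
                peaks=list(entry.spectrum.peaks),
                groups=frozenset({"G1"}),
            )
            hit = library_match(node, theoretical_library)
            assert hit is not None
            assert hit.entry.record.name == entry.record.name
            assert hit.score == pytest.approx(1.0, abs=1e-9)

    def test_empty_library_raises(self, seizure_result):
        with pytest.raises(ValueError):
            library_match(seizure_result.cleaned.nodes[0], [])

    def test_all_standards_annotated_in_standards_run(self, standards_result):
        names = set(standards_result.annotations.values())
        assert names == {c.name for c in load_standard_library()}

    def test_butyryl_type_not_confused_with_alpha_methylfentanyl(self, seizure_result):
        net = seizure_result.cleaned
        butyryl = node_by_precursor(net, 351.243, rt=212.88)
        assert butyryl.node_id not in seizure_result.annotations
        alpha = node_by_precursor(net, 351.243, rt=409.30)
        assert seizure_result.annotations[alpha.node_id] == "alpha-Methylfentanyl"

    def test_619_unknown_stays_unannotated(self, seizure_result):
        unk = node_by_precursor(seizure_result.cleaned, 619.365)
        assert unk.node_id not in seizure_result.annotations


class TestClassFlags:
    def test_seizure_unknowns_flagged_fentanyl_core(self, seizure_result):
        net = seizure_result.cleaned
        for mz in (403.238, 619.365, 437.280, 393.197):
            node = node_by_precursor(net, mz)
            assert "fentanyl_core" in net.class_flags[node.node_id]

    def test_alpha_methylfentanyl_not_flagged(self, seizure_result):
        net = seizure_result.cleaned
        alpha = node_by_precursor(net, 351.243, rt=409.30)
        assert "fentanyl_core" not in net.class_flags[alpha.node_id]

    def test_empty_spectrum_gets_no_flags(self):
        empty = ConsensusSpectrum(
            node_id=0, member_scan_ids=["x"], precursor_mz=300.0, rt=1.0,
            precursor_intensity=1.0, precursor_charge=1, peaks=[], groups=frozenset({"G1"}),
        )
        assert class_flags(empty) == frozenset()

    def test_any_mode(self):
        one = ConsensusSpectrum(
            node_id=0, member_scan_ids=["x"], precursor_mz=300.0, rt=1.0,
            precursor_intensity=1.0, precursor_charge=1,
            peaks=[Peak(105.0699, 50.0)], groups=frozenset({"G1"}),
        )
        assert class_flags(one) == frozenset()
        assert class_flags(one, require_all=False) == frozenset({"fentanyl_core"})


class TestPropagation:
    def test_headline_unknowns_receive_hypotheses(self, seizure_result):
        net = seizure_result.cleaned
        by_node = {}
        for h in seizure_result.hypotheses:
            by_node.setdefault(h.node_id, []).append(h)
        for mz, rt in ((351.243, 212.88), (393.197, 188.91)):
            node = node_by_precursor(net, mz, rt=rt)
            hyps = by_node[node.node_id]
            assert hyps and all(h.anchor_name for h in hyps)

    def test_393_anchored_by_despropionyl_with_furanyl_moiety(self, seizure_result):
        net = seizure_result.cleaned
        node = node_by_precursor(net, 393.197)
        hyp = next(
            h
            for h in seizure_result.hypotheses
            if h.node_id == node.node_id
            and h.anchor_name == "Despropionyl para-fluorofentanyl"
        )
        assert hyp.delta_mass == pytest.approx(94.005, abs=0.005)
        assert parse_formula("C5H2O2") in {c.formula for c in hyp.delta_formulas}
        assert hyp.cosine_to_anchor >= 0.7

    def test_393_anchored_by_furanylfentanyl_with_f_for_h(self, seizure_result):
        net = seizure_result.cleaned
        node = node_by_precursor(net, 393.197)
        hyp = next(
            h
            for h in seizure_result.hypotheses
            if h.node_id == node.node_id and h.anchor_name == "Furanylfentanyl"
        )
        assert hyp.delta_mass == pytest.approx(17.991, abs=0.005)
        assert ElementalFormula.from_counts({"F": 1, "H": -1}) in {
            c.formula for c in hyp.delta_formulas
        }

    def test_no_hypotheses_for_annotated_nodes(self, seizure_result):
        annotated = set(seizure_result.annotations)
        assert all(h.node_id not in annotated for h in seizure_result.hypotheses)

    def test_delta_matches_edge_delta(self, seizure_result):
        net = seizure_result.cleaned
        edges = {
            frozenset((e.node_a, e.node_b)): e.delta_mass for e in net.edges
        }
        for h in seizure_result.hypotheses:
            edge_delta = edges[frozenset((h.node_id, h.anchor_node_id))]
            assert abs(abs(h.delta_mass) - abs(edge_delta)) <= 1e-9


class TestReport:
    def test_seizure_report_rows(self, seizure_result):
        df = seizure_result.report
        row393 = df[(df["precursor_mz"].astype(float) - 393.197).abs() <= 0.02]
        assert len(row393) == 1
        assert row393.iloc[0]["groups"] == "G2,G3"
        assert row393.iloc[0]["class_flags"] == "fentanyl_core"
        unknown_rows = df[df["id_source"] != "library"]
        assert (unknown_rows["class_flags"] == "fentanyl_core").all()

    def test_standards_report_all_g1_library(self, standards_result):
        df = standards_result.report
        assert len(df) == 30
        assert (df["groups"] == "G1").all()
        assert (df["id_source"] == "library").all()

    def test_empty_network_report_is_header_only(self, tmp_path):
        df = report(MolecularNetwork(nodes=[], edges=[]), path=tmp_path / "r.tsv")
        assert df.empty
        assert (tmp_path / "r.tsv").read_text().startswith("node_id\t")
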