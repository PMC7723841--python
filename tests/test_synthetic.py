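"""The acquisition simulator: determinism, fragment content, artifacts."""

from __future__ import annotations

import filecmp

import numpy as np
import pytest

from molnet.library import load_seizure_compounds, load_standard_library
from molnet.spectra_io import read_mgf
from molnet.synthetic import (
    SimulationConfig,
    simulate_run,
    simulate_spectrum,
    theoretical_peaks,
)


def record(name):
    std = {c.name: c for c in load_standard_library()}
    if name in std:
        return std[name]
    for group in load_seizure_compounds().values():
        for c in group:
            if c.name == name:
                return c
    raise KeyError(name)


def has_peak(spectrum, mz, tol=0.01):
    return any(abs(p.mz - mz) <= tol for p in spectrum.peaks)


class TestLibraryContent:
    def test_library_size_and_classes(self):
        lib = load_standard_library()
        assert len(lib) == 30
        assert sum(c.is_cannabinoid for c in lib) == 16
        assert sum(c.class_tag == "fentanyl_core" for c in lib) == 10
        assert sum(c.class_tag == "fentanyl_noncore" for c in lib) == 4

    def test_jwh018_record(self):
        c = record("JWH-018")
        assert c.precursor_mz == pytest.approx(342.1852, abs=1e-4)
        frags = [mz for mz, _ in c.fragments]
        assert 155.0488 in frags and 214.1221 in frags

    def test_fentanyl_core_fragments(self):
        frags = [mz for mz, _ in record("Fentanyl").fragments]
        assert 188.1434 in frags and 105.0699 in frags

    def test_alpha_methyl_uses_methylated_core(self):
        frags = [mz for mz, _ in record("alpha-Methylfentanyl").fragments]
        assert 202.1590 in frags and 188.1434 not in frags

    def test_class_offset_series_shared(self):
        lib = load_standard_library()
        cann = [c for c in lib if c.is_cannabinoid]
        assert all(c.offset_series == cann[0].offset_series for c in cann)
        assert len(cann[0].offset_series) >= 4


class TestSimulateSpectrum:
    def test_fentanyl_contains_diagnostics_at_every_nce(self):
        cfg = SimulationConfig(seed=3)
        for nce in cfg.collision_energies:
            rng = np.random.default_rng(3)
            s = simulate_spectrum(record("Fentanyl"), nce, rng, cfg)
            assert has_peak(s, 188.1434) and has_peak(s, 105.0699)

    def test_isobaric_pair_discriminated_by_core_fragment(self):
        rng = np.random.default_rng(4)
        cfg = SimulationConfig(seed=4)
        alpha = simulate_spectrum(record("alpha-Methylfentanyl"), 30, rng, cfg)
        butyryl = simulate_spectrum(record("putative (iso)butyrylfentanyl"), 30, rng, cfg)
        assert has_peak(alpha, 202.1590) and not has_peak(alpha, 188.1434)
        assert has_peak(butyryl, 188.1434) and not has_peak(butyryl, 202.1590)

    def test_same_seed_same_spectrum(self):
        cfg = SimulationConfig(seed=5)
        s1 = simulate_spectrum(record("Fentanyl"), 30, np.random.default_rng(5), cfg)
        s2 = simulate_spectrum(record("Fentanyl"), 30, np.random.default_rng(5), cfg)
        assert s1 == s2

    def test_nonnoise_peaks_within_three_sigma(self):
        cfg = SimulationConfig(seed=6, noise_peaks=0)
        rng = np.random.default_rng(6)
        for name in ("Fentanyl", "JWH-018", "WIN-55"):
            rec = record(name)
            s = simulate_spectrum(rec, 20, rng, cfg)
            theo = [p.mz for p in theoretical_peaks(rec)]
            for p in s.peaks:
                assert min(abs(p.mz - t) for t in theo) <= 3.0 * cfg.mz_jitter_sd

    def test_noise_stays_below_five_percent_of_base(self):
        cfg = SimulationConfig(seed=7, noise_peaks=20)
        rng = np.random.default_rng(7)
        rec = record("Fentanyl")
        s = simulate_spectrum(rec, 30, rng, cfg)
        theo = [p.mz for p in theoretical_peaks(rec)]
        noise = [
            p for p in s.peaks if min(abs(p.mz - t) for t in theo) > 3 * cfg.mz_jitter_sd
        ]
        assert noise and all(p.intensity < 0.05 * s.base_peak_intensity for p in noise)


class TestSimulateRun:
    def test_determinism_is_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=11)
        r1 = simulate_run(cfg, "standards", tmp_path / "a")
        r2 = simulate_run(cfg, "standards", tmp_path / "b")
        for p1, p2 in zip(sorted(r1.files), sorted(r2.files)):
            assert filecmp.cmp(p1, p2, shallow=False), (p1, p2)

    def test_different_seeds_differ(self, tmp_path):
        r1 = simulate_run(SimulationConfig(seed=11), "standards", tmp_path / "a")
        r2 = simulate_run(SimulationConfig(seed=12), "standards", tmp_path / "c")
        assert any(
            not filecmp.cmp(p1, p2, shallow=False)
            for p1, p2 in zip(sorted(r1.files), sorted(r2.files))
        )

    def test_standards_scenario_layout(self, tmp_path):
        result = simulate_run(SimulationConfig(seed=1), "standards", tmp_path)
        assert len(result.files) == 3
        assert set(result.files.values()) == {"G1"}
        for path in result.files:
            spectra = read_mgf(path)
            distinct = {round(s.precursor_mz, 2) for s in spectra}
            assert len(distinct) >= 30

    def test_artifact_records_in_g1(self, tmp_path):
        result = simulate_run(SimulationConfig(seed=2), "standards", tmp_path)
        path = next(iter(sorted(result.files)))
        spectra = read_mgf(path)
        jwh_art = [s for s in spectra if abs(s.precursor_mz - 341.1774) <= 0.02]
        assert jwh_art and all(s.precursor_charge == 0 for s in jwh_art)
        truth_art = [t for t in result.truth if t.is_artifact]
        assert len(truth_art) == 5 and all(t.parent for t in truth_art)

    def test_seizure_a_contains_fentanyl_like_unknown(self, tmp_path):
        result = simulate_run(SimulationConfig(seed=3), "seizureA", tmp_path)
        assert set(result.files.values()) == {"G1", "G2"}
        g2 = [p for p, g in result.files.items() if g == "G2"]
        spectra = read_mgf(g2[0])
        hits = [s for s in spectra if abs(s.precursor_mz - 403.238) <= 0.02]
        assert hits
        assert all(has_peak(s, 188.143, 0.02) and has_peak(s, 105.070, 0.02) for s in hits)

    def test_unknown_scenario_raises(self, tmp_path):
        with pytest.raises(ValueError, match="scenario"):
            simulate_run(SimulationConfig(seed=1), "seizureC", tmp_path)

    def test_impurities_are_orders_of_magnitude_lower(self, tmp_path):
        result = simulate_run(SimulationConfig(seed=4), "seizureB", tmp_path)
        g2 = sorted(p for p, g in result.files.items() if g == "G2")
        spectra = read_mgf(g2[0])

        def level(mz):
            vals = [s.precursor_intensity for s in spectra if abs(s.precursor_mz - mz) <= 0.02]
            return float(np.median(vals))

        main = level(393.197)
        for mz in (403.238, 619.365, 437.280):
            ratio = main / level(mz)
            assert 1e2 <= ratio <= 1e3 * 10  # 2–3 orders of magnitude
            assert level(mz) > 1e7  # still above the curation intensity floor
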