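"""Synthetic data-dependent acquisition runs of the standard mixtures.

Emulates the statistical structure the downstream analysis relies on:

* triplicate injections per sample group, three collision-energy (NCE)
  variants per precursor;
* class-shared fragments plus a shared neutral-loss offset series, so
  homologs match both directly and precursor-shifted;
* m/z jitter (normal, truncated at ±3 sd), multiplicative intensity
  noise, low-level random noise peaks;
* in-source artifact records co-eluting with a parent standard, with
  precursor mass [M+H]+ − 1.0078 and undetermined (0) charge;
* G1 standards at 1e8–1e9 precursor intensity, seizure main compounds
  ~1e10, unknown impurities ~2.5 orders of magnitude below those.

Not emulated: real fragmentation chemistry, chromatographic peak shapes,
isotope envelopes. Output is byte-identical for a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .library import (
    SEIZURE_IMPURITIES,
    CompoundRecord,
    load_seizure_compounds,
    load_standard_library,
)
from .spectra_io import Peak, Spectrum, write_mgf

#: Mass of a hydrogen atom, Da — the [M−1] artifact offset.
HYDROGEN_MASS = 1.0078

SCENARIOS = ("standards", "seizureA", "seizureB")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults are the emulated acquisition design
    (triplicates, NCE 20/30/40, 30 s-scale chromatographic stability)."""

    seed: int = 0
    replicates: int = 3
    collision_energies: tuple[int, ...] = (20, 30, 40)
    mz_jitter_sd: float = 0.002  # Th
    intensity_cv: float = 0.2
    noise_peaks: int = 5
    rt_jitter_sd: float = 0.5  # seconds, per scan
    artifact_parents: tuple[str, ...] = (
        "JWH-018",
        "UR-144",
        "JWH-122",
        "Fentanyl",
        "Furanylfentanyl",
    )
    artifact_intensity_scale: float = 1e-3


@dataclass(frozen=True)
class TruthCompound:
    """Generator ground truth for one distinct analyte (or artifact)."""

    name: str
    precursor_mz: float
    rt: float
    class_tag: str
    groups: tuple[str, ...]
    is_artifact: bool = False
    parent: Optional[str] = None


@dataclass
class SimulationResult:
    files: dict[str, str]  # path -> group label
    truth: list[TruthCompound]
    out_dir: str


def _truncated_normal(rng: np.random.Generator, sd: float, size=None):
    """Normal deviate clipped at ±3 sd (keeps every peak within the
    documented 3·sd envelope of its theoretical m/z)."""
    return np.clip(rng.normal(0.0, sd, size=size), -3.0 * sd, 3.0 * sd)


def theoretical_peaks(record: CompoundRecord) -> list[Peak]:
    """Noise-free peak list: fragments plus offset-series peaks."""
    peaks = [Peak(mz, ri) for mz, ri in record.fragments]
    peaks += [
        Peak(record.precursor_mz - off, ri)
        for off, ri in record.offset_series
        if record.precursor_mz - off > 50.0
    ]
    return sorted(peaks)


def simulate_spectrum(
    record: CompoundRecord,
    nce: int,
    rng: np.random.Generator,
    config: SimulationConfig = SimulationConfig(),
    level: float = 1e8,
    charge: int = 1,
    scan_id: str = "",
    source_file: str = "",
    group: str = "",
) -> Spectrum:
    """One DDA scan of ``record`` at collision energy ``nce``.

    Higher NCE tilts the intensity profile toward low-mass fragments;
    noise peaks stay below 5 % of the base peak.
    """
    alpha = 0.25 * (nce - 30) / 10.0  # NCE 20/30/40 -> -0.25/0/+0.25
    mzs, ints = [], []
    for p in theoretical_peaks(record):
        factor = float(np.exp(alpha * (200.0 - p.mz) / 200.0))
        noise = float(np.exp(rng.normal(0.0, config.intensity_cv)))
        mzs.append(p.mz + float(_truncated_normal(rng, config.mz_jitter_sd)))
        ints.append(p.intensity * factor * noise)

    base = max(ints, default=100.0)
    for _ in range(config.noise_peaks):
        mzs.append(float(rng.uniform(50.0, record.precursor_mz - 5.0)))
        ints.append(float(rng.uniform(0.005, 0.03)) * base)

    order = np.argsort(mzs)
    peaks: list[Peak] = []
    last = -np.inf
    for k in order:
        mz = mzs[k]
        if mz - last < 1e-6:
            mz = last + 2e-6
        peaks.append(Peak(mz, ints[k]))
        last = mz

    return Spectrum(
        scan_id=scan_id or f"{record.name}@{nce}",
        precursor_mz=record.precursor_mz + float(_truncated_normal(rng, config.mz_jitter_sd)),
        peaks=peaks,
        precursor_charge=charge,
        precursor_intensity=level * float(np.exp(rng.normal(0.0, 0.3))),
        rt=record.rt + float(_truncated_normal(rng, config.rt_jitter_sd)),
        source_file=source_file,
        group=group,
    )


def _artifact_record(parent: CompoundRecord, rng: np.random.Generator) -> CompoundRecord:
    """In-source [M−1] artifact co-eluting with its parent standard."""
    return CompoundRecord(
        name=f"{parent.name} [M-1]",
        formula=None,
        precursor_mz=parent.precursor_mz - HYDROGEN_MASS,
        rt=parent.rt * (1.0 + float(rng.uniform(-0.001, 0.001))),
        class_tag="artifact",
        fragments=parent.fragments,
        offset_series=parent.offset_series,
    )


def _scenario_groups(scenario: str) -> list[str]:
    if scenario == "standards":
        return ["G1"]
    if scenario == "seizureA":
        return ["G1", "G2"]
    if scenario == "seizureB":  # the full study: both seizures + standards
        return ["G1", "G2", "G3"]
    raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


def simulate_run(
    config: SimulationConfig,
    scenario: str,
    out_dir: str | os.PathLike,
) -> SimulationResult:
    """Write the grouped triplicate MGF files for a scenario.

    ``standards`` produces G1 only; ``seizureA`` adds the seizure-A
    constituents as G2; ``seizureB`` is the full study (G1+G2+G3).
    Returns the file→group map and the per-compound ground truth.
    """
    groups = _scenario_groups(scenario)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    standards = load_standard_library()
    seizure = load_seizure_compounds()

    rng_setup = np.random.default_rng(config.seed)
    # Per-compound precursor-intensity levels, drawn in a fixed order.
    levels: dict[tuple[str, str], float] = {}
    for c in standards:
        levels[("G1", c.name)] = 10.0 ** (8.0 + float(rng_setup.uniform(0.0, 1.0)))
    artifacts = []
    for name in config.artifact_parents:
        parent = next((c for c in standards if c.name == name), None)
        if parent is None:
            raise ValueError(f"artifact parent {name!r} is not a standard")
        art = _artifact_record(parent, rng_setup)
        artifacts.append((art, parent))
        levels[("G1", art.name)] = levels[("G1", parent.name)] * config.artifact_intensity_scale
    for g in ("G2", "G3"):
        for c in seizure[g]:
            if c.name in SEIZURE_IMPURITIES:
                # 2–3 orders of magnitude below the main seizure peaks,
                # yet safely above the 1e7 curation intensity floor
                levels[(g, c.name)] = 10.0 ** (7.7 + float(rng_setup.uniform(0.0, 0.3)))
            else:
                levels[(g, c.name)] = 10.0 ** (10.0 + float(rng_setup.uniform(0.0, 0.3)))

    contents: dict[str, list[tuple[CompoundRecord, float, int]]] = {
        "G1": [(c, levels[("G1", c.name)], 1) for c in standards]
        + [(a, levels[("G1", a.name)], 0) for a, _ in artifacts],
    }
    for g in ("G2", "G3"):
        contents[g] = [(c, levels[(g, c.name)], 1) for c in seizure[g]]

    n_files = len(groups) * config.replicates
    streams = np.random.SeedSequence(config.seed).spawn(n_files)
    files: dict[str, str] = {}
    i = 0
    for g in groups:
        for rep in range(1, config.replicates + 1):
            rng = np.random.default_rng(streams[i])
            i += 1
            fname = f"{g}_rep{rep}.mgf"
            path = os.path.join(out_dir, fname)
            spectra = []
            scan = 0
            for record, level, charge in contents[g]:
                for nce in config.collision_energies:
                    scan += 1
                    spectra.append(
                        simulate_spectrum(
                            record,
                            nce,
                            rng,
                            config,
                            level=level,
                            charge=charge,
                            scan_id=f"{g}_rep{rep}.scan{scan:04d}",
                            source_file=fname,
                            group=g,
                        )
                    )
            write_mgf(spectra, path)
            files[path] = g

    truth_map: dict[str, TruthCompound] = {}
    for g in groups:
        for record, _level, _charge in contents[g]:
            prev = truth_map.get(record.name)
            grps = (prev.groups if prev else ()) + (g,)
            truth_map[record.name] = TruthCompound(
                name=record.name,
                precursor_mz=record.precursor_mz,
                rt=record.rt,
                class_tag=record.class_tag,
                groups=grps,
                is_artifact=record.class_tag == "artifact",
                parent=next((p.name for a, p in artifacts if a.name == record.name), None),
            )
    return SimulationResult(files=files, truth=list(truth_map.values()), out_dir=out_dir)
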