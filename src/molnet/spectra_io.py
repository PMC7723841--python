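"""Reading, writing and group-labelling of centroided MS/MS spectra (MGF).

MGF (Mascot generic format) is the interchange format of the pipeline:
plain text, one ``BEGIN IONS``/``END IONS`` block per scan. Parsing goes
through :mod:`pyteomics.mgf`; writing is done by hand so that output is
byte-stable for a given spectrum list. Charge-0 records are accepted and
round-trip — in-source artifact scans carry an undetermined charge.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from pyteomics import mgf as _mgf


class MGFParseError(ValueError):
    """Malformed MGF record; the message names the offending record."""


class Peak(NamedTuple):
    """One centroided fragment peak."""

    mz: float  # Th, > 0
    intensity: float  # arbitrary units, >= 0


@dataclass
class Spectrum:
    """One centroided MS/MS scan with precursor metadata.

    Peaks are kept strictly sorted by m/z with no duplicates within
    1e-6 Th. ``precursor_charge`` 0 means undetermined. ``group`` is the
    sample-group label (G1 standards, G2/G3 seizures) attached by
    :func:`assign_groups`.
    """

    scan_id: str
    precursor_mz: float
    peaks: list[Peak]
    precursor_charge: int = 0
    precursor_intensity: float = 0.0
    rt: float = 0.0  # seconds
    source_file: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"{self.scan_id}: precursor_mz must be positive")
        if self.precursor_charge < 0:
            raise ValueError(f"{self.scan_id}: precursor_charge must be >= 0")
        self.peaks = [Peak(float(mz), float(i)) for mz, i in self.peaks]
        for p in self.peaks:
            if p.mz <= 0 or p.intensity < 0:
                raise ValueError(f"{self.scan_id}: invalid peak {p}")
        self.peaks.sort(key=lambda p: p.mz)
        for a, b in zip(self.peaks, self.peaks[1:]):
            if b.mz - a.mz < 1e-6:
                raise ValueError(
                    f"{self.scan_id}: duplicate peak m/z {a.mz!r}/{b.mz!r}"
                )

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    @property
    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)


def read_mgf(path: str | os.PathLike, rt_missing: str = "zero") -> list[Spectrum]:
    """Read an MGF file into :class:`Spectrum` records.

    ``rt_missing`` controls records without RTINSECONDS: ``"zero"`` stores
    0.0, ``"error"`` raises. Missing CHARGE is stored as 0 (undetermined).
    A record without PEPMASS, or with a non-numeric peak line, raises
    :class:`MGFParseError` naming the record index.
    """
    if rt_missing not in ("zero", "error"):
        raise ValueError("rt_missing must be 'zero' or 'error'")
    path = os.fspath(path)
    spectra: list[Spectrum] = []
    source = os.path.basename(path)
    with _mgf.MGF(path, convert_arrays=1) as reader:
        index = 0
        while True:
            try:
                entry = next(reader)
            except StopIteration:
                break
            except Exception as exc:  # pyteomics raises on bad numeric fields
                raise MGFParseError(f"{source}: malformed record {index}: {exc}") from exc
            params = entry.get("params", {})
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise MGFParseError(f"{source}: record {index} lacks PEPMASS")
            pepmass = params["pepmass"]
            prec_int = float(pepmass[1]) if len(pepmass) > 1 and pepmass[1] else 0.0
            charge_field = params.get("charge")
            charge = int(charge_field[0]) if charge_field else 0
            if "rtinseconds" in params:
                rt = float(params["rtinseconds"])
            elif rt_missing == "error":
                raise MGFParseError(f"{source}: record {index} lacks RTINSECONDS")
            else:
                rt = 0.0
            scan_id = str(params.get("title", "")) or f"{source}:{index}"
            peaks = [
                Peak(float(mz), float(i))
                for mz, i in zip(entry["m/z array"], entry["intensity array"])
            ]
            try:
                spectra.append(
                    Spectrum(
                        scan_id=scan_id,
                        precursor_mz=float(pepmass[0]),
                        peaks=peaks,
                        precursor_charge=charge,
                        precursor_intensity=prec_int,
                        rt=rt,
                        source_file=source,
                    )
                )
            except ValueError as exc:
                raise MGFParseError(f"{source}: record {index}: {exc}") from exc
            index += 1
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | os.PathLike) -> None:
    """Write spectra as MGF; byte-identical output for identical input.

    Floats are written with ``repr`` (shortest exact form) so a
    read-after-write round-trip reproduces the in-memory values exactly.
    Charge 0 is written as no CHARGE line and re-reads as 0.
    """
    with open(path, "w", newline="\n") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.scan_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz!r} {s.precursor_intensity!r}\n")
            if s.precursor_charge > 0:
                fh.write(f"CHARGE={s.precursor_charge}+\n")
            fh.write(f"RTINSECONDS={s.rt!r}\n")
            for p in s.peaks:
                fh.write(f"{p.mz!r} {p.intensity!r}\n")
            fh.write("END IONS\n")


def assign_groups(
    group_map: Mapping[str, str], spectra: Iterable[Spectrum]
) -> list[Spectrum]:
    """Attach group labels (G1/G2/G3/...) by source file name.

    ``group_map`` maps file names (basenames or full paths, as produced by
    :func:`read_mgf`) to labels. A spectrum whose source file has no label
    raises ``KeyError``.
    """
    norm = {os.path.basename(k): v for k, v in group_map.items()}
    out = []
    for s in spectra:
        key = os.path.basename(s.source_file)
        if key not in norm:
            raise KeyError(f"no group label for file {s.source_file!r}")
        label = norm[key]
        if not label:
            raise ValueError(f"empty group label for file {s.source_file!r}")
        out.append(replace(s, group=label))
    return out
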