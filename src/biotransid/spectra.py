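"""MS1 peak tables and MS2 spectra across biological matrices.

Seven matrix codes are recognised: PM, PA, PS (plasma prepared by methanol
precipitation, acetonitrile precipitation, and solid-phase extraction), U
(urine), F (feces), L (liver), LM (liver microsome incubation). Peak tables
travel as CSV (matrix, polarity, rt_min, mz, intensity[, feature_id]); MS2
spectra travel as MGF with retention time converted to minutes on read and
fragment intensities rescaled so the base peak is 100.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

from pyteomics import mgf as _mgf

MATRICES: Tuple[str, ...] = ("PM", "PA", "PS", "U", "F", "L", "LM")
PLASMA_MATRICES: Tuple[str, ...] = ("PM", "PA", "PS")
POLARITIES: Tuple[str, ...] = ("negative", "positive")


class PeakTableError(ValueError):
    """Invalid peak-table contents; the message names the offending row."""


@dataclass(frozen=True)
class Peak:
    """One MS1 feature observed in one matrix.

    ``feature_id`` is an optional provenance label (kept through round trips)
    used by synthetic runs to tag which true signal or decoy produced the
    peak; real acquisitions leave it empty.
    """

    matrix: str
    polarity: str
    rt: float
    mz: float
    intensity: float
    feature_id: Optional[str] = None

    def __post_init__(self):
        if self.matrix not in MATRICES:
            raise PeakTableError(f"unknown matrix {self.matrix!r}")
        if self.polarity not in POLARITIES:
            raise PeakTableError(f"unknown polarity {self.polarity!r}")
        if self.mz <= 0:
            raise PeakTableError("mz must be positive")
        if self.rt < 0:
            raise PeakTableError("rt must be non-negative")
        if self.intensity < 0:
            raise PeakTableError("intensity must be non-negative")


@dataclass(frozen=True)
class MS2Spectrum:
    """A product-ion spectrum with base-peak-normalised intensities."""

    precursor_mz: float
    polarity: str
    rt: float
    fragments: Tuple[Tuple[float, float], ...]
    feature_id: Optional[str] = None

    def __post_init__(self):
        if not self.fragments:
            raise ValueError("spectrum must contain at least one fragment")
        if self.polarity not in POLARITIES:
            raise ValueError(f"unknown polarity {self.polarity!r}")
        for mz, rel in self.fragments:
            if not 0 < rel <= 100:
                raise ValueError(f"relative intensity {rel} outside (0, 100]")
            if mz >= self.precursor_mz + 1.0:
                raise ValueError(
                    f"fragment m/z {mz} above precursor {self.precursor_mz} + 1.0"
                )

    @staticmethod
    def normalise(fragments: Sequence[Tuple[float, float]]) -> Tuple[Tuple[float, float], ...]:
        """Rescale raw fragment intensities so the base peak is 100."""
        base = max(i for _, i in fragments)
        return tuple((mz, i / base * 100.0) for mz, i in fragments if i > 0)


@dataclass(frozen=True)
class IntensityThresholds:
    """Polarity-specific minimum MS1 intensities for feature selection."""

    positive_min: float = 40_000.0
    negative_min: float = 10_000.0

    def __post_init__(self):
        if self.positive_min <= 0 or self.negative_min <= 0:
            raise ValueError("intensity thresholds must be positive")

    def minimum(self, polarity: str) -> float:
        return self.positive_min if polarity == "positive" else self.negative_min


def filter_by_intensity(peaks: Sequence[Peak], thresholds: IntensityThresholds) -> List[Peak]:
    """Keep peaks with intensity >= the threshold for their polarity (inclusive)."""
    return [p for p in peaks if p.intensity >= thresholds.minimum(p.polarity)]


_PEAK_COLUMNS = ("matrix", "polarity", "rt_min", "mz", "intensity")
_POLARITY_ALIASES = {
    "neg": "negative", "negative": "negative", "-": "negative",
    "pos": "positive", "positive": "positive", "+": "positive",
}


def read_peak_table(path: str | Path) -> List[Peak]:
    """Read a peak-table CSV; raises :class:`PeakTableError` naming bad rows."""
    peaks: List[Peak] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        missing = [c for c in _PEAK_COLUMNS if c not in header]
        if missing:
            raise PeakTableError(f"missing column(s) {missing} in {path}")
        for lineno, row in enumerate(reader, start=2):
            try:
                polarity = _POLARITY_ALIASES[row["polarity"].strip().lower()]
                peak = Peak(
                    matrix=row["matrix"].strip(),
                    polarity=polarity,
                    rt=float(row["rt_min"]),
                    mz=float(row["mz"]),
                    intensity=float(row["intensity"]),
                    feature_id=(row.get("feature_id") or None),
                )
            except (KeyError, ValueError) as exc:
                raise PeakTableError(f"{path} row {lineno}: {exc}") from exc
            peaks.append(peak)
    return peaks


def write_peak_table(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as CSV, m/z at 5 decimals and intensity at 2 (bit-stable)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(_PEAK_COLUMNS + ("feature_id",))
        for p in peaks:
            writer.writerow(
                [p.matrix, p.polarity, f"{p.rt:.2f}", f"{p.mz:.5f}",
                 f"{p.intensity:.2f}", p.feature_id or ""]
            )


def read_ms2_mgf(path: str | Path) -> List[MS2Spectrum]:
    """Read MS2 spectra from MGF; intensities are base-peak normalised.

    PEPMASS is required per block; CHARGE sign sets polarity (negative when
    the charge string carries '-'); RTINSECONDS is converted to minutes.
    """
    spectra: List[MS2Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for block in reader:
            params = block["params"]
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise ValueError(f"{path}: MGF block without PEPMASS")
            if len(block["m/z array"]) == 0:
                raise ValueError(f"{path}: MGF block with empty fragment list")
            charge = params.get("charge")
            negative = "-" in str(charge) if charge is not None else False
            raw = list(zip(block["m/z array"].tolist(), block["intensity array"].tolist()))
            spectra.append(
                MS2Spectrum(
                    precursor_mz=float(params["pepmass"][0]),
                    polarity="negative" if negative else "positive",
                    rt=float(params.get("rtinseconds", 0.0)) / 60.0,
                    fragments=MS2Spectrum.normalise(raw),
                    feature_id=params.get("title") or None,
                )
            )
    return spectra


def write_ms2_mgf(spectra: Sequence[MS2Spectrum], path: str | Path) -> None:
    """Write spectra as MGF (RT in seconds, charge 1 with polarity sign)."""
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": [mz for mz, _ in s.fragments],
                "intensity array": [rel for _, rel in s.fragments],
                "params": {
                    "title": s.feature_id or "",
                    "pepmass": s.precursor_mz,
                    "rtinseconds": s.rt * 60.0,
                    "charge": "1-" if s.polarity == "negative" else "1+",
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")
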