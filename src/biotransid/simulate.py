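"""Synthetic multi-matrix LC-MS runs built from the packaged metabolite table.

The generator emulates the study conditions: for every reference row and
every matrix in which it was detected, one MS1 peak is emitted at the row's
experimental m/z perturbed by a seeded uniform ppm jitter, with an intensity
above the polarity-specific selection threshold; one MS2 spectrum per row
reproduces its published (truncated, base-peak-normalised) fragment list.
Decoy peaks — true negatives by construction — are drawn uniformly in m/z but
rejected within an exclusion window of every reference mass and of any extra
masses supplied (typically the full candidate-set ion masses, so that no
decoy can legitimately satisfy the matcher). The run is fully deterministic
given the seed.

Not emulated: chromatographic peak shape, isotope envelopes, correlated
noise, and real ion-suppression effects — so perfect recovery here bounds
pipeline correctness, not instrument performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .dataset import FixtureRow, load_fixture
from .spectra import MS2Spectrum, Peak


@dataclass(frozen=True)
class SyntheticRunConfig:
    """Study-condition knobs for a synthetic run.

    Defaults mirror the source acquisition: up to ~5 ppm observed mass error,
    negative-mode base intensity 50,000 (five times the negative selection
    threshold; absolute intensities are not published, so any supra-threshold
    scale is equivalent), and no deliberately sub-threshold emissions.
    """

    jitter_ppm: float = 5.0
    decoy_count_per_matrix: int = 8
    decoy_mz_range: Tuple[float, float] = (100.0, 700.0)
    base_intensity: float = 50_000.0
    below_threshold_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.jitter_ppm < 0:
            raise ValueError("jitter_ppm must be >= 0")
        if self.decoy_count_per_matrix < 0:
            raise ValueError("decoy_count_per_matrix must be >= 0")
        if not 0 <= self.below_threshold_fraction < 1:
            raise ValueError("below_threshold_fraction must be in [0, 1)")
        if self.decoy_mz_range[0] >= self.decoy_mz_range[1]:
            raise ValueError("decoy_mz_range must be (min, max) with min < max")


def generate_run(
    fixture: Optional[Sequence[FixtureRow]] = None,
    config: SyntheticRunConfig = SyntheticRunConfig(),
    exclusion_masses: Sequence[float] = (),
    exclusion_ppm: float = 20.0,
) -> Tuple[List[Peak], List[MS2Spectrum]]:
    """Generate (MS1 peaks, MS2 spectra) for all seven matrices.

    ``exclusion_masses`` extends the decoy keep-out list beyond the reference
    experimental and theoretical masses; ``exclusion_ppm`` is the half-width
    of the keep-out window (twice the default 10-ppm matching tolerance).
    Peaks carry the originating row's metabolite label (or ``decoy:<matrix>:n``)
    as ``feature_id``.
    """
    fixture = list(load_fixture() if fixture is None else fixture)
    rng = np.random.default_rng(config.seed)

    peaks: List[Peak] = []
    spectra: List[MS2Spectrum] = []
    for row in fixture:
        for matrix, present in row.presence.items():
            if not present:
                continue
            eps = rng.uniform(-config.jitter_ppm, config.jitter_ppm)
            mz = row.experimental_mz * (1 + eps * 1e-6)
            threshold = 40_000.0 if row.polarity == "positive" else 10_000.0
            intensity = max(config.base_intensity, threshold * 1.25) * rng.uniform(1.0, 3.0)
            if config.below_threshold_fraction and rng.random() < config.below_threshold_fraction:
                intensity = threshold * 0.5
            peaks.append(
                Peak(matrix=matrix, polarity=row.polarity, rt=row.rt, mz=mz,
                     intensity=intensity, feature_id=row.metabolite_id)
            )
        # published fragment lists occasionally include ions above the
        # precursor (in-source artifacts); a valid MS2 spectrum cannot
        fragments = [(mz, i) for mz, i in row.fragments if mz < row.experimental_mz + 1.0]
        if fragments:
            spectra.append(
                MS2Spectrum(
                    precursor_mz=row.experimental_mz,
                    polarity=row.polarity,
                    rt=row.rt,
                    fragments=MS2Spectrum.normalise(fragments),
                    feature_id=row.metabolite_id,
                )
            )

    keepout = np.array(
        sorted(
            {r.experimental_mz for r in fixture}
            | {r.theoretical_mz_printed for r in fixture}
            | set(exclusion_masses)
        )
    )
    lo_mz, hi_mz = config.decoy_mz_range
    for matrix in sorted({m for r in fixture for m, p in r.presence.items() if p}):
        n_emitted = 0
        while n_emitted < config.decoy_count_per_matrix:
            mz = rng.uniform(lo_mz, hi_mz)
            if _near_any(mz, keepout, exclusion_ppm):
                continue
            intensity = config.base_intensity * rng.uniform(1.0, 3.0)
            peaks.append(
                Peak(matrix=matrix, polarity="negative",
                     rt=float(rng.uniform(1.0, 25.0)), mz=mz, intensity=intensity,
                     feature_id=f"decoy:{matrix}:{n_emitted}")
            )
            n_emitted += 1
    return peaks, spectra


def _near_any(mz: float, sorted_masses: np.ndarray, ppm: float) -> bool:
    half = ppm * 1e-6 * mz
    i = np.searchsorted(sorted_masses, mz)
    for j in (i - 1, i):
        if 0 <= j < len(sorted_masses) and abs(mz - sorted_masses[j]) <= half:
            return True
    return False
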