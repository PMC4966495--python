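"""Intact-protein ESI mass spectrometry utilities.

Continuum electrospray spectra of intact antibody sub-units show a series
of multiply protonated charge states; the neutral average mass M appears
at m/z = (M + z * m_proton) / z for each charge z.  Deconvolution here is
a transparent charge-comb score: for every candidate neutral mass on a
grid, the continuum intensity is sampled (linear interpolation) at the
m/z positions implied by each charge in the search range and summed.
Local maxima of that score, supported by at least two distinct charge
states, are accepted and refined to sub-grid precision with a quadratic
fit around the apex.  Two supporting charges are the minimum because a
single peak cannot determine its own charge.

Mass deltas between deconvolved species are interpreted against a small
modification table (water loss, glycoform hexose spacing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "PROTON_MASS",
    "MassSpectrum",
    "DeconvolvedMass",
    "MassMatch",
    "Modification",
    "ModificationTable",
    "DEFAULT_MODIFICATIONS",
    "pick_peaks",
    "deconvolve",
    "ppm_error",
    "explain_mass_delta",
]

#: Average mass of the charge carrier (proton), positive-ion mode.
PROTON_MASS: float = 1.00728


@dataclass
class MassSpectrum:
    """A continuum spectrum: m/z (Th) vs intensity on an increasing grid."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.size == 0:
            raise ValueError("spectrum needs a non-empty 1-D m/z axis")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z grid must be strictly increasing")


@dataclass
class DeconvolvedMass:
    """A neutral average mass inferred from a charge-state envelope."""

    neutral_average_mass: float
    summed_intensity: float
    supporting_charges: tuple[int, ...]
    score: float


@dataclass
class MassMatch:
    observed: float
    predicted: float
    ppm_error: float
    modification: str | None = None


@dataclass(frozen=True)
class Modification:
    name: str
    mass_delta: float
    tolerance: float

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError(f"modification {self.name!r}: tolerance must be positive")


@dataclass
class ModificationTable:
    """Known mass deltas between sub-unit species.

    Entries must be mutually distinguishable: any two deltas must differ by
    more than the sum of their tolerances, otherwise a lookup could tie.
    """

    entries: tuple[Modification, ...]

    def __post_init__(self) -> None:
        for i, a in enumerate(self.entries):
            for b in self.entries[i + 1 :]:
                if abs(a.mass_delta - b.mass_delta) <= a.tolerance + b.tolerance:
                    raise ValueError(
                        f"overlapping modification entries: {a.name!r} and {b.name!r}"
                    )


#: Water loss (in-source or in-solution dehydration) and the one-hexose
#: spacing between the G0F and G1F heavy-chain glycoforms.
DEFAULT_MODIFICATIONS = ModificationTable(
    entries=(
        Modification("dehydration", -18.02, 1.5),
        Modification("hexose", +162.14, 0.8),
    )
)


def pick_peaks(spec: MassSpectrum, snr_threshold: float = 3.0) -> list[tuple[float, float]]:
    """Centroid a continuum spectrum.

    Contiguous regions above ``snr_threshold`` times the robust noise level
    (median absolute deviation of first differences, scaled) are collapsed
    to their intensity-weighted centroid.  For noise-free input a small
    floor relative to the base peak is used instead.

    Returns a list of ``(mz, intensity)`` with intensity the region's
    summed continuum intensity.
    """
    if spec.mz.size == 0:
        raise ValueError("empty spectrum")
    intensity = spec.intensity
    max_int = float(intensity.max(initial=0.0))
    if max_int <= 0:
        return []
    diffs = np.diff(intensity)
    noise_sd = float(np.median(np.abs(diffs - np.median(diffs)))) / 0.6745 / np.sqrt(2.0)
    threshold = max(snr_threshold * noise_sd, 1e-6 * max_int)
    above = intensity > threshold
    centroids: list[tuple[float, float]] = []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = [0] if above[0] else []
    starts += [int(e) + 1 for e in edges if not above[e]]
    stops = [int(e) + 1 for e in edges if above[e]]
    if above[-1]:
        stops.append(int(above.size))
    for start, stop in zip(starts, stops):
        seg_i = intensity[start:stop]
        seg_mz = spec.mz[start:stop]
        total = float(seg_i.sum())
        if total <= 0:
            continue
        centroids.append((float(np.dot(seg_mz, seg_i) / total), total))
    return centroids


def _refine_apex(masses: np.ndarray, score: np.ndarray, idx: int, max_half_width: int) -> float:
    """Least-squares parabola through the score apex neighborhood.

    The fit spans the contiguous region around the apex where the score
    stays above 60% of its apex value (clipped to ``max_half_width`` grid
    points each side) — roughly the +/- one-sigma core of the score peak.
    Averaging over that region is markedly more noise-stable than a
    three-point vertex while reducing to it exactly for a locally
    quadratic score.
    """
    level = 0.6 * score[idx]
    lo = idx
    while lo > max(0, idx - max_half_width) and score[lo - 1] >= level:
        lo -= 1
    hi = idx
    while hi < min(score.size - 1, idx + max_half_width) and score[hi + 1] >= level:
        hi += 1
    if hi - lo < 2:
        lo, hi = max(0, idx - 1), min(score.size - 1, idx + 1)
    if hi - lo < 2:
        return float(masses[idx])
    x = masses[lo : hi + 1] - masses[idx]
    y = score[lo : hi + 1]
    a, b, _c = np.polyfit(x, y, 2)
    if a >= 0:
        return float(masses[idx])
    vertex = -b / (2 * a)
    # clamp to the fit window; a vertex outside it means the fit is unreliable
    vertex = float(np.clip(vertex, x[0], x[-1]))
    return float(masses[idx] + vertex)


def deconvolve(
    spec: MassSpectrum,
    mass_window: tuple[float, float],
    charge_range: tuple[int, int],
    grid_step: float = 0.1,
    min_supporting_charges: int = 2,
    support_threshold_rel: float = 0.02,
    min_separation: float = 5.0,
) -> list[DeconvolvedMass]:
    """Charge-comb deconvolution of a continuum spectrum to neutral masses.

    Parameters
    ----------
    mass_window
        ``(low, high)`` neutral mass search window in Da.
    charge_range
        ``(z_min, z_max)`` inclusive positive charge states to sum over.
    grid_step
        Candidate-mass grid spacing in Da.
    min_supporting_charges
        Distinct charge states whose sampled intensity must exceed
        ``support_threshold_rel`` times the base peak for a mass to be
        accepted (default 2: a single charge state is charge-ambiguous).
    min_separation
        Minimum spacing in Da between reported score maxima.

    Returns accepted masses sorted by descending score.
    """
    lo, hi = mass_window
    if hi <= lo:
        raise ValueError("empty mass window")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    z_min, z_max = charge_range
    if z_min < 1 or z_max < z_min:
        raise ValueError("invalid charge range")

    masses = np.arange(lo, hi + grid_step / 2, grid_step)
    score = np.zeros_like(masses)
    per_charge = np.zeros((z_max - z_min + 1, masses.size))
    mz_lo, mz_hi = float(spec.mz[0]), float(spec.mz[-1])
    for row, z in enumerate(range(z_min, z_max + 1)):
        mz = (masses + z * PROTON_MASS) / z
        vals = np.interp(mz, spec.mz, spec.intensity, left=0.0, right=0.0)
        vals[(mz < mz_lo) | (mz > mz_hi)] = 0.0
        per_charge[row] = vals
        score += vals

    max_int = float(spec.intensity.max(initial=0.0))
    if max_int <= 0 or score.max() <= 0:
        return []
    support_level = support_threshold_rel * max_int
    distance = max(1, int(round(min_separation / grid_step)))
    apices, _ = find_peaks(score, distance=distance, height=1e-9 * score.max())
    results: list[DeconvolvedMass] = []
    max_half_width = max(1, int(round(0.5 * min_separation / grid_step)))
    for idx in apices:
        supporters = tuple(
            z
            for row, z in enumerate(range(z_min, z_max + 1))
            if per_charge[row, idx] > support_level
        )
        if len(supporters) < min_supporting_charges:
            continue
        refined = _refine_apex(masses, score, int(idx), max_half_width)
        results.append(
            DeconvolvedMass(
                neutral_average_mass=refined,
                summed_intensity=float(score[idx]),
                supporting_charges=supporters,
                score=float(score[idx]),
            )
        )
    results.sort(key=lambda r: r.score, reverse=True)
    return results


def ppm_error(observed: float, predicted: float) -> float:
    """Signed parts-per-million mass error of ``observed`` vs ``predicted``."""
    if predicted <= 0:
        raise ValueError("predicted mass must be positive")
    return 1e6 * (observed - predicted) / predicted


def explain_mass_delta(
    observed_delta: float, table: ModificationTable = DEFAULT_MODIFICATIONS
) -> Modification | None:
    """Return the unique modification explaining a mass delta, or ``None``.

    The table invariant (deltas distinct beyond combined tolerances)
    guarantees at most one entry can match.
    """
    for entry in table.entries:
        if abs(observed_delta - entry.mass_delta) <= entry.tolerance:
            return entry
    return None
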