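"""Synthetic instrument data with controlled ground truth.

Generators for every input the pipeline consumes:

* first-dimension HIC-UV chromatograms of three conjugate batches (low,
  medium, high drug load) with the eight-peak distribution profile,
  per-load target areas, replicate area jitter and baseline noise;
* second-dimension RP traces and continuum ESI spectra of the dissociated
  sub-units of any isoform, as multi-charge envelopes with glycoform
  variants and an optional dehydration satellite;
* complete batch datasets (triplicate chromatograms + per-peak heart-cut
  spectra + a JSON ground-truth manifest).

The generators emulate the *statistical* structure of the measurements —
elution order by drug load, relative areas, replicate variability, charge
envelopes inside the 500–4,000 m/z acquisition window — not the physics of
retention or ionization.  Ground truth always travels alongside generated
data in a manifest so downstream tests never read truth from the code
path under test.

The bundled conjugate fixture is SYNTHETIC: its chain base masses are
back-derived from the observed conjugated sub-unit masses of the study
system (light+1 drug = 23,580.0 Da, heavy(G0F)+3 drugs = 51,630.6 Da) with
a 376.46 Da drug-mimic, since the mAb sequence is proprietary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from cysadc.conjugate_model import (
    AssemblySpec,
    ChainSpec,
    ChemicalFormula,
    DisulfideBond,
    DissociationSignature,
    DrugLinker,
    IsoformClass,
    dissociate,
    enumerate_isoforms,
)
from cysadc.hic_quant import Chromatogram
from cysadc.ms_tools import PROTON_MASS, MassSpectrum

__all__ = [
    "LIGHT_REDUCED_MASS",
    "HEAVY_G0F_REDUCED_MASS",
    "G1F_DELTA",
    "DRUG_AVERAGE_MASS",
    "DRUG_FORMULA",
    "reference_igg1_assembly",
    "HicPeakSpec",
    "BatchProfileConfig",
    "EnvelopeConfig",
    "batch_config",
    "BATCH_AREA_PERCENTS",
    "DEFAULT_PEAK_GROUPING",
    "DEFAULT_PEAK_ISOFORMS",
    "make_hic_chromatogram",
    "make_heart_cut_spectrum",
    "make_batch_dataset",
    "charge_range_for_mass",
]

# --- synthetic conjugate fixture (back-derived, see module docstring) ----
LIGHT_REDUCED_MASS: float = 23203.54
HEAVY_G0F_REDUCED_MASS: float = 50501.22
G1F_DELTA: float = 162.14
DRUG_AVERAGE_MASS: float = 376.46
DRUG_FORMULA: str = "C23H24N2O3"


def reference_igg1_assembly() -> AssemblySpec:
    """The bundled IgG1 drug-mimic conjugate fixture.

    Four inter-chain disulfides (two light–heavy, two hinge), the
    two-fold molecular symmetry plus the hinge-bond exchange, and the
    synthetic back-derived chain masses above.
    """
    light = ChainSpec(role="light", reduced_average_mass=LIGHT_REDUCED_MASS)
    heavy = ChainSpec(
        role="heavy",
        reduced_average_mass=HEAVY_G0F_REDUCED_MASS,
        glycoforms=(("G0F", 0.0), ("G1F", G1F_DELTA)),
    )
    bonds = (
        DisulfideBond("LC-HC-1", (("L1", "LC-HC"), ("H1", "LC-HC"))),
        DisulfideBond("LC-HC-2", (("L2", "LC-HC"), ("H2", "LC-HC"))),
        DisulfideBond("hinge-1", (("H1", "hinge"), ("H2", "hinge"))),
        DisulfideBond("hinge-2", (("H1", "hinge"), ("H2", "hinge"))),
    )
    flip = {
        "LC-HC-1": "LC-HC-2",
        "LC-HC-2": "LC-HC-1",
        "hinge-1": "hinge-2",
        "hinge-2": "hinge-1",
    }
    hinge_swap = {
        "LC-HC-1": "LC-HC-1",
        "LC-HC-2": "LC-HC-2",
        "hinge-1": "hinge-2",
        "hinge-2": "hinge-1",
    }
    return AssemblySpec(
        chains={"L1": light, "L2": light, "H1": heavy, "H2": heavy},
        bonds=bonds,
        drug=DrugLinker(
            average_mass=DRUG_AVERAGE_MASS,
            formula=ChemicalFormula.from_string(DRUG_FORMULA),
        ),
        symmetries=(flip, hinge_swap),
    )


# --- HIC batch profiles --------------------------------------------------

#: Per-load relative areas (%) of the three conjugate batches.
BATCH_AREA_PERCENTS: dict[str, dict[int, float]] = {
    "low": {0: 16.73, 2: 40.71, 4: 28.56, 6: 12.54, 8: 1.50},
    "medium": {0: 2.80, 2: 18.85, 4: 41.69, 6: 26.87, 8: 9.79},
    "high": {0: 0.37, 2: 3.42, 4: 30.67, 6: 28.60, 8: 36.90},
}

#: Elution layout: (label, apex min, drug load).  Apex times are plumbing;
#: only the elution ORDER (increasing load/hydrophobicity) is meaningful.
_PEAK_LAYOUT: tuple[tuple[str, float, int], ...] = (
    ("A", 2.0, 0),
    ("B", 3.0, 2),
    ("C", 4.0, 4),
    ("D", 4.5, 4),
    ("E", 5.3, 6),
    ("F", 5.8, 6),
    ("G", 6.3, 6),
    ("H", 7.5, 8),
)

#: Within-load area splits.  The DAR-6 split is the observed, batch-stable
#: E/F/G proportion; the DAR-4 C:D split is a configurable default (C is
#: the dominant DAR-4 species).
_WITHIN_LOAD_FRACTIONS: dict[int, dict[str, float]] = {
    0: {"A": 1.0},
    2: {"B": 1.0},
    4: {"C": 0.8, "D": 0.2},
    6: {"E": 0.437, "F": 0.141, "G": 0.422},
    8: {"H": 1.0},
}

DEFAULT_PEAK_GROUPING: dict[str, int] = {lbl: load for lbl, _apex, load in _PEAK_LAYOUT}

#: Isoform behind each HIC peak in the simulation.  C, E, F and H follow
#: MS-confirmed identities; B, D and G are configuration choices (the
#: study leaves D's and G's individual isoform labels open).
DEFAULT_PEAK_ISOFORMS: dict[str, str] = {
    "A": "0",
    "B": "2a",
    "C": "4a",
    "D": "4b",
    "E": "6a",
    "F": "6b",
    "G": "6a",
    "H": "8",
}


@dataclass(frozen=True)
class HicPeakSpec:
    label: str
    apex_min: float
    sigma_min: float
    load: int
    area: float  # AU*min


@dataclass
class BatchProfileConfig:
    """Everything needed to synthesize one batch's HIC chromatograms."""

    batch: str
    peaks: tuple[HicPeakSpec, ...]
    load_percents: dict[int, float]
    replicate_cv_percent: float = 0.3
    baseline_noise_sd: float = 1e-4  # AU, additive white noise
    run_length_min: float = 10.0
    sampling_hz: float = 20.0
    total_area: float = 1.0  # AU*min across all peaks
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.load_percents.values())
        if abs(total - 100.0) > 0.1:
            raise ValueError(f"load percents must sum to 100, got {total}")
        for load, fracs in _WITHIN_LOAD_FRACTIONS.items():
            if abs(sum(fracs.values()) - 1.0) > 1e-9:
                raise ValueError(f"within-load fractions for load {load} must sum to 1")

    def true_group_percents(self) -> dict[int, float]:
        """Ground-truth per-load area percents (normalized to sum to 100)."""
        total = sum(self.load_percents.values())
        return {load: 100.0 * pct / total for load, pct in sorted(self.load_percents.items())}

    def true_peak_areas(self) -> dict[str, float]:
        return {p.label: p.area for p in self.peaks}

    def true_total_dar(self) -> float:
        return sum(pct * load / 100.0 for load, pct in self.true_group_percents().items())


def batch_config(
    batch: str,
    seed: int = 0,
    replicate_cv_percent: float = 0.3,
    baseline_noise_sd: float = 1e-4,
    peak_sigma_min: float = 0.07,
    dar4_split: Mapping[str, float] | None = None,
) -> BatchProfileConfig:
    """Build the bundled profile config for one of the three batches."""
    if batch not in BATCH_AREA_PERCENTS:
        raise ValueError(f"unknown batch {batch!r}; expected one of {sorted(BATCH_AREA_PERCENTS)}")
    percents = BATCH_AREA_PERCENTS[batch]
    norm = sum(percents.values())
    fractions = dict(_WITHIN_LOAD_FRACTIONS)
    if dar4_split is not None:
        if abs(sum(dar4_split.values()) - 1.0) > 1e-9:
            raise ValueError("DAR-4 split fractions must sum to 1")
        fractions[4] = dict(dar4_split)
    peaks = []
    for label, apex, load in _PEAK_LAYOUT:
        frac = fractions[load].get(label, 0.0)
        area = percents[load] / norm * frac  # total_area = 1.0
        peaks.append(HicPeakSpec(label=label, apex_min=apex, sigma_min=peak_sigma_min, load=load, area=area))
    return BatchProfileConfig(
        batch=batch,
        peaks=tuple(peaks),
        load_percents=dict(percents),
        replicate_cv_percent=replicate_cv_percent,
        baseline_noise_sd=baseline_noise_sd,
        seed=seed,
    )


def _gaussian(t: np.ndarray, apex: float, sigma: float, area: float) -> np.ndarray:
    amp = area / (sigma * np.sqrt(2.0 * np.pi))
    return amp * np.exp(-0.5 * ((t - apex) / sigma) ** 2)


def make_hic_chromatogram(
    config: BatchProfileConfig, replicate_index: int = 0
) -> tuple[Chromatogram, dict[str, np.ndarray]]:
    """Synthesize one replicate HIC chromatogram.

    Returns the chromatogram and the per-peak component profiles (the
    ground-truth species traces, used for heart-cut composition checks).
    Deterministic for a fixed ``(config.seed, replicate_index)``.
    """
    dt = 1.0 / (config.sampling_hz * 60.0)  # minutes per sample
    t = np.arange(0.0, config.run_length_min + dt / 2, dt)
    rng = np.random.default_rng([config.seed % (2**31), replicate_index, 1742])
    cv = config.replicate_cv_percent / 100.0
    intensity = np.zeros_like(t)
    components: dict[str, np.ndarray] = {}
    for peak in config.peaks:
        if cv > 0:
            sigma_ln = np.sqrt(np.log1p(cv**2))
            jitter = float(rng.lognormal(mean=-0.5 * sigma_ln**2, sigma=sigma_ln))
        else:
            rng.lognormal(0.0, 1.0)  # keep the stream aligned across cv settings
            jitter = 1.0
        profile = _gaussian(t, peak.apex_min, peak.sigma_min, config.total_area * peak.area * jitter)
        components[peak.label] = profile
        intensity = intensity + profile
    if config.baseline_noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.baseline_noise_sd, size=t.size)
    chrom = Chromatogram(
        time=t,
        intensity=intensity,
        metadata={
            "wavelength_nm": 220,
            "sampling_rate_hz": config.sampling_hz,
            "batch": config.batch,
            "replicate": replicate_index,
            "seed": config.seed,
        },
    )
    return chrom, components


# --- ESI envelopes -------------------------------------------------------


def charge_range_for_mass(mass: float) -> tuple[int, int]:
    """Default charge-state window per sub-unit mass bracket.

    Chosen so every envelope falls inside the 500–4,000 m/z acquisition
    window: z 15–25 for light-chain-scale species (~23 kDa), 30–45 for
    heavy-chain-scale (~52 kDa), 45–60 for half-antibody/heavy-heavy and
    intact-scale species.
    """
    if mass < 30_000:
        return (15, 25)
    if mass < 70_000:
        return (30, 45)
    return (45, 60)


@dataclass
class EnvelopeConfig:
    """Shape and noise parameters for synthetic continuum ESI envelopes.

    Per-charge peaks are Gaussian in m/z with a width set in *mass* space:
    sigma_mass = ``peak_width_coeff * sqrt(mass)`` unless ``peak_sigma_mass``
    is given explicitly.  The square-root scaling mimics the growth of the
    unresolved isotope envelope of an average-mass protein peak (about
    2.3 Da at a light chain, 4.8 Da at a heavy-heavy pair), which is what
    limits resolution for intact sub-units on a QTOF.
    """

    mz_min: float = 500.0
    mz_max: float = 4000.0
    grid_step: float = 0.02  # Th
    peak_width_coeff: float = 0.015  # sigma_mass = coeff * sqrt(mass) [Da]
    peak_sigma_mass: float | None = None  # explicit sigma_mass in Da, overrides coeff
    charge_bell_width_fraction: float = 0.25  # sigma_z / (z_max - z_min)
    noise_sd_rel: float = 0.005  # additive Gaussian, relative to base peak
    seed: int = 0

    def sigma_mass(self, mass: float) -> float:
        if self.peak_sigma_mass is not None:
            return self.peak_sigma_mass
        return self.peak_width_coeff * np.sqrt(mass)


def _envelope_on_grid(
    grid: np.ndarray,
    mass: float,
    weight: float,
    charge_range: tuple[int, int],
    cfg: EnvelopeConfig,
) -> np.ndarray:
    z_min, z_max = charge_range
    z_center = 0.5 * (z_min + z_max)
    sigma_z = max(cfg.charge_bell_width_fraction * (z_max - z_min), 0.5)
    sigma_mass = cfg.sigma_mass(mass)
    out = np.zeros_like(grid)
    for z in range(z_min, z_max + 1):
        mz = (mass + z * PROTON_MASS) / z
        sigma_mz = sigma_mass / z
        # keep every emitted peak inside the acquisition window
        if mz - 4 * sigma_mz < cfg.mz_min or mz + 4 * sigma_mz > cfg.mz_max:
            continue
        wz = np.exp(-0.5 * ((z - z_center) / sigma_z) ** 2)
        lo = np.searchsorted(grid, mz - 6 * sigma_mz)
        hi = np.searchsorted(grid, mz + 6 * sigma_mz)
        seg = grid[lo:hi]
        out[lo:hi] += weight * wz * np.exp(-0.5 * ((seg - mz) / sigma_mz) ** 2)
    return out


def make_heart_cut_spectrum(
    isoform: IsoformClass | str,
    glycoform_mix: Mapping[str, float] | None = None,
    envelope: EnvelopeConfig | None = None,
    modifications: Sequence[tuple[str, float, float]] | None = None,
    assembly: AssemblySpec | None = None,
    seed: int | None = None,
) -> tuple[MassSpectrum, Chromatogram, DissociationSignature]:
    """Continuum ESI spectrum (plus companion RP trace) of one isoform's sub-units.

    Parameters
    ----------
    isoform
        Isoform class or its label within the assembly's enumeration.
    glycoform_mix
        Relative abundances of heavy-chain glycoforms (default
        ``{"G0F": 0.6, "G1F": 0.4}``); multi-heavy sub-units receive
        multinomially weighted combination variants.
    modifications
        Optional satellites as ``(subunit_composition_label, mass_delta,
        relative_intensity)`` — e.g. ``("2H+2drug", -18.02, 0.25)`` for a
        dehydration satellite on the heavy-heavy sub-unit.
    seed
        Overrides ``envelope.seed`` for the additive noise stream.

    Returns ``(spectrum, rp_trace, signature)``; the signature carries the
    ground-truth sub-unit masses (canonical glycoform).
    """
    assembly = assembly or reference_igg1_assembly()
    envelope = envelope or EnvelopeConfig()
    if glycoform_mix is None:
        glycoform_mix = {"G0F": 0.6, "G1F": 0.4}
    if isinstance(isoform, str):
        matches = [c for c in enumerate_isoforms(assembly) if c.label == isoform]
        if not matches:
            raise ValueError(f"isoform {isoform!r} not in the assembly's enumeration")
        isoform = matches[0]
    heavy = next(s for s in assembly.chains.values() if s.role == "heavy")
    canonical = next(iter(glycoform_mix))
    sig = dissociate(isoform, assembly, glycoform=canonical)

    grid = np.arange(envelope.mz_min, envelope.mz_max + envelope.grid_step / 2, envelope.grid_step)
    intensity = np.zeros_like(grid)
    seen: set[int] = set()
    unique_subunits = []
    for unique in sig.unique_masses:
        for i, sub in enumerate(sig.subunits):
            if i not in seen and abs(sub.mass - unique) <= sig.merge_tolerance:
                seen.add(i)
                unique_subunits.append(sub)
                break
    mix = list(glycoform_mix.items())
    mix_total = sum(w for _n, w in mix)
    for sub in unique_subunits:
        n_heavy = sum(1 for c in sub.chain_ids if assembly.chains[c].role == "heavy")
        glycan_free = sub.mass - n_heavy * heavy.glycoform_delta(canonical)
        zrange = charge_range_for_mass(sub.mass)
        variants: list[tuple[float, float]]
        if n_heavy == 0:
            variants = [(glycan_free, 1.0)]
        else:
            variants = []
            for combo in _combos_with_weights(mix, n_heavy, mix_total):
                delta = sum(heavy.glycoform_delta(n) for n in combo[0])
                variants.append((glycan_free + delta, combo[1]))
        for vmass, weight in variants:
            intensity += _envelope_on_grid(grid, vmass, weight, zrange, envelope)
        if modifications:
            comp = sub.composition_label(assembly.chains)
            for target, delta, rel in modifications:
                if target == comp:
                    for vmass, weight in variants:
                        intensity += _envelope_on_grid(
                            grid, vmass + delta, rel * weight, zrange, envelope
                        )

    rng = np.random.default_rng(
        [(envelope.seed if seed is None else seed) % (2**31), 9157]
    )
    if envelope.noise_sd_rel > 0 and intensity.max() > 0:
        intensity = intensity + rng.normal(
            0.0, envelope.noise_sd_rel * intensity.max(), size=grid.size
        )

    spectrum = MassSpectrum(
        mz=grid,
        intensity=intensity,
        metadata={"isoform": isoform.label, "glycoform_mix": dict(glycoform_mix)},
    )
    rp_trace = _rp_trace(unique_subunits)
    return spectrum, rp_trace, sig


def _combos_with_weights(
    mix: list[tuple[str, float]], n_heavy: int, mix_total: float
) -> list[tuple[tuple[str, ...], float]]:
    """Multinomially weighted glycoform combinations for n heavy chains."""
    import itertools
    import math

    out: dict[tuple[str, ...], float] = {}
    for combo in itertools.product(mix, repeat=n_heavy):
        names = tuple(sorted(n for n, _w in combo))
        weight = math.prod(w / mix_total for _n, w in combo)
        out[names] = out.get(names, 0.0) + weight
    return list(out.items())


def _rp_trace(unique_subunits: Sequence) -> Chromatogram:
    """Companion RP-UV trace: one Gaussian per unique sub-unit, light first."""
    dt = 1.0 / (20.0 * 60.0)
    t = np.arange(0.0, 15.0 + dt / 2, dt)
    intensity = np.zeros_like(t)
    n = max(len(unique_subunits), 1)
    for rank, sub in enumerate(sorted(unique_subunits, key=lambda s: s.mass)):
        apex = 4.0 + 8.0 * rank / n
        intensity += _gaussian(t, apex, 0.1, 1.0)
    return Chromatogram(time=t, intensity=intensity, metadata={"dimension": "RP", "gradient_min": 15.0})


# --- batch datasets ------------------------------------------------------


def make_batch_dataset(
    batch: str,
    seed: int,
    out_dir: str | Path,
    n_replicates: int = 3,
    config: BatchProfileConfig | None = None,
    envelope: EnvelopeConfig | None = None,
) -> dict:
    """Write a complete synthetic dataset for one batch and return its manifest.

    Emits ``n_replicates`` chromatogram CSVs, one heart-cut spectrum CSV
    per HIC peak (A–H), and ``manifest.json`` holding the ground truth
    (true per-load areas, per-peak areas and isoforms, expected sub-unit
    masses, true total DAR).
    """
    from cysadc import io as cio  # local import to avoid a cycle at import time

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or batch_config(batch, seed=seed)
    if config.seed != seed:
        config = replace(config, seed=seed)
    envelope = envelope or EnvelopeConfig(seed=seed)
    assembly = reference_igg1_assembly()

    chrom_files = []
    for rep in range(n_replicates):
        chrom, _components = make_hic_chromatogram(config, replicate_index=rep)
        path = out / f"hic_{batch}_rep{rep}.csv"
        cio.write_chromatogram_csv(chrom, path)
        chrom_files.append(path.name)

    spectrum_files = {}
    peak_truth = {}
    for peak in config.peaks:
        label = peak.label
        iso_label = DEFAULT_PEAK_ISOFORMS[label]
        mods = [("2H+2drug", -18.02, 0.25)] if label == "C" else None
        spectrum, _rp, sig = make_heart_cut_spectrum(
            iso_label,
            envelope=envelope,
            modifications=mods,
            assembly=assembly,
            seed=(seed * 131 + ord(label)) % (2**31),
        )
        path = out / f"heartcut_{batch}_{label}.csv"
        cio.write_spectrum_csv(spectrum, path)
        spectrum_files[label] = path.name
        peak_truth[label] = {
            "isoform": iso_label,
            "load": peak.load,
            "true_area": peak.area,
            "subunit_masses_g0f": list(sig.unique_masses),
            "dehydration_satellite": bool(mods),
        }

    manifest = {
        "batch": batch,
        "seed": seed,
        "n_replicates": n_replicates,
        "chromatograms": chrom_files,
        "spectra": spectrum_files,
        "group_percents": {str(k): v for k, v in config.true_group_percents().items()},
        "peak_grouping": DEFAULT_PEAK_GROUPING,
        "peaks": peak_truth,
        "total_dar": config.true_total_dar(),
        "replicate_cv_percent": config.replicate_cv_percent,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
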