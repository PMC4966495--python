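"""Plain-text I/O: chromatograms, spectra, configs, signature libraries.

Chromatograms and spectra travel as two-column CSV with ``#``-prefixed
``key=value`` metadata lines before the header.  Conjugate configurations
are YAML.  A single profile-mode MS1 scan can optionally be read from an
mzML file via pyteomics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from cysadc.conjugate_model import (
    AssemblySpec,
    ChainSpec,
    ChemicalFormula,
    DisulfideBond,
    DrugLinker,
    average_mass,
)
from cysadc.hic_quant import Chromatogram, DARReport, PeakTable, ReplicateSummary
from cysadc.ms_tools import MassSpectrum

__all__ = [
    "read_chromatogram_csv",
    "write_chromatogram_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_mzml_scan",
    "load_conjugate_config",
    "default_conjugate_config_path",
    "write_signature_library_csv",
    "read_masses_csv",
    "write_dar_report_csv",
]


def _read_metadata(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                try:
                    parsed: object = float(value) if "." in value else int(value)
                except ValueError:
                    parsed = value.strip()
                meta[key.strip()] = parsed
    return meta


def _write_two_column(
    path: Path, x: np.ndarray, y: np.ndarray, header: str, metadata: Mapping
) -> None:
    with open(path, "w") as fh:
        for key, value in metadata.items():
            fh.write(f"# {key}={value}\n")
        fh.write(header + "\n")
        np.savetxt(fh, np.column_stack([x, y]), fmt="%.8g", delimiter=",")


def write_chromatogram_csv(chrom: Chromatogram, path: str | Path) -> None:
    _write_two_column(
        Path(path), chrom.time, chrom.intensity, "time_min,intensity_au", chrom.metadata
    )


def _read_two_column(path: Path) -> np.ndarray:
    frame = pd.read_csv(path, comment="#")
    if frame.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two data columns")
    return frame.to_numpy(dtype=float)


def read_chromatogram_csv(path: str | Path) -> Chromatogram:
    path = Path(path)
    data = _read_two_column(path)
    return Chromatogram(time=data[:, 0], intensity=data[:, 1], metadata=_read_metadata(path))


def write_spectrum_csv(spec: MassSpectrum, path: str | Path) -> None:
    _write_two_column(Path(path), spec.mz, spec.intensity, "mz,intensity", spec.metadata)


def read_spectrum_csv(path: str | Path) -> MassSpectrum:
    path = Path(path)
    data = _read_two_column(path)
    return MassSpectrum(mz=data[:, 0], intensity=data[:, 1], metadata=_read_metadata(path))


def read_mzml_scan(path: str | Path, scan_index: int = 0) -> MassSpectrum:
    """Read one profile-mode MS1 scan from an mzML file (pyteomics backend)."""
    from pyteomics import mzml  # optional dependency path; imported lazily

    with mzml.MzML(str(path)) as reader:
        for i, scan in enumerate(reader):
            if i == scan_index:
                return MassSpectrum(
                    mz=np.asarray(scan["m/z array"], dtype=float),
                    intensity=np.asarray(scan["intensity array"], dtype=float),
                    metadata={"source": str(path), "scan_index": scan_index},
                )
    raise ValueError(f"scan index {scan_index} not found in {path}")


# --- conjugate configuration ---------------------------------------------


def default_conjugate_config_path() -> Path:
    """Path of the bundled IgG1 drug-mimic conjugate configuration."""
    return Path(__file__).parent / "data" / "igg1_drug_mimic.yaml"


def load_conjugate_config(path: str | Path | None = None) -> AssemblySpec:
    """Load an :class:`AssemblySpec` from a YAML conjugate configuration.

    The file describes chain species (role, reduced average mass,
    glycoforms), chain instances, the drug-linker (formula or explicit
    mass), the inter-chain bonds with endpoint site classes, and the
    symmetry generators as bond-id pair lists.
    """
    path = Path(path) if path is not None else default_conjugate_config_path()
    if not path.exists():
        raise FileNotFoundError(f"conjugate configuration not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)

    chain_species: dict[str, ChainSpec] = {}
    for name, spec in cfg["chain_species"].items():
        chain_species[name] = ChainSpec(
            role=spec["role"],
            reduced_average_mass=float(spec["reduced_average_mass"]),
            glycoforms=tuple(
                (g["name"], float(g["mass_delta"])) for g in spec.get("glycoforms", [])
            ),
        )
    chains = {inst: chain_species[species] for inst, species in cfg["chain_instances"].items()}

    drug_cfg = cfg["drug"]
    if "formula" in drug_cfg:
        formula = ChemicalFormula.from_string(drug_cfg["formula"])
        mass = float(drug_cfg.get("average_mass", average_mass(formula)))
        drug = DrugLinker(average_mass=mass, formula=formula)
    else:
        drug = DrugLinker(average_mass=float(drug_cfg["average_mass"]))

    bonds = tuple(
        DisulfideBond(
            id=b["id"],
            endpoints=(
                (b["endpoints"][0]["chain"], b["endpoints"][0]["site_class"]),
                (b["endpoints"][1]["chain"], b["endpoints"][1]["site_class"]),
            ),
        )
        for b in cfg["bonds"]
    )

    symmetries = []
    for gen in cfg.get("symmetries", []):
        perm = {b.id: b.id for b in bonds}
        for pair in gen:
            a, b = pair
            perm[a], perm[b] = b, a
        symmetries.append(perm)

    return AssemblySpec(
        chains=chains,
        bonds=bonds,
        drug=drug,
        symmetries=tuple(symmetries),
        disulfide_mass_decrement=float(cfg.get("disulfide_mass_decrement", 2.016)),
    )


# --- tables --------------------------------------------------------------


def write_signature_library_csv(lib, path: str | Path) -> None:
    """Export a signature library as CSV (one row per expected-mass variant)."""
    rows = []
    for entry in lib.entries:
        for exp in entry.expected:
            for glyco, mass in exp.variants:
                rows.append(
                    {
                        "isoform_label": entry.label,
                        "dar": entry.dar,
                        "subunit_composition": exp.subunit,
                        "drug_count": _drug_count_from_label(exp.subunit),
                        "glycoform": glyco,
                        "mass_da": round(mass, 1),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def _drug_count_from_label(subunit_label: str) -> int:
    head, _, _ = subunit_label.rpartition("drug")
    _, _, count = head.rpartition("+")
    try:
        return int(count)
    except ValueError:
        return 0


def read_masses_csv(path: str | Path) -> list[float]:
    """Read observed neutral masses: one column named ``mass_da`` (or first column)."""
    frame = pd.read_csv(path, comment="#")
    column = "mass_da" if "mass_da" in frame.columns else frame.columns[0]
    return [float(v) for v in frame[column].dropna()]


def write_dar_report_csv(
    summary: ReplicateSummary, path: str | Path, batch: str = ""
) -> None:
    """Write a per-load DAR table (area %, RSD %, contribution; totals)."""
    rows = []
    for load in sorted(summary.mean_area_percent):
        rows.append(
            {
                "batch": batch,
                "drug_load": load,
                "area_percent": round(summary.mean_area_percent[load], 2),
                "rsd_percent": (
                    round(summary.rsd_area_percent[load], 2)
                    if summary.rsd_area_percent is not None
                    else "n/a"
                ),
                "dar_contribution": round(summary.mean_dar_contribution[load], 2),
            }
        )
    frame = pd.DataFrame(rows)
    frame["total_dar"] = round(summary.mean_total_dar, 2)
    frame["total_rsd_percent"] = (
        round(summary.rsd_total_dar, 2) if summary.rsd_total_dar is not None else "n/a"
    )
    frame.to_csv(path, index=False)
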