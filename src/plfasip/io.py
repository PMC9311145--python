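"""Delimited-text readers/writers, unit helpers and configuration.

Tables are long/tidy: one row per sample × biomarker.  The dialect is
fixed — UTF-8, "." decimal separator, comma-delimited by default with a
``delimiter`` argument for tab.  Unicode "ω" in biomarker names is
accepted and normalized internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biomarkers import Group, assign_group, default_group_mapping, load_group_mapping, normalize_name
from .datamodel import IsotopeConstants, TreatmentClass, TreatmentDesign
from .isotope import delta_to_atom_fraction

logger = logging.getLogger("plfasip")

__all__ = [
    "read_measurements",
    "write_measurements",
    "read_design",
    "write_design",
    "quantify_from_areas",
    "nmol_to_ugC",
    "PipelineConfig",
    "load_config",
]

#: Atomic mass of carbon, g / mol.
ATOMIC_MASS_C = 12.011

MEASUREMENT_COLUMNS = ["sample_id", "treatment_id", "replicate", "biomarker", "conc_ugC", "delta13C_fame"]
_REQUIRED = {"concentration": ["sample_id", "treatment_id", "replicate", "biomarker", "conc_ugC"],
             "peak_area": ["sample_id", "treatment_id", "replicate", "biomarker", "peak_area"]}


def read_measurements(
    path: str | Path,
    schema: str = "concentration",
    delimiter: str = ",",
    mapping: dict[str, Group] | None = None,
) -> pd.DataFrame:
    """Read a long-format measurement table.

    ``schema="concentration"`` expects a ``conc_ugC`` column (μg C per g
    dry soil); ``schema="peak_area"`` expects raw GC-FID ``peak_area``
    values to be converted later with :func:`quantify_from_areas`.  A
    ``delta13C_fame`` column (‰ vs PDB) is optional — unlabelled-only
    runs may omit it.  Unknown biomarkers are kept and assigned
    ``unassigned`` with a logged warning.
    """
    if schema not in _REQUIRED:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in _REQUIRED[schema] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    df = df.copy()
    df["biomarker"] = df["biomarker"].map(normalize_name)
    df["replicate"] = df["replicate"].astype(int)
    value_col = "conc_ugC" if schema == "concentration" else "peak_area"
    bad = df.index[df[value_col] < 0]
    if len(bad):
        raise ValueError(
            f"{path}: negative {value_col} at row {int(bad[0]) + 2} "
            f"(sample {df.loc[bad[0], 'sample_id']!r})"
        )
    if "delta13C_fame" in df.columns:
        vals = df["delta13C_fame"].dropna()
        if not np.isfinite(vals.to_numpy(dtype=float)).all():
            raise ValueError(f"{path}: non-finite δ¹³C values present")
    else:
        df["delta13C_fame"] = np.nan
    dup = df.duplicated(subset=["sample_id", "biomarker"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (sample_id, biomarker) at row {int(df.index[dup][0]) + 2}"
        )
    if mapping is None:
        mapping = default_group_mapping()
    df["group"] = [assign_group(b, mapping).value for b in df["biomarker"]]
    return df


def write_measurements(df: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write a measurement table in the long format read_measurements expects."""
    cols = [c for c in MEASUREMENT_COLUMNS if c in df.columns]
    df.to_csv(path, sep=delimiter, columns=cols, index=False)


# -- design tables ----------------------------------------------------------

_DESIGN_COLUMNS = [
    "treatment_id", "klass", "species", "c_share", "labelled",
    "labelled_c_fraction", "atom_fraction_13c", "cn_ratio", "c_rate",
]


def write_design(designs: list[TreatmentDesign], path: str | Path, delimiter: str = ",") -> None:
    """Write treatments as a long table (one row per treatment × species)."""
    rows = []
    for d in designs:
        if d.klass is TreatmentClass.CONTROL:
            rows.append({"treatment_id": d.treatment_id, "klass": d.klass.value,
                         "species": "", "c_share": 0.0, "labelled": 0,
                         "labelled_c_fraction": 0.0,
                         "atom_fraction_13c": np.nan, "cn_ratio": np.nan,
                         "c_rate": 0.0})
            continue
        for sp, share in d.species_c_share.items():
            rows.append({
                "treatment_id": d.treatment_id,
                "klass": d.klass.value,
                "species": sp,
                "c_share": share,
                "labelled": int(sp == d.labelled_species),
                "labelled_c_fraction": d.labelled_c_fraction,
                "atom_fraction_13c": d.residue_atom_fraction.get(sp, np.nan),
                "cn_ratio": d.residue_cn.get(sp, np.nan),
                "c_rate": d.c_rate,
            })
    pd.DataFrame(rows, columns=_DESIGN_COLUMNS).to_csv(path, sep=delimiter, index=False)


def read_design(path: str | Path, delimiter: str = ",") -> dict[str, TreatmentDesign]:
    """Read a long-format design table back into ``TreatmentDesign`` records."""
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in _DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing design column(s) {', '.join(missing)}")
    designs: dict[str, TreatmentDesign] = {}
    for tid, sub in df.groupby("treatment_id", sort=False):
        klass = TreatmentClass(sub["klass"].iloc[0])
        if klass is TreatmentClass.CONTROL:
            designs[tid] = TreatmentDesign(tid, klass)
            continue
        shares = dict(zip(sub["species"], sub["c_share"].astype(float)))
        labelled_rows = sub[sub["labelled"] == 1]
        labelled = labelled_rows["species"].iloc[0] if len(labelled_rows) else None
        labelled_fraction = float(sub["labelled_c_fraction"].iloc[0]) if labelled is not None else 0.0
        designs[tid] = TreatmentDesign(
            treatment_id=tid,
            klass=klass,
            species_c_share=shares,
            labelled_species=labelled,
            labelled_c_fraction=labelled_fraction,
            residue_atom_fraction={
                sp: float(v) for sp, v in zip(sub["species"], sub["atom_fraction_13c"])
                if np.isfinite(v)
            },
            residue_cn={
                sp: float(v) for sp, v in zip(sub["species"], sub["cn_ratio"])
                if np.isfinite(v)
            },
            c_rate=float(sub["c_rate"].iloc[0]),
        )
    return designs


# -- quantification helpers -------------------------------------------------

def quantify_from_areas(areas: pd.DataFrame, calibration: dict[str, float]) -> pd.DataFrame:
    """Convert GC-FID peak areas to μg C g⁻¹ with per-biomarker response factors.

    External calibration against a FAME standard mix is linear through
    the origin: ``conc = area × response_factor``.
    """
    calibration = {normalize_name(k): v for k, v in calibration.items()}
    out = areas.copy()
    missing = sorted(set(out["biomarker"].map(normalize_name)) - set(calibration))
    if missing:
        raise ValueError(f"no calibration entry for biomarker(s): {', '.join(missing)}")
    rf = out["biomarker"].map(normalize_name).map(calibration)
    out["conc_ugC"] = out["peak_area"].astype(float) * rf
    return out.drop(columns=["peak_area"])


def nmol_to_ugC(nmol, n_carbon: int):
    """Convert nmol fatty acid per g soil to μg fatty-acid carbon per g soil."""
    if n_carbon < 2:
        raise ValueError("n_carbon must be >= 2")
    nmol = np.asarray(nmol, dtype=float)
    if np.any(nmol < 0):
        raise ValueError("nmol must be non-negative")
    out = nmol * n_carbon * ATOMIC_MASS_C / 1000.0
    return float(out) if out.ndim == 0 else out


# -- configuration ----------------------------------------------------------

@dataclass
class PipelineConfig:
    """User-facing knobs of the pipeline, loadable from a YAML file."""

    r_pdb: float = 0.01118
    delta_methanol: float | None = None
    natural_delta13c: float = -28.0
    group_mapping_path: str | None = None
    alpha: float = 0.05
    anosim_permutations: int = 999
    nmds_dimensions: int = 2
    nmds_restarts: int = 20
    correction_space: str = "delta"  # or "atom_fraction"
    delimiter: str = ","

    def isotope_constants(self) -> IsotopeConstants:
        return IsotopeConstants(
            r_pdb=self.r_pdb,
            delta_methanol=self.delta_methanol,
            natural_atom_fraction_default=delta_to_atom_fraction(
                self.natural_delta13c, IsotopeConstants(r_pdb=self.r_pdb)
            ),
        )

    def group_mapping(self) -> dict[str, Group]:
        if self.group_mapping_path is None:
            return default_group_mapping()
        return load_group_mapping(self.group_mapping_path)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML key/value configuration file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = PipelineConfig.__dataclass_fields__
    unknown = sorted(set(raw) - set(known))
    if unknown:
        raise ValueError(f"{path}: unknown configuration key(s): {', '.join(unknown)}")
    return PipelineConfig(**raw)
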