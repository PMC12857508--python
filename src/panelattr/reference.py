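"""Provider reference tables: specialty roster, NPI registry, taxonomy crosswalk,
and the specialty→designation map.

The roster emulates an MD-PPAS-style annual NPI→specialty file, the registry an
NPPES-style NPI→(entity type, primary taxonomy) enumeration, and the crosswalk a
taxonomy→CMS-specialty translation. All are plain CSV with enforced columns.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

DESIGNATIONS = ("PCP", "SCP", "APP", "OTHER")
# tie-break priority when claim lines of one encounter disagree on designation
DESIGNATION_PRIORITY = {"PCP": 0, "SCP": 1, "APP": 2, "OTHER": 3}

ROSTER_COLUMNS = ["npi", "year", "specialty_code"]
REGISTRY_COLUMNS = ["npi", "entity_type", "primary_taxonomy"]
CROSSWALK_COLUMNS = ["taxonomy_code", "specialty_code"]
DESIGNATION_COLUMNS = ["specialty_code", "designation"]


def _read_csv(path: str | Path, columns: list[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{name} file {path} is missing required columns: {missing}")
    return df[columns]


def load_roster(path: str | Path) -> pd.DataFrame:
    """Load an annual NPI→specialty roster (npi, year, specialty_code)."""
    df = _read_csv(path, ROSTER_COLUMNS, "roster")
    df["year"] = df["year"].astype(int)
    if df.duplicated(["npi", "year"]).any():
        raise ValueError(f"roster file {path} has duplicate (npi, year) rows")
    return df


def load_registry(path: str | Path) -> pd.DataFrame:
    """Load an NPI registry (npi, entity_type, primary_taxonomy)."""
    df = _read_csv(path, REGISTRY_COLUMNS, "registry")
    if df["npi"].duplicated().any():
        raise ValueError(f"registry file {path} has duplicate NPIs")
    bad = set(df["entity_type"]) - {"individual", "organization"}
    if bad:
        raise ValueError(f"registry file {path} has unknown entity types: {sorted(bad)}")
    return df


def load_crosswalk(path: str | Path) -> pd.DataFrame:
    """Load a taxonomy→specialty crosswalk.

    Duplicate taxonomy rows that map to conflicting specialty codes are a
    load-time error; exact duplicate rows are collapsed.
    """
    df = _read_csv(path, CROSSWALK_COLUMNS, "crosswalk").drop_duplicates()
    dup = df["taxonomy_code"].duplicated(keep=False)
    if dup.any():
        codes = sorted(df.loc[dup, "taxonomy_code"].unique())
        raise ValueError(
            f"crosswalk file {path} maps taxonomies to conflicting specialties: {codes}"
        )
    return df


def load_designations(path: str | Path | None = None) -> pd.DataFrame:
    """Load a specialty→designation reference (PCP/SCP/APP/OTHER).

    With no path, the bundled default (real CMS specialty code values) is used.
    """
    if path is None:
        path = resources.files("panelattr.data") / "designations.csv"
    df = _read_csv(path, DESIGNATION_COLUMNS, "designation")
    if df["specialty_code"].duplicated().any():
        raise ValueError(f"designation file {path} has duplicate specialty codes")
    bad = set(df["designation"]) - set(DESIGNATIONS)
    if bad:
        raise ValueError(f"designation file {path} has unknown designations: {sorted(bad)}")
    return df


def default_crosswalk() -> pd.DataFrame:
    return load_crosswalk(resources.files("panelattr.data") / "taxonomy_crosswalk.csv")


def default_designations() -> pd.DataFrame:
    return load_designations(None)
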