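"""Encounter preparation: HCPCS range filters, designation mapping, and
consolidation of claim lines to unique patient–provider–date encounters.

The unit of analysis for attribution is the encounter: all claim lines for
one patient with one provider identifier on one service date, with fees
summed and an any-line E&M flag. Exact duplicate claim records (a known
artifact of encounter data) collapse before fees are summed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .reference import DESIGNATION_PRIORITY

logger = logging.getLogger(__name__)

MEDICAL_RANGE = (90281, 99607)  # inclusive HCPCS medical range
EM_RANGE = (99201, 99499)  # inclusive evaluation & management subrange

ENCOUNTER_COLUMNS = [
    "patient_id",
    "provider_id",
    "level",
    "entity_type",
    "service_date",
    "year",
    "designation",
    "specialty_code",
    "is_em",
    "fee_total",
    "n_lines",
    "is_mapped",
    "tin",
]


def _numeric_hcpcs(codes: pd.Series) -> pd.Series:
    """Numeric value of purely 5-digit HCPCS codes; NaN for alphanumeric."""
    s = codes.astype(str)
    ok = s.str.fullmatch(r"\d{5}")
    return pd.to_numeric(s.where(ok), errors="coerce")


def filter_medical(claims: pd.DataFrame) -> pd.DataFrame:
    """Retain claims with numeric HCPCS in the medical range 90281–99607.

    Alphanumeric codes (drugs, DME, etc.) fall outside the range by definition.
    """
    v = _numeric_hcpcs(claims["hcpcs"])
    return claims.loc[(v >= MEDICAL_RANGE[0]) & (v <= MEDICAL_RANGE[1])].copy()


def flag_em(claims: pd.DataFrame) -> pd.Series:
    """True per claim iff the HCPCS code is in the E&M range 99201–99499."""
    v = _numeric_hcpcs(claims["hcpcs"])
    return ((v >= EM_RANGE[0]) & (v <= EM_RANGE[1])).rename("is_em")


def map_designation(codes: pd.Series, designations: pd.DataFrame) -> pd.Series:
    """Map specialty codes to PCP/SCP/APP/OTHER designations.

    Unresolved (missing) specialties and codes absent from the reference map
    to OTHER; unknown codes additionally emit one logged warning with a count.
    """
    ref = dict(zip(designations["specialty_code"], designations["designation"]))
    present = codes.notna()
    unknown = present & ~codes.isin(ref)
    if unknown.any():
        logger.warning(
            "%d claims carry specialty codes absent from the designation reference; "
            "mapped to OTHER", int(unknown.sum())
        )
    return codes.map(ref).where(present & ~unknown, None).fillna("OTHER").rename("designation")


def _modal(df: pd.DataFrame, keys: list[str], col: str, priority: dict | None = None) -> pd.DataFrame:
    """Per-group modal value of ``col`` among non-null rows; ties break by
    ``priority`` (ascending) when given, else lexicographically."""
    sub = df.loc[df[col].notna(), keys + [col]]
    if sub.empty:
        return pd.DataFrame(columns=keys + [col])
    g = sub.groupby(keys + [col], dropna=False).size().rename("_n").reset_index()
    if priority is not None:
        g["_tie"] = g[col].map(priority).fillna(len(priority))
    else:
        g["_tie"] = g[col]
    g = g.sort_values(keys + ["_n", "_tie"], ascending=[True] * len(keys) + [False, True])
    return g.drop_duplicates(subset=keys)[keys + [col]]


def consolidate_encounters(
    claims: pd.DataFrame,
    designations: pd.DataFrame,
    level: str = "NPI",
) -> pd.DataFrame:
    """Collapse enriched, medical-filtered claim lines to encounters.

    One encounter per (patient, identifier-at-level, service date): fees are
    summed over distinct constituent lines, ``is_em`` is true if any line is
    E&M, and the designation/specialty of the encounter is the modal value
    over lines with a resolved specialty (designation ties break by priority
    PCP > SCP > APP > OTHER). Exact duplicate claim records collapse first.

    ``is_mapped`` — the completeness-gate numerator — requires both an
    assigned identifier and a resolved specialty on the encounter.
    """
    if level not in ("NPI", "TIN"):
        raise ValueError(f"level must be NPI or TIN, got {level!r}")
    df = claims.copy()
    if "suppress" in df.columns:
        df = df.loc[~df["suppress"]]
    df = df.drop_duplicates()  # exact duplicate claim records
    df["is_em"] = flag_em(df)
    df["_desig"] = map_designation(df["specialty_code"], designations).where(
        df["specialty_code"].notna(), None
    )

    keys = ["patient_id", "assigned_npi", "service_date"]
    grouped = df.groupby(keys, dropna=False)
    enc = grouped.agg(
        year=("year", "first"),
        fee_total=("standardized_fee", "sum"),
        is_em=("is_em", "any"),
        n_lines=("claim_id", "size"),
        entity_type=("entity_type", "first"),
        tin=("billing_tin", "first"),
    ).reset_index()
    enc = enc.merge(_modal(df, keys, "_desig", DESIGNATION_PRIORITY), on=keys, how="left")
    enc = enc.merge(_modal(df, keys, "specialty_code"), on=keys, how="left")
    enc = enc.rename(columns={"assigned_npi": "provider_id", "_desig": "designation"})
    enc["designation"] = enc["designation"].fillna("OTHER")
    enc["level"] = "NPI"
    enc["is_mapped"] = enc["provider_id"].notna() & enc["specialty_code"].notna()
    enc = enc[ENCOUNTER_COLUMNS].sort_values(
        ["patient_id", "service_date", "provider_id"], na_position="last"
    ).reset_index(drop=True)
    if level == "TIN":
        enc = aggregate_to_tin(enc)
    return enc


def aggregate_to_tin(npi_encounters: pd.DataFrame) -> pd.DataFrame:
    """Re-aggregate NPI-level encounters to (patient, billing TIN, date).

    Distinct clinicians of one practice seen on one date merge into a single
    practice-level encounter. Entity type is ``unknown`` (a TIN is not an
    NPI, so registry entity types do not apply).
    """
    enc = npi_encounters
    if enc["tin"].isna().all():
        raise ValueError(
            "cannot consolidate at TIN level: no billing TINs present; use level=NPI"
        )
    keys = ["patient_id", "tin", "service_date"]
    grouped = enc.groupby(keys, dropna=False)
    out = grouped.agg(
        year=("year", "first"),
        fee_total=("fee_total", "sum"),
        is_em=("is_em", "any"),
        n_lines=("n_lines", "sum"),
    ).reset_index()
    out = out.merge(_modal(enc, keys, "designation", DESIGNATION_PRIORITY), on=keys, how="left")
    out = out.merge(_modal(enc, keys, "specialty_code"), on=keys, how="left")
    out = out.rename(columns={"tin": "provider_id"})
    out["designation"] = out["designation"].fillna("OTHER")
    out["level"] = "TIN"
    out["entity_type"] = "unknown"
    out["tin"] = out["provider_id"]
    out["is_mapped"] = out["provider_id"].notna() & out["specialty_code"].notna()
    return out[ENCOUNTER_COLUMNS].sort_values(
        ["patient_id", "service_date", "provider_id"], na_position="last"
    ).reset_index(drop=True)
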