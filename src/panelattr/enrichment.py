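"""Provider enrichment: fill in clinician NPIs and specialty codes on claims.

Encounter-style claims often lack a clinician identifier on the line level.
Each claim gets an *assigned NPI* via a dialect-specific fallback hierarchy —

    carrier:    line performing NPI → base rendering NPI → organization NPI
    outpatient: base attending NPI → organization NPI

— where invalid (check-digit-failing) identifiers count as missing. The
specialty code is then resolved by a four-step hierarchy:

    1. specialty code recorded on the claim;
    2. assigned NPI matched to the annual specialty roster (claim's calendar
       year, falling back up to two years earlier);
    3. organization taxonomy code on the claim, translated through the
       taxonomy→specialty crosswalk;
    4. the assigned NPI's registry primary taxonomy, translated through the
       same crosswalk.

Every claim carries provenance tags recording which step supplied its NPI
and specialty, and the registry supplies the entity type (individual vs
organization) of the assigned identifier.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .npi import validate_npi

NPI_SOURCES = ["LINE_PERFORMING", "BASE_RENDERING", "BASE_ATTENDING", "BASE_ORG", "UNASSIGNED"]
SPECIALTY_SOURCES = ["RECORDED", "ROSTER_MATCH", "CLAIM_TAXONOMY", "REGISTRY_TAXONOMY", "UNRESOLVED"]

_NPI_FALLBACK = {
    "carrier": [
        ("line_performing_npi", "LINE_PERFORMING"),
        ("base_rendering_npi", "BASE_RENDERING"),
        ("base_org_npi", "BASE_ORG"),
    ],
    "outpatient": [
        ("base_attending_npi", "BASE_ATTENDING"),
        ("base_org_npi", "BASE_ORG"),
    ],
}

ROSTER_LOOKBACK_YEARS = 2


def _present(col: pd.Series) -> pd.Series:
    return col.notna() & (col.astype(object) != "")


def _valid_npi_mask(col: pd.Series) -> pd.Series:
    uniq = {v: validate_npi(v) for v in col.dropna().unique()}
    return col.map(lambda v: uniq.get(v, False)).astype(bool)


def assign_npi(claims: pd.DataFrame) -> pd.DataFrame:
    """Assign each claim the first present *and valid* NPI in its dialect's
    fallback order. Returns columns ``assigned_npi`` and ``npi_source``."""
    out = pd.DataFrame(index=claims.index)
    out["assigned_npi"] = pd.Series(pd.NA, index=claims.index, dtype=object)
    out["npi_source"] = "UNASSIGNED"
    for dialect, order in _NPI_FALLBACK.items():
        in_dialect = claims["dialect"] == dialect
        unassigned = in_dialect.copy()
        for col, source in order:
            if col not in claims.columns:
                continue
            usable = unassigned & _present(claims[col]) & _valid_npi_mask(claims[col])
            out.loc[usable, "assigned_npi"] = claims.loc[usable, col]
            out.loc[usable, "npi_source"] = source
            unassigned &= ~usable
    return out


def resolve_specialty(
    claims: pd.DataFrame,
    assigned: pd.DataFrame,
    roster: pd.DataFrame,
    crosswalk: pd.DataFrame,
    registry: pd.DataFrame,
) -> pd.DataFrame:
    """Resolve a specialty code per claim by the four-step hierarchy.

    Returns columns ``specialty_code`` and ``specialty_source``; a later
    step is consulted only for claims every earlier step failed on.
    """
    n = len(claims)
    code = pd.Series(pd.NA, index=claims.index, dtype=object)
    source = pd.Series("UNRESOLVED", index=claims.index, dtype=object)

    # 1. recorded on the claim
    rec = _present(claims["recorded_specialty"])
    code[rec] = claims.loc[rec, "recorded_specialty"]
    source[rec] = "RECORDED"

    # 2. roster match on (assigned NPI, claim year), nearest earlier year within 2
    roster_map = {(r.npi, r.year): r.specialty_code for r in roster.itertuples()}
    todo = ~rec & _present(assigned["assigned_npi"])
    years = claims["year"].astype(int)
    for offset in range(ROSTER_LOOKBACK_YEARS + 1):
        if not todo.any():
            break
        keys = list(zip(assigned.loc[todo, "assigned_npi"], years[todo] - offset))
        hit = pd.Series([roster_map.get(k) for k in keys], index=claims.index[todo], dtype=object)
        found = hit.notna()
        idx = hit.index[found]
        code[idx] = hit[found]
        source[idx] = "ROSTER_MATCH"
        todo.loc[idx] = False

    # 3. organization taxonomy recorded on the claim, via crosswalk
    xmap = dict(zip(crosswalk["taxonomy_code"], crosswalk["specialty_code"]))
    todo = source.eq("UNRESOLVED") & _present(claims["claim_taxonomy"])
    hit = claims.loc[todo, "claim_taxonomy"].map(xmap)
    idx = hit.index[hit.notna()]
    code[idx] = hit[hit.notna()]
    source[idx] = "CLAIM_TAXONOMY"

    # 4. registry primary taxonomy of the assigned NPI, via crosswalk
    reg_tax = dict(zip(registry["npi"], registry["primary_taxonomy"]))
    todo = source.eq("UNRESOLVED") & _present(assigned["assigned_npi"])
    hit = assigned.loc[todo, "assigned_npi"].map(reg_tax).map(lambda t: xmap.get(t) if pd.notna(t) else None)
    hit = hit.astype(object)
    idx = hit.index[hit.notna()]
    code[idx] = hit[hit.notna()]
    source[idx] = "REGISTRY_TAXONOMY"

    assert len(code) == n
    return pd.DataFrame({"specialty_code": code, "specialty_source": source})


def resolve_entity_type(assigned: pd.DataFrame, registry: pd.DataFrame) -> pd.Series:
    """Entity type of each assigned NPI from the registry; ``unknown`` when the
    claim is unassigned or the identifier is not enumerated."""
    reg = dict(zip(registry["npi"], registry["entity_type"]))
    out = assigned["assigned_npi"].map(lambda v: reg.get(v, "unknown") if pd.notna(v) else "unknown")
    return out.rename("entity_type")


def match_carrier_outpatient(claims: pd.DataFrame) -> pd.Index:
    """Claim ids of outpatient claims whose (patient, HCPCS, service date) key
    also appears on a carrier claim.

    The carrier record carries the richer clinician fields, so the matched
    facility record is suppressed before consolidation; carrier claims are
    never suppressed.
    """
    key_cols = ["patient_id", "hcpcs", "service_date"]
    carrier_keys = set(map(tuple, claims.loc[claims["dialect"] == "carrier", key_cols].itertuples(index=False)))
    outp = claims["dialect"] == "outpatient"
    matched = claims.loc[outp, key_cols].apply(tuple, axis=1).map(carrier_keys.__contains__) if outp.any() else pd.Series(dtype=bool)
    return pd.Index(claims.loc[outp, "claim_id"][matched]) if outp.any() else pd.Index([])


def enrich_claims(
    claims: pd.DataFrame,
    roster: pd.DataFrame,
    crosswalk: pd.DataFrame,
    registry: pd.DataFrame,
) -> pd.DataFrame:
    """Full enrichment pass: assigned NPI, specialty, entity type, suppression flag.

    Idempotent — recomputes from the raw claim fields, so enriching an
    already-enriched table reproduces the same appended columns.
    """
    claims = claims.drop(
        columns=["assigned_npi", "npi_source", "specialty_code", "specialty_source", "entity_type", "suppress"],
        errors="ignore",
    )
    assigned = assign_npi(claims)
    spec = resolve_specialty(claims, assigned, roster, crosswalk, registry)
    entity = resolve_entity_type(assigned, registry)
    enriched = pd.concat([claims.reset_index(drop=True),
                          assigned.reset_index(drop=True),
                          spec.reset_index(drop=True),
                          entity.reset_index(drop=True)], axis=1)
    suppressed = match_carrier_outpatient(enriched)
    enriched["suppress"] = enriched["claim_id"].isin(set(suppressed))
    return enriched


def provenance_summary(enriched: pd.DataFrame) -> pd.DataFrame:
    """Counts and within-dialect proportions of NPI source, specialty source,
    and entity type — the tabular analog of a source-of-information figure."""
    frames = []
    for dim in ("npi_source", "specialty_source", "entity_type"):
        g = enriched.groupby(["dialect", dim], observed=True).size().rename("count").reset_index()
        g["dimension"] = dim
        g = g.rename(columns={dim: "category"})
        totals = g.groupby("dialect")["count"].transform("sum")
        g["proportion"] = g["count"] / totals
        frames.append(g)
    return pd.concat(frames, ignore_index=True)[
        ["dimension", "dialect", "category", "count", "proportion"]
    ]
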