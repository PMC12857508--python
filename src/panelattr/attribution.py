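"""Retrospective attribution of each patient-year to a usual source of care.

The rule: among a patient's qualifying encounters, attribute the patient to
the provider identifier with a plurality of encounters, breaking count ties
by total standardized fee (resource intensity) and residual ties by smallest
identifier. A patient qualifies only if at least a threshold share (default
50%) of their medical encounters are mapped to both a provider identifier
and a specialty.

Method permutations span three axes — encounter scope (all medical vs E&M
only), clinician scope (all MDs/APPs, MDs only, PCPs only, or PCPs-then-all
hierarchical), and a prior-year lookback — giving 16 canonical methods, plus
robustness variants: practice (TIN) level, TIN-then-NPI two-stage, no fee
tiebreak, fee-primary tiebreak, raised completeness thresholds, and counting
APPs as primary care.
"""

from __future__ import annotations

from typing import Literal, Mapping

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .encounters import aggregate_to_tin

REASONS = ("none", "failed_gate", "no_eligible_encounters", "tie_unbroken")

_SCOPE_DESIGNATIONS = {
    "ALL_MD_APP": {"PCP", "SCP", "APP"},
    "MD_ONLY": {"PCP", "SCP"},
}

RESULT_COLUMNS = [
    "patient_id",
    "year",
    "attributed_id",
    "id_entity_type",
    "year_used",
    "tier_used",
    "reason_unattributed",
]


class AttributionConfig(BaseModel, frozen=True):
    """One fully specified attribution method."""

    encounter_scope: Literal["MEDICAL", "EM"] = "MEDICAL"
    clinician_scope: Literal["ALL_MD_APP", "MD_ONLY", "PCP_ONLY", "PCP_THEN_ALL", "CUSTOM"] = (
        "PCP_THEN_ALL"
    )
    custom_specialties: frozenset[str] | None = None
    lookback: bool = False
    level: Literal["NPI", "TIN", "TIN_THEN_NPI"] = "NPI"
    tiebreak: Literal["COUNT_THEN_FEE", "COUNT_ONLY", "FEE_THEN_COUNT"] = "COUNT_THEN_FEE"
    completeness_threshold: float = Field(default=0.5, ge=0, le=1)
    app_as_pcp: bool = False
    # try the prior year's PCP tier before the current year's all-clinician
    # tier under PCP_THEN_ALL + lookback (non-default ordering)
    prior_pcp_first: bool = False

    @model_validator(mode="after")
    def _check(self) -> "AttributionConfig":
        if self.clinician_scope == "CUSTOM" and not self.custom_specialties:
            raise ValueError("CUSTOM clinician scope requires a nonempty custom_specialties set")
        if self.clinician_scope != "CUSTOM" and self.custom_specialties:
            raise ValueError("custom_specialties is only valid with CUSTOM clinician scope")
        return self

    @property
    def label(self) -> str:
        parts = [self.encounter_scope, self.clinician_scope,
                 "lookback" if self.lookback else "no-lookback"]
        if self.level != "NPI":
            parts.append(self.level)
        if self.tiebreak != "COUNT_THEN_FEE":
            parts.append(self.tiebreak)
        if self.completeness_threshold != 0.5:
            parts.append(f"thr{self.completeness_threshold:g}")
        if self.app_as_pcp:
            parts.append("APP_AS_PCP")
        return "/".join(parts)


def canonical_configs() -> list[AttributionConfig]:
    """The 16 canonical permutations: {MEDICAL, EM} × {ALL_MD_APP, MD_ONLY,
    PCP_ONLY, PCP_THEN_ALL} × {no-lookback, lookback}, at NPI level with the
    count-then-fee tiebreak and a 0.5 completeness threshold."""
    out = []
    for enc_scope in ("MEDICAL", "EM"):
        for clin_scope in ("ALL_MD_APP", "MD_ONLY", "PCP_ONLY", "PCP_THEN_ALL"):
            for lookback in (False, True):
                out.append(
                    AttributionConfig(
                        encounter_scope=enc_scope,
                        clinician_scope=clin_scope,
                        lookback=lookback,
                    )
                )
    return out


def completeness_gate(encounters: pd.DataFrame, threshold: float = 0.5) -> bool:
    """True iff at least ``threshold`` of one patient's medical encounters are
    mapped to a provider identifier and specialty. Empty input fails."""
    if len(encounters) == 0:
        return False
    return encounters["is_mapped"].mean() >= threshold


def _gate_table(year_enc: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Per-patient gate outcome over one year's medical encounters."""
    if year_enc.empty:
        return pd.DataFrame(columns=["n_encounters", "n_mapped", "passed"])
    g = year_enc.groupby("patient_id").agg(
        n_encounters=("is_mapped", "size"), n_mapped=("is_mapped", "sum")
    )
    g["passed"] = (g["n_mapped"] / g["n_encounters"]) >= threshold
    return g


def candidate_set(
    encounters: pd.DataFrame, config: AttributionConfig, tier: str = "ALL"
) -> pd.DataFrame:
    """Encounters eligible for attribution in one tier.

    Unmapped encounters are always excluded; ``encounter_scope=EM`` keeps
    E&M encounters only; the tier/clinician scope restricts designations
    (or, for CUSTOM, specialty codes).
    """
    e = encounters.loc[encounters["is_mapped"]]
    if config.encounter_scope == "EM":
        e = e.loc[e["is_em"]]
    if tier == "PCP":
        allowed = {"PCP"} | ({"APP"} if config.app_as_pcp else set())
        e = e.loc[e["designation"].isin(allowed)]
    elif config.clinician_scope == "CUSTOM":
        e = e.loc[e["specialty_code"].isin(config.custom_specialties)]
    elif config.clinician_scope in _SCOPE_DESIGNATIONS:
        e = e.loc[e["designation"].isin(_SCOPE_DESIGNATIONS[config.clinician_scope])]
    elif config.clinician_scope == "PCP_THEN_ALL":
        e = e.loc[e["designation"].isin(_SCOPE_DESIGNATIONS["ALL_MD_APP"])]
    return e


def _winner_table(eligible: pd.DataFrame, tiebreak: str) -> tuple[pd.DataFrame, set]:
    """Per-patient plurality winner over eligible encounters.

    Returns (winners, tied): winners has one row per resolved patient with
    the attributed identifier and its entity type; ``tied`` is the set of
    patients left unresolved by an unbroken count tie (COUNT_ONLY only).
    """
    if eligible.empty:
        return pd.DataFrame(columns=["patient_id", "attributed_id", "id_entity_type"]), set()
    agg = (
        eligible.groupby(["patient_id", "provider_id"])
        .agg(n=("provider_id", "size"), fee=("fee_total", "sum"),
             entity=("entity_type", "first"))
        .reset_index()
    )
    if tiebreak == "FEE_THEN_COUNT":
        order, asc = ["fee", "n", "provider_id"], [False, False, True]
    else:
        order, asc = ["n", "fee", "provider_id"], [False, False, True]
    agg = agg.sort_values(["patient_id"] + order, ascending=[True] + asc)
    winners = agg.drop_duplicates("patient_id")
    tied: set = set()
    if tiebreak == "COUNT_ONLY":
        nmax = agg.groupby("patient_id")["n"].transform("max")
        at_max = agg.loc[agg["n"] == nmax]
        counts = at_max.groupby("patient_id").size()
        tied = set(counts.index[counts > 1])
        winners = winners.loc[~winners["patient_id"].isin(tied)]
    winners = winners.rename(columns={"provider_id": "attributed_id", "entity": "id_entity_type"})
    return winners[["patient_id", "attributed_id", "id_entity_type"]], tied


def plurality_attribute(
    eligible: pd.DataFrame, tiebreak: str = "COUNT_THEN_FEE"
) -> tuple[str | None, str]:
    """Single-patient plurality rule; returns (attributed id or None, reason)."""
    if eligible.empty:
        return None, "no_eligible_encounters"
    e = eligible.copy()
    e["patient_id"] = "_one"
    winners, tied = _winner_table(e, tiebreak)
    if "_one" in tied:
        return None, "tie_unbroken"
    return winners["attributed_id"].iloc[0], "none"


def _tiers(config: AttributionConfig) -> list[tuple[str, str]]:
    """Ordered (year_used, tier) attempts for a config."""
    scope = config.clinician_scope
    if scope == "PCP_ONLY":
        per_year = ["PCP"]
    elif scope == "PCP_THEN_ALL":
        per_year = ["PCP", "ALL"]
    else:
        per_year = ["ALL"]
    tiers = [("current", t) for t in per_year]
    if config.lookback:
        prior = [("prior", t) for t in per_year]
        if scope == "PCP_THEN_ALL" and config.prior_pcp_first:
            tiers = [("current", "PCP"), ("prior", "PCP"), ("current", "ALL"), ("prior", "ALL")]
        else:
            tiers = tiers + prior
    return tiers


def _attribute_year(
    patients: pd.Series,
    enc_by_yearused: dict[str, pd.DataFrame],
    config: AttributionConfig,
) -> pd.DataFrame:
    """Attribute one target year for all enrolled patients.

    ``enc_by_yearused`` maps 'current'/'prior' to that year's NPI-level
    medical encounter table.
    """
    two_stage = config.level == "TIN_THEN_NPI"
    level_tables: dict[str, pd.DataFrame] = {}
    npi_tables: dict[str, pd.DataFrame] = {}
    for yu, enc in enc_by_yearused.items():
        npi_tables[yu] = enc
        if config.level == "NPI":
            level_tables[yu] = enc
        else:
            level_tables[yu] = aggregate_to_tin(enc) if not enc.empty else enc

    gates = {
        yu: _gate_table(tbl, config.completeness_threshold) for yu, tbl in level_tables.items()
    }

    res = pd.DataFrame(
        {
            "patient_id": patients.to_numpy(),
            "attributed_id": pd.Series(pd.NA, index=range(len(patients)), dtype=object),
            "id_entity_type": "unknown",
            "year_used": "none",
            "tier_used": "none",
        }
    ).set_index("patient_id")
    # default failure reason from the current (primary) year's gate
    cur_gate = gates["current"]
    reason = pd.Series("no_eligible_encounters", index=res.index, dtype=object)
    has_enc = res.index.isin(cur_gate.index)
    passed = (
        res.index.isin(cur_gate.index[cur_gate["passed"]]) if len(cur_gate) else has_enc & False
    )
    reason[has_enc & ~passed] = "failed_gate"

    unattributed = pd.Series(True, index=res.index)
    # an unbroken count tie (COUNT_ONLY) terminates the whole tier sequence:
    # later tiers or years never override a tie, so the attributed set under
    # COUNT_ONLY is a same-identifier subset of the count-then-fee set
    blocked = pd.Series(False, index=res.index)
    for yu, tier in _tiers(config):
        tbl = level_tables[yu]
        gate = gates[yu]
        gated = set(gate.index[gate["passed"]]) if len(gate) else set()
        todo = set(res.index[unattributed & ~blocked]) & gated
        if not todo:
            continue
        eligible = candidate_set(tbl.loc[tbl["patient_id"].isin(todo)], config, tier)
        winners, tied = _winner_table(eligible, config.tiebreak)
        if two_stage and not winners.empty:
            winners, tied2 = _refine_tin_to_npi(winners, npi_tables[yu], config, tier)
            tied |= tied2
        if tied:
            hit_tied = res.index.intersection(list(tied))
            blocked.loc[hit_tied] = True
            reason.loc[hit_tied] = "tie_unbroken"
        if winners.empty:
            continue
        winners = winners.set_index("patient_id")
        hit = winners.index.intersection(res.index[unattributed & ~blocked])
        res.loc[hit, "attributed_id"] = winners.loc[hit, "attributed_id"]
        res.loc[hit, "id_entity_type"] = winners.loc[hit, "id_entity_type"]
        res.loc[hit, "year_used"] = yu
        if config.clinician_scope in ("PCP_ONLY", "PCP_THEN_ALL"):
            res.loc[hit, "tier_used"] = tier
        else:
            res.loc[hit, "tier_used"] = "ALL"
        unattributed.loc[hit] = False

    res["reason_unattributed"] = reason.where(unattributed, "none")
    return res.reset_index()


def _refine_tin_to_npi(
    tin_winners: pd.DataFrame, npi_enc: pd.DataFrame, config: AttributionConfig, tier: str
) -> tuple[pd.DataFrame, set]:
    """Second stage of TIN-then-NPI: rerun the plurality rule over NPI-level
    encounters restricted to each patient's winning TIN.

    A patient whose winning practice has no mapped clinician-level encounters
    ends up unattributed for this tier.
    """
    merged = npi_enc.merge(
        tin_winners.rename(columns={"attributed_id": "_win_tin"})[["patient_id", "_win_tin"]],
        on="patient_id",
    )
    restricted = merged.loc[merged["tin"] == merged["_win_tin"]]
    eligible = candidate_set(restricted, config, tier)
    return _winner_table(eligible, config.tiebreak)


def attribute_patient(
    current: pd.DataFrame,
    prior: pd.DataFrame | None,
    config: AttributionConfig,
) -> dict:
    """Attribute a single patient from their current- (and optionally prior-)
    year NPI-level medical encounters."""
    if config.lookback and prior is None:
        raise ValueError("lookback=True requires prior-year encounters")
    pid = "_patient"
    cur = current.assign(patient_id=pid)
    tables = {"current": cur}
    if config.lookback:
        tables["prior"] = prior.assign(patient_id=pid)
    res = _attribute_year(pd.Series([pid]), tables, config).iloc[0].to_dict()
    res.pop("patient_id")
    return res


def attribute_cohort(
    encounters_by_year: Mapping[int, pd.DataFrame],
    enrollment: pd.DataFrame,
    config: AttributionConfig,
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Attribute every enrolled patient-year under one method.

    ``encounters_by_year`` maps calendar year to that year's NPI-level
    medical encounter table (TIN aggregation happens internally when the
    config's level requires it). With lookback, each target year also needs
    the prior year's table. Returns one row per enrolled patient-year.
    """
    if years is None:
        years = sorted(enrollment["year"].unique())
        if config.lookback and years and (years[0] - 1) not in encounters_by_year:
            years = years[1:]
    frames = []
    for y in years:
        if y not in encounters_by_year:
            raise ValueError(f"no encounter table supplied for requested year {y}")
        tables = {"current": encounters_by_year[y]}
        if config.lookback:
            if (y - 1) not in encounters_by_year:
                raise ValueError(
                    f"lookback attribution for {y} requires encounter data for {y - 1}"
                )
            tables["prior"] = encounters_by_year[y - 1]
        patients = enrollment.loc[enrollment["year"] == y, "patient_id"].drop_duplicates()
        res = _attribute_year(patients, tables, config)
        res["year"] = y
        frames.append(res)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=RESULT_COLUMNS)
    return out[RESULT_COLUMNS]
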