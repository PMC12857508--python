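"""Independent brute-force attribution oracle.

Pure-Python reimplementation of the attribution contract over lists of
encounter dicts: explicit per-patient enumeration of counts and fees, no
pandas, no shared code with the engine. Used to cross-check the vectorized
engine on small cohorts.
"""

from __future__ import annotations

from collections import defaultdict

PRIORITY = {"PCP": 0, "SCP": 1, "APP": 2, "OTHER": 3}
SCOPES = {"ALL_MD_APP": {"PCP", "SCP", "APP"}, "MD_ONLY": {"PCP", "SCP"}}


def _modal(values, key=None):
    counts = defaultdict(int)
    for v in values:
        counts[v] += 1
    if not counts:
        return None
    key = key or (lambda v: v)
    return min(counts, key=lambda v: (-counts[v], key(v)))


def _to_tin_level(encs):
    """Aggregate NPI-level encounter dicts to (patient, tin, date)."""
    groups = defaultdict(list)
    for e in encs:
        groups[(e["patient_id"], e["tin"], e["service_date"])].append(e)
    out = []
    for (pat, tin, date), members in groups.items():
        desigs = [m["designation"] for m in members if m["designation"] is not None]
        specs = [m["specialty_code"] for m in members if m["specialty_code"] is not None]
        spec = _modal(specs)
        out.append(
            {
                "patient_id": pat,
                "provider_id": tin,
                "tin": tin,
                "service_date": date,
                "designation": _modal(desigs, key=lambda d: PRIORITY.get(d, 9)) or "OTHER",
                "specialty_code": spec,
                "entity_type": "unknown",
                "is_em": any(m["is_em"] for m in members),
                "fee_total": sum(m["fee_total"] for m in members),
                "is_mapped": tin is not None and spec is not None,
            }
        )
    return out


def _gate(encs, threshold):
    if not encs:
        return False
    mapped = sum(1 for e in encs if e["is_mapped"])
    return mapped / len(encs) >= threshold


def _eligible(encs, cfg, tier):
    out = []
    for e in encs:
        if not e["is_mapped"]:
            continue
        if cfg["encounter_scope"] == "EM" and not e["is_em"]:
            continue
        if tier == "PCP":
            allowed = {"PCP"} | ({"APP"} if cfg.get("app_as_pcp") else set())
            if e["designation"] not in allowed:
                continue
        elif cfg["clinician_scope"] == "CUSTOM":
            if e["specialty_code"] not in cfg["custom_specialties"]:
                continue
        elif cfg["clinician_scope"] in SCOPES:
            if e["designation"] not in SCOPES[cfg["clinician_scope"]]:
                continue
        elif cfg["clinician_scope"] == "PCP_THEN_ALL":
            if e["designation"] not in SCOPES["ALL_MD_APP"]:
                continue
        out.append(e)
    return out


def _plurality(encs, tiebreak):
    """Returns (winner_id or None, tie_flag)."""
    counts = defaultdict(int)
    fees = defaultdict(float)
    for e in encs:
        counts[e["provider_id"]] += 1
        fees[e["provider_id"]] += e["fee_total"]
    if not counts:
        return None, False
    ids = sorted(counts)
    if tiebreak == "COUNT_ONLY":
        best = max(counts.values())
        top = [i for i in ids if counts[i] == best]
        if len(top) > 1:
            return None, True
        return top[0], False
    if tiebreak == "FEE_THEN_COUNT":
        return min(ids, key=lambda i: (-fees[i], -counts[i], i)), False
    return min(ids, key=lambda i: (-counts[i], -fees[i], i)), False


def _tier_sequence(cfg):
    scope = cfg["clinician_scope"]
    per_year = {"PCP_ONLY": ["PCP"], "PCP_THEN_ALL": ["PCP", "ALL"]}.get(scope, ["ALL"])
    seq = [("current", t) for t in per_year]
    if cfg.get("lookback"):
        seq += [("prior", t) for t in per_year]
    return seq


def attribute_one(cfg, current_encs, prior_encs):
    """Attribute one patient; returns (attributed_id or None, year_used)."""
    level = cfg.get("level", "NPI")
    tables = {"current": current_encs, "prior": prior_encs or []}
    npi_tables = dict(tables)
    if level in ("TIN", "TIN_THEN_NPI"):
        tables = {k: _to_tin_level(v) for k, v in tables.items()}
    threshold = cfg.get("completeness_threshold", 0.5)
    tiebreak = cfg.get("tiebreak", "COUNT_THEN_FEE")
    for year_used, tier in _tier_sequence(cfg):
        encs = tables[year_used]
        if not _gate(encs, threshold):
            continue
        winner, tied = _plurality(_eligible(encs, cfg, tier), tiebreak)
        if tied:
            return None, "none"  # unbroken tie terminates the sequence
        if winner is None:
            continue
        if level == "TIN_THEN_NPI":
            within = [e for e in npi_tables[year_used] if e["tin"] == winner]
            winner, tied = _plurality(_eligible(within, cfg, tier), tiebreak)
            if tied:
                return None, "none"
            if winner is None:
                continue
        return winner, year_used
    return None, "none"


def attribute_cohort_bruteforce(cfg, encounters, enrollment_patients, year):
    """Per-patient attribution for one target year.

    ``encounters``: list of encounter dicts carrying a ``year`` key.
    Returns {patient_id: (attributed_id or None, year_used)}.
    """
    by_patient_year = defaultdict(list)
    for e in encounters:
        by_patient_year[(e["patient_id"], e["year"])].append(e)
    out = {}
    for pat in enrollment_patients:
        cur = by_patient_year.get((pat, year), [])
        pri = by_patient_year.get((pat, year - 1), [])
        out[pat] = attribute_one(cfg, cur, pri)
    return out
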