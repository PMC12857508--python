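"""Attribution engine: gate, scopes, plurality, tiers, lookback, invariants."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from panelattr.attribution import (
    AttributionConfig,
    attribute_cohort,
    attribute_patient,
    canonical_configs,
    candidate_set,
    completeness_gate,
    plurality_attribute,
)
from panelattr.encounters import consolidate_encounters, filter_medical
from panelattr.enrichment import enrich_claims

from _oracle import attribute_cohort_bruteforce
from conftest import random_encounters


def _enc(rows):
    base = {
        "patient_id": "P1", "provider_id": "A", "level": "NPI",
        "entity_type": "individual", "service_date": "2022-01-01", "year": 2022,
        "designation": "PCP", "specialty_code": "08", "is_em": True,
        "fee_total": 100.0, "n_lines": 1, "is_mapped": True, "tin": "T1",
    }
    out = []
    for i, r in enumerate(rows):
        d = dict(base, service_date=f"2022-01-{i + 1:02d}")
        d.update(r)
        out.append(d)
    return pd.DataFrame(out)


class TestConfig:
    def test_sixteen_canonical_permutations(self):
        configs = canonical_configs()
        assert len(configs) == 16
        assert len({c.label for c in configs}) == 16
        assert all(c.level == "NPI" and c.tiebreak == "COUNT_THEN_FEE"
                   and c.completeness_threshold == 0.5 for c in configs)

    def test_custom_scope_requires_specialties(self):
        with pytest.raises(ValidationError, match="custom_specialties"):
            AttributionConfig(clinician_scope="CUSTOM")
        with pytest.raises(ValidationError, match="custom_specialties"):
            AttributionConfig(clinician_scope="MD_ONLY", custom_specialties=frozenset({"90"}))


class TestCompletenessGate:
    def test_boundary_inclusive(self):
        enc = _enc([{"is_mapped": True}, {"is_mapped": True},
                    {"is_mapped": False}, {"is_mapped": False}])
        assert completeness_gate(enc, 0.5)  # 2 of 4, "minimum of 50%" inclusive
        assert not completeness_gate(enc.iloc[1:], 0.5)  # 1 of 3

    def test_empty_fails(self):
        assert not completeness_gate(_enc([]).iloc[0:0], 0.5)


class TestCandidateSet:
    def test_scope_designations(self):
        enc = _enc([
            {"designation": "PCP"}, {"designation": "SCP"},
            {"designation": "APP"}, {"designation": "OTHER"},
        ])
        get = lambda cfg, tier="ALL": set(
            candidate_set(enc, cfg, tier)["designation"]
        )
        assert get(AttributionConfig(clinician_scope="ALL_MD_APP")) == {"PCP", "SCP", "APP"}
        assert get(AttributionConfig(clinician_scope="MD_ONLY")) == {"PCP", "SCP"}
        assert get(AttributionConfig(clinician_scope="PCP_ONLY"), "PCP") == {"PCP"}
        assert get(
            AttributionConfig(clinician_scope="PCP_ONLY", app_as_pcp=True), "PCP"
        ) == {"PCP", "APP"}

    def test_custom_specialty_set(self):
        enc = _enc([{"specialty_code": "90", "designation": "SCP"},
                    {"specialty_code": "83", "designation": "SCP"},
                    {"specialty_code": "08", "designation": "PCP"}])
        cfg = AttributionConfig(clinician_scope="CUSTOM",
                                custom_specialties=frozenset({"90", "83"}))
        assert set(candidate_set(enc, cfg)["specialty_code"]) == {"90", "83"}

    def test_em_scope_and_unmapped_exclusion(self):
        enc = _enc([{"is_em": False}, {"is_em": True}, {"is_mapped": False}])
        cfg = AttributionConfig(encounter_scope="EM", clinician_scope="ALL_MD_APP")
        assert len(candidate_set(enc, cfg)) == 1


class TestPlurality:
    def test_strict_plurality_all_modes(self):
        enc = _enc([{"provider_id": "A"}] * 3 + [{"provider_id": "B"}] * 2)
        for tb in ("COUNT_THEN_FEE", "COUNT_ONLY"):
            assert plurality_attribute(enc, tb) == ("A", "none")

    def test_fee_breaks_count_tie(self):
        enc = _enc([
            {"provider_id": "A", "fee_total": 150.0},
            {"provider_id": "A", "fee_total": 100.0},
            {"provider_id": "B", "fee_total": 100.0},
            {"provider_id": "B", "fee_total": 80.0},
        ])
        assert plurality_attribute(enc, "COUNT_THEN_FEE") == ("A", "none")
        assert plurality_attribute(enc, "COUNT_ONLY") == (None, "tie_unbroken")

    def test_fee_primary_mode(self):
        enc = _enc([
            {"provider_id": "A", "fee_total": 900.0},
            {"provider_id": "B", "fee_total": 100.0},
            {"provider_id": "B", "fee_total": 100.0},
            {"provider_id": "B", "fee_total": 100.0},
        ])
        assert plurality_attribute(enc, "FEE_THEN_COUNT") == ("A", "none")
        assert plurality_attribute(enc, "COUNT_THEN_FEE") == ("B", "none")

    def test_order_invariance_brute_force(self):
        """Winner is invariant to encounter row order (checked by explicit
        enumeration over permuted inputs)."""
        rng = np.random.default_rng(0)
        enc = _enc([
            {"provider_id": "A", "fee_total": 900.0},
            {"provider_id": "B", "fee_total": 300.0},
            {"provider_id": "B", "fee_total": 300.0},
            {"provider_id": "B", "fee_total": 300.0},
            {"provider_id": "C", "fee_total": 450.0},
        ])
        for tb in ("COUNT_THEN_FEE", "COUNT_ONLY", "FEE_THEN_COUNT"):
            results = {
                plurality_attribute(enc.sample(frac=1.0, random_state=s), tb)
                for s in range(10)
            }
            assert len(results) == 1

    def test_residual_tie_smallest_identifier(self):
        enc = _enc([{"provider_id": "B"}, {"provider_id": "A"}])
        assert plurality_attribute(enc, "COUNT_THEN_FEE") == ("A", "none")

    def test_empty(self):
        assert plurality_attribute(_enc([]).iloc[0:0]) == (None, "no_eligible_encounters")


class TestAttributePatient:
    def test_pcp_tier_tried_first(self):
        enc = _enc(
            [{"designation": "PCP", "provider_id": "PCP1"}]
            + [{"designation": "SCP", "provider_id": "SCP1"}] * 5
        )
        res = attribute_patient(enc, None, AttributionConfig(clinician_scope="PCP_THEN_ALL"))
        assert res["attributed_id"] == "PCP1"
        assert res["tier_used"] == "PCP"

    def test_fallback_to_all_tier(self):
        enc = _enc([{"designation": "SCP", "provider_id": "SCP1"}] * 3)
        res = attribute_patient(enc, None, AttributionConfig(clinician_scope="PCP_THEN_ALL"))
        assert res["attributed_id"] == "SCP1"
        assert res["tier_used"] == "ALL"

    def test_lookback_used_when_current_fails(self):
        cur = _enc([]).iloc[0:0]
        prior = _enc([{"provider_id": "A"}] * 2)
        prior["year"] = 2021
        cfg = AttributionConfig(clinician_scope="ALL_MD_APP", lookback=True)
        res = attribute_patient(cur, prior, cfg)
        assert res["attributed_id"] == "A"
        assert res["year_used"] == "prior"

    def test_lookback_requires_prior(self):
        with pytest.raises(ValueError, match="prior"):
            attribute_patient(_enc([{}]), None,
                              AttributionConfig(clinician_scope="ALL_MD_APP", lookback=True))


class TestAttributeCohort:
    def test_enrolled_without_claims_gets_reason(self):
        enc = _enc([{"patient_id": "P1"}] * 2)
        enrollment = pd.DataFrame({"patient_id": ["P1", "P2"], "year": [2022, 2022]})
        res = attribute_cohort({2022: enc}, enrollment,
                               AttributionConfig(clinician_scope="ALL_MD_APP"))
        r2 = res.set_index("patient_id").loc["P2"]
        assert pd.isna(r2["attributed_id"])
        assert r2["reason_unattributed"] == "no_eligible_encounters"

    def test_missing_year_error_names_year(self):
        enrollment = pd.DataFrame({"patient_id": ["P1"], "year": [2022]})
        with pytest.raises(ValueError, match="2022"):
            attribute_cohort({}, enrollment, AttributionConfig(clinician_scope="ALL_MD_APP"),
                             years=[2022])

    def test_tin_then_npi_two_stage(self):
        """Stage 1 picks the plurality TIN, stage 2 the plurality NPI within it,
        even when another TIN's best NPI has more encounters."""
        enc = _enc([
            {"provider_id": "X", "tin": "T1"},
            {"provider_id": "X", "tin": "T1"},
            {"provider_id": "Y", "tin": "T1"},
            {"provider_id": "Z", "tin": "T2", "service_date": "2022-02-01"},
            {"provider_id": "Z", "tin": "T2", "service_date": "2022-02-02"},
        ])
        enrollment = pd.DataFrame({"patient_id": ["P1"], "year": [2022]})
        cfg = AttributionConfig(clinician_scope="ALL_MD_APP", level="TIN_THEN_NPI")
        res = attribute_cohort({2022: enc}, enrollment, cfg)
        assert res.loc[0, "attributed_id"] == "X"

    def test_results_independent_of_patient_order(self):
        rng = np.random.default_rng(42)
        enc = random_encounters(rng, n_patients=15)
        pats = sorted(enc["patient_id"].unique())
        enrollment = pd.DataFrame({"patient_id": pats, "year": 2022})
        cfg = AttributionConfig(clinician_scope="PCP_THEN_ALL", lookback=True)
        by_year = {y: enc[enc["year"] == y] for y in (2021, 2022)}
        a = attribute_cohort(by_year, enrollment, cfg)
        b = attribute_cohort(by_year, enrollment.iloc[::-1], cfg)
        pd.testing.assert_frame_equal(
            a.sort_values("patient_id").reset_index(drop=True),
            b.sort_values("patient_id").reset_index(drop=True),
        )


def _encounters_by_year(sim):
    refs = sim.references
    enriched = enrich_claims(sim.claims, refs.roster, refs.crosswalk, refs.registry)
    enc = consolidate_encounters(filter_medical(enriched), refs.designations)
    by_year = {int(y): g.reset_index(drop=True) for y, g in enc.groupby("year")}
    for y in sim.enrollment["year"].unique():
        by_year.setdefault(int(y), enc.iloc[0:0])
    return by_year


def _fraction(results):
    return results["attributed_id"].notna().mean()


class TestInvariants:
    def test_scope_and_lookback_monotonicity(self, small_sim):
        by_year = _encounters_by_year(small_sim)
        enrollment = small_sim.enrollment
        year = [2022]
        frac = {}
        for scope in ("PCP_ONLY", "MD_ONLY", "ALL_MD_APP", "PCP_THEN_ALL"):
            for lb in (False, True):
                cfg = AttributionConfig(clinician_scope=scope, lookback=lb)
                frac[(scope, lb)] = _fraction(
                    attribute_cohort(by_year, enrollment, cfg, years=year)
                )
        for lb in (False, True):
            assert frac[("PCP_ONLY", lb)] <= frac[("MD_ONLY", lb)]
            assert frac[("MD_ONLY", lb)] <= frac[("ALL_MD_APP", lb)]
            assert frac[("PCP_THEN_ALL", lb)] >= max(
                frac[("PCP_ONLY", lb)], frac[("ALL_MD_APP", lb)]
            )
        for scope in ("PCP_ONLY", "MD_ONLY", "ALL_MD_APP", "PCP_THEN_ALL"):
            assert frac[(scope, False)] <= frac[(scope, True)]

    def test_lookback_never_changes_current_year_result(self, small_sim):
        by_year = _encounters_by_year(small_sim)
        base_cfg = dict(clinician_scope="PCP_THEN_ALL", encounter_scope="MEDICAL")
        no_lb = attribute_cohort(by_year, small_sim.enrollment,
                                 AttributionConfig(**base_cfg), years=[2022])
        lb = attribute_cohort(by_year, small_sim.enrollment,
                              AttributionConfig(**base_cfg, lookback=True), years=[2022])
        merged = no_lb.merge(lb, on="patient_id", suffixes=("_n", "_l"))
        attributed = merged[merged["attributed_id_n"].notna()]
        assert (attributed["attributed_id_n"] == attributed["attributed_id_l"]).all()
        assert (attributed["year_used_l"] == "current").all()

    def test_threshold_monotonicity(self, small_sim):
        by_year = _encounters_by_year(small_sim)
        fracs = [
            _fraction(attribute_cohort(
                by_year, small_sim.enrollment,
                AttributionConfig(clinician_scope="ALL_MD_APP", completeness_threshold=t),
                years=[2022],
            ))
            for t in (0.5, 0.6, 0.75, 0.9)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_tiebreak_refinement(self):
        """Patients attributed under COUNT_ONLY get the same identifier under
        COUNT_THEN_FEE, whose attributed set is a superset."""
        rng = np.random.default_rng(7)
        for trial in range(8):
            enc = random_encounters(rng, n_patients=15)
            pats = sorted(set(enc["patient_id"]))
            enrollment = pd.DataFrame({"patient_id": pats, "year": 2022})
            by_year = {y: enc[enc["year"] == y] for y in (2021, 2022)}
            kw = dict(clinician_scope="PCP_THEN_ALL", lookback=True)
            strict = attribute_cohort(by_year, enrollment,
                                      AttributionConfig(**kw, tiebreak="COUNT_ONLY"))
            full = attribute_cohort(by_year, enrollment, AttributionConfig(**kw))
            merged = strict.merge(full, on="patient_id", suffixes=("_s", "_f"))
            got = merged[merged["attributed_id_s"].notna()]
            assert got["attributed_id_f"].notna().all()
            assert (got["attributed_id_s"] == got["attributed_id_f"]).all()

    def test_matches_bruteforce_oracle_small(self):
        rng = np.random.default_rng(123)
        cfgs = [
            AttributionConfig(clinician_scope="PCP_THEN_ALL", lookback=True),
            AttributionConfig(clinician_scope="ALL_MD_APP", level="TIN"),
            AttributionConfig(clinician_scope="MD_ONLY", tiebreak="COUNT_ONLY"),
        ]
        for trial in range(5):
            enc = random_encounters(rng, n_patients=10)
            pats = sorted(set(enc["patient_id"]))
            enrollment = pd.DataFrame({"patient_id": pats, "year": 2022})
            by_year = {y: enc[enc["year"] == y] for y in (2021, 2022)}
            records = enc.where(enc.notna(), None).to_dict("records")
            for cfg in cfgs:
                engine = attribute_cohort(by_year, enrollment, cfg).set_index("patient_id")
                oracle = attribute_cohort_bruteforce(
                    cfg.model_dump(), records, pats, 2022
                )
                for pat, (oid, _) in oracle.items():
                    eid = engine.loc[pat, "attributed_id"]
                    assert (oid is None and pd.isna(eid)) or oid == eid
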