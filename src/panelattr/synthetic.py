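"""Synthetic Medicare-style claims with known ground-truth affiliations.

Emulates the inputs of a claims-based attribution study: an enrollment
roster, provider reference files (annual NPI→specialty roster, NPI registry
with entity types and taxonomies, taxonomy→specialty crosswalk), and claim
lines in two dialects — carrier (professional) and outpatient (facility) —
with configurable field-level missingness mimicking encounter-data gaps.

Every patient-year has exactly one true affiliated provider; visits go to
that provider with probability ``concentration`` and otherwise scatter
uniformly, so plurality-recovery difficulty is tunable. Affiliations churn
between years with a configurable probability, which drives year-over-year
attribution stability downstream.

All randomness flows from one root seed through named substreams, so any
single parameter can change without perturbing unrelated draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .npi import generate_npis
from .reference import DESIGNATIONS, default_crosswalk, default_designations

CLAIM_COLUMNS = [
    "claim_id",
    "patient_id",
    "dialect",
    "year",
    "service_date",
    "hcpcs",
    "line_performing_npi",
    "base_rendering_npi",
    "base_attending_npi",
    "base_org_npi",
    "recorded_specialty",
    "claim_taxonomy",
    "billing_tin",
    "standardized_fee",
]

# mean standardized fee by rendering designation; gamma-distributed so fee
# tiebreaks are non-degenerate
FEE_MEANS = {"PCP": 120.0, "SCP": 210.0, "APP": 90.0, "OTHER": 70.0}
FACILITY_FEE_MEAN = 60.0


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Named, order-independent child stream of a root seed."""
    spawn = tuple(zlib.crc32(str(k).encode()) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=spawn))


class CohortSpec(BaseModel, frozen=True):
    """Study-population parameters for one synthetic cohort."""

    n_patients: int = Field(gt=0)
    n_providers_by_designation: dict[str, int] = Field(
        default={"PCP": 12, "SCP": 10, "APP": 6, "OTHER": 6}
    )
    start_year: int = 2021
    n_years: int = Field(default=2, gt=0)
    visits_mean: float = Field(default=6.0, ge=0)
    visits_min: int = Field(default=0, ge=0)
    p_zero_visits: float = Field(default=0.05, ge=0, le=1)
    concentration: float = Field(default=0.6, ge=0, le=1)
    churn: float = Field(default=0.15, ge=0, le=1)
    em_share: float = Field(default=0.55, ge=0, le=1)
    carrier_share: float = Field(default=0.7, ge=0, le=1)
    p_facility_pair: float = Field(default=0.15, ge=0, le=1)
    p_extra_line: float = Field(default=0.2, ge=0, le=1)
    affiliation_weights: dict[str, float] = Field(
        default={"PCP": 0.70, "SCP": 0.15, "APP": 0.15, "OTHER": 0.0}
    )
    practice_size: int = Field(default=4, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        for d, n in self.n_providers_by_designation.items():
            if d not in DESIGNATIONS:
                raise ValueError(f"n_providers_by_designation: unknown designation {d!r}")
            if n <= 0:
                raise ValueError(f"n_providers_by_designation[{d!r}] must be positive")
        for d, w in self.affiliation_weights.items():
            if d not in DESIGNATIONS:
                raise ValueError(f"affiliation_weights: unknown designation {d!r}")
            if w < 0:
                raise ValueError(f"affiliation_weights[{d!r}] must be nonnegative")
        if sum(self.affiliation_weights.values()) <= 0:
            raise ValueError("affiliation_weights must have positive total mass")
        return self

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))


class MissingnessSpec(BaseModel, frozen=True):
    """Per-field presence probabilities for provider identifiers on claims."""

    p_line_performing_present: float = Field(default=1.0, ge=0, le=1)
    p_base_rendering_present: float = Field(default=1.0, ge=0, le=1)
    p_base_attending_present: float = Field(default=1.0, ge=0, le=1)
    p_recorded_specialty_present: float = Field(default=1.0, ge=0, le=1)
    p_claim_taxonomy_present: float = Field(default=1.0, ge=0, le=1)
    p_org_npi_is_individual: float = Field(default=0.0, ge=0, le=1)

    @classmethod
    def complete(cls) -> "MissingnessSpec":
        """No missingness: every provider field populated."""
        return cls()

    @classmethod
    def tm_like(cls) -> "MissingnessSpec":
        """Near-complete provider fields, as in fee-for-service claims."""
        return cls(
            p_line_performing_present=0.99,
            p_base_rendering_present=0.95,
            p_base_attending_present=0.98,
            p_recorded_specialty_present=0.99,
            p_claim_taxonomy_present=0.90,
            p_org_npi_is_individual=0.10,
        )

    @classmethod
    def ma_like(cls) -> "MissingnessSpec":
        """Encounter-data-like gaps: clinician NPI on roughly two-thirds of
        claims, specialty codes rarely recorded, heavy reliance on the
        organization NPI (which often actually carries an individual NPI)."""
        return cls(
            p_line_performing_present=0.55,
            p_base_rendering_present=0.30,
            p_base_attending_present=0.45,
            p_recorded_specialty_present=0.10,
            p_claim_taxonomy_present=0.85,
            p_org_npi_is_individual=0.55,
        )


@dataclass
class ReferenceFiles:
    """Bundle of provider reference tables consumed by enrichment."""

    roster: pd.DataFrame
    registry: pd.DataFrame
    crosswalk: pd.DataFrame
    designations: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("roster", "registry", "crosswalk", "designations"):
            p = outdir / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        return paths


def scenario(name: str, n_patients: int = 400, seed: int = 0) -> tuple[CohortSpec, MissingnessSpec]:
    """Preset study conditions for plan-type comparisons.

    ``ma_like``: managed-care-style population — regular patient contact
    (few visit-free years, more visits), weaker clinician ties (higher
    churn), and encounter-data-like provider-field gaps. ``tm_like``:
    fee-for-service-style — more visit-free patients, stable affiliations,
    near-complete provider fields. Three simulated years support lookback
    and year-over-year stability.
    """
    if name == "ma_like":
        spec = CohortSpec(
            n_patients=n_patients, n_years=3, start_year=2020, seed=seed,
            visits_mean=6.0, p_zero_visits=0.05, churn=0.30, concentration=0.6,
        )
        return spec, MissingnessSpec.ma_like()
    if name == "tm_like":
        spec = CohortSpec(
            n_patients=n_patients, n_years=3, start_year=2020, seed=seed,
            visits_mean=4.5, p_zero_visits=0.18, churn=0.08, concentration=0.6,
        )
        return spec, MissingnessSpec.tm_like()
    raise ValueError(f"unknown scenario {name!r}; choose 'ma_like' or 'tm_like'")


def generate_providers(spec: CohortSpec) -> pd.DataFrame:
    """Synthesize the provider population, grouped into single-designation practices.

    Each provider gets a valid NPI, a specialty drawn from the bundled
    designation reference, and membership in a practice carrying a TIN, an
    organization NPI, and an organization taxonomy matching the practice's
    designation.
    """
    rng = substream(spec.seed, "providers")
    desig_df = default_designations()
    xwalk = default_crosswalk()
    spec_to_tax = dict(zip(xwalk["specialty_code"], xwalk["taxonomy_code"]))
    pools = {
        d: sorted(desig_df.loc[desig_df["designation"] == d, "specialty_code"])
        for d in DESIGNATIONS
    }

    rows = []
    for desig in DESIGNATIONS:
        n = spec.n_providers_by_designation.get(desig, 0)
        for _ in range(n):
            code = pools[desig][int(rng.integers(len(pools[desig])))]
            rows.append({"designation": desig, "specialty_code": code})
    prov = pd.DataFrame(rows)
    prov["npi"] = generate_npis(len(prov), rng)
    prov["taxonomy"] = prov["specialty_code"].map(spec_to_tax)

    # practices: contiguous groups within a designation
    prov["practice_id"] = ""
    pid = 0
    for desig in DESIGNATIONS:
        idx = prov.index[prov["designation"] == desig]
        for start in range(0, len(idx), spec.practice_size):
            prov.loc[idx[start : start + spec.practice_size], "practice_id"] = f"PR{pid:04d}"
            pid += 1
    practices = prov.groupby("practice_id").first().reset_index()
    org_npis = generate_npis(len(practices), rng)
    tins = [
        f"{rng.integers(1, 10)}{''.join(str(d) for d in rng.integers(0, 10, size=8))}"
        for _ in range(len(practices))
    ]
    practices["org_npi"] = org_npis
    practices["tin"] = tins
    prov = prov.merge(
        practices[["practice_id", "org_npi", "tin", "taxonomy"]].rename(
            columns={"taxonomy": "org_taxonomy"}
        ),
        on="practice_id",
    )
    return prov[
        [
            "npi",
            "designation",
            "specialty_code",
            "taxonomy",
            "practice_id",
            "org_npi",
            "org_taxonomy",
            "tin",
        ]
    ]


def generate_cohort(
    spec: CohortSpec, providers: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enrollment roster and ground-truth affiliations, one row per patient-year.

    Year 1 affiliations are drawn by designation weight then uniformly within
    the designation; each later year keeps the prior provider except with
    probability ``churn``, in which case a different provider is drawn.
    """
    rng = substream(spec.seed, "cohort")
    patients = [f"P{i:06d}" for i in range(spec.n_patients)]
    weights = np.array([spec.affiliation_weights.get(d, 0.0) for d in DESIGNATIONS])
    weights = weights / weights.sum()
    by_desig = {d: providers.loc[providers["designation"] == d] for d in DESIGNATIONS}

    def draw_affiliation(exclude: str | None = None) -> tuple[str, str]:
        while True:
            desig = DESIGNATIONS[int(rng.choice(len(DESIGNATIONS), p=weights))]
            pool = by_desig[desig]
            if len(pool) == 0:
                continue
            if exclude is not None:
                pool = pool.loc[pool["npi"] != exclude]
                if len(pool) == 0:
                    continue
            row = pool.iloc[int(rng.integers(len(pool)))]
            return row["npi"], row["designation"]

    truth_rows = []
    current: dict[str, tuple[str, str]] = {}
    for yi, year in enumerate(spec.years):
        for p in patients:
            if yi == 0:
                current[p] = draw_affiliation()
            elif rng.random() < spec.churn:
                current[p] = draw_affiliation(exclude=current[p][0])
            npi, desig = current[p]
            truth_rows.append(
                {
                    "patient_id": p,
                    "year": year,
                    "true_provider_id": npi,
                    "true_provider_designation": desig,
                }
            )
    truth = pd.DataFrame(truth_rows)
    enrollment = truth[["patient_id", "year"]].copy()
    return enrollment, truth


def generate_reference_files(spec: CohortSpec, providers: pd.DataFrame) -> ReferenceFiles:
    """Roster, registry, crosswalk and designation tables covering the cohort.

    Individual providers appear in the roster for every simulated year;
    organization NPIs appear only in the registry (entity_type=organization),
    so a roster lookup on them fails and exercises the taxonomy fallback.
    """
    roster = (
        providers.loc[:, ["npi", "specialty_code"]]
        .merge(pd.DataFrame({"year": spec.years}), how="cross")
        .loc[:, ["npi", "year", "specialty_code"]]
        .sort_values(["npi", "year"])
        .reset_index(drop=True)
    )
    indiv = providers[["npi", "taxonomy"]].rename(columns={"taxonomy": "primary_taxonomy"})
    indiv["entity_type"] = "individual"
    orgs = (
        providers[["org_npi", "org_taxonomy"]]
        .drop_duplicates()
        .rename(columns={"org_npi": "npi", "org_taxonomy": "primary_taxonomy"})
    )
    orgs["entity_type"] = "organization"
    registry = (
        pd.concat([indiv, orgs], ignore_index=True)[["npi", "entity_type", "primary_taxonomy"]]
        .sort_values("npi")
        .reset_index(drop=True)
    )
    return ReferenceFiles(
        roster=roster,
        registry=registry,
        crosswalk=default_crosswalk(),
        designations=default_designations(),
    )


def _presence_mask(spec: CohortSpec, field: str, n: int, p: float) -> np.ndarray:
    # one uniform per row from a field-named substream: monotone in p by coupling
    return substream(spec.seed, "missingness", field).random(n) < p


def generate_claims(
    spec: CohortSpec,
    providers: pd.DataFrame,
    truth: pd.DataFrame,
    miss: MissingnessSpec,
) -> pd.DataFrame:
    """Turn ground-truth affiliations into claim lines with field-level gaps.

    Visit structure (who, when, which code, which dialect) is independent of
    the missingness spec; presence masks come from separate named substreams
    so that lowering one presence probability only blanks more of that field.
    """
    rng = substream(spec.seed, "claims")
    prov_idx = providers.set_index("npi")
    by_desig = {
        d: providers.loc[providers["designation"] == d, "npi"].to_numpy()
        for d in DESIGNATIONS
    }

    visit_rows = []
    for (year,), grp in truth.groupby(["year"], sort=True):
        for _, trow in grp.iterrows():
            if rng.random() < spec.p_zero_visits:
                n_visits = 0
            else:
                extra_mean = max(spec.visits_mean - spec.visits_min, 0.0)
                n_visits = spec.visits_min + int(rng.poisson(extra_mean))
            for _ in range(n_visits):
                if rng.random() < spec.concentration:
                    npi = trow["true_provider_id"]
                else:
                    desig = DESIGNATIONS[int(rng.integers(len(DESIGNATIONS)))]
                    pool = by_desig[desig]
                    npi = pool[int(rng.integers(len(pool)))]
                day = int(rng.integers(0, 365))
                date = (
                    pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=day)
                ).strftime("%Y-%m-%d")
                if rng.random() < spec.em_share:
                    code = int(rng.integers(99201, 99500))
                elif rng.random() < 0.85:
                    code = int(rng.integers(90281, 99201))
                else:
                    code = int(rng.integers(99500, 99608))
                dialect = "carrier" if rng.random() < spec.carrier_share else "outpatient"
                visit_rows.append((trow["patient_id"], year, date, npi, str(code), dialect))

    lines = []
    for patient_id, year, date, npi, code, dialect in visit_rows:
        p = prov_idx.loc[npi]
        fee_mean = FEE_MEANS[p["designation"]]
        fee = round(float(rng.gamma(4.0, fee_mean / 4.0)), 2)
        lines.append((patient_id, year, date, npi, code, dialect, fee))
        if rng.random() < spec.p_extra_line:
            extra_code = str(int(rng.integers(90281, 99201)))
            extra_fee = round(float(rng.gamma(4.0, fee_mean / 4.0)), 2)
            lines.append((patient_id, year, date, npi, extra_code, dialect, extra_fee))
        if dialect == "carrier" and rng.random() < spec.p_facility_pair:
            fac_fee = round(float(rng.gamma(4.0, FACILITY_FEE_MEAN / 4.0)), 2)
            lines.append((patient_id, year, date, npi, code, "outpatient", fac_fee))

    df = pd.DataFrame(
        lines,
        columns=["patient_id", "year", "service_date", "_npi", "hcpcs", "dialect", "standardized_fee"],
    )
    n = len(df)
    df["claim_id"] = [f"C{i:07d}" for i in range(n)]
    p = prov_idx.loc[df["_npi"]]
    df["_specialty"] = p["specialty_code"].to_numpy()
    df["_org_npi"] = p["org_npi"].to_numpy()
    df["_org_taxonomy"] = p["org_taxonomy"].to_numpy()
    df["billing_tin"] = p["tin"].to_numpy()

    carrier = (df["dialect"] == "carrier").to_numpy()
    m_line = _presence_mask(spec, "line_performing", n, miss.p_line_performing_present)
    m_rend = _presence_mask(spec, "base_rendering", n, miss.p_base_rendering_present)
    m_att = _presence_mask(spec, "base_attending", n, miss.p_base_attending_present)
    m_spec = _presence_mask(spec, "recorded_specialty", n, miss.p_recorded_specialty_present)
    m_tax = _presence_mask(spec, "claim_taxonomy", n, miss.p_claim_taxonomy_present)
    m_orgind = _presence_mask(spec, "org_npi_individual", n, miss.p_org_npi_is_individual)

    npi = df["_npi"].to_numpy()
    df["line_performing_npi"] = np.where(carrier & m_line, npi, None)
    df["base_rendering_npi"] = np.where(carrier & m_rend, npi, None)
    df["base_attending_npi"] = np.where(~carrier & m_att, npi, None)
    df["base_org_npi"] = np.where(m_orgind, npi, df["_org_npi"].to_numpy())
    df["recorded_specialty"] = np.where(m_spec, df["_specialty"].to_numpy(), None)
    df["claim_taxonomy"] = np.where(m_tax, df["_org_taxonomy"].to_numpy(), None)

    return df[CLAIM_COLUMNS].reset_index(drop=True)


def inject_duplicates(claims: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Append exact duplicates of a fraction ``rate`` of claim lines.

    Encounter-level consolidation downstream must neutralize these.
    """
    if not 0 <= rate <= 1:
        raise ValueError("duplicate rate must be in [0, 1]")
    if rate == 0 or claims.empty:
        return claims.copy()
    rng = substream(seed, "duplicates")
    k = int(round(rate * len(claims)))
    pick = rng.choice(len(claims), size=k, replace=False)
    dup = claims.iloc[np.sort(pick)]
    return pd.concat([claims, dup], ignore_index=True)


@dataclass
class SyntheticData:
    """Everything one simulated study needs, with ground truth attached."""

    spec: CohortSpec
    missingness: MissingnessSpec
    providers: pd.DataFrame
    enrollment: pd.DataFrame
    truth: pd.DataFrame
    references: ReferenceFiles
    claims: pd.DataFrame


def simulate(
    spec: CohortSpec,
    miss: MissingnessSpec | None = None,
    duplicate_rate: float = 0.0,
) -> SyntheticData:
    """End-to-end synthesis: providers → cohort → reference files → claims."""
    miss = miss or MissingnessSpec.complete()
    providers = generate_providers(spec)
    enrollment, truth = generate_cohort(spec, providers)
    refs = generate_reference_files(spec, providers)
    claims = generate_claims(spec, providers, truth, miss)
    if duplicate_rate:
        claims = inject_duplicates(claims, duplicate_rate, spec.seed)
    return SyntheticData(spec, miss, providers, enrollment, truth, refs, claims)
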