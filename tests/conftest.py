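from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from panelattr.synthetic import CohortSpec, MissingnessSpec, simulate

# small specialty pool with its designation map, used by the random
# encounter generator (codes match the bundled designation reference)
SPECIALTY_POOL = {"01": "PCP", "08": "PCP", "06": "SCP", "83": "SCP", "50": "APP", "35": "OTHER"}

ENC_COLUMNS = [
    "patient_id", "provider_id", "level", "entity_type", "service_date", "year",
    "designation", "specialty_code", "is_em", "fee_total", "n_lines", "is_mapped", "tin",
]


def random_encounters(
    rng: np.random.Generator,
    n_patients: int = 12,
    max_per_year: int = 10,
    years: tuple[int, ...] = (2021, 2022),
    n_providers: int = 6,
    n_tins: int = 3,
) -> pd.DataFrame:
    """Adversarial random NPI-level encounter table: small fee/count sets to
    force ties, occasional unmapped rows, mixed designations."""
    providers = [f"N{i:03d}" for i in range(n_providers)]
    # fixed provider -> (specialty, tin, entity) so aggregates are well defined
    specs = list(SPECIALTY_POOL)
    pmap = {
        p: (
            specs[int(rng.integers(len(specs)))],
            f"T{int(rng.integers(n_tins)):02d}",
            "organization" if rng.random() < 0.2 else "individual",
        )
        for p in providers
    }
    rows = []
    for pi in range(n_patients):
        pat = f"P{pi:03d}"
        for year in years:
            for _ in range(int(rng.integers(0, max_per_year + 1))):
                if rng.random() < 0.12:
                    provider, spec, tin, entity = None, None, None, "unknown"
                else:
                    provider = providers[int(rng.integers(n_providers))]
                    spec, tin, entity = pmap[provider]
                    if rng.random() < 0.1:
                        spec = None  # unresolved specialty on a known provider
                desig = SPECIALTY_POOL.get(spec, "OTHER")
                rows.append(
                    {
                        "patient_id": pat,
                        "provider_id": provider,
                        "level": "NPI",
                        "entity_type": entity,
                        "service_date": f"{year}-{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 28)):02d}",
                        "year": year,
                        "designation": desig,
                        "specialty_code": spec,
                        "is_em": bool(rng.random() < 0.5),
                        "fee_total": float(rng.choice([50.0, 100.0, 100.0, 150.0, 200.0])),
                        "n_lines": 1,
                        "is_mapped": provider is not None and spec is not None,
                        "tin": tin,
                    }
                )
    return pd.DataFrame(rows, columns=ENC_COLUMNS)


@pytest.fixture(scope="session")
def small_sim():
    """One shared small simulation with encounter-data-like missingness."""
    spec = CohortSpec(n_patients=80, n_years=2, start_year=2021, seed=11, churn=0.2)
    return simulate(spec, MissingnessSpec.ma_like())


@pytest.fixture(scope="session")
def clean_sim():
    """Fully observed claims: no missingness, no churn."""
    spec = CohortSpec(
        n_patients=60, n_years=2, start_year=2021, seed=5, churn=0.0,
        concentration=0.85, visits_min=3, visits_mean=6.0, p_zero_visits=0.0,
    )
    return simulate(spec, MissingnessSpec.complete())
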