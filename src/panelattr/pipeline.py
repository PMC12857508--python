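"""End-to-end orchestration: simulate (or load) → enrich → prepare → attribute → measure.

A run is described by one declarative config (YAML/JSON): either a synthesis
spec or paths to external input files, a list of attribution methods, and a
root seed. Every stage writes CSV artifacts plus a manifest of file hashes
and row counts; reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .attribution import AttributionConfig, attribute_cohort, canonical_configs
from .encounters import consolidate_encounters, filter_medical
from .enrichment import enrich_claims, provenance_summary
from .metrics import method_comparison_table, panel_metrics
from .npi import validate_npi
from .reference import (
    load_crosswalk,
    load_designations,
    load_registry,
    load_roster,
)
from .synthetic import CLAIM_COLUMNS, CohortSpec, MissingnessSpec, simulate

logger = logging.getLogger(__name__)

_STR_COLUMNS = [
    "claim_id", "patient_id", "dialect", "service_date", "hcpcs",
    "line_performing_npi", "base_rendering_npi", "base_attending_npi",
    "base_org_npi", "recorded_specialty", "claim_taxonomy", "billing_tin",
]

_MISSINGNESS_PRESETS = {
    "complete": MissingnessSpec.complete,
    "tm_like": MissingnessSpec.tm_like,
    "ma_like": MissingnessSpec.ma_like,
}


class InputPaths(BaseModel, frozen=True):
    claims: str
    roster: str
    registry: str
    crosswalk: str
    enrollment: str
    designations: str | None = None


class RunConfig(BaseModel):
    """Declarative description of one end-to-end run."""

    seed: int = 0
    output_dir: str = "panelattr_out"
    cohort: CohortSpec | None = None
    missingness: MissingnessSpec | str | None = None
    duplicate_rate: float = Field(default=0.0, ge=0, le=1)
    inputs: InputPaths | None = None
    years: list[int] | None = None
    methods: list[AttributionConfig] = Field(default_factory=list)
    include_canonical: bool = False
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if (self.cohort is None) == (self.inputs is None):
            raise ValueError("exactly one of `cohort` (synthesis) or `inputs` must be given")
        if isinstance(self.missingness, str):
            if self.missingness not in _MISSINGNESS_PRESETS:
                raise ValueError(
                    f"unknown missingness preset {self.missingness!r}; "
                    f"choose from {sorted(_MISSINGNESS_PRESETS)}"
                )
            object.__setattr__(self, "missingness", _MISSINGNESS_PRESETS[self.missingness]())
        if not self.methods and not self.include_canonical:
            raise ValueError("no attribution methods configured")
        if self.years is not None and any(m.lookback for m in self.all_methods()):
            ys = sorted(self.years)
            if any(b - a != 1 for a, b in zip(ys, ys[1:])):
                raise ValueError("years must be contiguous when any method uses lookback")
        return self

    def all_methods(self) -> list[AttributionConfig]:
        methods = list(self.methods)
        if self.include_canonical:
            methods = canonical_configs() + methods
        return methods

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.model_validate(data)


def read_claims(path: str | Path) -> pd.DataFrame:
    """Read a claim table, enforcing the documented schema."""
    df = pd.read_csv(path, dtype={c: str for c in _STR_COLUMNS})
    missing = [c for c in CLAIM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"claims file {path} is missing required columns: {missing}")
    df["year"] = df["year"].astype(int)
    df["standardized_fee"] = df["standardized_fee"].astype(float)
    bad_dialect = set(df["dialect"].dropna()) - {"carrier", "outpatient"}
    if bad_dialect:
        raise ValueError(f"claims file {path} has unknown dialects: {sorted(bad_dialect)}")
    return df


def validate_inputs(paths: InputPaths | dict) -> dict:
    """Schema-check a set of input files.

    Missing required columns are fatal; data anomalies (invalid NPIs, unknown
    specialty codes) are counted and reported, never silently dropped.
    """
    if isinstance(paths, dict):
        paths = InputPaths.model_validate(paths)
    claims = read_claims(paths.claims)
    roster = load_roster(paths.roster)
    registry = load_registry(paths.registry)
    crosswalk = load_crosswalk(paths.crosswalk)
    designations = load_designations(paths.designations)
    enrollment = pd.read_csv(paths.enrollment, dtype={"patient_id": str})
    if not {"patient_id", "year"} <= set(enrollment.columns):
        raise ValueError(f"enrollment file {paths.enrollment} needs patient_id and year columns")

    issues: list[str] = []
    counts: dict[str, int] = {}
    npi_cols = ["line_performing_npi", "base_rendering_npi", "base_attending_npi", "base_org_npi"]
    n_invalid = 0
    for col in npi_cols:
        vals = claims[col].dropna()
        n_invalid += int((~vals.map(validate_npi)).sum())
    counts["invalid_npis"] = n_invalid
    if n_invalid:
        issues.append(f"{n_invalid} provider identifiers fail NPI check-digit validation")
    known = set(designations["specialty_code"])
    unk = int((~claims["recorded_specialty"].dropna().isin(known)).sum())
    counts["unknown_specialty_codes"] = unk
    if unk:
        issues.append(f"{unk} recorded specialty codes absent from the designation reference")
    uncovered = set(claims["claim_taxonomy"].dropna()) - set(crosswalk["taxonomy_code"])
    counts["uncovered_taxonomies"] = len(uncovered)
    if uncovered:
        issues.append(f"{len(uncovered)} claim taxonomy codes missing from the crosswalk")
    counts["registry_npis"] = len(registry)
    counts["roster_rows"] = len(roster)
    return {"issues": issues, "counts": counts}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False)
    manifest["files"][path.name] = {"sha256": _sha256(path), "rows": int(len(df))}
    logger.info("wrote %s (%d rows)", path.name, len(df))


def run(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Execute one full pipeline run; returns the artifact manifest."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "files": {},
    }

    if config.cohort is not None:
        miss = config.missingness or MissingnessSpec.complete()
        data = simulate(config.cohort, miss, duplicate_rate=config.duplicate_rate)
        claims, enrollment = data.claims, data.enrollment
        roster, registry = data.references.roster, data.references.registry
        crosswalk, designations = data.references.crosswalk, data.references.designations
        _write(data.truth, outdir / "ground_truth.csv", manifest)
        for name, df in (
            ("roster", roster), ("registry", registry),
            ("crosswalk", crosswalk), ("designations", designations),
        ):
            _write(df, outdir / f"{name}.csv", manifest)
        _write(claims, outdir / "claims.csv", manifest)
        _write(enrollment, outdir / "enrollment.csv", manifest)
    else:
        claims = read_claims(config.inputs.claims)
        roster = load_roster(config.inputs.roster)
        registry = load_registry(config.inputs.registry)
        crosswalk = load_crosswalk(config.inputs.crosswalk)
        designations = load_designations(config.inputs.designations)
        enrollment = pd.read_csv(config.inputs.enrollment, dtype={"patient_id": str})

    enriched = enrich_claims(claims, roster, crosswalk, registry)
    _write(enriched, outdir / "enriched_claims.csv", manifest)
    _write(provenance_summary(enriched), outdir / "provenance.csv", manifest)

    medical = filter_medical(enriched)
    encounters = consolidate_encounters(medical, designations, level="NPI")
    _write(encounters, outdir / "encounters.csv", manifest)
    enc_by_year = {int(y): g.reset_index(drop=True) for y, g in encounters.groupby("year")}
    for y in enrollment["year"].unique():
        enc_by_year.setdefault(int(y), encounters.iloc[0:0])

    metric_rows = []
    for i, method in enumerate(config.all_methods()):
        years = config.years
        results = attribute_cohort(enc_by_year, enrollment, method, years=years)
        _write(results, outdir / f"attribution_{i:02d}.csv", manifest)
        for y in sorted(results["year"].unique()):
            prior = results if (y - 1) in set(results["year"]) else None
            metric_rows.append(
                panel_metrics(results, enrollment, int(y), label=method.label, prior_results=prior)
            )
    _write(method_comparison_table(metric_rows), outdir / "metrics.csv", manifest)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
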