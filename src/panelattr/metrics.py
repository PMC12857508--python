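"""Evaluation measures for attribution runs.

Two headline measures: *fraction attributed* — the share of the enrolled
population assigned a usual provider — and *attribution stability* — among
patients attributed in the current year who were also enrolled in the prior
year, the share assigned the same identifier in the prior year. Stability
conflates true affiliation churn with spurious attribution, so it is a
relative measure for comparing methods, not an accuracy estimate.

Undefined ratios (empty denominators) are reported as missing, never as 0.
"""

from __future__ import annotations

import pandas as pd


def fraction_attributed(results: pd.DataFrame, enrollment: pd.DataFrame, year: int) -> float:
    """Share of patients enrolled in ``year`` with an attributed identifier."""
    enrolled = enrollment.loc[enrollment["year"] == year, "patient_id"].drop_duplicates()
    if len(enrolled) == 0:
        raise ValueError(f"no patients enrolled in {year}")
    res = results.loc[results["year"] == year]
    extra = set(res["patient_id"]) - set(enrolled)
    if extra:
        raise ValueError(f"results contain patients absent from the enrollment roster: {sorted(extra)[:5]}")
    attributed = res.loc[res["attributed_id"].notna(), "patient_id"].drop_duplicates()
    return len(attributed) / len(enrolled)


def attribution_stability(
    current: pd.DataFrame,
    prior: pd.DataFrame,
    enrollment: pd.DataFrame,
    year: int,
) -> float | None:
    """Among patients attributed in ``year`` and enrolled in ``year - 1``, the
    share attributed to the same identifier in the prior year.

    A patient unattributed in the prior year counts as not-same. Returns None
    when no patient qualifies for the denominator.
    """
    prior_enrolled = set(enrollment.loc[enrollment["year"] == year - 1, "patient_id"])
    cur = current.loc[(current["year"] == year) & current["attributed_id"].notna()]
    cur = cur.loc[cur["patient_id"].isin(prior_enrolled)]
    if cur.empty:
        return None
    prev = prior.loc[prior["year"] == year - 1, ["patient_id", "attributed_id"]].rename(
        columns={"attributed_id": "prior_id"}
    )
    merged = cur.merge(prev, on="patient_id", how="left")
    same = (merged["attributed_id"] == merged["prior_id"]) & merged["prior_id"].notna()
    return float(same.sum()) / len(merged)


def organization_share(results: pd.DataFrame, year: int | None = None) -> float | None:
    """Share of attributed patients whose identifier is an organization NPI.

    None when no patient is attributed (undefined, not zero).
    """
    res = results if year is None else results.loc[results["year"] == year]
    attributed = res.loc[res["attributed_id"].notna()]
    if attributed.empty:
        return None
    return float((attributed["id_entity_type"] == "organization").mean())


def panel_metrics(
    results: pd.DataFrame,
    enrollment: pd.DataFrame,
    year: int,
    label: str = "",
    prior_results: pd.DataFrame | None = None,
) -> dict:
    """All measures for one (config, year): counts, fraction attributed,
    stability (when prior results are supplied), and organization share."""
    enrolled = enrollment.loc[enrollment["year"] == year, "patient_id"].drop_duplicates()
    res = results.loc[results["year"] == year]
    attributed = res.loc[res["attributed_id"].notna()]
    row = {
        "label": label,
        "year": year,
        "n_population": len(enrolled),
        "n_attributed": len(attributed),
        "fraction_attributed": fraction_attributed(results, enrollment, year),
        "share_attributed_to_organization": organization_share(results, year),
        "n_stability_denominator": None,
        "n_same_provider": None,
        "stability": None,
    }
    if prior_results is not None:
        prior_enrolled = set(enrollment.loc[enrollment["year"] == year - 1, "patient_id"])
        denom = attributed.loc[attributed["patient_id"].isin(prior_enrolled)]
        row["n_stability_denominator"] = len(denom)
        stab = attribution_stability(results, prior_results, enrollment, year)
        row["stability"] = stab
        row["n_same_provider"] = (
            int(round(stab * len(denom))) if stab is not None else None
        )
    return row


def method_comparison_table(metric_rows: list[dict]) -> pd.DataFrame:
    """Long-format table over configs × years, for plotting the
    sensitivity–stability frontier."""
    cols = [
        "label",
        "year",
        "n_population",
        "n_attributed",
        "fraction_attributed",
        "n_stability_denominator",
        "n_same_provider",
        "stability",
        "share_attributed_to_organization",
    ]
    if not metric_rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(metric_rows)[cols]


def plot_frontier(table: pd.DataFrame, path: str) -> None:
    """Scatter of fraction attributed vs stability, one point per config-year."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    sub = table.dropna(subset=["stability"])
    ax.scatter(sub["fraction_attributed"], sub["stability"], s=30)
    for _, r in sub.iterrows():
        ax.annotate(str(r["label"]), (r["fraction_attributed"], r["stability"]), fontsize=5)
    ax.set_xlabel("fraction attributed")
    ax.set_ylabel("attribution stability")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
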