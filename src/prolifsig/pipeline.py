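"""End-to-end orchestration: filtering -> ranking -> screen -> strata -> outcomes.

`run_full_analysis` ties the stages together and writes a report bundle:
a ranked screen table, a stratum table, contingency comparisons of
disease-control rates, tidy Kaplan-Meier curves with log-rank tests, the
multivariate logistic fit with its sequential deviance table, single-gene
accuracy, and a JSON manifest recording the seed, thresholds, patient
counts at every filter step and any analysis warnings — every number in
the report is re-derivable by calling the module functions with the
manifest's recorded thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import pandas as pd

from . import __version__
from .cohort import (classify_cohort, disposition_counts, evaluable_for_response,
                     read_clinical, split_by_institution)
from .config import DEFAULT_THRESHOLDS, Thresholds
from .gene_sets import read_gmt, validate_catalog
from .outcomes import dc_contingency, fit_dc_logistic, km_estimate, logrank_test
from .ranking import ReferencePopulation, read_expression
from .screen import screen_categories, screen_table
from .stratify import assign_strata, single_gene_accuracy


@dataclass
class RunConfig:
    """Inputs, thresholds and output location of one pipeline run."""

    clinical_path: Path
    expression_path: Path
    reference_path: Path
    gene_sets_path: Path
    out_dir: Path
    seed: int = 0
    thresholds: Thresholds = DEFAULT_THRESHOLDS
    holm_family: str = "category"

    def validate(self) -> None:
        for name in ("clinical_path", "expression_path", "reference_path",
                     "gene_sets_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p}")
        # Thresholds validates its own ordering at construction


@dataclass
class ReportBundle:
    """In-memory results of a full pipeline run."""

    manifest: Dict
    screen: pd.DataFrame
    strata: pd.DataFrame
    contingency: pd.DataFrame
    km_curves: pd.DataFrame
    logrank: pd.DataFrame
    coefficients: pd.DataFrame
    deviance: pd.DataFrame
    accuracy: pd.DataFrame


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Execute every stage and write the report bundle under ``out_dir``."""
    config.validate()
    thr = config.thresholds
    warnings_log: List[str] = []

    clinical = read_clinical(config.clinical_path)
    expr = read_expression(config.expression_path)
    ref_expr = read_expression(config.reference_path)
    catalog = read_gmt(config.gene_sets_path)
    validate_catalog(catalog)
    reference = ReferencePopulation(ref_expr)

    labels = classify_cohort(clinical, thr)
    counts = disposition_counts(clinical, thr)
    evaluable = evaluable_for_response(clinical, thr)
    survival_set = clinical.loc[
        ~labels.reindex(clinical["patient_id"]).isin(
            ["excluded_early_death", "excluded_insufficient_followup"]
        ).to_numpy()
    ]

    try:
        split = split_by_institution(evaluable)
        counts["n_training"] = split.n_training
        counts["n_test"] = split.n_test
        counts["test_institution"] = split.test_institution
    except ValueError as exc:
        warnings_log.append(f"split_by_institution: {exc}")

    ranks = reference.rank_samples(expr)
    eval_labels = labels[labels.isin(["DC", "NDC"])]
    screen_res = screen_categories(ranks, eval_labels, catalog, thr,
                                   holm_family=config.holm_family)
    screen_df = screen_table(screen_res)
    for r in screen_res:
        if r.excluded:
            warnings_log.append(f"screen: {r.category} excluded ({r.exclusion_reason})")

    strata_surv = assign_strata(ranks, survival_set, reference, thr)
    strata = strata_surv.merge(
        labels.rename("response_label"), left_on="patient_id", right_index=True)

    contingency_df = _contingency_report(strata, warnings_log)
    km_df, logrank_df = _survival_report(strata_surv, survival_set, thr, warnings_log)

    ev = strata[strata["response_label"].isin(["DC", "NDC"])].merge(
        clinical, on="patient_id")
    model_df = pd.DataFrame({
        "dc": (ev["response_label"] == "DC").astype(int),
        "proliferation": (ev["proliferation"] == "moderately"),
        "pd_l1": ev["pd_l1"].isin(["weak_positive", "strong_positive"]),
        "histology": ev["histology"],
        "race": ev["race"],
        "sex": ev["sex"],
        "age_category": ev["age_category"],
    })
    fit = fit_dc_logistic(model_df)
    if fit.separation_detected:
        warnings_log.append(
            f"logistic: separation suspected for {fit.separation_terms}")

    accuracy = single_gene_accuracy(ranks, eval_labels, reference, thr)

    manifest = {
        "package": "prolifsig",
        "version": __version__,
        "seed": config.seed,
        "thresholds": thr.to_dict(),
        "holm_family": config.holm_family,
        "disposition": counts,
        "null_deviance": fit.null_deviance,
        "residual_deviance": fit.residual_deviance,
        "warnings": warnings_log,
    }

    bundle = ReportBundle(
        manifest=manifest, screen=screen_df, strata=strata,
        contingency=contingency_df, km_curves=km_df, logrank=logrank_df,
        coefficients=fit.coefficients, deviance=fit.deviance_table,
        accuracy=accuracy,
    )
    _write_bundle(bundle, Path(config.out_dir))
    return bundle


def _contingency_report(strata: pd.DataFrame,
                        warnings_log: List[str]) -> pd.DataFrame:
    s = strata[strata["response_label"].isin(["DC", "NDC"])].copy()
    s["dc"] = s["response_label"] == "DC"
    mod = s["proliferation"] == "moderately"
    strong = s["pd_l1"] == "strong_positive"
    pos = s["pd_l1"].isin(["weak_positive", "strong_positive"])
    known = s["pd_l1"] != "missing"

    comparisons = [
        ("moderately_vs_extremes", mod, ~mod, None),
        ("strong_vs_not_strong", strong & known, ~strong & known, None),
        ("positive_vs_negative", pos & known, ~pos & known, None),
        ("moderately_vs_extremes_strong", mod, ~mod, strong),
        ("moderately_vs_extremes_not_strong", mod, ~mod, ~strong & known),
        ("moderately_vs_highly_not_strong", mod,
         s["proliferation"] == "highly", ~strong & known),
        ("moderately_vs_poorly_not_strong", mod,
         s["proliferation"] == "poorly", ~strong & known),
        ("cold15_moderately_vs_extremes", mod, ~mod, s["cold_15"]),
        ("cold33_moderately_vs_extremes", mod, ~mod, s["cold_33"]),
    ]
    rows = []
    for name, a_mask, b_mask, within in comparisons:
        a = s[a_mask if within is None else (a_mask & within)]
        b = s[b_mask if within is None else (b_mask & within)]
        if a.empty or b.empty:
            warnings_log.append(f"contingency: {name} skipped (empty group)")
            continue
        res = dc_contingency({
            "A": (int(a["dc"].sum()), int((~a["dc"]).sum())),
            "B": (int(b["dc"].sum()), int((~b["dc"]).sum())),
        })
        rows.append({
            "comparison": name,
            "dc_a": res.dc[0], "ndc_a": res.ndc[0], "rate_a": res.dc_rates[0],
            "dc_b": res.dc[1], "ndc_b": res.ndc[1], "rate_b": res.dc_rates[1],
            "statistic": res.statistic, "p_value": res.p_value,
        })
    return pd.DataFrame(rows)


def _survival_report(strata: pd.DataFrame, survival_set: pd.DataFrame,
                     thr: Thresholds,
                     warnings_log: List[str]) -> Tuple[pd.DataFrame, pd.DataFrame]:
    merged = survival_set.merge(strata, on="patient_id")
    mod = merged["proliferation"] == "moderately"
    strong = merged["pd_l1"] == "strong_positive"
    groups = {
        "moderately": mod,
        "poorly_highly": ~mod,
        "moderately_strong": mod & strong,
        "moderately_not_strong": mod & ~strong,
        "poorly_highly_strong": ~mod & strong,
        "poorly_highly_not_strong": ~mod & ~strong,
    }
    km_rows = []
    for name, mask in groups.items():
        sub = merged[mask]
        if sub.empty:
            warnings_log.append(f"km: stratum {name} empty")
            continue
        curve = km_estimate(sub["survival_months"],
                            sub["vital_status"] == "dead", thr.km_horizon_months)
        frame = curve.to_frame()
        frame.insert(0, "stratum", name)
        frame["median"] = curve.median
        km_rows.append(frame)
    km_df = pd.concat(km_rows, ignore_index=True) if km_rows else pd.DataFrame()

    pairs = [
        ("moderately_vs_extremes", "moderately", "poorly_highly"),
        ("mod_strong_vs_extremes_not_strong",
         "moderately_strong", "poorly_highly_not_strong"),
        ("mod_not_strong_vs_extremes_strong",
         "moderately_not_strong", "poorly_highly_strong"),
    ]
    lr_rows = []
    for name, ga, gb in pairs:
        a, b = merged[groups[ga]], merged[groups[gb]]
        if a.empty or b.empty:
            warnings_log.append(f"logrank: {name} skipped (empty group)")
            continue
        stat, p = logrank_test(a["survival_months"], a["vital_status"] == "dead",
                               b["survival_months"], b["vital_status"] == "dead",
                               thr.km_horizon_months)
        lr_rows.append({"comparison": name, "n_a": len(a), "n_b": len(b),
                        "statistic": stat, "p_value": p})
    return km_df, pd.DataFrame(lr_rows)


def _write_bundle(bundle: ReportBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.screen.to_csv(out_dir / "screen.csv", index=False)
    bundle.strata.to_csv(out_dir / "strata.csv", index=False)
    bundle.contingency.to_csv(out_dir / "contingency.csv", index=False)
    bundle.km_curves.to_csv(out_dir / "km_curves.csv", index=False)
    bundle.logrank.to_csv(out_dir / "logrank.csv", index=False)
    bundle.coefficients.to_csv(out_dir / "coefficients.csv", index=False)
    bundle.deviance.to_csv(out_dir / "deviance.csv", index=False)
    bundle.accuracy.to_csv(out_dir / "accuracy.csv", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, default=str)
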