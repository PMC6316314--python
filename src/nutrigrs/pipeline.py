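"""End-to-end study orchestration.

Takes validated genotype, curve, clinical and anthropometry tables,
scores subjects, splits them at the median weighted genetic risk score,
derives the metabolic index panel per subject-visit, and produces three
report tables:

* a baseline-characteristics table (continuous variables compared by
  unpaired t test, categorical by Pearson chi-square, genotype blocks by
  2x3 chi-square, plus pooled Hardy-Weinberg tests per locus);
* a metabolic-outcomes table (per-visit ANCOVA-adjusted group means with
  standard errors and the between-group p, plus within-group
  post-minus-baseline paired-t mean differences with 95% CIs);
* a diet / body-composition / activity table with its own covariate set.

Covariate families are config-driven; the defaults mirror a typical
nutrigenetic intervention analysis (age, sex, BMI, family history,
energy intake, activity energy expenditure, and total cholesterol for
metabolic outcomes; the glucose area swapped in for cholesterol when the
outcome itself is a lipid or blood pressure). All statistics are kept at
full precision in a machine-readable dict; rounding happens only when
formatting the report tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import indices as idx
from . import stattests as st
from .grs import (
    HIGH_GROUP,
    LOW_GROUP,
    assign_groups,
    genotype_counts,
    hwe_chi_square,
    score_cohort,
)
from .panel import Panel
from .simulate import BASELINE, INTERVENTION, VISITS

log = logging.getLogger(__name__)

#: Outcomes drawn from the clinical table and index panel (metabolic family).
METABOLIC_OUTCOMES = [
    "fpg", "fsi",
    "auc_glu_0_30", "auc_glu_30_120", "auc_glu_0_120",
    "auc_ins_0_30", "auc_ins_30_120", "auc_ins_0_120",
    "hba1c", "homa_ir", "homa_beta", "reciprocal_fsi",
    "igi", "inc_auc_ins_glu", "oral_di",
]
LIPID_BP_OUTCOMES = ["tc", "hdl_c", "ldl_c", "tg", "sbp", "dbp"]
DIET_ANTHRO_OUTCOMES = [
    "energy_kcal", "protein_g", "fat_g", "carbohydrate_g", "calcium_mg",
    "weight_kg", "skeletal_muscle_mass_kg", "body_fat_mass_kg",
    "waist_cm", "paee",
]


@dataclass
class AnalysisConfig:
    auc_mode: str = "incremental"
    variance_mode: str = "pooled"
    covariates_metabolic: list[str] = field(default_factory=lambda: [
        "age", "sex", "bmi", "family_history", "energy_kcal", "paee", "tc",
    ])
    covariates_lipid_bp: list[str] = field(default_factory=lambda: [
        "age", "sex", "bmi", "family_history", "energy_kcal", "paee",
        "auc_glu_0_120",
    ])
    covariates_diet_anthro: list[str] = field(default_factory=lambda: [
        "age", "sex", "family_history",
    ])
    decimals: int = 2


@dataclass
class StudyDataset:
    genotypes: pd.DataFrame
    curves: pd.DataFrame
    clinical: pd.DataFrame
    anthro: pd.DataFrame
    panel: Panel
    diagnostics: list[str] = field(default_factory=list)


@dataclass
class StudyResult:
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    scores: pd.DataFrame
    index_panel: pd.DataFrame
    stats: dict


class ValidationError(ValueError):
    """Dataset fails schema or consistency checks; carries diagnostics."""

    def __init__(self, diagnostics: list[str]):
        self.diagnostics = diagnostics
        super().__init__("dataset validation failed:\n" + "\n".join(diagnostics))


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (report-table convention)."""
    if not math.isfinite(x):
        return x
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def validate_dataset(
    genotypes: pd.DataFrame,
    curves: pd.DataFrame,
    clinical: pd.DataFrame,
    anthro: pd.DataFrame,
    panel: Panel,
) -> StudyDataset:
    """Schema, range and cross-table consistency checks; per-protocol trim.

    Hard failures (malformed schema, out-of-range measurements, a curve
    without its fasting sample) raise :class:`ValidationError` with
    per-row diagnostics. Subjects missing from any required table are
    excluded with a logged diagnostic and analysis proceeds on the
    remainder.
    """
    errors: list[str] = []
    diagnostics: list[str] = []
    for name, df, cols in (
        ("genotypes", genotypes, {"subject_id", "rsid", "allele1", "allele2"}),
        ("curves", curves, {"subject_id", "visit", "analyte", "time_min", "value"}),
        ("clinical", clinical, {"subject_id", "visit", "fpg", "fsi"}),
        ("anthro", anthro, {"subject_id", "visit", "weight_kg", "height_m"}),
    ):
        missing = cols - set(df.columns)
        if missing:
            errors.append(f"{name}: missing columns {sorted(missing)}")
    if errors:
        raise ValidationError(errors)

    glu = curves[curves["analyte"] == "glucose"]
    bad = glu[(glu["value"] < 30) | (glu["value"] > 400)]
    for r in bad.itertuples():
        errors.append(
            f"curves: subject {r.subject_id} {r.visit} glucose {r.value} mg/dL "
            f"at t={r.time_min} outside sanity range 30-400"
        )
    ins = curves[curves["analyte"] == "insulin"]
    bad = ins[(ins["value"] < 0) | (ins["value"] > 300)]
    for r in bad.itertuples():
        errors.append(
            f"curves: subject {r.subject_id} {r.visit} insulin {r.value} "
            f"at t={r.time_min} outside sanity range 0-300"
        )
    for (sid, visit, analyte), sub in curves.groupby(
        ["subject_id", "visit", "analyte"]
    ):
        times = set(sub["time_min"])
        for needed in (0.0, 30.0, 120.0):
            if needed not in times:
                errors.append(
                    f"curves: subject {sid} {visit} {analyte} curve lacks the "
                    f"t={needed:g} min sample"
                )
    if errors:
        raise ValidationError(errors)

    subject_sets = {
        "genotypes": set(genotypes["subject_id"].astype(str)),
        "curves": set(curves["subject_id"].astype(str)),
        "clinical": set(clinical["subject_id"].astype(str)),
        "anthro": set(anthro["subject_id"].astype(str)),
    }
    complete = set.intersection(*subject_sets.values())
    for name, ids in subject_sets.items():
        for sid in sorted(ids - complete):
            diagnostics.append(
                f"subject {sid} present in {name} but not all tables; "
                "excluded per-protocol"
            )
    def trim(df: pd.DataFrame) -> pd.DataFrame:
        return df[df["subject_id"].astype(str).isin(complete)].reset_index(drop=True)

    for d in diagnostics:
        log.warning("%s", d)
    return StudyDataset(
        genotypes=trim(genotypes),
        curves=trim(curves),
        clinical=trim(clinical),
        anthro=trim(anthro),
        panel=panel,
        diagnostics=diagnostics,
    )


def _covariate_frame(
    merged: pd.DataFrame, names: list[str]
) -> pd.DataFrame:
    missing = [c for c in names if c not in merged.columns]
    if missing:
        raise ValueError(f"covariates not found in dataset: {missing}")
    return merged[names].astype(float)


def _comparison_row(
    outcome: str,
    merged: pd.DataFrame,
    covariate_names: list[str],
    variance_mode: str,
) -> dict:
    """Build one report row: per-visit adjusted means + within-group paired t."""
    row: dict = {"outcome": outcome}
    for visit in VISITS:
        sub = merged[merged["visit"] == visit]
        y = sub[outcome].to_numpy(dtype=float)
        try:
            res = st.ancova_adjusted_means(
                y, sub["group"].to_numpy(), _covariate_frame(sub, covariate_names)
            )
            row[f"{visit}_mean_L"] = res.adjusted_means[LOW_GROUP]
            row[f"{visit}_se_L"] = res.standard_errors[LOW_GROUP]
            row[f"{visit}_mean_H"] = res.adjusted_means[HIGH_GROUP]
            row[f"{visit}_se_H"] = res.standard_errors[HIGH_GROUP]
            row[f"{visit}_p_between"] = res.p_value
        except ValueError as exc:
            log.warning("ANCOVA failed for %s at %s: %s", outcome, visit, exc)
            for k in ("mean_L", "se_L", "mean_H", "se_H", "p_between"):
                row[f"{visit}_{k}"] = float("nan")
    wide = merged.pivot_table(
        index=["subject_id", "group"], columns="visit", values=outcome,
        aggfunc="first",
    ).reset_index()
    for group, tag in ((LOW_GROUP, "L"), (HIGH_GROUP, "H")):
        sub = wide[wide["group"] == group]
        diffs = (sub[INTERVENTION] - sub[BASELINE]).to_numpy(dtype=float)
        diffs = diffs[~np.isnan(diffs)]
        if diffs.size >= 2:
            t = st.paired_t(diffs)
            row[f"diff_{tag}"] = t.estimate
            row[f"diff_{tag}_ci_low"] = t.ci_low
            row[f"diff_{tag}_ci_high"] = t.ci_high
            row[f"diff_{tag}_p"] = t.p_value
        else:
            for k in ("", "_ci_low", "_ci_high", "_p"):
                row[f"diff_{tag}{k}"] = float("nan")
    return row


def run_study(
    dataset: StudyDataset, config: AnalysisConfig | None = None
) -> StudyResult:
    """Score, split, derive indices, and build the three report tables."""
    config = config or AnalysisConfig()
    scores = assign_groups(score_cohort(dataset.genotypes, dataset.panel))
    cutoff = scores.attrs["cutoff"]
    panel_idx = idx.compute_indices(
        dataset.curves, dataset.clinical, auc_mode=config.auc_mode
    )

    anthro = dataset.anthro.copy()
    anthro["bmi"] = [
        idx.bmi(w, h) for w, h in zip(anthro["weight_kg"], anthro["height_m"])
    ]
    anthro["paee"] = [
        idx.paee(m, w) for m, w in zip(anthro["met_minutes"], anthro["weight_kg"])
    ] if "met_minutes" in anthro.columns else np.nan

    merged = (
        panel_idx.merge(dataset.clinical, on=["subject_id", "visit"], how="inner")
        .merge(anthro, on=["subject_id", "visit"], how="inner")
        .merge(scores[["subject_id", "grs", "weighted_grs", "group"]],
               on="subject_id", how="inner")
    )

    table1, table1_stats = _baseline_table(dataset, scores, merged)
    rows2 = [
        _comparison_row(
            outcome, merged,
            config.covariates_lipid_bp if outcome in LIPID_BP_OUTCOMES
            else config.covariates_metabolic,
            config.variance_mode,
        )
        for outcome in METABOLIC_OUTCOMES + LIPID_BP_OUTCOMES
        if outcome in merged.columns
    ]
    rows3 = [
        _comparison_row(outcome, merged, config.covariates_diet_anthro,
                        config.variance_mode)
        for outcome in DIET_ANTHRO_OUTCOMES
        if outcome in merged.columns
    ]
    table2 = pd.DataFrame(rows2)
    table3 = pd.DataFrame(rows3)
    n_tests = (
        sum(1 for r in rows2 + rows3 for k in r
            if k.endswith("_p") or k.endswith("p_between"))
        + len(table1_stats.get("p_values", {}))
    )
    stats = {
        "cutoff": float(cutoff),
        "n_subjects": int(scores.shape[0]),
        "group_sizes": scores["group"].value_counts().to_dict(),
        "n_tests_performed": int(n_tests),
        "multiple_testing_adjustment": "none",
        "table1": table1_stats,
        "table2": table2.to_dict(orient="records"),
        "table3": table3.to_dict(orient="records"),
        "diagnostics": dataset.diagnostics,
    }
    return StudyResult(
        table1=table1, table2=table2, table3=table3,
        scores=scores, index_panel=panel_idx, stats=stats,
    )


def _baseline_table(
    dataset: StudyDataset, scores: pd.DataFrame, merged: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Baseline characteristics by risk group, with genotype and HWE blocks."""
    base = merged[merged["visit"] == BASELINE]
    low = base[base["group"] == LOW_GROUP]
    high = base[base["group"] == HIGH_GROUP]
    rows = []
    p_values: dict[str, float] = {}

    continuous = [c for c in ("age", "height_m", "weight_kg", "bmi",
                              "skeletal_muscle_mass_kg", "body_fat_mass_kg",
                              "waist_cm") if c in base.columns]
    for var in continuous:
        a = low[var].to_numpy(dtype=float)
        b = high[var].to_numpy(dtype=float)
        t = st.unpaired_t(a, b)
        rows.append({
            "variable": var, "L_mean": float(np.nanmean(a)),
            "L_sd": float(np.nanstd(a, ddof=1)),
            "H_mean": float(np.nanmean(b)), "H_sd": float(np.nanstd(b, ddof=1)),
            "p_value": t.p_value, "test": "unpaired t",
        })
        p_values[var] = t.p_value
    for var in ("sex", "family_history"):
        if var not in base.columns:
            continue
        tab = np.array([
            [int((low[var] == 1).sum()), int((low[var] == 0).sum())],
            [int((high[var] == 1).sum()), int((high[var] == 0).sum())],
        ])
        try:
            chi = st.pearson_chi_square(tab)
            p = chi.p_value
        except ValueError:
            p = float("nan")
        rows.append({
            "variable": var,
            "L_mean": float((low[var] == 1).mean() * 100),
            "L_sd": float("nan"),
            "H_mean": float((high[var] == 1).mean() * 100),
            "H_sd": float("nan"),
            "p_value": p, "test": "chi-square (%)",
        })
        p_values[var] = p

    for var in ("grs", "weighted_grs"):
        a = low[var].to_numpy(dtype=float)
        b = high[var].to_numpy(dtype=float)
        t = st.unpaired_t(a, b)
        rows.append({
            "variable": var, "L_mean": float(a.mean()), "L_sd": float(a.std(ddof=1)),
            "H_mean": float(b.mean()), "H_sd": float(b.std(ddof=1)),
            "p_value": t.p_value, "test": "unpaired t",
        })
        p_values[var] = t.p_value

    genotype_block = {}
    hwe_block = {}
    low_ids = set(scores.loc[scores["group"] == LOW_GROUP, "subject_id"])
    for snp in dataset.panel:
        g = dataset.genotypes
        counts_low = genotype_counts(
            g[g["subject_id"].isin(low_ids)], snp, LOW_GROUP
        )
        counts_high = genotype_counts(
            g[~g["subject_id"].isin(low_ids)], snp, HIGH_GROUP
        )
        pooled = genotype_counts(g, snp)
        table = np.array([counts_low.counts, counts_high.counts])
        try:
            chi = st.pearson_chi_square(table[:, table.sum(axis=0) > 0])
            p_geno = chi.p_value
        except ValueError as exc:
            log.warning("genotype chi-square failed for %s: %s", snp.rsid, exc)
            p_geno = float("nan")
        hwe = hwe_chi_square(pooled)
        genotype_block[snp.rsid] = {
            "L_counts": counts_low.counts, "H_counts": counts_high.counts,
            "p_value": p_geno,
        }
        hwe_block[snp.rsid] = {"chi2": hwe.chi2, "p_value": hwe.p_value}
        p_values[f"genotype_{snp.rsid}"] = p_geno
        rows.append({
            "variable": f"genotype {snp.rsid}",
            "L_mean": float("nan"), "L_sd": float("nan"),
            "H_mean": float("nan"), "H_sd": float("nan"),
            "p_value": p_geno, "test": "chi-square 2x3",
        })
    table1 = pd.DataFrame(rows)
    stats = {
        "p_values": p_values,
        "genotype_counts": genotype_block,
        "hwe": hwe_block,
        "group_sizes": {LOW_GROUP: int(low.shape[0]), HIGH_GROUP: int(high.shape[0])},
    }
    return table1, stats


def format_table(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Presentation-layer rounding (half away from zero) of numeric columns."""
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda x: round_half_away(x, decimals))
    return out
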