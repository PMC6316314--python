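"""Synthetic study-shaped cohorts with known ground truth.

Emulates a small single-arm nutrition-intervention design: genotypes at
five biallelic type-2-diabetes susceptibility loci drawn under
Hardy-Weinberg equilibrium, postprandial glucose/insulin curves at a
baseline and a post-intervention visit whose shapes depend on the
subject's weighted genetic risk score, and per-visit clinical,
anthropometry, diet and activity records.

The curve model is deliberately simple so that trapezoid-rule oracles
are exact: each analyte is a fasting level plus a unimodal
piecewise-linear bump peaking at a configurable time (default 30 min)
and returning to baseline at 120 min. The bump amplitude scales
log-normally between subjects, multiplicatively with the centered
weighted risk score for glucose (higher score, larger glycemic
excursion) and with an attenuation factor for insulin (higher score,
weaker early insulin response). The intervention multiplies the glucose
amplitude by a configured ratio — by default only in subjects in the
upper half of the weighted-score distribution — and shifts their fasting
insulin. Latent (noise-free) per-subject areas are retained so parameter
recovery is testable.

Default parameter values reproduce the shape of the motivating cohort:
32 subjects, risk-allele frequencies matching its pooled genotype
counts, a roughly 800 mg/dL.min baseline incremental-glucose-AUC gap
between high and low risk groups, and a 21% post-intervention reduction
of that area in the high-risk group. Odds ratios in the default panel
are synthetic placeholders on a realistic scale (1.15-1.30 per allele).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grs import HIGH_GROUP, LOW_GROUP, score_cohort
from .panel import Panel, SnpDefinition

BASELINE = "baseline"
INTERVENTION = "intervention"
VISITS = (BASELINE, INTERVENTION)

#: Synthetic five-locus panel. Loci and alleles follow the published
#: susceptibility variants; the odds ratios are invented placeholders
#: (the source study used published ORs it did not print).
SYNTHETIC_PANEL: Panel = [
    SnpDefinition("rs2237892", "C", "T", 1.26),   # KCNQ1
    SnpDefinition("rs2206734", "T", "C", 1.19),   # CDKAL1
    SnpDefinition("rs2383208", "A", "G", 1.20),   # CDKN2B
    SnpDefinition("rs6780569", "G", "A", 1.16),   # UBE2E2
    SnpDefinition("rs1470579", "C", "A", 1.23),   # IGF2BP2
]

#: Risk-allele frequencies matching the motivating cohort's pooled
#: genotype counts (n = 32, 64 chromosomes per locus).
DEFAULT_RISK_FREQS: dict[str, float] = {
    "rs2237892": 38 / 64,
    "rs2206734": 28 / 64,
    "rs2383208": 38 / 64,
    "rs6780569": 54 / 64,
    "rs1470579": 26 / 64,
}


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort, with study-shaped defaults."""

    n_subjects: int = 32
    seed: int = 0
    panel: Panel = field(default_factory=lambda: list(SYNTHETIC_PANEL))
    risk_allele_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RISK_FREQS)
    )
    grid: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0)
    peak_time: float = 30.0
    # fasting levels
    fasting_glucose_mean: float = 81.0   # mg/dL
    fasting_glucose_sd: float = 6.0
    fasting_insulin_mean: float = 5.4    # study insulin units
    fasting_insulin_sd: float = 1.5
    # latent incremental AUC model
    glucose_auc_mean: float = 1750.0     # mg/dL.min over 0-120
    insulin_auc_mean: float = 360.0
    beta_glucose: float = 1.0            # per weighted-GRS unit
    beta_insulin: float = 2.0            # attenuation per weighted-GRS unit
    insulin_attenuation_floor: float = 0.05
    subject_sd_log: float = 0.35         # between-subject log-amplitude SD
    # measurement noise on curve values
    noise_glucose_sd: float = 4.0        # mg/dL
    noise_insulin_sd: float = 1.0
    # visit-to-visit wobble of the fasting state
    fasting_glucose_visit_sd: float = 2.5
    fasting_insulin_visit_sd: float = 0.6
    # intervention effects
    intervention_auc_ratio: float = 0.79     # multiplies glucose amplitude
    concentrated_in_high: bool = True
    intervention_fsi_shift: float = -1.55    # additive, high group

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for snp in self.panel:
            f = self.risk_allele_freqs.get(snp.rsid)
            if f is None or not (0.0 < f < 1.0):
                raise ValueError(
                    f"{snp.rsid}: risk-allele frequency must lie in (0, 1), got {f}"
                )
        grid = np.asarray(self.grid, dtype=float)
        if grid[0] != 0.0 or 30.0 not in grid or 120.0 not in grid:
            raise ValueError("grid must start at 0 and include 30 and 120 min")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.peak_time not in grid:
            raise ValueError("peak_time must be a grid point")
        if not (0.0 < self.peak_time < grid[-1]):
            raise ValueError("peak_time must be interior to the grid")
        for name in ("fasting_glucose_sd", "fasting_insulin_sd", "subject_sd_log",
                     "noise_glucose_sd", "noise_insulin_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.glucose_auc_mean <= 0 or self.insulin_auc_mean <= 0:
            raise ValueError("latent AUC means must be positive")
        if self.intervention_auc_ratio < 0:
            raise ValueError("intervention_auc_ratio must be >= 0")


@dataclass
class SimulatedCohort:
    """In-memory synthetic dataset plus its ground truth."""

    genotypes: pd.DataFrame     # subject_id, rsid, allele1, allele2
    curves: pd.DataFrame        # subject_id, visit, analyte, time_min, value
    clinical: pd.DataFrame      # subject_id, visit, fpg, fsi, lipids, ...
    anthro: pd.DataFrame        # subject_id, visit, covariates and diet
    scores: pd.DataFrame        # subject_id, grs, weighted_grs, group
    ground_truth: dict


def _bump_shape(grid: np.ndarray, peak_time: float) -> np.ndarray:
    """Unit piecewise-linear bump: 0 at t=0, 1 at the peak, 0 at the end."""
    up = grid <= peak_time
    shape = np.empty_like(grid)
    shape[up] = grid[up] / peak_time
    shape[~up] = (grid[-1] - grid[~up]) / (grid[-1] - peak_time)
    return shape


def sample_genotypes(
    config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw per-subject genotypes independently per locus under HWE.

    Genotype probabilities at each locus are (p^2, 2pq, q^2) for the
    configured risk-allele frequency p.
    """
    config.validate()
    n = config.n_subjects
    subject_ids = [f"S{i + 1:03d}" for i in range(n)]
    records = []
    for snp in config.panel:
        p = config.risk_allele_freqs[snp.rsid]
        probs = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
        dosage = rng.choice([2, 1, 0], size=n, p=probs)
        for sid, d in zip(subject_ids, dosage):
            a1 = snp.risk_allele if d >= 1 else snp.other_allele
            a2 = snp.risk_allele if d == 2 else snp.other_allele
            records.append((sid, snp.rsid, a1, a2))
    return pd.DataFrame(
        records, columns=["subject_id", "rsid", "allele1", "allele2"]
    ).sort_values(["subject_id", "rsid"], ignore_index=True)


def simulate_cohort(config: CohortConfig | None = None) -> SimulatedCohort:
    """Generate a complete two-visit synthetic cohort.

    A single RNG stream seeded from ``config.seed`` drives everything,
    so identical configs give bit-identical datasets.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    grid = np.asarray(config.grid, dtype=float)
    shape = _bump_shape(grid, config.peak_time)
    shape_area = float(np.trapezoid(shape, grid))  # minutes of unit bump

    genotypes = sample_genotypes(config, rng)
    scores = score_cohort(genotypes, config.panel)
    wgrs = scores["weighted_grs"].to_numpy()
    centered = wgrs - wgrs.mean()
    cutoff = float(np.median(wgrs))
    high = wgrs > cutoff
    scores = scores.assign(group=np.where(high, HIGH_GROUP, LOW_GROUP))
    scores.attrs["cutoff"] = cutoff
    subject_ids = scores["subject_id"].tolist()

    # latent per-subject incremental AUCs (visit-independent genetics,
    # log-normal between-subject heterogeneity)
    eta_g = rng.normal(0.0, config.subject_sd_log, n)
    eta_i = rng.normal(0.0, config.subject_sd_log, n)
    glu_gene = np.maximum(1.0 + config.beta_glucose * centered, 0.05)
    ins_gene = np.maximum(
        1.0 - config.beta_insulin * centered, config.insulin_attenuation_floor
    )
    latent_glu = config.glucose_auc_mean * glu_gene * np.exp(eta_g)
    latent_ins = config.insulin_auc_mean * ins_gene * np.exp(eta_i)

    fpg = np.maximum(rng.normal(config.fasting_glucose_mean,
                                config.fasting_glucose_sd, n), 50.0)
    fsi = np.maximum(rng.normal(config.fasting_insulin_mean,
                                config.fasting_insulin_sd, n), 0.5)

    affected = high if config.concentrated_in_high else np.ones(n, bool)
    curve_rows: list[tuple] = []
    clinical_rows: list[dict] = []
    latent_auc: dict[str, dict[str, dict[str, float]]] = {}
    for i, sid in enumerate(subject_ids):
        latent_auc[sid] = {}
        for visit in VISITS:
            ratio = (
                config.intervention_auc_ratio
                if visit == INTERVENTION and affected[i]
                else 1.0
            )
            fpg_v = max(
                fpg[i] + rng.normal(0.0, config.fasting_glucose_visit_sd), 50.0
            )
            fsi_v = max(
                fsi[i] + rng.normal(0.0, config.fasting_insulin_visit_sd), 0.3
            )
            if visit == INTERVENTION and affected[i]:
                fsi_v = max(fsi_v + config.intervention_fsi_shift, 0.3)
            amp_g = latent_glu[i] * ratio / shape_area
            amp_i = latent_ins[i] / shape_area
            glu_mean = fpg_v + amp_g * shape
            ins_mean = fsi_v + amp_i * shape
            glu_obs = glu_mean + rng.normal(0.0, config.noise_glucose_sd, grid.size)
            ins_obs = ins_mean + rng.normal(0.0, config.noise_insulin_sd, grid.size)
            glu_obs[0], ins_obs[0] = fpg_v, fsi_v  # fasting draw is the t=0 sample
            glu_obs = np.maximum(glu_obs, 0.0)
            ins_obs = np.maximum(ins_obs, 0.0)
            for t, gv, iv in zip(grid, glu_obs, ins_obs):
                curve_rows.append((sid, visit, "glucose", float(t), float(gv)))
                curve_rows.append((sid, visit, "insulin", float(t), float(iv)))
            latent_auc[sid][visit] = {
                "glucose_inc_auc": float(latent_glu[i] * ratio),
                "insulin_inc_auc": float(latent_ins[i]),
            }
            clinical_rows.append(
                _clinical_record(rng, sid, visit, fpg_v, fsi_v)
            )

    anthro = _anthro_records(rng, subject_ids)
    truth = {
        "seed": config.seed,
        "cutoff": cutoff,
        "config": _config_echo(config),
        "group": {sid: (HIGH_GROUP if h else LOW_GROUP)
                  for sid, h in zip(subject_ids, high)},
        "latent_auc": latent_auc,
    }
    return SimulatedCohort(
        genotypes=genotypes,
        curves=pd.DataFrame(
            curve_rows,
            columns=["subject_id", "visit", "analyte", "time_min", "value"],
        ),
        clinical=pd.DataFrame(clinical_rows),
        anthro=anthro,
        scores=scores,
        ground_truth=truth,
    )


def _clinical_record(
    rng: np.random.Generator, sid: str, visit: str, fpg: float, fsi: float
) -> dict:
    tg = max(rng.normal(67.0, 25.0), 20.0)
    hdl = max(rng.normal(68.0, 10.0), 30.0)
    ldl = max(rng.normal(104.0, 20.0), 40.0)
    shift = -9.0 if visit == INTERVENTION else 0.0
    tc = ldl + hdl + tg / 5.0 + shift  # Friedewald closure
    return {
        "subject_id": sid,
        "visit": visit,
        "fpg": round(fpg, 2),
        "fsi": round(fsi, 3),
        "tc": round(tc, 1),
        "hdl_c": round(hdl, 1),
        "ldl_c": round(ldl + shift, 1),
        "tg": round(tg, 1),
        "hba1c": round(float(np.clip(rng.normal(5.1, 0.15), 4.5, 6.0)), 2),
        "sbp": round(rng.normal(97.0, 8.0), 1),
        "dbp": round(rng.normal(53.0, 6.0), 1),
    }


def _anthro_records(rng: np.random.Generator, subject_ids: list[str]) -> pd.DataFrame:
    n = len(subject_ids)
    sex = (rng.random(n) < 0.094).astype(int)  # 1 = male, cohort ~9% male
    age = rng.integers(20, 24, n)
    fam = (rng.random(n) < 0.344).astype(int)
    height = np.clip(rng.normal(1.61, 0.06, n), 1.45, 1.90)
    weight0 = np.clip(rng.normal(54.0, 9.0, n), 38.0, 95.0)
    met = np.maximum(rng.normal(430.0, 150.0, n), 0.0)
    energy0 = np.maximum(rng.normal(1550.0, 300.0, n), 800.0)
    rows = []
    for visit in VISITS:
        post = visit == INTERVENTION
        weight = weight0 - (0.6 if post else 0.0) + rng.normal(0.0, 0.3, n)
        energy = energy0 + (150.0 if post else 0.0) + rng.normal(0.0, 120.0, n)
        calcium0 = np.maximum(rng.normal(340.0, 90.0, n), 100.0)
        for i, sid in enumerate(subject_ids):
            rows.append({
                "subject_id": sid,
                "visit": visit,
                "age": int(age[i]),
                "sex": int(sex[i]),
                "family_history": int(fam[i]),
                "height_m": round(float(height[i]), 3),
                "weight_kg": round(float(weight[i]), 1),
                "skeletal_muscle_mass_kg": round(float(weight[i] * 0.72), 1),
                "body_fat_mass_kg": round(float(weight[i] * 0.25 - (0.9 if post else 0.0)), 1),
                "waist_cm": round(float(weight[i] * 1.35), 1),
                "met_minutes": round(float(met[i]), 1),
                "energy_kcal": round(float(energy[i]), 0),
                "protein_g": round(float(energy[i] * 0.035), 1),
                "fat_g": round(float(energy[i] * 0.031), 1),
                "carbohydrate_g": round(float(energy[i] * 0.133), 0),
                "calcium_mg": round(float(calcium0[i] + (415.0 if post else 0.0)), 0),
            })
    return pd.DataFrame(rows)


def _config_echo(config: CohortConfig) -> dict:
    echo = asdict(config)
    echo["panel"] = [
        {"rsid": s.rsid, "risk_allele": s.risk_allele,
         "other_allele": s.other_allele, "odds_ratio": s.odds_ratio}
        for s in config.panel
    ]
    echo["grid"] = list(config.grid)
    return echo


def generate_cohort(
    config: CohortConfig | None = None, out_dir: str | Path = "."
) -> SimulatedCohort:
    """Simulate a cohort and write its CSV/JSON files to ``out_dir``.

    Emits genotypes.csv, curves.csv, clinical.csv, anthro.csv,
    scores.csv, panel.json and ground_truth.json in exactly the schemas
    the scoring, index and pipeline layers consume.
    """
    from .panel import save_panel

    cohort = simulate_cohort(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.genotypes.to_csv(out / "genotypes.csv", index=False)
    cohort.curves.to_csv(out / "curves.csv", index=False)
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    cohort.anthro.to_csv(out / "anthro.csv", index=False)
    cohort.scores.to_csv(out / "scores.csv", index=False)
    save_panel((config or CohortConfig()).panel, out / "panel.json")
    (out / "ground_truth.json").write_text(
        json.dumps(cohort.ground_truth, indent=2, sort_keys=True) + "\n"
    )
    return cohort
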