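"""Genetic risk score construction and Hardy-Weinberg testing.

Genotypes are recoded to risk-allele dosages (0/1/2 per locus). The
unweighted score is the dosage sum; the weighted score multiplies each
dosage by the natural log of the locus odds ratio. Cohorts are split at
the median weighted score into low (L) and high (H) risk groups, ties
going to the low group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import Panel, SnpDefinition

log = logging.getLogger(__name__)

LOW_GROUP = "L-GRS"
HIGH_GROUP = "H-GRS"


class InvalidGenotypeError(ValueError):
    """An allele call does not match either defined allele at its locus."""


class MissingGenotypeError(ValueError):
    """A subject lacks a call at one or more panel loci."""


@dataclass(frozen=True)
class RiskScoreResult:
    subject_id: str
    grs: int
    weighted_grs: float


@dataclass(frozen=True)
class GenotypeCountTable:
    """Genotype counts at one locus: (hom-risk, het, hom-other)."""

    rsid: str
    n_homozygous_risk: int
    n_heterozygous: int
    n_homozygous_other: int
    group_label: str | None = None

    def __post_init__(self) -> None:
        for c in self.counts:
            if c < 0 or int(c) != c:
                raise ValueError(f"{self.rsid}: counts must be nonnegative integers")

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_homozygous_risk, self.n_heterozygous, self.n_homozygous_other)

    @property
    def n(self) -> int:
        return sum(self.counts)

    @property
    def risk_allele_frequency(self) -> float:
        return (2 * self.n_homozygous_risk + self.n_heterozygous) / (2 * self.n)


@dataclass(frozen=True)
class GroupAssignment:
    subject_id: str
    group: str  # LOW_GROUP or HIGH_GROUP
    cutoff: float


@dataclass(frozen=True)
class HweResult:
    rsid: str
    chi2: float
    p_value: float
    degenerate: bool = False


def risk_allele_dosage(
    genotype: tuple[str, str] | None, snp: SnpDefinition, subject_id: str = "?"
) -> int:
    """Count risk alleles in an unordered allele pair (0, 1, or 2).

    A missing call (``None``) raises :class:`MissingGenotypeError` rather
    than silently contributing zero; an allele outside the locus's two
    defined alleles raises :class:`InvalidGenotypeError`.
    """
    if genotype is None:
        raise MissingGenotypeError(
            f"subject {subject_id}: no genotype call at {snp.rsid}"
        )
    a, b = (allele.strip().upper() for allele in genotype)
    for allele in (a, b):
        if allele not in snp.alleles:
            raise InvalidGenotypeError(
                f"subject {subject_id}: allele {allele!r} at {snp.rsid} is not "
                f"one of {sorted(snp.alleles)}"
            )
    return int(a == snp.risk_allele) + int(b == snp.risk_allele)


def compute_scores(
    dosages: dict[str, int], panel: Panel, subject_id: str = "?"
) -> RiskScoreResult:
    """Unweighted and ln(OR)-weighted risk scores from a complete dosage map.

    grs = sum of dosages; weighted_grs = sum of ln(OR) * dosage. The
    dosage map must cover every panel locus.
    """
    missing = [snp.rsid for snp in panel if snp.rsid not in dosages]
    if missing:
        raise MissingGenotypeError(
            f"subject {subject_id}: missing dosages at {', '.join(missing)}"
        )
    grs = 0
    weighted = 0.0
    for snp in panel:
        d = dosages[snp.rsid]
        if d not in (0, 1, 2):
            raise InvalidGenotypeError(
                f"subject {subject_id}: dosage {d!r} at {snp.rsid} not in {{0,1,2}}"
            )
        grs += d
        weighted += snp.weight * d
    return RiskScoreResult(subject_id=subject_id, grs=grs, weighted_grs=weighted)


def score_cohort(genotypes: pd.DataFrame, panel: Panel) -> pd.DataFrame:
    """Score every subject in a long-format genotype table.

    ``genotypes`` has columns subject_id, rsid, allele1, allele2. Subjects
    with a missing or incomplete locus are excluded with a logged warning
    (per-protocol), never imputed. Returns a frame with columns
    subject_id, grs, weighted_grs.
    """
    required = {"subject_id", "rsid", "allele1", "allele2"}
    if not required.issubset(genotypes.columns):
        raise ValueError(f"genotype table needs columns {sorted(required)}")
    by_snp = {s.rsid: s for s in panel}
    rows = []
    for subject_id, sub in genotypes.groupby("subject_id", sort=True):
        calls = {
            r.rsid: (str(r.allele1), str(r.allele2))
            for r in sub.itertuples()
            if r.rsid in by_snp
        }
        try:
            dosages = {
                rsid: risk_allele_dosage(calls.get(rsid), by_snp[rsid], str(subject_id))
                for rsid in by_snp
            }
            rows.append(compute_scores(dosages, panel, str(subject_id)))
        except MissingGenotypeError as exc:
            log.warning("excluding subject from scoring: %s", exc)
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in rows],
            "grs": [r.grs for r in rows],
            "weighted_grs": [r.weighted_grs for r in rows],
        }
    )


def genotype_counts(
    genotypes: pd.DataFrame, snp: SnpDefinition, group_label: str | None = None
) -> GenotypeCountTable:
    """Tally (hom-risk, het, hom-other) for one locus over a genotype table."""
    sub = genotypes[genotypes["rsid"] == snp.rsid]
    tallies = [0, 0, 0]
    for r in sub.itertuples():
        d = risk_allele_dosage((str(r.allele1), str(r.allele2)), snp, str(r.subject_id))
        tallies[2 - d] += 1
    return GenotypeCountTable(
        rsid=snp.rsid,
        n_homozygous_risk=tallies[0],
        n_heterozygous=tallies[1],
        n_homozygous_other=tallies[2],
        group_label=group_label,
    )


def mean_grs_from_counts(tables: list[GenotypeCountTable], group_size: int) -> float:
    """Mean unweighted GRS from per-locus genotype counts alone.

    By linearity the mean of the dosage sum equals the sum of per-locus
    mean dosages, ``sum((2*n_hom_risk + n_het) / n)``, so no
    individual-level data are needed.
    """
    for t in tables:
        if t.n != group_size:
            raise ValueError(
                f"{t.rsid}: counts sum to {t.n}, expected group size {group_size}"
            )
    return sum((2 * t.n_homozygous_risk + t.n_heterozygous) / group_size for t in tables)


def hwe_chi_square(counts: GenotypeCountTable) -> HweResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg equilibrium.

    The allele frequency is estimated from the counts themselves;
    expected genotype counts are ``n*p^2, 2npq, n*q^2``. A monomorphic
    sample (p = 0 or 1) is degenerate: the statistic is defined as 0.
    """
    n = counts.n
    if n < 1:
        raise ValueError(f"{counts.rsid}: empty genotype count table")
    p = counts.risk_allele_frequency
    q = 1.0 - p
    if p == 0.0 or p == 1.0:
        return HweResult(rsid=counts.rsid, chi2=0.0, p_value=1.0, degenerate=True)
    observed = np.asarray(counts.counts, dtype=float)
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HweResult(
        rsid=counts.rsid, chi2=chi2, p_value=float(stats.chi2.sf(chi2, df=1))
    )


def hwe_chi_square_counts(n_hom_risk: int, n_het: int, n_hom_other: int) -> HweResult:
    """Convenience wrapper taking the three genotype counts directly."""
    return hwe_chi_square(
        GenotypeCountTable("", n_hom_risk, n_het, n_hom_other)
    )


def median_split(
    scores: list[RiskScoreResult],
) -> tuple[list[GroupAssignment], float]:
    """Split subjects at the median weighted GRS.

    The cutoff is the sample median (mean of the middle order statistics
    for even n). Subjects at or below the cutoff form the low-risk group;
    strictly above, the high-risk group — ties at the cutoff go low. If
    every score is identical, everyone lands in the low group and a
    warning is emitted.
    """
    if len(scores) < 2:
        raise ValueError("median split needs at least 2 subjects")
    values = np.array([s.weighted_grs for s in scores], dtype=float)
    cutoff = float(np.median(values))
    if np.all(values == values[0]):
        warnings.warn(
            "all weighted GRS values identical; entire cohort assigned to "
            f"{LOW_GROUP}",
            stacklevel=2,
        )
    assignments = [
        GroupAssignment(
            subject_id=s.subject_id,
            group=LOW_GROUP if s.weighted_grs <= cutoff else HIGH_GROUP,
            cutoff=cutoff,
        )
        for s in scores
    ]
    return assignments, cutoff


def assign_groups(scores: pd.DataFrame) -> pd.DataFrame:
    """Median split over a score frame; returns it with a ``group`` column."""
    results = [
        RiskScoreResult(str(r.subject_id), int(r.grs), float(r.weighted_grs))
        for r in scores.itertuples()
    ]
    assignments, cutoff = median_split(results)
    out = scores.copy()
    out["group"] = [a.group for a in assignments]
    out.attrs["cutoff"] = cutoff
    return out
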