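"""Readers and writers for the pipeline's plain-text interchange formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

GENOTYPE_COLUMNS = ["subject_id", "rsid", "allele1", "allele2"]
CURVE_COLUMNS = ["subject_id", "visit", "analyte", "time_min", "value"]


def read_genotypes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "rsid": str,
                                  "allele1": str, "allele2": str})
    missing = set(GENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df[GENOTYPE_COLUMNS + [c for c in df.columns if c not in GENOTYPE_COLUMNS]]


def read_curves_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "visit": str, "analyte": str})
    missing = set(CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_table_csv(path: str | Path) -> pd.DataFrame:
    """Generic subject-visit table (clinical or anthropometry/diet)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "visit": str})
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing subject_id column")
    return df


def read_genotypes_vcf(path: str | Path) -> pd.DataFrame:
    """Minimal VCF v4 genotype reader (diploid GT field only).

    Parses the fixed columns plus sample GT calls; phasing separators
    are treated as unphased. Returns the same long-format frame as the
    CSV reader, with the ID column as the rsid and REF/ALT indexing the
    allele codes. Sites with missing calls (``.``) yield no row for that
    subject, so downstream per-protocol exclusion applies.
    """
    samples: list[str] = []
    records: list[tuple[str, str, str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise ValueError(f"{path}: VCF has no sample columns")
                samples = fields[9:]
                continue
            if not samples:
                raise ValueError(f"{path}: data line before #CHROM header")
            fields = line.split("\t")
            rsid, ref, alt = fields[2], fields[3], fields[4]
            alleles = [ref] + alt.split(",")
            fmt = fields[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                raise ValueError(f"{path}: record {rsid} has no GT field") from None
            for sample, cell in zip(samples, fields[9:]):
                gt = cell.split(":")[gt_idx].replace("|", "/")
                parts = gt.split("/")
                if len(parts) != 2 or "." in parts:
                    continue  # missing or non-diploid call
                a1, a2 = (alleles[int(p)] for p in parts)
                records.append((sample, rsid, a1, a2))
    return pd.DataFrame(records, columns=GENOTYPE_COLUMNS)


def write_scores_csv(scores: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("subject_id", "grs", "weighted_grs", "group")
            if c in scores.columns]
    scores[cols].to_csv(path, index=False)
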