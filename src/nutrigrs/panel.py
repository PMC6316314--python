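"""SNP panel definitions: each locus carries its risk allele and log-odds weight.

A panel is a list of biallelic loci. The weight used for the weighted
genetic risk score is the natural log of the per-risk-allele diabetes
odds ratio, so a weighted score is ``sum(ln(OR_i) * dosage_i)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class SnpDefinition:
    """One biallelic locus with its risk allele and odds-ratio weight.

    Parameters
    ----------
    rsid : str
        dbSNP-style locus identifier (e.g. ``"rs2237892"``).
    risk_allele : str
        The allele counted toward the risk score. Single character,
        compared case-insensitively.
    other_allele : str
        The non-risk allele. Must differ from ``risk_allele``.
    odds_ratio : float
        Per-risk-allele diabetes odds ratio; must be positive. The
        score weight is ``ln(odds_ratio)``.
    """

    rsid: str
    risk_allele: str
    other_allele: str
    odds_ratio: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "risk_allele", self.risk_allele.strip().upper())
        object.__setattr__(self, "other_allele", self.other_allele.strip().upper())
        if not self.rsid:
            raise ValueError("rsid must be a nonempty string")
        if self.risk_allele == self.other_allele:
            raise ValueError(
                f"{self.rsid}: risk allele and other allele are both "
                f"{self.risk_allele!r}"
            )
        if not (self.odds_ratio > 0):
            raise ValueError(f"{self.rsid}: odds_ratio must be > 0, got {self.odds_ratio}")

    @property
    def weight(self) -> float:
        """Natural log of the odds ratio."""
        return math.log(self.odds_ratio)

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.risk_allele, self.other_allele))


Panel = list[SnpDefinition]


def load_panel(path: str | Path) -> Panel:
    """Read a SNP panel from a JSON array of locus records.

    Each record must have keys ``rsid``, ``risk_allele``, ``other_allele``,
    ``odds_ratio``. Duplicate rsids are rejected.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"{path}: panel JSON must be an array of locus records")
    panel = [
        SnpDefinition(
            rsid=rec["rsid"],
            risk_allele=rec["risk_allele"],
            other_allele=rec["other_allele"],
            odds_ratio=float(rec["odds_ratio"]),
        )
        for rec in raw
    ]
    seen: set[str] = set()
    for snp in panel:
        if snp.rsid in seen:
            raise ValueError(f"duplicate rsid in panel: {snp.rsid}")
        seen.add(snp.rsid)
    return panel


def save_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel back to its JSON interchange form."""
    records = [
        {
            "rsid": s.rsid,
            "risk_allele": s.risk_allele,
            "other_allele": s.other_allele,
            "odds_ratio": s.odds_ratio,
        }
        for s in panel
    ]
    Path(path).write_text(json.dumps(records, indent=2) + "\n")
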