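import numpy as np
import pandas as pd
import pytest

from nutrigrs.panel import SnpDefinition
from nutrigrs.grs import GenotypeCountTable
from nutrigrs.simulate import SYNTHETIC_PANEL

# Published genotype counts (hom-risk, het, hom-other) per locus for the
# motivating 32-subject cohort, split at the weighted-GRS median.
LOW_COUNTS = {
    "rs2237892": (2, 11, 4),
    "rs2206734": (1, 9, 7),
    "rs2383208": (1, 12, 4),
    "rs6780569": (11, 5, 1),
    "rs1470579": (2, 7, 8),
}
HIGH_COUNTS = {
    "rs2237892": (9, 5, 1),
    "rs2206734": (5, 7, 3),
    "rs2383208": (9, 6, 0),
    "rs6780569": (12, 3, 0),
    "rs1470579": (4, 7, 4),
}


def count_tables(counts: dict, label: str) -> list[GenotypeCountTable]:
    return [
        GenotypeCountTable(rsid, *triple, group_label=label)
        for rsid, triple in counts.items()
    ]


@pytest.fixture(scope="session")
def panel() -> list[SnpDefinition]:
    return list(SYNTHETIC_PANEL)


@pytest.fixture(scope="session")
def low_tables():
    return count_tables(LOW_COUNTS, "L-GRS")


@pytest.fixture(scope="session")
def high_tables():
    return count_tables(HIGH_COUNTS, "H-GRS")


@pytest.fixture(scope="session")
def pooled_tables():
    pooled = {
        rsid: tuple(a + b for a, b in zip(LOW_COUNTS[rsid], HIGH_COUNTS[rsid]))
        for rsid in LOW_COUNTS
    }
    return count_tables(pooled, "all")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180)


@pytest.fixture(scope="session")
def small_genotypes(panel) -> pd.DataFrame:
    """Three hand-built subjects: all-risk, all-het, all-other."""
    rows = []
    for sid, dosage in (("A", 2), ("B", 1), ("C", 0)):
        for snp in panel:
            a1 = snp.risk_allele if dosage >= 1 else snp.other_allele
            a2 = snp.risk_allele if dosage == 2 else snp.other_allele
            rows.append((sid, snp.rsid, a1, a2))
    return pd.DataFrame(rows, columns=["subject_id", "rsid", "allele1", "allele2"])
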