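import numpy as np
import pandas as pd
import pytest

from slegrs.genotypes import GenotypeMatrix
from slegrs.panel import RiskPanel


def make_panel(ors, hla=None):
    """Panel with given odds ratios, A risk allele / G other."""
    m = len(ors)
    return RiskPanel.from_frame(pd.DataFrame({
        "snp_id": [f"rs{j}" for j in range(m)],
        "chrom": ["1"] * m,
        "pos": np.arange(1, m + 1) * 100,
        "risk_allele": ["A"] * m,
        "other_allele": ["G"] * m,
        "odds_ratio": ors,
        "hla_flag": [j in (hla or ()) for j in range(m)],
    }))


def make_genotypes(dosage, snp_ids=None):
    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    ids = [f"i{k}" for k in range(n)]
    snps = snp_ids or [f"rs{j}" for j in range(m)]
    return GenotypeMatrix(ids, snps, dosage)


@pytest.fixture
def two_snp_panel():
    return make_panel([2.0, 2.0])


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-sized simulated cohort shared by read-only tests."""
    from slegrs.simulate import SimConfig, simulate_cohort
    cfg = SimConfig(seed=20240901, n_individuals=4000)
    panel, genos, status, scores, cohort = simulate_cohort(cfg)
    return {"config": cfg, "panel": panel, "genotypes": genos,
            "status": status, "scores": scores, "cohort": cohort}
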