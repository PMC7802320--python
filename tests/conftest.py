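import numpy as np
import pandas as pd
import pytest

import dsvpipe as dp


@pytest.fixture(scope="session")
def planted_risk_sim():
    """600+600 cohort with 20 planted OR=3 deletions among 300 total."""
    planted = [dp.PlantedRisk(j, 3.0, 0.20) for j in range(20)]
    cfg = dp.SimulationConfig(
        n_cancer=600, n_control=600, m_background=280, planted_risk=planted, seed=11
    )
    records, cohort, truth = dp.simulate_genotypes(cfg)
    carriers = dp.build_carrier_matrix(records, cohort)
    return cfg, records, cohort, carriers, truth


@pytest.fixture(scope="session")
def trained_attention(planted_risk_sim):
    _, _, cohort, carriers, truth = planted_risk_sim
    y = (cohort["cohort_label"] == "cancer").to_numpy().astype(int)
    model = dp.train_attention(carriers, y, seed=0)
    return model, carriers, y, truth


@pytest.fixture(scope="session")
def survival_sim():
    """300 patients, 51 deletions, one planted log-HR = 1.2."""
    cfg = dp.SimulationConfig(
        n_cancer=300,
        n_control=5,
        m_background=51,
        planted_hazard=[dp.PlantedHazard(0, 1.2)],
        seed=5,
    )
    records, cohort, truth = dp.simulate_genotypes(cfg)
    carriers = dp.build_carrier_matrix(records, cohort)
    patients = cohort[cohort["cohort_label"] == "cancer"]
    cm = dp.CarrierMatrix(
        data=carriers.data.loc[patients["sample_id"]], metadata=carriers.metadata
    )
    filled = dp.simulate_survival(cm, cfg, patients)
    data = dp.SurvivalData.from_cohort(cm, filled)
    return cfg, cm, data, truth


def toy_records(n_samples: int = 40):
    """Six hand-built deletions exercising each filter criterion once.

    Record 0 fails the autosome rule, 1 and 2 the size window, 3 the MAF
    floor, 4 the per-cohort carrier fraction; record 5 passes everything.
    """
    def geno(n_case_het, n_ctrl_het):
        g = np.zeros(n_samples, dtype=np.int8)
        g[:n_case_het] = 1
        g[n_samples // 2 : n_samples // 2 + n_ctrl_het] = 1
        return g

    common = geno(4, 4)
    return [
        dp.DeletionRecord("d_chrx", "chrX", 1000, 2000, common.copy()),
        dp.DeletionRecord("d_short", "chr1", 1000, 1400, common.copy()),
        dp.DeletionRecord("d_long", "chr2", 1000, 13000, common.copy()),
        dp.DeletionRecord("d_rare", "chr3", 1000, 2000, geno(1, 0)),
        dp.DeletionRecord("d_case_only", "chr4", 1000, 2000, geno(6, 0)),
        dp.DeletionRecord("d_pass", "chr5", 1000, 2000, common.copy()),
    ]


def toy_cohort(n_samples: int = 40) -> pd.DataFrame:
    half = n_samples // 2
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(n_samples)],
            "cohort_label": ["cancer"] * half + ["non-cancer"] * (n_samples - half),
            "fch": "unknown",
            "sex": "female",
            "age": 50,
            "cancer_type": "colorectal",
            "recurrence": "not-applicable",
            "rfs_time": np.nan,
            "rfs_event": np.nan,
        }
    )
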