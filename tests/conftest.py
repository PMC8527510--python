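import numpy as np
import pandas as pd
import pytest

from mbmixups import Scenario, SimulationConfig, simulate_cohort

FOUNDERS = [f"F{i}" for i in range(1, 9)]


def founder_frame(rows: dict[str, tuple]) -> pd.DataFrame:
    """Founder SNP table from {snp_id: 8-tuple of alleles}."""
    records = []
    for i, (snp, alleles) in enumerate(rows.items()):
        records.append({"snp_id": snp, "chrom": "1", "pos": 1000 * (i + 1),
                        **dict(zip(FOUNDERS, alleles))})
    return pd.DataFrame(records)


@pytest.fixture
def founder_table() -> pd.DataFrame:
    return founder_frame(
        {
            "snp_a": ("A", "A", "A", "C", "C", "C", "C", "C"),  # biallelic, major C
            "snp_b": ("A", "C", "G", "A", "A", "A", "A", "A"),  # triallelic
            "snp_c": ("T", "T", "T", "T", "T", "T", "T", "T"),  # monomorphic
            "snp_d": ("G", "G", "G", "G", "T", "T", "T", "T"),  # 4-4 tie
            "snp_e": ("A", "C", "C", "C", "C", "C", "C", "C"),  # biallelic, major C
            "snp_f": ("A", "A", "N", "C", "C", "C", "C", "C"),  # missing founder allele
        }
    )


@pytest.fixture(scope="session")
def anomaly_cohort():
    """20-sample cohort with a planted swap pair, a swap trio cycle, and a
    42% mixture; ~180k reads per sample at uniform depth."""
    cfg = SimulationConfig(
        seed=101,
        n_samples=20,
        n_snps=3000,
        mean_depth=60.0,
        depth_multiplier_range=(1.0, 1.0),
        scenarios={
            "S001": Scenario("swap", "S002"),
            "S002": Scenario("swap", "S001"),
            "S003": Scenario("swap", "S004"),
            "S004": Scenario("swap", "S005"),
            "S005": Scenario("swap", "S003"),
            "S006": Scenario("mixture", "S007", 0.42),
        },
    )
    geno, counts, truth = simulate_cohort(cfg)
    return cfg, geno, counts, truth
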