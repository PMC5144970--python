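import numpy as np
import pandas as pd
import pytest

from plastinorm import synthetic_data as sd

TEMPERATURE_GRID = [15.0, 20.0, 25.0, 30.0, 35.0, 40.0]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def quadratic_table(
    peaks: dict[str, float],
    sigma: float = 0.2,
    n_replicates: int = 5,
    height: float = 3.3,
    curvature: float = 0.03,
    seed: int = 0,
    env_param: str = "temperature",
    settings=TEMPERATURE_GRID,
) -> pd.DataFrame:
    """Growth-rate table from truncated-quadratic norms, one row per assay."""
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, peak in peaks.items():
        for s in settings:
            mean = max(0.0, height - curvature * (s - peak) ** 2)
            for rep in range(1, n_replicates + 1):
                rows.append({
                    "genotype": genotype,
                    "mechanism": "control" if genotype == "4200" else "mutant",
                    "env_param": env_param,
                    "setting": float(s),
                    "replicate": rep,
                    "rate_mm_per_hr": max(0.0, mean + rng.normal(0.0, sigma)),
                    "missing_flag": 0,
                })
    return pd.DataFrame(rows)


def flat_table(
    genotype_means: dict[str, float],
    sigma: float = 0.2,
    n_replicates: int = 5,
    seed: int = 0,
    env_param: str = "temperature",
    settings=TEMPERATURE_GRID,
) -> pd.DataFrame:
    """Environment-independent means: pure elevation differences, no G x E."""
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, mean in genotype_means.items():
        for s in settings:
            for rep in range(1, n_replicates + 1):
                rows.append({
                    "genotype": genotype,
                    "mechanism": "control" if genotype == "4200" else "mutant",
                    "env_param": env_param,
                    "setting": float(s),
                    "replicate": rep,
                    "rate_mm_per_hr": mean + rng.normal(0.0, sigma),
                    "missing_flag": 0,
                })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_design():
    genotypes = [("4200", "control"), ("mut-a", "DNA methylation"), ("mut-b", "other")]
    return sd.enumerate_design(genotypes, {"temperature": TEMPERATURE_GRID}, 3)
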