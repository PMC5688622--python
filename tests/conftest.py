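import numpy as np
import pandas as pd
import pytest

from pdprs import (
    DosageMatrix,
    SimulationConfig,
    load_panel_table,
    load_reference_panel,
    simulate_dataset,
)
from pdprs.panel import reference_panel_path


@pytest.fixture(scope="session")
def panel_variants():
    """All 26 rows of the packaged risk-locus table, printed weights."""
    return load_panel_table(reference_panel_path(), use_table_weights=True)


@pytest.fixture(scope="session")
def panel():
    """The 16-variant scoring panel with printed weights."""
    return load_reference_panel()


@pytest.fixture(scope="session")
def panel_table():
    return pd.read_csv(
        reference_panel_path(), sep="\t", na_values=["NA"], dtype={"chrom": str}
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20170978)


@pytest.fixture(scope="session")
def sim_data():
    """One synthetic two-cohort dataset at the default study conditions."""
    return simulate_dataset(SimulationConfig(seed=11))


def make_matrix(dosages: np.ndarray, platform=None, **kwargs) -> DosageMatrix:
    n, m = dosages.shape
    df = pd.DataFrame(
        np.asarray(dosages, dtype=float),
        index=pd.Index([f"s{i:04d}" for i in range(n)], name="sample_id"),
        columns=[f"v{j}" for j in range(m)],
    )
    plat = None
    if platform is not None:
        plat = pd.Series(platform, index=df.index, name="platform")
    return DosageMatrix(dosages=df, platform=plat, **kwargs)


def make_cohort(
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    n_female_cases: int | None = None,
    n_female_controls: int | None = None,
    platform: str = "P1",
) -> pd.DataFrame:
    """A minimal valid cohort table with the given composition."""
    n = n_cases + n_controls
    status = np.array(["case"] * n_cases + ["control"] * n_controls)
    sex = np.where(rng.random(n) < 0.4, "female", "male")
    if n_female_cases is not None:
        sex[:n_cases] = ["female"] * n_female_cases + ["male"] * (
            n_cases - n_female_cases
        )
    if n_female_controls is not None:
        sex[n_cases:] = ["female"] * n_female_controls + ["male"] * (
            n_controls - n_female_controls
        )
    onset = np.where(status == "case", rng.normal(61, 9, n).clip(30, 90), np.nan)
    last = np.where(
        status == "case", onset + rng.uniform(1, 6, n), rng.normal(64, 9, n).clip(30, 95)
    )
    return pd.DataFrame(
        {
            "status": status,
            "sex": sex,
            "age_at_onset": onset,
            "age_at_last_assessment": last,
            "age_at_lp": last - rng.uniform(0, 2, n),
            "family_history": np.where(rng.random(n) < 0.2, "yes", "no"),
            "platform": platform,
            "pc1": rng.normal(0, 1, n),
            "pc2": rng.normal(0, 1, n),
        },
        index=[f"s{i:04d}" for i in range(n)],
    )
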