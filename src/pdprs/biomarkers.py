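"""Cross-platform harmonization of CSF biomarker levels.

CSF analytes (alpha-synuclein, Abeta 1-42, total tau, phosphorylated
tau) measured with different immunoassay kits are on incompatible
raw scales; raw pg/mL values from two platforms cannot be pooled.
Harmonization log10-transforms the raw level and centers it on the
platform-and-analyte stratum mean, so a kit's multiplicative rescaling
drops out exactly and cohorts become jointly analysable.  Disease
status is deliberately not part of the stratum: centering within
status groups would erase the case-control contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ANALYTES = ("alpha_synuclein", "abeta_1_42", "t_tau", "p_tau")

REQUIRED_COLUMNS = ("sample_id", "analyte", "raw_level", "platform")


def validate_biomarker_table(table: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"biomarker table missing columns: {sorted(missing)}")
    levels = table["raw_level"]
    bad = table.loc[levels.notna() & (levels <= 0)]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValueError(
            f"non-positive raw level for sample {row['sample_id']} "
            f"({row['analyte']}, {row['platform']}): {row['raw_level']}"
        )


def harmonize(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``harmonized_level`` column: log10(raw) centered within
    each platform x analyte stratum.

    Raw values are untouched; strata are processed independently.
    A stratum with fewer than 2 observations is rejected (a centered
    singleton is identically zero and useless for inference).
    """
    validate_biomarker_table(table)
    out = table.copy()
    obs = out["raw_level"].notna()
    log10 = np.log10(out.loc[obs, "raw_level"].astype(float))
    centered = pd.Series(np.nan, index=out.index, dtype=float)
    for (platform, analyte), idx in (
        out.loc[obs].groupby(["platform", "analyte"], observed=True).groups.items()
    ):
        if len(idx) < 2:
            raise ValueError(
                f"singleton stratum (platform={platform}, analyte={analyte}): "
                "centering undefined for inference"
            )
        centered.loc[idx] = log10.loc[idx] - log10.loc[idx].mean()
    out["harmonized_level"] = centered
    return out


def read_biomarker_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    validate_biomarker_table(df)
    return df


def write_biomarker_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")
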