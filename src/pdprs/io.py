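"""Readers and writers for dosage matrices and QC reports.

Two on-disk genotype representations are supported: a VCF with a
per-genotype dosage (``DS``) FORMAT field and optionally genotype
probabilities (``GP``), read through cyvcf2; and a plain tab-separated
dosage matrix (rows = samples, columns = variants, first column the
sample ID, missing values as ``NA``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .qc import DosageMatrix

MISSING = "NA"


def read_dosage_tsv(
    path: str | Path,
    platform: str | pd.Series | dict | None = None,
    info_scores: pd.Series | None = None,
) -> DosageMatrix:
    """Read a samples x variants dosage TSV into a :class:`DosageMatrix`.

    ``platform`` may be a single label for all samples, or a per-sample
    mapping; default is one unnamed platform.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING, ""])
    df.index = df.index.astype(str)
    return DosageMatrix(
        dosages=df.astype(float),
        platform=_platform_series(platform, df.index),
        info_scores=info_scores,
    )


def write_dosage_tsv(matrix: DosageMatrix, path: str | Path) -> None:
    out = matrix.dosages.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=MISSING)


def read_info_scores(path: str | Path) -> pd.Series:
    """Read a two-column TSV ``variant_id info`` into a Series."""
    df = pd.read_csv(path, sep="\t", na_values=[MISSING, ""])
    return pd.Series(df["info"].values, index=df["variant_id"].astype(str), name="info")


def read_vcf_dosages(
    path: str | Path,
    platform: str | pd.Series | dict | None = None,
) -> DosageMatrix:
    """Read effect-allele dosages (and genotype probabilities when
    present) from a VCF with a ``DS`` FORMAT field.

    The ALT allele is taken as the effect allele; multi-allelic records
    are rejected.  Variants without an ID are skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids: list[str] = []
    dosage_cols: list[np.ndarray] = []
    gp_cols: list[np.ndarray | None] = []
    any_gp = False
    for v in vcf:
        if v.ID is None:
            continue
        if len(v.ALT) != 1:
            raise ValueError(f"variant {v.ID}: multi-allelic records are not supported")
        ds = v.format("DS")
        if ds is None:
            raise ValueError(f"variant {v.ID}: no DS field")
        ds = np.asarray(ds, dtype=float).reshape(-1)
        ds[ds < 0] = np.nan  # cyvcf2 encodes missing as large negative
        ids.append(v.ID)
        dosage_cols.append(ds)
        gp = v.format("GP")
        if gp is not None:
            any_gp = True
            gp_cols.append(np.asarray(gp, dtype=float))
        else:
            gp_cols.append(None)
    vcf.close()
    dosages = pd.DataFrame(
        np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="sample_id"),
        columns=ids,
    )
    probs = None
    if any_gp:
        probs = np.full((len(samples), len(ids), 3), np.nan)
        for j, gp in enumerate(gp_cols):
            if gp is not None:
                probs[:, j, :] = gp
    return DosageMatrix(
        dosages=dosages,
        platform=_platform_series(platform, dosages.index),
        genotype_probabilities=probs,
    )


def _platform_series(
    platform: str | pd.Series | dict | None, index: pd.Index
) -> pd.Series:
    if platform is None:
        return pd.Series("platform1", index=index, name="platform")
    if isinstance(platform, str):
        return pd.Series(platform, index=index, name="platform")
    s = pd.Series(platform, name="platform")
    return s.reindex(index)
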