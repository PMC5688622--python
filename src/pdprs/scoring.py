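"""Weighted polygenic risk score computation, leave-one-out scores and
score tertiles.

The score for an individual is the plain weighted sum over panel
variants of the effect-allele dosage times the variant weight
(log2 OR).  The sum convention (rather than a per-allele average)
keeps leave-one-variant-out scores exactly additive: removing a
variant subtracts exactly its dosage x weight contribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .panel import ScoringPanel
from .qc import DosageMatrix

MISSING_POLICIES = ("mean_impute", "omit")


@dataclass
class ScoreSet:
    """Per-sample PRS values with bookkeeping.

    ``table`` has index = sample IDs and columns ``score``,
    ``n_variants_used`` and, after :func:`assign_tertiles`,
    ``tertile`` (labels T1 = lowest third .. T3 = highest).
    """

    table: pd.DataFrame
    panel_id: str = ""

    def __post_init__(self) -> None:
        required = {"score", "n_variants_used"}
        if not required <= set(self.table.columns):
            raise ValueError(f"score table must have columns {sorted(required)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def score(self) -> pd.Series:
        return self.table["score"]

    @property
    def tertile(self) -> pd.Series:
        if "tertile" not in self.table.columns:
            raise KeyError("tertiles not assigned; call assign_tertiles first")
        return self.table["tertile"]

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", na_rep="NA")


def compute_prs(
    matrix: DosageMatrix,
    panel: ScoringPanel,
    missing_policy: str = "mean_impute",
) -> ScoreSet:
    """Score every sample against the panel.

    score(sample) = sum over panel variants of dosage x weight.  A
    missing dosage is replaced by ``2 x study_maf`` of that variant
    under ``mean_impute`` (falling back to the reference MAF when no
    study MAF is recorded), or contributes 0 with ``n_variants_used``
    decremented under ``omit``.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(
            f"missing_policy must be one of {MISSING_POLICIES}, got {missing_policy!r}"
        )
    absent = [v for v in panel.variant_ids if v not in matrix.dosages.columns]
    if absent:
        raise KeyError(f"panel variants absent from dosage matrix: {absent}")
    dosages = matrix.dosages[panel.variant_ids].to_numpy(dtype=float)
    weights = panel.weights.to_numpy(dtype=float)
    observed = ~np.isnan(dosages)
    filled = dosages.copy()
    if missing_policy == "mean_impute":
        fallback = np.array(
            [
                v.study_maf if v.study_maf is not None else v.ref_maf
                for v in panel.variants
            ],
            dtype=float,
        )
        miss = np.where(~observed)
        filled[miss] = 2.0 * np.take(fallback, miss[1])
        n_used = np.full(len(filled), len(panel))
    else:
        filled[~observed] = 0.0
        n_used = observed.sum(axis=1)
    scores = filled @ weights
    table = pd.DataFrame(
        {"score": scores, "n_variants_used": n_used},
        index=matrix.dosages.index.copy(),
    )
    return ScoreSet(table=table, panel_id=panel.provenance or "panel")


def leave_one_out_prs(
    matrix: DosageMatrix,
    panel: ScoringPanel,
    excluded_variant: str,
    missing_policy: str = "mean_impute",
) -> ScoreSet:
    """Score against the panel with one variant removed.

    For fully observed data this equals the full score minus the
    excluded variant's dosage x weight contribution, exactly.
    """
    reduced = panel.drop(excluded_variant)  # raises KeyError if absent
    scores = compute_prs(matrix, reduced, missing_policy)
    scores.panel_id = f"{panel.provenance or 'panel'} minus {excluded_variant}"
    return scores


def assign_tertiles(scores: ScoreSet) -> ScoreSet:
    """Label each sample T1/T2/T3 by ascending score.

    Samples are ranked by (score, sample ID) — the ID breaks ties
    deterministically — and cut at ceil(n/3) boundaries, so group
    sizes differ by at most 2.
    """
    n = len(scores.table)
    if n < 3:
        raise ValueError(f"tertiles need at least 3 samples, got {n}")
    order = sorted(
        scores.table.index, key=lambda s: (scores.table.at[s, "score"], str(s))
    )
    cut = math.ceil(n / 3)
    labels = pd.Series(index=scores.table.index, dtype=object, name="tertile")
    labels.loc[order[:cut]] = "T1"
    labels.loc[order[cut : 2 * cut]] = "T2"
    labels.loc[order[2 * cut :]] = "T3"
    table = scores.table.copy()
    table["tertile"] = labels
    return replace(scores, table=table)
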