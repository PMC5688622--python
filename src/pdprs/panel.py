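"""Risk-locus panel handling: weight derivation and call-rate selection.

A polygenic risk score (PRS) panel is a table of GWAS risk loci, one per
row, each carrying the effect allele, the meta-analysis odds ratio (OR)
per effect-allele copy, and the fraction of study individuals with a
usable genotype at that locus (the call rate).  The per-variant score
weight is the binary logarithm of the OR, so protective alleles
(OR < 1) contribute negatively and an OR of 1 contributes nothing.
Only variants whose overall call rate exceeds a threshold (default 85%)
enter the final scoring panel.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")

#: Default overall call-rate threshold for panel inclusion (strict >).
DEFAULT_CALL_RATE_THRESHOLD = 0.85


def compute_weight(odds_ratio: float, variant_id: str | None = None) -> float:
    """Return the PRS weight for a variant: log2 of its odds ratio.

    Parameters
    ----------
    odds_ratio
        Per-effect-allele odds ratio; must be positive and finite.
    variant_id
        Optional label used in error messages.

    Returns
    -------
    float
        ``log2(odds_ratio)``.  Negative for protective alleles
        (OR < 1), zero for OR = 1.
    """
    label = f" for variant {variant_id}" if variant_id else ""
    if not isinstance(odds_ratio, (int, float)) or isinstance(odds_ratio, bool):
        raise TypeError(f"odds ratio{label} must be a number, got {odds_ratio!r}")
    if not math.isfinite(odds_ratio) or odds_ratio <= 0:
        raise ValueError(
            f"odds ratio{label} must be positive and finite, got {odds_ratio!r}"
        )
    return math.log2(odds_ratio)


@dataclass(frozen=True)
class RiskVariant:
    """One GWAS risk locus with its scoring metadata.

    ``weight`` is ``None`` for loci that cannot be scored (no odds
    ratio, or excluded from the source table).  ``call_rate`` is
    ``None`` when the locus had no genotype data at all.
    """

    variant_id: str
    chromosome: str
    position: int
    gene_label: str
    effect_allele: str
    ref_maf: float
    odds_ratio: float | None
    study_maf: float | None = None
    call_rate: float | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in _VALID_ALLELES:
            raise ValueError(
                f"variant {self.variant_id}: effect allele must be one of "
                f"A/C/G/T, got {self.effect_allele!r}"
            )
        if not 0.0 <= self.ref_maf <= 1.0:
            raise ValueError(
                f"variant {self.variant_id}: ref_maf {self.ref_maf} outside [0, 1]"
            )
        for name in ("study_maf", "call_rate"):
            val = getattr(self, name)
            if val is not None and not 0.0 <= val <= 1.0:
                raise ValueError(
                    f"variant {self.variant_id}: {name} {val} outside [0, 1]"
                )
        if self.odds_ratio is not None and (
            not math.isfinite(self.odds_ratio) or self.odds_ratio <= 0
        ):
            raise ValueError(
                f"variant {self.variant_id}: odds ratio must be positive and "
                f"finite, got {self.odds_ratio!r}"
            )

    @property
    def scoreable(self) -> bool:
        """True when the variant has both a weight and a call rate."""
        return self.weight is not None and self.call_rate is not None


@dataclass(frozen=True)
class ScoringPanel:
    """The selected scoring panel: variants in stable table order.

    ``excluded`` records, for each rejected source variant, the reason
    it did not enter the panel (low call rate, no genotype data, or no
    usable weight).
    """

    variants: tuple[RiskVariant, ...]
    call_rate_threshold: float = DEFAULT_CALL_RATE_THRESHOLD
    provenance: str = ""
    excluded: tuple[tuple[str, str], ...] = field(default=())

    def __post_init__(self) -> None:
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("panel variant_ids must be unique")
        for v in self.variants:
            if v.weight is None:
                raise ValueError(f"panel variant {v.variant_id} has no weight")
            if v.call_rate is None or v.call_rate <= self.call_rate_threshold:
                raise ValueError(
                    f"panel variant {v.variant_id} fails the call-rate rule "
                    f"(> {self.call_rate_threshold})"
                )

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def weights(self) -> pd.Series:
        """Per-variant weights, indexed by variant_id, in panel order."""
        return pd.Series(
            [v.weight for v in self.variants], index=self.variant_ids, name="weight"
        )

    def get(self, variant_id: str) -> RiskVariant:
        for v in self.variants:
            if v.variant_id == variant_id:
                return v
        raise KeyError(f"variant {variant_id} not in panel")

    def drop(self, variant_id: str) -> "ScoringPanel":
        """Return a new panel without ``variant_id`` (leave-one-out)."""
        if variant_id not in self.variant_ids:
            raise KeyError(f"variant {variant_id} not in panel")
        return replace(
            self,
            variants=tuple(v for v in self.variants if v.variant_id != variant_id),
            provenance=f"{self.provenance} minus {variant_id}".strip(),
        )


def load_panel_table(
    table_source: str | Path | pd.DataFrame,
    use_table_weights: bool = False,
) -> list[RiskVariant]:
    """Load a risk-locus table into :class:`RiskVariant` records.

    The table is tab-separated with header columns
    ``variant_id chrom pos gene effect_allele ref_maf or study_maf
    call_rate [weight]``; missing cells are ``NA``.

    Weights are derived from the odds ratio via :func:`compute_weight`.
    With ``use_table_weights=True`` a non-missing ``weight`` column
    entry overrides the derived value, so a published panel whose
    printed weights deviate from the stated formula can be reproduced
    verbatim.  Rows without an odds ratio are retained but can never be
    selected for scoring.
    """
    if isinstance(table_source, pd.DataFrame):
        df = table_source.copy()
    else:
        df = pd.read_csv(table_source, sep="\t", na_values=["NA", ""], dtype={"chrom": str})
    required = {"variant_id", "chrom", "pos", "effect_allele", "or"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"panel table missing columns: {sorted(missing_cols)}")
    dup = df["variant_id"][df["variant_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate variant_id(s) in panel table: {sorted(dup)}")

    def _opt(row, col):
        if col not in df.columns:
            return None
        val = row[col]
        return None if pd.isna(val) else float(val)

    variants: list[RiskVariant] = []
    for _, row in df.iterrows():
        vid = str(row["variant_id"])
        odds_ratio = _opt(row, "or")
        weight = None
        if odds_ratio is not None:
            weight = compute_weight(odds_ratio, vid)
        else:
            logger.warning("variant %s has no odds ratio; row kept but unscoreable", vid)
        table_weight = _opt(row, "weight")
        if use_table_weights and table_weight is not None:
            weight = table_weight
        variants.append(
            RiskVariant(
                variant_id=vid,
                chromosome=str(row["chrom"]),
                position=int(row["pos"]),
                gene_label=str(row["gene"]) if "gene" in df.columns else "",
                effect_allele=str(row["effect_allele"]),
                ref_maf=float(row["ref_maf"]) if "ref_maf" in df.columns else 0.0,
                odds_ratio=odds_ratio,
                study_maf=_opt(row, "study_maf"),
                call_rate=_opt(row, "call_rate"),
                weight=weight,
            )
        )
    return variants


def select_panel(
    variants: Sequence[RiskVariant] | Iterable[RiskVariant],
    threshold: float = DEFAULT_CALL_RATE_THRESHOLD,
    provenance: str = "",
) -> ScoringPanel:
    """Apply the call-rate rule: keep variants with call_rate strictly
    above ``threshold`` and a defined weight, in input order.

    Excluded variants are recorded on the returned panel with a reason:
    ``no genotype data`` (call rate absent), ``low call rate``, or
    ``no weight``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    kept: list[RiskVariant] = []
    excluded: list[tuple[str, str]] = []
    for v in variants:
        if v.call_rate is None:
            excluded.append((v.variant_id, "no genotype data"))
        elif v.call_rate <= threshold:
            excluded.append((v.variant_id, f"low call rate ({v.call_rate:g})"))
        elif v.weight is None:
            excluded.append((v.variant_id, "no weight"))
        else:
            kept.append(v)
    return ScoringPanel(
        variants=tuple(kept),
        call_rate_threshold=threshold,
        provenance=provenance,
        excluded=tuple(excluded),
    )


def reference_panel_path() -> Path:
    """Path to the packaged 26-locus PD GWAS risk-locus table."""
    return Path(
        importlib.resources.files("pdprs.data").joinpath("risk_loci_nalls2014.tsv")
    )


def load_reference_panel(
    printed_weights: bool = True,
    threshold: float = DEFAULT_CALL_RATE_THRESHOLD,
) -> ScoringPanel:
    """The packaged 26-locus PD panel, selected by the call-rate rule.

    With ``printed_weights=True`` (default) the weights are the values
    printed in the source locus table, which for three loci differ from
    log2(OR); with ``False`` all weights are recomputed from the ORs.
    """
    variants = load_panel_table(
        reference_panel_path(), use_table_weights=printed_weights
    )
    return select_panel(variants, threshold, provenance="PD GWAS 26-locus table")
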