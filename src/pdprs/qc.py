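"""Genotype- and variant-level quality control for imputed dosage data.

The QC chain mirrors standard post-imputation practice for array
cohorts: uncertain genotypes are hard-call filtered (best-genotype
probability below 0.9, or imputation INFO below 0.3, become missing);
variants are then removed when they depart from Hardy-Weinberg
equilibrium (exact test p < 1e-6), when a platform's genotyping rate
falls below 95%, or when the overall call rate in the merged file is
below 85%.  Samples are finally restricted to a single ancestry
cluster on the first two principal components of the standardized
dosage matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

_GP_SUM_TOL = 1e-6


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; defaults follow common post-imputation QC."""

    hard_call_min_probability: float = 0.9
    min_info: float = 0.3
    hwe_alpha: float = 1e-6
    min_variant_call_rate: float = 0.95
    min_joint_call_rate: float = 0.85

    def __post_init__(self) -> None:
        for name in (
            "hard_call_min_probability",
            "min_info",
            "hwe_alpha",
            "min_variant_call_rate",
            "min_joint_call_rate",
        ):
            val = getattr(self, name)
            if not 0.0 < val <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {val}")


@dataclass
class DosageMatrix:
    """Individuals x variants effect-allele dosages with missingness.

    ``dosages`` is a float DataFrame (samples as index, variants as
    columns, NaN = missing genotype), each non-missing entry in [0, 2].
    ``platform`` labels each sample's cohort/array.  ``info_scores``
    (per variant) and ``genotype_probabilities`` (samples x variants x
    3, triples of hom-ref/het/hom-effect probabilities) are optional.
    """

    dosages: pd.DataFrame
    platform: pd.Series | None = None
    info_scores: pd.Series | None = None
    genotype_probabilities: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dosages.index.has_duplicates:
            raise ValueError("duplicate sample IDs")
        if self.dosages.columns.has_duplicates:
            raise ValueError("duplicate variant IDs")
        vals = self.dosages.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 2)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise ValueError(
                f"dosage outside [0, 2] at sample {self.dosages.index[i]}, "
                f"variant {self.dosages.columns[j]}: {vals[i, j]}"
            )
        if self.platform is None:
            self.platform = pd.Series(
                "platform1", index=self.dosages.index, name="platform"
            )
        else:
            self.platform = self.platform.reindex(self.dosages.index)
        if self.genotype_probabilities is not None:
            gp = np.asarray(self.genotype_probabilities, dtype=float)
            if gp.shape != (*self.dosages.shape, 3):
                raise ValueError(
                    f"genotype_probabilities shape {gp.shape} does not match "
                    f"dosages {self.dosages.shape} x 3"
                )
            with np.errstate(invalid="ignore"):
                out_of_range = (gp < 0) | (gp > 1)
                sums = gp.sum(axis=2)
            if np.any(out_of_range & ~np.isnan(gp)):
                i, j, _ = np.argwhere(out_of_range & ~np.isnan(gp))[0]
                raise ValueError(
                    f"genotype probability outside [0, 1] at sample "
                    f"{self.dosages.index[i]}, variant {self.dosages.columns[j]}"
                )
            over = (sums > 1 + _GP_SUM_TOL) & ~np.isnan(sums)
            if np.any(over):
                i, j = np.argwhere(over)[0]
                raise ValueError(
                    f"genotype probabilities sum to >1 at sample "
                    f"{self.dosages.index[i]}, variant {self.dosages.columns[j]}"
                )
            self.genotype_probabilities = gp

    # -- basic properties -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    def call_rate(self) -> pd.Series:
        """Per-variant observed call rate over all samples."""
        return self.dosages.notna().mean(axis=0).rename("call_rate")

    def platform_call_rate(self) -> pd.DataFrame:
        """Per-variant call rate within each platform (variants x platforms)."""
        return self.dosages.notna().groupby(self.platform, observed=True).mean().T

    def subset(
        self,
        samples: Sequence[str] | None = None,
        variants: Sequence[str] | None = None,
    ) -> "DosageMatrix":
        """Return a copy restricted to the given samples/variants."""
        samples = list(samples) if samples is not None else self.sample_ids
        variants = list(variants) if variants is not None else self.variant_ids
        srows = self.dosages.index.get_indexer(samples)
        scols = self.dosages.columns.get_indexer(variants)
        if (srows < 0).any():
            raise KeyError("unknown sample ID in subset")
        if (scols < 0).any():
            raise KeyError("unknown variant ID in subset")
        gp = self.genotype_probabilities
        return DosageMatrix(
            dosages=self.dosages.loc[samples, variants].copy(),
            platform=self.platform.loc[samples].copy(),
            info_scores=(
                self.info_scores.reindex(variants)
                if self.info_scores is not None
                else None
            ),
            genotype_probabilities=(
                gp[np.ix_(srows, scols)] if gp is not None else None
            ),
        )


def merge_platforms(matrices: Sequence[DosageMatrix]) -> DosageMatrix:
    """Merge per-platform matrices: union of samples, intersection of
    variants.  Sample ID namespaces must be disjoint."""
    if not matrices:
        raise ValueError("no matrices to merge")
    common = matrices[0].dosages.columns
    for m in matrices[1:]:
        common = common.intersection(m.dosages.columns)
    common = [v for v in matrices[0].variant_ids if v in set(common)]
    parts = [m.subset(variants=common) for m in matrices]
    dosages = pd.concat([p.dosages for p in parts], axis=0)
    platform = pd.concat([p.platform for p in parts])
    gp = None
    if all(p.genotype_probabilities is not None for p in parts):
        gp = np.concatenate([p.genotype_probabilities for p in parts], axis=0)
    info = None
    if all(p.info_scores is not None for p in parts):
        # merged INFO: minimum across platforms (conservative)
        info = pd.concat([p.info_scores for p in parts], axis=1).min(axis=1)
        info.name = "info"
    return DosageMatrix(dosages, platform, info, gp)


# -- hard-call filtering --------------------------------------------------


def hard_call_filter(
    matrix: DosageMatrix, thresholds: QCThresholds | None = None
) -> DosageMatrix:
    """Mask uncertain genotypes; dimensions are unchanged.

    With genotype probabilities present, a genotype whose maximum
    probability is below ``hard_call_min_probability`` becomes missing.
    Without them, the same intent is applied to plain dosages: a dosage
    farther than ``1 - hard_call_min_probability`` from the nearest
    integer is treated as an uncertain call and masked.  Every genotype
    of a variant with imputation INFO below ``min_info`` becomes
    missing.
    """
    thresholds = thresholds or QCThresholds()
    dosages = matrix.dosages.copy()
    vals = dosages.to_numpy(dtype=float)
    if matrix.genotype_probabilities is not None:
        with warnings.catch_warnings():
            # all-NaN triples (already-missing genotypes) stay missing
            warnings.simplefilter("ignore", RuntimeWarning)
            maxp = np.nanmax(matrix.genotype_probabilities, axis=2)
        mask = maxp < thresholds.hard_call_min_probability
    else:
        slack = 1.0 - thresholds.hard_call_min_probability
        with np.errstate(invalid="ignore"):
            mask = np.abs(vals - np.round(vals)) > slack
    vals[mask] = np.nan
    if matrix.info_scores is not None:
        low_info = matrix.info_scores.reindex(dosages.columns) < thresholds.min_info
        vals[:, low_info.to_numpy(dtype=bool)] = np.nan
    dosages.iloc[:, :] = vals
    return replace(
        matrix,
        dosages=dosages,
        platform=matrix.platform.copy(),
        genotype_probabilities=(
            matrix.genotype_probabilities.copy()
            if matrix.genotype_probabilities is not None
            else None
        ),
    )


# -- Hardy-Weinberg exact test -------------------------------------------


def hwe_exact_test(n_hom_effect: int, n_het: int, n_hom_other: int) -> float:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Conditional on the observed allele counts, sums the probabilities
    of all heterozygote counts no more probable than the observed one
    (the standard exact formulation).  Returns a p-value in (0, 1].
    """
    counts = (n_hom_effect, n_het, n_hom_other)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers, got {counts}")
    n_hom_effect, n_het, n_hom_other = (int(c) for c in counts)
    n = n_hom_effect + n_het + n_hom_other
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_eff = 2 * n_hom_effect + n_het  # effect-allele count
    n_oth = 2 * n_hom_other + n_het
    rare = min(n_eff, n_oth)
    if rare == 0:  # monomorphic: trivially in equilibrium
        return 1.0
    # heterozygote count shares the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(het = h | n, allele counts), up to a shared constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    # tolerate float noise when comparing tail membership
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# -- variant-level filters ------------------------------------------------


def variant_filters(
    matrix: DosageMatrix, thresholds: QCThresholds | None = None
) -> tuple[DosageMatrix, pd.DataFrame]:
    """Drop variants failing HWE, per-platform call rate, or joint
    call rate; return the surviving submatrix and an exclusion report.

    Call rates are computed on the matrix as given (apply
    :func:`hard_call_filter` first so they reflect hard-called
    missingness).  HWE uses hard-called genotypes obtained by rounding
    dosages to the nearest integer.
    """
    thresholds = thresholds or QCThresholds()
    joint_rate = matrix.call_rate()
    plat_rate = matrix.platform_call_rate()
    records = []
    kept: list[str] = []
    for vid in matrix.variant_ids:
        reasons = []
        geno = matrix.dosages[vid].dropna().round().astype(int)
        hwe_p = np.nan
        if len(geno) > 0:
            hwe_p = hwe_exact_test(
                int((geno == 2).sum()), int((geno == 1).sum()), int((geno == 0).sum())
            )
            if hwe_p < thresholds.hwe_alpha:
                reasons.append("hwe_failure")
        min_plat = plat_rate.loc[vid].min()
        if min_plat < thresholds.min_variant_call_rate:
            reasons.append("low_platform_call_rate")
        if joint_rate[vid] < thresholds.min_joint_call_rate:
            reasons.append("low_joint_call_rate")
        if reasons:
            records.append(
                {
                    "variant_id": vid,
                    "reason_dropped": ";".join(reasons),
                    "hwe_p": hwe_p,
                    "min_platform_call_rate": min_plat,
                    "joint_call_rate": joint_rate[vid],
                }
            )
        else:
            kept.append(vid)
    report = pd.DataFrame(
        records,
        columns=[
            "variant_id",
            "reason_dropped",
            "hwe_p",
            "min_platform_call_rate",
            "joint_call_rate",
        ],
    )
    return matrix.subset(variants=kept), report


# -- ancestry restriction -------------------------------------------------


def ancestry_restrict(
    matrix: DosageMatrix,
    n_components: int = 2,
    reference_samples: Sequence[str] | None = None,
    max_iter: int = 100,
) -> tuple[list[str], pd.DataFrame]:
    """Principal-component ancestry clustering and restriction.

    Computes PCs of the mean-imputed, allele-frequency-standardized
    dosage matrix, partitions samples into two clusters on PC1-PC2
    (two-means with deterministic initialization at the two most
    distant samples), and retains the cluster containing the declared
    reference samples (majority vote) or, absent a reference, the
    larger cluster.

    Returns the retained sample IDs and a DataFrame of PC coordinates
    for *all* samples (columns ``PC1`` .. ``PCk``).
    """
    n, m = matrix.shape
    if n < 3 or n <= n_components:
        raise ValueError(f"need at least 3 samples and more samples than components, got {n}")
    if m < 2:
        raise ValueError(f"need at least 2 variants, got {m}")
    X = matrix.dosages.to_numpy(dtype=float).copy()
    col_mean = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = np.take(col_mean, nan_idx[1])
    p = col_mean / 2.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    usable = denom > 0
    if not usable.any():
        raise ValueError("degenerate input: all variants have zero variance")
    Z = (X[:, usable] - 2.0 * p[usable]) / denom[usable]
    Zc = Z - Z.mean(axis=0)
    if not np.any(Zc != 0):
        raise ValueError("degenerate input: all samples identical")
    U, S, _ = np.linalg.svd(Zc, full_matrices=False)
    k = min(n_components, S.size)
    pcs = U[:, :k] * S[:k]
    pc_df = pd.DataFrame(
        pcs, index=matrix.dosages.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    coords = pcs[:, : min(2, k)]
    labels = _two_means(coords, max_iter)
    if _single_cluster(coords, labels):
        return list(matrix.sample_ids), pc_df
    if reference_samples is not None:
        ref_idx = matrix.dosages.index.get_indexer(list(reference_samples))
        if (ref_idx < 0).any():
            raise KeyError("unknown reference sample ID")
        keep_label = int(np.round(labels[ref_idx].mean()))
    else:
        keep_label = int(labels.sum() * 2 > len(labels))
    retained = [s for s, lab in zip(matrix.sample_ids, labels) if lab == keep_label]
    return retained, pc_df


def _single_cluster(coords: np.ndarray, labels: np.ndarray) -> bool:
    """Homogeneity guard: a 2-means split of a single cloud is spurious
    when the center separation does not exceed twice the pooled
    within-cluster RMS radius (the classical 2-sigma separability
    requirement for a bimodal mixture)."""
    c0 = coords[labels == 0]
    c1 = coords[labels == 1]
    if len(c0) == 0 or len(c1) == 0:
        return True
    sep = np.linalg.norm(c0.mean(axis=0) - c1.mean(axis=0))
    within = np.concatenate(
        [c0 - c0.mean(axis=0), c1 - c1.mean(axis=0)], axis=0
    )
    rms = np.sqrt((within**2).sum(axis=1).mean())
    return bool(sep <= 2.0 * rms)


def _two_means(coords: np.ndarray, max_iter: int) -> np.ndarray:
    """Deterministic 2-means: centers start at the two most distant points."""
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    if d2[i, j] == 0:
        raise ValueError("degenerate input: no variation among samples in PC space")
    centers = coords[[i, j]].copy()
    labels = np.zeros(len(coords), dtype=int)
    for _ in range(max_iter):
        dist = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = dist.argmin(axis=1)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for c in (0, 1):
            if (labels == c).any():
                centers[c] = coords[labels == c].mean(axis=0)
    return labels
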