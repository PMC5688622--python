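"""Synthetic two-cohort datasets with the statistical structure the
pipeline assumes.

The generator emulates a two-platform Parkinson-disease study:
genotypes at the panel loci are drawn under Hardy-Weinberg equilibrium
at the study allele frequencies, per-variant missingness matches the
panel call rates in expectation, disease status follows a logistic
liability on the weighted PRS (per-allele odds ratios equal to the
panel's, scaled by ``effect_scale``), onset ages shift earlier with
higher PRS, control ages are censoring ages, and CSF biomarkers are
log-normal around platform-specific means so the two kits' scales
differ the way real immunoassay platforms do.

Everything is deterministic under a fixed seed: each generator stage
derives its stream from ``(seed, stage)`` so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .panel import ScoringPanel, load_reference_panel
from .qc import DosageMatrix
from .scoring import ScoreSet, compute_prs

#: Platform-wise log10 mean CSF levels (pg/mL), set to the control
#: means of the two real assay platforms the generator emulates.
DEFAULT_BIOMARKER_LOG10_MEANS: dict[str, dict[str, float]] = {
    "PPMI": {
        "alpha_synuclein": math.log10(2173.5),
        "abeta_1_42": math.log10(378.40),
        "t_tau": math.log10(53.95),
        "p_tau": math.log10(17.49),
    },
    "WUSTL": {
        "alpha_synuclein": math.log10(1725.0),
        "abeta_1_42": math.log10(926.40),
        "t_tau": math.log10(250.40),
        "p_tau": math.log10(47.00),
    },
}

_ONSET_BOUNDS = (25.0, 95.0)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-cohort dataset.

    Defaults reproduce the emulated study's scale: 336/139
    cases/controls on the first platform, 493/293 on the second
    (1261 individuals in total), female fractions 33.53% in cases and
    45.60% in controls, family-history rates 25%/3%, mean onset 61 y
    (SD 9), control assessment age 64 y (SD 9), and 4 years earlier
    onset per PRS unit.
    """

    seed: int = 0
    n_by_platform: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"PPMI": (336, 139), "WUSTL": (493, 293)}
    )  # platform -> (n_cases, n_controls)
    panel: ScoringPanel | None = None
    effect_scale: float = 1.0
    onset_shift_per_prs_unit: float = -4.0
    baseline_onset_mean: float = 61.0
    baseline_onset_sd: float = 9.0
    control_age_mean: float = 64.0
    control_age_sd: float = 9.0
    female_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"case": 0.3353, "control": 0.4560}
    )
    family_history_rate: Mapping[str, float] = field(
        default_factory=lambda: {"case": 0.25, "control": 0.03}
    )
    biomarker_log10_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_BIOMARKER_LOG10_MEANS
    )
    biomarker_log10_sd: float = 0.15
    prs_biomarker_beta: Mapping[str, float] = field(
        default_factory=lambda: {
            "alpha_synuclein": 0.0,
            "abeta_1_42": 0.0,
            "t_tau": 0.0,
            "p_tau": 0.0,
        }
    )
    apply_missingness: bool = True

    def __post_init__(self) -> None:
        if self.panel is None:
            self.panel = load_reference_panel()
        for plat, (nc, nk) in self.n_by_platform.items():
            if nc <= 0 or nk <= 0:
                raise ValueError(f"platform {plat}: counts must be positive")
        for frac in (*self.female_fraction.values(), *self.family_history_rate.values()):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if self.baseline_onset_sd <= 0 or self.control_age_sd <= 0:
            raise ValueError("age standard deviations must be positive")

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])

    @property
    def n_total(self) -> int:
        return sum(nc + nk for nc, nk in self.n_by_platform.values())


def simulate_genotypes(config: SimulationConfig) -> DosageMatrix:
    """Draw HWE genotypes at the panel loci with panel missingness.

    Dosages are hard genotypes in {0, 1, 2}; the genotype-probability
    triples put mass 1 on the drawn genotype.  A genotype is masked
    missing with probability ``1 - call_rate`` of its variant.
    """
    rng = config._rng(stage=1)
    panel = config.panel
    sample_ids: list[str] = []
    platforms: list[str] = []
    for plat, (nc, nk) in config.n_by_platform.items():
        n = nc + nk
        sample_ids.extend(f"{plat}_{i:05d}" for i in range(n))
        platforms.extend([plat] * n)
    n_total = len(sample_ids)
    mafs = np.array(
        [v.study_maf if v.study_maf is not None else v.ref_maf for v in panel],
        dtype=float,
    )
    genos = rng.binomial(2, mafs[None, :], size=(n_total, len(panel))).astype(float)
    probs = np.zeros((n_total, len(panel), 3))
    gi = genos.astype(int)
    ii, jj = np.meshgrid(np.arange(n_total), np.arange(len(panel)), indexing="ij")
    probs[ii, jj, gi] = 1.0
    if config.apply_missingness:
        call_rates = np.array(
            [v.call_rate if v.call_rate is not None else 1.0 for v in panel]
        )
        miss = rng.random((n_total, len(panel))) > call_rates[None, :]
        genos[miss] = np.nan
        probs[miss] = np.nan
    dosages = pd.DataFrame(
        genos, index=pd.Index(sample_ids, name="sample_id"), columns=panel.variant_ids
    )
    platform = pd.Series(platforms, index=dosages.index, name="platform")
    return DosageMatrix(dosages=dosages, platform=platform, genotype_probabilities=probs)


def _solve_intercept(liability: np.ndarray, target: float) -> float:
    """Intercept alpha with mean(expit(alpha + liability)) = target."""
    if not 0.0 < target < 1.0:
        raise ValueError(f"target case fraction {target} unattainable")

    def gap(alpha: float) -> float:
        return float(expit(alpha + liability).mean() - target)

    return brentq(gap, -60.0, 60.0, xtol=1e-10)


def simulate_phenotypes(
    matrix: DosageMatrix, config: SimulationConfig
) -> pd.DataFrame:
    """Assign status, ages, sex, family history and PCs to the
    genotyped samples.

    Case probability is ``expit(alpha + effect_scale * PRS)`` with
    alpha solved per platform so the expected case fraction matches
    the configured counts.  Case onset age is
    ``baseline + onset_shift_per_prs_unit * (PRS - mean PRS) + noise``
    truncated to [25, 95]; control age at last assessment is Normal.
    """
    rng = config._rng(stage=2)
    scores = compute_prs(matrix, config.panel, missing_policy="mean_impute")
    s = scores.score.to_numpy() * config.effect_scale
    platform = matrix.platform
    status = np.empty(len(s), dtype=object)
    for plat, (nc, nk) in config.n_by_platform.items():
        sel = (platform == plat).to_numpy()
        if not sel.any():
            continue
        target = nc / (nc + nk)
        alpha = _solve_intercept(s[sel], target)
        is_case = rng.random(sel.sum()) < expit(alpha + s[sel])
        status[sel] = np.where(is_case, "case", "control")
    is_case = status == "case"
    centered = scores.score.to_numpy() - scores.score.to_numpy().mean()
    onset = (
        config.baseline_onset_mean
        + config.onset_shift_per_prs_unit * centered
        + rng.normal(0.0, config.baseline_onset_sd, len(s))
    )
    onset = np.clip(onset, *_ONSET_BOUNDS)
    age_onset = np.where(is_case, onset, np.nan)
    followup = np.abs(rng.normal(3.7, 2.0, len(s)))  # years from onset to assessment
    control_age = np.clip(
        rng.normal(config.control_age_mean, config.control_age_sd, len(s)),
        *_ONSET_BOUNDS,
    )
    age_last = np.where(is_case, np.minimum(onset + followup, 119.0), control_age)
    age_lp = np.clip(age_last - rng.uniform(0.0, 2.0, len(s)), 25.0, 119.0)
    female_p = np.where(
        is_case, config.female_fraction["case"], config.female_fraction["control"]
    )
    sex = np.where(rng.random(len(s)) < female_p, "female", "male")
    fh_p = np.where(
        is_case,
        config.family_history_rate["case"],
        config.family_history_rate["control"],
    )
    family_history = np.where(rng.random(len(s)) < fh_p, "yes", "no")
    cohort = pd.DataFrame(
        {
            "status": status,
            "sex": sex,
            "age_at_onset": age_onset,
            "age_at_last_assessment": age_last,
            "age_at_lp": age_lp,
            "family_history": family_history,
            "platform": platform.to_numpy(),
            "pc1": rng.normal(0.0, 1.0, len(s)),
            "pc2": rng.normal(0.0, 1.0, len(s)),
        },
        index=matrix.dosages.index.copy(),
    )
    return cohort


def simulate_biomarkers(
    cohort: pd.DataFrame, scores: ScoreSet, config: SimulationConfig
) -> pd.DataFrame:
    """Draw raw CSF analyte levels per sample on each platform's own
    scale: log10 level = platform/analyte mean + beta * (PRS - mean)
    + Normal(0, sd)."""
    rng = config._rng(stage=3)
    s = scores.table.loc[cohort.index, "score"].to_numpy()
    centered = s - s.mean()
    rows = []
    for analyte, beta in config.prs_biomarker_beta.items():
        for plat in cohort["platform"].unique():
            sel = (cohort["platform"] == plat).to_numpy()
            mean = config.biomarker_log10_means[plat][analyte]
            log10 = (
                mean
                + beta * centered[sel]
                + rng.normal(0.0, config.biomarker_log10_sd, int(sel.sum()))
            )
            for sid, lvl, age in zip(
                cohort.index[sel], 10.0 ** log10, cohort.loc[sel, "age_at_lp"]
            ):
                rows.append(
                    {
                        "sample_id": sid,
                        "analyte": analyte,
                        "raw_level": lvl,
                        "platform": plat,
                        "age_at_lp": age,
                    }
                )
    return pd.DataFrame(rows, columns=["sample_id", "analyte", "raw_level", "platform", "age_at_lp"])


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[DosageMatrix, pd.DataFrame, ScoreSet, pd.DataFrame]:
    """Convenience: genotypes -> phenotypes -> PRS -> biomarkers."""
    matrix = simulate_genotypes(config)
    cohort = simulate_phenotypes(matrix, config)
    scores = compute_prs(matrix, config.panel)
    biomarkers = simulate_biomarkers(cohort, scores, config)
    return matrix, cohort, scores, biomarkers
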