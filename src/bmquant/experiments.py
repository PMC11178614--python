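"""Seeded simulation experiments over the synthetic cohort generator.

These are the calibration studies the survival stage is validated with:
confidence-interval coverage and type-I error of the univariable Cox test for
the MTV effect, the null distribution of the log-rank p-value, and the
closed-form Kaplan–Meier check on uncensored exponential data. Each function
is a pure function of its arguments (all randomness flows from the seed) and
is shared by the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from .survival import cox_fit, dichotomize_at_median, km_estimate, log_rank_test
from .synthetic import CohortConfig, generate_cohort

__all__ = [
    "cox_mtv_coverage",
    "cox_mtv_type1_error",
    "logrank_null_pvalues",
    "km_exponential_median",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n)


def cox_mtv_coverage(n_subjects: int = 500, beta_mtv: float = 0.0012,
                     n_replicates: int = 200, seed: int = 0) -> dict:
    """Fraction of replicates whose 95% Wald CI covers the true HR per mL.

    Also returns the mean HR estimate, so parameter recovery and calibration
    come from the same run.
    """
    true_hr = float(np.exp(beta_mtv))
    covered = 0
    hrs = []
    for s in _child_seeds(seed, n_replicates):
        cohort = generate_cohort(CohortConfig(
            n_subjects=n_subjects, beta_mtv_per_ml=beta_mtv, beta_cyto=0.0,
            seed=int(s)))
        fit = cox_fit(cohort, ["mtv_ml"])
        hrs.append(fit.hazard_ratios["mtv_ml"])
        if fit.ci_lower["mtv_ml"] <= true_hr <= fit.ci_upper["mtv_ml"]:
            covered += 1
    return {"coverage": covered / n_replicates, "true_hr": true_hr,
            "mean_hr": float(np.mean(hrs)), "n_replicates": n_replicates,
            "n_subjects": n_subjects}


def cox_mtv_type1_error(n_subjects: int = 500, n_replicates: int = 400,
                        seed: int = 0, alpha: float = 0.05) -> dict:
    """Rejection rate of the univariable Cox Wald test when MTV has no effect."""
    rejections = 0
    for s in _child_seeds(seed, n_replicates):
        cohort = generate_cohort(CohortConfig(
            n_subjects=n_subjects, beta_mtv_per_ml=0.0, beta_cyto=0.0,
            seed=int(s)))
        fit = cox_fit(cohort, ["mtv_ml"])
        if fit.p_values["mtv_ml"] < alpha:
            rejections += 1
    return {"type1_error": rejections / n_replicates,
            "n_replicates": n_replicates, "n_subjects": n_subjects}


def logrank_null_pvalues(n_subjects: int = 100, n_replicates: int = 1000,
                         seed: int = 0) -> np.ndarray:
    """Log-rank p-values on median-dichotomized markers unrelated to survival."""
    pvals = np.empty(n_replicates)
    rng_seeds = _child_seeds(seed, n_replicates)
    for i, s in enumerate(rng_seeds):
        rng = np.random.default_rng(s)
        time = rng.exponential(20.0, n_subjects)
        event = np.ones(n_subjects, dtype=int)
        marker = rng.normal(size=n_subjects)
        groups = dichotomize_at_median(marker)
        _, pvals[i] = log_rank_test(time, event, groups)
    return pvals


def km_exponential_median(n_subjects: int = 2000, true_median: float = 12.0,
                          seed: int = 0) -> float:
    """KM median on uncensored exponential data with the given true median."""
    rng = np.random.default_rng(seed)
    rate = np.log(2) / true_median
    times = rng.exponential(1.0 / rate, n_subjects)
    return km_estimate(times, np.ones(n_subjects)).median_months
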