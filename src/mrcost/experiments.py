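"""Reproducible Monte-Carlo experiment helpers.

Thin driver functions that repeatedly simulate cohorts under a named
scenario, run the estimator suite, and tabulate per-replicate estimates.
They exist so that the test-suite's parameter-recovery and robustness
experiments and the reporting scripts run the exact same code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimators import IVW, RAPS, MREgger, PenalizedWeightedMedian, WeightedMode
from .simulate import (
    StructuralParams,
    default_bmi_panel,
    make_two_sample_summaries,
    simulate_unrelated_cohort,
)

__all__ = ["two_sample_summaries", "recovery_replicates"]


def two_sample_summaries(
    panel, params: StructuralParams, n: int, seed: int, n_outcome: int | None = None
):
    """Simulate two disjoint cohorts from one panel and return the
    harmonized two-sample summary statistics (exposure associations from
    cohort 1 of size ``n``, outcome associations from cohort 2 of size
    ``n_outcome``, defaulting to ``n``)."""
    n_outcome = n if n_outcome is None else n_outcome
    cohort_x = simulate_unrelated_cohort(panel, params, n, seed=seed, id_start=0)
    cohort_y = simulate_unrelated_cohort(
        panel, params, n_outcome, seed=seed + 1_000_003, id_start=n
    )
    return make_two_sample_summaries(cohort_x, cohort_y)


def recovery_replicates(
    n_reps: int,
    n: int = 20_000,
    n_snps: int = 79,
    beta: float = 20.0,
    pleiotropy: str = "none",
    seed: int = 0,
    n_boot: int = 200,
    methods: tuple[str, ...] = ("ivw", "median", "mode", "raps", "egger"),
    n_outcome: int | None = None,
) -> pd.DataFrame:
    """Repeatedly simulate a two-sample study and fit the estimator suite.

    Returns one row per (replicate, method) with the point estimate, its
    standard error and (for MR-Egger) the intercept and its p-value.
    Each replicate draws a fresh SNP panel so that panel-level quantities
    (allele frequencies, effect-size spread, pleiotropy assignment) are
    averaged over rather than conditioned on.
    """
    rows = []
    params = StructuralParams(beta=beta)
    base = int(seed) % (2**31 - 1)
    for rep in range(n_reps):
        rep_seed = (base + 7_919 * rep) % (2**31 - 1)
        panel = default_bmi_panel(n_snps=n_snps, seed=rep_seed, pleiotropy=pleiotropy)
        summ = two_sample_summaries(panel, params, n, seed=rep_seed + 17, n_outcome=n_outcome)
        fits = {}
        if "ivw" in methods:
            fits["ivw"] = IVW(summ).fit("multiplicative_random")
        if "median" in methods:
            fits["median"] = PenalizedWeightedMedian(summ).fit(
                n_boot=n_boot, seed=rep_seed + 29
            )
        if "mode" in methods:
            fits["mode"] = WeightedMode(summ).fit(n_boot=n_boot, seed=rep_seed + 31)
        if "raps" in methods:
            fits["raps"] = RAPS(summ).fit()
        if "egger" in methods:
            fits["egger"] = MREgger(summ).fit()
        for name, res in fits.items():
            rows.append(
                {
                    "rep": rep,
                    "method": name,
                    "beta": res.beta,
                    "se": res.se,
                    "intercept": res.intercept if res.intercept is not None else np.nan,
                    "intercept_pval": res.intercept_pval
                    if res.intercept_pval is not None
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)
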