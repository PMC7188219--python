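"""Pipeline orchestration, policy arithmetic and reporting.

Ties the simulator, association layer, estimator suite and sensitivity
analyses into one reproducible run driven by a declarative config: same
config + seed ⇒ byte-identical outputs.  Also houses the small exact
arithmetic used for policy projection (population × ΔBMI × £/unit) and
currency conversion.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mrio
from .assoc import allele_score, instrument_diagnostics
from .estimators import (
    IVW,
    RAPS,
    MREgger,
    PenalizedWeightedMedian,
    WeightedMode,
    wald_ratio,
)
from .exceptions import PipelineStageError
from .individual import (
    NonlinearMR,
    clustered_iv,
    conventional_estimates,
    family_fixed_effect_iv,
    gxe_interaction_mr,
)
from .simulate import (
    StructuralParams,
    default_bmi_panel,
    make_two_sample_summaries,
    simulate_family_cohort,
    simulate_unrelated_cohort,
)

__all__ = [
    "PolicyProjection",
    "policy_cost_projection",
    "currency_convert",
    "PipelineConfig",
    "SCENARIOS",
    "run_pipeline",
    "forest_and_scatter_tables",
]

SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# exact policy arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolicyProjection:
    """Back-of-the-envelope annual cost of a population-wide exposure shift.

    ``total_cost`` is exactly population × delta_exposure × beta, carried
    at full floating precision (rounding happens only at display time).
    """

    population: float
    delta_exposure: float
    beta: float

    @property
    def total_cost(self) -> float:
        return self.population * self.delta_exposure * self.beta

    def difference(self, other: "PolicyProjection") -> float:
        return self.total_cost - other.total_cost


def policy_cost_projection(
    population: float, delta_exposure: float, beta: float
) -> PolicyProjection:
    if population < 0:
        raise ValueError("population must be non-negative")
    for v in (population, delta_exposure, beta):
        if not np.isfinite(v):
            raise ValueError("policy projection inputs must be finite")
    return PolicyProjection(population, delta_exposure, beta)


def currency_convert(amount_usd: float, usd_per_gbp: float) -> float:
    """US dollars to pounds sterling at ``usd_per_gbp`` dollars per pound.

    Returns full precision; round to 2 decimals only for display.
    """
    if usd_per_gbp <= 0:
        raise ValueError("exchange rate must be positive")
    return amount_usd / usd_per_gbp


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Scenario presets: panel and structural-parameter settings by name.
SCENARIOS: dict[str, dict] = {
    "no-pleiotropy": {"panel": {"pleiotropy": "none"}, "params": {}},
    "balanced-pleiotropy": {"panel": {"pleiotropy": "balanced"}, "params": {}},
    "directional-pleiotropy": {"panel": {"pleiotropy": "directional"}, "params": {}},
    "confounder-pleiotropy": {"panel": {"pleiotropy": "confounder-mediated"}, "params": {}},
    "dynastic": {"panel": {"pleiotropy": "none"}, "params": {"dynastic_effect": 10.0}},
    "quadratic": {"panel": {"pleiotropy": "none"}, "params": {"beta_quadratic": 2.5}},
    "gxe": {"panel": {"pleiotropy": "none"}, "params": {"gxe_strength": 0.5}},
}


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative description of a full run; unknown keys are rejected."""

    seed: int = 1
    n_exposure: int = 20_000
    n_outcome: int = 20_000
    n_snps: int = 79
    beta: float = 20.0
    scenario: str = "no-pleiotropy"
    estimators: tuple[str, ...] = ("ivw", "egger", "median", "mode", "raps")
    k_strata: int = 100
    n_boot: int = 500
    n_families: int = 0
    run_nonlinear: bool = False
    run_family: bool = False
    run_gxe: bool = False
    run_conventional: bool = True
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("n_exposure", "n_outcome", "n_snps", "k_strata", "n_boot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; registered: {sorted(SCENARIOS)}"
            )
        unknown = [e for e in self.estimators if e not in _ESTIMATOR_REGISTRY]
        if unknown:
            raise ValueError(f"unknown estimator(s): {unknown}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "estimators" in data:
            data["estimators"] = tuple(data["estimators"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["estimators"] = list(d["estimators"])
        return d

    def science_dict(self) -> dict:
        """Config without execution details (output location)."""
        return {k: v for k, v in self.to_dict().items() if k != "out_dir"}

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.science_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _fit_ivw(s, cfg, seed):
    return IVW(s).fit("multiplicative_random")


def _fit_egger(s, cfg, seed):
    return MREgger(s).fit()


def _fit_median(s, cfg, seed):
    return PenalizedWeightedMedian(s).fit(n_boot=cfg.n_boot, seed=seed + 101)


def _fit_mode(s, cfg, seed):
    return WeightedMode(s).fit(n_boot=cfg.n_boot, seed=seed + 103)


def _fit_raps(s, cfg, seed):
    return RAPS(s).fit()


_ESTIMATOR_REGISTRY = {
    "ivw": _fit_ivw,
    "egger": _fit_egger,
    "median": _fit_median,
    "mode": _fit_mode,
    "raps": _fit_raps,
}


# ---------------------------------------------------------------------------
# plot-data tables
# ---------------------------------------------------------------------------

def forest_and_scatter_tables(summaries, estimates: list) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forest-plot and scatter-plot data as tidy tables.

    The forest table carries one per-SNP Wald-ratio row (95 % CI, ordered
    by effect size, largest first) followed by one summary row per
    estimator; the scatter table carries the per-SNP (γ̂, Γ̂) pairs with
    CIs plus per-method fitted lines.
    """
    k = summaries.kept
    if len(k) == 0:
        raise ValueError("no SNPs to plot")
    ratios = [
        wald_ratio(g, sx, G, sy, snp_id=s)
        for s, g, sx, G, sy in zip(
            k["snp"], k["beta_exposure"], k["se_exposure"], k["beta_outcome"], k["se_outcome"]
        )
    ]
    forest = pd.DataFrame(
        {
            "label": [r.snp_id for r in ratios],
            "kind": "snp",
            "beta": [r.ratio for r in ratios],
            "se": [r.se_ratio for r in ratios],
        }
    ).sort_values("beta", ascending=False, kind="stable")
    rows = [forest]
    for res in estimates:
        rows.append(
            pd.DataFrame(
                {"label": [res.method], "kind": "summary", "beta": [res.beta], "se": [res.se]}
            )
        )
    forest = pd.concat(rows, ignore_index=True)
    forest["ci_low"] = forest["beta"] - 1.96 * forest["se"]
    forest["ci_high"] = forest["beta"] + 1.96 * forest["se"]

    scatter = pd.DataFrame(
        {
            "snp": k["snp"].to_numpy(),
            "gamma": k["beta_exposure"].to_numpy(),
            "gamma_low": (k["beta_exposure"] - 1.96 * k["se_exposure"]).to_numpy(),
            "gamma_high": (k["beta_exposure"] + 1.96 * k["se_exposure"]).to_numpy(),
            "Gamma": k["beta_outcome"].to_numpy(),
            "Gamma_low": (k["beta_outcome"] - 1.96 * k["se_outcome"]).to_numpy(),
            "Gamma_high": (k["beta_outcome"] + 1.96 * k["se_outcome"]).to_numpy(),
        }
    )
    lines = pd.DataFrame(
        {
            "snp": [f"__line_{r.method}" for r in estimates],
            "gamma": 0.0,
            "gamma_low": np.nan,
            "gamma_high": np.nan,
            "Gamma": [r.intercept if r.intercept is not None else 0.0 for r in estimates],
            "Gamma_low": [r.beta for r in estimates],  # slope stored here
            "Gamma_high": np.nan,
        }
    )
    return forest, pd.concat([scatter, lines], ignore_index=True)


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate, associate, estimate and report; returns the bundle dict.

    Writes under ``config.out_dir``: harmonized summaries, the tidy
    estimates table, forest/scatter plot data, a versioned JSON summary
    (deterministic given config + seed) and a log with per-stage timings.
    Stage failures raise :class:`PipelineStageError` carrying the stage
    name; outputs written before the failure are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    bundle: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config": config.science_dict(),
        "config_digest": config.digest(),
    }
    scenario = SCENARIOS[config.scenario]
    params = StructuralParams(beta=config.beta, **scenario["params"])
    seed = int(config.seed)

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except PipelineStageError:
            raise
        except Exception as exc:
            record = {"stage": name, "error": type(exc).__name__, "message": str(exc)}
            (out / "error.json").write_text(json.dumps(record, indent=2))
            raise PipelineStageError(name, str(exc)) from exc
        log_lines.append(f"INFO stage={name} elapsed={time.perf_counter() - t0:.2f}s")
        return result

    panel = stage(
        "simulate", lambda: default_bmi_panel(n_snps=config.n_snps, seed=seed, **scenario["panel"])
    )
    cohort_x = stage(
        "simulate-exposure-cohort",
        lambda: simulate_unrelated_cohort(panel, params, config.n_exposure, seed=seed + 1),
    )
    cohort_y = stage(
        "simulate-outcome-cohort",
        lambda: simulate_unrelated_cohort(
            panel, params, config.n_outcome, seed=seed + 2, id_start=config.n_exposure
        ),
    )
    summaries = stage("assoc", lambda: make_two_sample_summaries(cohort_x, cohort_y))
    mrio.write_summary_stats(summaries.to_association_frames()[0], out / "exposure_assoc.tsv")
    mrio.write_summary_stats(summaries.to_association_frames()[1], out / "outcome_assoc.tsv")
    summaries.table.to_csv(out / "harmonized.tsv", sep="\t", index=False)

    estimates = [
        stage(f"estimate-{name}", lambda name=name: _ESTIMATOR_REGISTRY[name](summaries, config, seed))
        for name in config.estimators
    ]
    est_frame = pd.DataFrame([r.to_dict() for r in estimates])
    est_frame.to_csv(out / "estimates.tsv", sep="\t", index=False)
    bundle["estimates"] = [r.to_dict() for r in estimates]

    # instrument diagnostics on the outcome cohort with exposure-sample weights
    weights = pd.Series(summaries.gamma, index=summaries.snp_ids)
    score = stage("allele-score", lambda: allele_score(cohort_y, weights, orient=True))
    diag = stage(
        "diagnostics",
        lambda: instrument_diagnostics(cohort_y, score, list(cohort_y.covariates.columns)),
    )
    bundle["diagnostics"] = {
        "f_statistic": diag.f_statistic,
        "r_squared": diag.r_squared,
        "balance_pvals": diag.score_covariate_pvals.to_dict(),
    }

    if config.run_conventional:
        ols, glm = stage("conventional", lambda: conventional_estimates(cohort_y))
        bundle["conventional"] = {
            "ols": ols.to_dict(),
            "glm": glm.to_dict() if glm is not None else None,
        }
    if config.run_nonlinear:
        nl = stage("nonlinear", lambda: NonlinearMR(cohort_y, score, K=config.k_strata).fit())
        nl.frame().to_csv(out / "lace.tsv", sep="\t", index=False)
        bundle["nonlinear"] = {
            "fracpoly_d1_vs_linear_pval": nl.fracpoly_d1_vs_linear_pval,
            "fracpoly_d2_vs_d1_pval": nl.fracpoly_d2_vs_d1_pval,
            "quadratic_pval": nl.quadratic_pval,
            "trend_pval": nl.trend_pval,
            "first_stage_heterogeneity_pval": nl.first_stage_heterogeneity_pval,
        }
    if config.run_family and config.n_families > 0:
        fam_cohort = stage(
            "simulate-family",
            lambda: simulate_family_cohort(panel, params, config.n_families, seed=seed + 3),
        )
        fam_score = allele_score(
            fam_cohort, pd.Series(summaries.gamma, index=summaries.snp_ids), orient=True
        )
        fe = stage("family", lambda: family_fixed_effect_iv(fam_cohort, fam_score))
        cl = stage("family-clustered", lambda: clustered_iv(fam_cohort, fam_score))
        bundle["family"] = {
            "fixed_effects": dataclasses.asdict(fe),
            "clustered_only": dataclasses.asdict(cl),
        }
    if config.run_gxe:
        gxe = stage("gxe", lambda: gxe_interaction_mr(cohort_y, score))
        bundle["gxe"] = gxe.to_dict()

    forest, scatter = stage(
        "report", lambda: forest_and_scatter_tables(summaries, estimates)
    )
    forest.to_csv(out / "forest.tsv", sep="\t", index=False)
    scatter.to_csv(out / "scatter.tsv", sep="\t", index=False)

    bundle["targets"] = {
        "policy_projection_50m_1unit_median": policy_cost_projection(
            50_000_000, 1.0, next(
                (r.beta for r in estimates if r.method == "Penalized weighted median"),
                estimates[0].beta,
            )
        ).total_cost,
        "currency_usd54_at_1p82": currency_convert(54.0, 1.82),
    }

    (out / "summary.json").write_text(
        json.dumps(_round_floats(bundle), indent=2, sort_keys=True) + "\n"
    )
    mrio.write_sidecar(out / "summary.json", config.to_dict(), config.seed)
    log_lines.append(f"INFO run complete seed={config.seed} digest={config.digest()}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return bundle
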