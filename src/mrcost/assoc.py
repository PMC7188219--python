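"""Per-SNP association estimation, harmonization, clumping and scores.

This is the layer between raw data and the MR estimators: it turns a
cohort into GWAS-style per-SNP summary statistics, aligns two sets of
summary statistics onto a common effect allele, prunes correlated SNPs,
builds weighted allele scores and reports instrument-strength
diagnostics.

Summary-statistic tables use a fixed header throughout:
``snp, chr, pos, effect_allele, other_allele, eaf, beta, se, pval, n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .exceptions import DegenerateSnpWarning, HarmonizationError

__all__ = [
    "SUMMARY_COLUMNS",
    "HarmonizedSummaries",
    "InstrumentDiagnostics",
    "per_snp_regression",
    "harmonize",
    "ld_clump",
    "allele_score",
    "instrument_diagnostics",
]

SUMMARY_COLUMNS = [
    "snp",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMES = ({"A", "T"}, {"C", "G"})

GENOME_WIDE_P = 5e-8  # genome-wide significance threshold for exposure hits


def genome_wide_significant(assocs: pd.DataFrame, p_threshold: float = GENOME_WIDE_P) -> pd.DataFrame:
    """Restrict exposure associations to genome-wide-significant hits.

    Applied to exposure summaries only (instrument selection); simulated
    panels emulate an already-selected instrument list, so the pipeline
    does not re-filter them.
    """
    return assocs[assocs["pval"] <= p_threshold].reset_index(drop=True)


# ---------------------------------------------------------------------------
# per-SNP regression
# ---------------------------------------------------------------------------

def _design(cohort: Cohort, covariate_names: list[str]) -> np.ndarray:
    cols = [np.ones(cohort.n)]
    for name in covariate_names:
        cols.append(np.asarray(cohort.covariates[name], dtype=float))
    return np.column_stack(cols)


def per_snp_regression(
    cohort: Cohort,
    trait_name: str,
    covariate_names: list[str] | None = None,
    robust: bool | None = None,
) -> pd.DataFrame:
    """Marginal OLS of a trait on each SNP dosage plus covariates.

    Implemented in closed form via Frisch–Waugh–Lovell residualisation so
    that thousands of SNP regressions cost one matrix solve; identical to
    per-SNP OLS (checked against statsmodels to 1e-10 in the tests).
    P-values are two-sided against the normal reference.  Monomorphic
    (constant-dosage) SNPs are excluded with a warning.

    Standard errors are heteroskedasticity-robust (HC1) for the cost
    outcome — whose two-part, right-skewed distribution has variance
    rising with its mean — and classical for the (near-homoskedastic)
    exposure traits; pass ``robust`` to override.
    """
    covariate_names = list(covariate_names or [])
    y = {
        "exposure": cohort.exposure,
        "exposure2": cohort.exposure2,
        "cost": cohort.cost,
    }.get(trait_name)
    if y is None:
        raise ValueError(f"trait {trait_name!r} not present in cohort")
    y = np.asarray(y, dtype=float)
    g = cohort.genotypes.astype(float)
    n, j = g.shape

    keep = g.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} monomorphic SNP(s) excluded from per-SNP regression",
            DegenerateSnpWarning,
            stacklevel=2,
        )
    z = _design(cohort, covariate_names)
    p = z.shape[1]
    if n <= p + 1:
        raise ValueError("sample too small for the requested regression")
    # residualize trait and dosages on the covariate block
    zty = z.T @ y
    ztg = z.T @ g
    ztz = z.T @ z
    y_res = y - z @ np.linalg.solve(ztz, zty)
    g_res = g - z @ np.linalg.solve(ztz, ztg)

    if robust is None:
        robust = trait_name == "cost"
    gg = np.einsum("ij,ij->j", g_res, g_res)
    gy = g_res.T @ y_res
    yy = float(y_res @ y_res)
    dof = n - p - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(gg > 0, gy / np.where(gg > 0, gg, 1.0), np.nan)
        if robust:
            # HC1 sandwich: Σ g̃²ê² expanded in per-column moments
            a = np.einsum("ij,i->j", g_res**2, y_res**2)
            b = np.einsum("ij,i->j", g_res**3, y_res)
            c = np.einsum("ij->j", g_res**4)
            meat = np.maximum(a - 2 * beta * b + beta**2 * c, 0.0)
            se = np.sqrt(n / dof * meat / np.where(gg > 0, gg, 1.0) ** 2)
            se = np.where(gg > 0, se, np.nan)
        else:
            ssr = np.maximum(yy - beta**2 * gg, 0.0)
            sigma2 = ssr / dof
            se = np.sqrt(np.where(gg > 0, sigma2 / np.where(gg > 0, gg, 1.0), np.nan))
    with np.errstate(invalid="ignore", divide="ignore"):
        zstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.where(beta == 0, 0.0, np.inf))
    pval = 2.0 * stats.norm.sf(np.abs(zstat))

    info = cohort.snp_info
    out = pd.DataFrame(
        {
            "snp": info["snp_id"].to_numpy(),
            "chr": info["chrom"].to_numpy(),
            "pos": info["pos_bp"].to_numpy(),
            "effect_allele": info["effect_allele"].to_numpy(),
            "other_allele": info["other_allele"].to_numpy(),
            "eaf": g.mean(axis=0) / 2.0,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n,
        }
    )
    return out.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizedSummaries:
    """Aligned per-SNP exposure and outcome associations.

    ``table`` has one row per matched SNP with columns
    ``snp, effect_allele, other_allele, eaf_exposure, eaf_outcome,
    beta_exposure, se_exposure, beta_outcome, se_outcome, n_exposure,
    n_outcome, disposition``.  Dispositions are ``kept``, ``flipped``,
    ``dropped-palindromic``, ``dropped-triallelic`` or ``dropped-clumped``.
    Estimator-facing accessors expose the retained SNPs only.
    """

    table: pd.DataFrame

    _KEPT = ("kept", "flipped")

    @property
    def kept(self) -> pd.DataFrame:
        return self.table[self.table["disposition"].isin(self._KEPT)]

    @property
    def n_snps(self) -> int:
        return len(self.kept)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.kept["snp"].to_numpy()

    @property
    def gamma(self) -> np.ndarray:
        """SNP→exposure estimates γ̂_j."""
        return self.kept["beta_exposure"].to_numpy(dtype=float)

    @property
    def se_x(self) -> np.ndarray:
        return self.kept["se_exposure"].to_numpy(dtype=float)

    @property
    def Gamma(self) -> np.ndarray:
        """SNP→outcome estimates Γ̂_j."""
        return self.kept["beta_outcome"].to_numpy(dtype=float)

    @property
    def se_y(self) -> np.ndarray:
        return self.kept["se_outcome"].to_numpy(dtype=float)

    def drop_clumped(self, kept_ids) -> "HarmonizedSummaries":
        """Mark SNPs outside ``kept_ids`` as dropped-clumped."""
        table = self.table.copy()
        mask = table["disposition"].isin(self._KEPT) & ~table["snp"].isin(list(kept_ids))
        table.loc[mask, "disposition"] = "dropped-clumped"
        return HarmonizedSummaries(table)

    @classmethod
    def from_aligned(cls, exposure: pd.DataFrame, outcome: pd.DataFrame) -> "HarmonizedSummaries":
        """Build from two association tables already on the same allele."""
        merged = exposure.merge(
            outcome, on="snp", suffixes=("_exposure", "_outcome"), validate="1:1"
        )
        table = pd.DataFrame(
            {
                "snp": merged["snp"],
                "effect_allele": merged["effect_allele_exposure"],
                "other_allele": merged["other_allele_exposure"],
                "eaf_exposure": merged["eaf_exposure"],
                "eaf_outcome": merged["eaf_outcome"],
                "beta_exposure": merged["beta_exposure"],
                "se_exposure": merged["se_exposure"],
                "beta_outcome": merged["beta_outcome"],
                "se_outcome": merged["se_outcome"],
                "n_exposure": merged["n_exposure"],
                "n_outcome": merged["n_outcome"],
                "disposition": "kept",
            }
        )
        return cls(table)

    def to_association_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Rebuild (exposure, outcome) association tables for the kept SNPs."""
        k = self.kept
        def _frame(side: str) -> pd.DataFrame:
            return pd.DataFrame(
                {
                    "snp": k["snp"],
                    "chr": 0,
                    "pos": 0,
                    "effect_allele": k["effect_allele"],
                    "other_allele": k["other_allele"],
                    "eaf": k[f"eaf_{side}"],
                    "beta": k[f"beta_{side}"],
                    "se": k[f"se_{side}"],
                    "pval": 2 * stats.norm.sf(np.abs(k[f"beta_{side}"] / k[f"se_{side}"])),
                    "n": k[f"n_{side}"],
                }
            ).reset_index(drop=True)
        return _frame("exposure"), _frame("outcome")


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in _PALINDROMES


def harmonize(
    exposure_assocs: pd.DataFrame,
    outcome_assocs: pd.DataFrame,
    palindromic_eaf_window: float = 0.08,
) -> HarmonizedSummaries:
    """Align outcome associations onto the exposure effect allele.

    Rules, applied per SNP matched on id:

    * same alleles (directly or after strand complement): kept as-is;
    * swapped alleles: outcome beta sign flipped, eaf complemented;
    * palindromic (A/T, C/G) SNPs: strand is ambiguous, so they are kept
      only when both allele frequencies are on the same side of 0.5 and
      both lie outside 0.5 ± ``palindromic_eaf_window``, otherwise
      dropped as unreconciled;
    * any other allele configuration: dropped as triallelic/irreconcilable.
    """
    for name, frame in (("exposure", exposure_assocs), ("outcome", outcome_assocs)):
        if frame["snp"].duplicated().any():
            raise HarmonizationError(f"duplicate snp ids in {name} associations")
    merged = exposure_assocs.merge(
        outcome_assocs, on="snp", suffixes=("_x", "_y"), validate="1:1"
    )

    rows = []
    for rec in merged.itertuples(index=False):
        ea_x, oa_x = rec.effect_allele_x, rec.other_allele_x
        ea_y, oa_y = rec.effect_allele_y, rec.other_allele_y
        beta_y, eaf_y = rec.beta_y, rec.eaf_y
        disposition = None

        valid = all(a in _COMPLEMENT for a in (ea_x, oa_x, ea_y, oa_y))
        if not valid or ea_x == oa_x or ea_y == oa_y:
            disposition = "dropped-triallelic"
        elif _is_palindromic(ea_x, oa_x):
            if {ea_y, oa_y} != {ea_x, oa_x}:
                disposition = "dropped-triallelic"
            else:
                w = palindromic_eaf_window
                near = abs(rec.eaf_x - 0.5) < w or abs(eaf_y - 0.5) < w
                same_side = (rec.eaf_x - 0.5) * (eaf_y - 0.5) > 0
                if near or not same_side:
                    disposition = "dropped-palindromic"
                else:
                    # frequencies agree on which allele is which; labels
                    # cannot settle strand for palindromes, so keep as-is
                    disposition = "kept"
        else:
            pair_y = {ea_y, oa_y}
            if pair_y == {ea_x, oa_x}:
                flipped = ea_y != ea_x
            elif pair_y == {_COMPLEMENT[ea_x], _COMPLEMENT[oa_x]}:
                flipped = ea_y != _COMPLEMENT[ea_x]  # other strand
            else:
                flipped = None
                disposition = "dropped-triallelic"
            if flipped is not None:
                if flipped:
                    beta_y = -beta_y
                    eaf_y = 1.0 - eaf_y
                    disposition = "flipped"
                else:
                    disposition = "kept"

        rows.append(
            {
                "snp": rec.snp,
                "effect_allele": ea_x,
                "other_allele": oa_x,
                "eaf_exposure": rec.eaf_x,
                "eaf_outcome": eaf_y,
                "beta_exposure": rec.beta_x,
                "se_exposure": rec.se_x,
                "beta_outcome": beta_y,
                "se_outcome": rec.se_y,
                "n_exposure": rec.n_x,
                "n_outcome": rec.n_y,
                "disposition": disposition,
            }
        )
    return HarmonizedSummaries(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------

def ld_clump(
    assocs: pd.DataFrame,
    positions: pd.DataFrame | None = None,
    ld_matrix: np.ndarray | pd.DataFrame | None = None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
) -> list[str]:
    """Greedy LD clumping: keep SNPs by ascending p-value, dropping any
    SNP within ``window_kb`` of an already-kept SNP on the same chromosome
    with squared correlation at or above ``r2_threshold``.

    ``positions`` defaults to the chr/pos columns of ``assocs``;
    ``ld_matrix`` may be a DataFrame indexed by snp id or an array aligned
    with the rows of ``assocs``.  Ties in p-value break on snp id.
    """
    snps = assocs["snp"].to_numpy()
    if positions is None:
        positions = assocs[["snp", "chr", "pos"]]
    pos = positions.set_index("snp")
    missing = [s for s in snps if s not in pos.index]
    if missing:
        raise ValueError(f"missing position for SNP(s): {missing[:5]}")

    if ld_matrix is None:
        r2 = np.eye(len(snps))
    elif isinstance(ld_matrix, pd.DataFrame):
        r2 = ld_matrix.loc[snps, snps].to_numpy(dtype=float)
    else:
        r2 = np.asarray(ld_matrix, dtype=float)
    if r2.shape != (len(snps), len(snps)):
        raise ValueError("ld_matrix shape does not match associations")
    if not np.allclose(r2, r2.T) or not np.allclose(np.diag(r2), 1.0):
        raise ValueError("ld_matrix must be symmetric with unit diagonal")

    order = np.lexsort((snps, assocs["pval"].to_numpy()))
    chrom = pos.loc[snps, "chr"].to_numpy()
    bp = pos.loc[snps, "pos"].to_numpy(dtype=float)

    kept: list[int] = []
    for i in order:
        clash = any(
            chrom[i] == chrom[k]
            and abs(bp[i] - bp[k]) <= window_kb * 1000.0
            and r2[i, k] >= r2_threshold
            for k in kept
        )
        if not clash:
            kept.append(i)
    kept_ids = set(snps[kept])
    return [s for s in snps if s in kept_ids]  # input order


# ---------------------------------------------------------------------------
# allele scores and diagnostics
# ---------------------------------------------------------------------------

def allele_score(cohort: Cohort, weights, orient: bool = False) -> np.ndarray:
    """Weighted sum of effect-allele dosages, score_i = Σ_j w_j G_ij.

    Weights are a mapping/Series keyed by snp id, oriented so each weight
    is the effect of the exposure-increasing allele (all weights ≥ 0).
    With ``orient=True`` negative weights are re-oriented internally by
    counting the opposite allele (2 − dosage), which changes the score
    only by a constant.
    """
    w = pd.Series(weights, dtype=float)
    missing = [s for s in w.index if s not in cohort.snp_ids]
    if missing:
        raise ValueError(f"weights refer to SNP(s) absent from the cohort: {missing[:5]}")
    if not orient and (w < 0).any():
        raise ValueError("weights must be oriented to the exposure-increasing allele")
    cols = [cohort.snp_ids.index(s) for s in w.index]
    g = cohort.genotypes[:, cols].astype(float)
    wv = w.to_numpy()
    if orient:
        neg = wv < 0
        g[:, neg] = 2.0 - g[:, neg]
        wv = np.abs(wv)
    return g @ wv


@dataclass
class InstrumentDiagnostics:
    """First-stage strength and covariate-balance summary."""

    f_statistic: float
    r_squared: float
    score_covariate_pvals: pd.Series
    f_capped: bool = False

    def __post_init__(self) -> None:
        if self.f_statistic < 0:
            raise ValueError("F-statistic must be non-negative")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")


def instrument_diagnostics(
    cohort: Cohort, score: np.ndarray, covariate_names: list[str] | None = None
) -> InstrumentDiagnostics:
    """First-stage F for exposure~score, variance in the exposure explained
    by the SNP set, and score-vs-covariate balance p-values.

    A perfect instrument (R² = 1) yields an infinite F, reported as
    ``inf`` with ``f_capped=True``.
    """
    import statsmodels.api as sm

    covariate_names = list(covariate_names or cohort.covariates.columns)
    score = np.asarray(score, dtype=float)
    if score.std() == 0:
        raise ValueError("score is constant; diagnostics undefined")
    if cohort.n <= len(covariate_names) + 2:
        raise ValueError("sample too small for the requested diagnostics")

    exog = sm.add_constant(np.column_stack([score, _design(cohort, covariate_names)[:, 1:]]))
    fit = sm.OLS(cohort.exposure, exog).fit()
    t_score = fit.tvalues[1]
    f_stat = float(t_score**2)
    capped = not np.isfinite(f_stat)
    if capped:
        f_stat = np.inf

    # variance in exposure explained by the SNPs jointly
    g = sm.add_constant(cohort.genotypes.astype(float))
    r2 = float(sm.OLS(cohort.exposure, g).fit().rsquared)
    r2 = min(max(r2, 0.0), 1.0)

    pvals = {}
    for name in covariate_names:
        x = sm.add_constant(np.asarray(cohort.covariates[name], dtype=float))
        pvals[name] = float(sm.OLS(score, x).fit().pvalues[1])
    return InstrumentDiagnostics(
        f_statistic=np.inf if capped else f_stat,
        r_squared=r2,
        score_covariate_pvals=pd.Series(pvals),
        f_capped=capped or r2 >= 1.0,
    )
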