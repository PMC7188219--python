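"""Individual-level cohort container.

A :class:`Cohort` is the package's in-memory representation of a
biobank-style analysis table: a dosage matrix (0/1/2 copies of the effect
allele per SNP), one or two continuous exposures (BMI in kg/m², optionally
body-fat %), a non-negative per-person-year cost outcome in pounds
sterling, a covariate table, and an optional family identifier for
sibling designs.  The (hidden) confounder used by the simulator is kept on
the object so that tests can condition on the truth; real data simply
leaves it ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Cohort"]

#: Column order used when a cohort is written as a delimited table.
_PHENO_COLUMNS = ("id", "family_id", "exposure", "exposure2", "cost")


@dataclass
class Cohort:
    """Genotypes, phenotypes and covariates for one analysis sample.

    Parameters
    ----------
    genotypes : (n, J) integer array
        Effect-allele dosages in {0, 1, 2}; column j corresponds to
        ``snp_info.iloc[j]``.
    snp_info : DataFrame
        Per-SNP metadata with columns ``snp_id, chrom, pos_bp,
        effect_allele, other_allele, eaf`` (one row per genotype column).
    exposure : (n,) array
        Primary continuous exposure (kg/m²).
    cost : (n,) array
        Outcome, £ per person-year, all values ≥ 0.
    covariates : DataFrame
        Individual covariates (sex, age, deprivation, PC proxies, ...).
    exposure2 : optional (n,) array
        Secondary exposure (body-fat %) for multivariable MR.
    family_id : optional (n,) integer array
        Family membership for sibling cohorts.
    confounder : optional (n,) array
        Hidden confounder, retained by the simulator for testing only.
    ids : optional (n,) integer array
        Unique individual identifiers (used to detect sample overlap).
    """

    genotypes: np.ndarray
    snp_info: pd.DataFrame
    exposure: np.ndarray
    cost: np.ndarray
    covariates: pd.DataFrame
    exposure2: np.ndarray | None = None
    family_id: np.ndarray | None = None
    confounder: np.ndarray | None = None
    ids: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.exposure = np.asarray(self.exposure, dtype=float)
        self.cost = np.asarray(self.cost, dtype=float)
        n, j = self.genotypes.shape
        if len(self.snp_info) != j:
            raise ValueError("snp_info rows must match genotype columns")
        if self.exposure.shape != (n,) or self.cost.shape != (n,):
            raise ValueError("exposure/cost length must match genotype rows")
        if np.any(self.cost < 0):
            raise ValueError("cost values must be non-negative")
        vals = np.unique(self.genotypes)
        if not np.isin(vals, (0, 1, 2)).all():
            raise ValueError("genotype dosages must be in {0, 1, 2}")
        if self.ids is None:
            self.ids = np.arange(n)
        else:
            self.ids = np.asarray(self.ids)
            if len(np.unique(self.ids)) != n:
                raise ValueError("individual ids must be unique")
        if self.family_id is not None:
            self.family_id = np.asarray(self.family_id)

    # -- basic geometry ------------------------------------------------
    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_info["snp_id"])

    def dosage(self, snp_id: str) -> np.ndarray:
        j = self.snp_ids.index(snp_id)
        return self.genotypes[:, j]

    # -- serialisation -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """One row per individual; genotype columns named by snp_id."""
        out = pd.DataFrame({"id": self.ids})
        out["family_id"] = self.family_id if self.family_id is not None else -1
        out["exposure"] = self.exposure
        out["exposure2"] = self.exposure2 if self.exposure2 is not None else np.nan
        out["cost"] = self.cost
        for c in self.covariates.columns:
            out[c] = np.asarray(self.covariates[c])
        geno = pd.DataFrame(self.genotypes, columns=self.snp_ids)
        return pd.concat([out, geno], axis=1)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, snp_info: pd.DataFrame) -> "Cohort":
        snp_cols = list(snp_info["snp_id"])
        cov_cols = [c for c in frame.columns if c not in _PHENO_COLUMNS and c not in snp_cols]
        exposure2 = frame["exposure2"].to_numpy()
        if np.isnan(exposure2).all():
            exposure2 = None
        family = frame["family_id"].to_numpy()
        if (family == -1).all():
            family = None
        return cls(
            genotypes=frame[snp_cols].to_numpy(dtype=np.int8),
            snp_info=snp_info.reset_index(drop=True),
            exposure=frame["exposure"].to_numpy(),
            cost=frame["cost"].to_numpy(),
            covariates=frame[cov_cols].copy(),
            exposure2=exposure2,
            family_id=family,
            ids=frame["id"].to_numpy(),
        )
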