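"""Phenotypic PCA and genetic-vs-phenotypic comparison statistics.

The phenotypic arm mirrors the genetic one: a Pearson correlation matrix
of the raw (optionally covariate-residualised) trait values is
eigendecomposed through exactly the same conventions as the genetic PCA,
so loadings and variance explained are directly comparable.  Congruence
between the two domains is quantified by ordinary least squares on the
stacked correlation vectors / loading vectors and by the Tucker
congruence coefficient

    φ(a, b) = Σ a_i b_i / √(Σ a_i² · Σ b_i²),

which is sensitive to both the ordering and the absolute magnitude of the
loadings.  Age sensitivity is a trait's cross-sectional Pearson
correlation with chronological age.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, InsufficientDataError
from .pca import PcaResult, eigen_pca


@dataclass
class PhenotypeMatrix:
    """Subjects × traits continuous measures with optional covariates."""

    subject_ids: list
    labels: list
    values: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape
        if len(self.subject_ids) != n or len(self.labels) != k:
            raise InputError("phenotype matrix shape/labels mismatch")
        if n < 3:
            raise InputError("phenotype matrix needs >= 3 subjects")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim == 1:
                self.covariates = self.covariates[:, None]
            if self.covariates.shape[0] != n:
                raise InputError("covariates row count mismatch")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids,
                            columns=self.labels)


def read_phenotypes(path, id_column: str = "subject_id",
                    covariate_columns: Sequence[str] = ()) -> PhenotypeMatrix:
    """Read a delimited subjects × traits table with a subject-id column."""
    df = pd.read_csv(path, sep=r"\s+|,|\t", engine="python", comment="#")
    if id_column not in df.columns:
        raise InputError(f"{path}: missing id column {id_column!r}")
    ids = df[id_column].tolist()
    cov = None
    if covariate_columns:
        cov = df[list(covariate_columns)].to_numpy(float)
    traits = [c for c in df.columns
              if c != id_column and c not in covariate_columns]
    return PhenotypeMatrix(ids, traits, df[traits].to_numpy(float), cov)


@dataclass
class VectorComparison:
    """OLS summary for one numeric vector regressed on another."""

    slope: float
    intercept: float
    r: float
    r2: float
    n: int
    p_value: float


def _residualise(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(values)), covariates])
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ coef


def phenotypic_pca(pm: PhenotypeMatrix, residualise: bool = False) -> PcaResult:
    """PCA of the phenotypic Pearson correlation matrix.

    Covariate residualisation (least squares, intercept included) is
    applied per trait when requested.  Correlations use pairwise-complete
    observations; the eigen path is shared with the genetic PCA so that
    conventions (ordering, signs, loading scale) are identical.
    """
    vals = pm.values
    if residualise:
        if pm.covariates is None:
            raise InputError("residualise=True but no covariates supplied")
        vals = _residualise(vals, pm.covariates)
    sds = np.nanstd(vals, axis=0)
    const = np.where(sds < 1e-12)[0]
    if const.size:
        names = [pm.labels[i] for i in const]
        raise InputError(f"constant trait column(s) after residualisation: "
                         f"{names}")
    corr = pd.DataFrame(vals, columns=pm.labels).corr().to_numpy()
    if np.isnan(corr).any():
        raise InsufficientDataError("pairwise-complete correlations undefined "
                                    "for some trait pair")
    # pairwise deletion can leave a slightly indefinite matrix
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        from .ldsc import nearest_pd
        corr = nearest_pd(corr)
    return eigen_pca(corr, pm.labels, domain_tag="phenotypic")


def tucker_congruence(a: Sequence[float], b: Sequence[float]) -> float:
    """Tucker congruence coefficient of two loading vectors, in [−1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise InputError("tucker_congruence needs two equal-length vectors (>= 2)")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise InputError("zero-norm loading vector")
    return float(a @ b / (na * nb))


def compare_vectors(x: Sequence[float], y: Sequence[float]) -> VectorComparison:
    """OLS of y on x with intercept, plus Pearson r and two-sided p.

    The p-value uses the t distribution with n−2 df; when the vectors are
    stacked correlation-matrix cells the entries are not independent, so
    treat it as descriptive.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise InputError("compare_vectors needs equal-length vectors (>= 3)")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("non-finite values in comparison vectors")
    if np.ptp(x) == 0:
        raise InputError("zero variance in x")
    res = stats.linregress(x, y)
    return VectorComparison(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r=float(res.rvalue), r2=float(res.rvalue ** 2),
                            n=len(x), p_value=float(res.pvalue))


def age_sensitivity(pm: PhenotypeMatrix, age: Sequence[float]) -> np.ndarray:
    """Per-trait Pearson correlation with age, pairwise-complete."""
    age = np.asarray(age, dtype=float)
    if age.shape != (pm.values.shape[0],):
        raise InputError("age vector length mismatch")
    finite_age = np.isfinite(age)
    if finite_age.sum() < 3 or np.ptp(age[finite_age]) == 0:
        raise InputError("age must be finite (>= 3 values) and non-constant")
    out = np.empty(len(pm.labels))
    for i, label in enumerate(pm.labels):
        v = pm.values[:, i]
        ok = np.isfinite(v) & finite_age
        if ok.sum() < 3:
            raise InsufficientDataError(
                f"trait {label!r}: fewer than 3 complete (trait, age) pairs")
        out[i] = stats.pearsonr(v[ok], age[ok]).statistic
    return out


def network_size_adjust(effects: Sequence[float],
                        sizes: Sequence[int]) -> np.ndarray:
    """Divide per-network effect sizes by network member counts."""
    effects = np.asarray(effects, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if effects.shape != sizes.shape:
        raise InputError("effects and sizes must have the same length")
    if (sizes < 1).any():
        raise InputError("network sizes must be >= 1")
    return effects / sizes
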