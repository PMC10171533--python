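"""Minimal one-common-factor model for genetic correlation matrices.

Fits the single-factor structure R ≈ λλᵀ (unit diagonal) to an observed
genetic correlation matrix by unweighted least squares over the
off-diagonal cells, and optionally the correlation ρ between the factor
and one external trait whose indicator correlations are modelled as
ρ·λ_i.  This is deliberately lighter than a full SEM treatment: no
sampling-covariance weight matrix, so no model chi-square — fit quality
is summarised by the SRMR over off-diagonal residuals.  Heywood cases
(residual variance < 0 or |ρ| > 1 before clamping) are clamped and
flagged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import ConvergenceError, InputError
from .ldsc import GeneticCorrMatrix

log = logging.getLogger(__name__)

_MAX_ITER = 10_000
_FTOL = 1e-14  # objective-change tolerance passed to the optimizer


@dataclass
class FactorFit:
    """One-factor ULS fit: standardised loadings and fit residual."""

    labels: list
    loadings: np.ndarray          # λ per indicator, in [−1, 1]
    residual_variances: np.ndarray  # 1 − λ², clamped at 0
    srmr: float
    factor_external_r: float | None = None
    heywood: bool = False
    n_iter: int = 0
    objective_trace: list = field(default_factory=list)


def _offdiag_mask(k: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(k, 1)


def _prepare(m, indicators):
    if isinstance(m, GeneticCorrMatrix):
        gcm = m.restrict(indicators) if indicators is not None else m
        return list(gcm.labels), np.asarray(gcm.r_g, dtype=float)
    r = np.asarray(m, dtype=float)
    labels = list(indicators) if indicators is not None else [
        f"ind{i+1}" for i in range(r.shape[0])]
    return labels, r


def fit_common_factor(m, indicators=None) -> FactorFit:
    """Fit λ in R ≈ λλᵀ (unit diagonal) by bounded quasi-Newton ULS.

    ``m`` is a :class:`GeneticCorrMatrix` (optionally restricted to
    ``indicators``) or a plain correlation array.  Starting values are the
    first-eigenvector standardised loadings; λ is constrained to [−1, 1];
    the sign convention makes the mean loading nonnegative.
    """
    labels, r = _prepare(m, indicators)
    k = r.shape[0]
    if k == 2:
        raise InputError("one-factor model is under-identified with 2 indicators")
    if k < 3:
        raise InputError("need >= 3 indicators")
    if np.linalg.eigvalsh(r).min() < -1e-8:
        raise InputError("correlation matrix must be PSD (smooth it first)")
    iu = _offdiag_mask(k)
    robs = r[iu]

    if np.max(np.abs(robs)) < 1e-12:
        # no shared variance: the zero vector is the canonical solution
        return FactorFit(labels=labels, loadings=np.zeros(k),
                         residual_variances=np.ones(k), srmr=0.0)

    vals, vecs = np.linalg.eigh(r)
    x0 = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
    if x0.mean() < 0:
        x0 = -x0
    x0 = np.clip(x0, -1.0, 1.0)

    trace: list[float] = []

    def objective(lam):
        resid = robs - (np.outer(lam, lam))[iu]
        return float(resid @ resid)

    def grad(lam):
        resid_mat = np.zeros((k, k))
        resid_mat[iu] = robs - (np.outer(lam, lam))[iu]
        resid_mat = resid_mat + resid_mat.T
        return -2.0 * resid_mat @ lam

    res = optimize.minimize(
        objective, x0, jac=grad, method="L-BFGS-B",
        bounds=[(-1.0, 1.0)] * k,
        callback=lambda xk: trace.append(objective(xk)),
        options={"maxiter": _MAX_ITER, "ftol": _FTOL, "gtol": 1e-12})
    if not res.success and res.fun > 1e-8:
        raise ConvergenceError(
            f"one-factor ULS did not converge: {res.message}",
            last_objective=float(res.fun))
    lam = res.x
    if lam.mean() < 0:
        lam = -lam
    resvar = 1.0 - lam ** 2
    heywood = bool((resvar < -1e-10).any())
    if heywood:
        log.warning("Heywood case: residual variance clamped at 0")
    resvar = np.clip(resvar, 0.0, None)
    srmr = float(np.sqrt(np.mean((robs - np.outer(lam, lam)[iu]) ** 2)))
    return FactorFit(labels=labels, loadings=lam, residual_variances=resvar,
                     srmr=srmr, heywood=heywood, n_iter=int(res.nit),
                     objective_trace=trace)


def implied_matrix(fit: FactorFit) -> np.ndarray:
    """Model-implied correlation matrix λλᵀ with unit diagonal."""
    r = np.outer(fit.loadings, fit.loadings)
    np.fill_diagonal(r, 1.0)
    return r


def factor_external_correlation(m_ext, fit: FactorFit) -> FactorFit:
    """Jointly refit λ and the factor–external-trait correlation ρ.

    ``m_ext`` is a correlation matrix (or :class:`GeneticCorrMatrix`) over
    the fit's indicators plus exactly one external trait; the external
    trait's indicator correlations are modelled as ρ·λ_i.  Returns a new
    fit carrying ``factor_external_r``; |ρ| > 1 before clamping raises a
    Heywood warning and sets the flag.
    """
    if isinstance(m_ext, GeneticCorrMatrix):
        labels_all, r_all = list(m_ext.labels), np.asarray(m_ext.r_g, float)
    else:
        r_all = np.asarray(m_ext, dtype=float)
        labels_all = None
    ind = list(fit.labels)
    if labels_all is not None:
        external = [l for l in labels_all if l not in ind]
        if len(external) != 1:
            raise InputError(
                f"expected exactly one external trait, found {external}")
        order = [labels_all.index(l) for l in ind] + [
            labels_all.index(external[0])]
        r_all = r_all[np.ix_(order, order)]
        ext_label = external[0]
    else:
        if r_all.shape[0] != len(ind) + 1:
            raise InputError("matrix must cover the indicators plus one "
                             "external trait")
        ext_label = "external"
    k = len(ind)
    r_ind = r_all[:k, :k]
    r_ext = r_all[:k, k]
    iu = _offdiag_mask(k)
    robs = r_ind[iu]

    def objective(theta):
        lam, rho = theta[:k], theta[k]
        res1 = robs - np.outer(lam, lam)[iu]
        res2 = r_ext - rho * lam
        return float(res1 @ res1 + res2 @ res2)

    def grad(theta):
        lam, rho = theta[:k], theta[k]
        resid_mat = np.zeros((k, k))
        resid_mat[iu] = robs - np.outer(lam, lam)[iu]
        resid_mat = resid_mat + resid_mat.T
        res2 = r_ext - rho * lam
        g_lam = -2.0 * resid_mat @ lam - 2.0 * rho * res2
        g_rho = -2.0 * float(res2 @ lam)
        return np.append(g_lam, g_rho)

    denom = float(fit.loadings @ fit.loadings)
    rho0 = float(r_ext @ fit.loadings / denom) if denom > 0 else 0.0
    x0 = np.append(fit.loadings, np.clip(rho0, -2.0, 2.0))
    bounds = [(-1.0, 1.0)] * k + [(None, None)]
    res = optimize.minimize(objective, x0, jac=grad, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": _MAX_ITER, "ftol": _FTOL,
                                     "gtol": 1e-12})
    if not res.success and res.fun > 1e-8:
        raise ConvergenceError(
            f"factor-external ULS did not converge: {res.message}",
            last_objective=float(res.fun))
    lam, rho = res.x[:k], float(res.x[k])
    if lam.mean() < 0:
        lam, rho = -lam, -rho
    heywood = bool(abs(rho) > 1 or (1 - lam ** 2 < -1e-10).any())
    if abs(rho) > 1:
        log.warning("Heywood case: factor-external correlation %.4f clamped "
                    "into [-1, 1]", rho)
        rho = float(np.clip(rho, -1.0, 1.0))
    srmr = float(np.sqrt(np.mean(
        np.concatenate([(robs - np.outer(lam, lam)[iu]),
                        r_ext - rho * lam]) ** 2)))
    return FactorFit(labels=ind, loadings=lam,
                     residual_variances=np.clip(1 - lam ** 2, 0.0, None),
                     srmr=srmr, factor_external_r=rho, heywood=heywood,
                     n_iter=int(res.nit))
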