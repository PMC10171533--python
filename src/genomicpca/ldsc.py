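"""LD score regression: heritability, genetic covariance and intercepts.

Univariate model (per SNP j, sample size N_j, LD score ℓ_j, M SNPs)::

    E[χ²_j] = intercept + (N_j · h² / M) · ℓ_j

Cross-trait model::

    E[Z1_j · Z2_j] = cti + (√(N1_j · N2_j) · gencov / M) · ℓ_j

Both are fitted by two-pass iteratively reweighted least squares.  Pass 1
weights by 1/max(ℓ_j, 1); pass 2 additionally downweights by the squared
model-predicted statistic variance, 1/(1 + N̄·ĥ²·ℓ_j/M)² in the
univariate case and the analogous product of the two traits' terms in the
cross-trait case.  Standard errors come from a delete-a-block jackknife
over contiguous variant blocks.  Intercepts are always estimated freely:
the cross-trait intercept (CTI) carries the sample-overlap signal that the
PC-GWAS synthesis later uses to correct its standard errors.

The genetic correlation is rg = gencov / √(h²₁·h²₂).  Assembled k×k
matrices are smoothed to the nearest positive-semidefinite correlation
matrix (Higham alternating projections) when sampling noise pushes an
eigenvalue below zero, so that eigendecomposition downstream is well
defined.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, InsufficientDataError
from .sumstats import LdScoreTable, SumStatsTable

log = logging.getLogger(__name__)

MIN_OVERLAP = 200  # minimum variants shared between sumstats and LD scores


@dataclass
class LdscFit:
    """Univariate LD score regression result."""

    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    mean_chisq: float
    n_snps_used: int
    n_blocks: int


@dataclass
class CrossTraitFit:
    """Cross-trait LD score regression result.

    ``rg`` is clamped into [−1, 1]; ``rg_raw`` keeps the unclamped
    estimate.  When either heritability is non-positive ``rg`` is NaN and
    a warning is logged, but ``gencov`` and ``cti`` are still returned.
    """

    gencov: float
    gencov_se: float
    rg: float
    rg_se: float
    cti: float
    cti_se: float
    rg_raw: float = np.nan


@dataclass
class GeneticCorrMatrix:
    """k×k genetic correlation matrix with SE and cross-trait intercepts.

    The CTI diagonal is fixed at 1 by convention (Z statistics of a QC'd
    GWAS have variance ≈ 1); the per-trait univariate intercepts are kept
    in ``uni_intercepts`` and can be placed on the diagonal via
    :meth:`cti_with_diag`.
    """

    labels: list
    r_g: np.ndarray
    se: np.ndarray
    cti: np.ndarray
    smoothed: bool = False
    min_eigen_raw: float = np.nan
    uni_intercepts: np.ndarray | None = None
    uni_h2: np.ndarray | None = None
    n_clamped: int = 0

    def __post_init__(self):
        k = len(self.labels)
        for name in ("r_g", "se", "cti"):
            a = getattr(self, name)
            if a.shape != (k, k):
                raise InputError(f"{name} must be {k}x{k}")
            if not np.allclose(a, a.T, atol=1e-12):
                raise InputError(f"{name} not symmetric")

    @property
    def k(self) -> int:
        return len(self.labels)

    def restrict(self, members: Sequence[str]) -> "GeneticCorrMatrix":
        """Submatrix over ``members`` (order preserved as given)."""
        idx = []
        for m in members:
            if m not in self.labels:
                raise InputError(f"unknown trait label {m!r}")
            idx.append(self.labels.index(m))
        idx = np.asarray(idx)
        sub = lambda a: a[np.ix_(idx, idx)]
        return GeneticCorrMatrix(
            labels=[self.labels[i] for i in idx],
            r_g=sub(self.r_g), se=sub(self.se), cti=sub(self.cti),
            smoothed=self.smoothed,
            min_eigen_raw=float(np.linalg.eigvalsh(sub(self.r_g)).min()),
            uni_intercepts=(None if self.uni_intercepts is None
                            else self.uni_intercepts[idx]),
            uni_h2=None if self.uni_h2 is None else self.uni_h2[idx])

    def cti_with_diag(self, mode: str = "one") -> np.ndarray:
        """CTI matrix with diagonal per ``mode``: 'one' or 'univariate-intercept'."""
        out = self.cti.copy()
        if mode == "one":
            return out
        if mode == "univariate-intercept":
            if self.uni_intercepts is None:
                raise InputError("univariate intercepts not available")
            np.fill_diagonal(out, self.uni_intercepts)
            return out
        raise InputError(f"unknown cti diagonal mode {mode!r}")


# ---------------------------------------------------------------------------
# weighted least squares with delete-a-block jackknife

def _block_edges(m: int, n_blocks: int) -> np.ndarray:
    return np.linspace(0, m, n_blocks + 1).astype(int)


def _wls_jackknife(x, y, w, n_blocks):
    """WLS of y on [1, x] with weights w; delete-a-block jackknife.

    Returns (intercept, slope, intercept_se, slope_se,
    intercept_deleted, slope_deleted) where the deleted arrays hold the
    n_blocks leave-one-block-out estimates.
    """
    m = len(x)
    if not (2 <= n_blocks < m):
        raise InputError(f"need 2 <= n_blocks < n_snps, got {n_blocks} / {m}")
    edges = _block_edges(m, n_blocks)[:-1]
    terms = np.vstack([w, w * x, w * x * x, w * y, w * x * y])
    block = np.add.reduceat(terms, edges, axis=1)  # 5 x B
    total = block.sum(axis=1)

    def solve(s):
        s0, s1, s2, sy, sxy = s
        det = s0 * s2 - s1 * s1
        a = (s2 * sy - s1 * sxy) / det
        b = (s0 * sxy - s1 * sy) / det
        return a, b

    a, b = solve(total)
    deleted = total[:, None] - block
    a_del, b_del = solve(deleted)
    B = n_blocks
    a_se = np.sqrt((B - 1) / B * np.sum((a_del - a_del.mean()) ** 2))
    b_se = np.sqrt((B - 1) / B * np.sum((b_del - b_del.mean()) ** 2))
    return a, b, a_se, b_se, a_del, b_del


def _wls_simple(x, y, w):
    sw, sx, sxx = w.sum(), (w * x).sum(), (w * x * x).sum()
    sy, sxy = (w * y).sum(), (w * x * y).sum()
    det = sw * sxx - sx * sx
    return (sxx * sy - sx * sxy) / det, (sw * sxy - sx * sy) / det


def _uni_arrays(z, n, l2, M, n_blocks):
    """Two-pass univariate fit on aligned arrays; returns a detail dict."""
    chi2 = z * z
    if not np.isfinite(chi2).all():
        raise InputError("non-finite chi-square statistics")
    x = n * l2 / M
    w1 = 1.0 / np.maximum(l2, 1.0)
    _, b1 = _wls_simple(x, chi2, w1)
    h2w = float(np.clip(b1, 0.0, 1.0))
    nbar = n.mean()
    w2 = w1 / (1.0 + nbar * h2w * l2 / M) ** 2
    a, b, a_se, b_se, a_del, b_del = _wls_jackknife(x, chi2, w2, n_blocks)
    return {
        "intercept": a, "h2": b, "intercept_se": a_se, "h2_se": b_se,
        "intercept_del": a_del, "h2_del": b_del, "h2w_pass1": h2w,
        "mean_chisq": float(chi2.mean()), "nbar": float(nbar),
    }


def _cross_arrays(z1, n1, z2, n2, l2, M, n_blocks, uni1, uni2):
    """Two-pass cross-trait fit; weights reuse the univariate pass-1 slopes."""
    y = z1 * z2
    x = np.sqrt(n1 * n2) * l2 / M
    w1 = 1.0 / np.maximum(l2, 1.0)
    w2 = w1 / ((1.0 + uni1["nbar"] * uni1["h2w_pass1"] * l2 / M)
               * (1.0 + uni2["nbar"] * uni2["h2w_pass1"] * l2 / M))
    a, b, a_se, b_se, a_del, b_del = _wls_jackknife(x, y, w2, n_blocks)
    return {"cti": a, "gencov": b, "cti_se": a_se, "gencov_se": b_se,
            "cti_del": a_del, "gencov_del": b_del}


def _jackknife_se(theta_del: np.ndarray) -> float:
    ok = np.isfinite(theta_del)
    t = theta_del[ok]
    B = len(t)
    if B < 2:
        return np.nan
    return float(np.sqrt((B - 1) / B * np.sum((t - t.mean()) ** 2)))


# ---------------------------------------------------------------------------
# public operations

def _merge_with_ld(table: SumStatsTable, ld: LdScoreTable):
    merged = table.df.merge(ld.df, on="snp", how="inner")
    if len(merged) < MIN_OVERLAP:
        raise InsufficientDataError(
            f"{table.trait_label}: only {len(merged)} variants overlap the "
            f"LD scores (need >= {MIN_OVERLAP})")
    return merged


def univariate_ldsc(table: SumStatsTable, ld: LdScoreTable,
                    n_blocks: int = 200) -> LdscFit:
    """SNP-heritability and intercept by univariate LD score regression."""
    merged = _merge_with_ld(table, ld)
    d = _uni_arrays(merged["z"].to_numpy(float), merged["n"].to_numpy(float),
                    merged["l2"].to_numpy(float), ld.m_total, n_blocks)
    return LdscFit(h2=d["h2"], h2_se=d["h2_se"], intercept=d["intercept"],
                   intercept_se=d["intercept_se"], mean_chisq=d["mean_chisq"],
                   n_snps_used=len(merged), n_blocks=n_blocks)


def _check_same_frame(tables: Sequence[SumStatsTable]) -> None:
    ids0 = tables[0].variant_ids
    for t in tables[1:]:
        if len(t.df) != len(ids0) or not np.array_equal(t.variant_ids, ids0):
            raise InputError(
                "tables are not on a shared variant frame; run harmonize first")


def cross_trait_ldsc(t1: SumStatsTable, t2: SumStatsTable, ld: LdScoreTable,
                     n_blocks: int = 200) -> CrossTraitFit:
    """Genetic covariance, correlation and cross-trait intercept for a pair.

    ``t1`` and ``t2`` must already share a variant frame.  The rg standard
    error jackknifes gencov and both heritabilities over the same deleted
    blocks.
    """
    _check_same_frame([t1, t2])
    m1 = _merge_with_ld(t1, ld)
    keep = t1.df["snp"].isin(m1["snp"]).to_numpy()
    z1 = t1.df.loc[keep, "z"].to_numpy(float)
    n1 = t1.df.loc[keep, "n"].to_numpy(float)
    z2 = t2.df.loc[keep, "z"].to_numpy(float)
    n2 = t2.df.loc[keep, "n"].to_numpy(float)
    l2 = m1["l2"].to_numpy(float)
    return _cross_fit(z1, n1, z2, n2, l2, ld.m_total, n_blocks,
                      labels=(t1.trait_label, t2.trait_label))


def _cross_fit(z1, n1, z2, n2, l2, M, n_blocks, labels=("t1", "t2"),
               uni1=None, uni2=None) -> CrossTraitFit:
    if uni1 is None:
        uni1 = _uni_arrays(z1, n1, l2, M, n_blocks)
    if uni2 is None:
        uni2 = _uni_arrays(z2, n2, l2, M, n_blocks)
    d = _cross_arrays(z1, n1, z2, n2, l2, M, n_blocks, uni1, uni2)
    h2_1, h2_2 = uni1["h2"], uni2["h2"]
    if h2_1 <= 0 or h2_2 <= 0:
        log.warning("rg undefined for (%s, %s): non-positive heritability "
                    "(%.4g, %.4g)", labels[0], labels[1], h2_1, h2_2)
        rg_raw = rg = rg_se = np.nan
    else:
        rg_raw = d["gencov"] / np.sqrt(h2_1 * h2_2)
        rg = float(np.clip(rg_raw, -1.0, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            denom_del = np.sqrt(np.where(
                (uni1["h2_del"] > 0) & (uni2["h2_del"] > 0),
                uni1["h2_del"] * uni2["h2_del"], np.nan))
            rg_del = d["gencov_del"] / denom_del
        rg_se = _jackknife_se(rg_del)
    return CrossTraitFit(gencov=d["gencov"], gencov_se=d["gencov_se"],
                         rg=rg, rg_se=rg_se, rg_raw=rg_raw,
                         cti=d["cti"], cti_se=d["cti_se"])


def genetic_correlation_matrix(tables: Sequence[SumStatsTable],
                               ld: LdScoreTable,
                               n_blocks: int = 200) -> GeneticCorrMatrix:
    """Assemble the k×k genetic correlation / SE / CTI matrices.

    Runs k univariate and k(k−1)/2 cross-trait fits on the shared variant
    frame, clamps |rg| to 1 (logged), and smooths the assembled matrix to
    the nearest PSD correlation matrix if its smallest eigenvalue is
    negative.
    """
    k = len(tables)
    if k < 2:
        raise InputError("genetic correlation matrix requires >= 2 traits")
    _check_same_frame(tables)
    merged = _merge_with_ld(tables[0], ld)
    keep = tables[0].df["snp"].isin(merged["snp"]).to_numpy()
    l2 = merged["l2"].to_numpy(float)
    M = ld.m_total
    Z = np.column_stack([t.df.loc[keep, "z"].to_numpy(float) for t in tables])
    N = np.column_stack([t.df.loc[keep, "n"].to_numpy(float) for t in tables])

    unis = [_uni_arrays(Z[:, i], N[:, i], l2, M, n_blocks) for i in range(k)]
    bad = [tables[i].trait_label for i in range(k) if unis[i]["h2"] <= 0]
    if bad:
        raise InsufficientDataError(
            f"non-positive heritability for traits {bad}; rg undefined")

    r_g = np.eye(k)
    se = np.zeros((k, k))
    cti = np.eye(k)
    n_clamped = 0
    for i in range(k):
        for j in range(i + 1, k):
            fit = _cross_fit(Z[:, i], N[:, i], Z[:, j], N[:, j], l2, M,
                             n_blocks, labels=(tables[i].trait_label,
                                               tables[j].trait_label),
                             uni1=unis[i], uni2=unis[j])
            if abs(fit.rg_raw) > 1:
                n_clamped += 1
            r_g[i, j] = r_g[j, i] = fit.rg
            se[i, j] = se[j, i] = fit.rg_se
            cti[i, j] = cti[j, i] = fit.cti
    if n_clamped:
        log.info("clamped %d of %d genetic correlations into [-1, 1]",
                 n_clamped, k * (k - 1) // 2)

    min_eig = float(np.linalg.eigvalsh(r_g).min())
    smoothed = False
    if min_eig < 0:
        r_g = nearest_pd(r_g)
        smoothed = True
        log.info("smoothed genetic correlation matrix to PSD "
                 "(raw min eigenvalue %.3e)", min_eig)
    return GeneticCorrMatrix(
        labels=[t.trait_label for t in tables], r_g=r_g, se=se, cti=cti,
        smoothed=smoothed, min_eigen_raw=min_eig,
        uni_intercepts=np.array([u["intercept"] for u in unis]),
        uni_h2=np.array([u["h2"] for u in unis]), n_clamped=n_clamped)


def nearest_pd(m: np.ndarray, tol: float = 1e-10,
               max_iter: int = 200) -> np.ndarray:
    """Nearest (Frobenius) PSD correlation matrix, unit diagonal restored.

    Higham-style alternating projections with Dykstra correction between
    the PSD cone and the unit-diagonal affine set.  Inputs that are
    already PSD with a unit diagonal are returned unchanged (fixed point).
    """
    a = np.asarray(m, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InputError("nearest_pd requires a square matrix")
    if not np.allclose(a, a.T, atol=1e-8):
        raise InputError("nearest_pd requires a symmetric matrix")
    a = (a + a.T) / 2
    if np.linalg.eigvalsh(a).min() >= -tol and np.allclose(np.diag(a), 1.0,
                                                           atol=tol):
        return a.copy()
    y = a.copy()
    ds = np.zeros_like(a)
    for _ in range(max_iter):
        r = y - ds
        vals, vecs = np.linalg.eigh((r + r.T) / 2)
        x = (vecs * np.clip(vals, 0, None)) @ vecs.T
        ds = x - r
        y_new = x.copy()
        np.fill_diagonal(y_new, 1.0)
        delta = np.linalg.norm(y_new - y) / max(1.0, np.linalg.norm(y_new))
        y = y_new
        if delta < tol and np.linalg.eigvalsh(y).min() >= -tol:
            break
    y = (y + y.T) / 2
    np.fill_diagonal(y, 1.0)
    return y


# ---------------------------------------------------------------------------
# persistence

def save_corr_matrix(gcm: GeneticCorrMatrix, directory,
                     stem: str = "genetic_corr",
                     header_lines: Sequence[str] = ()) -> None:
    """Write rg/se/cti as labelled TSVs plus a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mat in (("rg", gcm.r_g), ("se", gcm.se), ("cti", gcm.cti)):
        p = directory / f"{stem}.{name}.tsv"
        with open(p, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            pd.DataFrame(mat, index=gcm.labels, columns=gcm.labels).to_csv(
                fh, sep="\t", float_format="%.12g")
    meta = {"labels": list(gcm.labels), "smoothed": bool(gcm.smoothed),
            "min_eigen_raw": float(gcm.min_eigen_raw),
            "n_clamped": int(gcm.n_clamped),
            "uni_intercepts": (None if gcm.uni_intercepts is None
                               else [float(v) for v in gcm.uni_intercepts]),
            "uni_h2": (None if gcm.uni_h2 is None
                       else [float(v) for v in gcm.uni_h2])}
    (directory / f"{stem}.meta.json").write_text(json.dumps(meta, indent=1))


def load_corr_matrix(directory, stem: str = "genetic_corr") -> GeneticCorrMatrix:
    directory = Path(directory)
    mats = {}
    for name in ("rg", "se", "cti"):
        mats[name] = pd.read_csv(directory / f"{stem}.{name}.tsv", sep="\t",
                                 index_col=0, comment="#")
    meta = json.loads((directory / f"{stem}.meta.json").read_text())
    return GeneticCorrMatrix(
        labels=list(mats["rg"].index), r_g=mats["rg"].to_numpy(),
        se=mats["se"].to_numpy(), cti=mats["cti"].to_numpy(),
        smoothed=meta["smoothed"], min_eigen_raw=meta["min_eigen_raw"],
        uni_intercepts=(None if meta["uni_intercepts"] is None
                        else np.asarray(meta["uni_intercepts"])),
        uni_h2=(None if meta.get("uni_h2") is None
                else np.asarray(meta["uni_h2"])),
        n_clamped=meta.get("n_clamped", 0))
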