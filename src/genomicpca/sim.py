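"""Multi-trait GWAS simulator with block LD and a factor architecture.

The generator emulates the study design the estimators target: tens of
volumetric traits measured on the same ~10⁴ individuals, SNP
heritabilities of a few tenths, and a dominant shared genetic dimension.
Genotypes come from a liability-threshold model — per LD block, two
latent Gaussian haplotypes with exchangeable correlation ``block_rho``
are thresholded at each SNP's MAF, giving Hardy–Weinberg dosages whose
within-block correlation is known analytically (bivariate-normal orthant
probabilities).  The analytic LD score of SNP i is::

    ℓ_i = 1 + Σ_{j≠i in block} (r_ij² + (1 − r_ij²)/(n − 1))

i.e. the expected *sample* squared correlation, which is what LD score
regression on in-sample GWAS statistics responds to.

Trait architecture: per-SNP causal effects on the standardised genotype
scale are λ_t·f_j + √(1−λ_t²)·u_tj with f and u i.i.d. standard normal
(optionally several correlated shared factors), rescaled so the realised
genetic variance of trait t is exactly h²_t.  Environmental noise is
drawn with correlation structure either proportional to the genetic
correlations (the Cheverud regime, default) or independent.  Every
generating quantity is exported as ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .errors import ConfigurationError, InputError
from .pca import eigen_pca
from .sumstats import LdScoreTable, SumStatsTable, write_ldscores, write_sumstats

_COL_CHUNK = 1024  # genotype columns processed per chunk in dense passes


@dataclass
class SimConfig:
    """Generating parameters for one simulated study.

    ``block_rho`` is the latent within-block correlation: a scalar applies
    to every block, a ``(lo, hi)`` pair draws one value per block
    uniformly, emulating the heterogeneous LD strength of real genomes
    (and giving LD score regression a well-spread regressor).
    ``lambda_g`` and ``h2`` broadcast from scalars to length-k vectors.
    ``unique_frac`` is the trait-specific share of genetic variance
    (default 1 − λ²).  ``factor_assign`` maps traits to shared genetic
    factors (default: one factor for all) and ``factor_corr`` is the
    correlation between those factors.
    """

    n_ind: int = 10_000
    n_snp: int = 20_000
    block_size: int = 10
    block_rho: float | tuple = (0.0, 0.95)
    maf_range: tuple = (0.05, 0.5)
    k: int = 10
    lambda_g: float | Sequence[float] = 0.63
    h2: float | Sequence[float] = 0.25
    unique_frac: Sequence[float] | None = None
    overlap: str = "full"
    env_corr: str = "cheverud"
    factor_assign: Sequence[int] | None = None
    factor_corr: float | np.ndarray = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_snp % self.block_size != 0:
            raise ConfigurationError("n_snp must be divisible by block_size")
        rho = self.block_rho
        if np.isscalar(rho):
            rho = (float(rho), float(rho))
        rho = (float(rho[0]), float(rho[1]))
        if not (0 <= rho[0] <= rho[1] < 1):
            raise ConfigurationError("block_rho must lie in [0, 1) "
                                     "(scalar or (lo, hi) range)")
        self.block_rho = rho
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie in (0, 0.5]")
        if self.overlap not in ("full", "disjoint"):
            raise ConfigurationError("overlap must be 'full' or 'disjoint'")
        if self.env_corr not in ("cheverud", "independent"):
            raise ConfigurationError("env_corr must be 'cheverud' or "
                                     "'independent'")
        self.lambda_g = np.broadcast_to(
            np.asarray(self.lambda_g, float), (self.k,)).copy()
        self.h2 = np.broadcast_to(np.asarray(self.h2, float), (self.k,)).copy()
        if np.any((self.h2 < 0) | (self.h2 >= 1)):
            raise ConfigurationError("h2 must be in [0, 1)")
        if np.any(np.abs(self.lambda_g) >= 1):
            raise ConfigurationError("lambda_g must be in (-1, 1)")
        if self.unique_frac is None:
            self.unique_frac = 1.0 - self.lambda_g ** 2
        else:
            self.unique_frac = np.broadcast_to(
                np.asarray(self.unique_frac, float), (self.k,)).copy()
        tot = self.lambda_g ** 2 + self.unique_frac
        if np.any(self.unique_frac < 0) or np.any(tot > 1 + 1e-9):
            raise ConfigurationError("need unique_frac >= 0 and "
                                     "lambda_g^2 + unique_frac <= 1")
        if self.factor_assign is None:
            self.factor_assign = np.zeros(self.k, dtype=int)
        else:
            self.factor_assign = np.asarray(self.factor_assign, dtype=int)
            if self.factor_assign.shape != (self.k,):
                raise ConfigurationError("factor_assign must have length k")
        nf = int(self.factor_assign.max()) + 1
        fc = np.asarray(self.factor_corr, float)
        if fc.ndim == 0:
            mat = np.full((nf, nf), float(fc))
            np.fill_diagonal(mat, 1.0)
            fc = mat
        if fc.shape != (nf, nf):
            raise ConfigurationError("factor_corr shape mismatch")
        self.factor_corr = fc
        if nf > 1 and np.linalg.eigvalsh(fc).min() < -1e-10:
            raise ConfigurationError("factor_corr must be PSD")

    @property
    def n_factors(self) -> int:
        return int(np.max(self.factor_assign)) + 1

    def normalized_loadings(self):
        """(λ̃, ũ) rescaled so λ̃² + ũ = 1 per trait."""
        tot = self.lambda_g ** 2 + self.unique_frac
        tot = np.where(tot > 0, tot, 1.0)
        return self.lambda_g / np.sqrt(tot), self.unique_frac / tot

    def trait_labels(self) -> list:
        return [f"trait{i + 1}" for i in range(self.k)]


@dataclass
class SimTruth:
    """Generating quantities every estimator should recover."""

    r_g: np.ndarray
    h2: np.ndarray
    phen_corr: np.ndarray
    pheno_pc1_loadings: np.ndarray
    labels: list


@dataclass
class SimStudy:
    """Simulated sumstats bundle plus ground truth.

    ``pheno_pca`` is the sample phenotypic PCA actually used to build the
    phenotypic-PC1 GWAS (the truth object carries the matrix-implied
    loadings instead).
    """

    config: SimConfig
    sumstats: list
    pheno_pc1_sumstats: SumStatsTable
    true_ld: LdScoreTable
    truth: SimTruth
    pheno_pca: object = None

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for t in self.sumstats:
            write_sumstats(t, directory / f"{t.trait_label}.sumstats.tsv")
        write_sumstats(self.pheno_pc1_sumstats,
                       directory / "pheno_pc1.sumstats.tsv")
        write_ldscores(self.true_ld, directory / "true.l2.ldscore")
        truth = {
            "labels": list(self.truth.labels),
            "h2": [float(v) for v in self.truth.h2],
            "r_g": [[float(v) for v in row] for row in self.truth.r_g],
            "phen_corr": [[float(v) for v in row]
                          for row in self.truth.phen_corr],
            "pheno_pc1_loadings": [float(v)
                                   for v in self.truth.pheno_pc1_loadings],
            "seed": int(self.config.seed),
        }
        (directory / "truth.yaml").write_text(yaml.safe_dump(truth))


# ---------------------------------------------------------------------------
# genotypes

def _bvn_lower(a, b, rho, n_nodes=96):
    """P(X < a, Y < b) for a standard bivariate normal, vectorised.

    One-dimensional Gauss–Legendre quadrature of
    φ(x)·Φ((b − ρx)/√(1−ρ²)) over x ∈ (−∞, a], truncated at −8.5.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    rho = np.asarray(rho, float)
    lo = -8.5
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    half = (a - lo) / 2.0
    x = half[..., None] * (nodes + 1.0) + lo
    s = np.sqrt(np.maximum(1.0 - rho * rho, 1e-12))
    vals = norm.pdf(x) * norm.cdf(
        (b[..., None] - rho[..., None] * x) / s[..., None])
    return (vals * weights).sum(axis=-1) * half


def _variant_frame(n_snp: int) -> pd.DataFrame:
    return pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(n_snp)],
        "chrom": "1", "bp": np.arange(1, n_snp + 1, dtype=np.int64),
        "a1": "A", "a2": "G"})


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None
                       ) -> tuple[np.ndarray, LdScoreTable]:
    """Dosage matrix (n_ind × n_snp, int8) and analytic LD scores."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, m, bs = cfg.n_ind, cfg.n_snp, cfg.block_size
    n_blocks = m // bs
    lo, hi = cfg.maf_range
    mafs = rng.uniform(lo, hi, m)
    thresh = norm.ppf(mafs)  # haplotype allele present when latent < threshold
    rho_lo, rho_hi = cfg.block_rho
    if rho_lo == rho_hi:
        rho_blocks = np.full(n_blocks, rho_lo)
    else:
        rho_blocks = rng.uniform(rho_lo, rho_hi, n_blocks)
    sr, so = np.sqrt(rho_blocks), np.sqrt(1.0 - rho_blocks)

    X = np.empty((n, m), dtype=np.int8)
    blocks_per_chunk = max(1, 4_000_000 // max(1, n * bs))
    for start in range(0, n_blocks, blocks_per_chunk):
        nb = min(blocks_per_chunk, n_blocks - start)
        cols = slice(start * bs, (start + nb) * bs)
        tt = thresh[cols]
        sr_c = sr[start:start + nb][None, :, None]
        so_c = so[start:start + nb][None, :, None]
        g = np.zeros((n, nb * bs), dtype=np.int8)
        for _hap in range(2):
            common = rng.standard_normal((n, nb))
            eps = rng.standard_normal((n, nb, bs))
            latent = sr_c * common[:, :, None] + so_c * eps
            g += latent.reshape(n, nb * bs) < tt
        X[:, cols] = g

    l2 = np.ones(m)
    if bs > 1:
        ii, jj = np.triu_indices(bs, 1)
        t2 = thresh.reshape(n_blocks, bs)
        p2d = mafs.reshape(n_blocks, bs)
        a = t2[:, ii].ravel()
        b = t2[:, jj].ravel()
        pa = p2d[:, ii].ravel()
        pb = p2d[:, jj].ravel()
        rho_pairs = np.repeat(rho_blocks, len(ii))
        orthant = _bvn_lower(a, b, rho_pairs)
        r = (orthant - pa * pb) / np.sqrt(pa * (1 - pa) * pb * (1 - pb))
        r2 = r * r
        r2_sample = r2 + (1.0 - r2) / (n - 1)  # expected in-sample r^2
        blocks = np.repeat(np.arange(n_blocks), len(ii))
        np.add.at(l2, blocks * bs + np.tile(ii, n_blocks), r2_sample)
        np.add.at(l2, blocks * bs + np.tile(jj, n_blocks), r2_sample)
    ld = LdScoreTable(pd.DataFrame({"snp": _variant_frame(m)["snp"],
                                    "l2": l2}), m_total=m)
    return X, ld


def _column_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, m = X.shape
    mean = np.empty(m)
    sd = np.empty(m)
    for s in range(0, m, _COL_CHUNK):
        sl = slice(s, min(s + _COL_CHUNK, m))
        xs = X[:, sl].astype(np.float64)
        mean[sl] = xs.mean(axis=0)
        sd[sl] = xs.std(axis=0)
    return mean, sd


def _genetic_scores(X, weights, mean, sd) -> np.ndarray:
    """X_standardised @ weights without materialising the float matrix."""
    n, m = X.shape
    scores = np.zeros((n, weights.shape[1]))
    safe_sd = np.where(sd > 0, sd, 1.0)
    for s in range(0, m, _COL_CHUNK):
        sl = slice(s, min(s + _COL_CHUNK, m))
        wd = weights[sl] / safe_sd[sl, None]
        wd[sd[sl] == 0] = 0.0
        scores += X[:, sl].astype(np.float64) @ wd
        scores -= mean[sl] @ wd
    return scores


def _standardize(a: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=0)
    s = a.std(axis=0)
    return a / np.where(s > 0, s, 1.0)


def simulate_traits(genotypes: np.ndarray, cfg: SimConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[np.ndarray, SimTruth]:
    """Phenotype matrix (n_ind × k) plus generating ground truth."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n, m = genotypes.shape
    k = cfg.k
    lam, uniq = cfg.normalized_loadings()
    assign = cfg.factor_assign
    nf = cfg.n_factors
    fcorr = cfg.factor_corr

    # true genetic correlation structure from the generating parameters
    r_g = np.outer(lam, lam) * fcorr[np.ix_(assign, assign)]
    np.fill_diagonal(r_g, 1.0)

    # effect vectors on the standardised-genotype scale
    f_raw = rng.standard_normal((m, nf))
    chol_f = np.linalg.cholesky(fcorr + 1e-12 * np.eye(nf))
    f_eff = f_raw @ chol_f.T
    u_eff = rng.standard_normal((m, k))

    mean, sd = _column_stats(genotypes)
    s_f = _standardize(_genetic_scores(genotypes, f_eff, mean, sd))
    s_u = _standardize(_genetic_scores(genotypes, u_eff, mean, sd))

    g = s_f[:, assign] * lam + s_u * np.sqrt(uniq)
    g = _standardize(g) * np.sqrt(cfg.h2)  # realised genetic variance = h2

    if cfg.env_corr == "cheverud":
        sigma_e = r_g.copy()
    else:
        sigma_e = np.eye(k)
    chol_e = np.linalg.cholesky(sigma_e + 1e-10 * np.eye(k))
    e = _standardize(rng.standard_normal((n, k)) @ chol_e.T)
    y = g + e * np.sqrt(1.0 - cfg.h2)

    phen_corr = (np.sqrt(np.outer(cfg.h2, cfg.h2)) * r_g
                 + np.sqrt(np.outer(1 - cfg.h2, 1 - cfg.h2)) * sigma_e)
    np.fill_diagonal(phen_corr, 1.0)
    labels = cfg.trait_labels()
    pc1 = eigen_pca(phen_corr, labels, "phenotypic").pc1_loadings()
    truth = SimTruth(r_g=r_g, h2=cfg.h2.copy(), phen_corr=phen_corr,
                     pheno_pc1_loadings=pc1, labels=labels)
    return y, truth


def run_gwas(genotypes: np.ndarray, phenotype: np.ndarray,
             covariates: np.ndarray | None = None,
             trait_label: str = "trait",
             rows: np.ndarray | None = None) -> SumStatsTable:
    """Per-SNP simple linear regression of a standardised phenotype.

    ``rows`` restricts the analysis to a subset of individuals (used for
    disjoint-overlap designs).  Monomorphic SNPs are dropped with a count.
    """
    y = np.asarray(phenotype, dtype=float)
    X = genotypes
    if rows is not None:
        X = X[rows]
        y = y[rows]
    n = len(y)
    if y.shape != (X.shape[0],):
        raise InputError("phenotype length does not match genotypes")
    if np.ptp(y) == 0:
        raise InputError("constant phenotype")
    if covariates is not None:
        cov = np.asarray(covariates, float)
        if rows is not None:
            cov = cov[rows]
        design = np.column_stack([np.ones(n), cov])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        y = y - design @ coef
    y = y - y.mean()
    y = y / y.std()
    syy = float(y @ y)  # == n by construction

    m = X.shape[1]
    beta = np.empty(m)
    se = np.empty(m)
    eaf = np.empty(m)
    mono = np.zeros(m, dtype=bool)
    for s in range(0, m, _COL_CHUNK):
        sl = slice(s, min(s + _COL_CHUNK, m))
        xs = X[:, sl].astype(np.float64)
        mx = xs.mean(axis=0)
        sxx = (xs * xs).sum(axis=0) - n * mx * mx
        sxy = y @ xs  # y is centred, so no mean correction needed
        mono_sl = sxx <= 0
        sxx_safe = np.where(mono_sl, 1.0, sxx)
        b = sxy / sxx_safe
        sigma2 = np.maximum(syy - b * sxy, 0.0) / (n - 2)
        beta[sl] = b
        se[sl] = np.sqrt(np.maximum(sigma2 / sxx_safe, 1e-300))
        eaf[sl] = mx / 2.0
        mono[sl] = mono_sl

    frame = _variant_frame(m)
    df = frame.assign(eaf=eaf, beta=beta, se=se, z=beta / se,
                      n=np.full(m, n, dtype=np.int64))
    if mono.any():
        df = df.loc[~mono].reset_index(drop=True)
    return SumStatsTable(trait_label, df)


def make_study(cfg: SimConfig) -> SimStudy:
    """Compose genotypes, traits, per-trait GWAS and the phenotypic-PC1 GWAS."""
    rng = np.random.default_rng(cfg.seed)
    X, ld = simulate_genotypes(cfg, rng)
    y, truth = simulate_traits(X, cfg, rng)
    labels = cfg.trait_labels()

    if cfg.overlap == "full":
        row_sets = [None] * cfg.k
    else:
        perm = rng.permutation(cfg.n_ind)
        row_sets = [np.sort(part) for part in np.array_split(perm, cfg.k)]

    sumstats = [run_gwas(X, y[:, t], trait_label=labels[t], rows=row_sets[t])
                for t in range(cfg.k)]

    corr = np.corrcoef(_standardize(y), rowvar=False)
    if cfg.k == 1:
        corr = np.ones((1, 1))
    pheno_pca = eigen_pca(corr, labels, "phenotypic")
    scores = _standardize(y) @ pheno_pca.pc1_loadings()
    pheno_pc1 = run_gwas(X, scores, trait_label="pheno_pc1")
    return SimStudy(config=cfg, sumstats=sumstats,
                    pheno_pc1_sumstats=pheno_pc1, true_ld=ld, truth=truth,
                    pheno_pca=pheno_pca)
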