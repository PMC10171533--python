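"""Genetic principal components and PC-level GWAS synthesis.

The central operation of the package: eigendecompose a genetic
correlation matrix R_g into components, report standardised loadings
(eigenvector × √eigenvalue, so squared loadings sum to 1 per trait) and
variance explained (λ_c / p), then combine the per-trait GWAS Z statistics
into a single synthesized GWAS for PC1::

    z_pc,j = Σ_i w_i · Z_ij / √(wᵀ·CTI·w)
    n_eff,j = (Σ_i w_i · √N_ij)² / (wᵀ·CTI·w)

where w is the PC1 loading vector and CTI the matrix of LDSC cross-trait
intercepts.  Dividing by √(wᵀ·CTI·w) is the sample-overlap correction:
under full overlap the intercepts track phenotypic correlations, so the
combined statistic keeps unit variance under the null even though every
input GWAS used the same individuals.

Also here: Horn-style parallel analysis against nulls matched to the
per-cell jackknife SEs of the correlation matrix, and a random-grouping
null for the variance explained by a named trait network.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InputError, ConfigurationError
from .ldsc import GeneticCorrMatrix, nearest_pd
from .sumstats import SumStatsTable

log = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Eigendecomposition of a correlation matrix, PCA conventions.

    ``loadings[t, c]`` is the standardised loading of trait t on component
    c; ``r2[c] = eigenvalues[c] / p`` is the fraction of total variance
    the component explains.  Component signs are fixed so each component's
    mean loading is nonnegative.
    """

    labels: list
    eigenvalues: np.ndarray
    loadings: np.ndarray
    r2: np.ndarray
    domain_tag: str = "genetic"

    @property
    def p(self) -> int:
        return len(self.labels)

    def pc1_loadings(self) -> np.ndarray:
        return self.loadings[:, 0]

    def scree_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"component": np.arange(1, self.p + 1),
                             "eigenvalue": self.eigenvalues, "r2": self.r2})


@dataclass
class NetworkDefinition:
    """A named group of trait labels (size >= 2)."""

    name: str
    members: list

    def __post_init__(self):
        if len(self.members) < 2:
            raise InputError(f"network {self.name!r} needs >= 2 members")
        if len(set(self.members)) != len(self.members):
            raise InputError(f"network {self.name!r} has duplicate members")

    def validate_against(self, labels: Sequence[str]) -> None:
        missing = [m for m in self.members if m not in labels]
        if missing:
            raise InputError(
                f"network {self.name!r} members not in trait labels: {missing}")


def read_networks(path) -> list[NetworkDefinition]:
    """Read a YAML/JSON mapping of network name -> list of trait labels."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a mapping name -> members")
    return [NetworkDefinition(name, list(members))
            for name, members in raw.items()]


@dataclass
class ParallelResult:
    observed_eigenvalues: np.ndarray
    null_p95: np.ndarray
    n_retained: int
    n_draws: int
    seed: int


@dataclass
class NullR2Distribution:
    observed_r2: float
    null_r2: np.ndarray
    p_emp: float


@dataclass
class PcSumStats:
    """Synthesized GWAS summary statistics for a genetic PC1."""

    df: pd.DataFrame  # snp, chrom, bp, a1, a2, eaf, z_pc, n_eff, beta, se
    weights: np.ndarray
    denom: float
    trait_labels: list

    def to_sumstats(self, trait_label: str = "genetic_pc1") -> SumStatsTable:
        """Repackage in the standard sumstats layout for re-analysis."""
        out = self.df.rename(columns={"z_pc": "z", "n_eff": "n"})
        return SumStatsTable(trait_label, out[["snp", "chrom", "bp", "a1",
                                               "a2", "eaf", "beta", "se",
                                               "z", "n"]])


# ---------------------------------------------------------------------------
# eigendecomposition with fixed conventions

def eigen_pca(corr: np.ndarray, labels: Sequence[str],
              domain_tag: str = "genetic") -> PcaResult:
    """Shared eigen path for genetic and phenotypic PCA.

    Eigenvalues descending (ties broken by the solver's deterministic
    order, hence by input trait order); tiny negative eigenvalues from
    roundoff are clamped to 0 for the loadings; sign convention: mean
    loading per component >= 0.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    if corr.shape != (p, p) or len(labels) != p:
        raise InputError("correlation matrix / labels shape mismatch")
    vals, vecs = np.linalg.eigh((corr + corr.T) / 2)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    signs = np.where(vecs.mean(axis=0) < 0, -1.0, 1.0)
    vecs = vecs * signs
    loadings = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return PcaResult(labels=list(labels), eigenvalues=vals,
                     loadings=loadings, r2=vals / p, domain_tag=domain_tag)


def genomic_pca(m: GeneticCorrMatrix,
                subset: NetworkDefinition | None = None) -> PcaResult:
    """Genetic PCA of a (possibly network-restricted) correlation matrix."""
    if subset is not None:
        subset.validate_against(m.labels)
        m = m.restrict(subset.members)
    vals = np.linalg.eigvalsh(m.r_g)
    if vals.min() < -1e-8:
        raise InputError(
            f"correlation matrix is not PSD (min eigenvalue {vals.min():.3e}); "
            "apply nearest_pd / smoothing first")
    return eigen_pca(m.r_g, m.labels, domain_tag="genetic")


# ---------------------------------------------------------------------------
# chance baselines

def parallel_analysis(m: GeneticCorrMatrix, n_draws: int = 1000,
                      quantile: float = 0.95, seed: int = 0) -> ParallelResult:
    """Horn-style component retention against SE-matched null matrices.

    Each null draw builds a symmetric unit-diagonal matrix whose (i, j)
    off-diagonal is Normal(0, se[i, j]), smooths it to PSD and records its
    eigenvalues; a component is retained when its observed eigenvalue
    exceeds the per-rank null quantile.
    """
    if n_draws < 100:
        raise InputError("parallel analysis needs n_draws >= 100")
    if m.se is None:
        raise InputError("parallel analysis needs the SE matrix")
    p = m.k
    observed = np.sort(np.linalg.eigvalsh(m.r_g))[::-1]
    iu = np.triu_indices(p, 1)
    sds = m.se[iu]
    if np.all(sds == 0):
        log.warning("all-zero SE matrix: degenerate parallel-analysis null "
                    "(eigenvalues identically 1)")
        null_q = np.ones(p)
        n_ret = int(np.sum(observed > null_q))
        return ParallelResult(observed, null_q, n_ret, n_draws, seed)
    rng = np.random.default_rng(seed)
    null_eigs = np.empty((n_draws, p))
    for d in range(n_draws):
        a = np.eye(p)
        off = rng.normal(0.0, sds)
        a[iu] = off
        a.T[iu] = off
        vals = np.linalg.eigvalsh(a)
        if vals.min() < 0:
            a = nearest_pd(a, tol=1e-8, max_iter=100)
            vals = np.linalg.eigvalsh(a)
        null_eigs[d] = np.sort(vals)[::-1]
    null_q = np.quantile(null_eigs, quantile, axis=0)
    n_ret = int(np.sum(observed > null_q))
    return ParallelResult(observed, null_q, n_ret, n_draws, seed)


def random_grouping_null(m: GeneticCorrMatrix, group_size: int,
                         n_draws: int, observed: NetworkDefinition,
                         seed: int = 0) -> NullR2Distribution:
    """Empirical null for a network's PC1 variance explained.

    Draws random same-size trait groups and records PC1 r² of each
    submatrix; the empirical p-value uses the add-one correction
    (1 + #{null >= observed}) / (n_draws + 1).  Null draws that coincide
    exactly with the observed member set are redrawn (the null describes
    *alternative* groupings), except in the degenerate ``group_size == p``
    case where no alternative exists and every draw equals the observed.
    """
    p = m.k
    if not (2 <= group_size <= p):
        raise InputError(f"group_size must be in [2, {p}]")
    if n_draws < 100:
        raise InputError("random-grouping null needs n_draws >= 100")
    observed.validate_against(m.labels)

    def pc1_r2(sub: np.ndarray) -> float:
        return float(np.linalg.eigvalsh(sub).max() / sub.shape[0])

    idx_obs = np.array([m.labels.index(t) for t in observed.members])
    obs = pc1_r2(m.r_g[np.ix_(idx_obs, idx_obs)])
    if group_size == p:
        log.info("group_size equals the number of traits: all null draws "
                 "coincide with the full matrix")
    rng = np.random.default_rng(seed)
    obs_set = frozenset(idx_obs.tolist())
    null = np.empty(n_draws)
    for d in range(n_draws):
        for _ in range(1000):
            idx = rng.choice(p, size=group_size, replace=False)
            if group_size == p or frozenset(idx.tolist()) != obs_set:
                break
        null[d] = pc1_r2(m.r_g[np.ix_(idx, idx)])
    p_emp = (1 + int(np.sum(null >= obs - 1e-12))) / (n_draws + 1)
    return NullR2Distribution(observed_r2=obs, null_r2=null, p_emp=p_emp)


# ---------------------------------------------------------------------------
# PC-GWAS synthesis

def synthesize_pc_sumstats(tables: Sequence[SumStatsTable],
                           loadings: Sequence[float],
                           cti: np.ndarray) -> PcSumStats:
    """Combine per-trait GWAS into one PC-level GWAS.

    ``loadings`` is the length-k PC1 loading vector (any positive rescaling
    gives the same z_pc); ``cti`` the k×k cross-trait-intercept matrix
    whose diagonal convention the caller chooses (see
    :meth:`GeneticCorrMatrix.cti_with_diag`).  Alleles, positions and
    frequencies are copied from the first table's (reference) frame; beta
    and se are back-converted on the standardised scale via
    beta = z / √(n_eff · 2·p·(1−p)).
    """
    k = len(tables)
    w = np.asarray(loadings, dtype=float)
    if w.shape != (k,) or not np.isfinite(w).all():
        raise InputError("loadings must be a finite length-k vector")
    cti = np.asarray(cti, dtype=float)
    if cti.shape != (k, k) or not np.allclose(cti, cti.T, atol=1e-8):
        raise InputError("cti must be a symmetric k x k matrix")
    from .ldsc import _check_same_frame
    _check_same_frame(tables)

    denom2 = float(w @ cti @ w)
    if denom2 <= 0:
        raise InputError(
            f"w'·CTI·w = {denom2:.4g} <= 0: intercept matrix inconsistent "
            "with the loading vector")
    denom = np.sqrt(denom2)

    Z = np.column_stack([t.df["z"].to_numpy(float) for t in tables])
    sqN = np.column_stack([np.sqrt(t.df["n"].to_numpy(float)) for t in tables])
    z_pc = Z @ w / denom
    n_eff = (sqN @ w) ** 2 / denom2

    ref = tables[0].df
    p_j = ref["eaf"].to_numpy(float)
    het = 2.0 * p_j * (1.0 - p_j)
    se = 1.0 / np.sqrt(n_eff * het)
    beta = z_pc * se

    df = pd.DataFrame({
        "snp": ref["snp"], "chrom": ref["chrom"], "bp": ref["bp"],
        "a1": ref["a1"], "a2": ref["a2"], "eaf": p_j,
        "z_pc": z_pc, "n_eff": n_eff, "beta": beta, "se": se,
    })
    return PcSumStats(df=df, weights=w, denom=denom,
                      trait_labels=[t.trait_label for t in tables])


def write_scree(pca: PcaResult, path, header_lines: Sequence[str] = ()) -> None:
    """Write eigenvalues / r2 per component as delimited text."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pca.scree_frame().to_csv(fh, sep="\t", index=False,
                                 float_format="%.12g")
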