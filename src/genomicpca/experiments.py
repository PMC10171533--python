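"""End-to-end simulation experiments exercising the whole pipeline.

Each function composes simulator → per-trait GWAS → LDSC correlation
matrix → genetic PCA → PC-GWAS synthesis and measures one recoverable
property of the method:

* :func:`pc_gwas_validation` — the headline check: the genetic
  correlation between the synthesized genetic-PC1 GWAS and a GWAS run
  directly on phenotypic PC1 scores of the same individuals.
* :func:`intercept_phenotype_agreement` — under full sample overlap the
  LDSC cross-trait intercepts should track the true phenotypic
  correlations; measured as OLS R² over all trait pairs.
* :func:`null_calibration` — with zero heritability everywhere, the
  overlap-corrected synthesized statistics should keep mean χ² ≈ 1.
* :func:`factor_pc_experiment` — a one-factor "cognitive" battery plus a
  brain-trait block with a known factor–factor correlation; recovers the
  genetic correlation between the fitted common factor and the
  synthesized brain PC1.

Problem sizes default to desk scale (10⁴ individuals, a few 10⁴ SNPs);
every function is deterministic given its seed.
"""
from __future__ import annotations

import logging

import numpy as np

from .factor import factor_external_correlation, fit_common_factor
from .ldsc import cross_trait_ldsc, genetic_correlation_matrix
from .pca import genomic_pca, synthesize_pc_sumstats
from .pheno import compare_vectors, tucker_congruence
from .sim import SimConfig, make_study

log = logging.getLogger(__name__)


def pc_gwas_validation(seed: int = 0, cfg: SimConfig | None = None,
                       n_blocks: int = 200, cti_diag: str = "one") -> dict:
    """Synthesized genetic-PC1 GWAS vs direct phenotypic-PC1 GWAS.

    Defaults reproduce the validation design: 10 traits with factor
    loadings 0.8 and h² = 0.3 on 10,000 fully overlapping individuals,
    20,000 SNPs in LD blocks of 10 with latent correlation 0.8.  Returns
    the cross-trait LDSC genetic correlation between the two PC1 GWAS
    plus the intermediate objects.
    """
    if cfg is None:
        cfg = SimConfig(k=10, n_ind=10_000, n_snp=20_000, block_size=10,
                        block_rho=0.8, lambda_g=0.8, h2=0.3, overlap="full",
                        seed=seed)
    study = make_study(cfg)
    gcm = genetic_correlation_matrix(study.sumstats, study.true_ld, n_blocks)
    pca_res = genomic_pca(gcm)
    pc_ss = synthesize_pc_sumstats(study.sumstats, pca_res.pc1_loadings(),
                                   gcm.cti_with_diag(cti_diag))
    fit = cross_trait_ldsc(pc_ss.to_sumstats("genetic_pc1"),
                           study.pheno_pc1_sumstats, study.true_ld, n_blocks)
    congruence = tucker_congruence(pca_res.pc1_loadings(),
                                   study.pheno_pca.pc1_loadings())
    log.info("PC-GWAS validation: rg = %.4f (SE %.4f), PC1 R² = %.3f, "
             "Tucker = %.4f", fit.rg, fit.rg_se, pca_res.r2[0], congruence)
    return {"rg": fit.rg, "rg_se": fit.rg_se, "fit": fit,
            "pc1_r2": float(pca_res.r2[0]), "tucker": congruence,
            "study": study, "gcm": gcm, "pca": pca_res, "pc_sumstats": pc_ss}


def _default_t2_loadings() -> np.ndarray:
    # spread of factor loadings whose pairwise products (the true
    # phenotypic correlations in the Cheverud regime with equal h2)
    # cover roughly [-0.2, 0.9]
    return np.append(np.linspace(-0.22, 0.9, 18), [0.95, 0.95])


def intercept_phenotype_agreement(seed: int = 0,
                                  cfg: SimConfig | None = None,
                                  n_blocks: int = 200) -> dict:
    """Regress estimated cross-trait intercepts on true phenotypic correlations.

    Defaults: 20 fully overlapping traits on 10,000 individuals and
    50,000 SNPs, with true phenotypic correlations spread over roughly
    [−0.2, 0.9].  Returns the OLS summary over the k(k−1)/2 pairs.
    """
    if cfg is None:
        cfg = SimConfig(k=20, n_ind=10_000, n_snp=50_000, block_size=10,
                        lambda_g=_default_t2_loadings(),
                        h2=0.3, overlap="full", seed=seed)
    study = make_study(cfg)
    gcm = genetic_correlation_matrix(study.sumstats, study.true_ld, n_blocks)
    iu = np.triu_indices(cfg.k, 1)
    comp = compare_vectors(study.truth.phen_corr[iu], gcm.cti[iu])
    log.info("intercept vs phenotypic correlation: R² = %.4f, slope = %.3f",
             comp.r2, comp.slope)
    return {"r2": comp.r2, "slope": comp.slope, "comparison": comp,
            "study": study, "gcm": gcm,
            "cti": gcm.cti[iu], "true_phen": study.truth.phen_corr[iu]}


def null_calibration(seed: int = 0, k: int = 5, n_ind: int = 4_000,
                     n_snp: int = 10_000, n_blocks: int = 100) -> dict:
    """Mean χ² of the synthesized PC statistics in an all-noise study.

    All traits have h² = 0 but share correlated environmental noise, so
    their Z statistics are correlated through sample overlap alone.  The
    CTI denominator of the synthesis must absorb exactly that, keeping
    the combined statistic calibrated (mean χ² ≈ 1).  Loadings cannot
    come from a genetic PCA here (there is no genetic signal), so equal
    weights are used.
    """
    cfg = SimConfig(k=k, n_ind=n_ind, n_snp=n_snp, block_size=10,
                    block_rho=0.8, lambda_g=0.63, h2=0.0,
                    env_corr="cheverud", overlap="full", seed=seed)
    study = make_study(cfg)
    cti = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            fit = cross_trait_ldsc(study.sumstats[i], study.sumstats[j],
                                   study.true_ld, n_blocks)
            cti[i, j] = cti[j, i] = fit.cti
    w = np.full(k, 1.0 / np.sqrt(k))
    pc = synthesize_pc_sumstats(study.sumstats, w, cti)
    mean_chisq = float(np.mean(pc.df["z_pc"] ** 2))
    log.info("null calibration: mean chi^2 of synthesized PC = %.4f",
             mean_chisq)
    return {"mean_chisq": mean_chisq, "study": study, "cti": cti,
            "pc_sumstats": pc}


def factor_pc_experiment(seed: int = 0, n_ind: int = 6_000,
                         n_snp: int = 12_000, n_blocks: int = 100,
                         target_rg: float = 0.2) -> dict:
    """Common cognitive factor vs synthesized brain PC1.

    Simulates 7 single-factor "cognitive" indicators and 8 "brain"
    traits loading on a second genetic factor; the factor–factor
    correlation is calibrated so the true genetic correlation between the
    cognitive factor and the brain PC1 composite equals ``target_rg``.
    Returns the recovered correlation and the implied truth.
    """
    lam_cog = np.array([0.85, 0.8, 0.75, 0.7, 0.6, 0.5, 0.9])
    k_cog = len(lam_cog)
    k_brain = 8
    lam_b = 0.8
    # the PC1 composite of the brain block carries the shared factor at
    # weight lam_b and averaged unique parts at variance (1-lam_b^2)/k
    atten = lam_b / np.sqrt(lam_b ** 2 + (1 - lam_b ** 2) / k_brain)
    rho_f = target_rg / atten
    implied = rho_f * atten

    lam = np.concatenate([lam_cog, np.full(k_brain, lam_b)])
    assign = np.array([0] * k_cog + [1] * k_brain)
    fcorr = np.array([[1.0, rho_f], [rho_f, 1.0]])
    cfg = SimConfig(k=k_cog + k_brain, n_ind=n_ind, n_snp=n_snp,
                    block_size=10, block_rho=0.8, lambda_g=lam, h2=0.3,
                    factor_assign=assign, factor_corr=fcorr,
                    overlap="full", seed=seed)
    study = make_study(cfg)
    cog = study.sumstats[:k_cog]
    brain = study.sumstats[k_cog:]

    gcm_brain = genetic_correlation_matrix(brain, study.true_ld, n_blocks)
    pca_res = genomic_pca(gcm_brain)
    pc_ss = synthesize_pc_sumstats(brain, pca_res.pc1_loadings(),
                                   gcm_brain.cti_with_diag("one"))
    gcm_ext = genetic_correlation_matrix(
        cog + [pc_ss.to_sumstats("brain_pc1")], study.true_ld, n_blocks)
    base = fit_common_factor(gcm_ext.restrict([t.trait_label for t in cog]))
    fit = factor_external_correlation(gcm_ext, base)
    log.info("factor-PC experiment: rho = %.4f (implied truth %.4f)",
             fit.factor_external_r, implied)
    return {"rho": fit.factor_external_r, "implied": implied,
            "fit": fit, "base_fit": base, "gcm_ext": gcm_ext,
            "true_lambda_cog": lam_cog}
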