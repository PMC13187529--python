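"""Summary-data-based MR (SMR) and the HEIDI heterogeneity test.

SMR combines the top cis-eQTL's effect on expression with its effect on
the trait into a single ratio ``b_smr = b_gwas / b_eqtl`` and a 1-df
chi-square statistic ``T = z_g^2 z_e^2 / (z_g^2 + z_e^2)``.  A significant
SMR p-value is compatible with two genetic architectures: one variant
affecting both expression and trait (pleiotropy / a shared causal
variant) or two distinct variants in LD (linkage).  HEIDI distinguishes
them: under a single shared variant, every SNP in the region implies the
same b_smr, so the deviations ``d_i = b_smr(i) - b_smr(top)`` are jointly
zero in expectation.  HEIDI sums the squared standardized deviations and
compares the total against its null distribution — a weighted sum of
correlated 1-df chi-squares whose tail is approximated by Satterthwaite
moment matching on the eigenvalues of the correlation matrix of ``d``.

A drug-target candidate "passes" when the SMR test is significant and
HEIDI is not (no evidence of linkage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import LDMatrix


@dataclass
class HeidiConfig:
    eqtl_p_max: float = 1.57e-3  # |z_eqtl| > ~3.16, the published tool's default
    r2_min: float = 0.05
    r2_max: float = 0.9
    max_snps: int = 20
    min_heidi_snps: int = 3


@dataclass
class SMRResult:
    b_smr: float
    t_smr: float
    p_smr: float
    p_heidi: float | None
    n_heidi_snps: int
    verdict: str  # pass | fail-smr | fail-heidi | heidi-undetermined


def smr_test(b_eqtl: float, se_eqtl: float, b_gwas: float, se_gwas: float):
    """Returns ``(b_smr, t_smr, p_smr)`` for the top eQTL SNP."""
    if b_eqtl == 0:
        raise ValueError("SMR ratio undefined for b_eqtl == 0")
    z_e = b_eqtl / se_eqtl
    z_g = b_gwas / se_gwas
    t_smr = (z_g**2 * z_e**2) / (z_g**2 + z_e**2)
    return b_gwas / b_eqtl, float(t_smr), float(stats.chi2.sf(t_smr, 1))


def _heidi_covariance(bg, sg, be, se, r_mat, top: int) -> np.ndarray:
    """First-order delta-method covariance of d_i = bg_i/be_i - bg_top/be_top.

    GWAS and eQTL estimates come from independent samples; within each
    study the estimation errors correlate as the LD matrix.
    """
    others = [i for i in range(len(bg)) if i != top]
    m = len(others)
    # Jacobian wrt (bg_1..bg_k, be_1..be_k) stacked per study
    jg = np.zeros((m, len(bg)))
    je = np.zeros((m, len(bg)))
    for row, i in enumerate(others):
        jg[row, i] = 1.0 / be[i]
        jg[row, top] = -1.0 / be[top]
        je[row, i] = -bg[i] / be[i] ** 2
        je[row, top] = bg[top] / be[top] ** 2
    cov_g = r_mat * np.outer(sg, sg)
    cov_e = r_mat * np.outer(se, se)
    return jg @ cov_g @ jg.T + je @ cov_e @ je.T


def satterthwaite_p(t_stat: float, corr: np.ndarray) -> float:
    """Tail of a sum of correlated 1-df chi-squares by moment matching.

    T ~ sum lambda_k chi2_1 with lambda the eigenvalues of ``corr``; match
    the first two moments with c * chi2_nu.
    """
    lam = np.linalg.eigvalsh(corr)
    lam = lam[lam > 1e-12]
    s1, s2 = lam.sum(), (lam**2).sum()
    if s2 == 0:
        return 1.0
    c = s2 / s1
    nu = s1**2 / s2
    return float(stats.chi2.sf(t_stat / c, nu))


def heidi_test(
    eqtl: pd.DataFrame,
    gwas: pd.DataFrame,
    ld: LDMatrix,
    config: HeidiConfig | None = None,
):
    """Returns ``(p_heidi, n_heidi_snps)``; ``p_heidi`` is None when too few
    SNPs are eligible (verdict "heidi-undetermined").

    The top SNP is the strongest eQTL.  Eligible companions have eQTL
    ``p < eqtl_p_max`` and LD r2 with the top SNP inside
    ``[r2_min, r2_max]``; the ``max_snps`` most significant are used.
    """
    config = config or HeidiConfig()
    eqtl = eqtl.set_index(eqtl["snp"].astype(str))
    gwas = gwas.set_index(gwas["snp"].astype(str))
    shared = [s for s in eqtl.index if s in gwas.index and s in ld.snp_ids]
    if not shared:
        raise ValueError("no SNPs shared between eQTL, GWAS and LD inputs")
    eqtl, gwas = eqtl.loc[shared], gwas.loc[shared]

    z_e = (eqtl["beta"] / eqtl["se"]).abs()
    top = str(z_e.idxmax())
    eligible = []
    for s in shared:
        if s == top:
            continue
        if float(eqtl.loc[s, "pval"]) >= config.eqtl_p_max:
            continue
        r2 = ld.r2(s, top)
        if not (config.r2_min <= r2 <= config.r2_max):
            continue
        eligible.append(s)
    eligible.sort(key=lambda s: float(eqtl.loc[s, "pval"]))
    eligible = eligible[: config.max_snps]
    if len(eligible) < config.min_heidi_snps:
        return None, len(eligible)

    snps = [top] + eligible
    sub = ld.submatrix(snps)
    bg = gwas.loc[snps, "beta"].to_numpy(dtype=float)
    sg = gwas.loc[snps, "se"].to_numpy(dtype=float)
    be = eqtl.loc[snps, "beta"].to_numpy(dtype=float)
    se = eqtl.loc[snps, "se"].to_numpy(dtype=float)

    b_smr = bg / be
    d = b_smr[1:] - b_smr[0]
    cov_d = _heidi_covariance(bg, sg, be, se, sub.r, top=0)
    sd = np.sqrt(np.diag(cov_d))
    t_stat = float(np.sum((d / sd) ** 2))
    corr = cov_d / np.outer(sd, sd)
    return satterthwaite_p(t_stat, corr), len(eligible)


def run_smr(
    eqtl: pd.DataFrame,
    gwas: pd.DataFrame,
    ld: LDMatrix,
    smr_alpha: float = 0.05,
    heidi_alpha: float = 0.05,
    heidi_config: HeidiConfig | None = None,
) -> SMRResult:
    """SMR on the top eQTL SNP followed by HEIDI over the region."""
    eqtl_idx = eqtl.set_index(eqtl["snp"].astype(str))
    gwas_idx = gwas.set_index(gwas["snp"].astype(str))
    shared = [s for s in eqtl_idx.index if s in gwas_idx.index]
    if not shared:
        raise ValueError("no SNPs shared between eQTL and GWAS inputs")
    z_e = (eqtl_idx.loc[shared, "beta"] / eqtl_idx.loc[shared, "se"]).abs()
    top = str(z_e.idxmax())
    b_smr, t_smr, p_smr = smr_test(
        float(eqtl_idx.loc[top, "beta"]),
        float(eqtl_idx.loc[top, "se"]),
        float(gwas_idx.loc[top, "beta"]),
        float(gwas_idx.loc[top, "se"]),
    )
    p_heidi, n_heidi = heidi_test(eqtl, gwas, ld, heidi_config)
    if p_smr >= smr_alpha:
        verdict = "fail-smr"
    elif p_heidi is None:
        verdict = "heidi-undetermined"
    elif p_heidi > heidi_alpha:
        verdict = "pass"
    else:
        verdict = "fail-heidi"
    return SMRResult(b_smr, t_smr, p_smr, p_heidi, n_heidi, verdict)
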