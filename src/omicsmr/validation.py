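"""Self-validation studies: calibration, recovery and discrimination.

Each function runs a simulation study against the package's own synthetic
generators with planted truth and returns the measured operating
characteristic — type-I error, bias, coverage, detection rate, recovery
index.  They are used by the test suite and by ``scripts/acceptance.py``;
problem sizes default to the replication counts the studies were designed
for.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import coexpr, synthdata
from .mr import HarmonizedInstrumentSet, ivw, mr_egger, weighted_median
from .smr import run_smr, satterthwaite_p


def _spawn(seed: int, offset: int) -> int:
    return int(np.random.SeedSequence([seed, offset]).generate_state(1)[0] % (2**31))


def _harmonized_from(exposure: pd.DataFrame, outcome: pd.DataFrame) -> HarmonizedInstrumentSet:
    return HarmonizedInstrumentSet.from_arrays(
        exposure["beta"], exposure["se"], outcome["beta"], outcome["se"],
        snps=list(exposure["snp"]),
    )


def ivw_null_calibration(n_reps: int = 1000, seed: int = 0, alpha: float = 0.05) -> float:
    """Type-I error of IVW at ``alpha`` with 10 strong independent SNPs."""
    ld = synthdata.simulate_ld_matrix(10, rho=0.0)
    rejections = 0
    for i in range(n_reps):
        exposure, outcome, _ = synthdata.simulate_two_sample_study(
            10, ld, theta=0.0, seed=_spawn(seed, i)
        )
        rejections += ivw(_harmonized_from(exposure, outcome)).pval < alpha
    return rejections / n_reps


def ivw_recovery(theta: float = 0.3, n_reps: int = 500, seed: int = 0):
    """Returns ``(mean bias, 95% CI coverage)`` for IVW at the given theta."""
    ld = synthdata.simulate_ld_matrix(10, rho=0.0)
    estimates, covered = [], 0
    for i in range(n_reps):
        exposure, outcome, _ = synthdata.simulate_two_sample_study(
            10, ld, theta=theta, seed=_spawn(seed, 10_000 + i)
        )
        res = ivw(_harmonized_from(exposure, outcome), random_effects=False)
        estimates.append(res.beta)
        covered += res.beta - 1.96 * res.se <= theta <= res.beta + 1.96 * res.se
    return float(np.mean(estimates) - theta), covered / n_reps


def egger_intercept_recovery(
    pleiotropy_mean: float = 0.05, n_reps: int = 500, seed: int = 0
) -> float:
    """Mean MR-Egger intercept under directional pleiotropy.

    Exposure effects are oriented positive with spread instrument
    strengths — the regime (InSIDE plus strength variation) in which the
    Egger intercept identifies the mean direct effect.
    """
    ld = synthdata.simulate_ld_matrix(10, rho=0.0)
    intercepts = []
    for i in range(n_reps):
        exposure, outcome, _ = synthdata.simulate_two_sample_study(
            10, ld, theta=0.3, pleiotropy_mean=pleiotropy_mean, pleiotropy_sd=0.01,
            seed=_spawn(seed, 20_000 + i), oriented_effects=True,
            exposure_effect_mean=0.2, exposure_effect_sd=0.08,
        )
        _, intercept, _, _ = mr_egger(_harmonized_from(exposure, outcome))
        intercepts.append(intercept)
    return float(np.mean(intercepts))


def weighted_median_robustness(n_reps: int = 200, seed: int = 0) -> float:
    """How often the weighted median beats IVW with half the instruments
    carrying directional pleiotropy (the invalid half is less precise, so
    the majority of weight stays valid)."""
    ld = synthdata.simulate_ld_matrix(10, rho=0.0)
    theta, wins = 0.3, 0
    for i in range(n_reps):
        exposure, outcome, _ = synthdata.simulate_two_sample_study(
            10, ld, theta=theta, seed=_spawn(seed, 30_000 + i), oriented_effects=True
        )
        by = outcome["beta"].to_numpy().copy()
        sy = outcome["se"].to_numpy().copy()
        sy[:5] *= 2.0
        by[:5] += 0.25
        hset = HarmonizedInstrumentSet.from_arrays(exposure["beta"], exposure["se"], by, sy)
        wm = weighted_median(hset, n_boot=200, seed=_spawn(seed, 40_000 + i))
        iv = ivw(hset)
        wins += abs(wm.beta - theta) < abs(iv.beta - theta)
    return wins / n_reps


def heidi_discrimination(n_reps: int = 200, seed: int = 0):
    """Returns ``(pleiotropy retention rate, linkage detection rate)``:
    the fraction of shared-causal-variant regions with HEIDI p > 0.05 and
    of two-variant (r = 0.5) regions with HEIDI p < 0.05."""
    retained = detected = 0
    for i in range(n_reps):
        eqtl, gwas, ld, _ = synthdata.simulate_smr_region(
            "pleiotropy", seed=_spawn(seed, 50_000 + i)
        )
        res = run_smr(eqtl, gwas, ld)
        retained += res.p_heidi is not None and res.p_heidi > 0.05
        eqtl, gwas, ld, _ = synthdata.simulate_smr_region(
            "linkage", r_linkage=0.5, seed=_spawn(seed, 60_000 + i)
        )
        res = run_smr(eqtl, gwas, ld)
        detected += res.p_heidi is not None and res.p_heidi < 0.05
    return retained / n_reps, detected / n_reps


def satterthwaite_tail_accuracy(seed: int = 0, n_draws: int = 100_000, dim: int = 6) -> float:
    """Satterthwaite p evaluated at the Monte-Carlo 5% critical value of a
    correlated chi-square sum (exact agreement would give 0.05)."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((dim, dim))
    cov = a @ a.T
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(dim))
    z = chol @ rng.standard_normal((dim, n_draws))
    t_crit = float(np.quantile((z**2).sum(axis=0), 0.95))
    return satterthwaite_p(t_crit, corr)


def dea_null_uniformity(n_genes: int = 5000, seed: int = 0) -> float:
    """Kolmogorov-Smirnov p for uniformity of DEA p-values under the
    global null (no modules, no fold changes)."""
    matrix, samples, _ = synthdata.simulate_expression_study(
        n_genes=n_genes, n_samples_per_group=(10, 10), n_modules=0, module_sizes=(),
        de_fraction=0.0, de_log2fc=0.0, batch_offsets=(0.0,), batch_scales=(1.0,),
        noise_sd=0.3, seed=seed,
    )
    deg = coexpr.differential_expression(matrix, samples)
    return float(stats.kstest(deg["pval"], "uniform").pvalue)


def dea_planted_recovery(seed: int = 0):
    """Returns ``(called, planted)`` DEG counts for 4-fold shifts at low noise."""
    matrix, samples, truth = synthdata.simulate_expression_study(
        n_genes=1000, n_samples_per_group=(10, 10), n_modules=0, module_sizes=(),
        de_fraction=0.05, de_log2fc=2.0, batch_offsets=(0.0,), batch_scales=(1.0,),
        noise_sd=0.2, seed=seed,
    )
    deg = coexpr.differential_expression(matrix, samples)
    return int((deg["status"] != "ns").sum()), len(truth.de_gene_ids)


def wgcna_scale_free_fit(seed: int = 0):
    """Returns ``(signed fit at the chosen power, chosen power)`` on
    graded-membership data."""
    matrix, *_ = synthdata.simulate_expression_study(
        **synthdata.GRADED_NETWORK_KWARGS, seed=seed
    )
    table, power = coexpr.pick_soft_threshold(matrix)
    return float(table.loc[table["power"] == power, "fit"].iloc[0]), int(power)


def wgcna_module_recovery(seed: int = 0, power: int = 6) -> float:
    """Adjusted Rand index of detected vs planted modules on
    well-separated data at the reference unsigned-network power."""
    matrix, _, truth = synthdata.simulate_expression_study(
        **synthdata.SEPARATED_MODULE_KWARGS, seed=seed
    )
    tom = coexpr.tom_similarity(coexpr.adjacency_matrix(matrix, power))
    labels = coexpr.detect_modules(tom, matrix.index, min_module_size=5)
    return float(
        adjusted_rand_score([truth.module_assignment[g] for g in labels.index], labels)
    )


def trait_module_win_rate(n_reps: int = 200, seed: int = 0) -> float:
    """How often the planted trait module has the top module-trait |cor|
    (eigengenes over the true gene-module assignment, default study)."""
    wins = 0
    for i in range(n_reps):
        matrix, samples, truth = synthdata.simulate_expression_study(
            seed=_spawn(seed, 70_000 + i)
        )
        adjusted = coexpr.adjust_batch(matrix, samples)
        labels = pd.Series(
            {g: truth.module_assignment[g] for g in matrix.index}
        ).replace("none", coexpr.GREY)
        eigengenes = coexpr.module_eigengenes(adjusted, labels)
        trait = (
            samples.set_index("sample").loc[matrix.columns, "group"] == "case"
        ).astype(float).to_numpy()
        mt = coexpr.module_trait_stats(eigengenes, trait)
        wins += mt["cor"].abs().idxmax() in truth.trait_assoc_modules
    return wins / n_reps
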