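"""Two-sample Mendelian randomization estimators and sensitivity suite.

Exposure and outcome summary statistics are first harmonized to a common
effect allele (sign-flipping swapped alleles, resolving strand flips, and
dropping palindromic SNPs with intermediate allele frequency).  Causal
effects are then estimated with the Wald ratio (single SNP) or, for
multi-SNP sets, inverse-variance weighting (IVW), MR-Egger regression,
the weighted median and the weighted mode.  Heterogeneity (Cochran's Q),
directional pleiotropy (Egger intercept) and influence (leave-one-out)
diagnostics accompany the estimates.

Effects are on the log-odds scale for a binary outcome, so ``exp(beta)``
is an odds ratio; 95% intervals are ``exp(beta -/+ 1.96 se)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_Z95 = 1.96


class InsufficientSnpsError(ValueError):
    """Raised when an estimator needs more instruments than are available."""


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class MRResult:
    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.or_ = math.exp(self.beta)
        self.ci_low = math.exp(self.beta - _Z95 * self.se)
        self.ci_high = math.exp(self.beta + _Z95 * self.se)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "pval": self.pval,
            "or": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_snp": self.n_snp,
        }


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


@dataclass
class SensitivityReport:
    q_ivw: float | None = None
    q_df_ivw: int | None = None
    q_p_ivw: float | None = None
    q_egger: float | None = None
    q_df_egger: int | None = None
    q_p_egger: float | None = None
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    loo: pd.DataFrame | None = None


@dataclass
class HarmonizedInstrumentSet:
    """Per-SNP exposure/outcome effects aligned to a common effect allele."""

    table: pd.DataFrame  # snp, bx, sx, by, sy, ea, oa, eaf_exposure, eaf_outcome
    dropped: list = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.table
        if len(t) and (t["bx"] == 0).any():
            raise ValueError("harmonized set contains bx == 0")
        self.table = t.assign(
            ratio=t["by"] / t["bx"], ratio_se=t["sy"] / t["bx"].abs()
        ).reset_index(drop=True)

    @classmethod
    def from_arrays(cls, bx, sx, by, sy, snps=None) -> "HarmonizedInstrumentSet":
        bx = np.asarray(bx, dtype=float)
        snps = snps if snps is not None else [f"rs{i + 1}" for i in range(len(bx))]
        return cls(
            pd.DataFrame(
                {
                    "snp": snps,
                    "bx": bx,
                    "sx": np.asarray(sx, dtype=float),
                    "by": np.asarray(by, dtype=float),
                    "sy": np.asarray(sy, dtype=float),
                    "ea": "A",
                    "oa": "G",
                    "eaf_exposure": np.nan,
                    "eaf_outcome": np.nan,
                }
            )
        )

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, mask) -> "HarmonizedInstrumentSet":
        cols = [c for c in self.table.columns if c not in ("ratio", "ratio_se")]
        return HarmonizedInstrumentSet(self.table.loc[mask, cols], dropped=list(self.dropped))


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea.upper()) == oa.upper()


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_af_tolerance: float = 0.08,
) -> HarmonizedInstrumentSet:
    """Align outcome effects to the exposure's effect allele, SNP by SNP.

    Swapped alleles negate the outcome beta and mirror its frequency;
    strand complements are flipped before alignment.  Palindromic (A/T or
    C/G) SNPs whose effect-allele frequency lies within
    ``palindromic_af_tolerance`` of 0.5 in either study are dropped as
    unresolvable; other palindromic SNPs are aligned by frequency
    concordance.  SNPs with a zero exposure effect are dropped because the
    Wald ratio is undefined for them.
    """
    out_by_snp = outcome.set_index(outcome["snp"].astype(str))
    rows, dropped = [], []
    shared = 0
    for rec in exposure.itertuples(index=False):
        snp = str(rec.snp)
        if snp not in out_by_snp.index:
            continue
        shared += 1
        o = out_by_snp.loc[snp]
        ea_x, oa_x = str(rec.ea).upper(), str(rec.oa).upper()
        ea_y, oa_y = str(o["ea"]).upper(), str(o["oa"]).upper()
        by, eaf_y = float(o["beta"]), float(o["eaf"])
        eaf_x = float(rec.eaf)

        if rec.beta == 0:
            dropped.append((snp, "zero-exposure-effect"))
            continue

        if _is_palindromic(ea_x, oa_x):
            if {ea_y, oa_y} != {ea_x, oa_x}:
                dropped.append((snp, "allele-mismatch"))
                continue
            if (
                abs(eaf_x - 0.5) <= palindromic_af_tolerance
                or abs(eaf_y - 0.5) <= palindromic_af_tolerance
            ):
                dropped.append((snp, "palindromic-intermediate"))
                continue
            # strand is unresolvable from allele labels; align by frequency
            if (eaf_x - 0.5) * (eaf_y - 0.5) < 0:
                by, eaf_y = -by, 1.0 - eaf_y
        else:
            flipped = (_COMPLEMENT.get(ea_y, "?"), _COMPLEMENT.get(oa_y, "?"))
            if (ea_y, oa_y) == (ea_x, oa_x) or flipped == (ea_x, oa_x):
                pass
            elif (ea_y, oa_y) == (oa_x, ea_x) or flipped == (oa_x, ea_x):
                by, eaf_y = -by, 1.0 - eaf_y
            else:
                dropped.append((snp, "allele-mismatch"))
                continue

        rows.append(
            {
                "snp": snp,
                "bx": float(rec.beta),
                "sx": float(rec.se),
                "by": by,
                "sy": float(o["se"]),
                "ea": ea_x,
                "oa": oa_x,
                "eaf_exposure": eaf_x,
                "eaf_outcome": eaf_y,
            }
        )
    if shared == 0:
        raise ValueError("no SNPs shared between exposure and outcome")
    return HarmonizedInstrumentSet(pd.DataFrame(rows, columns=[
        "snp", "bx", "sx", "by", "sy", "ea", "oa", "eaf_exposure", "eaf_outcome"
    ]), dropped=dropped)


def wald_ratio(
    bx: float, sx: float, by: float, sy: float, second_order: bool = False
) -> MRResult:
    """Single-instrument causal estimate by/bx with delta-method SE."""
    if bx == 0:
        raise ValueError("Wald ratio undefined for bx == 0")
    beta = by / bx
    if second_order:
        se = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / abs(bx)
    return MRResult("wald_ratio", beta, se, _normal_p(beta / se), 1)


def ivw(hset: HarmonizedInstrumentSet, random_effects: bool = True) -> MRResult:
    """Inverse-variance-weighted average of per-SNP Wald ratios.

    Equivalent to weighted least squares of by on bx through the origin
    with weights 1/sy^2.  Under the default multiplicative-random-effects
    model the SE is inflated by max(1, sqrt(Q / (n - 1))).
    """
    if len(hset) < 2:
        raise InsufficientSnpsError("IVW needs >= 2 SNPs; use wald_ratio")
    r = hset.table["ratio"].to_numpy()
    w = 1.0 / hset.table["ratio_se"].to_numpy() ** 2
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    if random_effects:
        q = float(np.sum(w * (r - beta) ** 2))
        se *= max(1.0, math.sqrt(q / (len(r) - 1)))
    return MRResult("ivw", beta, se, _normal_p(beta / se), len(r))


def mr_egger(hset: HarmonizedInstrumentSet, t_dist: bool = False):
    """Weighted regression of by on bx with intercept (pleiotropy probe).

    Pairs are oriented so bx >= 0 before fitting; weights are 1/sy^2 and
    SEs are inflated by max(1, sqrt(Q_egger / (n - 2))).

    Returns ``(slope MRResult, intercept, intercept_se, intercept_p)``.
    """
    if len(hset) < 3:
        raise InsufficientSnpsError("MR-Egger needs >= 3 SNPs")
    t = hset.table
    flip = np.sign(t["bx"].to_numpy())
    flip[flip == 0] = 1.0
    bx = t["bx"].to_numpy() * flip
    by = t["by"].to_numpy() * flip
    w = 1.0 / t["sy"].to_numpy() ** 2
    x = np.column_stack([np.ones_like(bx), bx])
    xtw = x.T * w
    cov = np.linalg.inv(xtw @ x)
    coef = cov @ (xtw @ by)
    resid = by - x @ coef
    n = len(bx)
    q = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(q / (n - 2)))
    se_int = math.sqrt(cov[0, 0]) * scale
    se_slope = math.sqrt(cov[1, 1]) * scale
    if t_dist:
        p_slope = float(2.0 * stats.t.sf(abs(coef[1] / se_slope), n - 2))
        p_int = float(2.0 * stats.t.sf(abs(coef[0] / se_int), n - 2))
    else:
        p_slope = _normal_p(coef[1] / se_slope)
        p_int = _normal_p(coef[0] / se_int)
    slope = MRResult("mr_egger", float(coef[1]), se_slope, p_slope, n)
    return slope, float(coef[0]), se_int, p_int


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    p = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, p, r))


def weighted_median(
    hset: HarmonizedInstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MRResult:
    """Weight-interpolated median of the ratio estimates.

    With weights w_j = 1/ratio_se_j^2 the estimate is the ratio at
    standardized cumulative weight 0.5 (linear interpolation between
    knots).  The SE is a parametric bootstrap: ratios are resampled from
    N(ratio_j, ratio_se_j^2) ``n_boot`` times with a fixed seed.
    """
    if len(hset) < 3:
        raise InsufficientSnpsError("weighted median needs >= 3 SNPs")
    r = hset.table["ratio"].to_numpy()
    s = hset.table["ratio_se"].to_numpy()
    w = 1.0 / s**2
    beta = _weighted_median_point(r, w)
    rng = np.random.default_rng(seed)
    draws = r[None, :] + s[None, :] * rng.standard_normal((n_boot, len(r)))
    boot = np.array([_weighted_median_point(d, w) for d in draws])
    se = float(boot.std(ddof=1))
    return MRResult("weighted_median", beta, se, _normal_p(beta / se), len(r))


def weighted_mode(
    hset: HarmonizedInstrumentSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    grid_size: int = 2048,
) -> MRResult:
    """Mode of the weighted kernel density over the ratio estimates.

    Normal kernel; bandwidth is the modified Silverman rule
    ``0.9 min(sd, mad) n^(-1/5)`` on the ratios, scaled by
    ``bandwidth_factor``.  SE by parametric bootstrap with fixed seed.
    """
    if len(hset) < 3:
        raise InsufficientSnpsError("weighted mode needs >= 3 SNPs")
    r = hset.table["ratio"].to_numpy()
    s = hset.table["ratio_se"].to_numpy()
    w = 1.0 / s**2
    w = w / w.sum()

    def mode_point(vals: np.ndarray) -> float:
        spread = min(
            float(np.std(vals, ddof=1)),
            float(stats.median_abs_deviation(vals, scale="normal")) or np.inf,
        )
        h = bandwidth_factor * 0.9 * spread * len(vals) ** (-0.2)
        if not np.isfinite(h) or h <= 0:
            h = max(1e-8, 1e-3 * (np.abs(vals).max() or 1.0))
        grid = np.linspace(vals.min() - 3 * h, vals.max() + 3 * h, grid_size)
        dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - vals[None, :]) / h) ** 2)).sum(axis=1)
        return float(grid[np.argmax(dens)])

    beta = mode_point(r)
    rng = np.random.default_rng(seed)
    draws = r[None, :] + s[None, :] * rng.standard_normal((n_boot, len(r)))
    boot = np.array([mode_point(d) for d in draws])
    se = float(boot.std(ddof=1))
    return MRResult("weighted_mode", beta, se, _normal_p(beta / se), len(r))


def cochran_q(hset: HarmonizedInstrumentSet, center: float, df: int | None = None):
    """Q = sum w_j (ratio_j - center)^2 with p from the chi-square upper tail."""
    if len(hset) < 2:
        raise InsufficientSnpsError("Cochran's Q needs >= 2 SNPs")
    r = hset.table["ratio"].to_numpy()
    w = 1.0 / hset.table["ratio_se"].to_numpy() ** 2
    q = float(np.sum(w * (r - center) ** 2))
    df = len(r) - 1 if df is None else df
    return q, df, float(stats.chi2.sf(q, df))


def leave_one_out(hset: HarmonizedInstrumentSet, random_effects: bool = True) -> pd.DataFrame:
    """IVW re-estimated with each SNP excluded in turn (input SNP order)."""
    if len(hset) < 3:
        raise InsufficientSnpsError("leave-one-out needs >= 3 SNPs")
    rows = []
    for i in range(len(hset)):
        mask = np.ones(len(hset), dtype=bool)
        mask[i] = False
        res = ivw(hset.subset(mask), random_effects=random_effects)
        rows.append({"excluded_snp": hset.table["snp"].iloc[i], **res.to_dict()})
    return pd.DataFrame(rows)


@dataclass
class MRConfig:
    palindromic_af_tolerance: float = 0.08
    random_effects: bool = True
    n_boot: int = 1000
    boot_seed: int = 20_240_101
    alpha: float = 0.05
    second_order_wald: bool = False


@dataclass
class MRAnalysis:
    results: pd.DataFrame
    sensitivity: SensitivityReport | None
    harmonized: HarmonizedInstrumentSet | None
    skip_reason: str | None = None

    @property
    def primary(self) -> pd.Series | None:
        """The headline estimate: Wald ratio for one SNP, IVW otherwise."""
        if self.results.empty:
            return None
        for method in ("ivw", "wald_ratio"):
            hit = self.results[self.results["method"] == method]
            if len(hit):
                return hit.iloc[0]
        return self.results.iloc[0]


def run_mr(
    exposure: pd.DataFrame, outcome: pd.DataFrame, config: MRConfig | None = None
) -> MRAnalysis:
    """Harmonize pre-selected instruments and dispatch the estimators.

    One harmonized SNP yields a single Wald-ratio row; two yield IVW; three
    or more yield IVW, MR-Egger, weighted median and weighted mode plus the
    full sensitivity report.
    """
    config = config or MRConfig()
    try:
        hset = harmonize(exposure, outcome, config.palindromic_af_tolerance)
    except ValueError as exc:
        return MRAnalysis(pd.DataFrame(), None, None, skip_reason=str(exc))
    n = len(hset)
    if n == 0:
        return MRAnalysis(pd.DataFrame(), None, hset, skip_reason="no SNPs survived harmonization")

    if n == 1:
        row = hset.table.iloc[0]
        res = wald_ratio(row["bx"], row["sx"], row["by"], row["sy"], config.second_order_wald)
        return MRAnalysis(results_to_frame([res]), None, hset)

    results = [ivw(hset, random_effects=config.random_effects)]
    report = SensitivityReport()
    report.q_ivw, report.q_df_ivw, report.q_p_ivw = cochran_q(hset, results[0].beta)
    if n >= 3:
        slope, intercept, int_se, int_p = mr_egger(hset)
        results.append(slope)
        report.egger_intercept, report.intercept_se, report.intercept_p = intercept, int_se, int_p
        # Q about the Egger fit: residual heterogeneity with n - 2 df
        t = hset.table
        flip = np.sign(t["bx"].to_numpy())
        flip[flip == 0] = 1.0
        fitted = intercept + slope.beta * (t["bx"].to_numpy() * flip)
        w = 1.0 / t["sy"].to_numpy() ** 2
        q_e = float(np.sum(w * (t["by"].to_numpy() * flip - fitted) ** 2))
        report.q_egger, report.q_df_egger = q_e, n - 2
        report.q_p_egger = float(stats.chi2.sf(q_e, n - 2))
        results.append(weighted_median(hset, config.n_boot, config.boot_seed))
        results.append(weighted_mode(hset, 1.0, config.n_boot, config.boot_seed))
        report.loo = leave_one_out(hset, random_effects=config.random_effects)
    return MRAnalysis(results_to_frame(results), report, hset)
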