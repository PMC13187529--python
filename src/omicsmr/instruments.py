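"""Instrumental-variable selection from exposure summary statistics.

A SNP qualifies as an instrument for a protein when it is genome-wide
significant (p < 5e-8), lies within the cis window around the encoding
gene's transcription start site (1 Mb), survives greedy LD clumping
(r2 > 0.001 within 10 Mb removed), and is a strong instrument (F >= 10,
with F approximated by the squared z statistic).  All threshold
comparisons are strict: p-values equal to the threshold are excluded,
r2 exactly at the threshold is tolerated, F exactly 10 is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata import LDMatrix


@dataclass
class InstrumentConfig:
    p_threshold: float = 5e-8
    cis_window: int = 1_000_000
    r2_threshold: float = 0.001
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0
    f_from_variance_explained: bool = False


@dataclass
class InstrumentSet:
    records: pd.DataFrame
    f_stats: pd.Series
    selection_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def snps(self) -> list[str]:
        return list(self.records["snp"])

    def __len__(self) -> int:
        return len(self.records)


def compute_f_statistic(beta: float, se: float) -> float:
    """Single-SNP instrument strength, F = (beta/se)^2."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def compute_f_statistic_r2(beta: float, eaf: float, n: float) -> float:
    """Variance-explained variant: R2 = 2 f (1-f) beta^2, F = R2 (n-2)/(1-R2)."""
    r2 = 2.0 * eaf * (1.0 - eaf) * beta**2
    if not 0.0 <= r2 < 1.0:
        raise ValueError("variance explained outside [0, 1)")
    return r2 * (n - 2) / (1.0 - r2)


def filter_significance(records: pd.DataFrame, p_threshold: float = 5e-8) -> pd.DataFrame:
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    return records[records["pval"] < p_threshold].copy()


def filter_cis(
    records: pd.DataFrame, gene_chr: str, gene_tss: int, window: int = 1_000_000
) -> pd.DataFrame:
    if window <= 0:
        raise ValueError("window must be positive")
    if records[["chr", "pos"]].isna().any().any():
        raise ValueError("records with missing chr/pos cannot be cis-filtered")
    keep = (records["chr"].astype(str) == str(gene_chr)) & (
        (records["pos"] - gene_tss).abs() <= window
    )
    return records[keep].copy()


def ld_clump(
    records: pd.DataFrame,
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
) -> pd.DataFrame:
    """Greedy p-value-ordered clumping.

    Iterate records by ascending p-value; each index SNP removes every
    not-yet-kept SNP within ``window_kb`` whose r2 with it exceeds
    ``r2_threshold``.  The output preserves genomic order.
    """
    missing = [s for s in records["snp"] if s not in ld.snp_ids]
    if missing:
        raise KeyError(f"SNPs absent from LD matrix: {missing}")
    order = records.sort_values("pval", kind="mergesort")
    kept: list[str] = []
    removed: set[str] = set()
    pos = dict(zip(records["snp"], records["pos"]))
    for snp in order["snp"]:
        if snp in removed:
            continue
        kept.append(snp)
        for other in order["snp"]:
            if other == snp or other in removed or other in kept:
                continue
            if abs(pos[other] - pos[snp]) <= window_kb * 1000 and ld.r2(snp, other) > r2_threshold:
                removed.add(other)
    out = records[records["snp"].isin(kept)].copy()
    return out.sort_values(["chr", "pos"], kind="mergesort").reset_index(drop=True)


def select_instruments(
    records: pd.DataFrame,
    ld: LDMatrix,
    gene_chr: str,
    gene_tss: int,
    config: InstrumentConfig | None = None,
) -> InstrumentSet:
    """Apply significance -> cis -> LD clump -> F filters, logging each SNP's fate."""
    config = config or InstrumentConfig()
    log = pd.DataFrame({"snp": records["snp"].astype(str)})
    log["status"] = "pass"
    log["reason"] = ""

    def mark(snps, reason):
        fail = log["snp"].isin(snps) & (log["status"] == "pass")
        log.loc[fail, ["status", "reason"]] = ["fail", reason]

    stage = filter_significance(records, config.p_threshold)
    mark(set(records["snp"]) - set(stage["snp"]), "not-significant")

    after_cis = filter_cis(stage, gene_chr, gene_tss, config.cis_window)
    mark(set(stage["snp"]) - set(after_cis["snp"]), "outside-cis-window")

    after_clump = ld_clump(after_cis, ld, config.r2_threshold, config.clump_window_kb)
    mark(set(after_cis["snp"]) - set(after_clump["snp"]), "ld-clumped")

    if config.f_from_variance_explained:
        f = after_clump.apply(
            lambda r: compute_f_statistic_r2(r["beta"], r["eaf"], r["n"]), axis=1
        )
    else:
        f = after_clump.apply(lambda r: compute_f_statistic(r["beta"], r["se"]), axis=1)
    f = pd.Series(np.asarray(f, dtype=float), index=after_clump.index)
    strong = f >= config.f_min if len(f) else pd.Series(dtype=bool)
    mark(set(after_clump.loc[~strong, "snp"]) if len(f) else set(), "weak-instrument")

    final = after_clump[strong].reset_index(drop=True) if len(f) else after_clump.iloc[0:0]
    f_final = pd.Series(
        f[strong].to_numpy() if len(f) else [], index=list(final["snp"]), name="f_stat"
    )
    return InstrumentSet(records=final, f_stats=f_final, selection_log=log)
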