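"""Transcriptomic stage: batch merging, differential expression and
weighted co-expression network analysis (WGCNA-core).

The chain mirrors a standard case/control microarray-style workflow on a
log2 expression matrix: quantile normalization across samples, per-batch
location-scale adjustment, per-gene Welch t-tests with Benjamini-Hochberg
FDR, then an unsigned soft-thresholded correlation network: scale-free
power selection, topological overlap (TOM), average-linkage module
detection, module eigengenes and module-trait statistics, plus the
target-gene Spearman correlation screen and gene-set intersections that
nominate "key genes".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

GREY = "grey"


# ---------------------------------------------------------------- normalization

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Map every sample (column) by rank onto the mean order-statistic profile.

    Tied ranks receive the average of the corresponding target values, so
    column distributions are identical afterwards up to tie handling.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    x = matrix.to_numpy(dtype=float)
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    ranks = pd.DataFrame(x).rank(method="average", axis=0).to_numpy()
    out = np.interp(ranks, np.arange(1, n + 1), reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def adjust_batch(matrix: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Location-scale batch adjustment, gene by gene.

    Each gene is centered and rescaled per batch onto the pooled per-gene
    mean and the pooled within-batch standard deviation.  Group labels are
    untouched; a batch with a single sample is an error because its scale
    is undefined.
    """
    batches = samples.set_index("sample").loc[matrix.columns, "batch"]
    counts = batches.value_counts()
    if (counts < 2).any():
        bad = list(counts[counts < 2].index)
        raise ValueError(f"batches with a single sample: {bad}")
    x = matrix.to_numpy(dtype=float)
    pooled_mean = x.mean(axis=1)
    # pooled within-batch variance: batch offsets must not inflate the target scale
    ss, df = np.zeros(x.shape[0]), 0
    for b in counts.index:
        cols = (batches == b).to_numpy()
        xb = x[:, cols]
        ss += ((xb - xb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += cols.sum() - 1
    pooled_sd = np.sqrt(ss / df)
    out = x.copy()
    for b in counts.index:
        cols = (batches == b).to_numpy()
        xb = x[:, cols]
        mb = xb.mean(axis=1, keepdims=True)
        sb = xb.std(axis=1, ddof=1, keepdims=True)
        scale = np.where(sb[:, 0] > 1e-12, pooled_sd / np.maximum(sb[:, 0], 1e-12), 1.0)
        out[:, cols] = (xb - mb) * scale[:, None] + pooled_mean[:, None]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ------------------------------------------------------- differential expression

def differential_expression(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch t-test (case vs control) with BH FDR.

    ``status`` is "up" when log2fc >= lfc_threshold and fdr <
    fdr_threshold (inclusive fold-change boundary, so an exact 2-fold gene
    at default thresholds is called), "down" symmetrically, else "ns".
    Genes with zero variance in both groups get the degenerate rule:
    p = 0 when the means differ, 1 otherwise, with a warning.
    """
    groups = samples.set_index("sample").loc[matrix.columns, "group"]
    case = matrix.loc[:, (groups == "case").to_numpy()].to_numpy(dtype=float)
    ctrl = matrix.loc[:, (groups == "control").to_numpy()].to_numpy(dtype=float)
    if case.shape[1] < 3 or ctrl.shape[1] < 3:
        raise ValueError("differential expression needs >= 3 samples per group")
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, pval = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    degenerate = (case.std(axis=1) == 0) & (ctrl.std(axis=1) == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero variance in both groups; "
            "p set to 0/1 by mean equality",
            stacklevel=2,
        )
        pval = np.where(degenerate, np.where(log2fc != 0, 0.0, 1.0), pval)
        t_stat = np.where(degenerate, np.where(log2fc != 0, np.inf, 0.0), t_stat)
    pval = np.nan_to_num(pval, nan=1.0)
    fdr = multipletests(pval, method="fdr_bh")[1]
    status = np.where(
        (log2fc >= lfc_threshold) & (fdr < fdr_threshold),
        "up",
        np.where((log2fc <= -lfc_threshold) & (fdr < fdr_threshold), "down", "ns"),
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "t_stat": t_stat, "pval": pval, "fdr": fdr, "status": status},
        index=matrix.index,
    )


# ----------------------------------------------------------------- WGCNA core

def _correlation(matrix: pd.DataFrame) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        cor = np.corrcoef(matrix.to_numpy(dtype=float))
    cor = np.nan_to_num(cor, nan=0.0)
    np.fill_diagonal(cor, 1.0)
    return cor


def adjacency_matrix(matrix: pd.DataFrame, power: float) -> np.ndarray:
    """Unsigned adjacency |cor|^power over genes (rows of ``matrix``)."""
    return np.abs(_correlation(matrix)) ** power


def scale_free_fit(k: np.ndarray, n_bins: int = 10):
    """Signed scale-free fit of a connectivity vector.

    Bin k into equal-width bins, drop empty bins, regress log10(bin
    frequency) on log10(bin mean k); returns ``(signed_r2, slope)`` with
    ``signed_r2 = -sign(slope) * R^2`` so that a decaying degree
    distribution scores positively.
    """
    k = np.asarray(k, dtype=float)
    if np.ptp(k) <= 0:
        raise ValueError("connectivity is constant; scale-free fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(idx, minlength=n_bins).astype(float)
    mean_k = np.array([k[idx == b].mean() if freq[b] else np.nan for b in range(n_bins)])
    keep = (freq > 0) & (mean_k > 0)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 usable bins; scale-free fit undefined")
    x, y = np.log10(mean_k[keep]), np.log10(freq[keep])
    slope, _, r, _, _ = stats.linregress(x, y)
    return float(-np.sign(slope) * r**2), float(slope)


def pick_soft_threshold(
    matrix: pd.DataFrame,
    candidate_powers=tuple(range(1, 21)),
    r2_target: float = 0.80,
    n_bins: int = 10,
):
    """Choose the smallest power whose signed scale-free fit reaches the target.

    Falls back to the best-fitting candidate (with a warning) when no
    power reaches ``r2_target``.  Returns ``(power_table, chosen_power)``.
    """
    if not len(tuple(candidate_powers)):
        raise ValueError("candidate_powers is empty")
    if matrix.shape[0] < 20:
        raise ValueError("soft-threshold search needs >= 20 genes")
    cor = np.abs(_correlation(matrix))
    rows = []
    for power in candidate_powers:
        a = cor**power
        k = a.sum(axis=0) - 1.0
        fit, slope = scale_free_fit(k, n_bins)
        rows.append({"power": power, "fit": fit, "slope": slope, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    reaching = table[table["fit"] >= r2_target]
    if len(reaching):
        chosen = int(reaching.iloc[0]["power"])
    else:
        chosen = int(table.loc[table["fit"].idxmax(), "power"])
        warnings.warn(
            f"no candidate power reached signed fit {r2_target}; using best ({chosen})",
            stacklevel=2,
        )
    return table, chosen


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: shared-neighbor strength normalized by the
    smaller connectivity, with unit diagonal."""
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(a), 1.0):
        raise ValueError("adjacency must have unit diagonal")
    k = a.sum(axis=0) - 1.0
    shared = a @ a - a  # for i != j: sum_{u != i,j} a_iu a_uj + a_ij
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denom > 0, shared / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray,
    gene_ids,
    min_module_size: int = 30,
    cut_height: float = 0.25,
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static cut.

    The dendrogram is cut at ``(1 - cut_height)`` of its maximum merge
    height (the merged-dendrogram scale: clusters whose members join
    within the lower 75% of the tree, by default, stay together).
    Clusters smaller than ``min_module_size`` are labelled grey; modules
    are labelled M1, M2, ... by descending size.
    """
    d = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = linkage(squareform(d, checks=False), method="average")
    max_h = z[:, 2].max() if len(z) else 0.0
    if max_h <= 0:
        flat = np.ones(len(gene_ids), dtype=int)
    else:
        flat = fcluster(z, t=(1.0 - cut_height) * max_h, criterion="distance")
    counts = pd.Series(flat).value_counts()
    ordered = [c for c in counts.index if counts[c] >= min_module_size]
    name = {c: f"M{i + 1}" for i, c in enumerate(ordered)}
    labels = [name.get(c, GREY) for c in flat]
    return pd.Series(labels, index=list(gene_ids), name="module")


def module_eigengenes(matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component of each module's z-scored submatrix.

    Rows are modules, columns samples; each eigengene has unit norm and
    its sign is fixed so that it correlates positively with the module's
    mean (z-scored) expression profile.
    """
    rows = {}
    for module in sorted(set(labels) - {GREY}):
        genes = labels.index[labels == module]
        sub = matrix.loc[genes].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=1)
        usable = sd > 0
        if not usable.any():
            raise ValueError(f"module {module} contains only zero-variance genes")
        z = (sub[usable] - sub[usable].mean(axis=1, keepdims=True)) / sd[usable, None]
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(eig, mean_profile) < 0:
            eig = -eig
        rows[module] = eig / np.linalg.norm(eig)
    return pd.DataFrame(rows, index=matrix.columns).T


def _pearson_p(r: float, n: int) -> float:
    if n < 3 or abs(r) >= 1.0:
        return 0.0 if abs(r) >= 1.0 else 1.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def module_trait_stats(eigengenes: pd.DataFrame, trait) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with a binary trait."""
    trait = np.asarray(trait, dtype=float)
    if np.ptp(trait) == 0:
        raise ValueError("trait is constant")
    n = len(trait)
    rows = []
    for module, eig in eigengenes.iterrows():
        r = float(np.corrcoef(eig.to_numpy(), trait)[0, 1])
        rows.append({"module": module, "cor": r, "pval": _pearson_p(r, n)})
    return pd.DataFrame(rows).set_index("module")


def gene_significance_membership(
    matrix: pd.DataFrame, eigengenes: pd.DataFrame, labels: pd.Series, trait
) -> pd.DataFrame:
    """Per gene: |cor(gene, trait)| (GS) and |cor(gene, own eigengene)| (MM)."""
    trait = np.asarray(trait, dtype=float)
    rows = []
    for gene in matrix.index:
        x = matrix.loc[gene].to_numpy(dtype=float)
        module = labels.loc[gene]
        gs = abs(float(np.corrcoef(x, trait)[0, 1])) if x.std() > 0 else 0.0
        if module != GREY and module in eigengenes.index and x.std() > 0:
            mm = abs(float(np.corrcoef(x, eigengenes.loc[module].to_numpy())[0, 1]))
        else:
            mm = np.nan
        rows.append({"gene": gene, "module": module, "gs": gs, "mm": mm})
    return pd.DataFrame(rows).set_index("gene")


# ------------------------------------------------------------ screens and sets

def spearman_screen(
    matrix: pd.DataFrame, target_gene: str, candidate_genes, alpha: float = 0.05
) -> pd.DataFrame:
    """Spearman correlation of each candidate with the target gene.

    Average ranks for ties, p via the t approximation; ``significant`` is
    ``p < alpha`` and ``direction`` records the sign of rho.
    """
    target = matrix.loc[target_gene].to_numpy(dtype=float)
    if np.ptp(target) == 0:
        raise ValueError("target gene expression is constant")
    rows = []
    for gene in candidate_genes:
        x = matrix.loc[gene].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append({"gene": gene, "rho": np.nan, "pval": np.nan,
                         "significant": False, "direction": "none"})
            continue
        rho, p = stats.spearmanr(target, x)
        rows.append(
            {
                "gene": gene,
                "rho": float(rho),
                "pval": float(p),
                "significant": bool(p < alpha),
                "direction": "positive" if rho > 0 else ("negative" if rho < 0 else "none"),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


@dataclass
class IntersectionResult:
    intersection: list
    sizes: dict
    venn: dict  # region (frozenset of set names) -> count, partition of the union


def intersect_gene_sets(**named_sets) -> IntersectionResult:
    """Exact-id intersection of >= 2 named sets with Venn-region counts."""
    if len(named_sets) < 2:
        raise ValueError("need at least 2 sets")
    sets = {k: set(v) for k, v in named_sets.items()}
    inter = set.intersection(*sets.values())
    venn: dict[frozenset, int] = {}
    if len(sets) <= 3:
        names = list(sets)
        union = set.union(*sets.values())
        for r in range(1, len(names) + 1):
            for combo in combinations(names, r):
                inside = set.intersection(*(sets[n] for n in combo))
                outside = set.union(set(), *(sets[n] for n in names if n not in combo))
                venn[frozenset(combo)] = len(inside - outside)
        assert sum(venn.values()) == len(union)
    return IntersectionResult(
        intersection=sorted(inter),
        sizes={k: len(v) for k, v in sets.items()},
        venn=venn,
    )


@dataclass
class WGCNAResult:
    power_table: pd.DataFrame
    chosen_power: int
    adjacency: np.ndarray
    tom: np.ndarray
    module_labels: pd.Series
    eigengenes: pd.DataFrame
    module_trait: pd.DataFrame
    gs_mm: pd.DataFrame


def run_wgcna(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    candidate_powers=tuple(range(1, 21)),
    r2_target: float = 0.80,
    min_module_size: int = 30,
    cut_height: float = 0.25,
) -> WGCNAResult:
    """The full WGCNA-core chain on an adjusted expression matrix."""
    trait = (samples.set_index("sample").loc[matrix.columns, "group"] == "case").astype(float)
    power_table, power = pick_soft_threshold(matrix, candidate_powers, r2_target)
    adj = adjacency_matrix(matrix, power)
    tom = tom_similarity(adj)
    labels = detect_modules(tom, matrix.index, min_module_size, cut_height)
    eigen = module_eigengenes(matrix, labels)
    mt = module_trait_stats(eigen, trait.to_numpy())
    gs_mm = gene_significance_membership(matrix, eigen, labels, trait.to_numpy())
    return WGCNAResult(power_table, power, adj, tom, labels, eigen, mt, gs_mm)
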