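"""Tab-separated readers and writers for the pipeline's on-disk formats.

All tables are UTF-8 TSV with a mandatory header row, ``.`` decimal point and
``NA`` for missing values.  Summary statistics follow the conventional GWAS
column set (snp, chr, pos, ea, oa, eaf, beta, se, pval, n); expression
matrices are genes x samples with the gene id in the first column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

#: canonical column order for GWAS/pQTL/eQTL summary statistics
SUMSTAT_COLUMNS = ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n"]

_TSV_KWARGS = dict(sep="\t", na_rep="NA", index=False)


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-stat table missing columns: {missing}")
    df.loc[:, SUMSTAT_COLUMNS].to_csv(path, **_TSV_KWARGS)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chr": str, "ea": str, "oa": str})
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing summary-stat columns {missing}")
    return df


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples matrix; the index holds gene ids."""
    out = matrix.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, **_TSV_KWARGS)


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    return df.set_index("gene")


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.loc[:, ["sample", "group", "batch"]].to_csv(path, **_TSV_KWARGS)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str, "batch": str})


def write_ld_matrix(snp_ids, r: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(r, index=list(snp_ids), columns=list(snp_ids)).to_csv(
        path, sep="\t", index_label="snp"
    )


def read_ld_matrix(path: str | Path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index.astype(str)), df.to_numpy(dtype=float)


def write_edge_list(edges, path: str | Path) -> None:
    pd.DataFrame(edges, columns=["node_a", "node_b"]).to_csv(path, **_TSV_KWARGS)


def read_edge_list(path: str | Path):
    df = pd.read_csv(path, sep="\t", dtype=str)
    return list(df.itertuples(index=False, name=None))
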