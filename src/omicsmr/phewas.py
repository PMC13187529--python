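"""MR-PheWAS: scan one exposure's instruments against an outcome catalog.

Each outcome in the catalog is harmonized against the exposure's
instruments and estimated with the Wald ratio (one shared SNP) or IVW
(two or more).  Outcomes sharing no SNPs with the instruments are
reported as skipped rather than dropped.  The default significance
threshold is 5e-5 (phenome-wide), recorded as -log10(p) > 4.301.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mr import MRConfig, harmonize, ivw, wald_ratio


def run_phewas(
    instruments: pd.DataFrame,
    catalog: dict[str, pd.DataFrame],
    threshold: float = 5e-5,
    config: MRConfig | None = None,
) -> pd.DataFrame:
    """Per-outcome MR table with significance flags.

    ``catalog`` maps outcome ids to outcome summary-stat tables.  Returns
    one row per catalog entry with columns outcome, method, n_snp, beta,
    se, pval, neg_log10_p, significant, skipped.
    """
    if not catalog:
        raise ValueError("outcome catalog is empty")
    config = config or MRConfig()
    rows = []
    for outcome_id in catalog:
        skipped_row = {
            "outcome": outcome_id, "method": "none", "n_snp": 0,
            "beta": np.nan, "se": np.nan, "pval": np.nan,
            "neg_log10_p": np.nan, "significant": False, "skipped": True,
        }
        try:
            hset = harmonize(instruments, catalog[outcome_id], config.palindromic_af_tolerance)
        except ValueError:
            rows.append(skipped_row)
            continue
        if len(hset) == 0:
            rows.append(skipped_row)
            continue
        if len(hset) == 1:
            r = hset.table.iloc[0]
            res = wald_ratio(r["bx"], r["sx"], r["by"], r["sy"], config.second_order_wald)
        else:
            res = ivw(hset, random_effects=config.random_effects)
        rows.append(
            {
                "outcome": outcome_id,
                "method": res.method,
                "n_snp": res.n_snp,
                "beta": res.beta,
                "se": res.se,
                "pval": res.pval,
                "neg_log10_p": -np.log10(res.pval) if res.pval > 0 else np.inf,
                "significant": bool(res.pval < threshold),
                "skipped": False,
            }
        )
    return pd.DataFrame(rows)
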