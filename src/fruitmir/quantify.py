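"""Relative expression by the 2^-ddCt method, and read-count profiles.

ddCt workflow: per sample, each replicate's dCt = Ct(target) − Ct(reference)
(replicates paired by index); ddCt = mean dCt(sample) − mean dCt(calibrator);
relative expression = 2^(−ddCt).  The standard error is the replicate SE of
dCt, propagated to the expression scale with the delta method
(se_rel = rel · ln2 · se_dCt).  No amplification-efficiency correction is
applied (pure 2^-ddCt).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample", "gene", "replicate", "ct")


def _delta_ct(
    ct: pd.DataFrame, sample: str, target_gene: str, reference_gene: str
) -> np.ndarray:
    sub = ct[ct["sample"] == sample]
    tgt = sub[sub["gene"] == target_gene].set_index("replicate")["ct"]
    ref = sub[sub["gene"] == reference_gene].set_index("replicate")["ct"]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} missing in sample {sample!r}")
    if tgt.empty:
        raise ValueError(f"target gene {target_gene!r} missing in sample {sample!r}")
    joined = pd.concat([tgt.rename("t"), ref.rename("r")], axis=1).dropna()
    return (joined["t"] - joined["r"]).to_numpy()


def ddct(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """Relative expression of one target gene across samples.

    ``ct_table`` columns: sample, gene, replicate, ct.  Returns one row per
    sample with delta_ct, delta_delta_ct, rel_expression and se.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in ct_table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    samples = list(dict.fromkeys(ct_table["sample"]))
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in table")

    cal_dct = _delta_ct(ct_table, calibrator_sample, target_gene, reference_gene)
    cal_mean = float(cal_dct.mean())
    rows = []
    for sample in samples:
        dct = _delta_ct(ct_table, sample, target_gene, reference_gene)
        mean_dct = float(dct.mean())
        n = len(dct)
        se_dct = float(dct.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        ddct_val = mean_dct - cal_mean
        rel = float(2.0 ** (-ddct_val))
        rows.append(
            {
                "sample": sample,
                "gene": target_gene,
                "n": n,
                "delta_ct": mean_dct,
                "delta_delta_ct": ddct_val,
                "rel_expression": rel,
                "se": rel * np.log(2.0) * se_dct,
            }
        )
    return pd.DataFrame(rows)


def count_profile(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-miRNA read-count table across libraries.

    ``hits`` columns: mirna_id, library, count.  Missing combinations are
    reported as 0; ranks within a library are invariant to total-count
    scaling.
    """
    for c in ("mirna_id", "library", "count"):
        if c not in hits.columns:
            raise ValueError(f"hits table missing column {c!r}")
    table = (
        hits.pivot_table(
            index="mirna_id", columns="library", values="count",
            aggfunc="sum", fill_value=0,
        )
        .sort_index()
    )
    table.columns.name = None
    return table
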