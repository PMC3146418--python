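"""ΔCT relative expression from qRT-PCR cycle thresholds.

Relative expression between two conditions (ribose vs. glucose) is
computed by the ΔCT method against an endogenous reference gene (gyrA in
the original design), assuming an amplification efficiency of exactly 2:
one cycle difference = one log2 unit of expression.  Lower CT means
higher expression, so

    log2fc = ΔCT_glucose − ΔCT_ribose,
    ΔCT_condition = mean CT(target) − mean CT(reference).
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CT_COLUMNS = ["sample", "condition", "gene", "replicate", "ct"]
CONDITIONS = ("glucose", "ribose")


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"conditions must be glucose/ribose, got {sorted(bad)}")
    return df


def delta_ct_log2fc(records: pd.DataFrame, reference_gene: str = "gyrA") -> pd.DataFrame:
    """Per-gene log2 ribose/glucose expression ratio by the ΔCT method.

    CT replicates are averaged arithmetically per (gene, condition) before
    differencing.  Genes are skipped (with a warning) if the reference
    gene lacks CT values in either condition.
    """
    means = records.groupby(["gene", "condition"])["ct"].agg(["mean", "count"])
    ref = {}
    for cond in CONDITIONS:
        try:
            ref[cond] = means.loc[(reference_gene, cond), "mean"]
        except KeyError:
            raise ValueError(
                f"reference gene {reference_gene!r} has no CT values for {cond}"
            )
    rows = []
    for gene in sorted(set(records["gene"]) - {reference_gene}):
        try:
            d_glc = means.loc[(gene, "glucose"), "mean"] - ref["glucose"]
            d_rib = means.loc[(gene, "ribose"), "mean"] - ref["ribose"]
        except KeyError:
            logger.warning("gene %s lacks CT values in one condition; skipped", gene)
            continue
        n = int(
            means.loc[(gene, "glucose"), "count"] + means.loc[(gene, "ribose"), "count"]
        )
        rows.append({"gene": gene, "log2fc_qpcr": d_glc - d_rib, "n_replicates": n})
    return pd.DataFrame(rows, columns=["gene", "log2fc_qpcr", "n_replicates"])


def concordance(
    qpcr_results: pd.DataFrame, array_log2fc: Mapping[str, float]
) -> dict:
    """Agreement between qPCR and array log2 ratios on shared genes.

    Returns sign-agreement fraction and Spearman rank correlation over
    genes present in both inputs.
    """
    shared = [g for g in qpcr_results["gene"] if g in array_log2fc]
    if not shared:
        return {"n": 0, "sign_agreement": np.nan, "rank_correlation": np.nan}
    qp = qpcr_results.set_index("gene").loc[shared, "log2fc_qpcr"].to_numpy(float)
    ar = np.asarray([array_log2fc[g] for g in shared], float)
    agree = float(np.mean(np.sign(qp) == np.sign(ar)))
    if len(shared) >= 2 and np.std(qp) > 0 and np.std(ar) > 0:
        rank_corr = float(stats.spearmanr(qp, ar).statistic)
    else:
        rank_corr = np.nan
    return {"n": len(shared), "sign_agreement": agree, "rank_correlation": rank_corr}
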