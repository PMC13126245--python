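"""Supervised differential methylation and category enrichment.

Per-CpG Welch t tests between a case and a control sample set, with
Benjamini-Hochberg FDR over all tested CpGs, and calls that must pass both
filters: q below ``q_max`` (default 0.01) and an absolute group mean
difference above ``delta_min`` (default 0.3 on the beta scale).  The sign
convention is case minus control, so hypomethylation in cases is negative.

Category enrichment (methylation-dynamics module membership or chromatin
state) of a DMC set against a CpG universe uses Fisher exact odds ratios
with FDR across categories.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats_core import bh_fdr, fisher_or

__all__ = ["dmc_analysis", "set_enrichment"]


def dmc_analysis(
    beta: pd.DataFrame,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    q_max: float = 0.01,
    delta_min: float = 0.3,
) -> pd.DataFrame:
    """Welch-t differential methylation with FDR and effect-size filters.

    Returns a frame indexed by CpG with columns ``statistic, p, q,
    delta_beta, call`` where call is hypo/hyper/none.  ``delta_beta`` is
    case mean minus control mean.
    """
    case_ids = list(case_ids)
    control_ids = list(control_ids)
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValueError("each group needs at least 2 samples")
    overlap = set(case_ids) & set(control_ids)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    missing = (set(case_ids) | set(control_ids)) - set(beta.columns)
    if missing:
        raise ValueError(f"samples missing from beta matrix: {sorted(missing)[:5]}")

    a = beta[case_ids].to_numpy(dtype=float)
    b = beta[control_ids].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
    # constant CpGs in both groups: no evidence either way
    p = np.where(np.isnan(p), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    q = bh_fdr(p)
    delta = a.mean(axis=1) - b.mean(axis=1)

    call = np.full(len(beta), "none", dtype=object)
    call[(q < q_max) & (delta < -delta_min)] = "hypo"
    call[(q < q_max) & (delta > delta_min)] = "hyper"

    return pd.DataFrame(
        {"statistic": t, "p": p, "q": q, "delta_beta": delta, "call": call},
        index=beta.index,
    )


def set_enrichment(
    dmc_set: Sequence[str],
    universe: Sequence[str],
    annotation: pd.DataFrame,
    grouping: str = "module",
) -> pd.DataFrame:
    """Fisher enrichment of a CpG set against its universe, per category.

    ``grouping`` is an annotation column ("module" or "state").  Each row
    reports the 2x2 membership counts, the odds ratio (inf flagged when the
    off-diagonal is empty), p and BH q across categories, plus the fraction
    of the DMC set falling in the category.
    """
    dmc = set(dmc_set)
    uni = set(universe)
    if not dmc <= uni:
        raise ValueError("dmc_set must be a subset of the universe")
    if grouping not in annotation.columns:
        raise ValueError(f"unknown grouping column: {grouping}")
    ann = annotation.loc[annotation["cpg_id"].isin(uni)]
    in_dmc = ann["cpg_id"].isin(dmc).to_numpy()
    cats = ann[grouping].to_numpy()

    rows = []
    for cat in sorted(pd.unique(cats)):
        m = cats == cat
        a = int((m & in_dmc).sum())       # in set, in category
        b = int((~m & in_dmc).sum())      # in set, outside category
        c = int((m & ~in_dmc).sum())      # rest of universe, in category
        d = int((~m & ~in_dmc).sum())
        res = fisher_or([[a, b], [c, d]])
        rows.append(
            {
                "category": str(cat),
                "n_set_in": a,
                "n_set_out": b,
                "n_rest_in": c,
                "n_rest_out": d,
                "set_fraction": a / max(1, len(dmc)),
                "odds_ratio": res.effect,
                "p": res.p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
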