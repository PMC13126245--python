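"""Copy-number calls from methylation-array-style intensity log-ratios.

A sample's per-probe log2-ratio-like values are first normalized against a
reference panel (per-probe median subtraction), then segmented per
chromosome with penalized binary changepoint splitting, and each segment is
called gain/loss/neutral by its median against a strict cutoff:
gain iff median > cutoff, loss iff median < -cutoff (default cutoff 0.1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SegmentCall", "reference_ratios", "segment_and_call"]


@dataclass
class SegmentCall:
    chromosome: str
    start: int
    end: int
    n_probes: int
    median: float
    state: str


def reference_ratios(sample: pd.Series, reference: pd.DataFrame) -> pd.Series:
    """Sample values minus the per-probe median of a reference panel."""
    if reference.shape[1] < 3:
        raise ValueError("need at least 3 reference samples")
    ref_median = reference.median(axis=1)
    out = sample - ref_median.reindex(sample.index)
    if out.isna().any():
        raise ValueError("reference panel does not cover all probes")
    return out


def _sse(prefix: np.ndarray, prefix2: np.ndarray, i: int, j: int) -> float:
    """Within-segment squared error of x[i:j] from O(1) prefix sums."""
    n = j - i
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return s2 - s * s / n


def _binary_segment(x: np.ndarray, min_size: int, penalty: float) -> list[int]:
    """Changepoint indices (split positions) by penalized binary splitting.

    A split is accepted while it reduces the within-segment squared error
    by more than ``penalty``; candidate splits respect ``min_size`` on both
    sides.  Returns sorted interior breakpoints.
    """
    n = len(x)
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix2 = np.concatenate([[0.0], np.cumsum(x * x)])

    breaks: list[int] = []
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < 2 * min_size:
            continue
        base = _sse(prefix, prefix2, i, j)
        ks = np.arange(i + min_size, j - min_size + 1)
        n_l = ks - i
        n_r = j - ks
        s_l = prefix[ks] - prefix[i]
        s_r = prefix[j] - prefix[ks]
        s2_l = prefix2[ks] - prefix2[i]
        s2_r = prefix2[j] - prefix2[ks]
        cost = (s2_l - s_l**2 / n_l) + (s2_r - s_r**2 / n_r)
        k_best = int(ks[np.argmin(cost)])
        if base - float(cost.min()) > penalty:
            breaks.append(k_best)
            stack.append((i, k_best))
            stack.append((k_best, j))
    return sorted(breaks)


def segment_and_call(
    ratios: pd.Series,
    annotation: pd.DataFrame,
    min_probes: int = 10,
    cutoff: float = 0.1,
    penalty: float | None = None,
) -> pd.DataFrame:
    """Segment per chromosome and call each segment gain/loss/neutral.

    ``ratios`` is indexed by probe/CpG id; probe positions come from the
    annotation.  The penalty defaults to ``6 * log(n) * sigma^2`` per
    chromosome, with sigma estimated robustly from first differences;
    segments tile each chromosome without overlap.  States use strict
    inequalities at the cutoff, so a segment median of exactly ``cutoff``
    is neutral.
    """
    ann = annotation.loc[annotation["cpg_id"].isin(ratios.index)]
    rows: list[SegmentCall] = []
    for chrom, sub in ann.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        x = ratios.reindex(sub["cpg_id"]).to_numpy(dtype=float)
        if len(x) == 0:
            logger.info("chromosome %s has no probes; skipped", chrom)
            continue
        if len(x) < 2 * min_probes:
            breaks = []
        else:
            # sigma from first differences: median|diff| * 1.4826 / sqrt(2)
            sigma = float(np.median(np.abs(np.diff(x)))) * 1.4826 / np.sqrt(2) or float(np.std(x))
            pen = penalty if penalty is not None else 6.0 * np.log(len(x)) * max(sigma, 1e-8) ** 2
            breaks = _binary_segment(x, min_probes, pen)
        bounds = [0] + breaks + [len(x)]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for i, j in zip(bounds[:-1], bounds[1:]):
            med = float(np.median(x[i:j]))
            if med > cutoff:
                state = "gain"
            elif med < -cutoff:
                state = "loss"
            else:
                state = "neutral"
            rows.append(
                SegmentCall(
                    chromosome=str(chrom),
                    start=int(starts[i]),
                    end=int(ends[j - 1]),
                    n_probes=j - i,
                    median=med,
                    state=state,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
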