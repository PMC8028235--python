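"""Scoring of calls against a spike-in truth set.

Sensitivity = true positives / total simulated variants, where a true
positive is a truth variant matched by a passed call on (chrom, pos, alt).
Because mosaic ground truth beyond the spiked set is unknowable, precision
is replaced by the proxy positive predictive value (pPPV): true positives
over all passed calls. Per-VAF-bin reports use lower-inclusive /
upper-exclusive bins of width 0.01 on the achieved VAF.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import PbviError

TRUTH_COLUMNS = ["chrom", "pos", "alt", "achieved_vaf"]


def _truth_keys(truth: pd.DataFrame) -> set[tuple[str, int, str]]:
    if truth.empty:
        raise PbviError("truth set is empty")
    keys = {(c, int(p), a) for c, p, a in truth[["chrom", "pos", "alt"]].itertuples(index=False)}
    if len(keys) != len(truth):
        raise PbviError("truth set has duplicate (chrom, pos, alt) keys")
    return keys


def _passed_calls(calls: pd.DataFrame) -> pd.DataFrame:
    if "passed" in calls.columns:
        return calls[calls["passed"].astype(bool)]
    return calls


def sensitivity(calls: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Fraction of truth variants recovered by a passed call."""
    keys = _truth_keys(truth)
    passed = _passed_calls(calls)
    if passed.empty:
        return 0.0
    called = {
        (c, int(p), a) for c, p, a in passed[["chrom", "pos", "alt"]].itertuples(index=False)
    }
    return len(keys & called) / len(keys)


def ppv_proxy(calls: pd.DataFrame, truth: pd.DataFrame) -> float | None:
    """True positives over total passed calls; None when nothing was
    called (undefined). A disjoint call set returns 0.0 with a warning."""
    keys = _truth_keys(truth)
    passed = _passed_calls(calls)
    if passed.empty:
        return None
    called = [
        (c, int(p), a) for c, p, a in passed[["chrom", "pos", "alt"]].itertuples(index=False)
    ]
    tp = sum(1 for k in called if k in keys)
    if tp == 0:
        warnings.warn("no overlap between calls and truth; pPPV is 0", stacklevel=2)
    return tp / len(called)


def bin_report(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    bin_width: float = 0.01,
    *,
    depth: int | None = None,
) -> pd.DataFrame:
    """Sensitivity per achieved-VAF bin ([k*w, (k+1)*w), lower-inclusive).

    Returns one row per occupied bin with bin bounds, truth count, true
    positives and sensitivity; ``depth`` is carried through as a label
    column when given.
    """
    keys = _truth_keys(truth)
    passed = _passed_calls(calls)
    called = {
        (c, int(p), a) for c, p, a in passed[["chrom", "pos", "alt"]].itertuples(index=False)
    } if not passed.empty else set()

    df = truth.copy()
    if "achieved_vaf" not in df.columns:
        raise PbviError("bin_report requires an achieved_vaf column in the truth set")
    df["bin_low"] = np.floor(df["achieved_vaf"].to_numpy() / bin_width) * bin_width
    df["hit"] = [
        (c, int(p), a) in called
        for c, p, a in df[["chrom", "pos", "alt"]].itertuples(index=False)
    ]
    rows = []
    for low, grp in df.groupby("bin_low", sort=True):
        rows.append(
            {
                "bin_low": round(float(low), 10),
                "bin_high": round(float(low) + bin_width, 10),
                "n_truth": len(grp),
                "n_called": int(grp["hit"].sum()),
                "sensitivity": float(grp["hit"].mean()),
            }
        )
    out = pd.DataFrame(rows)
    if depth is not None:
        out.insert(0, "depth", depth)
    return out


def replicate_summary(reports: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean and standard error of per-bin sensitivity across replicate
    runs (SE = sample SD with n-1 denominator / sqrt(n))."""
    if not reports:
        raise PbviError("no replicate reports")
    pooled = pd.concat(reports, ignore_index=True)
    group_cols = [c for c in ("depth", "bin_low", "bin_high") if c in pooled.columns]
    out = (
        pooled.groupby(group_cols)["sensitivity"]
        .agg(
            mean_sensitivity="mean",
            se_sensitivity=lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else 0.0,
            n_replicates="count",
        )
        .reset_index()
    )
    return out
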