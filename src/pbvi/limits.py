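"""Analytic detection limits: the smallest VAF the caller can flag.

For a given test depth and model alternate/reference counts, the minimum
detectable VAF is found by increasing the total test alternate count ``a``
one read at a time — alternating the increment between the forward and
reverse strand, beginning with the reverse strand, so the running split is
(ceil(a/2), floor(a/2)) — until the Stouffer-combined per-strand Fisher
p-value clears the Bonferroni threshold alpha / n_tests. The returned
limit is a / depth.

Two entry points share this search: :func:`min_detectable_vaf` for the
idealized query (model counts halved evenly across strands; the depth /
model-alt-count response surface), and :func:`scan_positions` for a real
model (each position's own strand-split counts; the per-position,
per-alternate landscape whose class means expose substitution-specific
error such as elevated C>A limits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .caller import _fisher_batch, _stouffer_batch
from .errors import PbviError
from .model import KEY_COLS, ModelTable, NUCLEOTIDES

#: default Bonferroni burden: number of positions in the full 11-gene model
DEFAULT_N_TESTS = 28_119
#: default model reference count: the full model's mean reference count
DEFAULT_MODEL_REF = 26_082

UNDETECTABLE = math.nan


@dataclass(frozen=True)
class LimitQuery:
    """One detection-limit question: test depth vs model composition."""

    depth: int
    model_alt: int
    model_ref: int = DEFAULT_MODEL_REF
    n_tests: int = DEFAULT_N_TESTS
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.depth < 2 or self.depth % 2:
            raise PbviError(f"depth must be even and >= 2, got {self.depth}")
        if self.model_ref <= 0:
            raise PbviError("model_ref must be > 0")
        if self.model_alt < 0:
            raise PbviError("model_alt must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise PbviError("alpha must be in (0, 1)")


def allocate_strands(a: int) -> tuple[int, int]:
    """Strand split of a total test alternate count after alternating
    single-read increments starting from (fwd=1, rev=0) and incrementing
    the reverse strand first: (ceil(a/2), floor(a/2))."""
    if a < 1:
        raise PbviError("total alternate count must be >= 1")
    return (a + 1) // 2, a // 2


def split_half(count: int) -> tuple[int, int]:
    """Halve a model count across strands; forward takes the ceiling."""
    return (count + 1) // 2, count // 2


def _search_min_alt(
    c_fwd: np.ndarray,
    c_rev: np.ndarray,
    d_fwd: np.ndarray,
    d_rev: np.ndarray,
    depth: int,
    alpha: float,
    n_tests: int,
) -> np.ndarray:
    """Vectorized first-significant search over rows of model counts.

    Returns, per row, the smallest total alt count a (1..depth) whose
    combined p-value is < alpha / n_tests, or 0 if none is.
    """
    n = len(c_fwd)
    half = depth // 2
    threshold = alpha / n_tests
    result = np.zeros(n, dtype=np.int64)
    open_rows = np.arange(n)
    for a in range(1, depth + 1):
        if open_rows.size == 0:
            break
        a_f, a_r = allocate_strands(a)
        if a_f > half:
            break
        p_f = _fisher_batch(
            np.full(open_rows.size, a_f), half - a_f, c_fwd[open_rows], d_fwd[open_rows]
        )
        p_r = _fisher_batch(
            np.full(open_rows.size, a_r), half - a_r, c_rev[open_rows], d_rev[open_rows]
        )
        p = _stouffer_batch(p_f, p_r)
        hit = p < threshold
        result[open_rows[hit]] = a
        open_rows = open_rows[~hit]
    return result


def min_detectable_vaf(
    depth: int,
    model_alt: int,
    model_ref: int = DEFAULT_MODEL_REF,
    *,
    alpha: float = 0.05,
    n_tests: int = DEFAULT_N_TESTS,
) -> float:
    """Minimum detectable VAF for an idealized strand-balanced query.

    Model counts are halved across strands (forward takes the ceiling of
    odd counts); the per-strand test depth is depth/2. Returns a/depth for
    the first significant total alternate count a, or NaN (undetectable)
    if no a <= depth reaches significance.
    """
    q = LimitQuery(depth=depth, model_alt=model_alt, model_ref=model_ref,
                   n_tests=n_tests, alpha=alpha)
    c_f, c_r = split_half(q.model_alt)
    d_f, d_r = split_half(q.model_ref)
    a = _search_min_alt(
        np.array([c_f]), np.array([c_r]), np.array([d_f]), np.array([d_r]),
        q.depth, q.alpha, q.n_tests,
    )[0]
    return UNDETECTABLE if a == 0 else a / q.depth


def solve(query: LimitQuery) -> float:
    """Dataclass-flavored alias for :func:`min_detectable_vaf`."""
    return min_detectable_vaf(
        query.depth, query.model_alt, query.model_ref,
        alpha=query.alpha, n_tests=query.n_tests,
    )


def limits_grid(
    depths: Sequence[int] = (150, 300, 600, 1200),
    model_alts: Sequence[int] = tuple(range(0, 101)),
    model_ref: int = DEFAULT_MODEL_REF,
    *,
    alpha: float = 0.05,
    n_tests: int = DEFAULT_N_TESTS,
) -> pd.DataFrame:
    """Detection-limit surface over depth x model-alternate-count.

    One row per (depth, model_alt) with the minimum detectable VAF — the
    response surface relating limits of detection to model contamination
    and sequencing depth.
    """
    records = []
    for depth in depths:
        LimitQuery(depth=depth, model_alt=0, model_ref=model_ref,
                   n_tests=n_tests, alpha=alpha)  # validation
        alts = np.asarray(list(model_alts), dtype=np.int64)
        c_f, c_r = (alts + 1) // 2, alts // 2
        d_f = np.full_like(alts, (model_ref + 1) // 2)
        d_r = np.full_like(alts, model_ref // 2)
        a = _search_min_alt(c_f, c_r, d_f, d_r, depth, alpha, n_tests)
        for alt, a_min in zip(alts, a):
            records.append(
                {
                    "depth": depth,
                    "model_alt": int(alt),
                    "min_alt_reads": int(a_min) if a_min else pd.NA,
                    "min_vaf": a_min / depth if a_min else UNDETECTABLE,
                }
            )
    return pd.DataFrame.from_records(records)


def scan_positions(
    model: ModelTable,
    region: tuple[str, int, int] | None = None,
    depth: int = 600,
    *,
    excluded: Iterable[tuple[str, int]] = (),
    positions: Iterable[tuple[str, int]] | None = None,
    alpha: float = 0.05,
    n_tests: int | str = "auto",
) -> pd.DataFrame:
    """Per-(position, alternate) minimum detectable VAF over a real model.

    Each position's own strand-split model counts feed the per-strand
    tables: forward uses (a_f, depth/2 - a_f, model fwd alt, model fwd
    ref), reverse likewise. ``region`` is (chrom, first_pos, last_pos)
    with 1-based inclusive bounds and must lie inside the model;
    ``excluded`` positions (e.g. known heterozygous sites in the cohort)
    are omitted from the output; ``positions`` optionally restricts the
    scan to an explicit (chrom, pos) subset. All three alternates of each
    position are scanned.
    """
    if depth < 2 or depth % 2:
        raise PbviError(f"depth must be even and >= 2, got {depth}")
    if n_tests == "auto":
        n_tests = model.n_positions
    df = model.counts
    if region is not None:
        chrom, lo, hi = region
        mask = (df["chrom"] == chrom) & (df["pos"] >= lo) & (df["pos"] <= hi)
        if not mask.any():
            raise PbviError(f"region {chrom}:{lo}-{hi} outside the model")
        span = hi - lo + 1
        if mask.sum() < span:
            raise PbviError(
                f"region {chrom}:{lo}-{hi} has positions missing from the model"
            )
        df = df[mask]
    if positions is not None:
        wanted = {(c, int(p)) for c, p in positions}
        df = df[[(c, int(p)) in wanted for c, p in zip(df["chrom"], df["pos"])]]
    excluded = {(c, int(p)) for c, p in excluded}
    if excluded:
        df = df[[(c, int(p)) not in excluded for c, p in zip(df["chrom"], df["pos"])]]
    if df.empty:
        raise PbviError("no positions to scan")

    rows = []
    for nuc in NUCLEOTIDES:  # candidate alternate
        sub = df[df["ref"] != nuc]
        if sub.empty:
            continue
        ref_f = np.zeros(len(sub), dtype=np.int64)
        ref_r = np.zeros(len(sub), dtype=np.int64)
        for r in NUCLEOTIDES:
            m = (sub["ref"] == r).to_numpy()
            ref_f[m] = sub[f"f{r}"].to_numpy()[m]
            ref_r[m] = sub[f"r{r}"].to_numpy()[m]
        a_min = _search_min_alt(
            sub[f"f{nuc}"].to_numpy(),
            sub[f"r{nuc}"].to_numpy(),
            ref_f,
            ref_r,
            depth,
            alpha,
            int(n_tests),
        )
        part = pd.DataFrame(
            {
                "chrom": sub["chrom"].to_numpy(),
                "pos": sub["pos"].to_numpy(),
                "ref": sub["ref"].to_numpy(),
                "alt": nuc,
                "min_alt_reads": np.where(a_min > 0, a_min, -1),
                "min_vaf": np.where(a_min > 0, a_min / depth, UNDETECTABLE),
            }
        )
        rows.append(part)
    out = pd.concat(rows, ignore_index=True)
    out.loc[out["min_alt_reads"] < 0, "min_alt_reads"] = pd.NA
    return out.sort_values(list(KEY_COLS) + ["alt"], kind="stable").reset_index(
        drop=True
    )


def class_summary(scan: pd.DataFrame) -> pd.DataFrame:
    """Mean minimum VAF per substitution class (the 12 ref>alt pairs).

    Undetectable rows (NaN limits) are dropped before averaging. Exposes
    class-specific error structure: classes the cohort mis-calls more
    often (canonically C>A) carry higher mean limits.
    """
    if scan.empty:
        raise PbviError("empty scan")
    df = scan.dropna(subset=["min_vaf"]).copy()
    df["substitution"] = df["ref"].astype(str) + ">" + df["alt"].astype(str)
    out = (
        df.groupby("substitution")["min_vaf"]
        .agg(mean_min_vaf="mean", n_sites="count")
        .reset_index()
    )
    return out.sort_values("substitution").reset_index(drop=True)
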