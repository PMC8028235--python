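"""The statistical core: position-based variant identification.

At every model position the test sample nominates one candidate — the
non-reference nucleotide with the largest VAF. Its strand-specific
alternate/reference counts (a, b) are compared to the model's counts
(c, d) for the same position, nucleotide and strand with a one-sided
Fisher's exact test (alternative: the sample's alternate proportion
exceeds the model's). The forward- and reverse-strand p-values are fused
with Stouffer's method,

    z_i = Phi^-1(1 - p_i),   z = (z_fwd + z_rev) / sqrt(2),   p = 1 - Phi(z),

and the combined p-value is Bonferroni-corrected by the number of model
positions. Candidates with corrected p < alpha pass. Requiring support on
both strands makes the test robust to strand-specific context errors: alt
reads confined to one strand leave the other strand's z near (or below)
zero and the combined p large.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from scipy.stats import hypergeom, norm

from .errors import PbviError
from .model import KEY_COLS, ModelTable, NUCLEOTIDES

#: sentinel returned when a strand has no sample coverage (a + b == 0)
NO_TEST = None

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16

CALL_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "alt_fwd", "alt_rev", "ref_fwd", "ref_rev",
    "depth", "vaf",
    "p_fwd", "p_rev", "p_comb", "p_adj",
    "no_test", "passed",
]


def select_candidate(
    fwd: Mapping[str, int], rev: Mapping[str, int], ref: str
) -> str | None:
    """The candidate variant: the non-reference nucleotide with the
    largest total (fwd+rev) count, i.e. the largest VAF. Ties break by
    fixed order A<C<G<T; returns None when no alternate base was seen."""
    best, best_count = None, 0
    for nuc in NUCLEOTIDES:
        if nuc == ref:
            continue
        total = fwd.get(nuc, 0) + rev.get(nuc, 0)
        if total > best_count:
            best, best_count = nuc, total
    return best


def fisher_one_strand(a: int, b: int, c: int, d: int) -> float | None:
    """One-sided Fisher's exact test for one strand's 2x2 table
    [[a, b], [c, d]] (test alt/ref vs model alt/ref), alternative
    'sample alt proportion greater'. Returns the exact hypergeometric
    upper-tail probability P(X >= a), or the no-test sentinel when the
    sample has no coverage on this strand (a + b == 0)."""
    if min(a, b, c, d) < 0:
        raise PbviError("contingency counts must be >= 0")
    if a + b == 0:
        return NO_TEST
    # X ~ Hypergeom(M = a+b+c+d, K = a+c successes, N = a+b draws)
    return float(hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def _fisher_batch(a, b, c, d) -> np.ndarray:
    a = np.asarray(a, dtype=np.int64)
    return hypergeom.sf(a - 1, a + b + c + d, a + c, a + b)


def stouffer_combine(p_fwd: float, p_rev: float) -> float:
    """Stouffer combination of two one-sided p-values (symmetric in its
    arguments; p=0.5 on both strands is a fixed point). Inputs are clamped
    away from 0 and 1 before the normal-quantile transform."""
    return float(_stouffer_batch(np.asarray([p_fwd]), np.asarray([p_rev]))[0])


def _stouffer_batch(p_fwd: np.ndarray, p_rev: np.ndarray) -> np.ndarray:
    pf = np.clip(p_fwd, _P_FLOOR, _P_CEIL)
    pr = np.clip(p_rev, _P_FLOOR, _P_CEIL)
    z = (norm.isf(pf) + norm.isf(pr)) / np.sqrt(2.0)
    return np.maximum(norm.sf(z), _P_FLOOR)


def read_blacklist(path: str | os.PathLike) -> set[tuple[str, int, str]]:
    """Read a (chrom, pos, alt) site blacklist TSV. Blacklisted candidate
    alleles are dropped before testing — a generic hook for e.g.
    population-frequency filtering."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["chrom", "pos", "alt"]
    )
    return {(str(c), int(p), str(a)) for c, p, a in df.itertuples(index=False)}


def call_variants(
    sample_counts: pd.DataFrame,
    model: ModelTable,
    *,
    alpha: float = 0.05,
    n_tests: int | str = "auto",
    blacklist: Iterable[tuple[str, int, str]] | None = None,
    min_alt_reads: int = 1,
) -> pd.DataFrame:
    """Run the per-strand Fisher + Stouffer + Bonferroni test at every
    sample position with a candidate alternate.

    Sample positions outside the model are ignored. ``n_tests='auto'``
    resolves to the number of model positions (every position carries a
    potential test, so the Bonferroni burden is the model size). Returns
    one row per tested candidate (including non-passing ones with at least
    ``min_alt_reads`` alternate reads), sorted by (chrom, pos), with
    per-strand p-values, the combined p, the Bonferroni-adjusted
    p_adj = min(1, p_comb * n_tests) and the pass flag (p_adj < alpha).
    Candidates where either strand has zero sample coverage are flagged
    ``no_test`` and never pass.
    """
    if model.n_positions == 0:
        raise PbviError("empty model")
    if not (0.0 < alpha <= 1.0):
        raise PbviError(f"alpha must be in (0, 1], got {alpha}")
    if n_tests == "auto":
        n_tests = model.n_positions
    n_tests = int(n_tests)
    if n_tests < 1:
        raise PbviError("n_tests must be >= 1")

    merged = sample_counts.merge(
        model.counts, on=list(KEY_COLS), how="inner", suffixes=("", "_model")
    )
    if merged.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)

    n = len(merged)
    s_fwd = np.stack([merged[f"f{x}"].to_numpy() for x in NUCLEOTIDES], axis=1)
    s_rev = np.stack([merged[f"r{x}"].to_numpy() for x in NUCLEOTIDES], axis=1)
    m_fwd = np.stack([merged[f"f{x}_model"].to_numpy() for x in NUCLEOTIDES], axis=1)
    m_rev = np.stack([merged[f"r{x}_model"].to_numpy() for x in NUCLEOTIDES], axis=1)
    ref_idx = np.array([NUCLEOTIDES.index(r) for r in merged["ref"]])

    totals = s_fwd + s_rev
    masked = totals.copy()
    masked[np.arange(n), ref_idx] = -1  # never pick the reference base
    alt_idx = masked.argmax(axis=1)  # ties resolve to A<C<G<T order
    alt_total = masked[np.arange(n), alt_idx]

    keep = alt_total >= max(1, int(min_alt_reads))
    if blacklist:
        bl = set(blacklist)
        alt_base = np.array(NUCLEOTIDES)[alt_idx]
        in_bl = np.array(
            [
                (c, int(p), a) in bl
                for c, p, a in zip(merged["chrom"], merged["pos"], alt_base)
            ]
        )
        keep &= ~in_bl
    if not keep.any():
        return pd.DataFrame(columns=CALL_COLUMNS)

    idx = np.nonzero(keep)[0]
    rows = np.arange(n)[idx]
    ai, ri = alt_idx[idx], ref_idx[idx]

    a_f = s_fwd[rows, ai]
    a_r = s_rev[rows, ai]
    b_f = s_fwd[rows, ri]
    b_r = s_rev[rows, ri]
    c_f = m_fwd[rows, ai]
    c_r = m_rev[rows, ai]
    d_f = m_fwd[rows, ri]
    d_r = m_rev[rows, ri]

    cov_f = s_fwd[rows].sum(axis=1)
    cov_r = s_rev[rows].sum(axis=1)
    no_test = ((a_f + b_f) == 0) | ((a_r + b_r) == 0)

    p_f = np.ones(len(rows))
    p_r = np.ones(len(rows))
    t = ~no_test
    p_f[t] = _fisher_batch(a_f[t], b_f[t], c_f[t], d_f[t])
    p_r[t] = _fisher_batch(a_r[t], b_r[t], c_r[t], d_r[t])
    p_comb = _stouffer_batch(p_f, p_r)
    p_adj = np.minimum(1.0, p_comb * n_tests)
    passed = (p_adj < alpha) & ~no_test

    depth = cov_f + cov_r
    vaf = np.where(depth > 0, (a_f + a_r) / np.maximum(depth, 1), 0.0)

    out = pd.DataFrame(
        {
            "chrom": merged["chrom"].to_numpy()[idx],
            "pos": merged["pos"].to_numpy()[idx],
            "ref": merged["ref"].to_numpy()[idx],
            "alt": np.array(NUCLEOTIDES)[ai],
            "alt_fwd": a_f,
            "alt_rev": a_r,
            "ref_fwd": b_f,
            "ref_rev": b_r,
            "depth": depth,
            "vaf": vaf,
            "p_fwd": np.where(no_test, np.nan, p_f),
            "p_rev": np.where(no_test, np.nan, p_r),
            "p_comb": np.where(no_test, np.nan, p_comb),
            "p_adj": np.where(no_test, np.nan, p_adj),
            "no_test": no_test,
            "passed": passed,
        }
    )
    return out.sort_values(list(KEY_COLS), kind="stable").reset_index(drop=True)


def write_calls_tsv(
    calls: pd.DataFrame,
    destination: str | os.PathLike,
    *,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Flat TSV mirror of the call table (all tested candidates, passing
    or not), with optional '#key=value' provenance header lines."""
    with open(destination, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"#{key}={value}\n")
        calls.to_csv(fh, sep="\t", index=False)


def write_vcf(
    calls: pd.DataFrame,
    destination: str | os.PathLike,
    *,
    contigs: Mapping[str, int] | None = None,
    sample_name: str = "SAMPLE",
) -> None:
    """Write candidate calls as VCF v4.2.

    INFO carries the strand-split allele depths (ADF/ADR alt, RDF/RDR ref),
    VAF, per-strand p-values (PF/PR), the Stouffer-combined PCOMB and
    Bonferroni-adjusted PADJ. FILTER is PASS for significant calls and
    ``pbvi_ns`` otherwise (not significant, or untestable on one strand).
    ``contigs`` maps chromosome name to length; if omitted, lengths are
    padded past the last call.
    """
    header = pysam.VariantHeader()
    header.add_line('##source=pbvi')
    for field, ftype, desc in [
        ("VAF", "Float", "Variant allele fraction (alt / total nucleotides)"),
        ("ADF", "Integer", "Alt read count, forward strand"),
        ("ADR", "Integer", "Alt read count, reverse strand"),
        ("RDF", "Integer", "Ref read count, forward strand"),
        ("RDR", "Integer", "Ref read count, reverse strand"),
        ("PF", "Float", "One-sided Fisher p-value, forward strand"),
        ("PR", "Float", "One-sided Fisher p-value, reverse strand"),
        ("PCOMB", "Float", "Stouffer-combined p-value"),
        ("PADJ", "Float", "Bonferroni-adjusted combined p-value"),
    ]:
        header.add_line(
            f'##INFO=<ID={field},Number=1,Type={ftype},Description="{desc}">'
        )
    header.add_line(
        '##FILTER=<ID=pbvi_ns,Description="Not significant after Bonferroni '
        'correction, or untestable on one strand">'
    )
    if contigs is None:
        contigs = {}
        for chrom, grp in calls.groupby("chrom"):
            contigs[str(chrom)] = int(grp["pos"].max()) + 1000
    for name, length in contigs.items():
        header.add_line(f"##contig=<ID={name},length={int(length)}>")
    header.add_sample(sample_name)

    with pysam.VariantFile(str(destination), "w", header=header) as vcf:
        for row in calls.itertuples(index=False):
            rec = vcf.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                alleles=(str(row.ref), str(row.alt)),
            )
            rec.info["VAF"] = float(row.vaf)
            rec.info["ADF"] = int(row.alt_fwd)
            rec.info["ADR"] = int(row.alt_rev)
            rec.info["RDF"] = int(row.ref_fwd)
            rec.info["RDR"] = int(row.ref_rev)
            if not row.no_test:
                rec.info["PF"] = float(row.p_fwd)
                rec.info["PR"] = float(row.p_rev)
                rec.info["PCOMB"] = float(row.p_comb)
                rec.info["PADJ"] = float(row.p_adj)
            rec.filter.add("PASS" if row.passed else "pbvi_ns")
            vcf.write(rec)
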