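"""Synthetic data: control cohorts, read sets, and variant spike-in.

Two layers share one error model:

* a fast *counts* layer — per-sample strand-split nucleotide counts drawn
  directly from position-specific substitution rates (Poisson strand
  depths, multinomial error bases). This is what model building and the
  end-to-end calling experiments consume.
* an *alignment* layer — single-end reads written to BAM so the pileup
  counter and the BAM-rewriting operations (spike-in, down-sampling,
  depth-doubling by self-merge) can be exercised on real files.

Spiking rewrites the base of a seeded uniform subset of reads covering a
position, so the achieved VAF is the closest attainable value to the
target (round(target * depth) reads, at least one when the target is
positive); base qualities are preserved. Everything is a pure function of
(inputs, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import RegionError, SimulationError
from .model import COUNT_COLS, KEY_COLS, NUCLEOTIDES
from .regions import Region, position_universe, read_bed

_NUC_ARR = np.array(NUCLEOTIDES)
_NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}


@dataclass(frozen=True)
class ErrorProfile:
    """Position-specific substitution-error model for the synthetic cohort.

    base_rate: per-base substitution probability at ordinary positions
        (default 0.001, the canonical short-read error scale).
    hot_fraction / hot_rate: a fraction of positions is error-prone and
        substitutes at ``hot_rate`` instead — the position-specific error
        structure the caller's model is designed to absorb.
    class_bias: relative weights per substitution class (e.g. {"C>A": 3.0})
        splitting each position's rate across the three alternates;
        unlisted classes weigh 1.
    strand_asymmetry: reverse-strand rate multiplier (rates are rescaled so
        the strand-averaged rate stays at the nominal value).
    """

    base_rate: float = 0.001
    hot_fraction: float = 0.02
    hot_rate: float = 0.005
    class_bias: Mapping[str, float] | None = None
    strand_asymmetry: float = 1.0

    def __post_init__(self) -> None:
        for name in ("base_rate", "hot_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise SimulationError(f"{name} must be in [0, 1), got {v}")
        if not (0.0 <= self.hot_fraction <= 1.0):
            raise SimulationError("hot_fraction must be in [0, 1]")
        if self.strand_asymmetry < 0:
            raise SimulationError("strand_asymmetry must be >= 0")
        if self.class_bias and any(w < 0 for w in self.class_bias.values()):
            raise SimulationError("class_bias weights must be >= 0")


@dataclass(frozen=True)
class SpikeInstruction:
    """One variant to inject: position, alternate, target VAF."""

    chrom: str
    pos: int  # 1-based
    alt: str
    target_vaf: float
    achieved_vaf: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_vaf < 1.0):
            raise SimulationError(f"target_vaf must be in [0, 1), got {self.target_vaf}")
        if self.alt not in NUCLEOTIDES:
            raise SimulationError(f"invalid alternate {self.alt!r}")


@dataclass
class ErrorField:
    """Realized per-position substitution rates for one universe.

    fwd_rates / rev_rates are (n_positions, 4) arrays giving the
    probability that a read base at the position reports each nucleotide
    erroneously (the reference column is zero).
    """

    universe: pd.DataFrame  # chrom, pos, ref
    fwd_rates: np.ndarray
    rev_rates: np.ndarray

    @property
    def n_positions(self) -> int:
        return len(self.universe)


def load_reference(reference: str | os.PathLike | Mapping[str, str]) -> dict[str, str]:
    """Chromosome sequences from a FASTA path or a name->sequence mapping."""
    if isinstance(reference, Mapping):
        return {str(k): str(v).upper() for k, v in reference.items()}
    with pysam.FastaFile(str(reference)) as fa:
        return {name: fa.fetch(name).upper() for name in fa.references}


def synthesize_reference(
    chrom_lengths: Mapping[str, int], seed: int, path: str | os.PathLike | None = None
) -> dict[str, str]:
    """Random reference sequences (uniform A/C/G/T), optionally written to
    an indexed FASTA."""
    rng = np.random.default_rng(seed)
    ref = {
        name: "".join(rng.choice(_NUC_ARR, size=length))
        for name, length in chrom_lengths.items()
    }
    if path is not None:
        with open(path, "w") as fh:
            for name, seq in ref.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        pysam.faidx(str(path))
    return ref


def universe_with_ref(
    reference: str | os.PathLike | Mapping[str, str],
    regions: str | os.PathLike | Sequence[Region],
) -> pd.DataFrame:
    """Expand regions to positions and attach the reference base."""
    if isinstance(regions, (str, os.PathLike)):
        regions = read_bed(regions)
    seqs = load_reference(reference)
    for chrom, start, end in regions:
        if chrom not in seqs:
            raise RegionError(f"chromosome {chrom!r} not in reference")
        if end > len(seqs[chrom]):
            raise RegionError(
                f"region {chrom}:{start}-{end} beyond reference length {len(seqs[chrom])}"
            )
    uni = position_universe(regions)
    uni["ref"] = [seqs[c][p - 1] for c, p in zip(uni["chrom"], uni["pos"])]
    return uni


def build_error_field(
    universe: pd.DataFrame, profile: ErrorProfile, seed: int
) -> ErrorField:
    """Draw the realized per-position rates (hot-position placement is part
    of the seeded randomness)."""
    rng = np.random.default_rng(seed)
    n = len(universe)
    rates = np.full(n, profile.base_rate)
    n_hot = int(round(profile.hot_fraction * n))
    if n_hot:
        hot = rng.choice(n, size=n_hot, replace=False)
        rates[hot] = profile.hot_rate

    ref_idx = np.array([_NUC_INDEX.get(r, -1) for r in universe["ref"]])
    weights = np.zeros((n, 4))
    bias = dict(profile.class_bias or {})
    for j, alt in enumerate(NUCLEOTIDES):
        for i_ref, ref in enumerate(NUCLEOTIDES):
            mask = ref_idx == i_ref
            if i_ref == j:
                continue
            weights[mask, j] = bias.get(f"{ref}>{alt}", 1.0)
    wsum = weights.sum(axis=1, keepdims=True)
    wsum[wsum == 0] = 1.0
    per_alt = rates[:, None] * weights / wsum

    sa = profile.strand_asymmetry
    fwd = per_alt * (2.0 / (1.0 + sa))
    rev = per_alt * (2.0 * sa / (1.0 + sa))
    return ErrorField(universe=universe.reset_index(drop=True),
                      fwd_rates=np.clip(fwd, 0.0, 1.0),
                      rev_rates=np.clip(rev, 0.0, 1.0))


def _multinomial_errors(
    depth: np.ndarray, rates: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Exact multinomial split of per-position error bases, vectorized via
    the conditional-binomial decomposition. Returns an (n, 4) count array
    whose reference column is the remaining (error-free) reads."""
    n = len(depth)
    counts = np.zeros((n, 4), dtype=np.int64)
    remaining = depth.astype(np.int64).copy()
    prob_left = np.ones(n)
    for j in range(4):
        p = rates[:, j]
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = np.where(prob_left > 0, np.minimum(p / prob_left, 1.0), 0.0)
        counts[:, j] = rng.binomial(remaining, cond)
        remaining -= counts[:, j]
        prob_left -= p
    return counts, remaining


def draw_sample(
    field: ErrorField, mean_depth: float, rng: np.random.Generator
) -> pd.DataFrame:
    """One sample's strand-split counts: Poisson(mean_depth/2) reads per
    strand per position, error bases multinomial at the field's rates,
    the rest reporting the reference."""
    n = field.n_positions
    ref_idx = np.array([_NUC_INDEX[r] for r in field.universe["ref"]])
    out = {}
    for tag, rates in (("f", field.fwd_rates), ("r", field.rev_rates)):
        depth = rng.poisson(mean_depth / 2.0, size=n)
        errs, ref_reads = _multinomial_errors(depth, rates, rng)
        errs[np.arange(n), ref_idx] += ref_reads
        for j, nuc in enumerate(NUCLEOTIDES):
            out[f"{tag}{nuc}"] = errs[:, j]
    df = field.universe[list(KEY_COLS)].copy()
    for col in COUNT_COLS:
        df[col] = out[col]
    return df


def generate_cohort(
    reference: str | os.PathLike | Mapping[str, str],
    regions: str | os.PathLike | Sequence[Region],
    n_samples: int = 502,
    mean_depth: float = 53.0,
    profile: ErrorProfile = ErrorProfile(),
    seed: int = 0,
) -> tuple[list[pd.DataFrame], ErrorField]:
    """Synthetic control cohort over a target universe.

    Defaults mirror the scale of a ~500-sample exome control set at ~53x
    per sample (aggregate coverage in the tens of thousands per position).
    Returns the per-sample counts frames and the realized error field
    (needed to draw further samples from the same error process).
    Deterministic given ``seed``.
    """
    if n_samples < 1:
        raise SimulationError("n_samples must be >= 1")
    universe = universe_with_ref(reference, regions)
    field = build_error_field(universe, profile, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    return [draw_sample(field, mean_depth, rng) for _ in range(n_samples)], field


def spike_counts(
    sample: pd.DataFrame,
    instructions: Iterable[SpikeInstruction],
) -> tuple[pd.DataFrame, list[SpikeInstruction]]:
    """Count-level spike-in: move round(target_vaf * depth) reads (at
    least one for a positive target) from the reference base to the
    alternate, split across strands proportionally to strand coverage.

    Returns the modified counts and the instructions with achieved_vaf
    filled (alt reads injected / total depth at the position).
    """
    df = sample.copy()
    key = {(c, int(p)): i for i, (c, p) in enumerate(zip(df["chrom"], df["pos"]))}
    done = []
    for ins in instructions:
        i = key.get((ins.chrom, ins.pos))
        if i is None:
            raise SimulationError(f"position {ins.chrom}:{ins.pos} not in sample")
        row = df.iloc[i]
        cov_f = int(sum(row[f"f{n}"] for n in NUCLEOTIDES))
        cov_r = int(sum(row[f"r{n}"] for n in NUCLEOTIDES))
        depth = cov_f + cov_r
        if depth == 0:
            raise SimulationError(f"zero coverage at {ins.chrom}:{ins.pos}")
        k = int(round(ins.target_vaf * depth))
        if ins.target_vaf > 0:
            k = max(k, 1)
        k = min(k, depth)
        k_f = int(round(k * cov_f / depth))
        k_r = k - k_f
        # take spiked reads from whichever bases are present, ref first
        for tag, take in (("f", k_f), ("r", k_r)):
            remaining = take
            for src in sorted(NUCLEOTIDES, key=lambda n: -int(row[f"{tag}{n}"])):
                if src == ins.alt or remaining == 0:
                    continue
                grab = min(remaining, int(df.at[df.index[i], f"{tag}{src}"]))
                df.at[df.index[i], f"{tag}{src}"] -= grab
                remaining -= grab
            df.at[df.index[i], f"{tag}{ins.alt}"] += take - remaining
        done.append(replace(ins, achieved_vaf=k / depth))
    return df, done


# ---------------------------------------------------------------------------
# alignment (BAM) layer
# ---------------------------------------------------------------------------


def _sort_index(unsorted_path: str, out_path: str) -> None:
    pysam.sort("-o", str(out_path), str(unsorted_path))
    pysam.index(str(out_path))
    os.unlink(unsorted_path)


def _bam_header(seqs: Mapping[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": len(seq)} for name, seq in seqs.items()],
        }
    )


def simulate_reads(
    reference: str | os.PathLike | Mapping[str, str],
    regions: str | os.PathLike | Sequence[Region],
    mean_depth: float,
    out_bam: str | os.PathLike,
    seed: int = 0,
    *,
    read_length: int = 100,
    base_quality: int = 30,
    error_rate: float = 0.0,
) -> None:
    """Write a sorted, indexed BAM of single-end reads tiling the regions
    at roughly ``mean_depth`` coverage, strands assigned at random, with
    optional uniform substitution errors."""
    if isinstance(regions, (str, os.PathLike)):
        regions = read_bed(regions)
    seqs = load_reference(reference)
    rng = np.random.default_rng(seed)
    header = _bam_header(seqs)
    tmp = str(out_bam) + ".unsorted.bam"
    n_read = 0
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        for chrom, start, end in regions:
            if chrom not in seqs:
                raise RegionError(f"chromosome {chrom!r} not in reference")
            chrom_len = len(seqs[chrom])
            span = end - start
            n_reads = int(np.ceil(mean_depth * (span + read_length) / read_length))
            lo = max(0, start - read_length + 1)
            hi = min(end, chrom_len - read_length)
            starts = rng.integers(lo, max(hi, lo + 1), size=n_reads)
            reverse = rng.random(n_reads) < 0.5
            for s, rev in zip(starts, reverse):
                seq = list(seqs[chrom][s : s + read_length])
                if error_rate > 0:
                    hits = np.nonzero(rng.random(read_length) < error_rate)[0]
                    for h in hits:
                        choices = [n for n in NUCLEOTIDES if n != seq[h]]
                        seq[h] = choices[rng.integers(0, 3)]
                read = pysam.AlignedSegment(header)
                read.query_name = f"sim{n_read:08d}"
                read.query_sequence = "".join(seq)
                read.query_qualities = pysam.qualitystring_to_array(
                    chr(base_quality + 33) * read_length
                )
                read.reference_id = header.get_tid(chrom)
                read.reference_start = int(s)
                read.mapping_quality = 60
                read.cigarstring = f"{read_length}M"
                read.flag = 16 if rev else 0
                bam.write(read)
                n_read += 1
    _sort_index(tmp, str(out_bam))


def spike(
    alignments: str | os.PathLike,
    instructions: Sequence[SpikeInstruction],
    out_bam: str | os.PathLike,
    seed: int = 0,
) -> list[SpikeInstruction]:
    """Inject variants into an existing BAM by rewriting read bases.

    For each instruction a seeded uniform subset of the reads carrying an
    aligned base at the position — round(target_vaf * coverage) of them,
    at least one for a positive target — has that base set to the
    alternate. Base qualities and all other alignment content are
    untouched. Returns the instructions with achieved_vaf filled in.
    """
    rng = np.random.default_rng(seed)
    with pysam.AlignmentFile(str(alignments), "rb") as bam:
        header = bam.header.copy()
        reads = [r for r in bam.fetch(until_eof=True)]

    done = []
    for ins in instructions:
        tid_name = ins.chrom
        targets = []  # (read index, query position)
        for i, read in enumerate(reads):
            if read.is_unmapped or read.reference_name != tid_name:
                continue
            if not (read.reference_start <= ins.pos - 1 < read.reference_end):
                continue
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if rpos == ins.pos - 1:
                    targets.append((i, qpos))
                    break
        cov = len(targets)
        if cov == 0:
            raise SimulationError(f"zero coverage at {ins.chrom}:{ins.pos}")
        k = int(round(ins.target_vaf * cov))
        if ins.target_vaf > 0:
            k = max(k, 1)
        k = min(k, cov)
        chosen = rng.choice(cov, size=k, replace=False) if k else []
        for j in chosen:
            i, qpos = targets[j]
            read = reads[i]
            quals = read.query_qualities
            seq = list(read.query_sequence)
            seq[qpos] = ins.alt
            read.query_sequence = "".join(seq)
            read.query_qualities = quals  # setter above clears qualities
        done.append(replace(ins, achieved_vaf=k / cov))

    tmp = str(out_bam) + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for read in reads:
            out.write(read)
    _sort_index(tmp, str(out_bam))
    return done


def mean_depth_of(
    alignments: str | os.PathLike, regions: Sequence[Region] | None = None
) -> float:
    """Mean coverage over the regions (aligned bases inside / positions)."""
    with pysam.AlignmentFile(str(alignments), "rb") as bam:
        if regions is None:
            regions = [
                (name, 0, length)
                for name, length in zip(bam.references, bam.lengths)
            ]
        total_bases = 0
        total_span = 0
        for chrom, start, end in regions:
            total_span += end - start
            for read in bam.fetch(chrom, start, end):
                if read.is_unmapped:
                    continue
                total_bases += read.get_overlap(start, end)
    if total_span == 0:
        raise SimulationError("empty region set")
    return total_bases / total_span


def downsample(
    alignments: str | os.PathLike,
    target_mean_depth: float,
    out_bam: str | os.PathLike,
    seed: int = 0,
    *,
    regions: str | os.PathLike | Sequence[Region] | None = None,
) -> None:
    """Thin a BAM to a target mean depth: each read kept independently
    with probability target/current (binomial thinning, so per-position
    VAFs are preserved in expectation). Deterministic given seed."""
    if isinstance(regions, (str, os.PathLike)):
        regions = read_bed(regions)
    current = mean_depth_of(alignments, regions)
    if target_mean_depth > current:
        raise SimulationError(
            f"target depth {target_mean_depth} exceeds current {current:.1f}"
        )
    p = target_mean_depth / current
    rng = np.random.default_rng(seed)
    with pysam.AlignmentFile(str(alignments), "rb") as bam:
        header = bam.header.copy()
        tmp = str(out_bam) + ".unsorted.bam"
        with pysam.AlignmentFile(tmp, "wb", header=header) as out:
            for read in bam.fetch(until_eof=True):
                if rng.random() < p:
                    out.write(read)
    _sort_index(tmp, str(out_bam))


def double_depth(
    alignments: str | os.PathLike, out_bam: str | os.PathLike
) -> None:
    """Merge a BAM with itself: every read appears twice (second copy
    renamed), so per-position counts double exactly and VAFs are
    unchanged."""
    with pysam.AlignmentFile(str(alignments), "rb") as bam:
        header = bam.header.copy()
        tmp = str(out_bam) + ".unsorted.bam"
        with pysam.AlignmentFile(tmp, "wb", header=header) as out:
            for read in bam.fetch(until_eof=True):
                out.write(read)
                dup = pysam.AlignedSegment.fromstring(read.to_string(), header)
                dup.query_name = read.query_name + ".m2"
                out.write(dup)
    _sort_index(tmp, str(out_bam))


def random_instructions(
    universe: pd.DataFrame,
    n_variants: int,
    seed: int,
    vaf_range: tuple[float, float] = (0.0, 0.06),
) -> list[SpikeInstruction]:
    """Pick spike targets: ``n_variants`` distinct positions, a random
    non-reference alternate each, target VAFs uniform on ``vaf_range``.
    Mirrors the default validation scenario (~150 variants, VAF 0-0.06).
    """
    if n_variants > len(universe):
        raise SimulationError("more variants requested than positions available")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(universe), size=n_variants, replace=False)
    out = []
    for i in sorted(picks):
        chrom, pos, ref = (
            universe["chrom"].iloc[i],
            int(universe["pos"].iloc[i]),
            universe["ref"].iloc[i],
        )
        alts = [n for n in NUCLEOTIDES if n != ref]
        alt = alts[rng.integers(0, len(alts))]
        vaf = float(rng.uniform(*vaf_range))
        out.append(SpikeInstruction(chrom=chrom, pos=pos, alt=alt, target_vaf=vaf))
    return out
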