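"""Strand-separated nucleotide counting from alignment files.

For every position of a BED-defined universe the counter tallies how many
aligned A/C/G/T bases each read strand contributed. Only aligned matches
count: deletions, reference skips and inserted bases are ignored (the
caller is SNV-only). Filtering follows standard pileup hygiene — unmapped,
secondary, supplementary, QC-fail and (by default) duplicate-flagged
records are skipped — plus two quality gates: reads must have mapping
quality strictly greater than ``min_mapq``, and bases must have quality of
at least ``min_baseq``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import PileupError, RegionError
from .model import COUNT_COLS, KEY_COLS, NUCLEOTIDES
from .regions import Region, read_bed

_NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}


@dataclass(frozen=True)
class CountingParams:
    """Quality gates for counting.

    min_baseq: minimum base quality; bases below it are not counted.
    min_mapq: reads are used only if mapping quality > min_mapq (strict).
    """

    min_baseq: int = 0
    min_mapq: int = 20

    def __post_init__(self) -> None:
        if self.min_baseq < 0 or self.min_mapq < 0:
            raise PileupError("quality thresholds must be >= 0")


def count_bam(
    alignments: str | os.PathLike | pysam.AlignmentFile,
    regions: str | os.PathLike | Sequence[Region],
    params: CountingParams = CountingParams(),
    *,
    exclude_duplicates: bool = True,
) -> pd.DataFrame:
    """Count strand-split nucleotides at every position of the universe.

    ``regions`` may be a BED path or a pre-parsed list of (chrom, start,
    end) intervals (0-based, half-open). Returns a canonical counts frame
    (chrom, pos 1-based, fA..rT) covering every universe position, zeros
    included.
    """
    if isinstance(regions, (str, os.PathLike)):
        regions = read_bed(regions)
    own_handle = not isinstance(alignments, pysam.AlignmentFile)
    bam = (
        pysam.AlignmentFile(str(alignments), "rb") if own_handle else alignments
    )
    try:
        if not bam.has_index():
            raise PileupError(
                f"{bam.filename.decode()}: missing index (sort and index the file first)"
            )
        known = set(bam.references)
        frames = []
        for chrom, start, end in regions:
            if chrom not in known:
                raise RegionError(
                    f"chromosome {chrom!r} absent from alignment header"
                )
            counts = np.zeros((end - start, 8), dtype=np.int64)
            for read in bam.fetch(chrom, start, end):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_qcfail
                    or (exclude_duplicates and read.is_duplicate)
                ):
                    continue
                if read.mapping_quality <= params.min_mapq:  # strict ">" keeps
                    continue
                seq = read.query_sequence
                quals = read.query_qualities
                if seq is None:
                    continue
                strand_offset = 4 if read.is_reverse else 0
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    if rpos < start or rpos >= end:
                        continue
                    if quals is not None and quals[qpos] < params.min_baseq:
                        continue
                    idx = _NUC_INDEX.get(seq[qpos])
                    if idx is None:  # N or ambiguity code
                        continue
                    counts[rpos - start, strand_offset + idx] += 1
            frame = pd.DataFrame(counts, columns=list(COUNT_COLS))
            frame.insert(0, "chrom", chrom)
            frame.insert(1, "pos", np.arange(start + 1, end + 1))
            frames.append(frame)
    finally:
        if own_handle:
            bam.close()

    out = pd.concat(frames, ignore_index=True)
    # overlapping BED intervals would double-count: collapse to first occurrence
    out = out.drop_duplicates(subset=list(KEY_COLS), keep="first")
    return out.sort_values(list(KEY_COLS), kind="stable").reset_index(drop=True)
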