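"""Target-region handling.

Regions come in as BED (0-based, half-open); every genomic coordinate the
rest of the package reports is 1-based. The *position universe* of a BED
file is the ordered list of single positions it covers, which is what the
model, the pileup counter and the simulator all iterate over.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd

from .errors import RegionError

Region = tuple[str, int, int]  # chrom, start (0-based), end (half-open)


def read_bed(path: str | os.PathLike) -> list[Region]:
    """Read a 3+ column BED file into a list of (chrom, start, end) tuples.

    Lines starting with '#', 'track' or 'browser' are ignored. Intervals
    must satisfy 0 <= start < end.
    """
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RegionError(f"{path}: line {lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise RegionError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise RegionError(
                    f"{path}: line {lineno}: invalid interval {start}-{end}"
                )
            regions.append((chrom, start, end))
    if not regions:
        raise RegionError(f"{path}: no usable BED intervals")
    return regions


def position_universe(regions: Iterable[Region]) -> pd.DataFrame:
    """Expand BED intervals into one row per covered position.

    Returns a DataFrame with columns ``chrom`` and ``pos`` (1-based),
    sorted by (chrom, pos) with duplicates from overlapping intervals
    collapsed.
    """
    frames = [
        pd.DataFrame({"chrom": chrom, "pos": range(start + 1, end + 1)})
        for chrom, start, end in regions
    ]
    uni = pd.concat(frames, ignore_index=True)
    uni = uni.drop_duplicates().sort_values(["chrom", "pos"], kind="stable")
    return uni.reset_index(drop=True)


def regions_span(regions: Sequence[Region]) -> int:
    """Total number of distinct positions covered (overlaps counted once)."""
    return len(position_universe(regions))
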