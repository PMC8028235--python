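"""The position-based error model ("the model").

The model is a per-position table of strand-split nucleotide counts
aggregated over a control cohort. For every target position it records how
many A/C/G/T bases the cohort produced on the forward and on the reverse
strand, plus the reference base. A test sample's alternate/reference counts
are later compared against these cohort counts with per-strand Fisher's
exact tests: positions where the cohort itself shows many alternate reads
(recurrent sequencing error, or real variation in the controls) demand a
correspondingly higher variant allele fraction before a call is made.

On disk the model is a TSV: '#'-prefixed ``key=value`` metadata lines,
then a header row ``chrom pos ref fA fC fG fT rA rC rG rT`` (``f`` =
forward strand, ``r`` = reverse strand; ``pos`` is 1-based).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ModelFormatError, PbviError

NUCLEOTIDES = ("A", "C", "G", "T")
FWD_COLS = tuple(f"f{n}" for n in NUCLEOTIDES)
REV_COLS = tuple(f"r{n}" for n in NUCLEOTIDES)
COUNT_COLS = FWD_COLS + REV_COLS
KEY_COLS = ("chrom", "pos")

_MODEL_VERSION = 1


@dataclass
class PositionCounts:
    """Strand-split nucleotide counts at one genomic position."""

    chrom: str
    pos: int  # 1-based
    fwd: dict[str, int] = field(default_factory=lambda: dict.fromkeys(NUCLEOTIDES, 0))
    rev: dict[str, int] = field(default_factory=lambda: dict.fromkeys(NUCLEOTIDES, 0))

    def total(self, nuc: str | None = None) -> int:
        if nuc is None:
            return sum(self.fwd.values()) + sum(self.rev.values())
        return self.fwd.get(nuc, 0) + self.rev.get(nuc, 0)

    def as_row(self) -> dict:
        row = {"chrom": self.chrom, "pos": self.pos}
        row.update({f"f{n}": int(self.fwd.get(n, 0)) for n in NUCLEOTIDES})
        row.update({f"r{n}": int(self.rev.get(n, 0)) for n in NUCLEOTIDES})
        return row


def counts_frame(rows: Iterable[PositionCounts]) -> pd.DataFrame:
    """Assemble single-position records into a canonical counts frame."""
    df = pd.DataFrame([r.as_row() for r in rows])
    return validate_counts(df)


def validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Check a counts frame: required columns, non-negative integer counts,
    unique (chrom, pos) keys. Returns the frame sorted by position."""
    missing = [c for c in KEY_COLS + COUNT_COLS if c not in df.columns]
    if missing:
        raise PbviError(f"counts frame missing columns: {missing}")
    sub = df[list(COUNT_COLS)]
    arr = sub.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise PbviError("counts must be integers")
        df = df.copy()
        df[list(COUNT_COLS)] = arr.astype(np.int64)
    if (df[list(COUNT_COLS)].to_numpy() < 0).any():
        raise PbviError("counts must be >= 0")
    if df.duplicated(list(KEY_COLS)).any():
        dup = df[df.duplicated(list(KEY_COLS))].iloc[0]
        raise PbviError(f"duplicate position {dup['chrom']}:{dup['pos']}")
    return df.sort_values(list(KEY_COLS), kind="stable").reset_index(drop=True)


@dataclass
class ModelTable:
    """Aggregated cohort counts plus reference bases and build metadata.

    ``counts`` has columns chrom, pos, ref, fA..fT, rA..rT — one row per
    target position, including positions the cohort never covered (all-zero
    rows still contribute to the multiple-testing burden).
    """

    counts: pd.DataFrame
    n_samples: int
    min_baseq: int = 0
    min_mapq: int = 20

    def __post_init__(self) -> None:
        if "ref" not in self.counts.columns:
            raise PbviError("model requires a 'ref' column")
        self.counts = validate_counts(self.counts)
        bad = ~self.counts["ref"].isin(NUCLEOTIDES + ("N",))
        if bad.any():
            raise PbviError(
                f"invalid reference base {self.counts.loc[bad, 'ref'].iloc[0]!r}"
            )

    @property
    def n_positions(self) -> int:
        return len(self.counts)

    def positions(self) -> pd.DataFrame:
        return self.counts[list(KEY_COLS)]

    def __eq__(self, other) -> bool:  # metadata + content equality
        if not isinstance(other, ModelTable):
            return NotImplemented
        return (
            self.n_samples == other.n_samples
            and self.min_baseq == other.min_baseq
            and self.min_mapq == other.min_mapq
            and self.counts.reset_index(drop=True).equals(
                other.counts.reset_index(drop=True)
            )
        )


def aggregate(
    sample_counts: Sequence[pd.DataFrame],
    ref_bases: Mapping[tuple[str, int], str] | pd.DataFrame | None = None,
    *,
    universe: pd.DataFrame | None = None,
    ref_from_majority: bool = False,
    min_baseq: int = 0,
    min_mapq: int = 20,
) -> ModelTable:
    """Element-wise sum of per-sample counts over a shared position universe.

    Parameters
    ----------
    sample_counts:
        One canonical counts frame per cohort sample. Positions missing
        from a sample are treated as zero counts.
    ref_bases:
        Reference base per position, either a mapping ``(chrom, pos) ->
        base`` or a frame with chrom/pos/ref columns. Samples may also
        carry their own ``ref`` column; conflicting assignments are a hard
        error.
    universe:
        Optional chrom/pos frame fixing the position set (e.g. expanded
        from the target BED). Positions with zero cohort coverage are kept
        as all-zero rows. Defaults to the union of sample positions.
    ref_from_majority:
        If no reference source is given, assign each position the majority
        nucleotide of the aggregated counts (ties by A<C<G<T).
    """
    if not sample_counts:
        raise PbviError("aggregate requires at least one sample")
    frames = [validate_counts(df) for df in sample_counts]

    ref_map: dict[tuple[str, int], str] = {}

    def _claim(chrom: str, pos: int, base: str, source: str) -> None:
        key = (chrom, int(pos))
        prev = ref_map.get(key)
        if prev is not None and prev != base:
            raise PbviError(
                f"conflicting reference base at {chrom}:{pos}: {prev} vs {base} ({source})"
            )
        ref_map[key] = base

    if isinstance(ref_bases, pd.DataFrame):
        for chrom, pos, base in ref_bases[["chrom", "pos", "ref"]].itertuples(index=False):
            _claim(chrom, pos, base, "ref table")
    elif ref_bases is not None:
        for (chrom, pos), base in ref_bases.items():
            _claim(chrom, pos, base, "ref mapping")
    for i, df in enumerate(frames):
        if "ref" in df.columns:
            for chrom, pos, base in df[["chrom", "pos", "ref"]].itertuples(index=False):
                _claim(chrom, pos, base, f"sample {i}")

    pooled = pd.concat(
        [df[list(KEY_COLS + COUNT_COLS)] for df in frames], ignore_index=True
    )
    agg = pooled.groupby(list(KEY_COLS), as_index=False, sort=True).sum()

    if universe is not None:
        uni = universe[list(KEY_COLS)].drop_duplicates()
        extra = agg.merge(uni, on=list(KEY_COLS), how="left", indicator=True)
        if (extra["_merge"] == "left_only").any():
            stray = extra[extra["_merge"] == "left_only"].iloc[0]
            raise PbviError(
                f"sample position {stray['chrom']}:{stray['pos']} outside the universe"
            )
        agg = uni.merge(agg, on=list(KEY_COLS), how="left")
        agg[list(COUNT_COLS)] = agg[list(COUNT_COLS)].fillna(0).astype(np.int64)
        agg = agg.sort_values(list(KEY_COLS), kind="stable").reset_index(drop=True)

    totals = np.stack(
        [(agg[f"f{n}"] + agg[f"r{n}"]).to_numpy() for n in NUCLEOTIDES], axis=1
    )
    majority = np.array(NUCLEOTIDES)[totals.argmax(axis=1)]  # argmax ties: A<C<G<T
    refs = []
    for i, (chrom, pos) in enumerate(agg[list(KEY_COLS)].itertuples(index=False)):
        base = ref_map.get((chrom, int(pos)))
        if base is None:
            if not ref_from_majority:
                raise PbviError(
                    f"no reference base for {chrom}:{pos} "
                    "(supply ref_bases or set ref_from_majority=True)"
                )
            base = str(majority[i])
        refs.append(base)
    agg.insert(2, "ref", refs)

    return ModelTable(
        counts=agg,
        n_samples=len(frames),
        min_baseq=min_baseq,
        min_mapq=min_mapq,
    )


def scale(model: ModelTable, factor: float) -> ModelTable:
    """Shrink the model to ``factor`` times its size, cell by cell.

    Every count is replaced by round-half-up(count * factor), so the
    alternate:reference proportions are approximately preserved while the
    evidence mass shrinks. factor must lie in [0, 1]; 1.0 is the identity.
    """
    if not (0.0 <= factor <= 1.0):
        raise PbviError(f"scale factor must be in [0, 1], got {factor}")
    counts = model.counts.copy()
    arr = counts[list(COUNT_COLS)].to_numpy(dtype=np.float64)
    counts[list(COUNT_COLS)] = np.floor(arr * factor + 0.5).astype(np.int64)
    return replace(model, counts=counts)


@dataclass
class ModelSummary:
    mean_ref_count: float
    mean_total_coverage: float
    alt_fraction: pd.Series  # per position, indexed by (chrom, pos)


def summarize(model: ModelTable) -> ModelSummary:
    """Mean reference-base count, mean total coverage and the per-position
    alternate fraction distribution (both strands summed)."""
    if model.n_positions == 0:
        raise PbviError("cannot summarize an empty model")
    df = model.counts
    totals = df[list(COUNT_COLS)].sum(axis=1).to_numpy(dtype=np.float64)
    ref_counts = np.zeros(len(df), dtype=np.float64)
    for n in NUCLEOTIDES:
        mask = (df["ref"] == n).to_numpy()
        ref_counts[mask] = (df[f"f{n}"] + df[f"r{n}"]).to_numpy()[mask]
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_frac = np.where(totals > 0, (totals - ref_counts) / totals, 0.0)
    idx = pd.MultiIndex.from_frame(df[list(KEY_COLS)])
    return ModelSummary(
        mean_ref_count=float(ref_counts.mean()),
        mean_total_coverage=float(totals.mean()),
        alt_fraction=pd.Series(alt_frac, index=idx, name="alt_fraction"),
    )


def write_model(model: ModelTable, destination: str | os.PathLike) -> None:
    """Serialize a model to its TSV format (metadata header + count rows)."""
    with open(destination, "w") as fh:
        fh.write(f"#pbvi_model_version={_MODEL_VERSION}\n")
        fh.write(f"#n_samples={model.n_samples}\n")
        fh.write(f"#min_baseq={model.min_baseq}\n")
        fh.write(f"#min_mapq={model.min_mapq}\n")
        fh.write(f"#n_positions={model.n_positions}\n")
        cols = list(KEY_COLS) + ["ref"] + list(COUNT_COLS)
        fh.write("\t".join(cols) + "\n")
        model.counts[cols].to_csv(fh, sep="\t", header=False, index=False)


def read_model(source: str | os.PathLike) -> ModelTable:
    """Parse a model TSV, validating counts and metadata.

    Malformed rows raise :class:`ModelFormatError` naming the line.
    """
    meta: dict[str, int] = {}
    rows = []
    expected_cols = list(KEY_COLS) + ["ref"] + list(COUNT_COLS)
    header_seen = False
    with open(source) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line[1:].partition("=")
                    try:
                        meta[key.strip()] = int(value.strip())
                    except ValueError:
                        raise ModelFormatError(
                            f"non-integer metadata value {value!r}", lineno
                        )
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != expected_cols:
                    raise ModelFormatError(
                        f"bad header, expected {expected_cols}", lineno
                    )
                header_seen = True
                continue
            if len(fields) != len(expected_cols):
                raise ModelFormatError(
                    f"expected {len(expected_cols)} columns, got {len(fields)}", lineno
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
                counts = [int(v) for v in fields[3:]]
            except ValueError:
                raise ModelFormatError("non-integer value", lineno)
            if pos < 1:
                raise ModelFormatError(f"position {pos} is not 1-based", lineno)
            if any(c < 0 for c in counts):
                raise ModelFormatError("negative count", lineno)
            if ref not in NUCLEOTIDES + ("N",):
                raise ModelFormatError(f"invalid reference base {ref!r}", lineno)
            rows.append((lineno, chrom, pos, ref, counts))
    if not header_seen:
        raise ModelFormatError(f"{source}: missing header row")
    if not rows:
        raise ModelFormatError(f"{source}: model has no positions")

    seen: set[tuple[str, int]] = set()
    for lineno, chrom, pos, _ref, _c in rows:
        if (chrom, pos) in seen:
            raise ModelFormatError(f"duplicate position {chrom}:{pos}", lineno)
        seen.add((chrom, pos))

    df = pd.DataFrame(
        [[chrom, pos, ref] + counts for _ln, chrom, pos, ref, counts in rows],
        columns=expected_cols,
    )
    model = ModelTable(
        counts=df,
        n_samples=meta.get("n_samples", 0),
        min_baseq=meta.get("min_baseq", 0),
        min_mapq=meta.get("min_mapq", 20),
    )
    if "n_positions" in meta and meta["n_positions"] != model.n_positions:
        raise ModelFormatError(
            f"{source}: header says n_positions={meta['n_positions']} "
            f"but {model.n_positions} rows were read"
        )
    return model


def write_counts(df: pd.DataFrame, destination: str | os.PathLike) -> None:
    """Write a per-sample counts frame in the model TSV dialect (no metadata)."""
    df = validate_counts(df)
    cols = [c for c in (list(KEY_COLS) + ["ref"] + list(COUNT_COLS)) if c in df.columns]
    df[cols].to_csv(destination, sep="\t", index=False)


def read_counts(source: str | os.PathLike) -> pd.DataFrame:
    """Read a per-sample counts TSV (header row, optional ref column)."""
    df = pd.read_csv(source, sep="\t", comment="#")
    return validate_counts(df)
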