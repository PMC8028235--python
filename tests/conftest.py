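import numpy as np
import pandas as pd
import pysam
import pytest

from pbvi import model as M
from pbvi import simulate as S


@pytest.fixture(scope="session")
def reference():
    return S.synthesize_reference({"geneA": 800, "geneB": 700}, seed=11)


@pytest.fixture(scope="session")
def regions():
    return [("geneA", 0, 800), ("geneB", 0, 700)]


@pytest.fixture(scope="session")
def universe(reference, regions):
    return S.universe_with_ref(reference, regions)


@pytest.fixture(scope="session")
def cohort(reference, regions):
    """60-sample synthetic control cohort with the default error profile."""
    samples, field = S.generate_cohort(
        reference, regions, n_samples=60, mean_depth=50.0, seed=7
    )
    return samples, field


@pytest.fixture(scope="session")
def model(cohort, universe):
    samples, field = cohort
    return M.aggregate(samples, field.universe, universe=universe[["chrom", "pos"]])


@pytest.fixture
def make_bam(tmp_path):
    """Factory building a sorted, indexed BAM from explicit read specs.

    Each spec: dict(name, chrom, start (0-based), seq, mapq=60,
    reverse=False, quals=None (phred ints), cigar=None (defaults to all-M),
    flag_extra=0 added on top of the strand flag).
    """

    def _make(read_specs, chrom_lengths, name="fixture.bam"):
        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [
                    {"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()
                ],
            }
        )
        tmp = str(tmp_path / (name + ".unsorted"))
        out = str(tmp_path / name)
        with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
            for spec in read_specs:
                read = pysam.AlignedSegment(header)
                read.query_name = spec["name"]
                read.query_sequence = spec["seq"]
                quals = spec.get("quals") or [30] * len(spec["seq"])
                read.query_qualities = quals
                read.reference_id = header.get_tid(spec["chrom"])
                read.reference_start = spec["start"]
                read.mapping_quality = spec.get("mapq", 60)
                read.cigarstring = spec.get("cigar") or f"{len(spec['seq'])}M"
                flag = 16 if spec.get("reverse") else 0
                read.flag = flag | spec.get("flag_extra", 0)
                bam.write(read)
        pysam.sort("-o", out, tmp)
        pysam.index(out)
        return out

    return _make


@pytest.fixture
def single_position_sample():
    """One-position counts frame builder for caller-level tests."""

    def _make(chrom="geneA", pos=100, **counts):
        row = {"chrom": chrom, "pos": pos}
        row.update({c: 0 for c in M.COUNT_COLS})
        row.update(counts)
        return pd.DataFrame([row])

    return _make


@pytest.fixture
def single_position_model():
    """One-position model builder: strand-split alt/ref counts plus ref base."""

    def _make(chrom="geneA", pos=100, ref="C", n_samples=10, **counts):
        row = {"chrom": chrom, "pos": pos, "ref": ref}
        row.update({c: 0 for c in M.COUNT_COLS})
        row.update(counts)
        return M.ModelTable(counts=pd.DataFrame([row]), n_samples=n_samples)

    return _make
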