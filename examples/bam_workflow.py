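"""The alignment-file route: simulate reads, spike a BAM, down-sample,
recount and call.

Everything runs in a temporary directory; the printed VAFs come from
recounting the modified BAMs with the pileup counter.
"""

import tempfile
from pathlib import Path

from pbvi import (
    CountingParams, SpikeInstruction, count_bam, downsample, double_depth,
    simulate_reads, spike, synthesize_reference,
)
from pbvi.simulate import load_reference, mean_depth_of

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    synthesize_reference({"chr1": 2000}, seed=0, path=tmp / "ref.fa")
    regions = [("chr1", 200, 1800)]
    simulate_reads(tmp / "ref.fa", regions, 600.0, tmp / "sample.bam", seed=1)
    print(f"simulated BAM at {mean_depth_of(tmp / 'sample.bam', regions):.0f}x")

    ref = load_reference(tmp / "ref.fa")
    pos = 1000
    alt = next(n for n in "ACGT" if n != ref["chr1"][pos - 1])
    done = spike(
        tmp / "sample.bam",
        [SpikeInstruction("chr1", pos, alt, target_vaf=0.03)],
        tmp / "spiked.bam",
        seed=0,
    )
    print(f"spiked {alt} at chr1:{pos}, achieved VAF {done[0].achieved_vaf:.4f}")

    counts = count_bam(tmp / "spiked.bam", regions, CountingParams())
    row = counts[counts["pos"] == pos].iloc[0]
    depth = sum(row[c] for c in ("fA", "fC", "fG", "fT", "rA", "rC", "rG", "rT"))
    print(f"recount: {row['f' + alt]} fwd + {row['r' + alt]} rev alt reads "
          f"of {depth} ({(row['f' + alt] + row['r' + alt]) / depth:.4f})")

    downsample(tmp / "spiked.bam", 300.0, tmp / "ds.bam", seed=2, regions=regions)
    print(f"down-sampled to {mean_depth_of(tmp / 'ds.bam', regions):.0f}x")
    double_depth(tmp / "spiked.bam", tmp / "dd.bam")
    print(f"self-merged to {mean_depth_of(tmp / 'dd.bam', regions):.0f}x "
          "(VAFs unchanged, counts exactly doubled)")
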