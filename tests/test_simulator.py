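"""Cohort generation, spike-in, down-sampling and depth doubling."""

import numpy as np
import pandas as pd
import pytest

from pbvi import model as M
from pbvi import pileup as P
from pbvi import simulate as S
from pbvi.errors import RegionError, SimulationError


class TestGenerateCohort:
    def test_zero_error_rate_gives_zero_alts(self, reference, regions):
        profile = S.ErrorProfile(base_rate=0.0, hot_fraction=0.0)
        samples, field = S.generate_cohort(
            reference, regions, n_samples=3, mean_depth=30, profile=profile, seed=1
        )
        for sample in samples:
            merged = sample.merge(field.universe, on=["chrom", "pos"])
            for r in M.NUCLEOTIDES:
                mask = merged["ref"] == r
                for n in M.NUCLEOTIDES:
                    if n != r:
                        assert merged.loc[mask, f"f{n}"].sum() == 0
                        assert merged.loc[mask, f"r{n}"].sum() == 0

    def test_pooled_alt_fraction_matches_binomial_expectation(self, reference, regions):
        profile = S.ErrorProfile(base_rate=0.001, hot_fraction=0.0)
        samples, field = S.generate_cohort(
            reference, regions, n_samples=40, mean_depth=60, profile=profile, seed=3
        )
        model = M.aggregate(samples, field.universe)
        frac = M.summarize(model).alt_fraction.mean()
        total = model.counts[list(M.COUNT_COLS)].to_numpy().sum()
        se = np.sqrt(0.001 * 0.999 / total)
        assert abs(frac - 0.001) < 4 * se + 1e-5

    def test_determinism(self, reference, regions):
        kw = dict(n_samples=2, mean_depth=25.0, seed=42)
        s1, _ = S.generate_cohort(reference, regions, **kw)
        s2, _ = S.generate_cohort(reference, regions, **kw)
        for a, b in zip(s1, s2):
            assert a.equals(b)

    def test_regions_outside_reference_rejected(self, reference):
        with pytest.raises(RegionError):
            S.generate_cohort(reference, [("geneA", 0, 10_000)], n_samples=1)

    def test_class_bias_shapes_error_spectrum(self, reference, regions):
        profile = S.ErrorProfile(
            base_rate=0.005, hot_fraction=0.0, class_bias={"C>A": 10.0}
        )
        samples, field = S.generate_cohort(
            reference, regions, n_samples=30, mean_depth=60, profile=profile, seed=5
        )
        model = M.aggregate(samples, field.universe)
        c_rows = model.counts[model.counts["ref"] == "C"]
        to_a = (c_rows["fA"] + c_rows["rA"]).sum()
        to_t = (c_rows["fT"] + c_rows["rT"]).sum()
        assert to_a > 3 * to_t


class TestSpikeCounts:
    def test_target_zero_changes_nothing(self, cohort):
        samples, field = cohort
        sample = samples[0]
        chrom, pos = sample["chrom"].iloc[0], int(sample["pos"].iloc[0])
        ref = field.universe["ref"].iloc[0]
        alt = next(n for n in M.NUCLEOTIDES if n != ref)
        spiked, done = S.spike_counts(
            sample, [S.SpikeInstruction(chrom, pos, alt, 0.0)]
        )
        assert spiked.equals(sample)
        assert done[0].achieved_vaf == 0.0

    def test_achieved_vaf_recount(self, cohort):
        samples, field = cohort
        sample = samples[1]
        row = sample.iloc[10]
        chrom, pos = row["chrom"], int(row["pos"])
        ref = field.universe.set_index(["chrom", "pos"]).loc[(chrom, pos), "ref"]
        alt = next(n for n in M.NUCLEOTIDES if n != ref)
        spiked, done = S.spike_counts(
            sample, [S.SpikeInstruction(chrom, pos, alt, 0.05)]
        )
        new_row = spiked[(spiked["chrom"] == chrom) & (spiked["pos"] == pos)].iloc[0]
        depth = sum(new_row[c] for c in M.COUNT_COLS)
        alt_reads = new_row[f"f{alt}"] + new_row[f"r{alt}"]
        old_row = sample[(sample["chrom"] == chrom) & (sample["pos"] == pos)].iloc[0]
        old_alt = old_row[f"f{alt}"] + old_row[f"r{alt}"]
        assert depth == sum(old_row[c] for c in M.COUNT_COLS)  # depth preserved
        assert (alt_reads - old_alt) / depth == pytest.approx(done[0].achieved_vaf)

    def test_minimum_one_read_for_positive_target(self, single_position_sample):
        sample = single_position_sample(fC=50, rC=50)
        spiked, done = S.spike_counts(
            sample, [S.SpikeInstruction("geneA", 100, "T", 0.001)]
        )
        assert spiked["fT"].iloc[0] + spiked["rT"].iloc[0] == 1
        assert done[0].achieved_vaf == pytest.approx(0.01)


@pytest.fixture(scope="module")
def bam_bundle(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("simbam")
    S.synthesize_reference({"chr1": 1200}, seed=31, path=tmp / "ref.fa")
    regions = [("chr1", 100, 1100)]
    S.simulate_reads(tmp / "ref.fa", regions, 300.0, tmp / "base.bam", seed=32)
    ref = S.load_reference(tmp / "ref.fa")
    return tmp, regions, ref


class TestBamOperations:
    def test_spike_exact_read_count_and_recount(self, bam_bundle):
        tmp, regions, ref = bam_bundle
        pos = 600
        alt = next(n for n in "ACGT" if n != ref["chr1"][pos - 1])
        before = P.count_bam(str(tmp / "base.bam"), regions)
        row = before[before["pos"] == pos].iloc[0]
        cov = int(sum(row[c] for c in M.COUNT_COLS))
        done = S.spike(
            tmp / "base.bam",
            [S.SpikeInstruction("chr1", pos, alt, 0.03)],
            tmp / "spiked.bam",
            seed=0,
        )
        k = int(round(0.03 * cov))
        assert done[0].achieved_vaf == pytest.approx(k / cov)
        after = P.count_bam(str(tmp / "spiked.bam"), regions)
        new_row = after[after["pos"] == pos].iloc[0]
        gained = (new_row[f"f{alt}"] + new_row[f"r{alt}"]) - (
            row[f"f{alt}"] + row[f"r{alt}"]
        )
        assert gained == k

    def test_spike_preserves_other_positions(self, bam_bundle):
        tmp, regions, _ = bam_bundle
        before = P.count_bam(str(tmp / "base.bam"), regions)
        after = P.count_bam(str(tmp / "spiked.bam"), regions)
        untouched_b = before[before["pos"] != 600].reset_index(drop=True)
        untouched_a = after[after["pos"] != 600].reset_index(drop=True)
        assert untouched_b.equals(untouched_a)

    def test_spike_zero_coverage_position_rejected(self, bam_bundle):
        tmp, _, _ = bam_bundle
        with pytest.raises(SimulationError, match="zero coverage"):
            S.spike(
                tmp / "base.bam",
                [S.SpikeInstruction("chr1", 1, "A", 0.02)],
                tmp / "nope.bam",
            )

    def test_downsample_hits_target_within_tolerance(self, bam_bundle):
        tmp, regions, _ = bam_bundle
        S.downsample(tmp / "base.bam", 150.0, tmp / "ds.bam", seed=2, regions=regions)
        got = S.mean_depth_of(tmp / "ds.bam", regions)
        assert abs(got - 150.0) / 150.0 < 0.05

    def test_downsample_determinism(self, bam_bundle, tmp_path):
        tmp, regions, _ = bam_bundle
        S.downsample(tmp / "base.bam", 100.0, tmp_path / "a.bam", seed=9, regions=regions)
        S.downsample(tmp / "base.bam", 100.0, tmp_path / "b.bam", seed=9, regions=regions)
        a = P.count_bam(str(tmp_path / "a.bam"), regions)
        b = P.count_bam(str(tmp_path / "b.bam"), regions)
        assert a.equals(b)

    def test_downsample_above_current_depth_rejected(self, bam_bundle, tmp_path):
        tmp, regions, _ = bam_bundle
        with pytest.raises(SimulationError, match="exceeds"):
            S.downsample(tmp / "base.bam", 10_000.0, tmp_path / "x.bam", regions=regions)

    def test_double_depth_doubles_counts_exactly(self, bam_bundle, tmp_path):
        tmp, regions, _ = bam_bundle
        S.double_depth(tmp / "spiked.bam", tmp_path / "dd.bam")
        once = P.count_bam(str(tmp / "spiked.bam"), regions)
        twice = P.count_bam(str(tmp_path / "dd.bam"), regions)
        assert (
            twice[list(M.COUNT_COLS)].to_numpy()
            == 2 * once[list(M.COUNT_COLS)].to_numpy()
        ).all()

    def test_double_depth_preserves_vaf(self, bam_bundle, tmp_path):
        tmp, regions, ref = bam_bundle
        pos = 600
        alt = next(n for n in "ACGT" if n != ref["chr1"][pos - 1])
        once = P.count_bam(str(tmp / "spiked.bam"), regions)
        S.double_depth(tmp / "spiked.bam", tmp_path / "dd2.bam")
        twice = P.count_bam(str(tmp_path / "dd2.bam"), regions)

        def vaf(df):
            row = df[df["pos"] == pos].iloc[0]
            return (row[f"f{alt}"] + row[f"r{alt}"]) / sum(row[c] for c in M.COUNT_COLS)

        assert vaf(twice) == pytest.approx(vaf(once))


class TestRandomInstructions:
    def test_alt_never_equals_reference(self, universe):
        ins = S.random_instructions(universe, 40, seed=13)
        refs = universe.set_index(["chrom", "pos"])["ref"]
        for i in ins:
            assert i.alt != refs.loc[(i.chrom, i.pos)]

    def test_vaf_range_respected(self, universe):
        ins = S.random_instructions(universe, 60, seed=14)
        assert all(0.0 <= i.target_vaf <= 0.06 for i in ins)

    def test_positions_unique(self, universe):
        ins = S.random_instructions(universe, 80, seed=15)
        keys = {(i.chrom, i.pos) for i in ins}
        assert len(keys) == 80
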