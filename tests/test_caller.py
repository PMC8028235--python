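"""Candidate selection, the per-strand Fisher tests, Stouffer combination
and the end-to-end call gate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from pbvi import caller as C
from pbvi import model as M
from pbvi.errors import PbviError


class TestSelectCandidate:
    def test_argmax_over_totals(self):
        fwd = {"A": 1, "G": 4, "T": 1}
        rev = {"A": 1, "G": 3}
        assert C.select_candidate(fwd, rev, "C") == "G"

    def test_no_alternate_returns_none(self):
        assert C.select_candidate({"C": 9}, {"C": 11}, "C") is None

    def test_tie_breaks_by_fixed_nucleotide_order(self):
        fwd = {"A": 5, "G": 5}
        assert C.select_candidate(fwd, {}, "C") == "A"

    def test_reference_never_selected(self):
        assert C.select_candidate({"C": 100, "T": 1}, {"C": 50}, "C") == "T"


class TestFisherOneStrand:
    def test_zero_alt_gives_p_one(self):
        assert C.fisher_one_strand(0, 50, 3, 997) == 1.0

    def test_matches_enumeration_oracle_on_deep_table(self):
        p = C.fisher_one_strand(3, 297, 13, 13041)
        expected = oracles.fisher_greater_exact(3, 297, 13, 13041)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_monotone_in_alt_count(self):
        depth = 80
        ps = [C.fisher_one_strand(a, depth - a, 5, 995) for a in range(0, 20)]
        assert all(p2 <= p1 for p1, p2 in zip(ps, ps[1:]))

    def test_no_coverage_returns_sentinel(self):
        assert C.fisher_one_strand(0, 0, 5, 995) is C.NO_TEST

    @settings(deadline=None, max_examples=150)
    @given(
        a=st.integers(0, 60),
        b=st.integers(0, 60),
        c=st.integers(0, 150),
        d=st.integers(0, 200),
    )
    def test_agrees_with_exact_enumeration(self, a, b, c, d):
        if a + b == 0:
            return
        p = C.fisher_one_strand(a, b, c, d)
        expected = oracles.fisher_greater_exact(a, b, c, d)
        assert p == pytest.approx(expected, rel=1e-9)


class TestStouffer:
    def test_half_is_fixed_point(self):
        assert C.stouffer_combine(0.5, 0.5) == pytest.approx(0.5, abs=1e-12)

    def test_z2_example(self):
        # both p at z=2 combine to z = 2*sqrt(2)
        p = 0.022750131948179195
        assert C.stouffer_combine(p, p) == pytest.approx(0.0023388674905236, rel=1e-6)

    def test_matches_erfc_oracle(self):
        for pf, pr in [(0.01, 0.2), (0.5, 0.001), (0.9, 0.9), (1e-8, 0.3)]:
            assert C.stouffer_combine(pf, pr) == pytest.approx(
                oracles.stouffer_ref(pf, pr), rel=1e-6
            )

    @settings(deadline=None, max_examples=100)
    @given(
        x=st.floats(1e-12, 1 - 1e-12),
        y=st.floats(1e-12, 1 - 1e-12),
    )
    def test_symmetry(self, x, y):
        assert C.stouffer_combine(x, y) == C.stouffer_combine(y, x)

    def test_extreme_inputs_stay_in_open_interval(self):
        assert 0 < C.stouffer_combine(1e-320, 1e-320) <= 1
        assert 0 < C.stouffer_combine(1.0, 1.0) <= 1


class TestCallVariants:
    def test_spiked_variant_above_analytic_limit_passes(
        self, single_position_sample, single_position_model
    ):
        """VAF 0.05 at 600x against a 26/26,082 model clears the gate
        (the analytic minimum there is ~0.013)."""
        sample = single_position_sample(fG=15, rG=15, fC=285, rC=285)
        model = single_position_model(ref="C", fG=13, rG=13, fC=13041, rC=13041)
        calls = C.call_variants(sample, model, n_tests=28_119)
        assert len(calls) == 1
        assert bool(calls["passed"].iloc[0])
        assert calls["alt"].iloc[0] == "G"
        assert calls["vaf"].iloc[0] == pytest.approx(0.05)

    def test_strand_exclusive_alt_scores_worse_than_even_split(
        self, single_position_sample, single_position_model
    ):
        model = single_position_model(ref="C", fG=13, rG=13, fC=13041, rC=13041)
        even = single_position_sample(fG=5, rG=5, fC=295, rC=295)
        one_strand = single_position_sample(fG=10, rG=0, fC=290, rC=300)
        p_even = C.call_variants(even, model)["p_comb"].iloc[0]
        p_one = C.call_variants(one_strand, model)["p_comb"].iloc[0]
        assert p_one > p_even

    def test_sample_matching_model_proportions_yields_no_calls(self, model):
        """A sample that is a scaled copy of the model (identical alt
        proportions) must produce zero passed calls."""
        scaled = M.scale(model, 0.05)
        sample = scaled.counts[["chrom", "pos"] + list(M.COUNT_COLS)]
        calls = C.call_variants(sample, model, alpha=0.05)
        assert not calls["passed"].any()

    def test_gating_disabled_reports_every_candidate(self, cohort, model):
        samples, _ = cohort
        sample = samples[0]
        strict = C.call_variants(sample, model, alpha=0.05, n_tests="auto")
        loose = C.call_variants(sample, model, alpha=1.0, n_tests=1)
        totals = sample[list(M.COUNT_COLS)].to_numpy()
        # every tested candidate appears regardless of gate
        assert len(loose) == len(strict)
        assert set(map(tuple, strict[["chrom", "pos"]].to_numpy())) == set(
            map(tuple, loose[["chrom", "pos"]].to_numpy())
        )
        assert strict["passed"].sum() <= loose["passed"].sum()

    def test_strand_swap_leaves_combined_p_unchanged(self, cohort, model):
        samples, _ = cohort
        sample = samples[1]

        def swap(df):
            out = df.copy()
            for n in M.NUCLEOTIDES:
                out[f"f{n}"], out[f"r{n}"] = df[f"r{n}"], df[f"f{n}"]
            return out

        swapped_model = M.ModelTable(
            counts=swap(model.counts), n_samples=model.n_samples
        )
        calls = C.call_variants(sample, model)
        calls_swapped = C.call_variants(swap(sample), swapped_model)
        assert np.allclose(
            calls["p_comb"].to_numpy(dtype=float),
            calls_swapped["p_comb"].to_numpy(dtype=float),
            equal_nan=True,
        )

    def test_zero_strand_coverage_is_flagged_never_passed(
        self, single_position_sample, single_position_model
    ):
        sample = single_position_sample(fG=50, fC=250)  # reverse strand empty
        model = single_position_model(ref="C", fC=10_000, rC=10_000)
        calls = C.call_variants(sample, model)
        assert bool(calls["no_test"].iloc[0])
        assert not bool(calls["passed"].iloc[0])

    def test_blacklisted_allele_not_tested(
        self, single_position_sample, single_position_model
    ):
        sample = single_position_sample(fG=30, rG=30, fC=270, rC=270)
        model = single_position_model(ref="C", fC=13041, rC=13041)
        calls = C.call_variants(
            sample, model, blacklist={("geneA", 100, "G")}
        )
        assert calls.empty

    def test_positions_outside_model_ignored(
        self, single_position_sample, single_position_model
    ):
        sample = single_position_sample(chrom="geneZ", fG=30, rG=30)
        model = single_position_model(ref="C", fC=100, rC=100)
        assert C.call_variants(sample, model).empty

    def test_empty_model_rejected(self, single_position_sample):
        empty = M.ModelTable(
            counts=pd.DataFrame(
                columns=["chrom", "pos", "ref"] + list(M.COUNT_COLS)
            ),
            n_samples=0,
        )
        with pytest.raises(PbviError, match="empty model"):
            C.call_variants(single_position_sample(fA=1), empty)

    def test_bonferroni_adjustment_capped_at_one(
        self, single_position_sample, single_position_model
    ):
        sample = single_position_sample(fG=1, rG=1, fC=299, rC=299)
        model = single_position_model(ref="C", fG=50, rG=50, fC=13041, rC=13041)
        calls = C.call_variants(sample, model, n_tests=28_119)
        assert calls["p_adj"].iloc[0] == 1.0


class TestVcfOutput:
    def test_round_trip_through_pysam(
        self, single_position_sample, single_position_model, tmp_path
    ):
        import pysam

        sample = single_position_sample(fG=15, rG=15, fC=285, rC=285)
        model = single_position_model(ref="C", fG=13, rG=13, fC=13041, rC=13041)
        calls = C.call_variants(sample, model, n_tests=28_119)
        path = tmp_path / "out.vcf"
        C.write_vcf(calls, path, contigs={"geneA": 1000})
        with pysam.VariantFile(str(path)) as vcf:
            records = list(vcf)
        assert len(records) == 1
        rec = records[0]
        assert rec.pos == 100
        assert rec.alleles == ("C", "G")
        assert rec.info["ADF"] == 15
        assert rec.info["VAF"] == pytest.approx(0.05, abs=1e-6)
        assert "PASS" in rec.filter

    def test_tsv_mirror_includes_non_passing(
        self, single_position_sample, single_position_model, tmp_path
    ):
        sample = single_position_sample(fG=1, rG=1, fC=299, rC=299)
        model = single_position_model(ref="C", fG=50, rG=50, fC=13041, rC=13041)
        calls = C.call_variants(sample, model, n_tests=28_119)
        path = tmp_path / "calls.tsv"
        C.write_calls_tsv(calls, path, provenance={"seed": 1})
        back = pd.read_csv(path, sep="\t", comment="#")
        assert len(back) == 1
        assert not back["passed"].iloc[0]
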