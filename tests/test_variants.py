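"""Variant-filter unit and property tests with independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from iotnl.simulate import simulate_read_fixture
from iotnl.variants import (
    CandidateVariant,
    InsufficientEvidenceError,
    filter_indels,
    filter_snvs,
    rank_test_vs_threshold,
)


def make_snv(pos=10_000, chrom="1", tumor_depth=100, tumor_alt=30, normal_depth=100,
             normal_alt=0, mapq=58.0, baseq=35.0, mut_end=40.0, ref_end=25.0, **kw):
    """A candidate that passes every criterion unless a field is overridden."""
    return CandidateVariant(
        chrom=chrom, pos=pos, ref="C", alt="T", variant_class="SNV",
        effect="missense",
        tumor_depth=tumor_depth, tumor_alt_count=tumor_alt,
        normal_depth=normal_depth, normal_alt_count=normal_alt,
        mutant_mapqs=[mapq + 0.1 * i for i in range(tumor_alt)],
        mutant_baseqs=[baseq + 0.1 * i for i in range(tumor_alt)],
        mutant_end_distances=[mut_end + 0.3 * i for i in range(tumor_alt)],
        ref_end_distances=[ref_end + 0.3 * i for i in range(tumor_depth - tumor_alt)],
        **kw,
    )


class TestRankTestVsThreshold:
    def test_values_far_above_threshold_are_significant(self):
        assert rank_test_vs_threshold([60, 60, 60, 60, 60], 30) < 0.2

    def test_all_zero_differences_carry_no_evidence(self):
        assert rank_test_vs_threshold([30, 30, 30], 30) >= 0.2

    def test_matches_exact_sign_enumeration(self):
        """p equals the tail mass over all 2^n sign assignments of the ranks."""
        values = [35, 28, 40, 33, 31, 45, 38]
        threshold = 30
        diffs = np.array(values, dtype=float) - threshold
        ranks = stats.rankdata(np.abs(diffs))
        observed = ranks[diffs > 0].sum()
        tail = sum(
            1
            for signs in itertools.product([0, 1], repeat=len(values))
            if sum(r for s, r in zip(signs, ranks) if s) >= observed
        )
        expected = tail / 2 ** len(values)
        assert rank_test_vs_threshold(values, threshold) == pytest.approx(expected)

    def test_empty_values_raise_insufficient_evidence(self):
        with pytest.raises(InsufficientEvidenceError):
            rank_test_vs_threshold([], 30)


# independent single-criterion checkers used as the oracle ------------------


def _oracle_criteria(v: CandidateVariant, batch) -> set[str]:
    failed = set()
    if v.tumor_depth < 10 or v.normal_depth < 10:
        failed.add("I")
    t_vaf = v.tumor_alt_count / v.tumor_depth if v.tumor_depth else 0.0
    n_vaf = v.normal_alt_count / v.normal_depth if v.normal_depth else 0.0
    if t_vaf < 0.05 or n_vaf >= 0.02:
        failed.add("II")
    if v.tumor_alt_count < 3:
        failed.add("III")
    if any(
        o is not v and o.chrom == v.chrom and abs(o.pos - v.pos) <= 10 for o in batch
    ):
        failed.add("IV")
    for crit, vals, thr, alpha in (
        ("V", v.mutant_mapqs, 30, 0.2),
        ("VI", v.mutant_baseqs, 20, 0.05),
    ):
        try:
            if rank_test_vs_threshold(vals, thr) >= alpha:
                failed.add(crit)
        except InsufficientEvidenceError:
            failed.add(crit)
    if not v.mutant_end_distances or not v.ref_end_distances:
        failed.add("VII")
    elif stats.mannwhitneyu(v.mutant_end_distances, v.ref_end_distances,
                            alternative="less").pvalue < 0.1:
        failed.add("VII")
    table = [[v.tumor_alt_count, v.tumor_depth - v.tumor_alt_count],
             [v.normal_alt_count, v.normal_depth - v.normal_alt_count]]
    if stats.fisher_exact(table)[1] >= 0.05:
        failed.add("VIII")
    return failed


class TestFilterSnvs:
    def test_low_depth_rejected_under_coverage_criterion(self):
        _, report = filter_snvs([make_snv(tumor_depth=8, tumor_alt=6)])
        assert report.n_passed == 0
        assert report.rejections["I"] == 1

    def test_subthreshold_tumor_vaf_rejected(self):
        v = make_snv(tumor_depth=100, tumor_alt=4)
        _, report = filter_snvs([v])
        assert "II" in report.rejections

    def test_pass_set_is_intersection_of_independent_criteria(self):
        variants, _ = simulate_read_fixture(
            200,
            {"I": 0.05, "II": 0.05, "III": 0.05, "IV": 0.05,
             "V": 0.05, "VI": 0.05, "VII": 0.05, "VIII": 0.05},
            seed=99,
        )
        passed, report = filter_snvs(variants)
        oracle_pass = [v for v in variants if not _oracle_criteria(v, variants)]
        assert [id(v) for v in passed] == [id(v) for v in oracle_pass]
        # per-criterion tallies agree with the independent checkers
        from collections import Counter

        oracle_tally = Counter()
        for v in variants:
            oracle_tally.update(_oracle_criteria(v, variants))
        for crit in ("I", "II", "III", "IV", "V", "VI", "VII", "VIII"):
            assert report.rejections.get(crit, 0) == oracle_tally[crit]

    def test_empty_input(self):
        passed, report = filter_snvs([])
        assert passed == [] and report.n_input == 0 and report.n_passed == 0

    def test_adjacent_pair_both_rejected(self):
        a, b = make_snv(pos=1000), make_snv(pos=1008)
        _, report = filter_snvs([a, b])
        assert report.rejections["IV"] == 2

    def test_missing_evidence_tallied_separately(self):
        v = make_snv()
        v.mutant_mapqs = []
        v.mutant_baseqs = []
        _, report = filter_snvs([v])
        assert report.rejections["insufficient_evidence"] == 1
        assert report.n_passed == 0

    def test_rejects_non_snv_input(self):
        indel = CandidateVariant(
            chrom="1", pos=5, ref="A", alt="AT", variant_class="insertion",
            effect="frameshift_indel", tumor_depth=50, tumor_alt_count=10,
            normal_depth=50, normal_alt_count=0,
        )
        with pytest.raises(ValueError, match="expects SNVs"):
            filter_snvs([indel])

    @given(perm_seed=st.integers(0, 1000))
    def test_filtering_is_order_independent(self, perm_seed):
        variants, _ = simulate_read_fixture(40, {"II": 0.2, "V": 0.2}, seed=5)
        passed_ref, _ = filter_snvs(variants)
        order = np.random.default_rng(perm_seed).permutation(len(variants))
        passed_perm, _ = filter_snvs([variants[i] for i in order])
        assert {id(v) for v in passed_perm} == {id(v) for v in passed_ref}

    @pytest.mark.parametrize("alt_lo,alt_hi", [(3, 10), (5, 30)])
    def test_more_alt_reads_never_flips_pass_to_fail(self, alt_lo, alt_hi):
        """Raising tumor_alt_count at fixed depth cannot break VAF or support criteria."""
        lo = make_snv(tumor_depth=100, tumor_alt=alt_lo)
        hi = make_snv(tumor_depth=100, tumor_alt=alt_hi)
        lo_fail = _oracle_criteria(lo, [lo])
        hi_fail = _oracle_criteria(hi, [hi])
        for crit in ("II", "III"):
            assert not (crit not in lo_fail and crit in hi_fail)

    def test_raising_mapqs_never_flips_pass_to_fail(self):
        base = make_snv(mapq=31.0)
        raised = make_snv(mapq=55.0)
        if "V" not in _oracle_criteria(base, [base]):
            assert "V" not in _oracle_criteria(raised, [raised])


class TestFilterIndels:
    def make_indel(self, alt, depth, germline=False):
        return CandidateVariant(
            chrom="1", pos=100, ref="A", alt="AT", variant_class="insertion",
            effect="frameshift_indel", tumor_depth=depth, tumor_alt_count=alt,
            normal_depth=50, normal_alt_count=0, germline_flag=germline,
        )

    def test_vaf_below_ten_percent_rejected(self):
        _, report = filter_indels([self.make_indel(9, 100)])
        assert report.rejections["indel_vaf"] == 1

    def test_exactly_ten_percent_passes(self):
        passed, _ = filter_indels([self.make_indel(10, 100)])
        assert len(passed) == 1

    def test_counts_on_generated_fixture(self, rng):
        """12 low-VAF, 5 germline, 1 overlapping -> 34 of 50 pass."""
        indels = []
        for i in range(50):
            low_vaf = i < 12
            germline = 11 <= i < 16  # i == 11 overlaps the low-VAF set
            alt = 5 if low_vaf else 20
            indels.append(self.make_indel(alt, 100, germline=germline))
        passed, report = filter_indels(indels)
        assert len(passed) == 34
        assert report.rejections["indel_vaf"] == 12
        assert report.rejections["indel_germline"] == 5
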