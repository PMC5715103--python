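"""Read filtering, ALLREADS parsing, expression normalisation and qPCR."""

import itertools
import math

import pytest

from strseek.expression import (
    AlignmentRecordLite,
    AlleleReadProfile,
    CtMeasurement,
    FLAG_DUPLICATE,
    FLAG_PROPER_PAIR,
    FLAG_SECONDARY,
    FLAG_SUPPLEMENTARY,
    expression_matrix,
    filter_alleles,
    format_allreads,
    keep_alignment,
    normalize_expression,
    observed_alleles,
    offsets_to_repeat_counts,
    parse_allreads,
    rel_expr_dct,
    rel_expr_ddct,
)


class TestKeepAlignment:
    def test_proper_pair_unique_kept(self):
        assert keep_alignment(AlignmentRecordLite(flag=99, alignment_hits=1))

    def test_duplicate_dropped(self):
        assert not keep_alignment(AlignmentRecordLite(flag=99 | FLAG_DUPLICATE))

    def test_exhaustive_truth_table(self):
        # every combination of the four decision bits x unique/multi-mapper
        for bits in itertools.product([0, FLAG_PROPER_PAIR], [0, FLAG_SECONDARY],
                                      [0, FLAG_DUPLICATE], [0, FLAG_SUPPLEMENTARY]):
            flag = sum(bits)
            for hits in (1, 2):
                expected = (
                    bool(flag & FLAG_PROPER_PAIR)
                    and not flag & FLAG_SECONDARY
                    and not flag & FLAG_DUPLICATE
                    and not flag & FLAG_SUPPLEMENTARY
                    and hits == 1
                )
                assert keep_alignment(AlignmentRecordLite(flag, hits)) is expected


class TestAllreads:
    def test_dialect_example(self):
        assert parse_allreads("-2|10;0|25;2|3") == {-2: 10, 0: 25, 2: 3}

    def test_missing_is_empty(self):
        assert parse_allreads(".") == {}
        assert parse_allreads("") == {}

    def test_malformed_token_named(self):
        with pytest.raises(ValueError, match="x\\|y"):
            parse_allreads("0|25;x|y")

    def test_format_parse_round_trip(self, rng):
        for _ in range(100):
            n = int(rng.integers(0, 8))
            alleles = rng.choice(range(-10, 11), size=n, replace=False)
            mapping = {int(a): int(rng.integers(0, 500)) for a in alleles}
            assert parse_allreads(format_allreads(mapping)) == mapping


def _profile(reads, total=10_000_000, locus="L1"):
    return AlleleReadProfile("S1", "tumor", locus, reads, total)


class TestFilterAlleles:
    def test_below_threshold_removed(self):
        assert filter_alleles(_profile({0: 25, 2: 9})).allele_reads == {0: 25}

    def test_boundary_kept(self):
        assert filter_alleles(_profile({0: 10})).allele_reads == {0: 10}

    def test_all_below_gives_unexpressed_profile(self):
        filtered = filter_alleles(_profile({0: 3, 2: 4}))
        assert filtered.allele_reads == {} and not filtered.is_expressed

    def test_idempotent(self, rng):
        for _ in range(25):
            p = _profile({int(a): int(rng.integers(0, 40)) for a in range(-3, 4)})
            once = filter_alleles(p)
            assert filter_alleles(once) == once


class TestNormalize:
    def test_fpkm_closed_form(self):
        p = _profile({0: 100}, total=10_000_000)
        assert normalize_expression(p, locus_length_bp=1000) == pytest.approx(10.0)

    def test_zero_reads_zero_expression(self):
        p = _profile({}, total=10_000_000)
        assert normalize_expression(p, locus_length_bp=1000) == 0.0
        assert normalize_expression(p, scheme="rpm") == 0.0

    def test_rpm_equals_fpkm_times_locus_kb(self, rng):
        for _ in range(25):
            reads = int(rng.integers(1, 1000))
            length = int(rng.integers(10, 5000))
            total = int(rng.integers(reads, 10**8))
            p = _profile({0: reads}, total=total)
            fpkm = normalize_expression(p, locus_length_bp=length)
            rpm = normalize_expression(p, scheme="rpm")
            assert rpm == pytest.approx(fpkm * length / 1000.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize_expression(AlleleReadProfile("S", "tumor", "L", {}, 0), 100)


def test_observed_alleles_union_ascending():
    profiles = [
        _profile({11: 20}),
        _profile({11: 15, 12: 30}),
        _profile({9: 12, 13: 11, 10: 40}),
    ]
    assert observed_alleles(profiles) == [9, 10, 11, 12, 13]
    assert observed_alleles([_profile({4: 20, 5: 12})]) == [4, 5]
    assert observed_alleles([]) == []


def test_offset_to_repeat_count_conversion():
    assert offsets_to_repeat_counts({-2: 10, 0: 25, 2: 3}, ref_repeats=11, period=2) == {
        10: 10, 11: 25, 12: 3
    }
    with pytest.raises(ValueError):
        offsets_to_repeat_counts({1: 5}, ref_repeats=11, period=2)


class TestQpcr:
    def test_identity_fold_change(self):
        m = CtMeasurement(25, [15])
        assert rel_expr_ddct(m, m) == pytest.approx(1.0)

    def test_one_cycle_is_twofold(self):
        assert rel_expr_ddct(CtMeasurement(24, [15]), CtMeasurement(25, [15])) == pytest.approx(2.0)

    def test_log2_equals_negative_ddct(self, rng):
        for _ in range(50):
            t_ct, t_hk, c_ct, c_hk = rng.uniform(10, 35, size=4)
            fold = rel_expr_ddct(CtMeasurement(t_ct, [t_hk]), CtMeasurement(c_ct, [c_hk]))
            ddct = (t_ct - t_hk) - (c_ct - c_hk)
            assert math.log2(fold) == pytest.approx(-ddct)

    def test_ddct_rejects_multiple_housekeepers(self):
        with pytest.raises(ValueError):
            rel_expr_ddct(CtMeasurement(25, [15, 16]), CtMeasurement(25, [15]))

    def test_dct_geomean(self):
        assert rel_expr_dct(CtMeasurement(20, [20, 20])) == pytest.approx(1.0)
        expected = 2.0 ** -(20 - math.sqrt(18 * 22))
        assert rel_expr_dct(CtMeasurement(20, [18, 22])) == pytest.approx(expected)

    def test_single_housekeeper_reduces_to_plain_dct(self):
        assert rel_expr_dct(CtMeasurement(22, [20])) == pytest.approx(2.0**-2)


def test_expression_matrix_shape_and_values():
    profiles = [
        AlleleReadProfile("P1", "tumor", "L1", {0: 100}, 10_000_000),
        AlleleReadProfile("P1", "adjacent", "L1", {0: 50, 2: 9}, 10_000_000),
        AlleleReadProfile("P1", "tumor", "L2", {0: 5}, 10_000_000),
    ]
    frame = expression_matrix(profiles, locus_lengths={"L1": 1000, "L2": 1000})
    assert frame.loc["L1", "P1:tumor"] == pytest.approx(10.0)
    # the 9-read allele is filtered, the 2-allele below threshold drops out
    assert frame.loc["L1", "P1:adjacent"] == pytest.approx(5.0)
    # all L2 alleles below 10 reads -> zero expression
    assert frame.loc["L2", "P1:tumor"] == 0.0


def test_keep_aligned_segment_on_sam_records(tmp_path):
    """The pysam wrapper applies the flag/NH rules to real SAM records."""
    import pysam

    from strseek.expression import keep_aligned_segment

    sam = tmp_path / "reads.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n"
        "@SQ\tSN:chr1\tLN:10000\n"
        "r1\t99\tchr1\t100\t60\t50M\t=\t200\t150\t" + "A" * 50 + "\t" + "I" * 50 + "\tNH:i:1\n"
        "r2\t99\tchr1\t300\t60\t50M\t=\t400\t150\t" + "A" * 50 + "\t" + "I" * 50 + "\tNH:i:3\n"
        "r3\t1123\tchr1\t500\t60\t50M\t=\t600\t150\t" + "A" * 50 + "\t" + "I" * 50 + "\tNH:i:1\n"
        "r4\t83\tchr1\t700\t60\t50M\t=\t600\t-150\t" + "A" * 50 + "\t" + "I" * 50 + "\tHI:i:1\n"
    )
    with pysam.AlignmentFile(str(sam), "r") as handle:
        kept = {rec.query_name: keep_aligned_segment(rec) for rec in handle}
    # r1 proper+unique kept; r2 multi-mapper dropped; r3 duplicate bit dropped;
    # r4 proper pair, HI-only tag, first hit -> kept
    assert kept == {"r1": True, "r2": False, "r3": False, "r4": True}


def test_read_lobstr_vcf_allreads_per_sample(tmp_path):
    from strseek.expression import read_lobstr_vcf

    vcf = tmp_path / "calls.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr9>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=ALLREADS,Number=1,Type=String,Description="Allele reads">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\n"
        "chr9\t79400651\tTG-PCA3\tT\t.\t.\tPASS\t.\tGT:ALLREADS\t0/0:-2|10;0|25\t0/0:.\n"
    )
    profiles = read_lobstr_vcf(
        vcf, total_mapped_reads={"P1": 1000000, "P2": 2000000},
        condition_of={"P1": "tumor", "P2": "adjacent"},
    )
    by_sample = {p.sample_id: p for p in profiles}
    assert by_sample["P1"].allele_reads == {-2: 10, 0: 25}
    assert by_sample["P1"].locus_id == "TG-PCA3"
    assert by_sample["P1"].condition == "tumor"
    assert by_sample["P2"].allele_reads == {}
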