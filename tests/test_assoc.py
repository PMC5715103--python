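"""Genotype tabulation, odds ratios, HWE, bootstrap, survival and KS."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strseek.assoc import (
    Genotype,
    SubjectRecord,
    allele_counts_from_genotypes,
    allele_frequencies,
    allelic_or,
    bootstrap_or,
    crude_or,
    dichotomize_gleason,
    fit_logistic,
    genotype_counts,
    genotype_or,
    heterozygosity,
    hwe_test,
    km_logrank,
    ks_two_sample,
    observed_alleles_in_table,
    read_cohort,
    restrict_genotypes,
    round_half_up,
    write_cohort,
)
from strseek.datasets import tg_pca3_case_control


class TestGenotype:
    def test_normalised_ascending(self):
        assert Genotype(12, 11) == Genotype(11, 12)
        assert str(Genotype(12, 11)) == "11/12"

    def test_parse(self):
        assert Genotype.parse("11/9") == Genotype(9, 11)

    def test_heterozygous(self):
        assert Genotype(11, 12).is_heterozygous
        assert not Genotype(11, 11).is_heterozygous


class TestAlleleTabulation:
    def test_single_heterozygote(self):
        table = {"g": {Genotype(11, 12): 1}}
        assert allele_counts_from_genotypes(table, "g") == {11: 1, 12: 1}

    def test_total_is_twice_subjects(self, rng):
        for _ in range(20):
            counts = {
                Genotype(int(a), int(b)): int(rng.integers(0, 50))
                for a in range(9, 14)
                for b in range(int(a), 14)
            }
            table = {"g": counts}
            totals = allele_counts_from_genotypes(table, "g")
            assert sum(totals.values()) == 2 * sum(counts.values())

    def test_matches_per_subject_enumeration(self, rng):
        counts = {Genotype(int(rng.integers(8, 14)), int(rng.integers(8, 14))): int(rng.integers(1, 30))
                  for _ in range(10)}
        table = {"g": counts}
        got = allele_counts_from_genotypes(table, "g")
        expected: dict[int, int] = {}
        for gt, n in counts.items():
            for _ in range(n):
                expected[gt.a1] = expected.get(gt.a1, 0) + 1
                expected[gt.a2] = expected.get(gt.a2, 0) + 1
        assert got == expected

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError):
            allele_counts_from_genotypes({"g": {}}, "other")

    def test_frequencies_sum_to_100(self, rng):
        counts = {a: int(rng.integers(1, 500)) for a in range(9, 14)}
        assert sum(allele_frequencies(counts).values()) == pytest.approx(100.0, abs=1e-9)
        assert allele_frequencies({11: 3, 12: 1}) == {11: 75.0, 12: 25.0}


def test_round_half_up_display():
    assert round_half_up(0.5) == 1.0
    assert round_half_up(75.38) == 75.0
    assert round_half_up(0.605, 2) == 0.61


class TestCrudeOr:
    def test_unit_table(self):
        r = crude_or(1, 1, 1, 1)
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.ci_low < 1.0 < r.ci_high

    def test_published_genotype_cells(self):
        # heterozygote and rare-homozygote cells of the case-control table
        assert crude_or(392, 680, 461, 634).odds_ratio == pytest.approx(0.7928, abs=1e-4)
        assert crude_or(73, 680, 113, 634).odds_ratio == pytest.approx(0.6023, abs=1e-4)

    def test_reciprocal_identity(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 200, size=4))
            assert crude_or(a, b, c, d).odds_ratio * crude_or(b, a, d, c).odds_ratio == pytest.approx(1.0)

    def test_zero_cell_haldane_flagged(self):
        r = crude_or(0, 10, 5, 10)
        assert "Haldane" in r.method
        assert r.odds_ratio == pytest.approx((0.5 * 10.5) / (10.5 * 5.5))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            crude_or(0, 0, 5, 10)


class TestLogistic:
    def test_single_binary_predictor_equals_cross_product(self, rng):
        for _ in range(10):
            a, b, c, d = (int(x) for x in rng.integers(5, 120, size=4))
            x = np.array([1] * a + [0] * b + [1] * c + [0] * d)
            y = np.array([1] * (a + b) + [0] * (c + d))
            fit = fit_logistic(pd.DataFrame({"x": x}), y)[0]
            assert fit.odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_intercept_only_balanced_response_is_zero(self):
        y = np.array([0, 1] * 25)
        result = fit_logistic(pd.DataFrame(index=range(50)), y)
        assert result[-1].term == "const"
        assert math.log(result[-1].odds_ratio) == pytest.approx(0.0, abs=1e-8)

    def test_separation_raises(self):
        x = np.array([0.0] * 10 + [1.0] * 10)
        y = np.array([0] * 10 + [1] * 10)
        from strseek.assoc import LogisticFitError

        with pytest.raises(LogisticFitError):
            fit_logistic(pd.DataFrame({"x": x}), y)


def _subjects_from_table(table):
    subjects = []
    i = 0
    for group, counts in table.items():
        status = "case" if group == "case" else "control"
        for gt, n in counts.items():
            for _ in range(n):
                i += 1
                subjects.append(SubjectRecord(f"S{i}", status, gt, age=60.0))
    return subjects


class TestRestrictGenotypes:
    def test_published_case_count(self):
        subjects = _subjects_from_table(tg_pca3_case_control())
        kept, removed = restrict_genotypes(subjects)
        cases = [s for s in kept if s.status == "case"]
        assert len(cases) == 680 + 392 + 73 == 1145

    def test_empty_and_identity(self):
        assert restrict_genotypes([]) == ([], 0)
        subjects = _subjects_from_table({"case": {Genotype(9, 9): 3}, "control": {}})
        kept, removed = restrict_genotypes(subjects, kept=frozenset({Genotype(9, 9)}))
        assert kept == subjects and removed == 0


class TestHwe:
    def test_exact_equilibrium(self):
        r = hwe_test({Genotype(1, 1): 25, Genotype(1, 2): 50, Genotype(2, 2): 25})
        assert r.chi2 == pytest.approx(0.0) and r.p_value == pytest.approx(1.0)

    def test_maximal_disequilibrium_closed_form(self):
        # p = q = 0.5, no heterozygotes: chi2 = 100 with df 1
        r = hwe_test({Genotype(1, 1): 50, Genotype(2, 2): 50})
        assert r.chi2 == pytest.approx(100.0) and r.df == 1

    def test_matches_direct_recomputation_multiallelic(self, rng):
        for _ in range(10):
            alleles = [9, 10, 11]
            counts = {}
            for i, a in enumerate(alleles):
                for b in alleles[i:]:
                    counts[Genotype(a, b)] = int(rng.integers(5, 200))
            r = hwe_test(counts, pool_threshold=0.0)
            n = sum(counts.values())
            ac = {a: 0 for a in alleles}
            for gt, c in counts.items():
                ac[gt.a1] += c
                ac[gt.a2] += c
            freqs = {a: ac[a] / (2 * n) for a in alleles}
            chi2 = 0.0
            for i, a in enumerate(alleles):
                for b in alleles[i:]:
                    exp = n * (freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b])
                    chi2 += (counts[Genotype(a, b)] - exp) ** 2 / exp
            assert r.chi2 == pytest.approx(chi2)
            assert r.df == 6 - 3

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="polymorphic"):
            hwe_test({Genotype(11, 11): 100})


def test_heterozygosity():
    assert heterozygosity({Genotype(11, 11): 1, Genotype(11, 12): 1}) == 0.5
    assert heterozygosity({Genotype(11, 11): 10}) == 0.0
    counts = {Genotype(10, 11): 7, Genotype(11, 11): 13, Genotype(9, 12): 5}
    expected = (7 + 5) / 25
    assert heterozygosity(counts) == pytest.approx(expected)


class TestBootstrap:
    def _cohort(self, seed=1, n=400):
        rng = np.random.default_rng(seed)
        subjects = []
        for i in range(n):
            status = "case" if i < n // 2 else "control"
            gt = Genotype(11, 11) if rng.random() < 0.6 else Genotype(11, 12)
            subjects.append(SubjectRecord(f"S{i}", status, gt, age=60.0))
        return subjects

    def test_same_seed_is_bit_reproducible(self):
        subjects = self._cohort()
        a = bootstrap_or(subjects, Genotype(11, 12), Genotype(11, 11), seed=7)
        b = bootstrap_or(subjects, Genotype(11, 12), Genotype(11, 11), seed=7)
        assert a == b

    def test_constant_statistic_collapses_ci_and_floors_p(self):
        subjects = self._cohort()
        r = bootstrap_or(
            subjects, Genotype(11, 12), Genotype(11, 11),
            statistic=lambda s: 1.5, n_resamples=200, seed=3,
        )
        assert r.ci_low == r.ci_high == 1.5
        assert r.p_value == 2 / 200

    def test_generic_statistic_agrees_with_default_path(self):
        subjects = self._cohort(seed=5)
        from strseek.assoc import _default_log_or

        generic = bootstrap_or(
            subjects, Genotype(11, 12), Genotype(11, 11),
            statistic=lambda s: _default_log_or(s, Genotype(11, 12), Genotype(11, 11)),
            n_resamples=400, seed=11,
        )
        fast = bootstrap_or(
            subjects, Genotype(11, 12), Genotype(11, 11), n_resamples=400, seed=11
        )
        # same estimator, same stratified scheme: CIs agree to sampling noise
        assert generic.estimate == pytest.approx(fast.estimate)
        assert generic.ci_low == pytest.approx(fast.ci_low, abs=0.15)
        assert generic.ci_high == pytest.approx(fast.ci_high, abs=0.15)


def test_dichotomize_gleason_boundary():
    assert dichotomize_gleason(7) == "less aggressive"
    assert dichotomize_gleason(8) == "aggressive"
    assert dichotomize_gleason(10) == "aggressive"
    with pytest.raises(ValueError):
        dichotomize_gleason(11)


class TestKmLogrank:
    def test_hand_worked_four_event_example(self):
        # A events at t=1,3; B events at t=2,4; all uncensored.
        # O_A=2, E_A=4/3, V=13/18 -> chi2=8/13; HR=(O_A/E_A)/(O_B/E_B)=2
        groups = {"A": [(1.0, True), (3.0, True)], "B": [(2.0, True), (4.0, True)]}
        r = km_logrank(groups)
        assert r.chi2 == pytest.approx(8 / 13)
        assert r.p_value == pytest.approx(float(stats.chi2.sf(8 / 13, 1)))
        assert r.hazard_ratio == pytest.approx(2.0)
        assert r.observed == {"A": 2, "B": 2}
        assert r.expected["A"] == pytest.approx(4 / 3)

    def test_identical_groups_are_null(self):
        data = [(float(t), t % 2 == 0) for t in range(1, 21)]
        r = km_logrank({"A": data, "B": list(data)})
        assert r.chi2 == pytest.approx(0.0, abs=1e-9)
        assert r.hazard_ratio == pytest.approx(1.0)

    def test_km_curve_product_limit(self):
        r = km_logrank({"A": [(1.0, True), (2.0, True)], "B": [(5.0, False), (6.0, True)]})
        curve = r.curves["A"].set_index("time")["survival"]
        assert curve.loc[1.0] == pytest.approx(0.5)
        assert curve.loc[2.0] == pytest.approx(0.0)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            km_logrank({"A": [(1.0, False)], "B": [(2.0, False)]})

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank({"A": [(1.0, True)], "B": []})


class TestKs:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        d, p = ks_two_sample(x, list(x))
        assert d == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == pytest.approx(1.0)

    def test_matches_brute_force_ecdf_sweep(self, rng):
        x = rng.normal(0, 1, size=40)
        y = rng.normal(0.5, 1, size=55)
        d, _ = ks_two_sample(x, y)
        grid = np.concatenate([x, y])
        ecdf_x = np.array([(x <= g).mean() for g in grid])
        ecdf_y = np.array([(y <= g).mean() for g in grid])
        assert d == pytest.approx(np.abs(ecdf_x - ecdf_y).max())


def test_allelic_or_codings_run_on_published_table():
    subjects = _subjects_from_table(tg_pca3_case_control())
    per_allele = allelic_or(subjects, 11, coding="per-allele")
    carrier = allelic_or(subjects, 11, coding="carrier")
    assert per_allele.odds_ratio > 1.0 and carrier.odds_ratio > 1.0
    assert per_allele.odds_ratio != pytest.approx(carrier.odds_ratio)


def test_genotype_or_equals_crude_on_published_table():
    subjects = _subjects_from_table(tg_pca3_case_control())
    kept, _ = restrict_genotypes(subjects)
    fit = genotype_or(kept, Genotype(11, 12), Genotype(11, 11))
    assert fit.odds_ratio == pytest.approx(crude_or(392, 680, 461, 634).odds_ratio, rel=1e-6)


def test_observed_alleles_ignores_zero_count_rows():
    table = {"g": {Genotype(11, 11): 5, Genotype(9, 11): 0, Genotype(12, 13): 2}}
    assert observed_alleles_in_table(table) == [11, 12, 13]


def test_cohort_csv_round_trip(tmp_path):
    subjects = [
        SubjectRecord("C1", "case", Genotype(11, 12), 63.5, True, 7, 48.0, True, False),
        SubjectRecord("H1", "control", Genotype(11, 11), 60.1, None, None, 120.0, False, False),
    ]
    path = tmp_path / "cohort.csv"
    write_cohort(subjects, path)
    assert read_cohort(path) == subjects


def test_genotype_counts_tabulates_subjects():
    subjects = [
        SubjectRecord("a", "case", Genotype(11, 11), 60.0),
        SubjectRecord("b", "case", Genotype(11, 12), 60.0),
        SubjectRecord("c", "control", Genotype(11, 11), 60.0),
    ]
    assert genotype_counts(subjects) == {
        "case": {Genotype(11, 11): 1, Genotype(11, 12): 1},
        "control": {Genotype(11, 11): 1},
    }
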