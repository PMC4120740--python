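"""Report parsing, temporal validation, 2x2 tables, PRR and chi-square."""

import math
from datetime import date
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from aesignal import (
    ContingencyTable,
    DegenerateTableError,
    ReportFormatError,
    ReportRecord,
    Thresholds,
    build_tables,
    chi_square,
    codae_detect,
    config_mapping,
    flat_ontology,
    load_mapping,
    make_figure4_fixture,
    make_study_config,
    prr,
    read_reports,
    simulate_reports,
    validate_record,
)
from aesignal.simulate import fixture_path

HEADER = "report_id\tintervention\tvax_date\tonset_date\tage\tsex\tcausality\tae_codes"


def tsv(*rows):
    return "\n".join((HEADER,) + rows) + "\n"


def record(t1="2010-01-01", t2="2010-01-03", codes=("F",)):
    return ReportRecord(
        report_id="R1",
        intervention="V1",
        ae_codes=list(codes),
        t1=date.fromisoformat(t1),
        t2=date.fromisoformat(t2) if t2 else None,
    )


class TestReadReports:
    def test_three_valid_rows(self):
        text = tsv(
            "R1\tV1\t2013-01-01\t2013-01-02\t30\tF\t\tA;B",
            "R2\tV1\t2013-01-03\t\t\t\tnot related\tA",
            "R3\tV2\t2013-01-04\t2013-01-05\t7\tM\tpossibly related\tC",
        )
        records = read_reports(text)
        assert len(records) == 3
        assert records[0].ae_codes == ["A", "B"]
        assert records[1].t2 is None
        assert records[2].causality_level == "possibly related"

    @pytest.mark.parametrize(
        "row, match",
        [
            ("R1\tV1\t2013-01-01\t\t\t\t\t", "empty AE code list"),
            ("R1\tV1\tnot-a-date\t\t\t\t\tA", "unparseable vax_date"),
            ("R1\tV1\t2013-01-01\t\t\t\tmaybe\tA", "causality"),
        ],
    )
    def test_bad_rows_name_the_row(self, row, match):
        with pytest.raises(ReportFormatError, match=match) as excinfo:
            read_reports(tsv(row))
        assert "row 2" in str(excinfo.value)

    def test_missing_column(self):
        with pytest.raises(ReportFormatError, match="missing mandatory column"):
            read_reports("report_id\tintervention\nR1\tV1\n")

    def test_duplicate_report_ids_rejected(self):
        text = tsv(
            "R1\tV1\t2013-01-01\t\t\t\t\tA",
            "R1\tV2\t2013-01-02\t\t\t\t\tB",
        )
        with pytest.raises(ReportFormatError, match="duplicate report id"):
            read_reports(text)

    def test_reversed_dates_parse_then_flag(self):
        """Parsing is lenient about temporal order; validation is strict."""
        text = tsv("R1\tV1\t2010-01-05\t2010-01-01\t\t\t\tA")
        (rec,) = read_reports(text)
        issues = validate_record(rec)
        assert [i.severity for i in issues] == ["violation"]


class TestValidateRecord:
    def test_ordered_dates_pass(self):
        assert validate_record(record("2010-01-01", "2010-01-03")) == []

    def test_onset_before_intervention_is_violation(self):
        issues = validate_record(record("2010-01-05", "2010-01-01"))
        assert len(issues) == 1 and issues[0].severity == "violation"
        assert "t1 must precede t2" in issues[0].message

    def test_missing_onset_is_warning_only(self):
        issues = validate_record(record(t2=None))
        assert [i.severity for i in issues] == ["warning"]


class TestBuildTables:
    def test_toy_dataset_hand_count(self, figure4_ontology, figure4_mapping):
        """Packaged 5-report file: 2 target, 3 other; fever in one of each."""
        with open(fixture_path("toy_reports.tsv")) as handle:
            reports = read_reports(handle)
        tables = build_tables(reports, "V1", figure4_mapping, figure4_ontology)
        fever = tables["OAE_0001006"]
        assert (fever.a, fever.b, fever.c, fever.d) == (1, 1, 1, 2)

    def test_single_intervention_degenerate_margin(self, figure4_ontology, figure4_mapping):
        reports = [
            ReportRecord("R1", "V1", ["10016558"], date(2013, 1, 1)),
            ReportRecord("R2", "V1", ["10011224"], date(2013, 1, 2)),
        ]
        tables = build_tables(reports, "V1", figure4_mapping, figure4_ontology)
        for table in tables.values():
            assert table.c == table.d == 0

    def test_two_codes_one_term_counted_once(self, figure4_ontology):
        """Report-level counting: synonymous codes collapse per report."""
        mapping = load_mapping("x\tOAE_0001006\ny\tOAE_0001006\n")
        reports = [
            ReportRecord("R1", "V1", ["x", "y"], date(2013, 1, 1)),
            ReportRecord("R2", "V2", ["x"], date(2013, 1, 2)),
        ]
        tables = build_tables(reports, "V1", mapping, figure4_ontology)
        assert tables["OAE_0001006"].a == 1

    def test_unmapped_codes_kept_as_raw_strata(self, figure4_ontology, figure4_mapping):
        reports = [
            ReportRecord("R1", "V1", ["NOT_A_CODE"], date(2013, 1, 1)),
            ReportRecord("R2", "V2", ["10016558"], date(2013, 1, 2)),
        ]
        with pytest.warns(UserWarning, match="no ontology mapping"):
            tables = build_tables(reports, "V1", figure4_mapping, figure4_ontology)
        assert tables["NOT_A_CODE"].a == 1


class TestPrr:
    def test_hand_derived_value(self):
        assert prr(ContingencyTable(20, 80, 100, 900)) == pytest.approx(2.0)

    def test_equal_proportions_give_unity(self):
        assert prr(ContingencyTable(5, 45, 20, 180)) == pytest.approx(1.0)

    def test_zero_comparator_convention(self):
        assert math.isinf(prr(ContingencyTable(5, 5, 0, 90)))
        assert prr(ContingencyTable(0, 10, 5, 85)) == 0.0

    def test_empty_target_row_is_error(self):
        with pytest.raises(DegenerateTableError):
            prr(ContingencyTable(0, 0, 5, 5))

    def test_scale_invariance_and_swap_inversion(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(1, 400, size=4))
            base = prr(ContingencyTable(a, b, c, d))
            scaled = prr(ContingencyTable(3 * a, 3 * b, 3 * c, 3 * d))
            assert scaled == pytest.approx(base, rel=1e-12)
            swapped = prr(ContingencyTable(c, d, a, b))
            assert swapped == pytest.approx(1.0 / base, rel=1e-12)


class TestChiSquare:
    def test_perfect_independence_floors_at_zero(self):
        assert chi_square(ContingencyTable(25, 25, 25, 25)) == 0.0

    def test_hand_derived_value(self):
        assert chi_square(ContingencyTable(20, 80, 100, 900)) == pytest.approx(
            8.3531, abs=5e-4
        )

    def test_extreme_diagonal_matches_exact_formula(self):
        table = ContingencyTable(10, 0, 0, 10)
        n = 20
        expected = n * (abs(100) - n / 2) ** 2 / (10 * 10 * 10 * 10)
        assert chi_square(table) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_margin_is_error(self):
        with pytest.raises(DegenerateTableError):
            chi_square(ContingencyTable(0, 0, 5, 5))
        with pytest.raises(DegenerateTableError):
            chi_square(ContingencyTable(0, 5, 0, 5))

    def test_matches_scipy_with_and_without_correction(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(1, 500, size=4))
            table = ContingencyTable(a, b, c, d)
            obs = [[a, b], [c, d]]
            assert chi_square(table, yates=True) == pytest.approx(
                chi2_contingency(obs, correction=True).statistic, rel=1e-9
            )
            assert chi_square(table, yates=False) == pytest.approx(
                chi2_contingency(obs, correction=False).statistic, rel=1e-9
            )

    def test_scales_linearly_with_counts(self):
        table = ContingencyTable(30, 70, 50, 850)
        big = ContingencyTable(300, 700, 500, 8500)
        assert chi_square(big, yates=False) == pytest.approx(
            10 * chi_square(table, yates=False), rel=1e-12
        )


class TestCodaeDetect:
    def test_planted_pair_is_flagged(self):
        config = make_study_config(seed=5)
        reports = simulate_reports(config)
        results = codae_detect(
            reports, "V1", config_mapping(config), flat_ontology(config)
        )
        planted_term = config_mapping(config).entries["10000010"]
        hit = next(r for r in results if r.ae_term == planted_term)
        assert hit.passes
        assert hit.prr > 2 and hit.chi2 > 4 and hit.case_fraction > 0.002

    def test_boundary_prr_exactly_two_fails(self, figure4_ontology):
        """The printed cutoffs are strict inequalities."""
        mapping = load_mapping("F\tOAE_0001006\n")
        reports = []
        # a=20,b=80 target; c=100,d=900 comparator -> PRR exactly 2.0
        for i in range(100):
            codes = ["F"] if i < 20 else ["X"]
            reports.append(ReportRecord(f"T{i}", "V1", codes, date(2013, 1, 1)))
        for i in range(1000):
            codes = ["F"] if i < 100 else ["X"]
            reports.append(ReportRecord(f"O{i}", "V2", codes, date(2013, 1, 1)))
        with pytest.warns(UserWarning):
            results = codae_detect(
                reports,
                "V1",
                mapping,
                figure4_ontology,
                thresholds=Thresholds(frac_min=0.001),
            )
        hit = next(r for r in results if r.ae_term == "OAE_0001006")
        assert hit.prr == pytest.approx(2.0)
        assert hit.chi2 > 4 and hit.case_fraction > 0.001
        assert not hit.passes

    def test_margin_conservation(self):
        config = make_study_config(seed=3, n_reports=2_000)
        reports = simulate_reports(config)
        results = codae_detect(
            reports, "V1", config_mapping(config), flat_ontology(config)
        )
        n_target = sum(1 for r in reports if r.intervention == "V1")
        for result in results:
            assert result.table.a + result.table.b == n_target
            assert result.table.n == len(reports)

    def test_sorted_by_descending_chi2(self):
        config = make_study_config(seed=9, n_reports=5_000)
        reports = simulate_reports(config)
        results = codae_detect(
            reports, "V1", config_mapping(config), flat_ontology(config)
        )
        scores = [r.chi2 for r in results if not math.isnan(r.chi2)]
        assert scores == sorted(scores, reverse=True)

    def test_null_chi2_pass_fraction_bounded(self):
        """Under independence the chi2 > 4 criterion alone fires at most
        ~5% of the time (it is slightly stricter than the 3.84 cutoff, and
        the Yates correction is conservative at small counts)."""
        n_pairs = 0
        n_pass = 0
        for seed in range(500):
            config = make_study_config(
                seed=30_000 + seed, n_reports=1_000, risk_ratio=1.0, n_rare_codes=7
            )
            reports = simulate_reports(config)
            results = codae_detect(
                reports, "V1", config_mapping(config), flat_ontology(config)
            )
            for result in results:
                if math.isnan(result.chi2):
                    continue
                n_pairs += 1
                n_pass += result.chi2 > 4
        assert n_pairs > 3_000
        assert n_pass / n_pairs <= 0.06


class TestFormulaOracles:
    """Exact-rational re-evaluation of both statistics, independent of the
    floating-point implementation path."""

    @staticmethod
    def exact_prr(a, b, c, d):
        return Fraction(a, a + b) / Fraction(c, c + d)

    @staticmethod
    def exact_yates(a, b, c, d):
        n = a + b + c + d
        diff = abs(a * d - b * c) - Fraction(n, 2)
        if diff < 0:
            diff = Fraction(0)
        return n * diff * diff / Fraction((a + b) * (c + d) * (a + c) * (b + d))

    def test_thousand_random_tables(self):
        rng = np.random.default_rng(2024)
        for _ in range(1_000):
            a, b, c, d = (int(x) for x in rng.integers(1, 1_000, size=4))
            table = ContingencyTable(a, b, c, d)
            assert prr(table) == pytest.approx(
                float(self.exact_prr(a, b, c, d)), rel=1e-12
            )
            assert chi_square(table) == pytest.approx(
                float(self.exact_yates(a, b, c, d)), rel=1e-12
            )
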