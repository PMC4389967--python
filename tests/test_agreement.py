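"""Kappa agreement statistics against printed values, an independent oracle
(plain summation), statsmodels, and distributional checks of the SE."""

import numpy as np
import pytest

from bindm.agreement import (
    ContingencyTable,
    InterRaterAgreement,
    PairingError,
    UndefinedKappaError,
    ca_weight,
    cross_tabulate,
    simple_kappa,
    weighted_kappa,
)
from bindm.rubric import ExamRecord, Rater, SubscoreAssessment


def kappa_oracle(counts, categories, weighted):
    """Direct cell-by-cell summation, no matrix shortcuts."""
    k = len(categories)
    n = sum(sum(row) for row in counts)
    span = max(categories) - min(categories)
    p_o = p_e = 0.0
    row_m = [sum(counts[i][j] for j in range(k)) / n for i in range(k)]
    col_m = [sum(counts[i][j] for i in range(k)) / n for j in range(k)]
    for i in range(k):
        for j in range(k):
            if weighted:
                w = 1.0 - abs(categories[i] - categories[j]) / span
            else:
                w = 1.0 if i == j else 0.0
            p_o += w * counts[i][j] / n
            p_e += w * row_m[i] * col_m[j]
    return (p_o - p_e) / (1.0 - p_e)


def _records_from_table(table):
    """Paired exam records whose mental-status cross-tab equals the table."""
    records, idx = [], 0
    for i, r_level in enumerate(table.categories):
        for j, c_level in enumerate(table.categories):
            for _ in range(int(table.counts[i, j])):
                infant = f"n{idx}"
                idx += 1
                records.append(ExamRecord(infant, Rater.RESIDENT,
                                          SubscoreAssessment(r_level, 0, 0, 0)))
                records.append(ExamRecord(infant, Rater.CONSULTANT,
                                          SubscoreAssessment(c_level, 0, 0, 0)))
    return records


class TestPublishedValues:
    """The printed inter-rater results, reproduced to 4 decimals."""

    @pytest.mark.parametrize("name, kappa, ci", [
        ("table2a", 0.7692, (0.6977, 0.8407)),  # mental status
        ("table2b", 0.8430, (0.7809, 0.9051)),  # muscle tone
        ("table2c", 0.8139, (0.7321, 0.8957)),  # cry
        ("table1", 0.7969, (0.7426, 0.8512)),   # total score
    ])
    def test_weighted_kappa(self, fx, name, kappa, ci):
        res = weighted_kappa(getattr(fx, name))
        assert round(res.estimate, 4) == kappa
        assert (round(res.ci_low, 4), round(res.ci_high, 4)) == ci

    def test_gaze_simple_kappa_and_ci(self, fx):
        res = simple_kappa(fx.table2d)
        assert round(res.estimate, 4) == 0.5802
        assert round(res.ci_low, 4) == 0.4055
        assert round(res.ci_high, 4) == 0.7549

    def test_model_fit_matches_function(self, fx):
        res = InterRaterAgreement(fx.table2a).fit()
        assert res.estimate == weighted_kappa(fx.table2a).estimate


@pytest.mark.parametrize("ci, cj, expected", [
    (0, 0, 1.0),
    (0, 3, 0.0),
    (1, 2, 2 / 3),
])
def test_linear_weight_formula(ci, cj, expected):
    assert ca_weight(ci, cj, 0, 3) == pytest.approx(expected)


def test_degenerate_category_span_rejected():
    with pytest.raises(ValueError):
        ca_weight(0, 0, 2, 2)


class TestKappaProperties:

    def test_oracle_equivalence_random_tables(self):
        rng = np.random.default_rng(42)
        cats = (0, 1, 2)
        for _ in range(200):
            counts = rng.integers(0, 6, size=(3, 3))
            if counts.sum() == 0 or counts.sum() > 30:
                continue
            t = ContingencyTable(cats, counts)
            try:
                ours = weighted_kappa(t).estimate
            except UndefinedKappaError:
                continue
            assert ours == pytest.approx(
                kappa_oracle(counts.tolist(), cats, weighted=True), abs=1e-12)
            assert simple_kappa(t).estimate == pytest.approx(
                kappa_oracle(counts.tolist(), cats, weighted=False), abs=1e-12)

    def test_transpose_invariance(self, fx):
        for name in ("table2a", "table2b", "table2c", "table2d", "table1"):
            t = getattr(fx, name)
            assert weighted_kappa(t).estimate == pytest.approx(
                weighted_kappa(t.transpose()).estimate, abs=1e-12)

    def test_binary_weighted_equals_simple(self, fx):
        """At k = 2 the linear weights degenerate to the identity."""
        rng = np.random.default_rng(7)
        tables = [fx.table2d]
        for _ in range(20):
            counts = rng.integers(1, 50, size=(2, 2))
            tables.append(ContingencyTable((0, 3), counts))
        for t in tables:
            w, s = weighted_kappa(t), simple_kappa(t)
            assert w.estimate == pytest.approx(s.estimate, abs=1e-12)
            assert w.se == pytest.approx(s.se, abs=1e-12)

    def test_perfect_agreement_is_one(self):
        t = ContingencyTable((0, 1, 2, 3), np.diag([5, 7, 1, 2]))
        assert weighted_kappa(t).estimate == pytest.approx(1.0)
        assert simple_kappa(t).estimate == pytest.approx(1.0)

    def test_chance_level_table_is_zero(self):
        # outer product of its own margins: agreement purely by chance
        t = ContingencyTable((0, 1), [[9, 3], [3, 1]])
        assert simple_kappa(t).estimate == pytest.approx(0.0, abs=1e-12)

    def test_estimate_within_bounds_and_ci_ordering(self, fx):
        for name in ("table1", "table2a", "table2b", "table2c", "table2d"):
            res = weighted_kappa(getattr(fx, name))
            assert -1.0 <= res.ci_low <= res.estimate <= res.ci_high <= 1.0

    def test_undefined_when_marginal_mass_concentrated(self):
        t = ContingencyTable((0, 1), [[5, 0], [0, 0]])
        with pytest.raises(UndefinedKappaError):
            simple_kappa(t)

    def test_against_statsmodels(self, fx):
        from statsmodels.stats.inter_rater import cohens_kappa

        for name in ("table2a", "table2b", "table2c", "table1"):
            t = getattr(fx, name)
            ref = cohens_kappa(np.asarray(t.counts), wt="linear")
            ours = weighted_kappa(t)
            assert ours.estimate == pytest.approx(ref.kappa, abs=1e-10)
            assert ours.se == pytest.approx(np.sqrt(ref.var_kappa), abs=1e-10)
        ref = cohens_kappa(np.asarray(fx.table2d.counts))
        ours = simple_kappa(fx.table2d)
        assert ours.estimate == pytest.approx(ref.kappa, abs=1e-10)
        assert ours.se == pytest.approx(np.sqrt(ref.var_kappa), abs=1e-10)

    def test_asymptotic_se_matches_monte_carlo_sd(self, fx):
        """Empirical SD of kappa over multinomial resamples of a fixed rating
        process matches the mean asymptotic SE within 15%."""
        p = fx.table2a.proportions.ravel()
        n = fx.table2a.n
        rng = np.random.default_rng(2024)
        draws = rng.multinomial(n, p, size=2000).reshape(-1, 4, 4)
        estimates, ses = [], []
        for counts in draws:
            t = ContingencyTable((0, 1, 2, 3), counts)
            res = weighted_kappa(t)
            estimates.append(res.estimate)
            ses.append(res.se)
        sd = np.std(estimates, ddof=1)
        assert abs(sd - np.mean(ses)) / sd < 0.15


class TestCrossTabulate:

    def test_two_identical_infants(self):
        records = []
        for i in ("a", "b"):
            records.append(ExamRecord(i, Rater.RESIDENT, SubscoreAssessment(0, 0, 0, 0)))
            records.append(ExamRecord(i, Rater.CONSULTANT, SubscoreAssessment(0, 0, 0, 0)))
        t = cross_tabulate(records, "mental_status")
        assert t.categories == (0, 1, 2, 3)  # declared space kept
        assert t.counts[0, 0] == 2 and t.n == 2

    def test_reconstructed_records_reproduce_margins(self, fx):
        t = cross_tabulate(_records_from_table(fx.table2a), "mental_status")
        assert np.array_equal(t.counts, fx.table2a.counts)
        assert tuple(t.counts.sum(axis=1)) == (261, 24, 32, 16)
        assert tuple(t.counts.sum(axis=0)) == (261, 24, 37, 11)

    def test_total_field_and_gaze_categories(self):
        recs = [
            ExamRecord("a", Rater.RESIDENT, SubscoreAssessment(3, 3, 3, 3)),
            ExamRecord("a", Rater.CONSULTANT, SubscoreAssessment(3, 3, 3, 0)),
        ]
        t = cross_tabulate(recs, "total")
        assert t.categories == tuple(range(13))
        assert t.counts[12, 9] == 1
        assert cross_tabulate(recs, "gaze").categories == (0, 3)

    def test_empty_input_is_an_error(self):
        with pytest.raises(PairingError):
            cross_tabulate([], "cry")

    def test_unmatched_infant_is_an_error(self):
        recs = [ExamRecord("a", Rater.RESIDENT, SubscoreAssessment(0, 0, 0, 0))]
        with pytest.raises(PairingError, match="missing a consultant"):
            cross_tabulate(recs, "cry")

    def test_duplicate_rater_is_an_error(self):
        a = SubscoreAssessment(0, 0, 0, 0)
        recs = [ExamRecord("a", Rater.RESIDENT, a),
                ExamRecord("a", Rater.RESIDENT, a)]
        with pytest.raises(PairingError, match="more than one"):
            cross_tabulate(recs, "cry")
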