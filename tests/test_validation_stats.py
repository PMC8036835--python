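"""Agreement battery: ICC(2,1), Bland-Altman, regression, Kruskal-Wallis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import radarvitals as rv
from radarvitals.errors import UndefinedStatisticError


def icc21_anova_oracle(x, y):
    """Textbook two-way ANOVA route to ICC(2,1), coded independently.

    Builds the full n x 2 table, computes sums of squares by explicit
    looping over cells, then applies the mean-square formula.
    """
    table = [[float(a), float(b)] for a, b in zip(x, y)]
    n, k = len(table), 2
    grand = sum(v for row in table for v in row) / (n * k)
    ss_rows = sum(k * (sum(row) / k - grand) ** 2 for row in table)
    col_means = [sum(row[j] for row in table) / n for j in range(k)]
    ss_cols = sum(n * (cm - grand) ** 2 for cm in col_means)
    ss_tot = sum((v - grand) ** 2 for row in table for v in row)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def kruskal_h_oracle(g1, g2):
    """Rank-sum route to the two-group Kruskal-Wallis H (no ties assumed)."""
    pooled = sorted((v, i) for i, g in enumerate((g1, g2)) for v in g)
    ranks = {0: 0.0, 1: 0.0}
    for r, (v, i) in enumerate(pooled, start=1):
        ranks[i] += r
    n1, n2 = len(g1), len(g2)
    n = n1 + n2
    return 12.0 / (n * (n + 1)) * (ranks[0] ** 2 / n1 + ranks[1] ** 2 / n2) - 3 * (n + 1)


def pairs_of(x, y):
    return rv.PairedRates(np.asarray(x, float), np.asarray(y, float))


class TestICC:
    def test_identical_series_gives_one(self):
        p = pairs_of([70, 80, 90, 100], [70, 80, 90, 100])
        assert rv.icc(p) == pytest.approx(1.0)

    def test_shift_invariance(self):
        x = np.array([72.0, 81.0, 88.0, 95.0, 103.0])
        y = np.array([70.0, 83.0, 90.0, 94.0, 101.0])
        assert rv.icc(pairs_of(x + 7, y + 7)) == pytest.approx(
            rv.icc(pairs_of(x, y)), abs=1e-12)

    def test_six_pair_table_matches_hand_anova(self):
        x = [70, 80, 90, 100, 110, 120]
        y = [72, 79, 93, 98, 112, 119]
        assert rv.icc(pairs_of(x, y)) == pytest.approx(icc21_anova_oracle(x, y), abs=1e-12)

    def test_matches_anova_oracle_on_random_tables(self):
        """Implementation agrees with the brute-force ANOVA route to 1e-10."""
        rng = np.random.default_rng(1234)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            x = rng.normal(90, 15, n)
            y = x + rng.normal(0, 4, n)
            assert abs(rv.icc(pairs_of(x, y)) - icc21_anova_oracle(x, y)) < 1e-10

    def test_matches_pingouin_icc2(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(7)
        x = rng.normal(90, 12, 25)
        y = x + rng.normal(0, 3, 25)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(25), 2),
            "raters": np.tile(["radar", "ref"], 25),
            "scores": np.column_stack([x, y]).ravel(),
        })
        res = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
        # ICC(A,1): two-way, absolute agreement, single rater
        icc2 = float(res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert rv.icc(pairs_of(x, y)) == pytest.approx(icc2, abs=1e-8)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedStatisticError):
            rv.icc(pairs_of([5, 5, 5], [5, 5, 5]))


class TestBlandAltman:
    def test_identical_series(self):
        assert rv.bland_altman(pairs_of([1, 2, 3], [1, 2, 3])) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        bias, lo, hi = rv.bland_altman(pairs_of([3, 4, 5], [1, 2, 3]))
        assert (bias, lo, hi) == (2.0, 2.0, 2.0)

    def test_diffs_one_two_three(self):
        """diffs {1,2,3}: bias 2, sample SD 1, LoA = 2 -+ 1.96."""
        bias, lo, hi = rv.bland_altman(pairs_of([11, 22, 33], [10, 20, 30]))
        assert bias == pytest.approx(2.0)
        assert lo == pytest.approx(0.04)
        assert hi == pytest.approx(3.96)

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(90, 10, 40), rng.normal(88, 10, 40)
        b1, l1, h1 = rv.bland_altman(pairs_of(x, y))
        b2, l2, h2 = rv.bland_altman(pairs_of(y, x))
        assert b2 == pytest.approx(-b1)
        assert (l2, h2) == (pytest.approx(-h1), pytest.approx(-l1))


class TestRegression:
    def test_identity_fit(self):
        s, i, r = rv.regression_identity(pairs_of([1, 2, 3, 4], [1, 2, 3, 4]))
        assert (s, i, r) == (pytest.approx(1.0), pytest.approx(0.0), pytest.approx(1.0))

    def test_exact_linear_map(self):
        s, i, _ = rv.regression_identity(pairs_of([2, 4, 6], [1, 2, 3]))
        assert s == pytest.approx(2.0)
        assert i == pytest.approx(0.0, abs=1e-12)

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(11)
        ref = rng.uniform(60, 140, 200)
        radar = ref + rng.normal(0, 2, 200)
        s, _, _ = rv.regression_identity(pairs_of(radar, ref))
        assert s == pytest.approx(1.0, abs=0.05)

    def test_constant_reference_raises(self):
        with pytest.raises(UndefinedStatisticError):
            rv.regression_identity(pairs_of([1, 2, 3], [5, 5, 5]))


class TestKruskalWallis:
    def test_identical_groups_give_zero_h(self):
        h, p = rv.kruskal_wallis(pairs_of([1, 2, 3], [1, 2, 3]))
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_match_rank_oracle(self):
        g1, g2 = [1, 2, 3], [10, 11, 12]
        h, _ = rv.kruskal_wallis(pairs_of(g1, g2))
        assert h == pytest.approx(kruskal_h_oracle(g1, g2), abs=1e-10)

    def test_p_value_is_probability(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 20))
            _, p = rv.kruskal_wallis(pairs_of(rng.normal(size=n), rng.normal(size=n)))
            assert 0.0 <= p <= 1.0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_h_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(90, 9, 15), rng.normal(85, 9, 15)
        h1, _ = rv.kruskal_wallis(pairs_of(x, y))
        h2, _ = rv.kruskal_wallis(pairs_of(np.exp(x / 50), np.exp(y / 50)))
        assert h2 == pytest.approx(h1, abs=1e-9)

    def test_all_tied_raises(self):
        with pytest.raises(UndefinedStatisticError):
            rv.kruskal_wallis(pairs_of([3, 3, 3], [3, 3, 3]))


class TestAgreementReport:
    def test_identical_series_composition(self):
        rep = rv.agreement_report(pairs_of([60, 70, 80], [60, 70, 80]))
        assert rep.icc == pytest.approx(1.0)
        assert rep.bias == 0.0
        assert rep.slope == pytest.approx(1.0)
        assert rep.kw_h == pytest.approx(0.0, abs=1e-12)

    def test_loa_ordering_invariant_on_random_inputs(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x, y = rng.normal(90, 10, n), rng.normal(90, 10, n)
            rep = rv.agreement_report(pairs_of(x, y))
            assert rep.loa_low <= rep.bias <= rep.loa_high

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd
        rep = rv.agreement_report(pairs_of([60, 72, 80, 95], [61, 70, 82, 93]))
        path = rep.to_csv(tmp_path / "report.csv")
        row = pd.read_csv(path).iloc[0]
        assert row["icc"] == pytest.approx(rep.icc, abs=1e-6)
        assert row["n"] == 4
        assert "ICC" in rep.summary()


class TestAlignment:
    def test_nearest_second_alignment(self, vital_cfg):
        study = rv.generate_study(1, vital_cfg, 60.0, seed=3,
                                  noise_std=0.0, movement_rate_per_min=0.0)
        pid = study.participant_ids[0]
        est = rv.extract_vitals(study.load_cube(pid))
        pairs = rv.align_rates(est, study.load_reference(pid), "hr")
        assert pairs.n == est.valid.sum()
        assert np.all(pairs.reference == study.profiles[pid].heart_rate)
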