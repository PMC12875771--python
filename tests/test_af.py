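import numpy as np
import pandas as pd
import pytest

from sdohmpi.af import (
    AFConfig,
    AFResult,
    af_measures,
    build_weight_scheme,
    burden,
    calibrate_cutoff,
    contributions,
    deprivation_scores,
    group_difference_test,
    identify_poor,
    m0_curve,
    relative_gap,
    subgroup_decompose,
)
from sdohmpi.indicators import DeprivationMatrix
from sdohmpi.registry import Factor, IndicatorRegistry, IndicatorRule


def _eiw(matrix):
    return pd.Series(1.0, index=matrix.indicator_names)


def _scheme(matrix, weights=None, convention="count"):
    from sdohmpi.af import WeightScheme

    w = _eiw(matrix) if weights is None else weights
    return WeightScheme("EIW" if convention == "count" else "ENW", w, convention)


def brute_force_af(g: np.ndarray, w: np.ndarray, d_share: float):
    """Direct per-participant, per-indicator loop oracle for H, A, M0, CH_j."""
    n, k = g.shape
    W = w.sum()
    poor, shares = [], []
    for i in range(n):
        c = sum(w[j] * g[i, j] for j in range(k))
        if c / W >= d_share - 1e-12:
            poor.append(i)
            shares.append(c / W)
    H = len(poor) / n
    A = float(np.mean(shares)) if poor else None
    M0 = H * A if poor else 0.0
    ch = np.zeros(k)
    for j in range(k):
        ch[j] = sum(1 for i in poor if g[i, j] == 1) / n
    contrib = w * ch / (W * M0) if M0 > 0 else None
    return H, A, M0, ch, contrib


class TestWeightSchemes:
    def test_eiw_all_ones(self, registry):
        w = build_weight_scheme(registry, "EIW")
        assert (w.weights == 1.0).all()
        assert w.total_weight == 37
        assert w.cutoff_convention == "count"

    def test_enw_nested_weights(self, registry):
        w = build_weight_scheme(registry, "ENW")
        assert w.weights["religiosity_organizational"] == pytest.approx(1 / 3)
        assert w.weights["john_henryism"] == pytest.approx(1.0)  # coping: 1 indicator
        assert w.total_weight == pytest.approx(10.0)  # one unit per factor

    def test_unknown_scheme(self, registry):
        with pytest.raises(ValueError):
            build_weight_scheme(registry, "XXX")


class TestScoresAndIdentification:
    def test_extreme_rows(self, toy_matrix):
        c = deprivation_scores(toy_matrix, _scheme(toy_matrix))
        assert c.loc[3] == 0.0  # all-zero row
        assert c.loc[2] == 3.0  # all-one row

    def test_enw_factor_sum(self):
        mat = DeprivationMatrix(
            pd.DataFrame([[1, 1, 1]], columns=["a", "b", "c"])
        )
        w = pd.Series(1 / 3, index=["a", "b", "c"])
        c = deprivation_scores(mat, _scheme(mat, w, "share"))
        assert c.iloc[0] == pytest.approx(1.0)

    def test_poor_cutoff_inclusive(self, toy_matrix):
        scores = pd.Series([11.0, 10.0, 10.999])
        w = pd.Series(1.0, index=[f"i{j}" for j in range(37)])
        cfg = AFConfig(d=11, weight_scheme=_scheme_from(w, "count"))
        assert identify_poor(scores, cfg).tolist() == [1, 0, 0]

    def test_share_cutoff_inclusive(self):
        w = pd.Series(1.0, index=[f"i{j}" for j in range(10)])
        cfg = AFConfig(d=0.30, weight_scheme=_scheme_from(w, "share"))
        assert identify_poor(pd.Series([3.0, 2.9]), cfg).tolist() == [1, 0]


def _scheme_from(weights, convention):
    from sdohmpi.af import WeightScheme

    return WeightScheme("EIW" if convention == "count" else "ENW", weights, convention)


class TestToyWorkedExample:
    """4x3 matrix {110, 100, 111, 000}, EIW, d = 2."""

    @pytest.fixture
    def result(self, toy_matrix):
        cfg = AFConfig(d=2, weight_scheme=_scheme(toy_matrix))
        return toy_matrix, cfg

    def test_h_a_m0(self, result):
        mat, cfg = result
        r = af_measures(mat, cfg)
        assert r.H == pytest.approx(0.5)
        assert r.A == pytest.approx(5 / 6)
        assert r.M0 == pytest.approx(5 / 12)
        assert r.n_poor == 2

    def test_contributions(self, result):
        mat, cfg = result
        c = contributions(mat, cfg)
        np.testing.assert_allclose(
            c.loc[c.level == "indicator", "contribution"], [0.4, 0.4, 0.2]
        )

    def test_decomposition_identity(self, result):
        mat, cfg = result
        groups = pd.Series(["a", "a", "b", "b"], index=mat.participant_ids)
        table = subgroup_decompose(mat, cfg, groups)
        recomposed = (table.population_share * table.M0).sum()
        assert recomposed == pytest.approx(5 / 12)


class TestBounds:
    def test_everyone_fully_deprived(self):
        mat = DeprivationMatrix(pd.DataFrame(np.ones((5, 4), dtype=int),
                                             columns=list("abcd")))
        r = af_measures(mat, AFConfig(d=2, weight_scheme=_scheme(mat)))
        assert (r.H, r.A, r.M0) == (1.0, 1.0, 1.0)

    def test_nobody_poor(self, toy_matrix):
        # drop the all-ones row: max weighted score is then 2 < d = 3
        mat = DeprivationMatrix(toy_matrix.values.drop(index=2))
        r = af_measures(mat, AFConfig(d=3, weight_scheme=_scheme(mat)))
        assert r.H == 0.0 and r.M0 == 0.0 and r.A is None

    def test_contributions_undefined_when_no_poor(self, toy_matrix):
        mat = DeprivationMatrix(toy_matrix.values.drop(index=2))
        with pytest.raises(ValueError, match="M0 = 0"):
            contributions(mat, AFConfig(d=3, weight_scheme=_scheme(mat)))

    def test_censoring_zeroes_nonpoor_indicator(self):
        # indicator c deprived only for a non-poor participant
        mat = DeprivationMatrix(
            pd.DataFrame([[1, 1, 0], [0, 0, 1]], columns=list("abc"))
        )
        c = contributions(mat, AFConfig(d=2, weight_scheme=_scheme(mat)))
        ind = c[c.level == "indicator"].set_index("name")
        assert ind.loc["c", "contribution"] == 0.0


class TestCurvesAndCalibration:
    def test_curve_monotone_nonincreasing(self, small_cohort, registry):
        from sdohmpi.indicators import build_deprivation_matrix

        mat = build_deprivation_matrix(small_cohort.table, registry)
        scheme = build_weight_scheme(registry, "EIW")
        curve = m0_curve(mat, scheme, list(range(1, 20)))
        assert len(curve) == 19
        assert (np.diff(curve.H) <= 1e-12).all()
        assert (np.diff(curve.M0) <= 1e-12).all()

    def test_curve_trivial_ends(self, toy_matrix):
        curve = m0_curve(toy_matrix, _scheme(toy_matrix), [1, 2, 3])
        assert curve.H.iloc[0] == pytest.approx(0.75)  # all but 000 deprived >= 1
        assert curve.H.iloc[2] == pytest.approx(0.25)

    def test_curve_hand_enumeration(self, toy_matrix):
        curve = m0_curve(toy_matrix, _scheme(toy_matrix), [1, 2, 3])
        # d=1: poor rows have c={2,1,3}; M0 = (2+1+3)/(4*3) = 0.5
        assert curve.M0.iloc[0] == pytest.approx(0.5)
        assert curve.M0.iloc[1] == pytest.approx(5 / 12)
        assert curve.M0.iloc[2] == pytest.approx(3 / 12)

    def test_beyond_max_score(self, toy_matrix):
        r = af_measures(toy_matrix, AFConfig(d=3.0, weight_scheme=_scheme(toy_matrix)))
        assert r.H == 0.25  # only the 111 row
        r = m0_curve(toy_matrix, _scheme(toy_matrix), [3])  # noqa: F841

    def test_calibrate_nearest_prevalence(self, toy_matrix):
        # H(1)=0.75, H(2)=0.5, H(3)=0.25
        assert calibrate_cutoff(toy_matrix, _scheme(toy_matrix), 0.55) == 2
        assert calibrate_cutoff(toy_matrix, _scheme(toy_matrix), 0.30) == 3

    def test_calibrate_tie_breaks_small_d(self):
        mat = DeprivationMatrix(
            pd.DataFrame([[1, 1], [1, 0], [0, 0], [0, 0]], columns=list("ab"))
        )
        # H(1)=0.5, H(2)=0.25; target equidistant at 0.375 -> smaller d
        assert calibrate_cutoff(mat, _scheme(mat), 0.375) == 1


class TestGapsAndTests:
    def test_relative_gap_arithmetic(self):
        a = AFResult(H=0.5, A=0.5, M0=0.25, n=10, n_poor=5)
        b = AFResult(H=0.5, A=0.4, M0=0.20, n=10, n_poor=5)
        assert relative_gap(a, b) == pytest.approx(25.0)
        assert relative_gap(b, b) == 0.0
        c = AFResult(H=0.5, A=0.2, M0=0.10, n=10, n_poor=5)
        assert relative_gap(c, b) == pytest.approx(-50.0)

    def test_relative_gap_zero_reference(self):
        z = AFResult(H=0.0, A=None, M0=0.0, n=10, n_poor=0)
        a = AFResult(H=0.5, A=0.5, M0=0.25, n=10, n_poor=5)
        with pytest.raises(ValueError):
            relative_gap(a, z)

    def test_identical_groups_null(self, toy_matrix):
        doubled = DeprivationMatrix(
            pd.DataFrame(
                np.vstack([toy_matrix.values, toy_matrix.values]),
                columns=toy_matrix.indicator_names,
            )
        )
        labels = pd.Series(["x"] * 4 + ["y"] * 4, index=doubled.participant_ids)
        res = group_difference_test(
            doubled, AFConfig(d=2, weight_scheme=_scheme(doubled)), labels,
            n_boot=400, seed=5,
        )
        assert res["difference"] == 0.0
        assert res["gap_percent"] == 0.0
        assert res["p_value"] > 0.5

    def test_null_calibration_type_i_error(self, rng):
        """Permuted labels under the null reject at roughly the nominal rate."""
        n, k = 120, 8
        rejections = 0
        reps = 120
        for rep in range(reps):
            g = (np.random.default_rng(rep).random((n, k)) < 0.3).astype(int)
            mat = DeprivationMatrix(pd.DataFrame(g, columns=[f"i{j}" for j in range(k)]))
            labels = pd.Series(
                np.random.default_rng(1000 + rep).permutation([0] * 60 + [1] * 60),
                index=mat.participant_ids,
            )
            res = group_difference_test(
                mat, AFConfig(d=3, weight_scheme=_scheme(mat)), labels,
                n_boot=200, seed=rep,
            )
            rejections += res["p_value"] < 0.05
        rate = rejections / reps
        assert 0.0 <= rate <= 0.12  # ~0.05 within Monte-Carlo error


class TestBurden:
    def test_extremes(self, toy_matrix):
        cfg = AFConfig(d=2, weight_scheme=_scheme(toy_matrix))
        b = burden(toy_matrix, cfg)
        assert b.loc[3] == 0.0
        assert b.loc[2] == pytest.approx(1.0)
        assert b.loc[1] == pytest.approx(1 / 3)

    def test_censored_mode(self, toy_matrix):
        cfg = AFConfig(d=2, weight_scheme=_scheme(toy_matrix))
        b = burden(toy_matrix, cfg, censored=True)
        assert b.loc[1] == 0.0  # c=1 < d=2: censored to zero
        assert b.loc[0] == pytest.approx(2 / 3)


class TestOracleEquivalence:
    def test_200_random_matrices(self):
        """Production path matches a brute-force loop on random inputs."""
        for rep in range(200):
            rng = np.random.default_rng(rep)
            n = rng.integers(2, 31)
            k = rng.integers(2, 13)
            g = (rng.random((n, k)) < rng.uniform(0.1, 0.6)).astype(int)
            w = rng.uniform(0.2, 2.0, size=k)
            W = w.sum()
            d_share = rng.uniform(0.05, 0.8)
            mat = DeprivationMatrix(
                pd.DataFrame(g, columns=[f"i{j}" for j in range(k)])
            )
            scheme = _scheme_from(
                pd.Series(w, index=mat.indicator_names), "share"
            )
            cfg = AFConfig(d=d_share, weight_scheme=scheme)
            r = af_measures(mat, cfg)
            H, A, M0, ch, contrib = brute_force_af(g, w, d_share)
            assert r.H == pytest.approx(H, abs=1e-12)
            assert r.M0 == pytest.approx(M0, abs=1e-12)
            if A is None:
                assert r.A is None
            else:
                assert r.A == pytest.approx(A, abs=1e-12)
                assert r.M0 == pytest.approx(r.H * r.A, abs=1e-15)
                table = contributions(mat, cfg)
                ind = table[table.level == "indicator"]
                np.testing.assert_allclose(ind.censored_headcount, ch, atol=1e-12)
                np.testing.assert_allclose(ind.contribution, contrib, atol=1e-12)
                assert ind.contribution.sum() == pytest.approx(1.0, abs=1e-9)

    def test_dimensional_monotonicity(self):
        """Flipping g_ij 0->1 for a poor participant raises M0 by w_j/(n*W)."""
        rng = np.random.default_rng(99)
        g = (rng.random((20, 6)) < 0.4).astype(int)
        w = rng.uniform(0.5, 1.5, size=6)
        mat = DeprivationMatrix(pd.DataFrame(g, columns=[f"i{j}" for j in range(6)]))
        scheme = _scheme_from(pd.Series(w, index=mat.indicator_names), "share")
        cfg = AFConfig(d=0.4, weight_scheme=scheme)
        c = deprivation_scores(mat, scheme)
        poor = identify_poor(c, cfg)
        i = poor[poor == 1].index[0]
        j = int(np.flatnonzero(g[i] == 0)[0])
        before = af_measures(mat, cfg).M0
        g2 = g.copy()
        g2[i, j] = 1
        mat2 = DeprivationMatrix(pd.DataFrame(g2, columns=mat.indicator_names))
        after = af_measures(mat2, cfg).M0
        assert after - before == pytest.approx(w[j] / (20 * w.sum()), abs=1e-12)

    def test_reordering_invariance(self, small_cohort, registry):
        from sdohmpi.indicators import build_deprivation_matrix

        mat = build_deprivation_matrix(small_cohort.table, registry)
        scheme = build_weight_scheme(registry, "ENW")
        cfg = AFConfig(d=0.3, weight_scheme=scheme)
        base = af_measures(mat, cfg).M0
        rng = np.random.default_rng(0)
        rows = rng.permutation(mat.values.index)
        cols = rng.permutation(mat.indicator_names)
        shuffled = DeprivationMatrix(mat.values.loc[rows, cols])
        assert af_measures(shuffled, cfg).M0 == pytest.approx(base, abs=1e-12)

    def test_eiw_enw_agree_with_one_indicator_per_factor(self):
        reg = IndicatorRegistry(
            factors=(
                Factor("f1", "environmental"),
                Factor("f2", "sociocultural"),
                Factor("f3", "behavioral"),
            ),
            indicators=(
                IndicatorRule("a", "direct_binary", "f1", ("a",)),
                IndicatorRule("b", "direct_binary", "f2", ("b",)),
                IndicatorRule("c", "direct_binary", "f3", ("c",)),
            ),
        )
        g = (np.random.default_rng(3).random((40, 3)) < 0.4).astype(int)
        mat = DeprivationMatrix(pd.DataFrame(g, columns=list("abc")))
        eiw = build_weight_scheme(reg, "EIW")
        enw = build_weight_scheme(reg, "ENW")
        for count in (1, 2, 3):
            poor_eiw = identify_poor(
                deprivation_scores(mat, eiw), AFConfig(d=count, weight_scheme=eiw)
            )
            poor_enw = identify_poor(
                deprivation_scores(mat, enw),
                AFConfig(d=count / 3, weight_scheme=enw),
            )
            pd.testing.assert_series_equal(poor_eiw, poor_enw)
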