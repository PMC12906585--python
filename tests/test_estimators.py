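"""Unit and property tests for the pairwise recombination estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from corrlink import estimators as est
from corrlink.estimators import (
    EMOptions,
    EstimationError,
    JointCountTable,
    PhenotypeCounts,
    build_joint_table,
    collapse_to_phenotypes,
    estimate_bc_direct,
    estimate_em_codominant,
    estimate_em_dominant,
    estimate_pcorr,
    loglik_codominant,
    loglik_dominant,
    pooled_correlation,
    segregation_chisq,
)
from conftest import random_f2_table


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def numeric_mle_codominant(table: JointCountTable) -> float:
    """Grid + refine maximizer of the observed-data codominant likelihood."""
    grid = np.linspace(1e-6, 0.5 - 1e-6, 2001)
    values = [loglik_codominant(t, table) for t in grid]
    centre = grid[int(np.argmax(values))]
    lo, hi = max(centre - 5e-4, 1e-9), min(centre + 5e-4, 0.5 - 1e-9)
    res = minimize_scalar(
        lambda t: -loglik_codominant(t, table), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def numeric_mle_dominant(counts: PhenotypeCounts) -> float:
    """Grid + refine maximizer of the dominant four-class likelihood in pi."""
    grid = np.linspace(1e-6, 1 - 1e-6, 2001)
    values = [loglik_dominant(p, counts) for p in grid]
    centre = grid[int(np.argmax(values))]
    lo, hi = max(centre - 1e-3, 1e-9), min(centre + 1e-3, 1 - 1e-9)
    res = minimize_scalar(
        lambda p: -loglik_dominant(p, counts), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-13},
    )
    return float(res.x)


def hessian_se(f, x: float, h: float = 1e-5) -> float:
    """SE from a central-difference second derivative of a log-likelihood."""
    d2 = (f(x + h) - 2.0 * f(x) + f(x - h)) / h**2
    return 1.0 / np.sqrt(-d2)


# ---------------------------------------------------------------------------
# joint tables and phenotype collapse
# ---------------------------------------------------------------------------

class TestBuildJointTable:
    def test_tallies_match_brute_force(self, rng):
        g_a = rng.integers(-1, 3, size=50)
        g_b = rng.integers(-1, 3, size=50)
        table = build_joint_table(g_a, g_b)
        # independent 9-cell tally
        expected = np.zeros((3, 3), dtype=int)
        for a, b in zip(g_a, g_b):
            if a >= 0 and b >= 0:
                expected[a, b] += 1
        assert (table.m == expected).all()
        assert table.n == expected.sum()

    def test_chr1_fixture_counts(self, chr1_table):
        g_a = np.repeat(np.repeat(np.arange(3), 3), chr1_table.m.ravel())
        g_b = np.repeat(np.tile(np.arange(3), 3), chr1_table.m.ravel())
        rebuilt = build_joint_table(g_a, g_b)
        assert rebuilt.m[1, 1] == 100
        assert rebuilt.n == 191

    def test_all_missing_raises(self):
        with pytest.raises(EstimationError, match="complete"):
            build_joint_table([-1, -1], [-1, -1])

    def test_invalid_code_raises(self):
        with pytest.raises(EstimationError, match="codes"):
            build_joint_table([0, 3], [1, 1])


class TestCollapse:
    @pytest.mark.parametrize(
        "fixture, expected",
        [("chr1_table", (146, 0, 4, 41)), ("chr4_table", (168, 5, 0, 18))],
    )
    def test_rice_pairs(self, fixture, expected, request):
        table = request.getfixturevalue(fixture)
        c = collapse_to_phenotypes(table)
        assert (c.n_AB, c.n_Ab, c.n_aB, c.n_ab) == expected
        assert c.total == table.n

    def test_zero_table(self):
        c = collapse_to_phenotypes(JointCountTable(np.zeros((3, 3), dtype=int)))
        assert (c.n_AB, c.n_Ab, c.n_aB, c.n_ab) == (0, 0, 0, 0)


# ---------------------------------------------------------------------------
# correlation-converted estimator
# ---------------------------------------------------------------------------

class TestPcorr:
    def test_perfect_correlation(self):
        table = JointCountTable(np.diag([50, 50, 50]))
        r = estimate_pcorr(table)
        assert r.r == pytest.approx(1.0)
        assert r.theta == 0.0
        assert not r.clamped

    def test_antidiagonal_clamps(self):
        table = JointCountTable(np.fliplr(np.diag([50, 50, 50])))
        r = estimate_pcorr(table)
        assert r.clamped
        assert r.theta == 0.5
        assert r.se == pytest.approx(1.0 / (2 * np.sqrt(150 - 3)))

    def test_theta_is_half_one_minus_r(self, chr1_table):
        r = estimate_pcorr(chr1_table)
        assert r.theta == (1.0 - r.r) / 2.0

    def test_transpose_symmetry(self, chr4_table):
        a = estimate_pcorr(chr4_table)
        b = estimate_pcorr(chr4_table.transpose())
        assert a.theta == pytest.approx(b.theta, abs=1e-15)
        assert a.se == pytest.approx(b.se, abs=1e-15)

    def test_flip_both_invariant_flip_one_clamps(self, chr1_table):
        both = estimate_pcorr(chr1_table.flip_both())
        assert both.theta == pytest.approx(estimate_pcorr(chr1_table).theta, abs=1e-15)
        one = estimate_pcorr(chr1_table.flip_a())
        assert one.clamped and one.theta == 0.5

    def test_small_n_rejected(self):
        with pytest.raises(EstimationError):
            estimate_pcorr(JointCountTable(np.diag([1, 1, 1])))

    def test_degenerate_margin_rejected(self):
        m = np.zeros((3, 3), dtype=int)
        m[1, :] = [10, 20, 10]  # locus A all heterozygous
        with pytest.raises(EstimationError, match="degenerate"):
            estimate_pcorr(JointCountTable(m))


# ---------------------------------------------------------------------------
# EM estimators against the numeric-MLE and numeric-information oracles
# ---------------------------------------------------------------------------

class TestCodominantEM:
    def test_matches_numeric_mle_and_hessian(self, rng):
        for _ in range(20):
            table = random_f2_table(rng)
            fit = estimate_em_codominant(table)
            assert fit.converged
            oracle = numeric_mle_codominant(table)
            assert fit.theta == pytest.approx(oracle, abs=1e-6)
            if fit.se is not None and 0.02 < fit.theta < 0.48:
                se_num = hessian_se(lambda t: loglik_codominant(t, table), fit.theta)
                assert fit.se == pytest.approx(se_num, rel=1e-3)

    def test_zero_recombinants_boundary(self):
        table = JointCountTable(np.diag([50, 0, 50]))
        fit = estimate_em_codominant(table)
        assert fit.theta == 0.0
        assert fit.iterations <= 2  # hits zero on the first update
        assert fit.se is None

    def test_nonconvergence_flagged(self, chr1_table):
        fit = estimate_em_codominant(chr1_table, EMOptions(tol=1e-16, max_iter=3))
        assert not fit.converged
        assert fit.iterations == 3

    def test_loglik_at_estimate_not_below_neighbours(self, chr4_table):
        fit = estimate_em_codominant(chr4_table)
        for d in (-1e-4, 1e-4):
            assert fit.loglik >= loglik_codominant(fit.theta + d, chr4_table)


class TestDominantEM:
    def test_matches_numeric_mle(self, rng):
        for _ in range(20):
            counts = collapse_to_phenotypes(random_f2_table(rng))
            fit = estimate_em_dominant(counts)
            pi_oracle = numeric_mle_dominant(counts)
            assert fit.pi == pytest.approx(pi_oracle, abs=1e-6)
            assert fit.theta == pytest.approx(
                min(max(1 - np.sqrt(pi_oracle), 0.0), 0.5), abs=1e-6
            )

    def test_louis_se_matches_hessian(self, chr1_table, chr4_table):
        for table in (chr1_table, chr4_table):
            counts = collapse_to_phenotypes(table)
            fit = estimate_em_dominant(counts)
            se_pi = hessian_se(lambda p: loglik_dominant(p, counts), fit.pi, h=1e-6)
            se_theta = se_pi / (2.0 * np.sqrt(fit.pi))
            assert fit.se == pytest.approx(se_theta, rel=1e-3)

    def test_no_repulsion_classes_gives_zero_theta(self):
        fit = estimate_em_dominant(PhenotypeCounts(150, 0, 0, 50))
        assert fit.pi == pytest.approx(1.0)
        assert fit.theta == 0.0
        assert fit.se is None


class TestBackcross:
    def test_direct_counting(self):
        assert estimate_bc_direct(90, 5, 5, 100).theta == pytest.approx(0.05)
        assert estimate_bc_direct(100, 0, 0, 100).theta == 0.0

    def test_simulation_consistency(self, rng):
        theta, n = 0.2, 10_000
        p = np.array([(1 - theta) / 2, theta / 2, theta / 2, (1 - theta) / 2])
        counts = rng.multinomial(n, p)
        fit = estimate_bc_direct(*counts)
        assert abs(fit.theta - theta) < 3 * fit.se

    def test_empty_raises(self):
        with pytest.raises(EstimationError):
            estimate_bc_direct(0, 0, 0, 0)


# ---------------------------------------------------------------------------
# segregation diagnostics and pooled correlation
# ---------------------------------------------------------------------------

class TestSegregationChisq:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((63, 110, 18), 25.607),
            ((43, 103, 45), 1.2199),
            ((50, 100, 50), 0.0),
        ],
    )
    def test_f2_statistics(self, counts, expected):
        res = segregation_chisq(counts, generation=2)
        assert res.statistic == pytest.approx(expected, abs=5e-4)
        assert res.df == 2

    def test_generation_changes_expected_ratios(self):
        res = segregation_chisq((70, 20, 70), generation=4)
        # H_4 = 1/8: expected (70, 20, 70) exactly for total 160
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(EstimationError):
            segregation_chisq((0, 0, 0))
        with pytest.raises(ValueError):
            segregation_chisq((1, 2, 1), generation=1)


class TestPooledCorrelation:
    def test_single_group_is_pearson(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        assert pooled_correlation([(x, y)]) == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=1e-12
        )

    def test_duplicated_group_invariance(self, rng):
        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(size=25)
        one = pooled_correlation([(x, y)])
        two = pooled_correlation([(x, y), (x, y)])
        assert one == pytest.approx(two, abs=1e-12)

    def test_shifted_groups_match_explicit_summation(self, rng):
        # two families with opposite linkage phase and different means
        groups = []
        for sign, shift in ((1.0, 0.0), (-1.0, 5.0)):
            x = rng.normal(size=40) + shift
            y = sign * x + rng.normal(size=40, scale=0.5)
            groups.append((x, y))
        # explicit evaluation of the pooled-correlation formula
        num = den_x = den_y = 0.0
        for x, y in groups:
            num += np.sum((x - x.mean()) * (y - y.mean()))
            den_x += np.sum((x - x.mean()) ** 2)
            den_y += np.sum((y - y.mean()) ** 2)
        assert pooled_correlation(groups) == pytest.approx(
            num / np.sqrt(den_x * den_y), abs=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(EstimationError):
            pooled_correlation([(np.ones(5), np.arange(5.0))])


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

@st.composite
def count_tables(draw):
    cells = draw(
        st.lists(st.integers(min_value=0, max_value=60), min_size=9, max_size=9)
    )
    return JointCountTable(np.array(cells).reshape(3, 3))


@settings(max_examples=60, derandomize=True, deadline=None)
@given(table=count_tables())
def test_estimates_stay_in_domain_and_transpose_symmetric(table):
    for estimator in (estimate_pcorr, estimate_em_codominant):
        try:
            a = estimator(table)
            b = estimator(table.transpose())
        except EstimationError:
            continue
        assert 0.0 <= a.theta <= 0.5
        assert a.theta == pytest.approx(b.theta, abs=1e-9)
        if a.se is not None and b.se is not None:
            assert a.se == pytest.approx(b.se, rel=1e-9)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(table=count_tables())
def test_dominant_em_pi_in_unit_interval(table):
    counts = collapse_to_phenotypes(table)
    if counts.total == 0:
        return
    fit = estimate_em_dominant(counts)
    assert 0.0 <= fit.pi <= 1.0
    assert 0.0 <= fit.theta <= 0.5
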