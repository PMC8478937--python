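"""Contingency tests, Bonferroni, Kruskal-Wallis and length regressions."""

import math
from math import comb

import numpy as np
import pytest

from pgx_landscape.model import PopulationVAF
from pgx_landscape.popstats import (
    bonferroni_alpha,
    compare_populations,
    kruskal_wallis_by_family,
    regress_counts_on_length,
    vaf_to_counts,
)

KEY = ("1", 100, "G", "A")


def pop(vaf, n, name="A"):
    return PopulationVAF(variant_key=KEY, population=name, vaf=vaf, n_alleles=n)


def pop_from_counts(alt, n, name="A"):
    """A population row whose reconstructed alt count is exactly `alt`."""
    return pop(alt / n, n, name)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    point probability does not exceed the observed one (with a relative
    tolerance for ties, as conventional).
    """
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = comb(n, col1)

    def prob(x):
        return comb(row1, x) * comb(row2, col1 - x) / denom

    p_obs = prob(a)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


class TestVafToCounts:
    @pytest.mark.parametrize(
        "vaf, n, expected",
        [
            (0.5, 100, (50, 50)),
            (0.0, 282_862, (0, 282_862)),
            (0.2021, 282_862, (57_166, 225_696)),  # 0.2021 x 282,862 = 57,166.4
        ],
    )
    def test_reconstruction(self, vaf, n, expected):
        assert vaf_to_counts(vaf, n) == expected

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 10_000))
            alt, ref = vaf_to_counts(float(rng.random()), n)
            assert alt + ref == n and alt >= 0 and ref >= 0

    @pytest.mark.parametrize("vaf, n", [(1.5, 10), (-0.1, 10), (0.5, 0)])
    def test_invalid_inputs(self, vaf, n):
        with pytest.raises(ValueError):
            vaf_to_counts(vaf, n)


class TestBonferroni:
    def test_published_divisors(self):
        assert bonferroni_alpha(0.05, 18) == pytest.approx(0.05 / 18)
        assert bonferroni_alpha(0.05, 72) == pytest.approx(0.05 / 72)
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_alpha(1.5, 10)

    def test_significant_set_shrinks_with_m(self):
        p_values = np.linspace(0.0005, 0.04, 30)
        sizes = [
            sum(p < bonferroni_alpha(0.05, m) for p in p_values) for m in range(1, 100)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestComparePopulations:
    def test_identical_populations_not_significant(self):
        r = compare_populations(pop(0.1, 1000, "A"), pop(0.1, 1000, "B"), 0.05)
        assert r.p_value == pytest.approx(1.0)
        assert r.statistic == pytest.approx(0.0)
        assert not r.significant

    def test_fisher_chosen_for_small_expected_cells(self):
        # table [[1,9],[2,12]]: smallest expected cell is 3*10/24 = 1.25
        r = compare_populations(pop_from_counts(1, 10, "A"), pop_from_counts(2, 14, "B"), 0.05)
        assert r.test_used == "fisher_exact"
        assert r.p_value == pytest.approx(fisher_oracle(1, 9, 2, 12), rel=1e-8)

    def test_boundary_expected_cell_of_exactly_five_uses_chi_square(self):
        # table [[1,9],[11,3]]: expected cells are {5, 5, 7, 7}; the Fisher
        # trigger is strictly "expected < 5", so chi-square applies here
        r = compare_populations(pop_from_counts(1, 10, "A"), pop_from_counts(11, 14, "B"), 0.05)
        assert r.test_used == "chi_square"

    def test_zero_zero_table_degenerate(self):
        r = compare_populations(pop(0.0, 100, "A"), pop(0.0, 200, "B"), 0.05)
        assert r.degenerate and r.p_value == 1.0 and r.test_used == "degenerate"

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            na, nb = int(rng.integers(2, 500)), int(rng.integers(2, 500))
            a = pop(float(rng.random()), na, "A")
            b = pop(float(rng.random()), nb, "B")
            assert compare_populations(a, b, 0.05).p_value == pytest.approx(
                compare_populations(b, a, 0.05).p_value, rel=1e-9
            )

    def test_mismatched_variant_keys_rejected(self):
        other = PopulationVAF(variant_key=("2", 5, "C", "T"), population="B",
                              vaf=0.1, n_alleles=100)
        with pytest.raises(ValueError, match="different variants"):
            compare_populations(pop(0.1, 100), other, 0.05)

    def test_chi_square_p_converges_under_row_scaling(self):
        """Scaling both rows by a common factor makes chi-square p decrease
        monotonically toward its large-count limit for a fixed frequency gap."""
        ps = []
        for scale in (1, 2, 4, 8, 16):
            a = pop_from_counts(30 * scale, 100 * scale, "A")
            b = pop_from_counts(40 * scale, 100 * scale, "B")
            r = compare_populations(a, b, 0.05)
            assert r.test_used == "chi_square"
            ps.append(r.p_value)
        assert all(x > y for x, y in zip(ps, ps[1:]))


class TestKruskalWallis:
    def test_identical_constant_groups(self):
        h, p = kruskal_wallis_by_family({"A": [5, 5, 5], "B": [5, 5], "C": [5]})
        assert h == 0.0 and p == 1.0

    def test_matches_direct_rank_sum_arithmetic(self):
        """H from first principles on {1,2,3}, {4,5,6}, {7,8,9}: no ties, so
        H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2."""
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        n = 9
        rank_means = {"a": 2.0, "b": 5.0, "c": 8.0}  # ranks are the values here
        grand = (n + 1) / 2
        h_expected = 12 / (n * (n + 1)) * sum(
            3 * (rank_means[k] - grand) ** 2 for k in groups
        )
        h, p = kruskal_wallis_by_family(groups)
        assert h == pytest.approx(h_expected)
        from scipy import stats

        assert p == pytest.approx(stats.chi2.sf(h_expected, df=2))

    def test_tie_correction_increases_h(self):
        """The tie correction divides by a factor <= 1, so corrected H >=
        the uncorrected statistic computed from mid-ranks."""
        groups = {"a": [1.0, 2.0, 2.0], "b": [3.0, 4.0, 5.0]}
        ranks = {"a": [1.0, 2.5, 2.5], "b": [4.0, 5.0, 6.0]}
        n = 6
        grand = (n + 1) / 2
        h_uncorrected = 12 / (n * (n + 1)) * sum(
            len(r) * (np.mean(r) - grand) ** 2 for r in ranks.values()
        )
        h, _ = kruskal_wallis_by_family(groups)
        assert h >= h_uncorrected

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_by_family({"a": [1, 2, 3], "b": []})


class TestRegression:
    def test_exact_line(self):
        points = [(x, 2 * x + 1) for x in (1.0, 2.0, 3.0, 4.0)]
        r = regress_counts_on_length(points, "total")
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        r = regress_counts_on_length([(1.0, 7.0), (2.0, 7.0), (3.0, 7.0)], "total")
        assert r.slope == 0.0 and r.r_squared == 0.0 and r.p_value == 1.0

    def test_slope_recovery_on_simulated_family(self):
        """n = 50 genes at a density of 5 variants/kb: the generating slope
        lies inside the fit's 95% confidence interval."""
        rng = np.random.default_rng(42)
        lengths = rng.uniform(5, 200, size=50)
        counts = rng.poisson(5.0 * lengths)
        r = regress_counts_on_length(list(zip(lengths, counts)), "total")
        from scipy import stats

        fit = stats.linregress(lengths, counts)
        half_width = stats.t.ppf(0.975, df=48) * fit.stderr
        assert abs(r.slope - 5.0) < half_width + 1e-12
        assert r.slope == pytest.approx(5.0, rel=0.1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            regress_counts_on_length([(1.0, 1.0), (2.0, 2.0)], "total")

    def test_zero_length_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            regress_counts_on_length([(2.0, 1.0), (2.0, 2.0), (2.0, 3.0)], "total")
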