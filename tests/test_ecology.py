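import itertools

import numpy as np
import pandas as pd
import pytest

from cytospat.ecology import (
    SoilSample,
    bonferroni_adjust,
    bray_curtis_matrix,
    compare_presence_absence,
    occurrence_chi2,
    ranksum_test,
    redness_index,
)
from cytospat.errors import InsufficientDataError, InvalidParameterError
from cytospat.reference import N_ABSENT_2X, N_PRESENT_2X, TABLE_OCCURRENCE_2X


def exact_ranksum_oracle(x, y):
    """Two-sided rank-sum p by full enumeration of group labellings."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(x)
    obs = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2.0
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        s = ranks[list(comb)].sum()
        total += 1
        count += abs(s - mean) >= abs(obs - mean) - 1e-9
    return count / total


class TestRanksum:
    def test_small_exact_example(self):
        # {1,2} vs {3,4}: only the observed extreme labellings out of 6
        _, p = ranksum_test([1, 2, 3, 4], [True, True, False, False])
        assert p == pytest.approx(2.0 / 6.0)

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (5, 7), (7, 6)])
    def test_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(5):
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 1, n2)
            flags = np.r_[np.ones(n1, bool), np.zeros(n2, bool)]
            _, p = ranksum_test(np.r_[x, y], flags)
            assert p == pytest.approx(exact_ranksum_oracle(x, y), abs=1e-12)

    def test_identical_values_p_one(self):
        with pytest.warns(UserWarning, match="identical"):
            _, p = ranksum_test([5.0] * 8, [True] * 4 + [False] * 4)
        assert p == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(InsufficientDataError):
            ranksum_test([1.0, 2.0], [True, True])

    def test_ties_use_asymptotic_path(self):
        vals = [1, 1, 2, 2, 3, 3, 4, 4]
        flags = [True, False] * 4
        _, p = ranksum_test(vals, flags)
        assert 0 < p <= 1


class TestBonferroni:
    def test_clamped_and_scaled(self):
        assert bonferroni_adjust(0.5, 3) == 1.0
        assert bonferroni_adjust(0.001, 10) == pytest.approx(0.01)
        np.testing.assert_allclose(
            bonferroni_adjust([0.5, 0.001], 10), [1.0, 0.01]
        )

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            bonferroni_adjust(1.5, 2)
        with pytest.raises(InvalidParameterError):
            bonferroni_adjust(0.5, 0)


class TestOccurrenceChi2:
    @pytest.mark.parametrize(
        "species,expected_adj,half_ulp",
        [
            ("Scabiosa atropurpurea", 2.0e-5, 0.05e-5),
            ("Lagurus ovatus", 0.004, 0.0005),
            ("Erodium laciniatum", 0.006, 0.0005),
            ("Helichrysum stoechas", 0.037, 0.0005),
            ("Cyperus capitatus", 0.223, 0.0005),
        ],
    )
    def test_published_occurrence_tests(self, species, expected_adj, half_ulp):
        """Yates-corrected chi-square on the printed 2x2 occurrence
        counts, Bonferroni m=31, reproduces the published adjusted p to
        the printed precision."""
        c_abs, c_pres = TABLE_OCCURRENCE_2X[species]
        _, p = occurrence_chi2(
            c_pres, N_PRESENT_2X - c_pres, c_abs, N_ABSENT_2X - c_abs
        )
        adj = bonferroni_adjust(p, 31)
        assert abs(adj - expected_adj) <= half_ulp

    def test_balanced_table_clamps_to_zero(self):
        chi2, p = occurrence_chi2(10, 10, 10, 10)
        assert chi2 == 0.0 and p == 1.0

    def test_zero_marginal(self):
        with pytest.warns(UserWarning, match="marginal"):
            chi2, p = occurrence_chi2(0, 0, 5, 5)
        assert (chi2, p) == (0.0, 1.0)
        with pytest.raises(InsufficientDataError):
            occurrence_chi2(0, 0, 5, 5, zero_marginal="raise")

    def test_negative_counts(self):
        with pytest.raises(InvalidParameterError):
            occurrence_chi2(-1, 2, 3, 4)


class TestBrayCurtis:
    def test_hand_computed_values(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [6.0, 2.0], [2.0, 2.0]])
        dm = bray_curtis_matrix(x)
        assert dm[0, 1] == pytest.approx(1.0)   # disjoint supports
        assert dm[0, 2] == pytest.approx(0.0)   # identical rows
        assert dm[3, 4] == pytest.approx(1.0 / 3.0)
        assert np.all(dm >= 0) and np.all(dm <= 1)
        np.testing.assert_allclose(dm, dm.T)
        np.testing.assert_allclose(np.diag(dm), 0)

    def test_double_zero_rows(self):
        with pytest.warns(UserWarning, match="all-zero"):
            dm = bray_curtis_matrix(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]]))
        assert dm[0, 1] == 0.0

    def test_negative_rejected(self):
        with pytest.raises(InvalidParameterError):
            bray_curtis_matrix(np.array([[1.0, -1.0], [0.0, 1.0]]))


class TestSoil:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((1, 1, 1), 1.0), ((2, 1, 1), 4.0), ((128, 64, 64), 128**2 / (64 * 64**3))],
    )
    def test_redness_index(self, rgb, expected):
        assert redness_index(*rgb) == pytest.approx(expected)

    def test_redness_zero_channel(self):
        with pytest.raises(InvalidParameterError):
            redness_index(10, 0, 10)

    def test_soil_sample_validation(self):
        good = SoilSample(
            "S01", (2, 1, 2, 70, 24, 0.6, 0.4), 7.5, 0.1, 1.2,
            "10YR", 5.9, 2.5, (170, 160, 140),
        )
        assert good.redness_index == pytest.approx(170**2 / (140 * 160**3))
        with pytest.raises(InvalidParameterError, match="100"):
            SoilSample("S02", (50, 10, 5, 5, 5, 5, 5), 7.5, 0.1, 1.2,
                       "10YR", 5.9, 2.5, (170, 160, 140))
        with pytest.raises(InvalidParameterError, match="pH"):
            SoilSample("S03", (2, 1, 2, 70, 24, 0.6, 0.4), 15.0, 0.1, 1.2,
                       "10YR", 5.9, 2.5, (170, 160, 140))


def published_occurrence_table() -> pd.DataFrame:
    """Quadrat table whose species/diploid cross-counts equal the
    published ones (48 diploid-present, 60 diploid-absent quadrats)."""
    n = N_PRESENT_2X + N_ABSENT_2X
    table = pd.DataFrame({"quadrat_id": [f"Q{i}" for i in range(n)]})
    table["present_2x"] = np.r_[
        np.ones(N_PRESENT_2X, bool), np.zeros(N_ABSENT_2X, bool)
    ]
    for species, (c_abs, c_pres) in TABLE_OCCURRENCE_2X.items():
        col = np.zeros(n, bool)
        col[:c_pres] = True
        col[N_PRESENT_2X:N_PRESENT_2X + c_abs] = True
        table[f"sp: {species}"] = col
    return table


class TestComparePresenceAbsence:
    def test_reproduces_published_species_column(self):
        """From the printed cross-counts, 4 of 31 species remain
        significant after Bonferroni (m=31); the sedge just misses."""
        table = published_occurrence_table()
        _, occ = compare_presence_absence(table, "2x", variables=[])
        assert len(occ) == 31
        sig = {o.species for o in occ if o.p_adjusted < 0.05}
        assert sig == {
            "Scabiosa atropurpurea", "Lagurus ovatus",
            "Erodium laciniatum", "Helichrysum stoechas",
        }
        cyperus = next(o for o in occ if o.species == "Cyperus capitatus")
        assert cyperus.p_adjusted == pytest.approx(0.223, rel=0.05)

    def test_single_variable_m1_equals_raw_test(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(
            {
                "present_2x": rng.random(40) < 0.5,
                "total_cover": rng.uniform(0, 100, 40),
            }
        )
        comp, _ = compare_presence_absence(
            table, "2x", variables=["total_cover"], species=[], m_variables=1
        )
        _, p_raw = ranksum_test(
            table["total_cover"], table["present_2x"].to_numpy()
        )
        assert comp[0].p_adjusted == pytest.approx(p_raw)
        assert comp[0].n_absent + comp[0].n_present == 40

    def test_null_table_false_positives_vanish_after_adjustment(self):
        rng = np.random.default_rng(10)
        n, n_vars = 108, 10
        raw_hits = adj_hits = 0
        for rep in range(30):
            table = pd.DataFrame({"present_2x": rng.random(n) < 0.45})
            for v in range(n_vars):
                table[f"v{v}"] = rng.normal(0, 1, n)
            comp, _ = compare_presence_absence(
                table, "2x", variables=[f"v{v}" for v in range(n_vars)], species=[]
            )
            raw_hits += sum(c.p_raw < 0.05 for c in comp)
            adj_hits += sum(c.p_adjusted < 0.05 for c in comp)
        # ~alpha * m * reps raw false positives, almost none surviving
        assert 2 <= raw_hits <= 40
        assert adj_hits <= 2

    def test_family_size_cannot_undercount(self):
        table = published_occurrence_table()
        with pytest.raises(InvalidParameterError):
            compare_presence_absence(table, "2x", variables=[], m_species=5)

    def test_missing_taxon_column(self):
        with pytest.raises(InvalidParameterError):
            compare_presence_absence(pd.DataFrame({"a": [1]}), "5x")
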