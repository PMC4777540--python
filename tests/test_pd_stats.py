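import itertools

import numpy as np
import pytest

from mupscent.errors import MupscentError, UnknownIndividualError, ValidationError
from mupscent.pd_stats import (
    compare_pd_sets,
    delta_pd,
    ng_site_counts,
    pd_all_pairs,
    pd_pair,
    regress,
)
from mupscent.profiles import SiteRecord, VariantProfileMatrix

from conftest import random_profile_matrix


def matrix_from_columns(columns: dict, site_class=None):
    ids = list(columns)
    n_sites = len(next(iter(columns.values())))
    sites = [SiteRecord(f"s{i}", site_class) for i in range(n_sites)]
    values = np.array([columns[k] for k in ids], dtype=float).T
    return VariantProfileMatrix(ids, sites, values)


class TestPDPair:
    def test_self_comparison_is_zero(self, nonsyn_table):
        assert pd_pair(nonsyn_table, "TAS285", "TAS285").pd_raw == 0.0

    def test_published_pair_hand_sum(self, nonsyn_table):
        """TAS295 vs TAS296 differ by 0+4+3+1+0 percentage points at the
        five shared non-synonymous variants -> PD' = 0.08."""
        res = pd_pair(nonsyn_table, "TAS295", "TAS296", "nonsynonymous")
        assert res.pd_raw == pytest.approx(0.08, abs=1e-12)

    def test_hand_l1_sum(self):
        m = matrix_from_columns({"A": [28, 5, 0], "B": [1, 12, 19]})
        assert pd_pair(m, "A", "B").pd_raw == pytest.approx(0.53)

    def test_unknown_individual_rejected(self, nonsyn_table):
        with pytest.raises(UnknownIndividualError):
            pd_pair(nonsyn_table, "TAS285", "TASX")

    def test_per_site_scaling(self, nonsyn_table):
        r1 = pd_pair(nonsyn_table, "TAS285", "TAS286", denominator=10)
        r2 = pd_pair(nonsyn_table, "TAS285", "TAS286", denominator=40)
        assert r1.pd_per_site == pytest.approx(4 * r2.pd_per_site)
        assert r1.pd_per_site == pytest.approx(r1.pd_raw / 10)

    def test_pseudometric_properties(self, rng):
        for _ in range(30):
            m = random_profile_matrix(rng, n_individuals=4)
            ids = m.individuals
            d = {
                (a, b): pd_pair(m, a, b).pd_raw
                for a, b in itertools.product(ids, ids)
            }
            for a, b, c in itertools.permutations(ids, 3):
                assert d[a, b] >= 0
                assert d[a, b] == pytest.approx(d[b, a])
                assert d[a, a] == 0.0
                assert d[a, c] <= d[a, b] + d[b, c] + 1e-9


class TestPDAllPairs:
    def test_pair_count_and_order(self, nonsyn_table):
        res = pd_all_pairs(nonsyn_table)
        assert len(res) == 153
        assert [r.pair for r in res] == sorted(r.pair for r in res)

    def test_two_individuals(self):
        m = matrix_from_columns({"A": [1, 2], "B": [3, 4]})
        assert len(pd_all_pairs(m)) == 1

    def test_all_zero_matrix(self):
        m = matrix_from_columns({"A": [0, 0], "B": [0, 0], "C": [0, 0]})
        assert all(r.pd_raw == 0.0 for r in pd_all_pairs(m))

    def test_single_individual_rejected(self):
        m = matrix_from_columns({"A": [1]})
        with pytest.raises(ValidationError):
            pd_all_pairs(m)


def brute_force_u(a, b):
    """U of the first sample by direct pair counting with half-ties."""
    return sum(
        1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
    )


class TestComparePDSets:
    def test_complete_separation(self):
        rep = compare_pd_sets([1, 2, 3], [4, 5, 6], "mann_whitney")
        assert rep.statistic == 0.0

    def test_u_matches_brute_force_with_ties(self, rng):
        cases = [([1, 1, 2], [1, 2, 2])] + [
            (rng.integers(0, 5, size=6).tolist(), rng.integers(0, 5, size=7).tolist())
            for _ in range(20)
        ]
        for a, b in cases:
            rep = compare_pd_sets(a, b, "mann_whitney")
            assert rep.statistic == pytest.approx(brute_force_u(a, b))

    def test_u_complement_identity_tie_free(self, rng):
        a = rng.permutation(40)[:15].tolist()
        b = [x + 0.5 for x in rng.permutation(40)[:12]]
        u_ab = compare_pd_sets(a, b, "mann_whitney").statistic
        u_ba = compare_pd_sets(b, a, "mann_whitney").statistic
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    def test_ks_identical_sets(self):
        rep = compare_pd_sets([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "ks")
        assert rep.statistic == 0.0

    def test_unknown_test_rejected(self):
        with pytest.raises(MupscentError):
            compare_pd_sets([1], [2], "anova")

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            compare_pd_sets([], [1.0], "ks")


class TestDeltaPD:
    def test_identical_matrices_degenerate(self, nonsyn_table):
        res = delta_pd(nonsyn_table, nonsyn_table)
        assert np.all(res.pair_deltas == 0)
        assert res.t_pairs.extra.get("degenerate") is True

    def test_silencing_a_shared_variant_increases_difference(self):
        dna = matrix_from_columns({"A": [20.0], "B": [20.0], "C": [0.0]})
        rna = matrix_from_columns({"A": [0.0], "B": [20.0], "C": [0.0]})
        res = delta_pd(dna, rna)
        delta_ab = dict(zip(res.pairs, res.pair_deltas))[("A", "B")]
        assert delta_ab > 0

    def test_individual_means_are_pair_averages(self, nonsyn_table, syn_table):
        # any two same-shape matrices will do; reuse the fixture vs itself
        perturbed = VariantProfileMatrix(
            nonsyn_table.individuals,
            nonsyn_table.sites,
            np.clip(nonsyn_table.values * 0.9, 0, 100),
        )
        res = delta_pd(nonsyn_table, perturbed)
        for ind, mean_delta in zip(res.individuals, res.individual_mean_deltas):
            mine = [d for p, d in zip(res.pairs, res.pair_deltas) if ind in p]
            assert len(mine) == 17
            assert mean_delta == pytest.approx(np.mean(mine))

    def test_mismatched_individuals_rejected(self, nonsyn_table):
        with pytest.raises(ValidationError):
            delta_pd(nonsyn_table, nonsyn_table.drop_individual("TAS285"))


class TestRegress:
    def test_perfect_line(self):
        x = np.arange(5.0)
        rep = regress(x, 2 * x)
        assert rep.extra["r2"] == pytest.approx(1.0)
        assert rep.extra["slope"] == pytest.approx(2.0)

    def test_constant_y(self):
        rep = regress(np.arange(5.0), np.ones(5))
        assert rep.extra["r2"] == 0.0
        assert rep.statistic == 0.0

    def test_against_normal_equations(self):
        x = np.array([0.0, 1.0, 2.0, 4.0, 7.0])
        y = np.array([1.0, 2.0, 2.5, 5.0, 8.5])
        # closed-form normal equations
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        s2 = (resid**2).sum() / (len(x) - 2)
        t = slope / np.sqrt(s2 / sxx)
        rep = regress(x, y)
        assert rep.extra["slope"] == pytest.approx(slope)
        assert rep.extra["intercept"] == pytest.approx(intercept)
        assert rep.statistic == pytest.approx(t)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValidationError):
            regress(np.ones(5), np.arange(5.0))


class TestNgSiteCounts:
    def test_single_codon_oracle(self):
        # TTT (Phe): only the third-position T->C change is synonymous
        n, s = ng_site_counts("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)
        assert n + s == pytest.approx(3)

    def test_additive_over_codons(self):
        n1, s1 = ng_site_counts("TTT")
        n2, s2 = ng_site_counts("GGG")
        n12, s12 = ng_site_counts("TTTGGG")
        assert n12 == pytest.approx(n1 + n2)
        assert s12 == pytest.approx(s1 + s2)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValidationError):
            ng_site_counts("TAAGGG")

    def test_frame_violation_rejected(self):
        with pytest.raises(ValidationError):
            ng_site_counts("TTTG")
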