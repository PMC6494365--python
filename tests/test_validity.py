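"""Item consensus, outlier purification, phenotype summaries and the
chi-square outcome comparisons."""

import numpy as np
import pytest

from phenoclust.schema_io import OutcomeTable
from phenoclust.validity import (
    UNASSIGNED,
    cross_cluster_distribution,
    detect_outliers,
    item_consensus,
    outcome_comparison,
    phenotype_summary,
    purify,
)

from conftest import make_table


class TestItemConsensus:
    def test_perfect_blocks_all_one(self):
        M = np.kron(np.eye(2), np.ones((3, 3)))
        labels = np.array([0, 0, 0, 1, 1, 1])
        ic = item_consensus(M, labels)
        np.testing.assert_array_equal(ic.values, 1.0)

    def test_constant_mean(self):
        M = np.full((4, 4), 0.5)
        np.fill_diagonal(M, 1.0)
        ic = item_consensus(M, np.zeros(4, dtype=int))
        np.testing.assert_allclose(ic.values, 0.5)

    def test_hand_matrix(self):
        # 5 patients, clusters {0,1,2} and {3,4}
        M = np.eye(5)
        pairs = {(0, 1): 0.8, (0, 2): 0.6, (1, 2): 1.0,
                 (0, 3): 0.1, (0, 4): 0.0, (1, 3): 0.2, (1, 4): 0.1,
                 (2, 3): 0.0, (2, 4): 0.3, (3, 4): 0.9}
        for (i, j), v in pairs.items():
            M[i, j] = M[j, i] = v
        ic = item_consensus(M, np.array([0, 0, 0, 1, 1]))
        np.testing.assert_allclose(
            ic.values, [(0.8 + 0.6) / 2, (0.8 + 1.0) / 2, (0.6 + 1.0) / 2, 0.9, 0.9])

    def test_singleton_convention(self):
        M = np.eye(3)
        ic = item_consensus(M, np.array([0, 0, 1]))
        assert ic.values[2] == 1.0


class TestOutliers:
    def test_equal_values_no_outliers(self):
        ic = item_consensus(np.full((4, 4), 0.7) + 0.3 * np.eye(4),
                            np.zeros(4, dtype=int))
        rep = detect_outliers(ic)
        assert rep.outlier_flags.sum() == 0
        assert rep.cluster_sds[0] == 0.0

    def test_single_low_member_flagged(self):
        # 19 members at 0.9, one at 0.2: mean ~ 0.865, sd ~ 0.157
        from phenoclust.validity import ItemConsensus

        values = np.array([0.9] * 19 + [0.2])
        ic = ItemConsensus(values=values, labels=np.zeros(20, dtype=int))
        rep = detect_outliers(ic)
        mean, sd = values.mean(), values.std(ddof=1)
        assert bool(rep.outlier_flags[19]) is bool(0.2 < mean - 2 * sd)
        assert rep.outlier_flags[19]
        assert rep.outlier_flags[:19].sum() == 0
        assert rep.outlier_counts[0] == 1
        assert rep.outlier_fractions[0] == pytest.approx(0.05)

    def test_tiny_cluster_never_flagged(self):
        from phenoclust.validity import ItemConsensus

        ic = ItemConsensus(values=np.array([0.9, 0.1]), labels=np.zeros(2, dtype=int))
        assert detect_outliers(ic).outlier_flags.sum() == 0


class TestPurify:
    def test_no_outliers_unchanged(self):
        ic = item_consensus(np.full((4, 4), 0.8) + 0.2 * np.eye(4),
                            np.zeros(4, dtype=int))
        rep = detect_outliers(ic)
        labels = np.zeros(4, dtype=int)
        np.testing.assert_array_equal(purify(labels, rep), labels)

    def test_bookkeeping_and_mean_improvement(self, rng):
        # random consensus-ish matrix with a planted weak member per cluster
        n = 40
        labels = np.repeat([0, 1], 20)
        M = np.where(np.equal.outer(labels, labels),
                     rng.uniform(0.85, 1.0, (n, n)), rng.uniform(0.0, 0.1, (n, n)))
        M = (M + M.T) / 2
        M[0, 1:20] = M[1:20, 0] = 0.05   # patient 0 weakly tied to its cluster
        np.fill_diagonal(M, 1.0)
        ic = item_consensus(M, labels)
        rep = detect_outliers(ic)
        pur = purify(labels, rep)
        # retained labels unchanged; sizes drop by outlier counts
        keep = pur != UNASSIGNED
        np.testing.assert_array_equal(pur[keep], labels[keep])
        for c in (0, 1):
            assert (pur == c).sum() == (labels == c).sum() - rep.outlier_counts[c]
        # purification never lowers the cluster-mean item consensus
        ic2 = item_consensus(M, pur)
        for c in (0, 1):
            if (pur == c).sum() >= 2:
                assert ic2.values[pur == c].mean() >= rep.cluster_means[c] - 1e-12


class TestPhenotypeSummary:
    def test_binary_proportion(self):
        t = make_table({"shock": [1.0] * 9 + [0.0] + [0.0] * 5},
                       {"shock": "binary"})
        labels = np.array([0] * 10 + [1] * 5)
        s = phenotype_summary(t, labels)
        assert s[0]["shock"]["proportion"] == pytest.approx(0.9)
        assert s[1]["shock"]["proportion"] == 0.0

    def test_continuous_median_iqr_and_missing_denominator(self):
        t = make_table({"age": [10.0, 20.0, 30.0, None]}, {"age": "continuous"})
        s = phenotype_summary(t, np.zeros(4, dtype=int))
        assert s[0]["age"]["median"] == 20.0
        assert s[0]["age"]["n_observed"] == 3

    def test_patient_order_invariance(self, rng):
        vals = rng.normal(0, 1, 12)
        labels = np.array([0, 1] * 6)
        t1 = make_table({"x": vals}, {"x": "continuous"})
        perm = rng.permutation(12)
        t2 = make_table({"x": vals[perm]}, {"x": "continuous"},
                        ids=[f"p{i}" for i in perm])
        s1 = phenotype_summary(t1, labels)
        s2 = phenotype_summary(t2, labels[perm])
        assert s1[0]["x"]["mean"] == pytest.approx(s2[0]["x"]["mean"])
        assert s1[1]["x"]["median"] == pytest.approx(s2[1]["x"]["median"])


class TestCrossClusterDistribution:
    def test_all_in_one_cluster(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        ind = np.array([0, 0, 1, 1, 0, 0])
        d = cross_cluster_distribution(ind, labels)
        assert d["shares"] == {0: 0.0, 1: 1.0, 2: 0.0}

    def test_even_split(self):
        labels = np.repeat([0, 1, 2, 3], 4)
        ind = np.tile([1, 0, 0, 1], 4)
        d = cross_cluster_distribution(ind, labels)
        assert all(v == pytest.approx(0.25) for v in d["shares"].values())
        assert sum(d["shares"].values()) == pytest.approx(1.0)

    def test_zero_positives_flagged(self):
        d = cross_cluster_distribution(np.zeros(6), np.array([0, 0, 1, 1, 2, 2]))
        assert d["defined"] is False


def outcomes_for(labels, mort, disp=None):
    n = len(labels)
    disp = disp or ["home"] * (n // 2) + ["other"] * (n - n // 2)
    return OutcomeTable(tuple(f"p{i}" for i in range(n)), np.asarray(mort),
                        tuple(disp))


class TestOutcomeComparison:
    def test_independence_gives_zero_statistic(self):
        labels = np.repeat([0, 1], 20)
        mort = np.tile([1] * 10 + [0] * 10, 2)
        res = outcome_comparison(outcomes_for(labels, mort), labels)["mortality"]
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_oracle_2x2(self):
        # [[30,10],[10,30]]: E=20 everywhere, chi2 = 4 * 100/20 = 20, df 1
        labels = np.repeat([0, 1], 40)
        mort = np.concatenate([np.ones(30), np.zeros(10), np.ones(10), np.zeros(30)])
        res = outcome_comparison(outcomes_for(labels, mort), labels)["mortality"]
        assert res.statistic == pytest.approx(20.0, abs=1e-12)
        assert res.df == 1
        # margins conserve n
        assert res.table.to_numpy().sum() == 80

    def test_sparse_cell_warns_but_reports(self):
        labels = np.array([0] * 3 + [1] * 3)
        mort = np.array([1, 0, 0, 0, 0, 0])
        with pytest.warns(UserWarning, match="expected cell"):
            res = outcome_comparison(outcomes_for(labels, mort), labels)["mortality"]
        assert np.isfinite(res.statistic)

    def test_unassigned_excluded(self):
        labels = np.array([0, 0, 0, 1, 1, 1, UNASSIGNED, UNASSIGNED])
        mort = np.array([1, 1, 0, 0, 0, 1, 1, 1])
        res = outcome_comparison(outcomes_for(labels, mort), labels)["mortality"]
        assert res.table.to_numpy().sum() == 6
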