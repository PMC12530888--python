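import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sfactivity as sfa
from sfactivity import ValidationError
from sfactivity import programs as pg
from sfactivity.activity import NON_DRIVER, ONCOGENIC, TUMOR_SUPPRESSOR


def _acts(rows: dict, prefix: str) -> sfa.FeatureMatrix:
    n = len(next(iter(rows.values())))
    return sfa.FeatureMatrix(
        pd.DataFrame(rows, index=[f"{prefix}{j}" for j in range(n)]).T,
        "activity",
    )


def brute_force_bh(pvals):
    """Step-up Benjamini-Hochberg, written out naively."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        q[i] = min(prev, pvals[i] * m / rank_from_end)
        prev = q[i]
    return q


class TestDifferentialActivity:
    def test_fully_separated_groups(self):
        tumor = _acts({"SF1": list(range(11, 21))}, "t")
        normal = _acts({"SF1": list(range(1, 11))}, "n")
        res = pg.differential_activity(tumor, normal)
        assert res.loc["SF1", "U"] == 100.0
        assert res.loc["SF1", "p"] < 0.001
        assert res.loc["SF1", "direction"] == "activated"
        exact = stats.mannwhitneyu(
            np.arange(11, 21), np.arange(1, 11), alternative="two-sided",
            method="exact",
        )
        assert exact.statistic == 100.0  # independent exact-test cross-check

    def test_identical_groups_not_significant(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = pg.differential_activity(
            _acts({"SF1": vals}, "t"), _acts({"SF1": vals}, "n")
        )
        assert res.loc["SF1", "p"] == pytest.approx(1.0, abs=0.05)
        assert not res.loc["SF1", "significant"]

    def test_bh_adjustment_matches_hand_oracle(self):
        rng = np.random.default_rng(0)
        tumor = _acts({f"SF{i}": rng.normal(i * 0.3, 1, 10) for i in range(6)}, "t")
        normal = _acts({f"SF{i}": rng.normal(0, 1, 10) for i in range(6)}, "n")
        res = pg.differential_activity(tumor, normal)
        assert res["q"].to_numpy() == pytest.approx(
            brute_force_bh(res["p"].tolist()), abs=1e-12
        )
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_bh_on_worked_triple(self):
        assert brute_force_bh([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_underpowered_sf_excluded_with_warning(self, caplog):
        tumor = sfa.FeatureMatrix(
            pd.DataFrame(
                {"t1": [1.0, 1.0], "t2": [2.0, np.nan], "t3": [3.0, np.nan]},
                index=["SF1", "SF2"],
            ),
            "activity",
        )
        normal = sfa.FeatureMatrix(
            pd.DataFrame(
                {"n1": [1.0, 1.0], "n2": [2.0, 2.0], "n3": [0.0, 0.0]},
                index=["SF1", "SF2"],
            ),
            "activity",
        )
        with caplog.at_level("WARNING", logger="sfactivity"):
            res = pg.differential_activity(tumor, normal)
        assert "SF2" not in res.index and "SF1" in res.index


class TestClassifyRecurrent:
    def _result(self, sf, significant, direction):
        return pd.DataFrame(
            {
                "U": [50.0],
                "p": [0.01],
                "q": [0.01 if significant else 0.5],
                "direction": [direction],
                "median_diff": [1.0 if direction == "activated" else -1.0],
                "significant": [significant],
            },
            index=[sf],
        )

    def test_recurrently_activated_is_oncogenic_like(self):
        cohorts = [self._result("SF1", True, "activated") for _ in range(6)] + [
            self._result("SF1", False, "activated") for _ in range(8)
        ]
        prog = pg.classify_recurrent(cohorts, min_cohorts=5)
        assert prog.classes["SF1"] == ONCOGENIC
        assert prog.counts["SF1"] == (6, 0)

    def test_exactly_min_cohorts_counts(self):
        cohorts = [self._result("SF1", True, "inactivated") for _ in range(5)]
        prog = pg.classify_recurrent(cohorts, min_cohorts=5)
        assert prog.classes["SF1"] == TUMOR_SUPPRESSOR

    def test_never_significant_is_non_driver(self):
        cohorts = [self._result("SF1", False, "activated") for _ in range(8)]
        assert pg.classify_recurrent(cohorts).classes["SF1"] == NON_DRIVER

    def test_tied_directions_are_non_driver(self):
        cohorts = [self._result("SF1", True, "activated") for _ in range(5)] + [
            self._result("SF1", True, "inactivated") for _ in range(5)
        ]
        assert pg.classify_recurrent(cohorts, min_cohorts=5).classes["SF1"] == NON_DRIVER


class TestCrossRegulation:
    def _programs(self):
        return sfa.ProgramDefinition(
            {"A": ONCOGENIC, "B": TUMOR_SUPPRESSOR, "C": NON_DRIVER}
        )

    def test_regulation_via_exon_mapping(self):
        reg = sfa.Regulon("A", ("e1",), np.array([1.0]), np.ones(1))
        net = sfa.NetworkSet({"n": [reg]})
        table = pg.cross_regulation_ratios(
            net, self._programs(), {"e1": "B"}, mode="splicing"
        ).set_index(["source_class", "target_class"])
        assert table.loc[(ONCOGENIC, TUMOR_SUPPRESSOR), "fraction"] == 1.0
        assert table.loc[(ONCOGENIC, NON_DRIVER), "fraction"] == 0.0

    def test_empty_network_gives_zero_fractions(self):
        table = pg.cross_regulation_ratios(
            sfa.NetworkSet({"n": []}), self._programs(), {}, mode="splicing"
        )
        assert (table["fraction"] == 0).all()

    def test_self_interactions_excluded(self):
        reg = sfa.Regulon("A", ("e1",), np.array([1.0]), np.ones(1))
        net = sfa.NetworkSet({"n": [reg]})
        table = pg.cross_regulation_ratios(
            net, self._programs(), {"e1": "A"}, mode="splicing"
        ).set_index(["source_class", "target_class"])
        assert table.loc[(ONCOGENIC, ONCOGENIC), "count"] == 0

    def test_unmapped_exon_rejected(self):
        reg = sfa.Regulon("A", ("e1",), np.array([1.0]), np.ones(1))
        with pytest.raises(ValidationError, match="e1"):
            pg.cross_regulation_ratios(
                sfa.NetworkSet({"n": [reg]}), self._programs(), {}, mode="splicing"
            )

    def test_ppi_mode_uses_adjacency(self):
        g = nx.Graph([("A", "B")])
        table = pg.cross_regulation_ratios(
            g, self._programs(), mode="ppi"
        ).set_index(["source_class", "target_class"])
        assert table.loc[(ONCOGENIC, TUMOR_SUPPRESSOR), "fraction"] == 1.0
        assert table.loc[(TUMOR_SUPPRESSOR, ONCOGENIC), "fraction"] == 1.0


class TestShortestPaths:
    def test_path_graph(self):
        g = nx.path_graph(["A", "B", "C"])
        d = pg.shortest_paths(g, ["A", "B", "C"])
        assert d.loc["A", "C"] == 2 and d.loc["A", "A"] == 0

    def test_triangle_all_adjacent(self):
        g = nx.complete_graph(["A", "B", "C"])
        d = pg.shortest_paths(g, ["A", "B", "C"])
        off_diag = d.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off_diag == 1).all()

    def test_disconnected_pair_is_infinite(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_node("C")
        d = pg.shortest_paths(g, ["A", "C"])
        assert np.isinf(d.loc["A", "C"])

    def test_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            n = 8
            g = nx.Graph()
            g.add_nodes_from(range(n))
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.3:
                    g.add_edge(i, j)
            d = pg.shortest_paths(g, list(range(n)))

            def enumerate_shortest(src, dst):
                best = np.inf
                stack = [(src, {src}, 0)]
                while stack:
                    node, seen, depth = stack.pop()
                    if node == dst:
                        best = min(best, depth)
                        continue
                    for nb in g.neighbors(node):
                        if nb not in seen:
                            stack.append((nb, seen | {nb}, depth + 1))
                return best

            for i, j in itertools.combinations(range(n), 2):
                assert d.loc[i, j] == enumerate_shortest(i, j)


class TestCorrelate:
    def test_affine_relation_pearson_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = pg.correlate(x, [2 * v + 1 for v in x], "pearson")
        assert r == pytest.approx(1.0)

    def test_monotone_relation_spearman_one(self):
        x = [-2.0, -1.0, 1.0, 2.0, 3.0]
        r, _ = pg.correlate(x, [v**3 for v in x], "spearman")
        assert r == pytest.approx(1.0)

    def test_zero_variance_reported_missing(self, caplog):
        with caplog.at_level("WARNING", logger="sfactivity"):
            r, p = pg.correlate([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert np.isnan(r) and np.isnan(p)

    def test_infinite_distances_dropped(self):
        r, _ = pg.correlate([1.0, 2.0, 3.0, np.inf], [2.0, 4.0, 6.0, 1.0])
        assert r == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            pg.correlate([1.0, 2.0], [1.0, 2.0])

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        pvals = []
        for _ in range(1000):
            perm = rng.permutation(y)
            _, p = pg.correlate(x, perm, "pearson")
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3


class TestTargetClassFraction:
    def _setup(self):
        programs = sfa.ProgramDefinition(
            {"A": ONCOGENIC, "T1": TUMOR_SUPPRESSOR, "T2": TUMOR_SUPPRESSOR}
        )
        exon_map = {"e1": "T1", "e2": "T2", "e3": "G5", "e4": "G6"}
        return programs, exon_map

    def test_half_of_targets_in_class(self):
        programs, exon_map = self._setup()
        reg = sfa.Regulon("A", ("e1", "e2", "e3", "e4"), np.ones(4), np.ones(4))
        frac = pg.target_class_fraction(
            sfa.NetworkSet({"n": [reg]}), programs, exon_map, TUMOR_SUPPRESSOR
        )
        assert frac["A"] == 0.5

    @pytest.mark.parametrize(
        "targets,expected", [(("e3", "e4"), 0.0), (("e1", "e2"), 1.0)]
    )
    def test_boundary_fractions(self, targets, expected):
        programs, exon_map = self._setup()
        reg = sfa.Regulon("A", targets, np.ones(len(targets)), np.ones(len(targets)))
        frac = pg.target_class_fraction(
            sfa.NetworkSet({"n": [reg]}), programs, exon_map, TUMOR_SUPPRESSOR
        )
        assert frac["A"] == expected
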