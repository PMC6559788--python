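"""Network randomisation, superclass agreement and the validation stats."""

from math import comb

import numpy as np
import pytest
from scipy import stats

from gutchem.fingerprints import pairwise_similarity
from gutchem.network import build_network
from gutchem.synthetic import FixtureSpec, generate_compounds
from gutchem.validation import (
    category_self_similarity,
    compare_to_random,
    edge_match_table,
    randomize_network,
    structure_toxicity_regression,
    superclass_agreement,
    within_category_similarities,
    write_report,
)


def planted_net(n_compounds=80, min_similarity=0.05, seed=11):
    spec = FixtureSpec(n_compounds=n_compounds, seed=seed)
    compounds, clusters = generate_compounds(spec)
    attrs = {
        c.compound_id: {"category": c.category, "superclass": c.superclass}
        for c in compounds
    }
    net = build_network(
        pairwise_similarity(compounds), min_similarity, node_attrs=attrs
    )
    return net, compounds, clusters


class TestRandomize:
    def test_invariants_across_seeds(self):
        net, _, _ = planted_net(n_compounds=40, min_similarity=0.3)
        for seed in range(20):
            rand = randomize_network(net, seed=seed)
            assert sorted(rand.nodes) == sorted(net.nodes)
            assert len(rand.edges) == len(net.edges)
            assert rand.node_attrs == net.node_attrs
            assert all(a != b for a, b in rand.edges)
            assert len(set(rand.edges)) == len(rand.edges)
            assert sorted(e.score for e in rand.edges.values()) == (
                pytest.approx(sorted(e.score for e in net.edges.values()))
            )

    def test_complete_graph_randomizes_to_itself(self):
        nodes = [f"n{i}" for i in range(6)]
        scores = {
            (a, b): 0.9 for i, a in enumerate(nodes) for b in nodes[i + 1 :]
        }
        net = build_network(scores, 0.3)
        rand = randomize_network(net, seed=0)
        assert set(rand.edges) == set(net.edges)

    def test_too_many_edges_rejected(self):
        net = build_network({("A", "B"): 0.9}, 0.3)
        net.edges[("A", "C")] = net.edges[("A", "B")]
        net.edges[("B", "C")] = net.edges[("A", "B")]
        net.edges[("X", "Y")] = net.edges[("A", "B")]  # 4 edges, 3 nodes... n grows
        net.nodes = ["A", "B", "C"]
        with pytest.raises(ValueError):
            randomize_network(net, seed=0)

    def test_edge_inclusion_probability_uniform(self):
        # m/C(n,2) inclusion probability for a fixed pair, over 1000 seeds
        nodes = [f"n{i}" for i in range(12)]
        scores = {(nodes[i], nodes[i + 1]): 0.9 for i in range(0, 10, 2)}
        net = build_network(scores, 0.3, nodes=nodes)
        m, total = len(net.edges), comb(12, 2)
        probe = ("n00", "n01") if "n00" in nodes else (nodes[0], nodes[1])
        hits = sum(
            probe in randomize_network(net, seed=s).edges for s in range(1000)
        )
        p = m / total
        se = (p * (1 - p) / 1000) ** 0.5
        assert abs(hits / 1000 - p) < 3 * se + 1e-9

    def test_rewire_preserves_degrees(self):
        net, _, _ = planted_net(n_compounds=40, min_similarity=0.3)
        rand = randomize_network(net, seed=5, method="rewire")
        assert len(rand.edges) == len(net.edges)
        for node in net.nodes:
            assert rand.degree(node) == net.degree(node)


class TestAgreement:
    def test_single_superclass_fully_matched(self):
        scores = {("A", "B"): 0.9, ("B", "C"): 0.6}
        attrs = {n: {"superclass": "SC0"} for n in "ABC"}
        net = build_network(scores, 0.3, node_attrs=attrs)
        agreement = superclass_agreement(net)
        occupied = agreement[(agreement["matched"] + agreement["unmatched"]) > 0]
        assert (occupied["matched_fraction"] == 1.0).all()
        assert occupied["ratio"].isna().all()  # no unmatched pair anywhere

    def test_counts_match_brute_force(self):
        net, compounds, _ = planted_net(n_compounds=60)
        assert len(net.edges) >= 500
        superclass = {c.compound_id: c.superclass for c in compounds}
        agreement = superclass_agreement(net, bin_width=0.05)
        for row in agreement.itertuples(index=False):
            matched = unmatched = 0
            for (a, b), edge in net.edges.items():
                in_bin = row.bin_low <= edge.score < row.bin_high or (
                    row.bin_high == 1.0 and edge.score == 1.0
                )
                if not in_bin:
                    continue
                if superclass[a] == superclass[b]:
                    matched += 1
                else:
                    unmatched += 1
            assert (row.matched, row.unmatched) == (matched, unmatched)

    def test_matched_fraction_rises_with_similarity(self):
        # perfect superclass-cluster alignment makes the rise deterministic
        spec = FixtureSpec(n_compounds=120, superclass_alignment=1.0, seed=11)
        compounds, _ = generate_compounds(spec)
        attrs = {
            c.compound_id: {"superclass": c.superclass} for c in compounds
        }
        net = build_network(
            pairwise_similarity(compounds), 0.05, node_attrs=attrs
        )
        agreement = superclass_agreement(net, bin_width=0.25)
        occupied = agreement.dropna(subset=["matched_fraction"])
        fractions = occupied["matched_fraction"].to_numpy()
        assert (np.diff(fractions) >= -1e-12).all()

    def test_unannotated_nodes_excluded(self):
        scores = {("A", "B"): 0.9, ("B", "C"): 0.6}
        attrs = {"A": {"superclass": "SC0"}, "B": {"superclass": "SC0"}, "C": {}}
        net = build_network(scores, 0.3, node_attrs=attrs)
        agreement = superclass_agreement(net)
        assert agreement["matched"].sum() + agreement["unmatched"].sum() == 1


class TestRankSum:
    def test_identical_samples_not_significant(self):
        net, _, _ = planted_net(n_compounds=40)
        table = edge_match_table(net)
        result = compare_to_random(table, table)
        assert result.pvalue > 0.99

    def test_planted_structure_detected(self):
        net, _, _ = planted_net(n_compounds=80)
        assert len(net.edges) >= 500
        rand = randomize_network(net, seed=3)
        result = compare_to_random(edge_match_table(net), edge_match_table(rand))
        assert result.conclusive and result.pvalue < 0.01

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(44)
        import pandas as pd

        for _ in range(50):
            a = rng.normal(0, 1, rng.integers(5, 40))
            b = rng.normal(0.2, 1, rng.integers(5, 40))
            real = pd.DataFrame({"score": a, "matched": True})
            rand = pd.DataFrame({"score": b, "matched": True})
            result = compare_to_random(real, rand)
            stat, p = stats.ranksums(a, b)
            assert result.statistic == pytest.approx(stat)
            assert result.pvalue == pytest.approx(p)

    def test_degenerate_all_tied_inconclusive(self):
        import pandas as pd

        same = pd.DataFrame({"score": [0.5, 0.5], "matched": [True, True]})
        result = compare_to_random(same, same)
        assert not result.conclusive


class TestRegression:
    @staticmethod
    def edge_maps(x, y):
        struct = {(f"a{i}", f"b{i}"): float(v) for i, v in enumerate(x)}
        tox = {(f"a{i}", f"b{i}"): float(v) for i, v in enumerate(y)}
        return struct, tox

    def test_exact_linear_relation(self):
        x = np.linspace(0.1, 0.9, 20)
        struct, tox = self.edge_maps(x, 0.5 * x)
        fit = structure_toxicity_regression(struct, tox)
        assert fit.slope == pytest.approx(0.5)
        assert fit.r == pytest.approx(1.0)

    def test_planted_slope_ci_coverage(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 1, 1000)
            y = 0.3 * x + rng.normal(0, 0.1, 1000)
            fit = structure_toxicity_regression(*self.edge_maps(x, y))
            if fit.ci95[0] <= 0.3 <= fit.ci95[1]:
                hits += 1
        assert hits >= 90

    def test_null_slope_ci_coverage(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            x = rng.uniform(0, 1, 200)
            y = rng.normal(0, 0.1, 200)
            fit = structure_toxicity_regression(*self.edge_maps(x, y))
            if fit.ci95[0] <= 0.0 <= fit.ci95[1]:
                hits += 1
        assert hits >= 90

    def test_row_order_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, 50)
        y = 0.3 * x + rng.normal(0, 0.1, 50)
        struct, tox = self.edge_maps(x, y)
        shuffled = dict(reversed(list(struct.items())))
        assert structure_toxicity_regression(struct, tox) == (
            structure_toxicity_regression(shuffled, tox)
        )

    def test_degenerate_inputs_rejected(self):
        struct, tox = self.edge_maps([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="zero variance"):
            structure_toxicity_regression(struct, tox)
        with pytest.raises(ValueError, match="at least 3"):
            structure_toxicity_regression(
                {("a", "b"): 0.5}, {("a", "b"): 0.5}
            )


class TestCategorySelfSimilarity:
    def test_identical_distributions(self, small_fixture):
        # same compounds under both labels -> statistic 0
        compounds, _ = small_fixture
        stat, _ = category_self_similarity(compounds, "drug", "drug")
        assert stat == 0.0

    def test_planted_categories_compare(self, small_fixture):
        compounds, _ = small_fixture
        stat, p = category_self_similarity(compounds, "food", "drug")
        a = within_category_similarities(compounds, "food")
        b = within_category_similarities(compounds, "drug")
        expected = stats.ks_2samp(a, b)
        assert stat == pytest.approx(expected.statistic)
        assert p == pytest.approx(expected.pvalue)

    def test_disjoint_supports_statistic_one(self):
        a = np.array([0.1, 0.2, 0.15])
        b = np.array([0.8, 0.9, 0.85])
        assert stats.ks_2samp(a, b).statistic == 1.0

    def test_oracle_sup_difference(self, small_fixture):
        # independent empirical-CDF sup-difference oracle
        compounds, _ = small_fixture
        a = within_category_similarities(compounds, "food")
        b = within_category_similarities(compounds, "drug")
        grid = np.unique(np.concatenate([a, b]))
        cdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        cdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        sup = float(np.max(np.abs(cdf_a - cdf_b)))
        stat, _ = category_self_similarity(compounds, "food", "drug")
        assert stat == pytest.approx(sup)

    def test_small_category_rejected(self, small_fixture):
        compounds, _ = small_fixture
        with pytest.raises(ValueError):
            category_self_similarity(compounds, "drug", "other")


def test_report_writer(tmp_path):
    net, _, _ = planted_net(n_compounds=30)
    agreement = superclass_agreement(net)
    path = tmp_path / "report.tsv"
    write_report(path, agreement, parameters={"seed": 11, "bin_width": 0.05})
    text = path.read_text()
    assert text.startswith("# bin_width = 0.05\n# seed = 11\n")
    assert "matched_fraction" in text
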