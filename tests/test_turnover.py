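import itertools
import math

import numpy as np
import pytest

from phytoassembly.alpha import NullModelConfig
from phytoassembly.io import CommunityTable
from phytoassembly.turnover import (
    beta_mpd,
    beta_nri,
    bray_curtis,
    cophenetic_matrix,
    raup_crick_bray,
)

from .conftest import random_instance


class TestCophenetic:
    def test_hand_path_summation(self, four_tip_tree):
        d = cophenetic_matrix(four_tip_tree)
        assert d.loc["A", "B"] == pytest.approx(2.0)
        assert d.loc["A", "C"] == pytest.approx(4.0)
        assert d.loc["B", "D"] == pytest.approx(4.0)

    def test_ultrametric_tips_equidistant_from_root(self):
        """Extant-tip birth-death trees are ultrametric."""
        from phytoassembly.simulate import simulate_tree

        tree = simulate_tree(25, 1.0, 0.3, seed=6)
        depths = {}
        root = tree.tree.seed_node
        for leaf in tree.tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node is not root:
                d += node.edge.length
                node = node.parent_node
            depths[leaf.taxon.label] = d
        vals = np.array(list(depths.values()))
        assert np.allclose(vals, vals[0], atol=1e-9)

    def test_agrees_with_dendropy_patristic(self):
        """Independent oracle: dendropy's own patristic distances."""
        from phytoassembly.simulate import simulate_tree

        tree = simulate_tree(15, seed=12)
        d = tree.cophenetic_matrix()
        pdm = tree.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.tree.taxon_namespace}
        for a, b in itertools.combinations(d.index, 2):
            assert d.loc[a, b] == pytest.approx(
                pdm.patristic_distance(taxa[a], taxa[b]), abs=1e-9
            )


class TestBetaMPD:
    def test_disjoint_cherries(self, four_tip_tree):
        d = four_tip_tree.cophenetic_matrix()
        loc = d.index.get_loc
        a = np.array([loc("A"), loc("B")])
        b = np.array([loc("C"), loc("D")])
        assert beta_mpd(a, b, d.to_numpy()) == pytest.approx(4.0)

    def test_shared_taxon_zero_distance_included(self, four_tip_tree):
        d = four_tip_tree.cophenetic_matrix()
        loc = d.index.get_loc
        a = np.array([loc("A"), loc("B")])
        b = np.array([loc("A"), loc("C")])
        # cross pairs: (A,A)=0, (A,C)=4, (B,A)=2, (B,C)=4
        assert beta_mpd(a, b, d.to_numpy()) == pytest.approx(2.5)

    def test_self_comparison_identity(self, four_tip_tree):
        d = four_tip_tree.cophenetic_matrix().to_numpy()
        x = np.array([0, 1, 2])
        expected = d[np.ix_(x, x)].sum() / 9
        assert beta_mpd(x, x, d) == pytest.approx(expected)
        assert beta_mpd(np.array([0]), np.array([0]), d) == 0.0

    def test_empty_community_is_nan(self, four_tip_tree):
        d = four_tip_tree.cophenetic_matrix().to_numpy()
        assert np.isnan(beta_mpd(np.array([]), np.array([0]), d))

    def test_brute_force_oracle_equivalence(self):
        """Ordered cross-pair double loop on 100 random instances, 1e-10."""
        for rep in range(100):
            tree, dmat, occ_a, rng = random_instance(1000 + rep)
            n = dmat.shape[0]
            occ_b = rng.choice(n, size=int(rng.integers(1, n + 1)), replace=False)
            d = dmat.to_numpy()
            brute = np.mean([d[i, j] for i in occ_a for j in occ_b])
            assert beta_mpd(occ_a, occ_b, d) == pytest.approx(brute, abs=1e-10)


def exhaustive_beta_nri(tree, occ_a, occ_b):
    """Oracle: betaNRI from the full tip-label permutation distribution."""
    d = tree.cophenetic_matrix()
    labels = list(d.index)
    D = d.to_numpy()
    ia = [labels.index(t) for t in occ_a]
    ib = [labels.index(t) for t in occ_b]
    obs = np.mean([D[i, j] for i in ia for j in ib])
    null = np.array([
        np.mean([D[perm[i], perm[j]] for i in ia for j in ib])
        for perm in itertools.permutations(range(len(labels)))
    ])
    return (obs - null.mean()) / null.std(ddof=0)


class TestBetaNRI:
    def _table(self, occ_a, occ_b):
        counts = np.array(
            [[5 if t in occ_a else 0, 5 if t in occ_b else 0] for t in "ABCD"]
        )
        return CommunityTable(list("ABCD"), ["s1", "s2"], counts)

    @pytest.mark.parametrize(
        "occ_a,occ_b,sign",
        [(["A", "B"], ["A", "B"], -1), (["A", "B"], ["C", "D"], 1)],
        ids=["identical-single-clade", "opposite-clades"],
    )
    def test_monte_carlo_matches_exhaustive(self, four_tip_tree, occ_a, occ_b, sign):
        exact = exhaustive_beta_nri(four_tip_tree, occ_a, occ_b)
        n_reps = 9999
        res = beta_nri(
            self._table(occ_a, occ_b), four_tip_tree, NullModelConfig(n_reps, 23)
        ).iloc[0]
        assert np.sign(exact) == sign
        assert np.sign(res["beta_nri"]) == sign
        se = math.sqrt(1 / n_reps + exact**2 / (2 * n_reps))
        assert abs(res["beta_nri"] - exact) <= 3 * se

    def test_symmetry_under_sample_relabeling(self):
        """Shared permutation stream: value must not depend on pair order."""
        from phytoassembly.simulate import simulate_tree

        rng = np.random.default_rng(0)
        tree = simulate_tree(10, seed=6)
        tips = sorted(tree.tip_labels)
        counts = rng.integers(0, 20, size=(10, 3))
        t1 = CommunityTable(tips, ["s1", "s2", "s3"], counts)
        t2 = CommunityTable(tips, ["s2", "s1", "s3"],
                            counts[:, [1, 0, 2]].copy())
        a = beta_nri(t1, tree, NullModelConfig(199, 5))
        b = beta_nri(t2, tree, NullModelConfig(199, 5))
        def pick(df):
            m = df.apply(
                lambda r: {r["sample_a"], r["sample_b"]} == {"s1", "s2"}, axis=1
            )
            return df.loc[m, "beta_nri"].iloc[0]

        assert pick(a) == pytest.approx(pick(b), abs=1e-12)

    def test_determinism(self, four_tip_tree, four_tip_table):
        a = beta_nri(four_tip_table, four_tip_tree, NullModelConfig(99, 1))
        b = beta_nri(four_tip_table, four_tip_tree, NullModelConfig(99, 1))
        assert a.equals(b)


class TestBrayCurtis:
    def test_hand_arithmetic(self):
        assert bray_curtis([10, 0, 5], [2, 8, 5]) == pytest.approx(16 / 30)

    def test_identity_and_disjoint(self):
        assert bray_curtis([3, 1], [3, 1]) == 0.0
        assert bray_curtis([3, 0], [0, 9]) == 1.0

    def test_both_empty_is_nan(self):
        assert np.isnan(bray_curtis([0, 0], [0, 0]))


class TestRaupCrick:
    def _random_table(self, seed, n=25, s=6, depth=300):
        rng = np.random.default_rng(seed)
        p = rng.lognormal(0, 1, n)
        counts = np.column_stack(
            [rng.multinomial(depth, p / p.sum()) for _ in range(s)]
        )
        return CommunityTable(
            [f"t{i:02d}" for i in range(n)], [f"s{j}" for j in range(s)],
            counts, rarefied=True,
        )

    def test_identical_pair_is_extreme_low(self):
        """obs BC = 0 while nulls scatter membership: RC ~ -1."""
        rng = np.random.default_rng(0)
        n = 30
        p = rng.lognormal(0, 1, n)
        base = rng.multinomial(500, p / p.sum())
        others = np.column_stack(
            [rng.multinomial(500, p / p.sum()) for _ in range(4)]
        )
        counts = np.column_stack([base, base, others])
        table = CommunityTable(
            [f"t{i:02d}" for i in range(n)], [f"s{j}" for j in range(6)],
            counts, rarefied=True,
        )
        rc = raup_crick_bray(table, NullModelConfig(199, 1))
        row = rc[(rc.sample_a == "s0") & (rc.sample_b == "s1")].iloc[0]
        assert row["bray_curtis_obs"] == 0.0
        assert row["rc_bray"] <= -0.95

    def test_bounds_always_hold(self):
        for seed in range(20):
            rc = raup_crick_bray(self._random_table(seed), NullModelConfig(49, seed))
            vals = rc["rc_bray"].dropna()
            assert (vals >= -1).all() and (vals <= 1).all()

    def test_obs_above_all_nulls_is_plus_one(self):
        """An observed BC larger than every null forces RC = +1 exactly."""
        rng = np.random.default_rng(3)
        n = 40
        # two samples on disjoint 15-taxon halves; richness-15 null draws
        # from 40 taxa are essentially never disjoint (P ~ 3e-6), so the
        # observed BC of 1 strictly tops every null replicate
        a = np.zeros(n, dtype=int)
        b = np.zeros(n, dtype=int)
        a[:15] = 20
        b[15:30] = 20
        broad = np.column_stack(
            [rng.multinomial(300, np.ones(n) / n) for _ in range(4)]
        )
        counts = np.column_stack([a, b, broad])
        table = CommunityTable(
            [f"t{i:02d}" for i in range(n)], [f"s{j}" for j in range(6)],
            counts,
        )
        rc = raup_crick_bray(table, NullModelConfig(199, 4))
        row = rc[(rc.sample_a == "s0") & (rc.sample_b == "s1")].iloc[0]
        assert row["bray_curtis_obs"] == 1.0
        assert row["rc_bray"] == 1.0

    def test_symmetry_under_sample_relabeling(self):
        table = self._random_table(7)
        swapped = CommunityTable(
            table.taxon_ids,
            [table.sample_ids[1], table.sample_ids[0]] + table.sample_ids[2:],
            np.column_stack([table.counts[:, 1], table.counts[:, 0],
                             table.counts[:, 2:]]),
            rarefied=True,
        )
        a = raup_crick_bray(table, NullModelConfig(99, 2))
        b = raup_crick_bray(swapped, NullModelConfig(99, 2))
        pair_a = a[(a.sample_a == "s0") & (a.sample_b == "s1")]["rc_bray"].iloc[0]
        pair_b = b[(b.sample_a == "s1") & (b.sample_b == "s0")]["rc_bray"].iloc[0]
        assert pair_a == pytest.approx(pair_b, abs=1e-12)


class TestMonotoneSelectionResponse:
    def test_beta_nri_decreases_with_narrower_filter(self):
        """Stronger niche filtering -> stronger phylogenetic clustering."""
        from phytoassembly.simulate import ScenarioConfig, assemble_communities

        means = []
        for fw in (0.3, 0.1, 0.05):
            cfg = ScenarioConfig("homogeneous_selection", filter_width=fw, seed=3)
            ds = assemble_communities(cfg)
            bn = beta_nri(ds.table, ds.tree, NullModelConfig(99, 9))
            means.append(bn["beta_nri"].mean())
        assert means[0] > means[1] > means[2]
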