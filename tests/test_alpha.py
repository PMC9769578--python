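import itertools
import math

import numpy as np
import pytest

from phytoassembly.alpha import NullModelConfig, alpha_indices, faith_pd, mpd, nri
from phytoassembly.io import CommunityTable, Phylogeny

from .conftest import random_instance


class TestAlphaIndices:
    def test_uniform_four_taxon_closed_forms(self):
        table = CommunityTable(list("abcd"), ["s"], np.array([[25], [25], [25], [25]]))
        rec = alpha_indices(table).iloc[0]
        assert rec["richness"] == 4
        assert rec["shannon"] == pytest.approx(math.log(4))
        assert rec["simpson_1d"] == pytest.approx(0.75)

    def test_single_taxon_sample(self):
        table = CommunityTable(list("abc"), ["s"], np.array([[100], [0], [0]]))
        rec = alpha_indices(table).iloc[0]
        assert rec["richness"] == 1
        assert rec["shannon"] == pytest.approx(0.0)
        assert rec["simpson_1d"] == pytest.approx(0.0)

    def test_shannon_against_independent_recomputation(self):
        counts = np.array([[10], [5], [5]])
        table = CommunityTable(list("abc"), ["s"], counts)
        rec = alpha_indices(table).iloc[0]
        p = counts[:, 0] / counts.sum()
        brute = -sum(pi * math.log(pi) for pi in p if pi > 0)
        assert rec["shannon"] == pytest.approx(brute, abs=1e-12)

    def test_empty_sample_undefined_not_zero(self):
        table = CommunityTable(list("ab"), ["s1", "s2"], np.array([[3, 0], [1, 0]]))
        rec = alpha_indices(table)
        assert rec.loc["s2", "richness"] == 0
        assert np.isnan(rec.loc["s2", "shannon"])
        assert np.isnan(rec.loc["s2", "simpson_1d"])


class TestFaithPD:
    def test_full_tree_equals_total_branch_length(self, four_tip_tree):
        table = CommunityTable(list("ABCD"), ["s"], np.ones((4, 1), dtype=int))
        assert faith_pd(table, four_tip_tree)["s"] == pytest.approx(6.0)

    def test_single_cherry_path_enumeration(self, four_tip_tree):
        table = CommunityTable(list("ABCD"), ["s"],
                               np.array([[1], [1], [0], [0]]))
        # branches A (1) + B (1) + their stem to the root (1)
        assert faith_pd(table, four_tip_tree)["s"] == pytest.approx(3.0)

    def test_monotone_in_membership(self):
        """Adding a taxon never decreases PD (random trees, nested sets)."""
        from phytoassembly.simulate import simulate_tree

        rng = np.random.default_rng(0)
        for rep in range(30):
            tree = simulate_tree(int(rng.integers(5, 15)), seed=rep)
            tips = sorted(tree.tip_labels)
            order = rng.permutation(len(tips))
            prev = 0.0
            for k in range(1, len(tips) + 1):
                occupied = [tips[i] for i in order[:k]]
                counts = np.array([[1] if t in occupied else [0] for t in tips])
                table = CommunityTable(tips, ["s"], counts)
                val = faith_pd(table, tree)["s"]
                assert val >= prev - 1e-12
                prev = val

    def test_missing_taxon_raises(self, four_tip_tree):
        table = CommunityTable(["A", "Z"], ["s"], np.ones((2, 1), dtype=int))
        with pytest.raises(ValueError, match="absent"):
            faith_pd(table, four_tip_tree)

    def test_agrees_with_skbio(self):
        """Independent oracle: scikit-bio's Faith PD on random instances."""
        skbio = pytest.importorskip("skbio")
        from io import StringIO

        from skbio.diversity.alpha import faith_pd as sk_faith

        from phytoassembly.simulate import simulate_tree

        for rep in range(5):
            tree, dmat, occupied, rng = random_instance(600 + rep)
            tips = sorted(tree.tip_labels)
            counts = np.zeros((len(tips), 1), dtype=int)
            counts[occupied] = 1
            table = CommunityTable(tips, ["s"], counts)
            ours = faith_pd(table, tree)["s"]
            sk_tree = skbio.TreeNode.read(StringIO(tree.as_newick()))
            theirs = sk_faith(counts[:, 0], taxa=tips, tree=sk_tree)
            assert ours == pytest.approx(theirs, abs=1e-9)


class TestMPD:
    def test_hand_enumerated_triple(self, four_tip_tree):
        d = four_tip_tree.cophenetic_matrix()
        idx = [d.index.get_loc(t) for t in ("A", "B", "C")]
        assert mpd(np.array(idx), d.to_numpy()) == pytest.approx(10 / 3)

    def test_single_pair(self, four_tip_tree):
        d = four_tip_tree.cophenetic_matrix()
        idx = [d.index.get_loc(t) for t in ("A", "B")]
        assert mpd(np.array(idx), d.to_numpy()) == pytest.approx(2.0)

    def test_star_tree_membership_invariant(self, tmp_path):
        from phytoassembly.io import read_tree

        p = tmp_path / "star.nwk"
        p.write_text("(A:2,(B:1,C:1):1,D:2);\n")
        # star written as rooted bifurcation to pass rooting validation
        p.write_text("((A:2,B:2):0,(C:2,D:2):0);\n")
        tree = read_tree(p)
        d = tree.cophenetic_matrix().to_numpy()
        for k in (2, 3, 4):
            assert mpd(np.arange(k), d) == pytest.approx(4.0)

    def test_fewer_than_two_taxa_is_nan(self):
        assert np.isnan(mpd(np.array([0]), np.zeros((3, 3))))

    def test_brute_force_oracle_equivalence(self):
        """Double-loop enumeration on 100 random small instances, 1e-10."""
        for rep in range(100):
            tree, dmat, occupied, rng = random_instance(rep)
            d = dmat.to_numpy()
            brute = np.mean([
                d[i, j] for i, j in itertools.combinations(occupied, 2)
            ])
            assert mpd(occupied, d) == pytest.approx(brute, abs=1e-10)


def exhaustive_nri(tree: Phylogeny, occupied_labels: list[str]) -> float:
    """Oracle: NRI from the full permutation distribution of tip labels."""
    d = tree.cophenetic_matrix()
    labels = list(d.index)
    D = d.to_numpy()
    idx = [labels.index(t) for t in occupied_labels]
    obs = np.mean([D[i, j] for i, j in itertools.combinations(idx, 2)])
    null = []
    for perm in itertools.permutations(range(len(labels))):
        pidx = [perm[i] for i in idx]
        null.append(
            np.mean([D[i, j] for i, j in itertools.combinations(pidx, 2)])
        )
    null = np.asarray(null)
    return -(obs - null.mean()) / null.std(ddof=0)


class TestNRI:
    def _table(self, occupied, samples=("s1",)):
        counts = np.array([[5 if t in occupied else 0] for t in "ABCD"])
        return CommunityTable(list("ABCD"), list(samples), counts)

    @pytest.mark.parametrize(
        "occupied,sign",
        [(["A", "B"], 1), (["A", "C"], -1)],
        ids=["same-cherry-clustered", "cross-cherry-overdispersed"],
    )
    def test_monte_carlo_matches_exhaustive_enumeration(
        self, four_tip_tree, occupied, sign
    ):
        """Shuffle null vs full 4! label-permutation oracle, 3 MC SEs."""
        exact = exhaustive_nri(four_tip_tree, occupied)
        n_reps = 9999
        res = nri(
            self._table(occupied), four_tip_tree,
            NullModelConfig(n_reps=n_reps, seed=17),
        ).iloc[0]
        assert np.sign(res["nri"]) == sign
        assert np.sign(exact) == sign
        # z-estimate SE from null-mean and null-sd sampling error
        se = math.sqrt(1 / n_reps + exact**2 / (2 * n_reps))
        assert abs(res["nri"] - exact) <= 3 * se

    def test_exhaustive_null_mean_on_cherry(self, four_tip_tree):
        """Null MPD over label permutations of {A,B} is {2 x2, 4 x4}/6."""
        d = four_tip_tree.cophenetic_matrix()
        labels = list(d.index)
        D = d.to_numpy()
        vals = sorted(
            round(D[perm[labels.index("A")], perm[labels.index("B")]], 9)
            for perm in itertools.permutations(range(4))
        )
        assert vals.count(2.0) == 8 and vals.count(4.0) == 16  # 24 perms
        assert np.mean(vals) == pytest.approx(10 / 3)

    def test_star_tree_degenerate_null_flagged(self, tmp_path):
        from phytoassembly.io import read_tree

        p = tmp_path / "star.nwk"
        p.write_text("((A:2,B:2):0,(C:2,D:2):0);\n")
        tree = read_tree(p)
        res = nri(self._table(["A", "C"]), tree, NullModelConfig(99, 0)).iloc[0]
        assert not res["nri_defined"]
        assert np.isnan(res["nri"])

    def test_richness_below_two_flagged(self, four_tip_tree):
        res = nri(self._table(["A"]), four_tip_tree, NullModelConfig(99, 0)).iloc[0]
        assert not res["nri_defined"]

    def test_seed_determinism(self, four_tip_tree, four_tip_table):
        a = nri(four_tip_table, four_tip_tree, NullModelConfig(199, 3))
        b = nri(four_tip_table, four_tip_tree, NullModelConfig(199, 3))
        assert a.equals(b)
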