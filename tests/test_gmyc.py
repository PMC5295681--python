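"""GMYC: interval extraction, mixed Yule-coalescent likelihood (checked
against a brute-force evaluator), threshold fitting and newick validation."""

import numpy as np
import pytest

from clonedelim.gmyc import (
    Intervals, TreeError, UltrametricTree, branching_intervals,
    entities_at_threshold, fit_gmyc, gmyc_loglik, threshold_counts,
    chronogram_from_file,
)
from clonedelim.simulate import SimulationConfig, simulate_genealogy


def tree_from_newick(s):
    return UltrametricTree.from_newick(s)


BALANCED4 = "((A:1,B:1):2,(C:1,D:1):2);"          # node ages 3, 1, 1
CATERPILLAR3 = "((A:1,B:1):1,C:2);"               # node ages 2, 1


# ---------------------------------------------------------------------------
# brute-force likelihood oracle: walks the tree edges directly
# ---------------------------------------------------------------------------

def brute_loglik(tree, T, lam_y, p_y, lam_c, p_c, ages=None):
    """Direct re-summation of the mixed likelihood on small trees.

    Independently recomputes, for every inter-event interval, the number of
    branches crossing it, splits them into species-level lineages and
    within-entity lineages by checking each branch's position relative to
    T, and sums ln b - b x over event-terminated intervals.
    """
    n = tree.n_tips
    age = tree.age if ages is None else ages
    node_ages = sorted((float(age[v]) for v in range(n, 2 * n - 1)),
                       reverse=True)
    bounds = node_ages + [0.0]
    total = 0.0
    for i in range(len(node_ages) - 1):        # intervals ending in an event
        hi, lo = bounds[i], bounds[i + 1]
        mid = (hi + lo) / 2.0
        # branches crossing mid
        crossing = [v for v in range(2 * n - 1)
                    if tree.parent[v] >= 0
                    and age[v] < mid <= age[tree.parent[v]]]
        if mid > T:
            k = len(crossing)
            coal = 0.0
        else:
            # entity of each crossing branch: walk up to the branch that
            # crosses T
            stems = set()
            per_entity = {}
            for v in crossing:
                u = v
                while tree.parent[u] >= 0 and not (
                        age[u] < T <= age[tree.parent[u]]):
                    u = tree.parent[u]
                stems.add(u)
                per_entity[u] = per_entity.get(u, 0) + 1
            # species lineages = all entities alive (every stem crossing T)
            all_stems = [v for v in range(2 * n - 1)
                         if (tree.parent[v] >= 0
                             and age[v] < T <= age[tree.parent[v]])
                         or (tree.parent[v] < 0 and T > age[v])]
            k = len(all_stems)
            coal = sum((m * (m - 1)) ** p_c
                       for m in per_entity.values() if m > 1)
        b = lam_y * k ** p_y + lam_c * coal
        x = hi - lo
        total += np.log(b) - b * x
    return total


class TestIntervals:
    def test_balanced_four_tip_count(self):
        iv = branching_intervals(tree_from_newick(BALANCED4))
        assert len(iv.durations) == 3              # n_tips - 1

    def test_caterpillar_durations_and_counts(self):
        iv = branching_intervals(tree_from_newick(CATERPILLAR3))
        assert np.allclose(iv.durations, [1.0, 1.0])
        assert list(iv.crossings) == [2, 3]

    def test_length_conservation(self):
        tree = tree_from_newick(BALANCED4)
        iv = branching_intervals(tree)
        assert (iv.crossings * iv.durations).sum() == pytest.approx(
            tree.total_length())

    def test_tied_ages_perturbed(self):
        iv = branching_intervals(tree_from_newick(BALANCED4))
        assert iv.perturbed
        assert np.all(np.diff(iv.ages) < 0)


class TestLoglik:
    def test_hand_computed_caterpillar(self):
        # T=1.5: root event Yule, the age-1 node coalescent.
        # interval 1 spans 2->1 with 2 lineages, above T: b1 = ly*2^py
        tree = tree_from_newick(CATERPILLAR3)
        iv = branching_intervals(tree)
        ly, py, lc, pc = 0.7, 1.2, 3.0, 1.0
        b1 = ly * 2 ** py
        expect = np.log(b1) - b1 * 1.0
        got = gmyc_loglik(iv, 1.5, ly, py, lc, pc)
        assert got == pytest.approx(expect, abs=1e-9)

    def test_pure_coalescent_reduces_to_kingman_rates(self):
        # T above the root: one entity; with p_c = 1 the rate in interval i
        # is lam_c * n_i (n_i - 1) plus the (constant-k) Yule floor
        tree = tree_from_newick("(((A:1,B:1):1,C:2):1,D:3);")
        iv = branching_intervals(tree)
        ly, lc = 1e-12, 2.0
        T = 10.0
        got = gmyc_loglik(iv, T, ly, 1.0, lc, 1.0)
        expect = 0.0
        for n_i, x in zip([2, 3], iv.durations[:2]):
            b = ly * 1.0 + lc * n_i * (n_i - 1)
            expect += np.log(b) - b * x
        assert got == pytest.approx(expect, rel=1e-9)

    def test_boundary_thresholds(self):
        tree = tree_from_newick(BALANCED4)
        iv = branching_intervals(tree)
        # T=0: all events Yule; likelihood must not involve lam_c
        a = gmyc_loglik(iv, 0.0, 0.5, 1.0, 1.0, 1.0)
        b = gmyc_loglik(iv, 0.0, 0.5, 1.0, 99.0, 2.0)
        assert a == pytest.approx(b)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_brute_force_oracle_agreement(self, seed):
        cfg = SimulationConfig(n_lineages=2, within_ne_my=0.3,
                               locations=[("A", "A", 3, ("L0",)),
                                          ("B", "B", 3, ("L1",))],
                               seed=seed)
        tree, _ = simulate_genealogy(cfg, np.random.default_rng(seed))
        iv = branching_intervals(tree)
        rng = np.random.default_rng(seed + 100)
        for _ in range(5):
            T = rng.uniform(0, tree.root_age * 1.1)
            ly, lc = rng.uniform(0.1, 5, 2)
            py, pc = rng.uniform(0.2, 2, 2)
            got = gmyc_loglik(iv, T, ly, py, lc, pc)
            want = brute_loglik(tree, T, ly, py, lc, pc, ages=iv.node_age)
            assert got == pytest.approx(want, abs=1e-9)


class TestFit:
    def _five_clade_tree(self, seed):
        cfg = SimulationConfig(seed=seed)
        tree, _ = simulate_genealogy(cfg, np.random.default_rng(seed))
        return tree

    def test_five_deep_clades_recovered(self):
        tree = self._five_clade_tree(5)
        fit = fit_gmyc(tree)
        assert fit.n_ml_entities == 5
        assert fit.n_clusters == 5

    def test_lr_nonnegative_and_entities_partition(self):
        tree = self._five_clade_tree(6)
        fit = fit_gmyc(tree)
        assert fit.LR >= 0
        assert fit.logL_gmyc >= fit.logL_null - 1e-9
        tips = sorted(lab for ent in fit.entities for lab in ent)
        assert tips == sorted(tree.labels)

    def test_selected_threshold_is_argmax(self):
        tree = self._five_clade_tree(7)
        fit = fit_gmyc(tree)
        assert fit.logL_gmyc >= fit.candidate_logL.max() - 1e-6

    def test_entity_count_monotone_in_threshold(self):
        tree = self._five_clade_tree(8)
        counts = [len(entities_at_threshold(tree, T))
                  for T in np.linspace(1e-6, tree.root_age * 1.01, 25)]
        assert counts[0] == tree.n_tips
        assert counts[-1] == 1
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestNewickInput:
    def test_valid_ultrametric(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,(C:1,D:1):1);\n")
        tree = chronogram_from_file(p)
        assert tree.root_age == pytest.approx(2.0)

    def test_non_ultrametric_rejected_with_depth_report(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:2):1,C:3);\n")
        with pytest.raises(TreeError, match="not ultrametric"):
            chronogram_from_file(p)

    def test_force_ultrametric_smoothing(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1.2):1,(C:1.1,D:1):1);\n")
        tree = chronogram_from_file(p, force_ultrametric=True)
        assert np.allclose(tree.age[:4], 0.0, atol=1e-9)

    def test_polytomy_rejected(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1,C:1):1,D:2);\n")
        with pytest.raises(TreeError, match="polytomy"):
            chronogram_from_file(p)

    def test_root_trifurcation_hints_unrooted(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,B:1,C:1);\n")
        with pytest.raises(TreeError, match="unrooted"):
            chronogram_from_file(p)
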