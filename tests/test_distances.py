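"""Distance computation, group summaries, diversity and model fitting."""

import numpy as np
import pytest

from clonedelim.alignment_io import LineagePartition
from clonedelim.distances import (
    DistanceMatrix, SubstitutionModel, corrected_distance,
    difference_count_matrix, estimate_gamma_shape, fit_model,
    group_mean_distances, nucleotide_diversity, p_distance_matrix,
)
from clonedelim.simulate import LocusConfig, SimulationConfig, simulate_dataset
from conftest import make_alignment, random_alignment


class TestPDistance:
    def test_identical_sequences(self):
        D = p_distance_matrix(make_alignment(["ACGT", "ACGT"]))
        assert D.values[0, 1] == 0.0

    def test_one_difference_in_four(self):
        D = p_distance_matrix(make_alignment(["ACGT", "AGGT"]))
        assert D.values[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion(self):
        # gap column excluded for this pair: 1 difference over 3 sites
        D = p_distance_matrix(make_alignment(["AC-T", "AGGT"]))
        assert D.values[0, 1] == pytest.approx(1 / 3)

    def test_complete_deletion(self):
        aln = make_alignment(["AC-T", "AGGT", "ACGT"])
        D = p_distance_matrix(aln, pairwise_deletion=False)
        # column 3 dropped for everyone: s2 vs s3 differ at 1 of 3 sites
        assert D.values[1, 2] == pytest.approx(1 / 3)

    def test_no_comparable_sites_error(self):
        with pytest.raises(ValueError, match="s1.*s2"):
            p_distance_matrix(make_alignment(["AC--", "--GT"]))

    def test_symmetry_and_diagonal(self, rng):
        D = p_distance_matrix(random_alignment(rng, n=8, L=100))
        assert np.allclose(D.values, D.values.T)
        assert np.all(np.diag(D.values) == 0)


class TestGroupMeans:
    def _D(self, vals, ids):
        return DistanceMatrix(ids, np.array(vals, float))

    def test_two_clean_groups(self):
        vals = [[0, 0, 0.1, 0.1],
                [0, 0, 0.1, 0.1],
                [0.1, 0.1, 0, 0],
                [0.1, 0.1, 0, 0]]
        D = self._D(vals, ["a1", "a2", "b1", "b2"])
        part = LineagePartition({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        tab = group_mean_distances(D, part)
        between = tab[(tab.group_i == "A") & (tab.group_j == "B")]
        assert between["mean"].iloc[0] == pytest.approx(0.1)
        within = tab[tab.group_i == tab.group_j]
        assert (within["mean"] == 0).all()

    def test_singleton_group_degenerate(self):
        D = self._D([[0, 0.2], [0.2, 0]], ["a", "b"])
        part = LineagePartition({"a": "A", "b": "B"})
        tab = group_mean_distances(D, part)
        w = tab[(tab.group_i == "A") & (tab.group_j == "A")].iloc[0]
        assert w["mean"] == 0.0 and w.degenerate

    def test_within_mean_is_pair_average(self):
        vals = [[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]]
        D = self._D(vals, ["x", "y", "z"])
        part = LineagePartition({"x": "G", "y": "G", "z": "G"})
        tab = group_mean_distances(D, part)
        assert tab["mean"].iloc[0] == pytest.approx(0.2)

    def test_identity_partition_matches_global_mean(self, rng):
        aln = random_alignment(rng, n=7, L=80)
        D = p_distance_matrix(aln)
        part = LineagePartition({s: "all" for s in aln.sample_ids})
        tab = group_mean_distances(D, part)
        iu, ju = np.triu_indices(D.n, k=1)
        assert tab["mean"].iloc[0] == pytest.approx(D.values[iu, ju].mean())


class TestDiversity:
    def test_clones_have_zero_diversity(self):
        aln = make_alignment(["ACGT" * 10] * 4)
        cd_ = nucleotide_diversity(aln, aln.sample_ids)
        assert cd_.pi == 0.0 and cd_.mean_within_d == 0.0

    def test_direct_count(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=709))
        other = list(base)
        for i in range(7):
            other[i * 100] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[i * 100]]
        aln = make_alignment([base, "".join(other)])
        cd_ = nucleotide_diversity(aln, aln.sample_ids)
        assert cd_.mean_within_d == pytest.approx(7.0)
        assert cd_.pi == pytest.approx(7 / 709)

    def test_order_invariance(self, rng):
        aln = random_alignment(rng, n=5, L=60)
        a = nucleotide_diversity(aln, aln.sample_ids)
        b = nucleotide_diversity(aln, aln.sample_ids[::-1])
        assert a.pi == pytest.approx(b.pi)

    def test_empty_members_error(self, rng):
        with pytest.raises(ValueError):
            nucleotide_diversity(random_alignment(rng), [])


class TestCorrected:
    def test_zero_for_identical(self, rng):
        aln = make_alignment(["ACGTACGTAC", "ACGTACGTAC", "ACCTACGTAC"])
        for kind in ("JC69", "K2P"):
            D = corrected_distance(aln, kind)
            assert D.values[0, 1] == pytest.approx(0.0)
        m = SubstitutionModel()
        D = corrected_distance(aln, "GTRG", m)
        assert D.values[0, 1] == pytest.approx(0.0)

    def test_jc69_formula(self):
        p = 0.16
        d = -0.75 * np.log(1 - 4 * p / 3)
        D = DistanceMatrix(["a", "b"], np.array([[0, p], [p, 0]]))
        C = corrected_distance(D, "JC69")
        assert C.values[0, 1] == pytest.approx(d)
        assert C.values[0, 1] == pytest.approx(0.1797, abs=5e-4)

    def test_jc69_pole_reported_missing(self):
        D = DistanceMatrix(["a", "b"], np.array([[0, 0.8], [0.8, 0]]))
        with pytest.warns(UserWarning):
            C = corrected_distance(D, "JC69")
        assert np.isnan(C.values[0, 1])

    def test_k2p_hand_formula(self):
        # 2 transitions + 1 transversion over 10 sites: P=0.2, Q=0.1
        a = "AAAACCCCGG"
        b = "GAAATCCCTG"  # A->G ts, C->T ts, G->T tv
        D = corrected_distance(make_alignment([a, b]), "K2P")
        P, Q = 0.2, 0.1
        expect = -0.5 * np.log((1 - 2 * P - Q) * np.sqrt(1 - 2 * Q))
        assert D.values[0, 1] == pytest.approx(expect)

    def test_corrected_at_least_p(self, rng):
        aln = random_alignment(rng, n=6, L=400, p_gap=0.0)
        P = p_distance_matrix(aln).values
        for kind, model in (("JC69", None), ("K2P", None),
                            ("GTRG", SubstitutionModel(gamma_shape=2.0))):
            C = corrected_distance(aln, kind, model).values
            ok = ~np.isnan(C)
            assert np.all(C[ok] >= P[ok] - 1e-9)

    def test_gtrg_matches_jc_in_limit(self, rng):
        # equal exchangeabilities, uniform frequencies, no rate variation
        loci = [LocusConfig("X", 1500, 0.02, SubstitutionModel(), coding=False)]
        ds = simulate_dataset(SimulationConfig(
            n_lineages=2, loci=loci, seed=3,
            locations=[("A", "A", 3, ("L0",)), ("B", "B", 3, ("L1",))]))
        aln = ds.alignments["X"]
        jc = corrected_distance(aln, "JC69").values
        gtr = corrected_distance(aln, "GTRG", SubstitutionModel()).values
        assert np.nanmax(np.abs(jc - gtr)) < 1e-3


class TestFitModel:
    def test_empirical_frequencies(self):
        aln = make_alignment(["AACG", "AACG", "TTGC", "AACG"])
        m = fit_model(aln)
        counts = np.array([6, 4, 4, 2], float)  # A, C, G, T over all seqs
        assert np.allclose(m.base_frequencies, counts / counts.sum(),
                           atol=1e-4)

    def test_no_variable_sites_warns(self):
        with pytest.warns(UserWarning):
            m = fit_model(make_alignment(["ACGT", "ACGT"]))
        assert np.allclose(m.exchangeabilities, 1.0)

    def test_jc_exchangeabilities_recovered(self):
        # data simulated under JC: all six rates should be similar
        loci = [LocusConfig("X", 2000, 0.01, SubstitutionModel(), coding=False)]
        locs = [(f"P{i}", "X", 4, (f"L{i}",)) for i in range(5)]
        ds = simulate_dataset(SimulationConfig(
            n_lineages=5, loci=loci, locations=locs, seed=11))
        m = fit_model(ds.alignments["X"])
        ex = m.exchangeabilities
        assert ex.max() / ex.min() < 2.0

    def test_gamma_shape_monotone_in_heterogeneity(self):
        est = []
        for shape in (0.2, 1.0, 10.0):
            loci = [LocusConfig("X", 2000, 0.0115,
                                SubstitutionModel(gamma_shape=shape),
                                coding=False)]
            ds = simulate_dataset(SimulationConfig(loci=loci, seed=7))
            est.append(estimate_gamma_shape(ds.alignments["X"]))
        assert est[0] < est[1] < est[2] or np.isinf(est[2])
        assert est[0] < est[1]
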