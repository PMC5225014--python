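"""Fingerprint preprocessing, peak calling, diversity, Jaccard/ANOSIM, clustering."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster import hierarchy

from weanling import SimConfig, fingerprint, simulate
from weanling.datatypes import DistanceMatrix, FingerprintProfile, PeakSet

from conftest import random_distance_matrix


def gaussian_trace(centers, areas, sigma=1.5, lo=0.0, hi=200.0, step=0.1,
                   standards=((20.0, 20.0), (180.0, 180.0))):
    x = np.arange(lo, hi + 1e-9, step)
    y = np.zeros_like(x)
    for c, a in zip(centers, areas):
        y += a / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - c) / sigma) ** 2)
    return FingerprintProfile("t", x, y, standard_peaks=list(standards))


class TestPreprocess:
    def test_identity_on_nominal_grid(self):
        prof = gaussian_trace([100.0], [1.0])
        pre = fingerprint.preprocess_profile(prof)
        assert np.allclose(pre.positions, prof.positions, atol=1e-9)

    def test_constant_offset_invariance(self):
        prof = gaussian_trace([100.0], [1.0])
        shifted = FingerprintProfile("t", prof.positions, prof.intensities + 7.5,
                                     standard_peaks=prof.standard_peaks)
        a = fingerprint.preprocess_profile(prof)
        b = fingerprint.preprocess_profile(shifted)
        # rolling-minimum baseline removes a constant pedestal exactly
        assert np.allclose(a.intensities, b.intensities, atol=1e-6)

    def test_total_area_is_one(self):
        prof = gaussian_trace([60.0, 120.0], [2.0, 5.0])
        pre = fingerprint.preprocess_profile(prof)
        assert np.trapezoid(pre.intensities, pre.positions) == pytest.approx(1.0, abs=1e-9)

    def test_known_shift_recovered(self):
        cfg = SimConfig(seed=21, n_otus=30, trace_shift_max=5.0)
        cohort, truth = simulate.generate_cohort(cfg)
        table = simulate.simulate_otu_table(cohort, truth, cfg)
        profiles = simulate.simulate_fingerprints(table, cfg)
        planted = simulate.phylotype_positions(cfg).values
        for prof in list(profiles.values())[:5]:
            pre = fingerprint.preprocess_profile(prof)
            peaks = fingerprint.detect_peaks(pre, min_rel_height=0.05)
            for p in peaks.positions:
                assert np.min(np.abs(planted - p)) < 0.5

    def test_requires_two_standards(self):
        prof = gaussian_trace([100.0], [1.0], standards=((20.0, 20.0),))
        with pytest.raises(ValueError, match="standard"):
            fingerprint.preprocess_profile(prof)

    def test_all_zero_trace_rejected(self):
        x = np.arange(0.0, 10.0, 0.1)
        prof = FingerprintProfile("z", x, np.zeros_like(x),
                                  standard_peaks=[(1.0, 1.0), (9.0, 9.0)])
        with pytest.raises(ValueError, match="zero"):
            fingerprint.preprocess_profile(prof)


class TestDetectPeaks:
    def test_single_gaussian(self):
        pre = fingerprint.preprocess_profile(gaussian_trace([100.0], [1.0]))
        peaks = fingerprint.detect_peaks(pre)
        assert peaks.n_peaks == 1
        assert peaks.areas[0] == pytest.approx(1.0, abs=1e-9)
        assert abs(peaks.positions[0] - 100.0) < 0.2

    def test_two_equal_disjoint_gaussians(self):
        pre = fingerprint.preprocess_profile(gaussian_trace([60.0, 140.0], [1.0, 1.0]))
        peaks = fingerprint.detect_peaks(pre)
        assert peaks.n_peaks == 2
        assert np.allclose(peaks.areas, [0.5, 0.5], atol=0.01)

    def test_threshold_one_keeps_only_global_max(self):
        pre = fingerprint.preprocess_profile(gaussian_trace([60.0, 140.0], [1.0, 2.0]))
        peaks = fingerprint.detect_peaks(pre, min_rel_height=1.0)
        assert peaks.n_peaks == 1
        assert abs(peaks.positions[0] - 140.0) < 0.2


class TestAlphaDiversity:
    @pytest.mark.parametrize("areas, simpson, shannon, evenness", [
        ([1.0], 0.0, 0.0, 1.0),
        ([0.5, 0.5], 0.5, math.log(2), 1.0),
        ([0.7, 0.2, 0.1], 0.46, 0.8018185525433373, 0.8018185525433373 / math.log(3)),
    ])
    def test_analytic_values(self, areas, simpson, shannon, evenness):
        ps = PeakSet("s", np.arange(len(areas), dtype=float), np.array(areas),
                     np.array(areas))
        d = fingerprint.alpha_diversity(ps)
        assert d.simpson == pytest.approx(simpson, abs=1e-9)
        assert d.shannon == pytest.approx(shannon, abs=1e-9)
        assert d.evenness == pytest.approx(evenness, abs=1e-9)
        assert d.richness == len(areas)

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance_and_evenness_bound(self, areas):
        a = np.array(areas)
        ps1 = PeakSet("s", np.arange(a.size, dtype=float), a, a)
        perm = np.random.default_rng(0).permutation(a.size)
        ps2 = PeakSet("s", np.arange(a.size, dtype=float), a[perm], a[perm])
        d1 = fingerprint.alpha_diversity(ps1)
        d2 = fingerprint.alpha_diversity(ps2)
        assert d1.shannon == pytest.approx(d2.shannon, abs=1e-12)
        assert d1.simpson == pytest.approx(d2.simpson, abs=1e-12)
        # equal areas maximize both indices at fixed richness
        eq = np.full(a.size, 1.0 / a.size)
        ps_eq = PeakSet("s", np.arange(a.size, dtype=float), eq, eq)
        d_eq = fingerprint.alpha_diversity(ps_eq)
        assert d1.shannon <= d_eq.shannon + 1e-12
        assert d1.simpson <= d_eq.simpson + 1e-12
        assert d1.evenness <= 1.0 + 1e-12


def peakset_at(positions):
    pos = np.asarray(positions, dtype=float)
    areas = np.full(pos.size, 1.0 / pos.size)
    return PeakSet("s", pos, areas, areas)


class TestJaccard:
    def test_identical_sets_zero(self):
        d = fingerprint.binarize_and_jaccard(
            {"a": peakset_at([1, 5, 9]), "b": peakset_at([1, 5, 9])})
        assert d.values[0, 1] == 0.0

    def test_disjoint_sets_one(self):
        d = fingerprint.binarize_and_jaccard(
            {"a": peakset_at([1, 5, 9]), "b": peakset_at([20, 30, 40])})
        assert d.values[0, 1] == 1.0

    def test_partial_overlap(self):
        # bins {1,2,3} vs {2,3,4}: intersection 2, union 4
        d = fingerprint.binarize_and_jaccard(
            {"a": peakset_at([1, 2, 3]), "b": peakset_at([2, 3, 4])}, match_tol=0.4)
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_triangle_inequality(self, rng):
        sets = {f"s{i}": peakset_at(np.sort(rng.choice(np.arange(0, 100, 2.0), size=8,
                                                       replace=False)))
                for i in range(8)}
        d = fingerprint.binarize_and_jaccard(sets).values
        for i, j, k in itertools.permutations(range(8), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestAnosim:
    def test_random_grouping_mean_r_near_zero(self, rng):
        rs = []
        for _ in range(200):
            dm = random_distance_matrix(rng, 20)
            labels = np.array(["A"] * 10 + ["B"] * 10)
            rng.shuffle(labels)
            rs.append(fingerprint.anosim(dm, labels, n_permutations=0).R)
        assert abs(np.mean(rs)) < 0.05

    def test_perfect_separation_r_is_one(self):
        n = 8
        groups = ["A"] * 4 + ["B"] * 4
        vals = np.full((n, n), 0.9)
        for i in range(n):
            for j in range(n):
                if groups[i] == groups[j]:
                    vals[i, j] = 0.1
        np.fill_diagonal(vals, 0.0)
        dm = DistanceMatrix(labels=[f"s{i}" for i in range(n)], values=vals)
        res = fingerprint.anosim(dm, groups, n_permutations=99, seed=0)
        assert res.R == 1.0

    def test_p_floor(self, rng):
        # maximal observed R cannot beat itself: p >= 1/(n_perm+1)
        dm = random_distance_matrix(rng, 10)
        groups = ["A"] * 5 + ["B"] * 5
        res = fingerprint.anosim(dm, groups, n_permutations=999, seed=1)
        assert res.p_value >= 1.0 / 1000.0

    def test_exact_enumeration_matches_naive_oracle(self, rng):
        from scipy.stats import rankdata

        def oracle(dm, groups):
            d = dm.values
            n = d.shape[0]
            iu = np.triu_indices(n, 1)
            ranks = rankdata(d[iu])

            def r_stat(g):
                between = g[iu[0]] != g[iu[1]]
                return (ranks[between].mean() - ranks[~between].mean()) / (n * (n - 1) / 4)

            obs = r_stat(np.array(groups))
            perms = set(itertools.permutations(groups))
            rs = [r_stat(np.array(p)) for p in perms]
            p = np.mean([r >= obs - 1e-12 for r in rs])
            return obs, p

        for trial in range(3):
            dm = random_distance_matrix(rng, 7)
            groups = ["A", "A", "A", "B", "B", "B", "B"]
            res = fingerprint.anosim(dm, groups, exact=True)
            r_o, p_o = oracle(dm, groups)
            assert res.R == pytest.approx(r_o, abs=1e-12)
            assert res.p_value == pytest.approx(p_o, abs=1e-12)

    def test_matches_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as sk_anosim

        dm = random_distance_matrix(rng, 12)
        groups = ["A"] * 6 + ["B"] * 6
        res = fingerprint.anosim(dm, groups, n_permutations=99, seed=0)
        sk = sk_anosim(skbio.DistanceMatrix(dm.values, ids=dm.labels),
                       grouping=list(groups), permutations=99)
        assert res.R == pytest.approx(sk["test statistic"], abs=1e-12)

    def test_group_of_one_rejected(self, rng):
        dm = random_distance_matrix(rng, 5)
        with pytest.raises(ValueError, match="members"):
            fingerprint.anosim(dm, ["A", "A", "A", "A", "B"])

    def test_null_p_values_are_uniform(self, rng):
        # reduced-size check: 300 null runs at 199 permutations
        from scipy.stats import kstest
        ps = []
        for _ in range(300):
            dm = random_distance_matrix(rng, 12)
            labels = np.array(["A"] * 6 + ["B"] * 6)
            rng.shuffle(labels)
            ps.append(fingerprint.anosim(dm, labels, n_permutations=199,
                                         seed=int(rng.integers(2**31))).p_value)
        stat = kstest(ps, "uniform").statistic
        assert stat < 0.08


class TestDendrogram:
    def test_two_tight_blocks_split_first(self):
        n = 6
        vals = np.full((n, n), 0.9)
        vals[:3, :3] = 0.05
        vals[3:, 3:] = 0.05
        np.fill_diagonal(vals, 0.0)
        dm = DistanceMatrix(labels=list("abcdef"), values=vals)
        link = fingerprint.cluster_dendrogram(dm)
        cut = hierarchy.fcluster(link, t=2, criterion="maxclust")
        assert len(set(cut[:3])) == 1 and len(set(cut[3:])) == 1
        assert cut[0] != cut[3]

    def test_equal_distances_equal_heights(self):
        n = 5
        vals = np.full((n, n), 0.7)
        np.fill_diagonal(vals, 0.0)
        dm = DistanceMatrix(labels=[f"s{i}" for i in range(n)], values=vals)
        link = fingerprint.cluster_dendrogram(dm)
        assert np.allclose(link[:, 2], 0.7)

    def test_two_samples_single_merge(self):
        dm = DistanceMatrix(labels=["a", "b"], values=np.array([[0.0, 0.3], [0.3, 0.0]]))
        link = fingerprint.cluster_dendrogram(dm)
        assert link.shape[0] == 1
        assert link[0, 2] == pytest.approx(0.3)

    def test_newick_roundtrip_leaves(self):
        dm = random_distance_matrix(np.random.default_rng(0), 6)
        link = fingerprint.cluster_dendrogram(dm)
        nwk = fingerprint.linkage_to_newick(link, dm.labels)
        assert nwk.endswith(";")
        for lab in dm.labels:
            assert lab in nwk
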