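"""Enrichment, clustering, intra-TAD and CRISPR statistics against oracles."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from foldscreen.containers import ContactMatrix, GenomicIntervalSet
from foldscreen.stats import (TFProfile, cluster_factors, crispr_gene_scores,
                              distance_normalize, intra_tad_changes,
                              tf_enrichment)


def interval_set(triples):
    return GenomicIntervalSet(pd.DataFrame(triples,
                                           columns=["chrom", "start", "end"]))


def hypergeom_fisher_two_sided(a, b, c, d):
    """Oracle: exact two-sided Fisher p by enumerating all tables with the
    same margins and summing those no more probable than the observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestTFEnrichment:
    def _universe(self, n=1000, width=1000):
        return interval_set([("c", i * width, (i + 1) * width) for i in range(n)])

    def _profile_over(self, loci, name="tf", n_exp=2, width=1000):
        iv = interval_set([("c", int(l) * width + 200, int(l) * width + 700)
                           for l in loci])
        iv.df["name"] = name
        return TFProfile(name, iv, n_exp)

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        """Table (10, 90; 5, 895): odds ratio 19.888..., p from the tail oracle."""
        elements_loci = range(100)
        universe = self._universe(1000)
        elements = interval_set([("c", i * 1000, (i + 1) * 1000)
                                 for i in elements_loci])
        profile_loci = list(range(10)) + list(range(100, 105))
        prof = self._profile_over(profile_loci)
        df = tf_enrichment(elements, [prof], universe, min_hits=1)
        row = df.iloc[0]
        assert (row.a, row.b, row.c, row.d) == (10, 90, 5, 895)
        assert row.odds_ratio == pytest.approx((10 * 895) / (90 * 5))
        assert row.odds_ratio == pytest.approx(19.888, abs=1e-3)
        assert row.p == pytest.approx(
            hypergeom_fisher_two_sided(10, 90, 5, 895), rel=1e-8)

    def test_small_table_p_values_match_oracle_exhaustively(self):
        rng = np.random.default_rng(0)
        for _ in range(8):
            n_univ = 40
            universe = self._universe(n_univ)
            el = rng.choice(n_univ, size=12, replace=False)
            elements = interval_set([("c", int(i) * 1000, (int(i) + 1) * 1000)
                                     for i in el])
            pr = rng.choice(n_univ, size=15, replace=False)
            prof = self._profile_over(pr)
            df = tf_enrichment(elements, [prof], universe, min_hits=1)
            row = df.iloc[0]
            assert row.p == pytest.approx(hypergeom_fisher_two_sided(
                int(row.a), int(row.b), int(row.c), int(row.d)), rel=1e-8)

    def test_filters_drop_sparse_and_single_experiment_profiles(self):
        universe = self._universe(100)
        elements = interval_set([("c", 0, 1000)])
        small = self._profile_over(range(5), "small")
        single = self._profile_over(range(50), "single", n_exp=1)
        kept = self._profile_over(range(50), "kept")
        df = tf_enrichment(elements, [small, single, kept], universe, min_hits=20)
        assert list(df["factor"]) == ["kept"]

    def test_oversized_profile_downsampled_deterministically(self):
        universe = self._universe(200)
        elements = interval_set([("c", 0, 1000)])
        big = self._profile_over(np.repeat(np.arange(200), 2), "big")
        df1 = tf_enrichment(elements, [big], universe, min_hits=1,
                            downsample_above=100, seed=5)
        df2 = tf_enrichment(elements, [big], universe, min_hits=1,
                            downsample_above=100, seed=5)
        pd.testing.assert_frame_equal(df1, df2)

    def test_degenerate_full_overlap_is_continuity_corrected(self):
        universe = self._universe(50)
        elements = interval_set([("c", 0, 1000)])
        prof = self._profile_over(range(50), "all")
        df = tf_enrichment(elements, [prof], universe, min_hits=1)
        assert df.iloc[0]["corrected"]
        assert np.isfinite(df.iloc[0]["odds_ratio"])

    def test_bh_q_values_monotone_after_sorting_by_p(self):
        rng = np.random.default_rng(1)
        universe = self._universe(300)
        elements = interval_set([("c", i * 1000, (i + 1) * 1000)
                                 for i in range(40)])
        profiles = [self._profile_over(rng.choice(300, size=60, replace=False),
                                       f"tf{i}") for i in range(12)]
        df = tf_enrichment(elements, profiles, universe, min_hits=1)
        s = df.sort_values("p")
        assert (np.diff(s["q"]) >= -1e-12).all()
        assert (s["q"] >= s["p"] - 1e-12).all()

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            tf_enrichment(interval_set([("c", 0, 10)]), [], GenomicIntervalSet())


class TestClusterFactors:
    def test_well_separated_rows_get_distinct_clusters(self):
        odds = pd.DataFrame({"ct1": [1.0, 100.0, 1.0], "ct2": [1.0, 1.0, 100.0]},
                            index=["a", "b", "c"])
        labels = cluster_factors(odds, k=3, seed=0)
        assert len(set(labels)) == 3

    def test_two_blobs_recovered_against_brute_force_partition(self):
        rng = np.random.default_rng(2)
        blob1 = rng.normal(0.1, 0.01, size=(5, 2))
        blob2 = rng.normal(0.9, 0.01, size=(5, 2))
        X = pd.DataFrame(np.vstack([blob1, blob2]))
        labels = cluster_factors(X, k=2, seed=0, normalize=None)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[9]
        # brute-force 2-partition minimizer over all assignments agrees
        pts = X.to_numpy()
        best, best_cost = None, np.inf
        for mask in range(1, 2 ** 10 - 1):
            lab = np.array([(mask >> i) & 1 for i in range(10)])
            cost = sum(((pts[lab == g] - pts[lab == g].mean(axis=0)) ** 2).sum()
                       for g in (0, 1) if (lab == g).any())
            if cost < best_cost:
                best, best_cost = lab, cost
        assert (best[:5] == best[0]).all() and (best[5:] == best[9]).all()
        assert best_cost == pytest.approx(labels.attrs["inertia"], rel=1e-6)

    def test_row_permutation_gives_same_partition(self):
        rng = np.random.default_rng(3)
        centers = np.array([[0.1, 0.1, 0.1], [0.5, 0.9, 0.2], [0.9, 0.3, 0.8]])
        X = pd.DataFrame(np.vstack([c + rng.normal(0, 0.02, (4, 3))
                                    for c in centers]))
        labels = cluster_factors(X, k=3, seed=0)
        perm = rng.permutation(12)
        labels_p = cluster_factors(X.iloc[perm], k=3, seed=0)
        # same partition up to label renaming
        for i in range(12):
            for j in range(12):
                same_orig = labels.iloc[perm[i]] == labels.iloc[perm[j]]
                same_perm = labels_p.iloc[i] == labels_p.iloc[j]
                assert same_orig == same_perm


class TestDistanceNormalize:
    def cm(self, v):
        return ContactMatrix(np.asarray(v, float), 1000, transform="raw")

    def test_constant_diagonals_normalize_to_inverse_stratum_size(self):
        n = 6
        V = np.fromfunction(lambda i, j: 2.0 + np.abs(i - j), (n, n))
        out = distance_normalize(self.cm(V))
        for d in range(n):
            diag = np.diagonal(out.values, d)
            np.testing.assert_allclose(diag, 1.0 / (n - d))

    def test_diagonal_sums_are_one(self):
        rng = np.random.default_rng(4)
        out = distance_normalize(self.cm(rng.uniform(0.1, 5, (15, 15))))
        for d in range(15):
            assert np.diagonal(out.values, d).sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_diagonal_preserved_without_nan(self):
        V = np.zeros((5, 5))
        V[0, 0] = 1.0
        out = distance_normalize(self.cm(V))
        assert np.isfinite(out.values).all()
        assert np.diagonal(out.values, 2).sum() == 0.0


class TestIntraTAD:
    def make_pair(self, shift_tad=None, delta=0.2, n=30, seed=5):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.3, 1.1, (n, n))
        base = 0.5 * (base + base.T)
        S1 = ContactMatrix(base, 1000, transform="raw")
        v2 = base.copy()
        if shift_tad is not None:
            b0, b1 = shift_tad
            v2[b0:b1, b0:b1] += delta
        S2 = ContactMatrix(v2, 1000, transform="raw")
        tads = interval_set([("chr", 0, 10_000), ("chr", 10_000, 20_000),
                             ("chr", 20_000, 30_000)])
        return S1, S2, tads

    def test_identical_samples_are_all_stable_with_zero_change(self):
        S1, S2, tads = self.make_pair()
        recs = intra_tad_changes(S1, S1.copy(), tads)
        assert all(r.label == "Stable" for r in recs)
        assert all(r.change == 0 for r in recs)
        assert all(r.flagged for r in recs)      # zero-variance differences

    def test_constructed_within_tad_gain_is_classified(self):
        S1, S2, tads = self.make_pair(shift_tad=(10, 20), delta=0.2)
        recs = intra_tad_changes(S1, S2, tads)
        assert recs[1].change == pytest.approx(0.2)
        assert recs[1].label == "Gain"
        assert recs[0].label == "Stable" and recs[2].label == "Stable"
        # loss direction mirrors
        recs_rev = intra_tad_changes(S2, S1, tads)
        assert recs_rev[1].label == "Loss"

    def test_thresholds_are_strict_inequalities(self):
        """A change of exactly 0.1 (and log2fc exactly 0.25) stays Stable."""
        n = 20
        base = np.full((n, n), 1.0)
        jitter = np.triu(np.random.default_rng(0).normal(0, 1e-6, (n, n)))
        base = base + jitter + jitter.T
        S1 = ContactMatrix(base, 1000, transform="raw")
        v2 = base * (2 ** 0.25)     # log2fc exactly 0.25 (up to jitter)
        S2 = ContactMatrix(v2, 1000, transform="raw")
        tads = interval_set([("chr", 0, 10_000)])
        recs = intra_tad_changes(S1, S2, tads, change_threshold=
                                 float(np.mean(v2 - base)))
        assert recs[0].label == "Stable"


class TestCrisprScores:
    def make_counts(self, day4, day20, genes=None):
        n = len(day4)
        return pd.DataFrame({"guide": [f"g{i}" for i in range(n)],
                             "gene": genes or ["G1"] * n,
                             "day4": day4, "day20": day20})

    def test_identical_libraries_score_null(self):
        counts = self.make_counts([100, 200, 300], [100, 200, 300])
        df = crispr_gene_scores(counts)
        assert df.iloc[0]["mean_fc"] == pytest.approx(1.0)
        assert df.iloc[0]["log2fc"] == pytest.approx(0.0)
        assert np.isnan(df.iloc[0]["p"])     # zero variance -> no test

    def test_hand_computed_t_statistic(self):
        """Guides (200,100) day4 vs (100,100) day20 -> fold changes (2,1)."""
        counts = self.make_counts([200, 100], [100, 100])
        df = crispr_gene_scores(counts)
        total4, total20 = 300, 200
        fc = np.array([(200 / total4) / (100 / total20),
                       (100 / total4) / (100 / total20)])
        assert df.iloc[0]["mean_fc"] == pytest.approx(fc.mean())
        # textbook one-sample t against 1
        t = (fc.mean() - 1) / (fc.std(ddof=1) / np.sqrt(2))
        from scipy import stats as sps
        p = 2 * sps.t.sf(abs(t), df=1)
        assert df.iloc[0]["p"] == pytest.approx(p, rel=1e-10)

    def test_scaling_day4_counts_is_invariant(self):
        c1 = self.make_counts([50, 80, 20], [40, 90, 30])
        c2 = self.make_counts([100, 160, 40], [40, 90, 30])
        pd.testing.assert_frame_equal(crispr_gene_scores(c1),
                                      crispr_gene_scores(c2))

    def test_zero_day20_count_gets_pseudocount_and_flag(self):
        counts = self.make_counts([100, 100], [0, 100])
        df = crispr_gene_scores(counts)
        assert df.iloc[0]["flagged"]
        assert np.isfinite(df.iloc[0]["mean_fc"])

    def test_multiple_genes_scored_independently(self):
        counts = self.make_counts([100, 150, 30, 60], [100, 100, 60, 60],
                                  genes=["A", "A", "B", "B"])
        df = crispr_gene_scores(counts)
        assert list(df["gene"]) == ["A", "B"]
        assert (df["n_guides"] == 2).all()
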