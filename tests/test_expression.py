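"""Normalization, PAM clustering, cluster profiles and DEG-target association."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from cobind.expression import (
    PAM,
    cluster_category_enrichment,
    cluster_profiles,
    deg_target_association,
    normalize_counts,
    pam_cluster,
)
from cobind.genes import GeneModel, build_gene_database
from cobind.simulate import generate_genes_and_counts


class TestNormalizeCounts:
    def test_identical_samples_center_to_zero(self):
        counts = pd.DataFrame({"s1": [10, 20], "s2": [10, 20]})
        norm = normalize_counts(counts)
        assert np.allclose(norm.to_numpy(), 0.0)

    def test_frozen_profile_equal_depth(self):
        # one gene (100,100,200,200) among a constant backdrop at equal depth:
        # by the stated transform the centered profile is ±log2(201/101)/2
        counts = pd.DataFrame(
            {
                "s1": [100, 1000], "s2": [100, 1000],
                "s3": [200, 900], "s4": [200, 900],
            }
        )
        norm = normalize_counts(counts)
        half_gap = (math.log2(201) - math.log2(101)) / 2
        got = norm.iloc[0].to_numpy()
        depth_ratio = counts.sum(axis=0).mean() / counts.sum(axis=0)
        scaled = np.log2(100 * np.array([1, 1, 2, 2]) * depth_ratio + 1)
        np.testing.assert_allclose(got, scaled - scaled.mean(), atol=1e-12)
        # equal-depth idealization: gap close to 2*half_gap
        assert got[3] - got[0] == pytest.approx(2 * half_gap, abs=0.1)

    def test_library_size_invariance_at_high_counts(self):
        rng = np.random.default_rng(0)
        base = rng.integers(100, 5000, size=(50, 4))
        counts = pd.DataFrame(base, columns=list("abcd"))
        doubled = counts.copy()
        doubled["a"] = counts["a"] * 2
        n1 = normalize_counts(counts)
        n2 = normalize_counts(doubled)
        assert np.allclose(n1["a"], n2["a"], atol=0.01)

    def test_all_zero_rows_dropped_with_warning(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [0, 7]})
        with pytest.warns(UserWarning, match="all-zero"):
            norm = normalize_counts(counts)
        assert len(norm) == 1

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            normalize_counts(pd.DataFrame({"a": [1, 2]}))


class TestPAM:
    def test_separated_blobs_1d(self):
        X = np.array([[0.0], [0.1], [0.2], [10.0], [10.1]])
        est = PAM(n_clusters=2).fit(X)
        labels = est.labels_
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4]
        assert labels[0] != labels[3]

    def test_duplicated_dataset_invariance(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(6, 1, (20, 3))])
        base = PAM(n_clusters=2).fit(X)
        dup = PAM(n_clusters=2).fit(np.vstack([X, X]))
        assert adjusted_rand_score(
            np.tile(base.labels_, 2), dup.labels_
        ) == pytest.approx(1.0)

    def test_deterministic_for_fixed_input(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 4))
        a = PAM(n_clusters=3).fit(X)
        b = PAM(n_clusters=3).fit(X)
        assert np.array_equal(a.labels_, b.labels_)
        assert np.array_equal(a.medoid_indices_, b.medoid_indices_)

    def test_swap_does_not_increase_objective(self):
        # the SWAP-refined solution is never worse than assigning to the
        # BUILD medoids directly
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 5))
        from sklearn.metrics import pairwise_distances
        from cobind.expression import _pam_fit

        D = pairwise_distances(X)
        _, _, cost = _pam_fit(D, 4, max_iter=100)
        _, _, cost_build_only = _pam_fit(D, 4, max_iter=0)
        assert cost <= cost_build_only + 1e-9

    def test_sklearn_estimator_protocol(self):
        est = PAM(n_clusters=3, metric="euclidean")
        params = est.get_params()
        assert params["n_clusters"] == 3
        est2 = clone(est).set_params(n_clusters=4)
        assert est2.get_params()["n_clusters"] == 4
        X = np.random.default_rng(0).normal(size=(20, 2))
        labels = est.fit_predict(X)
        assert len(labels) == 20 and hasattr(est, "inertia_")

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            pam_cluster(pd.DataFrame(np.eye(3)), k=10)


class TestClusterProfiles:
    def _clustering(self, genes, k=1):
        from cobind.expression import Clustering

        labels = pd.Series(1, index=pd.Index(genes))
        return Clustering(labels, [genes[0]], k, 1.0)

    def test_identical_genes_profile(self):
        mat = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0]] * 3,
            index=["g1", "g2", "g3"],
            columns=["a1", "a2", "b1", "b2"],
        )
        gmap = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        prof = cluster_profiles(mat, self._clustering(["g1", "g2", "g3"]), gmap)
        assert prof.loc[1, "A"] == pytest.approx(1.5)
        assert prof.loc[1, "B"] == pytest.approx(3.5)

    def test_flat_genotypes_flat_profile(self):
        mat = pd.DataFrame(
            [[2.0, 2.0], [5.0, 5.0]], index=["g1", "g2"], columns=["a1", "b1"]
        )
        prof = cluster_profiles(mat, self._clustering(["g1", "g2"]), {"a1": "A", "b1": "B"})
        assert prof.loc[1, "A"] == prof.loc[1, "B"]

    def test_missing_genotype_rejected(self):
        mat = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["a1", "b1"])
        with pytest.raises(ValueError):
            cluster_profiles(mat, self._clustering(["g1"]), {"a1": "A"})

    def test_planted_effect_recovered(self, small_scenario):
        genes, counts, sheet, truth = generate_genes_and_counts(small_scenario)
        norm = normalize_counts(counts)
        clustering = pam_cluster(norm.loc[truth.deg_genes], k=5)
        gmap = dict(zip(sheet["sample"], sheet["genotype"]))
        prof = cluster_profiles(norm, clustering, gmap)
        # every planted archetype moves some genotype by ±2 log2 units
        # around its own mean; the recovered profiles must show ~that range
        spread = prof.max(axis=1) - prof.min(axis=1)
        assert (spread > 1.5).all()


class TestDegTargetAssociation:
    def test_targets_equal_degs(self):
        bg = {f"g{i}" for i in range(100)}
        degs = {f"g{i}" for i in range(20)}
        res = deg_target_association(degs, degs, bg)
        assert res.odds_ratio == math.inf
        assert res.p_value < 1e-10

    def test_toy_table_sample_or(self):
        bg = [f"g{i}" for i in range(300)]
        degs = set(bg[:30])
        targets = set(bg[:10]) | set(bg[30:60])
        res = deg_target_association(degs, targets, bg, or_estimator="sample")
        np.testing.assert_array_equal(res.table, [[10, 20], [30, 240]])
        assert res.odds_ratio == pytest.approx(4.0)

    def test_independent_sets_or_near_one(self):
        rng = np.random.default_rng(4)
        bg = np.array([f"g{i}" for i in range(5000)])
        ors = []
        for _ in range(20):
            degs = set(rng.choice(bg, 500, replace=False))
            targets = set(rng.choice(bg, 1000, replace=False))
            ors.append(deg_target_association(degs, targets, set(bg)).odds_ratio)
        assert np.median(ors) == pytest.approx(1.0, abs=0.15)


def test_cluster_category_enrichment_planted(small_sim):
    """Genes overlapping planted PRC2 bins, put in one cluster, enrich that cell."""
    sim = small_sim
    truth = sim.truth
    genes = [g.gene_id for g in sim.genes]
    prc2 = [g for g in genes if "PRC2" in truth.gene_complexes[g]]
    annotations = {
        t: set() for t in
        ["UBP5", "EPCR1", "PWWP1", "HAM1", "EPL1B", "JMJ14", "TRB2", "TRB3"]
    }
    annotations["CLF"] = set(prc2)
    annotations["SWN"] = set(prc2)
    annotations["TRB1"] = set(genes)  # everything TRB-bound so no no-TRB bucket
    db = build_gene_database(annotations, sim.genes)

    from cobind.expression import Clustering

    # cluster 1 = planted PRC2 genes plus noise, cluster 2 = the rest (sampled)
    rng = np.random.default_rng(0)
    others = [g for g in genes if g not in set(prc2)]
    c1 = prc2 + list(rng.choice(others, 20, replace=False))
    labels = pd.Series(
        [1] * len(c1) + [2] * 100,
        index=c1 + [g for g in others if g not in set(c1)][:100],
    )
    clustering = Clustering(labels, [], 2, 0.5)
    grid = cluster_category_enrichment(clustering, db)
    cell = grid[(grid.label_a == "cluster1") & (grid.label_b == "PRC2")].iloc[0]
    assert cell["fold_enrichment"] > 1.5
    col = grid[grid.label_b == "PRC2"]
    assert cell["p_enrichment"] == col["p_enrichment"].min()
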