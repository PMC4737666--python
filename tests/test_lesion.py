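import numpy as np
import pytest

from conngeo.embedding import Embedding
from conngeo.io import WeightedConnectome
from conngeo.lesion import (
    dbar,
    normalized_dbar,
    random_removal_distribution,
    removal_count,
    remove_nodes,
    scheme_ordering,
    targeted_removal,
)
from conngeo.metrics import clustering_coefficient, nodal_strength
from conftest import random_connected_connectome


class TestRemoveNodes:
    def test_leaf_removal_leaves_smaller_star(self, star_connectome):
        survivor = remove_nodes(star_connectome, ["L3"])
        assert survivor.n == 3
        assert survivor.labels == ("H", "L1", "L2")
        assert np.array_equal(survivor.weights, star_connectome.weights[:3, :3])

    def test_hub_removal_disconnects(self, star_connectome):
        with pytest.raises(ValueError, match="disconnect"):
            remove_nodes(star_connectome, ["H"])

    def test_surviving_weights_untouched(self, connectome_factory):
        c = connectome_factory(np.random.default_rng(0), 20)
        survivor = remove_nodes(c, [3, 7])
        keep = [i for i in range(20) if i not in (3, 7)]
        assert np.array_equal(survivor.weights, c.weights[np.ix_(keep, keep)])

    def test_paper_fraction_arithmetic(self):
        assert removal_count(0.215, 620) == 133  # 620 - 133 = 487 survivors
        assert removal_count(0.215, 200) == 43


class TestDbar:
    def test_unit_sphere_gives_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(50, 3))
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
        pair = np.vstack([v, -v])  # antipodal pairs: centroid exactly at origin
        e = Embedding(pair, "isomap", np.ones(3))
        assert dbar(e) == pytest.approx(1.0)

    def test_homogeneous_scaling(self):
        coords = np.random.default_rng(1).normal(size=(30, 3))
        coords -= coords.mean(axis=0)
        e1 = Embedding(coords, "isomap", np.ones(3))
        e2 = Embedding(coords * 4.0, "isomap", np.ones(3))
        assert dbar(e2) == pytest.approx(4.0 * dbar(e1))

    def test_matches_mean_of_norms(self):
        coords = np.random.default_rng(2).normal(size=(25, 3))
        coords -= coords.mean(axis=0)
        e = Embedding(coords, "isomap", np.ones(3))
        assert dbar(e) == pytest.approx(np.linalg.norm(coords, axis=1).mean(), abs=1e-12)

    def test_orthogonal_invariance(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(20, 3))
        coords -= coords.mean(axis=0)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert dbar(Embedding(coords, "isomap", np.ones(3))) == pytest.approx(
            dbar(Embedding(coords @ q, "isomap", np.ones(3))), abs=1e-12)


class TestNormalizedDbar:
    def test_simple_product(self):
        w = np.full((3, 3), 3.0)
        np.fill_diagonal(w, 0.0)
        c = WeightedConnectome(w)
        assert normalized_dbar(2.0, c) == pytest.approx(6.0)

    def test_unit_multiplier_is_identity(self):
        w = np.full((4, 4), 1.0)
        np.fill_diagonal(w, 0.0)
        c = WeightedConnectome(w)
        assert normalized_dbar(1.7, c) == pytest.approx(1.7)

    def test_weight_scaling_cancels_in_normalized_dbar(self, default_synthetic):
        c, t = default_synthetic
        r1 = targeted_removal(c, "strength", 0.2, table=t)
        c2 = WeightedConnectome(c.weights * 5.0, c.labels)
        r2 = targeted_removal(c2, "strength", 0.2, table=t)
        assert r1.removed == r2.removed
        # geodesics scale 1/s, the embedding scales 1/s, the multiplier scales s
        assert r2.dbar_raw == pytest.approx(r1.dbar_raw / 5.0, rel=1e-9)
        assert r2.dbar_normalized == pytest.approx(r1.dbar_normalized, rel=1e-9)


class TestTargetedRemoval:
    def test_strength_scheme_removes_strongest(self, default_synthetic):
        c, t = default_synthetic
        order = scheme_ordering(c, "strength")
        s = nodal_strength(c)
        assert np.array_equal(order, np.argsort(-s, kind="stable"))
        r = targeted_removal(c, "strength", 0.1, table=t)
        removed_idx = {c.index_of(lbl) for lbl in r.removed}
        assert removed_idx == set(order[: removal_count(0.1, c.n)].tolist())

    def test_clustering_scheme_is_ascending(self, default_synthetic):
        c, _ = default_synthetic
        order = scheme_ordering(c, "clustering")
        cl = clustering_coefficient(c)
        assert np.array_equal(order, np.argsort(cl, kind="stable"))

    def test_rich_club_scheme_takes_flagged_nodes(self, default_synthetic):
        c, t = default_synthetic
        r = targeted_removal(c, "rich_club", 0.215, table=t)
        flagged = {t.label[i] for i in np.flatnonzero(t.rich_club)}
        assert set(r.removed) == flagged

    def test_custom_ranking_descending(self, default_synthetic):
        c, t = default_synthetic
        rng = np.random.default_rng(5)
        ranking = rng.random(c.n)
        order = scheme_ordering(c, "custom", ranking=ranking)
        assert np.array_equal(order, np.argsort(-ranking, kind="stable"))

    def test_unknown_scheme_rejected(self, default_synthetic):
        c, t = default_synthetic
        with pytest.raises(ValueError, match="unknown scheme"):
            targeted_removal(c, "degree", 0.1, table=t)

    def test_result_counts_and_embedding(self, default_synthetic):
        c, t = default_synthetic
        r = targeted_removal(c, "betweenness", 0.1, table=t, embed_dim=3)
        assert len(r.removed) == removal_count(0.1, c.n)
        assert r.embedding.n == c.n - len(r.removed)
        assert r.dbar_raw > 0 and r.dbar_normalized > 0


class TestRandomRemoval:
    def test_same_seed_reproduces(self, connectome_factory):
        c = connectome_factory(np.random.default_rng(10), 40)
        d1 = random_removal_distribution(c, 0.2, trials=5, seed=42)
        d2 = random_removal_distribution(c, 0.2, trials=5, seed=42)
        assert np.array_equal(d1.dbar_values, d2.dbar_values)

    def test_single_trial_interval_collapses(self, connectome_factory):
        c = connectome_factory(np.random.default_rng(11), 30)
        d = random_removal_distribution(c, 0.2, trials=1, seed=0)
        assert d.interval[0] == d.interval[1] == d.mean

    def test_interval_brackets_mean(self, connectome_factory):
        c = connectome_factory(np.random.default_rng(12), 40)
        d = random_removal_distribution(c, 0.2, trials=25, seed=3)
        assert d.interval[0] <= d.mean <= d.interval[1]
        assert len(d.dbar_values) == 25

    def test_mean_stable_across_seeds(self, connectome_factory):
        c = connectome_factory(np.random.default_rng(13), 60)
        d1 = random_removal_distribution(c, 0.2, trials=150, seed=101)
        d2 = random_removal_distribution(c, 0.2, trials=150, seed=202)
        se = np.hypot(d1.dbar_values.std(ddof=1) / np.sqrt(d1.trials),
                      d2.dbar_values.std(ddof=1) / np.sqrt(d2.trials))
        assert abs(d1.mean - d2.mean) < 3 * se
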