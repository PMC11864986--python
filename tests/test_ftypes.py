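"""Exemplar finding, dendrogram cutting and f-type assignment."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from tectomap.ftypes import (
    assign_ftypes,
    cluster_exemplars,
    embed_scores,
    find_exemplars,
)


def _blobs(rng, centers, n_per, sd):
    X = np.vstack([c + rng.normal(0, sd, (n_per, len(c))) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return X, labels


class TestFindExemplars:
    def test_three_blobs_yield_three_exemplars_matching_medoids(self, rng):
        """AP exemplars on separated blobs equal the per-blob squared-distance medoids."""
        centers = np.array([[0, 0, 0, 0, 0, 0, 0, 0],
                            [10, 0, 0, 0, 0, 0, 0, 0],
                            [0, 10, 0, 0, 0, 0, 0, 0]], dtype=float)
        X, truth = _blobs(rng, centers, 100, 0.3)
        ex = find_exemplars(X)
        assert ex.n_exemplars == 3
        # each exemplar sits in its own blob
        blob_of_ex = truth[ex.exemplar_indices]
        assert sorted(blob_of_ex) == [0, 1, 2]
        # exhaustive per-blob medoid oracle under squared Euclidean distance
        for b in range(3):
            idx = np.flatnonzero(truth == b)
            d2 = ((X[idx, None, :] - X[None, idx, :]) ** 2).sum(-1)
            medoid = idx[d2.sum(axis=0).argmin()]
            assert medoid in ex.exemplar_indices
        # membership follows the blobs
        assert adjusted_rand_score(truth, ex.member_of) == 1.0

    def test_duplication_preserves_exemplar_locations(self, rng):
        centers = np.array([[0.0] * 8, [8.0] * 8])
        X, _ = _blobs(rng, centers, 50, 0.2)
        # exact duplicates make the message-passing symmetric; heavier
        # damping is needed for the ties to settle
        ex1 = find_exemplars(X, damping=0.8)
        ex2 = find_exemplars(np.vstack([X, X]), damping=0.8)
        v1 = {tuple(np.round(v, 9)) for v in ex1.exemplar_vectors}
        v2 = {tuple(np.round(v, 9)) for v in ex2.exemplar_vectors}
        assert v1 == v2

    def test_single_point_is_its_own_exemplar(self):
        ex = find_exemplars(np.array([[1.0, 2.0]]))
        assert list(ex.exemplar_indices) == [0]
        assert list(ex.member_of) == [0]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            find_exemplars(np.array([[np.nan, 0.0], [1.0, 1.0]]))


def _naive_complete_linkage_maxclust(vectors, k):
    """O(n^3) agglomeration on correlation distance, stopped at k clusters."""

    def corr_dist(u, v):
        uc, vc = u - u.mean(), v - v.mean()
        return 1.0 - float(uc @ vc / np.sqrt((uc @ uc) * (vc @ vc)))

    clusters = [[i] for i in range(len(vectors))]
    while len(clusters) > k:
        best, pair = np.inf, None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(
                    corr_dist(vectors[a], vectors[b])
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if d < best:
                    best, pair = d, (i, j)
        i, j = pair
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    labels = np.empty(len(vectors), dtype=int)
    for lab, members in enumerate(clusters):
        labels[members] = lab
    return labels


class _FakeExemplars:
    """Minimal stand-in exposing arbitrary exemplar vectors and member counts."""

    def __init__(self, vectors, counts):
        from tectomap.ftypes import ExemplarSet

        member_of = np.repeat(np.arange(len(vectors)), counts)
        self._set = ExemplarSet(
            vectors=np.asarray(vectors, dtype=float),
            exemplar_indices=np.arange(len(vectors)),
            member_of=member_of,
        )

    def __getattr__(self, name):
        return getattr(self._set, name)


class TestClusterExemplars:
    def test_k_equal_to_exemplar_count_gives_singletons(self, rng):
        vecs = rng.normal(0, 1, (6, 8))
        ex = _FakeExemplars(vecs, [12] * 6)._set
        a = cluster_exemplars(ex, k=6, min_members=10)
        assert len(set(a.exemplar_ftype)) == 6

    def test_perfect_anticorrelation_splits_two_ways(self):
        v = np.array([1.0, -1.0, 2.0, 0.5, -0.5, 1.5, 0.0, -2.0])
        vecs = np.vstack([2 * v, 3 * v + 1, -v, -2 * v + 0.5])
        ex = _FakeExemplars(vecs, [20] * 4)._set
        a = cluster_exemplars(ex, k=2, min_members=10)
        assert a.exemplar_ftype[0] == a.exemplar_ftype[1]
        assert a.exemplar_ftype[2] == a.exemplar_ftype[3]
        assert a.exemplar_ftype[0] != a.exemplar_ftype[2]

    def test_matches_naive_agglomeration_oracle(self, rng):
        vecs = rng.normal(0, 1, (12, 8))
        ex = _FakeExemplars(vecs, [15] * 12)._set
        a = cluster_exemplars(ex, k=4, min_members=10)
        oracle = _naive_complete_linkage_maxclust(vecs, 4)
        assert adjusted_rand_score(oracle, a.exemplar_ftype) == 1.0

    def test_pruning_is_monotone_in_min_members(self, rng):
        vecs = rng.normal(0, 1, (10, 8))
        counts = [3, 5, 8, 10, 12, 15, 20, 25, 30, 40]
        labelled = []
        for mm in (1, 5, 10, 15):
            ex = _FakeExemplars(vecs, counts)._set
            a = cluster_exemplars(ex, k=2, min_members=mm)
            labelled.append(int((a.roi_ftype > 0).sum()))
        assert labelled == sorted(labelled, reverse=True)

    def test_k_exceeding_survivors_rejected(self, rng):
        ex = _FakeExemplars(rng.normal(0, 1, (4, 8)), [12, 12, 3, 3])._set
        with pytest.raises(ValueError, match="k=3"):
            cluster_exemplars(ex, k=3, min_members=10)


class TestAssignFtypes:
    def _setup(self, rng):
        base = np.arange(8.0)
        vecs = np.vstack([base, base[::-1] + 10.0, -2.0 * base - 10.0])
        ex = _FakeExemplars(vecs, [20, 20, 20])._set
        a = cluster_exemplars(ex, k=3, min_members=10)
        return ex, a

    def test_coincident_roi_takes_exemplar_ftype(self, rng):
        ex, a = self._setup(rng)
        got = assign_ftypes(ex.vectors[1], ex, a)
        assert got[0] == a.exemplar_ftype[1]

    def test_equidistant_tie_goes_to_lowest_exemplar_index(self, rng):
        ex, a = self._setup(rng)
        mid = (ex.vectors[0] + ex.vectors[1]) / 2.0  # exactly between 0 and 1
        got = assign_ftypes(mid, ex, a)
        assert got[0] == a.exemplar_ftype[0]

    def test_recovers_planted_archetype_map(self):
        """Labelled ROIs inherit the f-type of their planted archetype (>= 95%)."""
        from tectomap.scoring import fit_response_scores, scale_scores
        from tectomap.stimulus import build_protocol, build_regressors
        from tectomap.synthetic import SyntheticConfig, generate_traces

        protocol = build_protocol()
        reg = build_regressors(protocol)
        rng = np.random.default_rng(0)
        archetypes = rng.integers(0, 3, 300)
        cfg = SyntheticConfig(n_archetypes=3, noise_sd=0.2, seed=0)
        traces, _ = generate_traces(protocol, cfg, archetypes)
        scaled = scale_scores(
            fit_response_scores(traces, reg, protocol).scores,
            fit_response_scores(traces, reg, protocol).scores,
        )
        ex = find_exemplars(scaled[:200], damping=0.7)
        a = cluster_exemplars(ex, k=3, min_members=5)
        new = assign_ftypes(scaled[200:], ex, a)
        # majority map archetype -> f-type from the clustered portion
        import pandas as pd

        df = pd.DataFrame({"arch": archetypes[:200], "f": a.roi_ftype})
        df = df[df.f > 0]
        mapping = df.groupby("arch")["f"].agg(lambda s: s.mode()[0])
        expect = mapping.loc[archetypes[200:]].to_numpy()
        assert (new == expect).mean() >= 0.95

    def test_empty_exemplar_set_rejected(self, rng):
        ex, a = self._setup(rng)
        a.exemplar_indices = np.array([], dtype=int)
        with pytest.raises(ValueError):
            assign_ftypes(np.zeros(8), ex, a)


class TestEmbedScores:
    def test_seeded_embedding_reproducible_and_separates_blobs(self, rng):
        from sklearn.metrics import silhouette_score

        centers = np.array([[0.0] * 8, [6.0] * 8, [-6.0] * 8])
        X, truth = _blobs(rng, centers, 40, 0.5)
        c1, _ = embed_scores(X, random_state=0)
        c2, _ = embed_scores(X, random_state=0)
        assert np.allclose(c1, c2)
        for seed in (0, 1, 2):
            coords, _ = embed_scores(X, random_state=seed)
            assert silhouette_score(coords, truth) > 0

    def test_identical_points_embed_nearby(self, rng):
        X = rng.normal(0, 1, (60, 8))
        X[1] = X[0]
        coords, _ = embed_scores(X, random_state=0)
        d = np.linalg.norm(coords[0] - coords[1])
        scale = np.linalg.norm(coords.max(0) - coords.min(0))
        assert d < 0.1 * scale
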