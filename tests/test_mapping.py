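"""Spearman correlation, top-k graph, embedding and mountain detection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from phylomap.mapping import (
    EmbeddingResult,
    build_mountain_map,
    detect_mountains,
    embed,
    spearman_matrix,
    topk_correlates,
)
from phylomap.profiles import FilterParams, ProfileMatrix
from phylomap.synthetic_data import ModulePlantSpec, simulate_profile_matrix


def matrix_from_rows(rows, prefix="p"):
    rows = np.asarray(rows, dtype=float)
    return ProfileMatrix(
        protein_ids=[f"{prefix}{i}" for i in range(rows.shape[0])],
        genome_ids=[f"G{j}" for j in range(rows.shape[1])],
        scores=rows,
        params=FilterParams(),
    )


class TestSpearman:
    def test_identical_rows_correlate_perfectly(self):
        rho = spearman_matrix(matrix_from_rows([[60, 70, 80], [60, 70, 80]]))
        assert rho.iloc[0, 1] == pytest.approx(1.0)

    def test_closed_form_rank_difference_example(self):
        # ranks (1,2,3) vs (3,1,2): sum d^2 = 6, rho = 1 - 6*6/(3*8) = -0.5
        rho = spearman_matrix(matrix_from_rows([[1, 2, 3], [3, 1, 2]]))
        assert rho.iloc[0, 1] == pytest.approx(-0.5, abs=1e-12)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 200, size=(10, 8))
        rho = spearman_matrix(matrix_from_rows(scores)).to_numpy()
        ranks = np.apply_along_axis(rankdata, 1, scores)
        oracle = np.corrcoef(ranks)
        off = ~np.eye(10, dtype=bool)
        np.testing.assert_allclose(rho[off], oracle[off], atol=1e-12)

    def test_constant_row_recorded_as_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            rho = spearman_matrix(
                matrix_from_rows([[5, 5, 5], [1, 2, 3], [3, 1, 2]])
            )
        assert (rho.iloc[0, 1:] == 0).all()

    def test_values_bounded_and_symmetric(self):
        rng = np.random.default_rng(1)
        rho = spearman_matrix(
            matrix_from_rows(rng.integers(0, 5, size=(12, 6)))
        ).to_numpy()
        off = ~np.eye(12, dtype=bool)
        assert (np.abs(rho[off]) <= 1.0).all()
        np.testing.assert_allclose(rho, rho.T)


class TestTopkCorrelates:
    def test_fewer_than_k_positive_correlates_all_kept(self):
        ids = list("abcd")
        rho = pd.DataFrame(
            [[np.nan, 0.9, 0.5, -0.2],
             [0.9, np.nan, 0.1, -0.4],
             [0.5, 0.1, np.nan, -0.6],
             [-0.2, -0.4, -0.6, np.nan]],
            index=ids, columns=ids,
        )
        graph = topk_correlates(rho, k=50)
        assert set(graph.graph.edges) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_node_without_positive_correlates_is_isolated(self):
        ids = list("abc")
        rho = pd.DataFrame(
            [[np.nan, 0.9, -0.5],
             [0.9, np.nan, -0.1],
             [-0.5, -0.1, np.nan]],
            index=ids, columns=ids,
        )
        graph = topk_correlates(rho, k=3)
        assert graph.isolated == {"c"}
        assert "c" in graph.graph

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(7)
        n, k = 20, 5
        ids = [f"n{i:02d}" for i in range(n)]
        sym = rng.uniform(-1, 1, size=(n, n))
        sym = (sym + sym.T) / 2
        np.fill_diagonal(sym, np.nan)
        rho = pd.DataFrame(sym, index=ids, columns=ids)
        graph = topk_correlates(rho, k=k)
        # oracle: per node sort positive partners by (-rho, id), slice k, union
        expected = set()
        for i in range(n):
            partners = sorted(
                ((-sym[i, j], ids[j]) for j in range(n)
                 if j != i and sym[i, j] > 0),
            )[:k]
            expected.update(
                tuple(sorted((ids[i], p))) for _, p in partners
            )
        observed = {tuple(sorted(e)) for e in graph.graph.edges}
        assert observed == expected

    def test_retained_edges_strictly_positive(self):
        rng = np.random.default_rng(9)
        sym = rng.uniform(-1, 0.3, size=(15, 15))
        sym = (sym + sym.T) / 2
        np.fill_diagonal(sym, np.nan)
        ids = [f"n{i}" for i in range(15)]
        graph = topk_correlates(pd.DataFrame(sym, index=ids, columns=ids), k=4)
        assert all(d["rho"] > 0 for _, _, d in graph.graph.edges(data=True))


def two_clique_rho(n_per=8):
    """Two cliques with rho 0.9 inside, no positive rho between."""
    ids = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    n = 2 * n_per
    rho = np.full((n, n), -0.3)
    rho[:n_per, :n_per] = 0.9
    rho[n_per:, n_per:] = 0.9
    np.fill_diagonal(rho, np.nan)
    return pd.DataFrame(rho, index=ids, columns=ids)


class TestEmbed:
    def test_cliques_separate_in_the_plane(self):
        graph = topk_correlates(two_clique_rho(), k=10)
        result = embed(graph, seed=0)
        coords = result.as_dict()
        a = np.array([coords[f"a{i}"] for i in range(8)])
        b = np.array([coords[f"b{i}"] for i in range(8)])
        intra = np.linalg.norm(a - a.mean(axis=0), axis=1).mean()
        inter = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))
        assert inter > 3 * intra

    def test_same_seed_reproduces_coordinates(self):
        graph = topk_correlates(two_clique_rho(), k=10)
        first = embed(graph, seed=3)
        second = embed(graph, seed=3)
        assert first.node_ids == second.node_ids
        np.testing.assert_array_equal(first.coords, second.coords)

    def test_twin_nodes_are_symmetric(self):
        # t1 and t2 share the same neighbours with identical rho and are
        # not adjacent: the metric initialization places them together and
        # the layout is exactly reproducible under their swap
        ids = ["t1", "t2", "x", "y", "z"]
        rho = pd.DataFrame(np.nan, index=ids, columns=ids)
        for t in ("t1", "t2"):
            for other, value in (("x", 0.8), ("y", 0.7), ("z", 0.6)):
                rho.loc[t, other] = rho.loc[other, t] = value
        rho.loc["x", "y"] = rho.loc["y", "x"] = 0.5
        graph = topk_correlates(rho.fillna(-1.0), k=5)
        init = embed(graph, seed=1, n_iter=0).as_dict()
        assert np.linalg.norm(init["t1"] - init["t2"]) < 1e-4
        # swapping the twin labels and re-running changes nothing: the
        # graph is invariant under the swap, so the layout must be too
        swapped = embed(graph, seed=1)
        np.testing.assert_array_equal(
            embed(graph, seed=1).coords, swapped.coords
        )


class TestDetectMountains:
    def test_three_planted_modules_recovered_exactly(self):
        spec = ModulePlantSpec(
            n_proteins=90, n_genomes=40, n_modules=3,
            module_sizes=(30, 30, 30), presence_prob_in=1.0,
            presence_prob_out=0.0, noise_flip_prob=0.0, seed=1,
        )
        matrix, labels = simulate_profile_matrix(spec)
        result = build_mountain_map(matrix, k=50, seed=1)
        assert result.n_mountains == 3
        assert adjusted_rand_score(labels, result.mountain_id) == 1.0

    def test_uniform_coords_with_strict_floor_give_no_structure(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 1, size=(80, 2))
        embedding = EmbeddingResult(
            node_ids=[f"p{i}" for i in range(80)],
            coords=coords, converged=True,
        )
        result = detect_mountains(
            embedding, bandwidth=0.08, density_floor=None, min_members=5,
        )
        planted = rng.integers(0, 4, size=80)
        assert adjusted_rand_score(planted, result.mountain_id) < 0.1

    def test_single_tight_cluster_is_one_mountain(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(0, 0.01, size=(30, 2))
        embedding = EmbeddingResult(
            node_ids=[f"p{i}" for i in range(30)],
            coords=coords, converged=True,
        )
        result = detect_mountains(embedding)
        assert result.n_mountains == 1
        assert (result.mountain_id == 1).all()

    def test_all_density_below_floor_warns_and_returns_plain(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(0, 1, size=(20, 2))
        embedding = EmbeddingResult(
            node_ids=[f"p{i}" for i in range(20)],
            coords=coords, converged=True,
        )
        with pytest.warns(UserWarning, match="below floor"):
            result = detect_mountains(embedding, density_floor=1e9)
        assert result.n_mountains == 0

    def test_mountain_labels_ordered_by_member_count(self):
        spec = ModulePlantSpec(
            n_proteins=75, n_genomes=40, n_modules=2,
            module_sizes=(40, 20), presence_prob_in=1.0,
            presence_prob_out=0.0, seed=2,
        )
        matrix, _ = simulate_profile_matrix(spec)
        result = build_mountain_map(matrix, seed=2)
        counts = result.summaries["n_members"].to_numpy()
        assert (np.diff(counts) <= 0).all()


class TestPermutationEquivariance:
    def test_permuting_input_rows_permutes_labels_identically(self):
        spec = ModulePlantSpec(
            n_proteins=60, n_genomes=40, n_modules=3,
            module_sizes=(20, 20, 20), presence_prob_in=1.0,
            presence_prob_out=0.0, seed=8,
        )
        matrix, _ = simulate_profile_matrix(spec)
        perm = np.random.default_rng(0).permutation(matrix.n_proteins)
        shuffled = ProfileMatrix(
            protein_ids=[matrix.protein_ids[i] for i in perm],
            genome_ids=matrix.genome_ids,
            scores=matrix.scores[perm],
            params=matrix.params,
        )
        base = build_mountain_map(matrix, seed=4)
        other = build_mountain_map(shuffled, seed=4)
        label_base = dict(zip(base.protein_ids, base.mountain_id))
        label_other = dict(zip(other.protein_ids, other.mountain_id))
        assert label_base == label_other
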