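"""PPI loading, transition matrices, random walk with restart, PSP."""

import numpy as np
import pytest
import scipy.sparse as sp

from ddifuse import (
    DiffusionProfile,
    DrugProteinMap,
    ProteinNetwork,
    build_psp,
    drug_diffusion_profiles,
    load_associations,
    load_ppi,
    rwr,
    rwr_closed_form,
    transition_matrix,
)


def write_ppi(tmp_path, rows):
    path = tmp_path / "ppi.tsv"
    lines = ["protein_a\tprotein_b\tscore"] + [f"{a}\t{b}\t{s}" for a, b, s in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


def random_connected_network(rng, n_nodes):
    """Random spanning tree plus extra edges: always connected."""
    edges = []
    for i in range(1, n_nodes):
        j = int(rng.integers(i))
        edges.append((f"P{j}", f"P{i}", float(rng.integers(700, 1000))))
    for _ in range(n_nodes):
        i, j = rng.choice(n_nodes, size=2, replace=False)
        edges.append((f"P{i}", f"P{j}", float(rng.integers(700, 1000))))
    best = {}
    for a, b, w in edges:
        key = (a, b) if a < b else (b, a)
        best[key] = max(best.get(key, 0), w)
    ids = sorted({p for k in best for p in k}, key=lambda s: int(s[1:]))
    return ProteinNetwork(ids, [(a, b, w) for (a, b), w in sorted(best.items())])


class TestLoadPpi:
    def test_threshold_filter(self, tmp_path):
        net = load_ppi(
            write_ppi(tmp_path, [("A", "B", 900), ("B", "C", 500), ("A", "C", 750)]),
            min_confidence=700,
        )
        assert len(net.edges) == 2
        assert net.dropped_below_threshold == 1

    def test_symmetric_dedup_keeps_max(self, tmp_path):
        net = load_ppi(
            write_ppi(tmp_path, [("A", "B", 900), ("B", "A", 700)]), min_confidence=0
        )
        assert net.edges == [("A", "B", 900.0)]
        assert net.dropped_duplicates == 1

    def test_self_loop_removed(self, tmp_path):
        net = load_ppi(
            write_ppi(tmp_path, [("P1", "P1", 950), ("P1", "P2", 800)]), min_confidence=0
        )
        assert net.edges == [("P1", "P2", 800.0)]
        assert net.dropped_self_loops == 1

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("protein_a\tprotein_b\tscore\nA\tB\t900\nA\tC\toops\n")
        with pytest.raises(ValueError, match="line 3"):
            load_ppi(path, min_confidence=0)

    def test_empty_after_filter(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            load_ppi(write_ppi(tmp_path, [("A", "B", 100)]), min_confidence=700)


class TestTransitionMatrix:
    def test_star_graph_hand_normalized(self):
        net = ProteinNetwork(
            ["a", "b", "c", "h"],
            [("h", "a", 1.0), ("h", "b", 1.0), ("h", "c", 1.0)],
        )
        W = transition_matrix(net).toarray()
        h = net.protein_ids.index("h")
        expected = np.zeros(4)
        for p in "abc":
            expected[net.protein_ids.index(p)] = 1 / 3
        assert np.allclose(W[:, h], expected)
        # leaves route all mass to the hub
        for p in "abc":
            col = W[:, net.protein_ids.index(p)]
            assert col[h] == 1.0

    def test_path_graph_hand_normalized(self):
        net = ProteinNetwork(["a", "b", "c"], [("a", "b", 1.0), ("b", "c", 1.0)])
        W = transition_matrix(net).toarray()
        assert np.allclose(W[:, 1], [0.5, 0.0, 0.5])

    def test_columns_stochastic(self, rng):
        net = random_connected_network(rng, 20)
        W = transition_matrix(net)
        sums = np.asarray(W.sum(axis=0)).ravel()
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestRwr:
    def test_single_node_fixed_point(self):
        W = sp.csr_matrix((1, 1))
        scores, converged, _ = rwr(W + sp.eye(1), np.array([1.0]), restart=0.3)
        assert converged and scores[0] == pytest.approx(1.0)

    def test_two_node_closed_form(self):
        """Single edge, seed (1,0), restart 0.5: stationary scores (2/3, 1/3)."""
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        scores, converged, _ = rwr(W, np.array([1.0, 0.0]), restart=0.5, tol=1e-12)
        assert converged
        assert scores == pytest.approx([2 / 3, 1 / 3], abs=1e-9)

    def test_matches_dense_solve_on_random_graphs(self, rng):
        for _ in range(10):
            net = random_connected_network(rng, 15)
            W = transition_matrix(net)
            seed = np.zeros(net.n_proteins)
            seed[int(rng.integers(net.n_proteins))] = 1.0
            iterative, converged, _ = rwr(W, seed, restart=0.5, tol=1e-10)
            exact = rwr_closed_form(W, seed, 0.5)
            assert converged
            assert np.max(np.abs(iterative - exact)) < 1e-6

    def test_probability_mass_conserved(self, rng):
        net = random_connected_network(rng, 25)
        W = transition_matrix(net)
        seed = np.full(net.n_proteins, 1.0 / net.n_proteins)
        p = seed.copy()
        for _ in range(30):
            p = 0.5 * (W @ p) + 0.5 * seed
            assert abs(p.sum() - 1.0) < 1e-8

    def test_restart_localizes_to_seed(self, rng):
        net = random_connected_network(rng, 12)
        W = transition_matrix(net)
        seed = np.zeros(net.n_proteins)
        seed[0] = 1.0
        dists = []
        for r in (0.2, 0.5, 0.8, 0.95):
            scores, _, _ = rwr(W, seed, restart=r, tol=1e-12)
            dists.append(np.abs(scores - seed).sum())
        assert all(a > b for a, b in zip(dists, dists[1:]))

    def test_invalid_seed_rejected(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="sums to 0"):
            rwr(W, np.zeros(2), restart=0.5)
        with pytest.raises(ValueError):
            rwr(W, np.array([0.5, 0.5]), restart=1.5)


class TestDrugProfiles:
    def test_identical_seed_sets_identical_profiles(self):
        net = ProteinNetwork(["a", "b", "c"], [("a", "b", 1.0), ("b", "c", 1.0)])
        dmap = DrugProteinMap({"d1": {"a", "b"}, "d2": {"a", "b"}})
        p1, p2 = drug_diffusion_profiles(dmap, net)
        assert np.array_equal(p1.scores, p2.scores)

    def test_unmapped_drug_flagged_zero(self):
        net = ProteinNetwork(["a", "b"], [("a", "b", 1.0)])
        dmap = DrugProteinMap({"d1": {"a"}, "d2": set()})
        profiles = {p.drug_id: p for p in drug_diffusion_profiles(dmap, net)}
        assert profiles["d2"].empty_seed
        assert np.all(profiles["d2"].scores == 0)
        assert not profiles["d1"].empty_seed

    def test_no_mass_crosses_components(self):
        net = ProteinNetwork(
            ["a", "b", "x", "y"], [("a", "b", 1.0), ("x", "y", 1.0)]
        )
        dmap = DrugProteinMap({"d": {"a"}})
        (prof,) = drug_diffusion_profiles(dmap, net)
        idx = net.index()
        assert prof.scores[idx["x"]] == 0.0 and prof.scores[idx["y"]] == 0.0
        assert prof.scores.sum() == pytest.approx(1.0, abs=1e-8)

    def test_association_loader_drops_unknown_proteins(self, tmp_path):
        net = ProteinNetwork(["a", "b"], [("a", "b", 1.0)])
        path = tmp_path / "assoc.tsv"
        path.write_text("drug_id\tprotein_id\nd1\ta\nd1\tzz\nd2\tqq\n")
        with pytest.warns(UserWarning):
            dmap = load_associations(path, net)
        assert dmap.mapping["d1"] == {"a"}
        assert dmap.dropped_proteins["d1"] == {"zz"}
        assert dmap.flagged_drugs == ["d2"]


class TestBuildPsp:
    def _profiles(self, vectors):
        return [
            DiffusionProfile(f"d{i}", np.asarray(v, float), 0.5, True, 1)
            for i, v in enumerate(vectors)
        ]

    def test_identical_profiles_similarity_one(self):
        from ddifuse.network import diffusion_similarity

        S = diffusion_similarity(self._profiles([[0.5, 0.5, 0.0]] * 2))
        assert S[0, 1] == pytest.approx(1.0)

    def test_orthogonal_profiles_similarity_zero(self):
        from ddifuse.network import diffusion_similarity

        S = diffusion_similarity(self._profiles([[1.0, 0.0], [0.0, 1.0]]))
        assert S[0, 1] == pytest.approx(0.0)

    def test_cosine_oracle(self, rng):
        from ddifuse.network import diffusion_similarity

        vecs = rng.random((10, 30))
        S = diffusion_similarity(self._profiles(vecs))
        for i in range(10):
            for j in range(10):
                if i == j:
                    continue
                expected = vecs[i] @ vecs[j] / (
                    np.linalg.norm(vecs[i]) * np.linalg.norm(vecs[j])
                )
                assert abs(S[i, j] - expected) < 1e-10
        assert np.array_equal(S, S.T)
        assert np.all((S >= 0) & (S <= 1))  # non-negative profiles

    def test_zero_profile_convention(self):
        from ddifuse.network import diffusion_similarity

        S = diffusion_similarity(self._profiles([[1.0, 0.0], [0.0, 0.0]]))
        assert S[0, 1] == 0.0 and S[1, 1] == 1.0

    def test_reduction_modes(self, rng):
        profiles = self._profiles(rng.random((12, 20)))
        cos = build_psp(profiles, k=4, mode="cosine")
        raw = build_psp(profiles, k=4, mode="raw")
        assert cos.components.shape == (12, 4)
        assert raw.components.shape == (12, 4)
        with pytest.raises(ValueError):
            build_psp(profiles, k=4, mode="jaccard")
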