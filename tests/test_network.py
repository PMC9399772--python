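"""Correlation matrices, dynamic networks, communities and optimal paths."""
import itertools

import networkx as nx
import numpy as np
import pytest

from dynalysis.io import Selection
from dynalysis.network import (CorrelationMatrix, build_network, communities,
                               dccm, generalized_correlation,
                               mutual_information, optimal_path,
                               path_physical_length)
from dynalysis.synthetic import GaussianEnsembleSpec, gen_gaussian_ensemble

from conftest import make_ensemble, make_topology


def _all(ens):
    return Selection(tuple(range(ens.n_atoms)))


class TestDccm:
    def test_matches_bruteforce_definition(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(100, 4, 3))
        ens = make_ensemble(coords)
        C = dccm(ens, _all(ens)).values
        d = coords - coords.mean(0)
        for i in range(4):
            for j in range(4):
                num = np.mean(np.einsum("fc,fc->f", d[:, i], d[:, j]))
                den = np.sqrt(np.mean((d[:, i] ** 2).sum(1)) *
                              np.mean((d[:, j] ** 2).sum(1)))
                assert C[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_planted_correlation_recovered(self):
        spec = GaussianEnsembleSpec(n_atoms=3, n_frames=50_000,
                                    correlations=[(0, 1, 0.8)], seed=1)
        ens = gen_gaussian_ensemble(spec)
        C = dccm(ens, _all(ens)).values
        assert C[0, 1] == pytest.approx(0.8, abs=0.02)
        assert abs(C[0, 2]) < 0.02
        assert np.allclose(np.diag(C), 1.0)

    def test_anticorrelation_sign(self):
        spec = GaussianEnsembleSpec(n_atoms=2, n_frames=20_000,
                                    correlations=[(0, 1, -0.7)], seed=2)
        ens = gen_gaussian_ensemble(spec)
        C = dccm(ens, _all(ens)).values
        assert C[0, 1] == pytest.approx(-0.7, abs=0.03)

    def test_orthogonal_coupled_motion_scores_zero(self):
        # atom 0 moves along x, atom 1 moves along y with the SAME amplitude
        # series: perfectly coupled but orthogonal => DCCM ~ 0
        rng = np.random.default_rng(3)
        a = rng.normal(size=5000)
        coords = np.zeros((5000, 2, 3))
        coords[:, 0, 0] = a
        coords[:, 1, 1] = a
        ens = make_ensemble(coords)
        C = dccm(ens, _all(ens)).values
        assert abs(C[0, 1]) < 1e-10

    def test_zero_variance_atom_nan_with_warning(self):
        coords = np.zeros((10, 2, 3))
        coords[:, 0, 0] = np.arange(10)
        ens = make_ensemble(coords)
        with pytest.warns(UserWarning, match="zero-variance"):
            C = dccm(ens, _all(ens)).values
        assert np.isnan(C[0, 1]) and np.isnan(C[1, 1])
        assert C[0, 0] == 1.0

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            CorrelationMatrix(np.array([[1.0, 0.5], [0.2, 1.0]]),
                              "dccm", ["A1", "A2"])


class TestMutualInformation:
    def test_independent_gaussians_near_zero(self):
        rng = np.random.default_rng(4)
        mi = mutual_information(rng.normal(size=(5000, 1)),
                                rng.normal(size=(5000, 1)))
        assert mi < 0.02

    def test_bivariate_gaussian_closed_form(self):
        # MI = -0.5 ln(1 - r^2) per scalar dimension
        rng = np.random.default_rng(5)
        r = 0.8
        n = 20_000
        x = rng.normal(size=n)
        y = r * x + np.sqrt(1 - r * r) * rng.normal(size=n)
        mi = mutual_information(x[:, None], y[:, None])
        assert mi == pytest.approx(-0.5 * np.log(1 - r * r), abs=0.03)

    def test_deterministic_nonlinear_coupling_detected(self):
        # y = x^2 is invisible to Pearson correlation but has high MI
        rng = np.random.default_rng(6)
        x = rng.normal(size=5000)
        y = x ** 2
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.05
        assert mutual_information(x[:, None], y[:, None]) > 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="100"):
            mutual_information(np.zeros((50, 1)), np.zeros((50, 1)))

    def test_duplicate_points_jittered_with_warning(self):
        x = np.zeros((200, 1))
        x[:100] = 1.0
        with pytest.warns(UserWarning, match="jitter"):
            mi = mutual_information(x, x.copy())
        assert np.isfinite(mi)


class TestGeneralizedCorrelation:
    def test_gaussian_gc_recovers_abs_r(self):
        # for jointly Gaussian 3-D fluctuations GC = |r|
        spec = GaussianEnsembleSpec(n_atoms=2, n_frames=20_000,
                                    correlations=[(0, 1, 0.8)], seed=7)
        ens = gen_gaussian_ensemble(spec)
        G = generalized_correlation(ens, _all(ens)).values
        assert G[0, 1] == pytest.approx(0.8, abs=0.03)
        assert np.allclose(np.diag(G), 1.0)

    def test_independent_atoms_near_zero(self):
        spec = GaussianEnsembleSpec(n_atoms=2, n_frames=20_000, seed=8)
        ens = gen_gaussian_ensemble(spec)
        G = generalized_correlation(ens, _all(ens)).values
        assert G[0, 1] < 0.05

    def test_orthogonal_coupling_seen_by_gc_not_dccm(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=5000)
        coords = np.zeros((5000, 2, 3))
        coords[:, 0, 0] = a
        coords[:, 1, 1] = a
        # small isotropic noise keeps the KSG estimator well-posed
        coords += 0.01 * rng.normal(size=coords.shape)
        ens = make_ensemble(coords)
        assert abs(dccm(ens, _all(ens)).values[0, 1]) < 0.05
        assert generalized_correlation(ens, _all(ens)).values[0, 1] > 0.9


def _chain_ensemble(positions, wiggle, corr_pairs, n_frames=200, seed=0):
    """Residue chain at fixed mean positions with planted correlations."""
    k = len(positions)
    spec = GaussianEnsembleSpec(n_atoms=k, n_frames=n_frames, sigma=wiggle,
                                correlations=corr_pairs,
                                mean_coords=np.asarray(positions, float),
                                seed=seed)
    return gen_gaussian_ensemble(spec)


class TestBuildNetwork:
    def test_contact_cutoff_and_occupancy_rule(self):
        # residues 1-2 at 4.0 A (always in contact), 1-3 at 9 A (never);
        # sequence neighbors excluded, so use resids 1,3,5
        pos = [[0, 0, 0], [4, 0, 0], [13, 0, 0]]
        top = make_topology(3, resids=[1, 3, 5])
        ens = _chain_ensemble(pos, 0.05, [(0, 1, 0.5), (0, 2, 0.5)], seed=1)
        ens = make_ensemble(ens.coordinates, top)
        corr = dccm(ens, _all(ens))
        G = build_network(ens, corr, _all(ens))
        assert G.has_edge("ALA1", "ALA3")
        assert not G.has_edge("ALA1", "ALA5")

    def test_weight_is_minus_log_abs_corr(self):
        pos = [[0, 0, 0], [4, 0, 0]]
        top = make_topology(2, resids=[1, 3])
        ens = _chain_ensemble(pos, 0.05, [(0, 1, 0.5)], n_frames=50_000,
                              seed=2)
        ens = make_ensemble(ens.coordinates, top)
        corr = dccm(ens, _all(ens))
        G = build_network(ens, corr, _all(ens))
        w = G["ALA1"]["ALA3"]["weight"]
        assert w == pytest.approx(-np.log(abs(corr.values[0, 1])), abs=1e-12)
        assert w == pytest.approx(-np.log(0.5), abs=0.05)

    def test_occupancy_threshold_boundary_inclusive(self):
        # contact in exactly 75% of frames qualifies; 50% does not
        n_frames = 8
        coords = np.zeros((n_frames, 2, 3))
        coords[:, 1, 0] = 4.0
        coords[:6, 1, 0] = 4.0       # 6/8 = 75% within cutoff
        coords[6:, 1, 0] = 9.0
        coords[:, 0, 1] = 0.001 * np.arange(n_frames)   # avoid zero variance
        coords[:, 1, 1] = 0.001 * np.arange(n_frames)
        top = make_topology(2, resids=[1, 3])
        ens = make_ensemble(coords, top)
        corr = dccm(ens, _all(ens))
        G75 = build_network(ens, corr, _all(ens), occupancy=0.75)
        assert G75.has_edge("ALA1", "ALA3")
        coords2 = coords.copy()
        coords2[4:, 1, 0] = 9.0      # 4/8 = 50%
        ens2 = make_ensemble(coords2, top)
        G2 = build_network(ens2, dccm(ens2, _all(ens2)), _all(ens2),
                           occupancy=0.75)
        assert not G2.has_edge("ALA1", "ALA3")

    def test_sequence_neighbors_excluded_by_default(self):
        pos = [[0, 0, 0], [3.8, 0, 0]]
        top = make_topology(2, resids=[1, 2])
        ens = _chain_ensemble(pos, 0.05, [(0, 1, 0.5)], seed=3)
        ens = make_ensemble(ens.coordinates, top)
        corr = dccm(ens, _all(ens))
        assert not build_network(ens, corr, _all(ens)).edges
        G = build_network(ens, corr, _all(ens), exclude_adjacent=False)
        assert G.has_edge("ALA1", "ALA2")

    def test_zero_correlation_edge_dropped_with_warning(self):
        coords = np.zeros((4, 2, 3))
        coords[:, 1, 0] = 4.0
        coords[:, 0, 1] = [0, 1, 0, -1]      # orthogonal motions => C = 0
        coords[:, 1, 2] = [0, 1, 0, -1]
        top = make_topology(2, resids=[1, 3])
        ens = make_ensemble(coords, top)
        corr = dccm(ens, _all(ens))
        assert abs(corr.values[0, 1]) < 1e-12
        with pytest.warns(UserWarning, match="dropped"):
            G = build_network(ens, corr, _all(ens))
        assert not G.edges


class TestCommunities:
    def _two_cliques(self):
        """Two 5-cliques joined by one weak bridge edge."""
        G = nx.Graph()
        for base in (0, 5):
            for i, j in itertools.combinations(range(base, base + 5), 2):
                G.add_edge(f"R{i}", f"R{j}", weight=0.2)
        G.add_edge("R4", "R5", weight=3.0)
        return G

    def test_two_clique_split_exact(self):
        part = communities(self._two_cliques())
        cm = part.community_of
        left = {cm[f"R{i}"] for i in range(5)}
        right = {cm[f"R{i}"] for i in range(5, 10)}
        assert len(left) == 1 and len(right) == 1 and left != right
        assert part.sizes == [5, 5]
        assert part.modularity > 0.0

    def test_modularity_matches_networkx(self):
        G = self._two_cliques()
        part = communities(G)
        groups = {}
        for node, cid in part.community_of.items():
            groups.setdefault(cid, set()).add(node)
        q = nx.community.modularity(G, list(groups.values()), weight="weight")
        assert part.modularity == pytest.approx(q, abs=1e-12)

    def test_disconnected_components_separate(self):
        G = nx.Graph()
        G.add_edge("A", "B", weight=1.0)
        G.add_edge("C", "D", weight=1.0)
        part = communities(G)
        assert part.community_of["A"] == part.community_of["B"]
        assert part.community_of["C"] == part.community_of["D"]
        assert part.community_of["A"] != part.community_of["C"]

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            communities(nx.Graph())


class TestOptimalPath:
    def _weighted_graph(self, seed):
        rng = np.random.default_rng(seed)
        G = nx.gnp_random_graph(12, 0.4, seed=int(seed))
        H = nx.Graph()
        for u, v in G.edges:
            H.add_edge(f"N{u:02d}", f"N{v:02d}",
                       weight=float(rng.uniform(0.1, 2.0)))
        return H

    def test_matches_exhaustive_enumeration(self):
        for seed in range(5):
            H = self._weighted_graph(seed)
            nodes = sorted(H.nodes)
            s, t = nodes[0], nodes[-1]
            path, w = optimal_path(H, s, t)
            if not nx.has_path(H, s, t):
                assert path is None and w == np.inf
                continue
            best = min(
                (sum(H[a][b]["weight"] for a, b in zip(p[:-1], p[1:]))
                 for p in nx.all_simple_paths(H, s, t)))
            assert w == pytest.approx(best, abs=1e-12)

    def test_low_weight_detour_beats_direct_edge(self):
        G = nx.Graph()
        G.add_edge("A", "C", weight=2.0)
        G.add_edge("A", "B", weight=0.5)
        G.add_edge("B", "C", weight=0.5)
        path, w = optimal_path(G, "A", "C")
        assert path == ["A", "B", "C"]
        assert w == pytest.approx(1.0)

    def test_tie_break_fewer_hops_then_lexicographic(self):
        G = nx.Graph()
        G.add_edge("A", "Z", weight=1.0)               # 1 hop, weight 1
        G.add_edge("A", "M", weight=0.5)               # 2 hops, weight 1
        G.add_edge("M", "Z", weight=0.5)
        path, _ = optimal_path(G, "A", "Z")
        assert path == ["A", "Z"]
        G2 = nx.Graph()
        G2.add_edge("A", "B", weight=0.5)
        G2.add_edge("B", "Z", weight=0.5)
        G2.add_edge("A", "C", weight=0.5)
        G2.add_edge("C", "Z", weight=0.5)
        path2, _ = optimal_path(G2, "A", "Z")
        assert path2 == ["A", "B", "Z"]                # lexicographic

    def test_same_node_and_disconnected(self):
        G = nx.Graph()
        G.add_edge("A", "B", weight=1.0)
        G.add_node("C")
        assert optimal_path(G, "A", "A") == (["A"], 0.0)
        path, w = optimal_path(G, "A", "C")
        assert path is None and w == np.inf
        with pytest.raises(KeyError):
            optimal_path(G, "A", "missing")

    def test_physical_length(self):
        G = nx.Graph()
        G.add_node("A", px=0.0, py=0.0, pz=0.0)
        G.add_node("B", px=3.0, py=4.0, pz=0.0)
        G.add_node("C", px=3.0, py=4.0, pz=12.0)
        assert path_physical_length(G, ["A", "B", "C"]) == pytest.approx(17.0)
        assert path_physical_length(G, ["A"]) == 0.0
        assert path_physical_length(G, None) == 0.0
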