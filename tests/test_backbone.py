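"""Encoder invariance, reparameterization, decoding determinism, and the
reconstruction log-likelihood against a brute-force per-entry oracle."""

import numpy as np
import pytest

from graphlda.backbone import (BackboneConfig, GraphAutoencoder,
                               LatentPosterior, posterior_entropy,
                               recon_loglik, reparameterize)
from graphlda.molgraph import GraphLogits, graph_to_logits
from tests.conftest import permute_graph


class TestEncoder:
    def test_permutation_invariance_20_perms(self, untrained_model,
                                             fixture_graphs, zinc_schema):
        rng = np.random.default_rng(7)
        g = next(gr for gr in fixture_graphs if gr.n_atoms >= 5)
        p0 = untrained_model.encode(g)
        for _ in range(20):
            perm = rng.permutation(g.n_atoms)
            g2 = permute_graph(g, perm, zinc_schema)
            p1 = untrained_model.encode(g2)
            assert np.abs(p1.mu - p0.mu).max() < 1e-4

    def test_sigma_positive_and_finite(self, untrained_model, fixture_graphs):
        for g in fixture_graphs[:20]:
            post = untrained_model.encode(g)
            assert np.all(post.sigma > 0)
            assert np.all(np.isfinite(post.sigma))
            assert np.all(np.isfinite(post.mu))

    def test_distinct_molecules_distinct_means(self, untrained_model,
                                               fixture_graphs):
        mus = untrained_model.encode_means(fixture_graphs[:10])
        for i in range(10):
            for j in range(i + 1, 10):
                assert np.linalg.norm(mus[i] - mus[j]) > 0

    def test_schema_mismatch_rejected(self, untrained_model):
        from graphlda.backbone import batch_graphs
        from graphlda.molgraph import build_schema, featurize

        qm9 = build_schema("qm9", "topological")
        g = featurize("CC", qm9, 9)
        with pytest.raises(ValueError, match="schema"):
            untrained_model.encode_batch(batch_graphs([g]))


class TestReparameterize:
    def test_sigma_floor_limit_returns_mu(self):
        mu = np.arange(4.0)
        post = LatentPosterior(mu, np.full(4, 1e-12))
        z = reparameterize(post, 0)
        assert np.allclose(z, mu, atol=1e-10)

    def test_fixed_seed_deterministic(self):
        post = LatentPosterior(np.zeros(6), np.ones(6))
        assert np.array_equal(reparameterize(post, 3), reparameterize(post, 3))

    def test_monte_carlo_moments(self):
        mu = np.array([1.0, -2.0])
        sigma = np.array([0.5, 2.0])
        post = LatentPosterior(mu, sigma)
        rng = np.random.default_rng(0)
        draws = np.array([reparameterize(post, rng) for _ in range(100_000)])
        se_mean = sigma / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(0) - mu) < 3 * se_mean)
        se_std = sigma / np.sqrt(2 * len(draws))
        assert np.all(np.abs(draws.std(0) - sigma) < 3 * se_std)


class TestDecoder:
    def test_deterministic(self, untrained_model):
        z = np.random.default_rng(1).normal(size=16)
        a = untrained_model.decode(z, 5)
        b = untrained_model.decode(z, 5)
        assert np.array_equal(a.node_logits, b.node_logits)
        assert np.array_equal(a.edge_logits, b.edge_logits)

    def test_edge_logits_symmetric(self, untrained_model):
        z = np.random.default_rng(2).normal(size=16)
        logits = untrained_model.decode(z, 7)
        assert np.allclose(logits.edge_logits,
                           logits.edge_logits.transpose(1, 0, 2))

    def test_n_atoms_out_of_range(self, untrained_model):
        z = np.zeros(16)
        with pytest.raises(ValueError):
            untrained_model.decode(z, 0)
        with pytest.raises(ValueError):
            untrained_model.decode(z, 10)


def _brute_force_loglik(graph, logits, schema):
    """Independent per-entry summation of block log-likelihoods."""
    total = 0.0
    node = logits.node_logits
    edge = 0.5 * (logits.edge_logits + logits.edge_logits.transpose(1, 0, 2))
    for i in range(graph.n_atoms):
        pos = 0
        for blk in schema.atom_blocks:
            sl = slice(pos, pos + blk.width)
            total += _entry_ll(node[i, sl], graph.node_features[i, sl], blk.kind)
            pos += blk.width
    for i in range(graph.n_atoms):
        for j in range(graph.n_atoms):
            pos = 0
            for blk in schema.bond_blocks:
                sl = slice(pos, pos + blk.width)
                total += _entry_ll(edge[i, j, sl],
                                   graph.edge_features[i, j, sl], blk.kind)
                pos += blk.width
    return total


def _entry_ll(scores, target, kind):
    if kind == "one_hot":
        p = np.exp(scores - scores.max())
        p /= p.sum()
        return float(np.log(p[np.argmax(target)]))
    if kind == "flag":
        p1 = 1 / (1 + np.exp(-scores[0]))
        return float(np.log(p1 if target[0] == 1 else 1 - p1))
    return float(-0.5 * (scores[0] - target[0]) ** 2
                 - 0.5 * np.log(2 * np.pi))


class TestReconLoglik:
    def test_perfect_prediction_categorical_part_zero(self, fixture_graphs,
                                                      zinc_schema):
        # +inf-margin one-hot logits: categorical and flag parts -> 0,
        # value parts -> their Gaussian normalizer at zero residual
        g = fixture_graphs[0]
        logits = graph_to_logits(g, zinc_schema, scale=1e4)
        ll = recon_loglik(g, logits, zinc_schema)
        n_value_entries = 2 * g.n_atoms  # formal charge + radicals per atom
        expected_value_part = -0.5 * np.log(2 * np.pi) * n_value_entries
        assert ll == pytest.approx(expected_value_part, abs=1e-6)

    def test_uniform_bond_block_analytic(self, zinc_schema):
        from graphlda.molgraph import featurize

        g = featurize("CC", zinc_schema, 9)
        logits = graph_to_logits(g, zinc_schema, scale=1e4)
        # zero out the bond-type logits of edge (0,1)/(1,0): uniform over 5
        lo, hi = zinc_schema.bond_offsets()["bond_type"]
        perfect = recon_loglik(g, logits, zinc_schema)
        logits.edge_logits[0, 1, lo:hi] = 0.0
        logits.edge_logits[1, 0, lo:hi] = 0.0
        ll = recon_loglik(g, logits, zinc_schema)
        assert ll - perfect == pytest.approx(2 * np.log(1 / 5), abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, fixture_graphs, zinc_schema,
                                        seed):
        rng = np.random.default_rng(seed)
        g = fixture_graphs[seed]
        logits = GraphLogits(rng.normal(size=(9, 43)),
                             rng.normal(size=(9, 9, 13)))
        ll = recon_loglik(g, logits, zinc_schema)
        assert np.isfinite(ll)
        assert ll == pytest.approx(_brute_force_loglik(g, logits, zinc_schema),
                                   rel=1e-10)

    def test_invariant_under_joint_permutation(self, fixture_graphs,
                                               zinc_schema):
        from dataclasses import replace

        rng = np.random.default_rng(9)
        g = next(gr for gr in fixture_graphs if gr.n_atoms >= 5)
        n = g.n_atoms
        logits = GraphLogits(rng.normal(size=(9, 43)),
                             rng.normal(size=(9, 9, 13)))
        ll = recon_loglik(g, logits, zinc_schema)
        # apply the same atom permutation to the graph and to the logits
        perm = rng.permutation(n)
        X2 = g.node_features.copy()
        E2 = g.edge_features.copy()
        X2[:n] = g.node_features[perm]
        E2[:n, :n] = g.edge_features[np.ix_(perm, perm)]
        g2 = replace(g, node_features=X2, edge_features=E2)
        node2 = logits.node_logits.copy()
        edge2 = logits.edge_logits.copy()
        node2[:n] = logits.node_logits[perm]
        edge2[:n, :n] = logits.edge_logits[np.ix_(perm, perm)]
        ll2 = recon_loglik(g2, GraphLogits(node2, edge2), zinc_schema)
        assert ll2 == pytest.approx(ll)


class TestPosteriorEntropy:
    def test_analytic_unit_sigma(self):
        post = LatentPosterior(np.zeros(50), np.ones(50))
        assert posterior_entropy(post) == pytest.approx(
            50 * 0.5 * np.log(2 * np.pi * np.e))

    def test_sigma_doubling_adds_d_log2(self):
        sigma = np.random.default_rng(0).uniform(0.5, 2.0, size=12)
        p1 = LatentPosterior(np.zeros(12), sigma)
        p2 = LatentPosterior(np.zeros(12), 2 * sigma)
        assert (posterior_entropy(p2) - posterior_entropy(p1)
                == pytest.approx(12 * np.log(2)))

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(1)
        sigma = np.array([0.3, 1.7, 2.5])
        post = LatentPosterior(np.array([1.0, 0.0, -2.0]), sigma)
        draws = post.mu + sigma * rng.standard_normal((100_000, 3))
        neg_logq = (0.5 * np.log(2 * np.pi * sigma ** 2)
                    + 0.5 * (draws - post.mu) ** 2 / sigma ** 2).sum(axis=1)
        se = neg_logq.std() / np.sqrt(len(draws))
        assert abs(neg_logq.mean() - posterior_entropy(post)) < 3 * se


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path, zinc_schema, desk_config,
                                 fixture_graphs):
        model = GraphAutoencoder(zinc_schema, desk_config, seed=5)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = GraphAutoencoder.load(path)
        g = fixture_graphs[0]
        assert np.array_equal(model.encode(g).mu, loaded.encode(g).mu)
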