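import math

import numpy as np
import pytest

from deeprisk.data_io import MISSING
from deeprisk.feature_encoding import build_connectivity, encode
from deeprisk.risk_model import (
    EPS,
    ModelConfig,
    build_model,
    class_weights,
    load_model,
    predict_scores,
    save_model,
    train,
    weighted_bce,
)
from deeprisk.simulator import SimConfig, simulate_gene_annotation, simulate_genotypes


@pytest.fixture(scope="module")
def micro():
    """Tiny two-chromosome problem for structural/gradient tests."""
    cfg = SimConfig(n_snps=12, n_genes=6, n_chromosomes=2, ld_block_size=4,
                    missing_rate=0.1, seed=3)
    geno = simulate_genotypes(cfg, 16, seed=3)
    genes = simulate_gene_annotation(cfg)
    conn = build_connectivity(geno.variant_ids, geno.variants, genes)
    return geno, conn


class TestClassWeights:
    def test_balanced_reduces_to_unweighted(self):
        assert class_weights(100, 50) == (1.0, 1.0)

    def test_imbalanced_values(self):
        w0, w1 = class_weights(100, 10)
        assert w0 == pytest.approx(0.5556, abs=1e-4)
        assert w1 == pytest.approx(5.0)

    @pytest.mark.parametrize("n_pos", [0, 10])
    def test_degenerate_cohort_rejected(self, n_pos):
        with pytest.raises(ValueError):
            class_weights(10, n_pos)


class TestWeightedBCE:
    def test_half_probability_balanced_is_log2(self):
        p = np.full(10, 0.5)
        y = np.array([0, 1] * 5, float)
        assert weighted_bce(p, y, 1.0, 1.0) == pytest.approx(math.log(2), abs=1e-12)

    def test_perfect_predictions_vanish(self):
        y = np.array([0.0, 1.0, 1.0])
        assert weighted_bce(y, y, 1.0, 1.0) < 1e-5

    def test_single_sample_weighted_value(self):
        assert weighted_bce(np.array([0.25]), np.array([1.0]), 0.5, 5.0) == pytest.approx(
            5 * -math.log(0.25), rel=1e-10
        )

    def test_balanced_weights_equal_plain_bce(self, rng):
        p = rng.uniform(0.01, 0.99, 50)
        y = rng.integers(0, 2, 50).astype(float)
        plain = float(np.mean(-y * np.log(p) - (1 - y) * np.log(1 - p)))
        assert abs(weighted_bce(p, y, *class_weights(100, 50)) - plain) < 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_bce(np.array([0.5]), np.array([1.0, 0.0]))


class TestNetworkGradients:
    @pytest.mark.parametrize("variant,mode", [
        ("full", "two_dim"), ("no_partial_layer", "two_dim"), ("additive_encoding", "additive"),
    ])
    def test_backprop_matches_finite_differences(self, micro, variant, mode):
        geno, conn = micro
        model = build_model(conn, ModelConfig(variant=variant, seed=1))
        X = encode(geno, conn.snp_ids, mode).tensor.astype(float)
        y = (np.arange(16) % 2).astype(float)
        net = model.network

        def loss():
            p, _, _ = net.forward(X)
            pc = np.clip(p, EPS, 1 - EPS)
            return float(np.mean(-y * np.log(pc) - (1 - y) * np.log(1 - pc)))

        p, _, cache = net.forward(X)
        pc = np.clip(p, EPS, 1 - EPS)
        grads = net.backward(cache, (y * (pc - 1) + (1 - y) * pc) / len(y))
        check_rng = np.random.default_rng(0)
        for name, g in grads.items():
            flat = net.params[name].reshape(-1)
            gflat = np.asarray(g).reshape(-1)
            for k in check_rng.choice(flat.size, size=min(8, flat.size), replace=False):
                h, orig = 1e-5, flat[k]
                flat[k] = orig + h
                lp = loss()
                flat[k] = orig - h
                lm = loss()
                flat[k] = orig
                num = (lp - lm) / (2 * h)
                assert gflat[k] == pytest.approx(num, rel=1e-4, abs=1e-7), name


class TestModelStructure:
    def test_scores_in_open_unit_interval(self, micro):
        geno, conn = micro
        model = build_model(conn, ModelConfig(seed=0))
        X = encode(geno, conn.snp_ids, "two_dim")
        s = predict_scores(model, X)
        assert s.shape == (16,) and np.all((s > 0) & (s < 1))

    def test_zero_head_gives_half(self, micro):
        geno, conn = micro
        model = build_model(conn, ModelConfig(seed=0))
        model.network.params["head_w"][:] = 0.0
        model.network.params["head_b"][:] = 0.0
        X = encode(geno, conn.snp_ids, "two_dim")
        np.testing.assert_allclose(predict_scores(model, X), 0.5)

    def test_unconnected_snp_does_not_touch_gene_feature(self, micro):
        """Sparsity of the partial layer: gene features ignore unconnected SNPs."""
        geno, conn = micro
        model = build_model(conn, ModelConfig(seed=0))
        X = encode(geno, conn.snp_ids, "two_dim").tensor.astype(float)
        net = model.network
        grp = conn.groups[1]
        gene_col = 0
        connected = set(grp.snp_indices[gene_col])
        free = next(s for s in range(conn.n_snps) if s not in connected)
        base = net._sequences(X)[1][gene_col].copy()
        X2 = X.copy()
        X2[:, free, :] = [0.0, 2.0]
        perturbed = net._sequences(X2)[1][gene_col]
        np.testing.assert_array_equal(base, perturbed)

    def test_masked_weights_stay_zero_through_training(self, micro):
        geno, conn = micro
        cfg = ModelConfig(seed=2, max_epochs=10, batch_size=8, early_stop_patience=100)
        model = build_model(conn, cfg)
        X = encode(geno, conn.snp_ids, "two_dim")
        y = (np.arange(16) % 2).astype(int)
        train(model, X, y, cfg=cfg)
        W = model.network.params["partial_W"]
        assert np.all(W[~model.network.mask] == 0.0)

    def test_all_missing_individual_scores_finite(self, micro):
        geno, conn = micro
        model = build_model(conn, ModelConfig(seed=0))
        ds = geno.subset_samples(np.arange(3))
        ds.alt_counts[0, :] = MISSING
        X = encode(ds, conn.snp_ids, "two_dim")
        s = predict_scores(model, X)
        assert np.isfinite(s[0]) and 0 < s[0] < 1


@pytest.fixture(scope="module")
def separable():
    """One SNP fully determines the label."""
    cfg = SimConfig(n_snps=10, n_genes=4, n_chromosomes=2, ld_block_size=5,
                    maf_range=(0.4, 0.5), missing_rate=0.0, seed=7)
    geno = simulate_genotypes(cfg, 500, seed=7)
    genes = simulate_gene_annotation(cfg)
    conn = build_connectivity(geno.variant_ids, geno.variants, genes)
    y = (geno.alt_counts[:, 4] >= 1).astype(int)
    return geno, conn, y


class TestTraining:
    def test_learns_separable_toy(self, separable):
        from deeprisk.risk_analysis import auc

        geno, conn, y = separable
        cfg = ModelConfig(seed=0, max_epochs=50, learning_rate=3e-3)
        model = build_model(conn, cfg)
        X = encode(geno, conn.snp_ids, "two_dim")
        _, report = train(model, X, y, cfg=cfg)
        scores = predict_scores(model, X)
        assert auc(scores, y) > 0.95
        assert report.train_loss[0] > report.train_loss[report.chosen_epoch]

    def test_same_seed_identical_scores(self, separable):
        geno, conn, y = separable
        X = encode(geno, conn.snp_ids, "two_dim")
        outs = []
        for _ in range(2):
            cfg = ModelConfig(seed=5, max_epochs=5)
            model = build_model(conn, cfg)
            train(model, X, y, cfg=cfg)
            outs.append(predict_scores(model, X))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_batch_of_one_matches_batch_prediction(self, separable):
        geno, conn, y = separable
        model = build_model(conn, ModelConfig(seed=1))
        X = encode(geno, conn.snp_ids, "two_dim")
        full = predict_scores(model, X)
        one = encode(geno.subset_samples([7]), conn.snp_ids, "two_dim")
        assert predict_scores(model, one)[0] == pytest.approx(full[7], abs=1e-6)

    def test_scores_invariant_to_sample_order(self, separable):
        geno, conn, y = separable
        model = build_model(conn, ModelConfig(seed=1))
        perm = np.random.default_rng(0).permutation(geno.n_samples)
        full = predict_scores(model, encode(geno, conn.snp_ids, "two_dim"))
        shuf = predict_scores(model, encode(geno.subset_samples(perm), conn.snp_ids, "two_dim"))
        np.testing.assert_allclose(shuf, full[perm], atol=1e-12)

    def test_wrong_encoding_mode_rejected(self, separable):
        geno, conn, y = separable
        model = build_model(conn, ModelConfig(seed=1))
        X = encode(geno, conn.snp_ids, "additive")
        with pytest.raises(ValueError, match="encoding mode"):
            predict_scores(model, X)

    def test_checkpoint_round_trip_and_mismatch_guard(self, separable, tmp_path):
        geno, conn, y = separable
        cfg = ModelConfig(seed=3, max_epochs=3)
        model = build_model(conn, cfg)
        X = encode(geno, conn.snp_ids, "two_dim")
        train(model, X, y, cfg=cfg)
        path = str(tmp_path / "model.npz")
        save_model(model, path)
        back = load_model(path, conn)
        np.testing.assert_array_equal(predict_scores(back, X), predict_scores(model, X))
        other = build_connectivity(conn.snp_ids[:5], geno.variants,
                                   simulate_gene_annotation(
                                       SimConfig(n_snps=10, n_genes=4, n_chromosomes=2,
                                                 ld_block_size=5, seed=7)))
        with pytest.raises(ValueError, match="connectivity"):
            load_model(path, other)
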