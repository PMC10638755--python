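import numpy as np
import pytest

from scattrib.attribution import (
    AttributionConfig, AttributionMatrix, attribute, deeplift,
    feature_ablation, gradient_shap, layer_relprop, lime, occlusion,
)
from scattrib.mlp import Layer, MLPModel, forward
from conftest import linear_model, random_model


def _fwd_loops(model, x):
    """Independent forward pass used only by the oracles below."""
    a = [np.asarray(x, dtype=float)]
    z = []
    for i, lay in enumerate(model.layers):
        zz = lay.W.T @ a[-1] + lay.b
        z.append(zz)
        if i < len(model.layers) - 1:
            slope = 0.0 if model.activations[i] == "relu" else 0.01
            a.append(np.where(zz > 0, zz, slope * zz))
        else:
            a.append(zz)
    return z, a


def deeplift_oracle(model, x, x0, target):
    """Brute-force rescale rule: explicit per-neuron multiplier loops."""
    z, a = _fwd_loops(model, x)
    z0, a0 = _fwd_loops(model, x0)
    n_layers = len(model.layers)
    m = np.zeros(model.n_outputs)
    m[target] = 1.0  # multiplier w.r.t. the logits
    for i in range(n_layers - 1, -1, -1):
        if i < n_layers - 1:  # nonlinearity between layer i output and m
            dz = z[i] - z0[i]
            da = a[i + 1] - a0[i + 1]
            ratio = np.empty_like(dz)
            for j in range(len(dz)):
                if abs(dz[j]) < 1e-7:
                    slope = 0.0 if model.activations[i] == "relu" else 0.01
                    ratio[j] = 1.0 if z[i][j] > 0 else slope
                else:
                    ratio[j] = da[j] / dz[j]
            m = m * ratio
        m = model.layers[i].W @ m
    return m * (np.asarray(x, dtype=float) - np.asarray(x0, dtype=float))


class TestDeepLift:
    def test_input_equal_to_reference_scores_zero(self):
        m = random_model(5, [4], 3, seed=0)
        ref = np.full(5, 0.3)
        cfg = AttributionConfig(deeplift_reference=ref)
        assert np.all(deeplift(m, ref, 0, cfg) == 0)

    def test_linear_closed_form_and_exact_summation(self):
        W = np.array([[1.0, -2.0], [0.5, 3.0], [-1.5, 0.25]])
        m = linear_model(W)
        x = np.array([2.0, -1.0, 4.0])
        s = deeplift(m, x, 1)
        assert np.allclose(s, W[:, 1] * x)
        assert np.isclose(s.sum(), forward(m, x).logits[0, 1])

    def test_matches_bruteforce_rescale_oracle_with_state_switch(self):
        """Toy ReLU net where units switch activation state between x0 and x."""
        rng = np.random.default_rng(7)
        for seed in range(5):
            m = random_model(4, [5, 3], 2, seed=seed, relu_only=True)
            x = rng.normal(size=4)
            x0 = rng.normal(size=4) * 0.5
            got = deeplift(m, x, 1, AttributionConfig(deeplift_reference=x0))
            want = deeplift_oracle(m, x, x0, 1)
            assert np.allclose(got, want, atol=1e-12)

    @pytest.mark.parametrize("relu_only", [True, False])
    def test_summation_to_delta(self, relu_only):
        rng = np.random.default_rng(1)
        for seed in range(10):
            m = random_model(6, [7, 4], 3, seed=seed, relu_only=relu_only)
            x = rng.normal(size=6)
            t = forward(m, x).logits[0, 2]
            t0 = forward(m, np.zeros(6)).logits[0, 2]
            s = deeplift(m, x, 2)
            assert abs(s.sum() - (t - t0)) <= 1e-6 * max(abs(t - t0), 1e-12)


def lrp_oracle_221(W1, W2, x, eps=1e-9):
    """Hand-executed z-rule message passing for a bias-free 2-2-1 ReLU net."""
    z1 = W1.T @ x
    a1 = np.maximum(z1, 0)
    z2 = W2.T @ a1
    R_out = z2[0]
    # messages from the output neuron down to hidden units
    denom2 = z2[0] + eps * (1 if z2[0] >= 0 else -1)
    R_hidden = np.array([a1[i] * W2[i, 0] / denom2 * R_out for i in range(2)])
    # messages from hidden units down to inputs
    R_in = np.zeros(2)
    for k in range(2):
        denom1 = z1[k] + eps * (1 if z1[k] >= 0 else -1)
        for i in range(2):
            R_in[i] += x[i] * W1[i, k] / denom1 * R_hidden[k]
    return R_in


class TestLayerRelProp:
    def test_single_linear_layer_closed_form(self):
        W = np.array([[2.0, 1.0], [-1.0, 3.0]])
        m = linear_model(W)
        x = np.array([1.5, 2.0])
        assert np.allclose(layer_relprop(m, x, 0), W[:, 0] * x, atol=1e-6)

    def test_hand_oracle_on_printed_221_network(self):
        W1 = np.array([[1.0, -0.5], [2.0, 1.5]])
        W2 = np.array([[1.0], [-2.0]])
        m = MLPModel([Layer(W1, np.zeros(2)), Layer(W2, np.zeros(1))],
                     ["relu"], 2, 1)
        x = np.array([0.8, -0.3])
        assert np.allclose(layer_relprop(m, x, 0), lrp_oracle_221(W1, W2, x))

    def test_conservation_zero_bias(self):
        """Relevance reaching the inputs equals the explained logit."""
        rng = np.random.default_rng(2)
        for seed in range(10):
            m = random_model(6, [5, 4], 3, seed=seed, zero_bias=True, relu_only=True)
            x = np.abs(rng.normal(size=6))
            r = layer_relprop(m, x, 1)
            t = forward(m, x).logits[0, 1]
            if abs(t) > 1e-6:
                assert abs(r.sum() - t) / abs(t) < 1e-3

    def test_strict_mode_rejects_leaky_model(self):
        m = random_model(4, [3], 2, seed=0, relu_only=False)
        with pytest.raises(ValueError, match="ReLU-only"):
            layer_relprop(m, np.ones(4), 0)


class TestFeatureAblation:
    def test_linear_closed_form(self):
        W = np.array([[1.0, 0.0], [2.0, -1.0], [0.5, 4.0]])
        m = linear_model(W)
        x = np.array([3.0, -2.0, 1.0])
        assert np.allclose(feature_ablation(m, x, 0), W[:, 0] * x)

    def test_gene_at_baseline_scores_exactly_zero(self):
        m = random_model(5, [4], 2, seed=3)
        x = np.array([1.0, 0.0, 2.0, 0.0, -1.0])
        s = feature_ablation(m, x, 0)
        assert s[1] == 0.0 and s[3] == 0.0

    def test_bit_for_bit_against_gene_loop_oracle(self):
        """Independent loop over genes calling the public forward pass."""
        rng = np.random.default_rng(5)
        m = random_model(8, [6, 4], 3, seed=9)
        X = rng.normal(size=(3, 8))
        got = feature_ablation(m, X, 2)
        for ci in range(3):
            f_full = forward(m, X[ci]).logits[0, 2]
            for g in range(8):
                xm = X[ci].copy()
                xm[g] = 0.0
                want = f_full - forward(m, xm).logits[0, 2]
                assert got[ci, g] == want  # bit-for-bit


class TestOcclusion:
    def test_window_one_identical_to_feature_ablation(self):
        m = random_model(7, [5], 3, seed=1)
        X = np.random.default_rng(3).normal(size=(4, 7))
        cfg = AttributionConfig(occlusion_window=1)
        assert np.array_equal(occlusion(m, X, 1, cfg), feature_ablation(m, X, 1))

    def test_linear_window3_matches_bruteforce_mask_enumerator(self):
        W = np.random.default_rng(4).normal(size=(6, 2))
        m = linear_model(W)
        x = np.random.default_rng(5).normal(size=6)
        got = occlusion(m, x, 0, AttributionConfig(occlusion_window=3))
        # brute force: enumerate placements, record drops, average coverage
        w = 3
        drops = []
        for p in range(6 - w + 1):
            xm = x.copy()
            xm[p : p + w] = 0.0
            drops.append(forward(m, x).logits[0, 0] - forward(m, xm).logits[0, 0])
        for g in range(6):
            covering = [d for p, d in enumerate(drops) if p <= g < p + w]
            assert np.isclose(got[g], np.mean(covering))

    def test_zero_weight_gene_in_zero_window_scores_zero(self):
        rng = np.random.default_rng(6)
        W1 = rng.normal(size=(5, 4))
        W1[2, :] = 0.0  # gene 2 has no outgoing weights
        m = MLPModel([Layer(W1, np.zeros(4)), Layer(rng.normal(size=(4, 2)), np.zeros(2))],
                     ["relu"], 5, 2)
        x = np.array([0.0, 0.0, 3.0, 0.0, 0.0])  # windows covering gene 2 are otherwise zero
        s = occlusion(m, x, 0, AttributionConfig(occlusion_window=3))
        assert s[2] == 0.0


class TestGradientShap:
    def test_constant_model_scores_zero(self):
        m = random_model(5, [4], 2, seed=0)
        for lay in m.layers:
            lay.W[:] = 0
        s = gradient_shap(m, np.ones(5), 0, AttributionConfig(seed=1))
        assert np.all(s == 0)

    def test_linear_zero_noise_is_exact(self):
        W = np.array([[1.0, 2.0], [-0.5, 1.0]])
        m = linear_model(W)
        x = np.array([2.0, 3.0])
        cfg = AttributionConfig(gradshap_noise_sd=0.0, seed=0)
        assert np.allclose(gradient_shap(m, x, 1, cfg), W[:, 1] * x)

    def test_linear_monte_carlo_expectation(self):
        """Mean over 200 seeded replicates within 3 SE of w * x."""
        W = np.random.default_rng(8).normal(size=(4, 2))
        m = linear_model(W)
        x = np.random.default_rng(9).normal(size=4)
        draws = np.stack([
            gradient_shap(m, x, 0, AttributionConfig(seed=s)) for s in range(200)
        ])
        mean = draws.mean(axis=0)
        se = draws.std(axis=0, ddof=1) / np.sqrt(200)
        assert np.all(np.abs(mean - W[:, 0] * x) <= 3 * se + 1e-12)

    def test_seeded_determinism(self):
        m = random_model(5, [4], 2, seed=2)
        x = np.random.default_rng(1).normal(size=(2, 5))
        a = gradient_shap(m, x, 1, AttributionConfig(seed=42))
        b = gradient_shap(m, x, 1, AttributionConfig(seed=42))
        assert np.array_equal(a, b)


class TestLime:
    def test_constant_model_coefficients_near_zero(self):
        m = random_model(4, [3], 2, seed=0)
        for lay in m.layers:
            lay.W[:] = 0
            lay.b[:] = 0
        s = lime(m, np.ones(4), 0, AttributionConfig(seed=0, lime_n_samples=100))
        assert np.all(np.abs(s) < 1e-6)

    def test_linear_surrogate_limit(self):
        """Coefficients approach w * x within 5% at 5000 sampled masks."""
        W = np.array([[2.0, 0.5], [-1.0, 1.5], [0.7, -0.2]])
        m = linear_model(W)
        x = np.array([1.0, 2.0, -1.5])
        s = lime(m, x, 0, AttributionConfig(seed=3, lime_n_samples=5000))
        target = W[:, 0] * x
        assert np.all(np.abs(s - target) <= 0.05 * np.abs(target))

    def test_seeded_determinism(self):
        m = random_model(5, [3], 2, seed=1)
        x = np.ones(5)
        cfg = AttributionConfig(seed=7, lime_n_samples=50)
        assert np.array_equal(lime(m, x, 0, cfg), lime(m, x, 0, cfg))

    def test_degenerate_design_errors(self):
        m = linear_model(np.array([[1.0]]))
        # two identical masks over a single gene (seed chosen so both agree)
        cfg = AttributionConfig(seed=1, lime_n_samples=2)
        with pytest.raises(ValueError, match="degenerate"):
            lime(m, np.array([2.0]), 0, cfg)


class TestCrossMethod:
    def test_all_methods_agree_on_biasfree_linear_model(self):
        """Exact (or MC-limit) collapse to w * x on a single linear layer."""
        W = np.array([[1.0, -1.0], [2.0, 0.5], [-0.5, 1.5], [0.25, 2.0]])
        m = linear_model(W)
        x = np.array([1.0, -2.0, 3.0, 0.5])
        expected = W[:, 1] * x
        assert np.allclose(feature_ablation(m, x, 1), expected)
        assert np.array_equal(
            occlusion(m, x, 1, AttributionConfig(occlusion_window=1)),
            feature_ablation(m, x, 1))
        assert np.allclose(deeplift(m, x, 1), expected)
        assert np.allclose(layer_relprop(m, x, 1), expected, atol=1e-6)
        gs = gradient_shap(m, x, 1, AttributionConfig(gradshap_noise_sd=0.0, seed=0))
        assert np.allclose(gs, expected)
        lm = lime(m, x, 1, AttributionConfig(seed=0, lime_n_samples=5000))
        assert np.all(np.abs(lm - expected) <= 0.05 * np.abs(expected))

    @pytest.mark.parametrize("method", [
        "LayerRelProp", "DeepLIFT", "GradientShap", "Occlusion",
        "FeatureAblation", "LIME",
    ])
    def test_finite_outputs_on_extreme_inputs(self, method):
        """All-zero cell and a single-expressed-gene cell stay finite."""
        m = random_model(6, [5, 4], 3, seed=0, relu_only=True)
        X = np.zeros((2, 6))
        X[1, 2] = 7.0
        cfg = AttributionConfig(seed=0, lime_n_samples=50)
        out = attribute(m, X, 0, method, cfg)
        assert isinstance(out, AttributionMatrix)
        assert np.all(np.isfinite(out.scores))

    def test_default_hyperparameters_follow_protocol(self):
        cfg = AttributionConfig()
        assert cfg.occlusion_window == 3
        assert cfg.gradshap_k == 5
        assert cfg.lime_n_samples == 500
        assert cfg.baseline_value == 0.0
        assert cfg.deeplift_reference is None  # all-zero reference

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            attribute(random_model(3, [2], 2), np.ones(3), 0, "Saliency")
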