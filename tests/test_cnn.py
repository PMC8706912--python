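import numpy as np
import pytest

from movefuse import (
    MovementRecording,
    SyntheticConfig,
    TrainingConfig,
    UniaxialSignal,
    build_architecture,
    cnn_classify,
    compute_target_lengths,
    conv_output_dims,
    decide,
    forward_posteriors,
    fuse_posteriors,
    generate_dataset,
    pool_output_dims,
    train_model,
)
from movefuse.cnn import _forward, _init_params

FAST = TrainingConfig(max_epochs=25, patience=25, val_frac=0.0)


class TestDimensionAlgebra:
    @pytest.mark.parametrize("in_dims,f,k,p,sc,expected", [
        ((6, 100, 1), (3, 3, 1), 32, 1, 1, (6, 100, 32)),   # "same"
        ((6, 100, 1), (1, 3, 1), 32, 0, 1, (6, 98, 32)),    # "valid" width
        ((100, 100, 3), (5, 5, 3), 8, 0, 1, (96, 96, 8)),
    ])
    def test_conv_dims(self, in_dims, f, k, p, sc, expected):
        assert conv_output_dims(in_dims, f, k, p=p, sc=sc) == expected

    def test_pool_dims(self):
        assert pool_output_dims((6, 100, 32), (2, 2), 2) == (3, 50, 32)
        assert pool_output_dims((1, 6, 32), (1, 2), 2) == (1, 3, 32)

    def test_filter_larger_than_input_rejected(self):
        with pytest.raises(ValueError):
            conv_output_dims((2, 2, 1), (5, 5, 1), 4, p=0)

    def test_chain_matches_closed_form_on_random_sizes(self, rng):
        """The layer-dimension chain follows the conv/pool relations
        H' = 1 + (H - f + 2p)/s for every model and random input sizes."""
        for _ in range(50):
            tag = rng.choice(["CNN1", "CNN2", "CNN3", "CNN4"])
            n = int(rng.integers(8, 120))
            if tag == "CNN1":
                shape = (1, n, 1)
            elif tag == "CNN2":
                shape = (int(rng.integers(2, 7)), n, 1)
            elif tag == "CNN3":
                shape = (int(rng.integers(2, 13)), n, 1)
            else:
                shape = (int(rng.integers(2, 7)), n, int(rng.integers(1, 4)))
            arch = build_architecture(tag, shape, n_classes=5)
            dims = arch.dims_chain()
            h0, w0, _ = shape
            f1h, f1w, _ = arch.filter1
            p1h, p1w = arch.same_padding(arch.filter1)
            c1 = (1 + (h0 - f1h + 2 * p1h), 1 + (w0 - f1w + 2 * p1w), arch.k1)
            assert dims[1] == c1 == (h0, w0, arch.k1)  # "same" preserves dims
            f2h, f2w, _ = arch.filter2
            p2h, p2w = arch.same_padding(arch.filter2)
            c2 = (1 + (c1[0] - f2h + 2 * p2h), 1 + (c1[1] - f2w + 2 * p2w),
                  arch.k2)
            assert dims[2] == c2
            ph, pw = arch.pool
            pl = (1 + (c2[0] - ph) // arch.pool_stride,
                  1 + (c2[1] - pw) // arch.pool_stride, arch.k2)
            assert dims[3] == pl
            assert dims[4] == (pl[0] * pl[1] * pl[2],)
            assert dims[-1] == (5,)


class TestBuildArchitecture:
    def test_reference_filter_dimensions(self):
        a1 = build_architecture("CNN1", (1, 100, 1), 18)
        assert a1.filter1 == (1, 3, 1) and a1.filter2 == (1, 3, 32)
        a2 = build_architecture("CNN2", (3, 100, 1), 18)
        assert a2.filter1 == (3, 3, 1) and a2.filter2 == (3, 3, 32)
        a3 = build_architecture("CNN3", (6, 100, 1), 18)
        assert a3.filter1 == (3, 3, 1) and a3.filter2 == (3, 3, 32)
        a4 = build_architecture("CNN4", (3, 100, 2), 18)
        assert a4.filter1 == (3, 3, 2) and a4.filter2 == (3, 3, 32)
        for a in (a1, a2, a3, a4):
            assert a.k1 == a.k2 == 32
            assert a.dims_chain()[-1] == (18,)

    def test_same_convolution_preserves_spatial_dims(self):
        arch = build_architecture("CNN3", (6, 100, 1), 4)
        assert arch.dims_chain()[1][:2] == (6, 100)
        assert arch.dims_chain()[2][:2] == (6, 100)

    def test_wrong_input_shapes_rejected(self):
        with pytest.raises(ValueError):
            build_architecture("CNN1", (3, 100, 1), 4)
        with pytest.raises(ValueError):
            build_architecture("CNN3", (6, 100, 2), 4)


class TestForward:
    def test_posteriors_sum_to_one(self, rng):
        arch = build_architecture("CNN3", (4, 20, 1), 5)
        params = _init_params(arch, rng, np.float32)
        params["w4"] = rng.standard_normal(params["w4"].shape).astype(np.float32)
        x = rng.normal(size=(3, 4, 20, 1)).astype(np.float32)
        probs, _ = _forward(params, arch, x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_zero_output_layer_gives_uniform_posterior(self, rng):
        arch = build_architecture("CNN1", (1, 16, 1), 4)
        params = _init_params(arch, rng, np.float64)  # w4, b4 start at zero
        probs, _ = _forward(params, arch, rng.normal(size=(1, 1, 16, 1)))
        np.testing.assert_allclose(probs, 0.25)

    def test_hand_rolled_forward_pass_oracle(self):
        """A 1-filter toy net checked against a directly computed pass."""
        arch = build_architecture("CNN1", (1, 3, 1), 2, k1=1, k2=1, fc_width=2)
        x = np.array([1.0, 2.0, -1.0])
        params = {
            "w1": np.array([[[[1.0]], [[0.0]], [[-1.0]]]]),  # (1,3,1,1)
            "b1": np.array([0.5]),
            "w2": np.array([[[[2.0]], [[0.0]], [[0.0]]]]),
            "b2": np.array([0.0]),
            "w3": np.ones((1, 2)),   # pool output is (1,1,1) -> flat dim 1
            "b3": np.zeros(2),
            "w4": np.array([[1.0, -1.0], [0.0, 0.0]]),
            "b4": np.array([0.0, 0.1]),
        }
        # conv1, same padding width 1: window sums w1=[1,0,-1] over [0,x,0]
        z1 = np.array([0 * 1 + 1 * 0 + 2 * (-1), 1 * 1 + 2 * 0 + (-1) * (-1),
                       2 * 1 + (-1) * 0 + 0 * (-1)]) + 0.5
        a1 = np.maximum(z1, 0)              # [0, 2.5, 2.5]
        # conv2 filter [2,0,0] correlates with the left neighbour
        z2 = np.array([2 * 0.0, 2 * 0.0, 2 * 2.5])
        a2 = np.maximum(z2, 0)              # [0, 0, 5]
        pooled = max(a2[0], a2[1])          # pool (1,2) stride 2 -> one cell
        h = 1.0 / (1.0 + np.exp(-(pooled * params["w3"][0] + params["b3"])))
        logits = h @ params["w4"] + params["b4"]
        expected = np.exp(logits) / np.exp(logits).sum()
        probs, _ = _forward(params, arch, x[None, None, :, None])
        np.testing.assert_allclose(probs[0], expected, atol=1e-12)


class TestFusionAndDecision:
    def test_fuse_examples(self):
        np.testing.assert_allclose(
            fuse_posteriors([np.array([1.0, 0.0]), np.array([0.0, 1.0])]),
            [0.5, 0.5])
        single = np.array([0.2, 0.3, 0.5])
        np.testing.assert_array_equal(fuse_posteriors([single]), single)
        three = [np.array([0.5, 0.3, 0.2]), np.array([0.6, 0.3, 0.1]),
                 np.array([0.4, 0.3, 0.3])]
        np.testing.assert_allclose(fuse_posteriors(three), [0.5, 0.3, 0.2])

    def test_fused_posterior_sums_to_one(self, rng):
        vs = [v / v.sum() for v in rng.uniform(size=(4, 6))]
        assert fuse_posteriors(vs).sum() == pytest.approx(1.0, abs=1e-12)

    def test_decide_and_ties(self):
        assert decide(np.array([0.1, 0.7, 0.2])) == 2
        assert decide(np.array([0.25, 0.25, 0.25, 0.25])) == 1  # tie rule
        assert decide(np.array([0.2, 0.8]), labels=[3, 9]) == 9

    def test_softmax_shift_invariance(self, rng):
        logits = rng.normal(size=7)
        p1 = np.exp(logits) / np.exp(logits).sum()
        shifted = logits + 123.4
        p2 = np.exp(shifted - shifted.max())
        p2 /= p2.sum()
        assert decide(p1) == decide(p2)
        np.testing.assert_allclose(p1, p2, atol=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fuse_posteriors([np.array([0.5, 0.5]), np.array([1.0])])


@pytest.fixture(scope="module")
def small_data():
    cfg = SyntheticConfig(n_classes=3, n_sensors=2, axes_per_sensor=2,
                          base_duration=24, trials_per_class=5,
                          noise_sigma=0.2, warp_intensity=0.1,
                          shift_max=3, duration_jitter=0.05, seed=21)
    return generate_dataset(cfg)


class TestTraining:
    def test_net_counts_per_model(self, small_data):
        spec = compute_target_lengths(small_data, "GMI")
        tiny = TrainingConfig(max_epochs=2)
        counts = {"CNN1": 4, "CNN2": 2, "CNN3": 1, "CNN4": 1}
        for tag, expected in counts.items():
            ens = train_model(small_data, tag, spec, hyper=tiny, seed=0)
            assert len(ens.nets) == expected

    def test_separable_problem_reaches_perfect_training_accuracy(self):
        cfg = SyntheticConfig(n_classes=2, n_sensors=1, axes_per_sensor=2,
                              base_duration=24, trials_per_class=6,
                              noise_sigma=0.0, warp_intensity=0.0,
                              shift_max=0, duration_jitter=0.0, seed=5)
        data = generate_dataset(cfg)
        spec = compute_target_lengths(data, "GMI")
        ens = train_model(data, "CNN3", spec, hyper=FAST, seed=1)
        assert all(cnn_classify(r, ens, spec)[0] == r.label for r in data)

    def test_same_seed_reproduces_loss_trajectory(self, small_data):
        spec = compute_target_lengths(small_data, "GMI")
        tiny = TrainingConfig(max_epochs=4)
        a = train_model(small_data, "CNN4", spec, hyper=tiny, seed=42)
        b = train_model(small_data, "CNN4", spec, hyper=tiny, seed=42)
        assert a.nets[0].log["loss"] == b.nets[0].log["loss"]
        for k in a.nets[0].params:
            np.testing.assert_array_equal(a.nets[0].params[k],
                                          b.nets[0].params[k])

    def test_label_permutation_equivariance(self, small_data):
        """Renaming the classes permutes posteriors exactly (zero-initialized
        output layer; identical seed)."""
        spec = compute_target_lengths(small_data, "GMI")
        tiny = TrainingConfig(max_epochs=3, dtype="float64")
        ens = train_model(small_data, "CNN3", spec, hyper=tiny, seed=9)
        perm = {1: 2, 2: 3, 3: 1}
        permuted = [
            MovementRecording(list(r.signals), label=perm[r.label],
                              metadata=dict(r.metadata))
            for r in small_data
        ]
        ens_p = train_model(permuted, "CNN3", spec, hyper=tiny, seed=9)
        rec = small_data[4]
        _, p = cnn_classify(rec, ens, spec)
        _, pp = cnn_classify(rec, ens_p, spec)
        # posterior for original class c sits at position perm[c] - 1
        for c in (1, 2, 3):
            assert p[c - 1] == pytest.approx(pp[perm[c] - 1], abs=1e-6)

    def test_single_class_rejected(self, small_data):
        spec = compute_target_lengths(small_data, "GMI")
        only_one = [r for r in small_data if r.label == 1]
        with pytest.raises(ValueError):
            train_model(only_one, "CNN3", spec, hyper=FAST, seed=0)

    def test_shape_mismatch_rejected(self, small_data, rng):
        spec = compute_target_lengths(small_data, "GMI")
        ens = train_model(small_data, "CNN3", spec,
                          hyper=TrainingConfig(max_epochs=1), seed=0)
        with pytest.raises(ValueError):
            forward_posteriors(ens.nets[0], rng.normal(size=(2, 5, 1)))
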