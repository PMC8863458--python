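"""Branch construction, fusion, the softmax head and parameter accounting."""

import numpy as np
import pytest

from eegfusion import (
    ArchConfig,
    BranchSpec,
    ConfigurationError,
    FusionHead,
    HybridNetwork,
    InvalidInputError,
    LayerSpec,
    branch_spec,
    build_branch,
    classify,
    count_parameters,
    fuse,
    predict_labels,
)
from eegfusion.architecture import build_head, stack_hybrids


class TestBranchSpec:
    def test_default_specs_are_valid(self):
        for name in ("raw", "dft", "stft", "dwt"):
            spec = branch_spec(name)
            convs = [l for l in spec.layers if l.kind.endswith("conv")]
            assert len(convs) == 5
            assert convs[0].kind == "standard_conv" and convs[0].kernels == 16
            assert [c.kernels for c in convs] == [16, 16, 32, 32, 32]
            assert spec.layers[-1].kind == "global_avg_pool"
            assert spec.feature_dim == 32

    def test_first_kernel_shapes(self):
        assert branch_spec("raw").layers[0].kernel_shape == (31,)
        assert branch_spec("stft").layers[0].kernel_shape == (15, 7)

    @pytest.mark.parametrize(
        "mutation",
        [
            lambda ls: ls[:2],  # too few conv layers
            lambda ls: (LayerSpec("depthwise_separable_conv", 16, (3,)),) + ls[1:],
            lambda ls: ls[:-1] + (LayerSpec("max_pool", stride=2),),  # no GAP at end
        ],
        ids=["five-layers", "first-standard", "final-gap"],
    )
    def test_invariant_violations_rejected(self, mutation):
        layers = branch_spec("raw").layers
        with pytest.raises(ConfigurationError):
            BranchSpec(input_kind="raw_1d", layers=tuple(mutation(layers)))

    def test_kernel_count_restriction(self):
        layers = list(branch_spec("raw").layers)
        idx = [i for i, l in enumerate(layers) if l.kind.endswith("conv")][2]
        layers[idx] = LayerSpec("depthwise_separable_conv", 64, (3,))
        with pytest.raises(ConfigurationError):
            BranchSpec(input_kind="raw_1d", layers=tuple(layers))


class TestBranches:
    @pytest.mark.parametrize("name,shape", [
        ("raw", (1, 3, 512)),
        ("dft", (1, 3, 257)),
        ("dwt", (1, 3, 515)),
        ("stft", (1, 3, 65, 49)),
    ])
    def test_branch_emits_32_dim_features(self, name, shape, rng):
        branch = build_branch(branch_spec(name), 7)
        out = branch.forward(rng.standard_normal(shape).astype(np.float32), False)
        assert out.shape == (3, 32)

    def test_feature_dim_independent_of_input_length(self, rng):
        branch = build_branch(branch_spec("raw"), 7)
        for n in (200, 512, 1111):
            out = branch.forward(rng.standard_normal((1, 2, n)).astype(np.float32), False)
            assert out.shape == (2, 32)

    def test_first_layer_is_16_kernels_of_31(self):
        branch = build_branch(branch_spec("raw"), 0)
        first = branch.layers[0]
        assert first.w.value.shape == (16, 31)

    def test_seeded_build_is_deterministic(self):
        spec = branch_spec("dft")
        b1, b2 = build_branch(spec, 42), build_branch(spec, 42)
        for p1, p2 in zip(b1.params(), b2.params()):
            np.testing.assert_array_equal(p1.value, p2.value)


class TestFusion:
    def test_four_vectors_fuse_to_128(self, rng):
        feats = [rng.standard_normal(32) for _ in range(4)]
        assert fuse(*feats).shape == (128,)

    def test_placement(self):
        fused = fuse(np.ones(32), np.zeros(32), np.zeros(32), np.zeros(32))
        assert np.all(fused[:32] == 1) and np.all(fused[32:] == 0)

    def test_injective_on_distinct_tuples(self, rng):
        a = [rng.standard_normal(32) for _ in range(4)]
        b = [f.copy() for f in a]
        b[2][5] += 1.0
        assert not np.array_equal(fuse(*a), fuse(*b))

    def test_dimension_errors(self, rng):
        with pytest.raises(InvalidInputError):
            fuse(rng.standard_normal(31))


class TestHead:
    def test_equal_logits_give_half_half(self, rng):
        head = build_head(FusionHead(input_dims=(32,)), 0, n_branches=1)
        head.w.value[:] = 0.0
        head.b.value[:] = 0.0
        p = classify(rng.standard_normal(32), head)
        np.testing.assert_allclose(p, [[0.5, 0.5]], atol=1e-9)

    def test_probabilities_normalized(self, rng):
        head = build_head(FusionHead(), 3)
        p = classify(rng.standard_normal((5, 128)), head)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_closed_form_logits_two_zero(self):
        head = build_head(FusionHead(input_dims=(32,)), 0, n_branches=1)
        head.w.value[:] = 0.0
        head.b.value[:] = np.array([2.0, 0.0], dtype=np.float32)
        p = classify(np.zeros(32), head)
        e2 = np.exp(2.0)
        np.testing.assert_allclose(p[0], [e2 / (e2 + 1), 1 / (e2 + 1)], atol=1e-7)

    def test_tie_breaks_to_epileptic(self):
        assert predict_labels(np.array([[0.5, 0.5]]))[0] == 1
        assert predict_labels(np.array([[0.6, 0.4]]))[0] == 0

    def test_dimension_mismatch_rejected(self, rng):
        head = build_head(FusionHead(), 3)
        with pytest.raises(InvalidInputError):
            classify(rng.standard_normal(64), head)

    def test_head_invariants(self):
        with pytest.raises(ConfigurationError):
            FusionHead(output_classes=3)
        assert FusionHead().fused_dim == 128


class TestParameterCounting:
    def test_total_is_sum_of_parts(self):
        net = HybridNetwork(seed=0)
        counts = count_parameters(net)
        assert counts["total"] == sum(counts["breakdown"].values())

    def test_separable_strictly_cheaper_than_standard(self):
        sep = HybridNetwork(seed=0, arch=ArchConfig(use_separable=True))
        std = HybridNetwork(seed=0, arch=ArchConfig(use_separable=False))
        assert count_parameters(sep)["total"] < count_parameters(std)["total"]

    def test_pointwise_16_to_32_is_512(self, rng):
        from eegfusion.nn import PointwiseConv

        layer = PointwiseConv(16, 32, rng)
        assert sum(p.size for p in layer.params()) == 512


class TestHybridNetwork:
    def test_eval_outputs_independent_of_batch_composition(self, short_hybrids):
        net = HybridNetwork(seed=3)
        arrays = stack_hybrids(short_hybrids[:5], net.branch_names)
        # prime BN running stats so eval mode is meaningful
        net.forward(arrays, training=True)
        full = net.predict_proba(arrays)
        one = net.predict_proba(
            {k: np.ascontiguousarray(a[:, 2:3]) for k, a in arrays.items()}
        )
        np.testing.assert_allclose(full[2], one[0], rtol=1e-4, atol=1e-6)

    def test_single_branch_network(self, short_hybrids):
        net = HybridNetwork(branches=("raw",), seed=0)
        assert net.fused_dim == 32
        arrays = stack_hybrids(short_hybrids[:4], net.branch_names)
        assert net.forward(arrays).shape == (4, 2)

    def test_unknown_branch_rejected(self):
        with pytest.raises(ConfigurationError):
            HybridNetwork(branches=("raw", "emg"))
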