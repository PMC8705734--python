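import numpy as np
import pytest

from vesselseg.losses import batch_dice_loss
from vesselseg.model import (
    DenseBlock,
    NetworkSpec,
    build_network,
    count_parameters,
    dense_block_plan,
    layer_plan,
)


class TestNetworkSpec:
    def test_defaults_valid(self):
        spec = NetworkSpec()
        assert spec.growth_rate == 12 and spec.input_size == 48

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkSpec(input_size=50, n_blocks_down=2)

    @pytest.mark.parametrize("field", ["growth_rate", "layers_per_block", "initial_channels"])
    def test_nonpositive_rejected(self, field):
        with pytest.raises(ValueError):
            NetworkSpec(**{field: 0})

    def test_json_round_trip(self):
        spec = NetworkSpec(growth_rate=6, layers_per_block=3)
        assert NetworkSpec.from_json(spec.to_json()) == spec


class TestDenseBlockPlan:
    def test_printed_channel_formula(self):
        # layer inputs for k0=16, k=12, L=4: 16, 28, 40, 52
        plan = dense_block_plan(16, 12, 4)
        assert [s[1] for s in plan.stages[:-1]] == [16, 28, 40, 52]
        assert all(s[2] == 12 for s in plan.stages[:-1])
        assert plan.stages[-1] == ("concat_out", 16, 16 + 12 * 4)

    def test_single_layer(self):
        plan = dense_block_plan(5, 3, 1)
        assert plan.stages[0] == ("layer1", 5, 3)
        assert plan.stages[-1] == ("concat_out", 5, 8)

    def test_zero_growth_rejected(self):
        with pytest.raises(ValueError):
            dense_block_plan(4, 0, 2)


class TestBuildNetwork:
    def test_forward_shape_and_range(self):
        spec = NetworkSpec(growth_rate=4, layers_per_block=2, n_blocks_down=2, initial_channels=4)
        model = build_network(spec, seed=0)
        x = np.random.default_rng(0).random((2, 1, 48, 48)).astype(np.float32)
        y = model.forward(x)
        assert y.shape == (2, 1, 48, 48)
        assert (y > 0).all() and (y < 1).all()

    def test_growth_rate_increases_parameters(self):
        base = dict(layers_per_block=2, n_blocks_down=1, initial_channels=4)
        small = build_network(NetworkSpec(growth_rate=4, **base))
        big = build_network(NetworkSpec(growth_rate=8, **base))
        assert count_parameters(big) > count_parameters(small)

    def test_layer_plan_matches_oracle(self):
        spec = NetworkSpec(growth_rate=5, layers_per_block=3, n_blocks_down=2, initial_channels=7)
        model = build_network(spec, seed=1)
        plans = layer_plan(model)
        for name, plan in plans.items():
            k0 = plan.stages[0][1]
            oracle = dense_block_plan(k0, spec.growth_rate, spec.layers_per_block)
            assert plan.stages == oracle.stages, name

    def test_indivisible_input_rejected_at_forward(self, tiny_model):
        with pytest.raises(ValueError, match="divisible"):
            tiny_model.forward(np.zeros((1, 1, 47, 48), dtype=np.float32))

    def test_any_divisible_size_accepted(self, tiny_model):
        # shape equivariance: whole-image inference sizes work too
        y = tiny_model.forward(np.zeros((1, 1, 64, 80), dtype=np.float32))
        assert y.shape == (1, 1, 64, 80)


class TestCountParameters:
    def test_deterministic_across_builds(self, tiny_spec):
        a = build_network(tiny_spec, seed=0)
        b = build_network(tiny_spec, seed=99)
        assert count_parameters(a) == count_parameters(b) > 0

    def test_toy_spec_hand_enumeration(self):
        # k0=1, k=1, L=1, one down block, 8x8 input. Hand count:
        #   init 3x3 conv 1->1:            9 + 1 = 10
        #   down block BN(1)+conv 1->1:    2 + 10 = 12   (out 2ch)
        #   trans-down BN(2)+1x1 2->1:     4 + 3  = 7
        #   bottleneck BN(1)+conv 1->1:    2 + 10 = 12   (out 2ch)
        #   trans-up 2x2 convT 2->1:       2*4 + 1 = 9
        #   up block BN(3)+conv 3->1:      6 + 28 = 34   (out 4ch)
        #   head 1x1 conv 4->1:            4 + 1 = 5
        spec = NetworkSpec(
            growth_rate=1, layers_per_block=1, n_blocks_down=1, initial_channels=1, input_size=8
        )
        model = build_network(spec)
        assert count_parameters(model) == 10 + 12 + 7 + 12 + 9 + 34 + 5


class TestDenseConnectivity:
    def test_ablating_inner_layer_changes_later_inputs(self):
        rng = np.random.default_rng(0)
        block = DenseBlock(in_channels=3, growth_rate=2, n_layers=4, rng=rng)
        x = np.random.default_rng(1).random((1, 3, 8, 8)).astype(np.float32)
        block.record_inputs = True
        block.forward(x)
        baseline = [inp.copy() for inp in block.last_inputs]

        j = 1  # ablate the second layer's output
        block.output_hooks[j] = lambda out: np.zeros_like(out)
        block.forward(x)
        ablated = block.last_inputs
        block.output_hooks.clear()

        assert np.array_equal(baseline[j], ablated[j])  # input to j unchanged
        for later in range(j + 1, 4):
            assert not np.array_equal(baseline[later], ablated[later])

    def test_gradient_flows_to_all_parameters(self):
        spec = NetworkSpec(growth_rate=3, layers_per_block=2, n_blocks_down=1, initial_channels=3, input_size=16)
        model = build_network(spec, seed=2, dtype=np.float64)
        x = np.random.default_rng(3).random((2, 1, 16, 16))
        g = (np.random.default_rng(4).random((2, 1, 16, 16)) > 0.8).astype(float)
        y = model.forward(x)
        _, grad = batch_dice_loss(y, g, eps=1.0)
        model.zero_grad()
        model.backward(grad)
        for name, p in model.named_params():
            assert np.abs(p.grad).sum() > 0, f"no gradient reached {name}"


class TestFullModelGradient:
    def test_matches_central_difference(self):
        spec = NetworkSpec(growth_rate=2, layers_per_block=2, n_blocks_down=1, initial_channels=3, input_size=8)
        model = build_network(spec, seed=1, dtype=np.float64)
        rng = np.random.default_rng(0)
        x = rng.random((2, 1, 8, 8))
        g = (rng.random((2, 1, 8, 8)) > 0.7).astype(float)

        def loss_and_grad():
            y = model.forward(x)
            return batch_dice_loss(y, g, eps=1.0)

        _, grad = loss_and_grad()
        model.zero_grad()
        model.backward(grad)
        h = 1e-6
        check_rng = np.random.default_rng(3)
        for name, p in model.named_params():
            flat = p.data.ravel()
            for i in check_rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + h
                lp, _ = loss_and_grad()
                flat[i] = orig - h
                lm, _ = loss_and_grad()
                flat[i] = orig
                numeric = (lp - lm) / (2 * h)
                analytic = p.grad.ravel()[i]
                assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-9), name
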