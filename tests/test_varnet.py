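"""Unrolled-chain structure: cascade steps, linearity with zeroed
regularizers, data-consistency guarantees, loss, and training mechanics
(determinism, divergence handling) at a small problem size.  Training
efficacy at the full desk scale is asserted in the acceptance suite."""

import numpy as np
import pytest

from mskrecon.containers import KSpaceData
from mskrecon.evaluation import nrmse
from mskrecon.sampling import make_regular_mask
from mskrecon.synthetic import make_training_set, simulate_acquisition
from mskrecon.varnet import (
    CascadeConfig,
    UnrolledNetworkParams,
    dc_gradient,
    load_params,
    loss,
    main_cascade_step,
    post_cascade_step,
    pre_cascade_step,
    reconstruct,
    save_params,
    train,
)

M = (96, 96)


@pytest.fixture(scope="module")
def zeroed_params():
    return UnrolledNetworkParams.init(CascadeConfig(), seed=0)


@pytest.fixture(scope="module")
def full_noiseless(sens, bias, knee_image):
    pat = make_regular_mask(M[0], 1, 16, n_ro=M[1])
    return simulate_acquisition(knee_image, sens, bias, pat, 0.0, 0)


@pytest.fixture(scope="module")
def r4_noiseless(sens, bias, knee_image):
    pat = make_regular_mask(M[0], 4, 16, n_ro=M[1])
    return simulate_acquisition(knee_image, sens, bias, pat, 0.0, 0)


class TestDcGradient:
    def test_zero_at_exact_solution(self, full_noiseless, sens, knee_truth):
        g = dc_gradient(
            knee_truth, full_noiseless.kspace, sens, full_noiseless.pattern
        )
        assert np.linalg.norm(g) / np.linalg.norm(knee_truth) < 1e-9

    def test_linear_in_x(self, r4_noiseless, sens):
        rng = np.random.default_rng(0)
        y, pat = r4_noiseless.kspace, r4_noiseless.pattern
        a = rng.standard_normal(M) + 1j * rng.standard_normal(M)
        b = rng.standard_normal(M) + 1j * rng.standard_normal(M)
        lhs = dc_gradient(a + b, y, sens, pat)
        rhs = (
            dc_gradient(a, y, sens, pat)
            + dc_gradient(b, y, sens, pat)
            - dc_gradient(np.zeros(M, complex), y, sens, pat)
        )
        assert np.linalg.norm(lhs - rhs) / np.linalg.norm(lhs) < 1e-10

    def test_matches_finite_difference_of_objective(self, r4_noiseless, sens):
        from mskrecon.sense import forward

        rng = np.random.default_rng(1)
        y, pat = r4_noiseless.kspace, r4_noiseless.pattern
        x = rng.standard_normal(M) + 1j * rng.standard_normal(M)
        d = rng.standard_normal(M) + 1j * rng.standard_normal(M)
        d /= np.linalg.norm(d)

        def obj(v):
            r = forward(v, sens, pat) - y
            return 0.5 * float(np.sum(np.abs(r) ** 2))

        eps = 1e-5
        fd = (obj(x + eps * d) - obj(x - eps * d)) / (2 * eps)
        analytic = float(np.real(np.vdot(d, dc_gradient(x, y, sens, pat))))
        assert abs(fd - analytic) / abs(fd) < 1e-5


class TestCascadeSteps:
    def test_zero_step_is_identity(self, r4_noiseless, sens):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(M) + 1j * rng.standard_normal(M)
        out = pre_cascade_step(
            x, x, r4_noiseless.kspace, sens, r4_noiseless.pattern, 0.0, 0.0
        )
        assert np.array_equal(out, x)

    def test_descent_decreases_objective(self, r4_noiseless, sens, knee_truth):
        from mskrecon.sense import forward, adjoint

        y, pat = r4_noiseless.kspace, r4_noiseless.pattern
        x = adjoint(y, sens, pat)
        xp = x

        def obj(v):
            return float(np.sum(np.abs(forward(v, sens, pat) - y) ** 2))

        vals = [obj(x)]
        for _ in range(10):
            x, xp = pre_cascade_step(x, xp, y, sens, pat, 0.5, 0.0), x
            vals.append(obj(x))
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_repeated_steps_converge_to_truth_on_full_data(
        self, full_noiseless, sens, knee_truth
    ):
        from mskrecon.sense import adjoint

        y, pat = full_noiseless.kspace, full_noiseless.pattern
        x = xp = adjoint(y, sens, pat)
        for _ in range(50):
            x, xp = pre_cascade_step(x, xp, y, sens, pat, 0.9, 0.3), x
        assert nrmse(x, knee_truth) < 1e-6

    def test_main_step_with_zero_regularizer_equals_pre_step(
        self, r4_noiseless, sens, zeroed_params
    ):
        rng = np.random.default_rng(3)
        y, pat = r4_noiseless.kspace, r4_noiseless.pattern
        x = rng.standard_normal(M) + 1j * rng.standard_normal(M)
        xp = rng.standard_normal(M) + 1j * rng.standard_normal(M)
        a = pre_cascade_step(x, xp, y, sens, pat, 0.4, 0.1)
        b = main_cascade_step(
            x, xp, y, sens, pat, 0.4, 0.1, zeroed_params.regularizer(0)
        )
        assert np.allclose(a, b)

    def test_post_step_fixed_point_and_residual_contraction(
        self, r4_noiseless, sens, knee_truth
    ):
        from mskrecon.sense import forward, adjoint

        y, pat = r4_noiseless.kspace, r4_noiseless.pattern
        # consistent input: unchanged
        out = post_cascade_step(knee_truth, y, sens, pat)
        assert np.linalg.norm(out - knee_truth) / np.linalg.norm(knee_truth) < 1e-9
        # arbitrary input: acquired-line residual never grows
        rng = np.random.default_rng(4)
        x = adjoint(y, sens, pat) + 0.3 * (
            rng.standard_normal(M) + 1j * rng.standard_normal(M)
        )
        before = np.linalg.norm(forward(x, sens, pat) - y)
        for _ in range(5):
            x = post_cascade_step(x, y, sens, pat)
            after = np.linalg.norm(forward(x, sens, pat) - y)
            assert after <= before + 1e-12
            before = after


class TestReconstruct:
    def test_linear_chain_superposition(self, r4_noiseless, sens, zeroed_params):
        rng = np.random.default_rng(5)
        pat = r4_noiseless.pattern
        shape = r4_noiseless.kspace.shape

        def rec(k):
            y = KSpaceData(kspace=k * pat.mask[:, None], pattern=pat)
            return reconstruct(y, zeroed_params, sens=sens).image

        k1 = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        k2 = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        lhs = rec(k1 + k2)
        assert np.linalg.norm(lhs - rec(k1) - rec(k2)) / np.linalg.norm(lhs) < 1e-8

    def test_noiseless_full_data_recovers_truth(
        self, full_noiseless, sens, knee_truth, zeroed_params, bias, knee_image
    ):
        res = reconstruct(full_noiseless, zeroed_params, sens=sens, bias=bias)
        assert nrmse(res.image, knee_truth) < 1e-3
        ok = bias.field > bias.floor
        assert nrmse(res.magnitude[ok], np.abs(knee_image)[ok]) < 1e-3

    def test_residual_trace_non_increasing_through_post(
        self, r4_noiseless, sens, zeroed_params
    ):
        res = reconstruct(r4_noiseless, zeroed_params, sens=sens)
        n_post = zeroed_params.config.n_post
        tail = res.residuals[-(n_post + 1):]
        assert all(a >= b - 1e-12 for a, b in zip(tail, tail[1:]))
        assert np.isfinite(res.residuals).all()

    def test_deterministic(self, r4_noiseless, zeroed_params, sens):
        a = reconstruct(r4_noiseless, zeroed_params, sens=sens)
        b = reconstruct(r4_noiseless, zeroed_params, sens=sens)
        assert np.array_equal(a.image, b.image)


class TestLoss:
    def test_zero_for_identical_and_nonnegative(self):
        rng = np.random.default_rng(0)
        img = np.abs(rng.standard_normal((48, 48)))
        assert loss(img, img) == pytest.approx(0.0, abs=1e-12)
        other = np.abs(rng.standard_normal((48, 48)))
        assert loss(img, other) >= 0.0

    def test_pure_l1_matches_direct_sum(self):
        rng = np.random.default_rng(1)
        p = rng.random((32, 32))
        t = rng.random((32, 32))
        assert loss(p, t, alpha=1.0, beta=0.0) == pytest.approx(
            float(np.mean(np.abs(p - t)))
        )

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            loss(np.ones((4, 4)), np.ones((4, 5)))
        with pytest.raises(ValueError):
            loss(np.ones((4, 4)), np.ones((4, 4)), alpha=-1.0)


@pytest.fixture(scope="module")
def tiny_set():
    return make_training_set(8, seed=21, matrix=(48, 48))


class TestTraining:
    def test_rerun_bit_identical(self, tiny_set):
        cfg = CascadeConfig(n_pre=1, n_main=1, n_post=1, base_channels=4)
        p1, h1 = train(tiny_set, cfg, epochs=1, seed=7)
        p2, h2 = train(tiny_set, cfg, epochs=1, seed=7)
        assert h1["train_loss"] == h2["train_loss"]
        assert np.array_equal(p1.t_main, p2.t_main)
        w1 = p1.regularizers[0].conv_out.W
        w2 = p2.regularizers[0].conv_out.W
        assert np.array_equal(w1, w2)

    def test_validation_loss_decreases_from_initialization(self, tiny_set):
        cfg = CascadeConfig(n_pre=1, n_main=2, n_post=1, base_channels=4)
        _, hist = train(tiny_set, cfg, epochs=5, seed=0)
        assert hist["val_loss"][-1] < hist["initial_val_loss"]

    @pytest.mark.filterwarnings("ignore:overflow")
    def test_divergence_raises(self, tiny_set):
        cfg = CascadeConfig(n_pre=1, n_main=1, n_post=1, base_channels=4)
        with pytest.raises(RuntimeError, match="diverged"):
            train(tiny_set, cfg, epochs=3, learning_rate=1e20, seed=0)

    def test_checkpoint_roundtrip(self, tiny_set, tmp_path):
        cfg = CascadeConfig(n_pre=1, n_main=1, n_post=1, base_channels=4)
        params, hist = train(tiny_set, cfg, epochs=1, seed=7)
        save_params(tmp_path / "model", params, hist)
        loaded = load_params(tmp_path / "model")
        item = tiny_set.test[0]
        a = reconstruct(item.acquire(), params)
        b = reconstruct(item.acquire(), loaded)
        assert np.allclose(a.image, b.image)
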