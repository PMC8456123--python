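import numpy as np
import pytest

from semimpute import (
    AutoencoderImputer,
    AutoencoderParams,
    Stage,
    TrainConfig,
    cost,
    cost_gradient,
    impute,
    init_params,
    load_checkpoint,
    reconstruct,
    save_checkpoint,
    train,
)
from conftest import make_em
from oracles import reconstruct_scalar


def random_problem(rng, n_genes=5, n_cells=4, zero_frac=0.4):
    R = rng.uniform(0.5, 3.0, size=(n_genes, n_cells))
    R[rng.random(R.shape) < zero_frac] = 0.0
    F = np.where(R > 0, R, rng.uniform(0.5, 3.0, size=R.shape))
    return R, F


def finite_difference_grad(R, F, p, cfg, eps=1e-5):
    fd = AutoencoderParams(*[np.zeros_like(getattr(p, k)) for k in ("E", "D", "b_E", "b_D")])
    for name in ("E", "D", "b_E", "b_D"):
        arr, out = getattr(p, name), getattr(fd, name)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            ix = it.multi_index
            old = arr[ix]
            arr[ix] = old + eps
            up = cost(R, F, p, cfg)
            arr[ix] = old - eps
            down = cost(R, F, p, cfg)
            arr[ix] = old
            out[ix] = (up - down) / (2 * eps)
    return fd


class TestInitParams:
    def test_seed_determinism(self):
        cfg = TrainConfig(hidden_dim=4, seed=3)
        a, b = init_params(6, cfg), init_params(6, cfg)
        assert np.array_equal(a.E, b.E) and np.array_equal(a.D, b.D)
        c = init_params(6, TrainConfig(hidden_dim=4, seed=4))
        assert not np.array_equal(a.E, c.E)

    def test_shapes_and_zero_biases(self):
        p = init_params(7, TrainConfig(hidden_dim=3))
        assert p.E.shape == (3, 7) and p.D.shape == (7, 3)
        assert (p.b_E == 0).all() and (p.b_D == 0).all()

    def test_entries_are_centered_normal(self):
        cfg = TrainConfig(hidden_dim=100, init_std=0.01, seed=0)
        p = init_params(200, cfg)  # 20,000 entries
        se = cfg.init_std / np.sqrt(p.E.size)
        assert abs(p.E.mean()) < 4 * se
        assert p.E.std() == pytest.approx(cfg.init_std, rel=0.05)

    def test_default_hidden_dim_caps_at_512(self):
        assert TrainConfig().resolve_hidden_dim(300) == 300
        assert TrainConfig().resolve_hidden_dim(2000) == 512


class TestReconstruct:
    def test_zero_weights_give_zero_output(self):
        p = AutoencoderParams(np.zeros((2, 3)), np.zeros((3, 2)), np.zeros(2), np.zeros(3))
        out = reconstruct(np.ones((3, 4)), p)
        np.testing.assert_array_equal(out, np.zeros((3, 4)))

    def test_sigmoid_midpoint_closed_form(self):
        # D * sigmoid(0) = 2 * 0.5 = 1
        p = AutoencoderParams(np.array([[0.0]]), np.array([[2.0]]), np.zeros(1), np.zeros(1))
        assert reconstruct(np.array([[0.0]]), p)[0, 0] == pytest.approx(1.0)

    def test_matches_scalar_loop_oracle(self, rng):
        R = rng.uniform(0, 2, size=(4, 3))
        p = AutoencoderParams(
            rng.normal(0, 0.5, (2, 4)),
            rng.normal(0, 0.5, (4, 2)),
            rng.normal(0, 0.5, 2),
            rng.normal(0, 0.5, 4),
        )
        expected = reconstruct_scalar(
            R.tolist(), p.E.tolist(), p.D.tolist(), p.b_E.tolist(), p.b_D.tolist()
        )
        np.testing.assert_allclose(reconstruct(R, p), expected, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        p = init_params(5, TrainConfig(hidden_dim=2))
        with pytest.raises(ValueError, match="genes"):
            reconstruct(np.ones((4, 2)), p)


class TestCost:
    def test_perfect_fit_zero_cost(self):
        # single observed entry reproduced exactly: R=[2] via D*sigmoid(large)
        p = AutoencoderParams(np.array([[20.0]]), np.array([[2.0]]), np.zeros(1), np.zeros(1))
        cfg = TrainConfig(hidden_dim=1, lambda_reg=0.0, delta_weight=0.0)
        R = np.array([[2.0]])
        assert cost(R, R, p, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_observed_entry_uses_fidelity_term_only(self):
        # Y = 1 at the single non-zero entry; label term must not double-count
        p = AutoencoderParams(np.array([[0.0]]), np.array([[2.0]]), np.zeros(1), np.zeros(1))
        cfg = TrainConfig(hidden_dim=1, lambda_reg=0.0, delta_weight=5.0)
        assert cost(np.array([[2.0]]), np.array([[2.0]]), p, cfg) == pytest.approx(1.0)

    def test_zero_entry_uses_weighted_label_term(self):
        # R=[2,0], F=[2,3]: fit observed exactly, Y(0)=1 => cost = 0.5*(3-1)^2 = 2
        p = AutoencoderParams(np.array([[20.0]]), np.array([[2.0]]), np.zeros(1), np.zeros(1))
        cfg = TrainConfig(hidden_dim=1, lambda_reg=0.0, delta_weight=0.5)
        R = np.array([[2.0, 0.0]])
        F = np.array([[2.0, 3.0]])
        assert cost(R, F, p, cfg) == pytest.approx(2.0, abs=1e-9)

    def test_regularizer_is_half_lambda_frobenius(self):
        p = AutoencoderParams(np.full((2, 2), 2.0), np.full((2, 2), 3.0), np.zeros(2), np.zeros(2))
        cfg = TrainConfig(hidden_dim=2, lambda_reg=4.0, delta_weight=0.0)
        R = np.zeros((2, 1))
        # no observed entries: cost is the regularizer alone = 2*(16+36)
        assert cost(R, R, p, cfg) == pytest.approx(0.5 * 4.0 * (4 * 4 + 4 * 9))

    def test_literal_masked_reading_doubles_fidelity(self, rng):
        R, F = random_problem(rng)
        cfg0 = TrainConfig(hidden_dim=3, lambda_reg=0.0, delta_weight=1.0, seed=0)
        p = init_params(R.shape[0], cfg0)
        literal = TrainConfig(hidden_dim=3, lambda_reg=0.0, delta_weight=1.0,
                              weight_term_on="observed")
        plain = TrainConfig(hidden_dim=3, lambda_reg=0.0, delta_weight=0.0)
        # F = R on observed entries, so the literal reading gives (1+delta) x fidelity
        assert cost(R, F, p, literal) == pytest.approx(2 * cost(R, F, p, plain))


class TestGradient:
    @pytest.mark.parametrize("delta,lam,use_bias,weight_on", [
        (0.7, 0.3, True, "zeros"),
        (0.0, 0.0, True, "zeros"),
        (1.0, 1.0, False, "zeros"),
        (0.5, 0.2, True, "observed"),
    ])
    def test_matches_central_finite_differences(self, rng, delta, lam, use_bias, weight_on):
        R, F = random_problem(rng)
        cfg = TrainConfig(hidden_dim=3, lambda_reg=lam, delta_weight=delta,
                          use_bias=use_bias, weight_term_on=weight_on, seed=1)
        p = init_params(5, cfg)
        p.b_E[:] = rng.normal(0, 0.1, 3) if use_bias else 0.0
        p.b_D[:] = rng.normal(0, 0.1, 5) if use_bias else 0.0
        _, g = cost_gradient(R, F, p, cfg)
        fd = finite_difference_grad(R, F, p, cfg)
        for name in ("E", "D") + (("b_E", "b_D") if use_bias else ()):
            an, num = getattr(g, name), getattr(fd, name)
            rel = np.abs(an - num) / np.maximum(np.abs(num), 1e-8)
            assert rel.max() < 1e-4, f"{name}: max rel err {rel.max():.2e}"


class TestTrain:
    def test_huge_threshold_stops_after_one_iteration(self, rng):
        R, F = random_problem(rng)
        p, trace = train(R, F, TrainConfig(hidden_dim=2, threshold=1e12, seed=0))
        assert trace.n_iters == 1 and trace.converged
        assert len(trace.losses) == 1 and np.isfinite(trace.initial_loss)

    def test_loss_trace_bitwise_deterministic(self, rng):
        R, F = random_problem(rng, n_genes=8, n_cells=6)
        cfg = TrainConfig(hidden_dim=3, max_iters=40, threshold=1e-12, seed=5)
        _, t1 = train(R, F, cfg)
        _, t2 = train(R, F, cfg)
        assert t1.losses == t2.losses  # bitwise identical floats

    def test_rank_one_noiseless_matrix_is_learned(self, rng):
        u, v = rng.uniform(0.5, 2.0, 10), rng.uniform(0.5, 2.0, 10)
        R = np.outer(u, v)  # no zeros, exactly representable with one hidden unit
        cfg = TrainConfig(hidden_dim=1, lambda_reg=0.0, delta_weight=0.0,
                          learning_rate=0.01, max_iters=5000, threshold=1e-12, seed=0)
        _, trace = train(R, R, cfg)
        assert trace.losses[-1] < 0.01 * trace.initial_loss

    def test_loss_mostly_nonincreasing_at_small_learning_rate(self, rng):
        R, F = random_problem(rng, n_genes=20, n_cells=15, zero_frac=0.3)
        cfg = TrainConfig(hidden_dim=4, learning_rate=1e-3, max_iters=300,
                          threshold=1e-14, seed=2)
        _, trace = train(R, F, cfg)
        losses = np.array([trace.initial_loss] + trace.losses)
        frac_down = np.mean(np.diff(losses) <= 0)
        assert frac_down >= 0.95

    def test_expression_matrix_stage_checked(self, rng):
        R, F = random_problem(rng)
        m = make_em(R)  # raw_counts stage
        with pytest.raises(ValueError, match="log-transformed"):
            train(m, F, TrainConfig(hidden_dim=2))


class TestImpute:
    def test_output_nonnegative_for_random_params(self, rng):
        for _ in range(10):
            p = AutoencoderParams(
                rng.normal(0, 2, (3, 6)), rng.normal(0, 2, (6, 3)),
                rng.normal(0, 2, 3), rng.normal(0, 2, 6),
            )
            R = rng.uniform(0, 3, size=(6, 4))
            for mode in ("fill_zeros_only", "full_reconstruction"):
                assert impute(R, p, mode=mode).min() >= 0

    def test_fill_zeros_only_preserves_observed_bitwise(self, rng):
        R, _ = random_problem(rng, n_genes=8, n_cells=6)
        p = init_params(8, TrainConfig(hidden_dim=3, seed=0))
        out = impute(R, p, mode="fill_zeros_only")
        nz = R > 0
        assert np.array_equal(out[nz], R[nz])

    def test_large_negative_decoder_bias_yields_zeros(self):
        p = AutoencoderParams(np.zeros((2, 3)), np.zeros((3, 2)), np.zeros(2),
                              np.full(3, -1e6))
        out = impute(np.ones((3, 4)), p, mode="full_reconstruction")
        np.testing.assert_array_equal(out, np.zeros((3, 4)))

    def test_unknown_mode_rejected(self, rng):
        p = init_params(3, TrainConfig(hidden_dim=2))
        with pytest.raises(ValueError, match="mode"):
            impute(np.ones((3, 2)), p, mode="everything")


class TestEstimator:
    def test_fit_transform_surface(self, rng):
        R, F = random_problem(rng, n_genes=10, n_cells=8)
        est = AutoencoderImputer(hidden_dim=3, max_iters=30, threshold=1e-12,
                                 learning_rate=1e-3, random_state=0)
        out = est.fit(R.T, F=F.T).transform(R.T)
        assert out.shape == R.T.shape
        assert est.n_iter_ == 30 and len(est.loss_trace_) == 30
        nz = R.T > 0
        assert np.array_equal(out[nz], R.T[nz])

    def test_get_set_params_roundtrip(self):
        est = AutoencoderImputer(delta_weight=0.5)
        est.set_params(**est.get_params())
        assert est.get_params()["delta_weight"] == 0.5

    def test_no_label_means_pure_masked_autoencoder(self, rng):
        R, _ = random_problem(rng, n_genes=6, n_cells=5)
        a = AutoencoderImputer(hidden_dim=2, max_iters=20, threshold=1e-12,
                               delta_weight=3.0, random_state=1).fit(R.T)
        b = AutoencoderImputer(hidden_dim=2, max_iters=20, threshold=1e-12,
                               delta_weight=0.0, random_state=1).fit(R.T, F=R.T)
        assert np.array_equal(a.loss_trace_, b.loss_trace_)


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, rng):
        R, F = random_problem(rng)
        cfg = TrainConfig(hidden_dim=2, max_iters=5, threshold=1e-12, seed=0)
        p, _ = train(R, F, cfg)
        path = tmp_path / "model.npz"
        save_checkpoint(path, p, cfg, [f"g{i}" for i in range(5)], [f"c{j}" for j in range(4)])
        p2, cfg2, genes, cells = load_checkpoint(path)
        np.testing.assert_array_equal(p.E, p2.E)
        np.testing.assert_array_equal(p.b_D, p2.b_D)
        assert cfg2 == cfg and genes[0] == "g0" and cells[-1] == "c3"
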