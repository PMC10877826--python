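"""The MIL survival network: attention, hazards, DPS, loss, gradients."""

import math

import numpy as np
import pytest

from milsurv.model import (
    AttentionParams,
    MILConfig,
    MILSurvivalModel,
    SurvivalHeadParams,
    SurvivalLabel,
    TimeGrid,
    aggregate_case,
    dps,
    fuse,
    gated_attention,
    make_time_grid,
    nll_loss,
    survival_function,
    survival_head,
)


def sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def attention_oracle(F, V, U, w):
    """Element-by-element transliteration of the gated-attention formula."""
    B, D = F.shape
    L = w.shape[0]
    logits = []
    for k in range(B):
        score = 0.0
        for l in range(L):
            t = math.tanh(sum(V[l][d] * F[k][d] for d in range(D)))
            s = sigmoid(sum(U[l][d] * F[k][d] for d in range(D)))
            score += w[l] * t * s
        logits.append(score)
    mx = max(logits)
    es = [math.exp(z - mx) for z in logits]
    return [e / sum(es) for e in es]


class TestGatedAttention:
    def test_singleton_bag_gets_weight_one(self, small_attention_params):
        w = gated_attention(np.ones((1, 4)), small_attention_params)
        assert w.a == pytest.approx([1.0])

    def test_identical_instances_share_weight(self, small_attention_params):
        f = np.tile(np.array([0.3, -1.2, 0.7, 2.0]), (2, 1))
        w = gated_attention(f, small_attention_params)
        assert w.a == pytest.approx([0.5, 0.5])

    def test_matches_formula_transliteration(self, rng):
        for _ in range(20):
            B, D, L = rng.integers(2, 6), 4, 3
            F = rng.normal(size=(B, D))
            p = AttentionParams(V=rng.normal(size=(L, D)),
                                U=rng.normal(size=(L, D)),
                                w=rng.normal(size=L))
            got = gated_attention(F, p).a
            want = attention_oracle(F, p.V, p.U, p.w)
            assert np.abs(got - np.array(want)).max() <= 1e-6

    def test_weights_sum_to_one_and_positive(self, rng, small_attention_params):
        f = rng.normal(size=(17, 4)) * 5
        w = gated_attention(f, small_attention_params)
        assert w.a.sum() == pytest.approx(1.0, abs=1e-6)
        assert (w.a > 0).all()

    def test_dimension_mismatch_rejected(self, small_attention_params):
        with pytest.raises(ValueError, match="dim"):
            gated_attention(np.ones((2, 7)), small_attention_params)

    def test_nonfinite_features_rejected(self, small_attention_params):
        f = np.ones((2, 4))
        f[0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            gated_attention(f, small_attention_params)


class TestAggregateAndFuse:
    def test_single_instance_passthrough(self):
        v = np.array([1.0, 2.0, 3.0])
        assert aggregate_case(np.array([1.0]), v[None]) == pytest.approx(v)

    def test_weighted_sum_arithmetic(self):
        f = np.array([[0.0, 0.0], [4.0, 8.0]])
        assert aggregate_case(np.array([0.25, 0.75]), f) == pytest.approx([3, 6])

    def test_matches_matvec_oracle(self, rng):
        a = rng.dirichlet(np.ones(9))
        f = rng.normal(size=(9, 6))
        assert np.abs(aggregate_case(a, f) - f.T @ a).max() <= 1e-8

    def test_fused_lengths(self, rng):
        e = {s: rng.normal(size=1024) for s in ("5x", "10x", "20x")}
        assert fuse(e, (1.0, 0.2)).shape == (3074,)
        assert fuse(e).shape == (3072,)
        assert fuse({"5x": e["5x"]}, (0.0, -1.0)).shape == (1026,)

    def test_fuse_order_is_canonical(self, rng):
        e = {"20x": np.full(2, 20.0), "5x": np.full(2, 5.0),
             "10x": np.full(2, 10.0)}
        fused = fuse(e)
        assert fused == pytest.approx([5, 5, 10, 10, 20, 20])


class TestSurvivalHead:
    def test_zero_params_give_half_hazards(self):
        p = survival_head(np.ones(6), SurvivalHeadParams(np.zeros((4, 6)),
                                                         np.zeros(4)))
        assert p == pytest.approx([0.5] * 4)

    def test_large_bias_saturates(self):
        params = SurvivalHeadParams(np.zeros((2, 3)), np.array([50.0, 0.0]))
        p = survival_head(np.zeros(3), params)
        assert p[0] == pytest.approx(1.0) and p[1] == pytest.approx(0.5)

    def test_matches_affine_sigmoid_oracle(self, rng):
        for _ in range(10):
            W = rng.normal(size=(5, 7))
            b = rng.normal(size=5)
            h = rng.normal(size=7)
            want = [sigmoid(sum(W[t][j] * h[j] for j in range(7)) + b[t])
                    for t in range(5)]
            got = survival_head(h, SurvivalHeadParams(W, b))
            assert np.abs(got - np.array(want)).max() <= 1e-6


class TestSurvivalFunctionAndDps:
    @pytest.mark.parametrize("p,S", [
        ([0, 0, 0], [1, 1, 1]),
        ([1, 0.2], [0, 0]),
        ([0.5, 0.5], [0.5, 0.25]),
    ])
    def test_closed_forms(self, p, S):
        assert survival_function(np.array(p)) == pytest.approx(S)

    def test_invalid_hazard_rejected(self):
        with pytest.raises(ValueError):
            survival_function(np.array([0.5, 1.2]))

    def test_dps_bounds(self):
        assert dps(np.ones(4)) == pytest.approx(-4.0)
        assert dps(np.zeros(4)) == pytest.approx(0.0)
        assert dps(survival_function(np.array([0.5, 0.5]))) == pytest.approx(-0.75)

    def test_dps_strictly_increases_in_every_hazard(self, rng):
        p = rng.uniform(0.05, 0.95, size=5)
        base = dps(survival_function(p))
        for t in range(5):
            q = p.copy()
            q[t] += 0.01
            assert dps(survival_function(q)) > base

    def test_geometric_series_limit_for_constant_hazard(self):
        # -dps -> sum_t (1-p)^t for constant hazards
        p = 0.2
        n = 200
        got = -dps(survival_function(np.full(n, p)))
        want = sum((1 - p) ** t for t in range(1, n + 1))
        assert got == pytest.approx(want, rel=1e-9)


def nll_oracle(p, bin_, event, eps=1e-7):
    """Independent enumeration of the discrete-time likelihood."""
    p = [min(max(x, eps), 1 - eps) for x in p]
    if event:
        ll = math.log(p[bin_ - 1])
        for tau in range(bin_ - 1):
            ll += math.log(1 - p[tau])
    else:
        ll = sum(math.log(1 - p[tau]) for tau in range(bin_))
    return -ll


class TestNllLoss:
    def test_event_first_bin_closed_form(self):
        lab = SurvivalLabel(1.0, 1, 1)
        assert nll_loss(np.array([0.5, 0.9]), lab) == pytest.approx(
            -math.log(0.5))

    def test_censored_first_bin_near_zero(self):
        lab = SurvivalLabel(1.0, 0, 1)
        assert nll_loss(np.array([1e-7, 0.5]), lab) == pytest.approx(0.0,
                                                                     abs=1e-6)

    def test_matches_likelihood_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 7))
            p = rng.uniform(0.01, 0.99, size=n)
            bin_ = int(rng.integers(1, n + 1))
            event = int(rng.integers(0, 2))
            lab = SurvivalLabel(1.0, event, bin_)
            assert nll_loss(p, lab) == pytest.approx(
                nll_oracle(list(p), bin_, event), abs=1e-8)

    def test_invalid_bin_rejected(self):
        with pytest.raises(ValueError):
            nll_loss(np.array([0.5, 0.5]), SurvivalLabel(1.0, 1, 3))

    def test_loss_gradient_direction_at_event_bin(self):
        """An event exactly at bin t is fit best by p_t -> 1 (holding
        other bins fixed); a late-censored case by p -> 0."""
        lab = SurvivalLabel(1.0, 1, 2)
        base = np.array([0.1, 0.5, 0.3])
        up, down = base.copy(), base.copy()
        up[1] += 0.05
        down[1] -= 0.05
        assert nll_loss(up, lab) < nll_loss(base, lab) < nll_loss(down, lab)
        cen = SurvivalLabel(9.0, 0, 3)
        lower = np.array([0.05, 0.05, 0.05])
        assert nll_loss(lower, cen) < nll_loss(base, cen)


class TestTimeGrid:
    def test_quantile_cut_points_match_sort_oracle(self):
        times = np.arange(1.0, 101.0)
        events = np.ones(100)
        grid = make_time_grid(times, events, n=4)
        assert grid.cut_points == pytest.approx([25.75, 50.5, 75.25])

    def test_two_bins_single_cut_at_median(self):
        grid = make_time_grid([1, 2, 3, 4], [1, 1, 1, 1], n=2)
        assert grid.cut_points == pytest.approx([2.5])

    def test_identical_times_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            make_time_grid([5.0] * 10, [1] * 10, n=4)

    def test_every_bin_contains_an_event(self, rng):
        times = rng.exponential(30, size=200)
        events = rng.random(200) < 0.7
        grid = make_time_grid(times, events, n=4)
        ev_bins = grid.bin_of(times[events])
        assert set(ev_bins) == {1, 2, 3, 4}

    def test_bin_of_respects_half_open_intervals(self):
        grid = TimeGrid(np.array([10.0, 20.0]))
        assert list(grid.bin_of([0.0, 9.99, 10.0, 19.99, 20.0, 1e9])) == \
            [1, 1, 2, 2, 3, 3]


class TestModelForward:
    def test_untrained_model_closed_form(self, rng):
        cfg = MILConfig(scales=("20x",), input_dim=16, attn_dim=8, n_bins=4,
                        use_clinical=False, seed=0)
        model = MILSurvivalModel(cfg)
        risk, _ = model.infer_case({"20x": rng.normal(size=(5, 16))})
        assert risk.p == pytest.approx([0.5] * 4)
        assert risk.S == pytest.approx([0.5, 0.25, 0.125, 0.0625])
        assert risk.dps == pytest.approx(-0.9375)

    def test_permutation_invariance(self, rng):
        cfg = MILConfig(scales=("20x",), input_dim=16, attn_dim=8, n_bins=3,
                        use_clinical=False, seed=1)
        model = MILSurvivalModel(cfg)
        model.params["W_head"] = rng.normal(size=model.params["W_head"].shape)
        f = rng.normal(size=(9, 16))
        r1, _ = model.infer_case({"20x": f})
        r2, _ = model.infer_case({"20x": f[rng.permutation(9)]})
        assert r1.dps == pytest.approx(r2.dps, abs=1e-12)

    def test_full_pipeline_matches_operation_composition(self, rng):
        cfg = MILConfig(scales=("5x", "20x"), input_dim=8, attn_dim=4,
                        n_bins=3, use_clinical=True, seed=2)
        model = MILSurvivalModel(cfg)
        model.params["W_head"] = rng.normal(size=model.params["W_head"].shape)
        model.params["b_head"] = rng.normal(size=3)
        bags = {s: rng.normal(size=(6, 8)) for s in cfg.scales}
        clin = ("female", 70.0)
        risk, weights = model.infer_case(bags, clin)
        # oracle: compose the public operations by hand
        embeds = {}
        for s in cfg.scales:
            w = gated_attention(bags[s], model.attention_params(s))
            assert np.abs(w.a - weights[s].a).max() <= 1e-12
            embeds[s] = aggregate_case(w, bags[s])
        fused = fuse(embeds, model.encode_clinical("female", 70.0),
                     scale_order=cfg.scales)
        p = survival_head(fused, model.head_params())
        assert np.abs(risk.p - p).max() <= 1e-6
        assert risk.dps == pytest.approx(dps(survival_function(p)), abs=1e-6)

    def test_missing_scale_rejected(self, rng):
        cfg = MILConfig(scales=("5x", "20x"), input_dim=8, n_bins=2,
                        use_clinical=False, seed=0)
        model = MILSurvivalModel(cfg)
        with pytest.raises(ValueError, match="missing"):
            model.infer_case({"5x": rng.normal(size=(3, 8))})


class TestGradients:
    @pytest.mark.parametrize("reduce_dim,use_clinical,scales", [
        (None, True, ("5x", "20x")),
        (12, False, ("10x",)),
    ])
    def test_analytic_gradients_match_finite_differences(
            self, rng, reduce_dim, use_clinical, scales):
        cfg = MILConfig(scales=scales, input_dim=24, attn_dim=10, n_bins=3,
                        dropout=0.0, use_clinical=use_clinical,
                        reduce_dim=reduce_dim, seed=5)
        model = MILSurvivalModel(cfg)
        model.params["W_head"] = rng.normal(0, 0.1,
                                            model.params["W_head"].shape)
        model.params["b_head"] = rng.normal(0, 0.1, 3)
        bags = {s: rng.normal(size=(4, 24)) for s in scales}
        clin = (1.0, 0.4) if use_clinical else None
        label = SurvivalLabel(5.0, 1, 2)
        _, grads, _ = model.loss_and_grads(bags, clin, label, train=False)
        eps = 1e-6
        check_rng = np.random.default_rng(0)
        for key, g in grads.items():
            flat_idx = check_rng.choice(g.size, size=min(10, g.size),
                                        replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, g.shape)
                orig = model.params[key][idx]
                model.params[key][idx] = orig + eps
                lp, _, _ = model.loss_and_grads(bags, clin, label, train=False)
                model.params[key][idx] = orig - eps
                lm, _, _ = model.loss_and_grads(bags, clin, label, train=False)
                model.params[key][idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - g[idx]) <= 1e-4 * max(1.0, abs(fd)), key


class TestCheckpoint:
    def test_save_load_roundtrip(self, rng, tmp_path):
        cfg = MILConfig(scales=("20x",), input_dim=16, attn_dim=8, n_bins=3,
                        use_clinical=True, seed=9)
        model = MILSurvivalModel(cfg, time_grid=TimeGrid(np.array([5., 10.])))
        model.set_age_norm(61.0, 9.0)
        model.params["W_head"] = rng.normal(size=model.params["W_head"].shape)
        model.feature_center["20x"] = rng.normal(size=16)
        path = tmp_path / "ckpt.npz"
        model.save(str(path))
        back = MILSurvivalModel.load(str(path))
        assert back.config == cfg
        assert np.array_equal(back.time_grid.cut_points, [5.0, 10.0])
        assert back.age_mean == 61.0 and back.age_sd == 9.0
        f = rng.normal(size=(4, 16))
        r1, _ = model.infer_case({"20x": f}, ("male", 55))
        r2, _ = back.infer_case({"20x": f}, ("male", 55))
        assert r1.dps == pytest.approx(r2.dps, abs=1e-12)
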