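"""Channel weighting, gradient descent, candidate selection and stitching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cabum.contraction_id import Contraction, DetectorConfig, detect_contractions
from cabum.fusion import (
    CostComponents,
    FrameContext,
    FusionConfig,
    GDSchedule,
    SelectionMetrics,
    WeightVector,
    blend_previous,
    build_subsets,
    cost,
    enhance_channels,
    fuse,
    gd_optimize,
    initial_weights_equal,
    initial_weights_voting,
    select_final,
    selection_metrics,
    stitch,
    vote_fractions,
)

FS = 4.0


def _bump_traces(n_ch=4, dur=900.0, seed=0, informative=None):
    rng = np.random.default_rng(seed)
    t = np.arange(int(dur * FS)) / FS
    env = np.exp(-0.5 * ((t - 300) / 20) ** 2) + np.exp(-0.5 * ((t - 600) / 25) ** 2)
    traces = 0.01 * rng.random((n_ch, t.size))
    informative = range(n_ch) if informative is None else informative
    for c in informative:
        traces[c] += 0.2 * rng.uniform(0.7, 1.3) * env
    return traces


class TestInitialWeights:
    def test_equal_init_is_one_over_n(self):
        seed = WeightVector(np.array([1.0] * 10))
        w = initial_weights_equal(seed)
        assert np.allclose(w.w, 0.1)

    def test_single_channel_weight_one(self):
        w = initial_weights_equal(WeightVector(np.array([0.0, 3.0, 0.0])))
        assert w.w.tolist() == [0.0, 1.0, 0.0]

    @given(st.integers(min_value=1, max_value=30))
    @settings(deadline=None, max_examples=30)
    def test_equal_init_sums_to_one(self, n):
        w = initial_weights_equal(WeightVector(np.ones(n)))
        assert w.w.sum() == pytest.approx(1.0)

    def test_damping_equation(self):
        # w01 = 0.6 * w_previous + 0.4 * w_current
        subset = WeightVector(np.ones(1))
        contrs = [[Contraction(100.0, 160.0, 130.0, 1.0)]]
        traces = np.ones((1, 2400))
        w_cur = initial_weights_voting(subset, contrs, traces, prev_weights=None)
        w_damped = initial_weights_voting(
            subset, contrs, traces, prev_weights=np.array([0.5])
        )
        assert w_damped.w[0] == pytest.approx(0.6 * 0.5 + 0.4 * w_cur.w[0])

    def test_damping_worked_example(self):
        # the damping arithmetic itself: 0.6*0.5 + 0.4*1.0 = 0.7
        assert 0.6 * 0.5 + 0.4 * 1.0 == pytest.approx(0.7)

    def test_identical_masks_vote_fraction_one(self):
        masks = np.zeros((5, 100), bool)
        masks[:, 20:60] = True
        assert np.allclose(vote_fractions(masks), 1.0)

    def test_vote_fractions_brute_force_oracle(self, rng):
        masks = rng.random((3, 200)) < 0.3
        out = vote_fractions(masks)
        for c in range(3):
            own = np.flatnonzero(masks[c])
            if own.size == 0:
                assert out[c] == 0.0
                continue
            fracs = [(masks[:, s].sum() - 1) / 2 for s in own]
            assert out[c] == pytest.approx(np.mean(fracs))

    def test_no_contractions_falls_back_to_equal(self):
        subset = WeightVector(np.ones(4))
        w = initial_weights_voting(subset, [[] for _ in range(4)], np.ones((4, 100)))
        assert np.allclose(w.w, 0.25)
        assert "voting_fallback_equal" in w.flags


class TestCost:
    def test_printed_formula_on_components(self):
        comp = CostComponents(e_tot=4.0, e_cont=2.0, a_cont=1.0, r=2.0)
        assert comp.c == pytest.approx(1.5)

    def test_no_contractions_gives_one(self):
        # oscillation far shorter than the minimum contraction duration
        t = np.arange(2400) / FS
        traces = np.tile(1.0 + 0.1 * np.sin(2 * np.pi * t / 10.0), (3, 1))
        comp = cost(np.ones(3) / 3, traces)
        assert comp.c == 1.0

    def test_components_match_numeric_oracle(self):
        traces = _bump_traces(n_ch=1, seed=3)
        comp = cost(np.array([1.0]), traces)
        ua = traces[0]
        assert comp.e_tot == pytest.approx(np.sum(ua**2), rel=1e-9)
        contrs = detect_contractions(ua, DetectorConfig())
        e_cont = 0.0
        for c in contrs:
            a, b = int(np.floor(c.onset_s * FS)), int(np.ceil(c.offset_s * FS)) + 1
            e_cont += np.sum(ua[a:b] ** 2)
        assert comp.e_cont == pytest.approx(e_cont, rel=1e-6)
        assert comp.e_tot >= comp.e_cont >= 0
        assert comp.r >= 0

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            cost(np.zeros(3), np.ones((3, 100)))


class TestGdOptimize:
    def test_zero_gradient_fixed_point(self):
        w0 = WeightVector(np.array([0.4, 0.6]))
        out = gd_optimize(w0, np.zeros((2, 10)), objective=lambda w, t: 1.0)
        assert np.allclose(out.w, w0.w)

    def test_weights_stay_nonnegative_under_adversarial_gradients(self, rng):
        # objective with violent random slopes: |.| update must keep w >= 0
        coefs = rng.standard_normal(5) * 100

        def obj(w, t):
            return float(np.dot(coefs, w))

        out = gd_optimize(WeightVector(np.full(5, 0.2)), np.zeros((5, 4)), objective=obj)
        assert np.all(out.w >= 0)

    def test_converges_to_known_quadratic_minimizer(self):
        wstar = np.array([0.3, 0.6, 0.9])

        def obj(w, t):
            return float(np.sum((w - wstar) ** 2))

        sched = GDSchedule(gamma0=0.4, n_mid=40, steepness=5, max_iter=100, tol=1e-10)
        out = gd_optimize(WeightVector(np.full(3, 0.5)), np.zeros((3, 4)), sched, objective=obj)
        assert np.max(np.abs(out.w - wstar)) < 1e-3

    def test_zeroed_channels_stay_zero(self):
        w0 = WeightVector(np.array([0.5, 0.0, 0.5]))

        def obj(w, t):
            return float(np.sum((w - 1.0) ** 2))

        out = gd_optimize(w0, np.zeros((3, 4)), objective=obj)
        assert out.w[1] == 0.0

    def test_step_schedule_is_positive_and_nonincreasing(self):
        sched = GDSchedule()
        steps = sched.steps()
        assert np.all(steps > 0)
        assert np.all(np.diff(steps) <= 0)


class TestSelectionMetrics:
    def test_identical_segments_index_zero(self, rng):
        ua = rng.random(500)
        m = selection_metrics(ua, CostComponents(1, 0, 0, 0), [], prev_ua=ua.copy())
        assert m.difference_index == pytest.approx(0.0)

    def test_anticorrelated_ranks_index_one(self):
        ua = np.arange(100.0)
        m = selection_metrics(ua, CostComponents(1, 0, 0, 0), [], prev_ua=ua[::-1].copy())
        assert m.difference_index == pytest.approx(1.0)

    def test_random_pair_matches_rank_correlation_oracle(self, rng):
        from scipy.stats import rankdata

        a, b = rng.random(300), rng.random(300)
        m = selection_metrics(a, CostComponents(1, 0, 0, 0), [], prev_ua=b)
        ra, rb = rankdata(b), rankdata(a)
        rho = np.corrcoef(ra, rb)[0, 1]
        assert m.difference_index == pytest.approx(1 - max(0.0, rho), abs=1e-9)

    def test_no_previous_ua_index_zero(self):
        m = selection_metrics(np.ones(10), CostComponents(1, 0, 0, 0), [], prev_ua=None)
        assert m.difference_index == 0.0

    def test_constant_candidate_flagged(self, rng):
        m = selection_metrics(np.full(100, 2.0), CostComponents(1, 0, 0, 0), [], prev_ua=rng.random(100))
        assert m.difference_index == 1.0
        assert "constant_segment" in m.flags


class TestEnhanceChannels:
    def test_identical_channels_all_retained(self):
        base = _bump_traces(n_ch=1, seed=5)[0]
        traces = np.tile(base, (4, 1))
        w = WeightVector(np.full(4, 0.25))
        out = enhance_channels(w, traces)
        assert np.allclose(out.w, 0.25, atol=1e-6)

    def test_noise_channel_zeroed(self, rng):
        traces = _bump_traces(n_ch=4, seed=6, informative=[0, 1, 2])
        traces[3] = 0.2 * rng.random(traces.shape[1])  # pure noise
        out = enhance_channels(WeightVector(np.full(4, 0.25)), traces)
        assert out.w[3] == 0.0
        assert out.w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_weights_sum_to_one(self, rng):
        traces = _bump_traces(n_ch=6, seed=7)
        w0 = rng.random(6)
        out = enhance_channels(WeightVector(w0), traces)
        assert out.w.sum() == pytest.approx(1.0, abs=1e-9)


class TestBlendPrevious:
    def test_first_frame_passthrough(self):
        w = WeightVector(np.array([0.4, 0.6]))
        out = blend_previous(w, FrameContext(k=1))
        assert np.allclose(out.w, w.w)

    def test_second_frame_arithmetic(self):
        w = WeightVector(np.array([0.4]))
        ctx = FrameContext(k=2, prev_weights=np.array([0.8]))
        out = blend_previous(w, ctx)
        assert out.w[0] == pytest.approx(0.5 * 0.4 + 0.5 * 0.8)

    @given(st.integers(min_value=2, max_value=20), st.integers(min_value=0, max_value=1000))
    @settings(deadline=None, max_examples=40)
    def test_blend_is_convex(self, k, seed):
        rng = np.random.default_rng(seed)
        cur, prev = rng.random(5), rng.random(5)
        out = blend_previous(WeightVector(cur), FrameContext(k=k, prev_weights=prev))
        lo, hi = np.minimum(cur, prev), np.maximum(cur, prev)
        assert np.all(out.w >= lo - 1e-12) and np.all(out.w <= hi + 1e-12)

    def test_missing_previous_forces_cw_one(self):
        out = blend_previous(WeightVector(np.array([0.3])), FrameContext(k=5))
        assert np.allclose(out.w, [0.3])
        assert "cw_forced_1" in out.flags


class TestSelectFinal:
    def _cand(self, subset, snr, cost_v, conf, diff):
        return (
            WeightVector(np.ones(2), subset=subset),
            SelectionMetrics(snr, cost_v, conf, diff),
        )

    def test_single_candidate_returned(self):
        c = self._cand("biopotential", 1.0, 1.2, 0.5, 0.1)
        assert select_final([c])[0] is c[0]

    def test_dominant_candidate_wins(self):
        weak = self._cand("biopotential", 1.0, 1.1, 0.2, 0.5)
        strong = self._cand("acoustic", 5.0, 1.8, 0.9, 0.0)
        assert select_final([weak, strong])[0].subset == "acoustic"

    def test_matches_brute_force_tournament_oracle(self, rng):
        cfg = FusionConfig()
        subsets = ["biopotential", "acoustic", "combined", "contractions_based"]

        def beats(a, b):
            wins_a = (
                int(a[1].ua_snr > b[1].ua_snr)
                + int(a[1].cost_value > b[1].cost_value)
                + int(a[1].mean_confidence > b[1].mean_confidence)
                + int(a[1].difference_index < b[1].difference_index)
            )
            wins_b = (
                int(b[1].ua_snr > a[1].ua_snr)
                + int(b[1].cost_value > a[1].cost_value)
                + int(b[1].mean_confidence > a[1].mean_confidence)
                + int(b[1].difference_index < a[1].difference_index)
            )
            if wins_a != wins_b:
                return a if wins_a > wins_b else b
            if a[1].cost_value != b[1].cost_value:
                return a if a[1].cost_value < b[1].cost_value else b
            if a[1].difference_index != b[1].difference_index:
                return a if a[1].difference_index < b[1].difference_index else b
            return a if subsets.index(a[0].subset) <= subsets.index(b[0].subset) else b

        for trial in range(30):
            cands = [
                self._cand(s, *np.round(rng.random(4), 2))
                for s in subsets
                for _ in range(2)
            ]
            winners = []
            for s in subsets:
                group = [c for c in cands if c[0].subset == s]
                best = group[0]
                for other in group[1:]:
                    best = beats(best, other)
                winners.append(best)
            expect = winners[0]
            for other in winners[1:]:
                expect = beats(expect, other)
            got = select_final(cands, cfg)
            assert got[1] is expect[1]


class TestFuseAndStitch:
    def test_one_hot_returns_channel(self, rng):
        traces = rng.random((4, 100))
        w = np.array([0.0, 1.0, 0.0, 0.0])
        assert np.allclose(fuse(w, traces), traces[1])

    def test_identical_channels_any_weights(self, rng):
        base = rng.random(100)
        traces = np.tile(base, (5, 1))
        w = rng.random(5)
        w /= w.sum()
        assert np.allclose(fuse(w, traces), base)

    def test_weighted_average_oracle(self, rng):
        traces = rng.random((6, 200))
        w = rng.random(6)
        w /= w.sum()
        ref = sum(w[c] * traces[c] for c in range(6))
        assert np.allclose(fuse(w, traces), ref)

    def test_permutation_invariance(self, rng):
        traces = rng.random((5, 300))
        w = rng.random(5)
        w /= w.sum()
        perm = rng.permutation(5)
        assert np.allclose(fuse(w, traces), fuse(w[perm], traces[perm]))

    def test_stitch_first_frame_unchanged(self, rng):
        seg = rng.random(100)
        assert np.array_equal(stitch(None, seg), seg)

    def test_stitch_offset_continuation_junction_below_tolerance(self, rng):
        full = np.cumsum(rng.standard_normal(400)) * 0.1
        prev, cont = full[:200], full[200:] + 10.0
        out = stitch(prev, cont)
        assert out.size == 400
        assert abs(out[200] - out[199]) <= abs(full[200] - full[199]) + 1e-9

    def test_stitch_lengths_add(self, rng):
        out = stitch(rng.random(150), rng.random(240))
        assert out.size == 390


class TestBuildSubsets:
    def test_subset_sizes(self):
        mods = ["biopotential"] * 8 + ["acoustic"] * 20
        contrs = [[] for _ in range(28)]
        subsets = build_subsets(mods, contrs)
        sizes = {s.subset: s.n_active for s in subsets}
        assert sizes["biopotential"] == 8
        assert sizes["acoustic"] == 20
        assert sizes["combined"] == 28
        assert sizes["contractions_based"] == 28  # fallback, too few contractions
        assert any("contractions_fallback_all" in s.flags for s in subsets)

    def test_feature_dominant_cluster_selected(self, rng):
        mods = ["biopotential"] * 9

        def contr(scale):
            c = Contraction(100.0, 160.0, 130.0, scale)
            c.kurtosis = scale
            c.energy = scale
            c.skewness = scale
            c.rise_time_s = scale * 10
            c.fall_time_s = scale * 10
            return c

        # channels 0-2 dominate 5 of 6 features (duration equal everywhere)
        contrs = [[contr(10.0)] for _ in range(3)]
        contrs += [[contr(1.0)] for _ in range(3)]
        contrs += [[contr(0.1)] for _ in range(3)]
        subsets = build_subsets(mods, contrs, FusionConfig(kmeans_seed=0))
        cb = [s for s in subsets if s.subset == "contractions_based"][0]
        assert set(np.flatnonzero(cb.active)) == {0, 1, 2}

    def test_identical_features_deterministic(self):
        mods = ["biopotential"] * 6
        contrs = [[Contraction(100.0, 160.0, 130.0, 1.0)] for _ in range(6)]
        a = build_subsets(mods, contrs, FusionConfig(kmeans_seed=7))
        b = build_subsets(mods, contrs, FusionConfig(kmeans_seed=7))
        cba = [s for s in a if s.subset == "contractions_based"][0]
        cbb = [s for s in b if s.subset == "contractions_based"][0]
        assert np.array_equal(cba.w, cbb.w)

    def test_no_channels_rejected(self):
        with pytest.raises(ValueError):
            build_subsets([], [])


def test_informative_channel_attracts_weight_mass():
    """With one modulated channel among noise, most weight lands on it."""
    traces = _bump_traces(n_ch=5, seed=11, informative=[2])
    mods = ["biopotential"] * 5
    from cabum.contraction_id import confidence_measures

    per_ch = []
    for row in traces:
        cs = detect_contractions(row, DetectorConfig())
        for c in cs:
            confidence_measures(c, row, cs, DetectorConfig())
        per_ch.append(cs)
    from cabum.fusion import optimize_frame

    seg, w, m = optimize_frame(traces, mods, per_ch, FrameContext(k=1))
    assert w.w[2] > 0.5
    assert np.all(w.w >= 0)
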