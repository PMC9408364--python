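"""Per-tick rules: movement, cultivation, willingness, behavior, run loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from safesim import (
    CultivationWeights,
    GridSpec,
    Worker,
    cultivation_increment,
    generate_behavior,
    init_world,
    move_worker,
    net_willingness,
    onset_tick,
    run,
    step,
    validate_config,
)


def _worker(**kwargs):
    base = dict(id=0, row=0, col=0, sb_cost=45.0, base_intention=20.0)
    base.update(kwargs)
    return Worker(**base)


class TestMovement:
    def test_degenerate_single_cell_torus_keeps_worker_in_place(self, rng):
        w = _worker()
        assert move_worker(w, GridSpec(width=1, height=1), rng) == (0, 0)

    def test_corner_cell_reaches_all_eight_wrapped_neighbors_uniformly(self, rng):
        # From (0, 0) on a 5x5 torus the Moore neighbors wrap to distinct
        # cells; 8000 moves must be uniform under a chi-square test.
        grid = GridSpec(width=5, height=5)
        w = _worker(row=0, col=0)
        counts = {}
        for _ in range(8000):
            dest = move_worker(w, grid, rng)
            counts[dest] = counts.get(dest, 0) + 1
        assert len(counts) == 8
        _, p = stats.chisquare(list(counts.values()))
        assert p > 1e-3

    def test_seeded_trajectory_is_reproducible(self):
        grid = GridSpec(width=7, height=7)
        w = _worker(row=3, col=3)
        path_a = [move_worker(w, grid, np.random.default_rng(7)) for _ in range(1)]
        path_b = [move_worker(w, grid, np.random.default_rng(7)) for _ in range(1)]
        assert path_a == path_b


class TestCultivation:
    def test_equal_fields_give_gain_times_field(self):
        w = CultivationWeights(1 / 3, 1 / 3, 1 / 3, gain=0.5)
        assert cultivation_increment((2, 2, 2), w) == pytest.approx(1.0)

    def test_hand_computed_weighted_mean(self):
        w = CultivationWeights(1 / 3, 1 / 3, 1 / 3, gain=0.75)
        assert cultivation_increment((8, 2, 2), w) == pytest.approx(3.0)

    @given(
        fields=st.tuples(*[st.floats(0, 10)] * 3),
        raw=st.tuples(*[st.floats(0.01, 1)] * 3),
        gain=st.floats(0.01, 5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_increment_bounded_by_gain_times_max_field(self, fields, raw, gain):
        total = sum(raw)
        w = CultivationWeights(*(x / total for x in raw), gain=gain)
        inc = cultivation_increment(fields, w)
        assert 0 <= inc <= gain * 10 + 1e-9

    def test_invalid_weights_rejected(self):
        with pytest.raises(Exception):
            CultivationWeights(0.5, 0.5, 0.5, gain=1)
        with pytest.raises(Exception):
            CultivationWeights(1 / 3, 1 / 3, 1 / 3, gain=0)


class TestWillingness:
    @pytest.mark.parametrize(
        "cultivated, expected_net, willing",
        [(0.0, -25.0, False), (25.0, 0.0, False), (25.1, 0.1, True)],
    )
    def test_net_willingness_and_strict_positivity(self, cultivated, expected_net, willing):
        w = _worker(cultivated=cultivated)
        net = net_willingness(w)
        assert net == pytest.approx(expected_net)
        assert (net > 0) is willing


class TestBehaviorGeneration:
    def test_unwilling_worker_never_exhibits(self, rng):
        assert not any(generate_behavior(False, 1.0, rng) for _ in range(100))

    def test_certain_adoption_always_exhibits(self, rng):
        assert all(generate_behavior(True, 1.0, rng) for _ in range(100))

    def test_empirical_frequency_matches_adoption_probability(self, rng):
        draws = [generate_behavior(True, 0.8, rng) for _ in range(10_000)]
        assert 0.79 <= np.mean(draws) <= 0.81


class TestStepAndRun:
    def test_zero_workers_still_advances_tick(self):
        cfg = validate_config({"initial_workers_count": 0})
        state = init_world(cfg)
        assert step(state, cfg) == (0, 0)
        assert state.tick == 1

    @pytest.mark.parametrize("gain", [0.25, 0.5, 0.75, 1.0, 2.0])
    def test_deterministic_limit_onset_matches_closed_form(
        self, deterministic_config, gain
    ):
        # With identical workers, homogeneous fields at 2, and certain
        # adoption, cultivated willingness after t ticks is 2*gain*t; the
        # first exhibiting tick is the first t with 2*gain*t > 45 - 20.
        cfg = deterministic_config.with_overrides(cultivation_gain=gain)
        res = run(cfg)
        expected = int(np.floor(25 / (2 * gain))) + 1
        assert onset_tick(res) == expected
        # All 50 workers cross simultaneously and p = 1: the series jumps
        # from 0 straight to 50 and stays there.
        assert np.all(res.exhibiting_count[:expected] == 0)
        assert np.all(res.exhibiting_count[expected:] == 50)

    def test_counts_nested_and_bounded(self, default_config):
        res = run(default_config)
        assert np.all(res.exhibiting_count <= res.willing_count)
        assert np.all(res.willing_count <= 50)
        assert np.all(res.exhibiting_count >= 0)

    def test_willing_count_is_monotone(self, default_config):
        for seed in range(20):
            res = run(default_config.with_overrides(seed=seed))
            assert np.all(np.diff(res.willing_count) >= 0)

    def test_run_is_deterministic(self, default_config):
        a, b = run(default_config), run(default_config)
        assert np.array_equal(a.exhibiting_count, b.exhibiting_count)
        assert np.array_equal(a.willing_count, b.willing_count)

    def test_zero_gain_prevents_any_adoption(self, default_config):
        # cultivation_gain must be positive, so take the limit with a gain
        # small enough that no crossing can occur within the tick budget.
        cfg = default_config.with_overrides(cultivation_gain=1e-9)
        for seed in range(50):
            res = run(cfg.with_overrides(seed=seed))
            assert res.exhibiting_count.sum() == 0

    def test_raising_a_field_mean_never_delays_onset_under_coupled_seeds(
        self, default_config
    ):
        for seed in range(30):
            low = run(default_config.with_overrides(seed=seed))
            high = run(
                default_config.with_overrides(seed=seed, initial_igii=8)
            )
            o_low, o_high = onset_tick(low), onset_tick(high)
            if o_low is not None:
                assert o_high is not None and o_high <= o_low

    def test_saturated_plateau_fluctuates_binomially(self):
        # Zero cost and high baseline make every worker willing from the
        # start; the exhibiting count is then i.i.d. Binomial(50, 0.8) per
        # tick. Check mean within 3 sigma and variance within 20% over a
        # 600-tick tail.
        cfg = validate_config(
            {"initial_sb_cost": 0, "initial_sb_intention": 90, "ticks": 600}
        )
        res = run(cfg)
        tail = res.exhibiting_count[100:]
        n, p, t = 50, 0.8, len(tail)
        assert abs(tail.mean() - n * p) <= 3 * np.sqrt(n * p * (1 - p) / t)
        assert abs(tail.var(ddof=1) - n * p * (1 - p)) <= 0.2 * n * p * (1 - p)
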