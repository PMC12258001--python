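"""Spot grouping: envelopes, OFF reassignment, ACO sequencing."""

import numpy as np
import pytest

import csgarc as cg
from csgarc.grouping import (AcoParams, GroupingParams, aco_sequence,
                             brute_force_sequence)
from csgarc.machine_time import plan_bdt


def spot(x, y, mu=1.0, cid="c"):
    return cg.Spot(f"s{x}_{y}", x, y, mu, cid)


class TestEffectivelyUncollimated:
    def test_all_bars_off_is_uncollimated(self):
        s = spot(0.0, 0.0)
        assert cg.is_effectively_uncollimated(s, cg.off_config(), 3.2, 3.0)

    def test_bar_on_spot_axis_is_collimated(self):
        s = spot(5.0, 0.0)
        cfg = cg.TrimmerConfig("c", 65.0, 5.0, 65.0, 65.0)  # edge at x=5
        assert not cg.is_effectively_uncollimated(s, cfg, 3.2, 3.0)

    def test_boundary_exactly_mult_sigma_inclusive(self):
        sigma, mult = 3.0, 3.0
        s = spot(0.0, 0.0)
        cfg = cg.TrimmerConfig("c", 65.0, mult * sigma, 65.0, 65.0)
        assert cg.is_effectively_uncollimated(s, cfg, sigma, mult)


class TestSharedConfig:
    def test_singleton_keeps_own_config(self):
        cfg = cg.TrimmerConfig("c", 10.0, 5.0, 65.0, 65.0)
        out = cg.shared_config([(spot(0, 0), cfg)])
        assert out.bars() == cfg.bars()

    def test_envelope_is_least_collimating(self):
        a = cg.TrimmerConfig("a", 65.0, 5.0, 65.0, 65.0)
        b = cg.TrimmerConfig("b", 65.0, 8.0, 65.0, 65.0)
        out = cg.shared_config([(spot(0, 0), a), (spot(3, 0), b)])
        assert out.x_pos == 8.0

    def test_all_off_group_gives_off(self):
        group = [(spot(0, 0), cg.off_config("a")),
                 (spot(3, 0), cg.off_config("b"))]
        assert cg.shared_config(group).is_off

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cg.shared_config([])


class TestAcoSequencing:
    def _random_configs(self, rng, n):
        return [cg.TrimmerConfig(f"c{i}", *(float(v) for v in
                                            rng.uniform(-10, 65, size=4)))
                for i in range(n)]

    @pytest.mark.parametrize("n", [2, 4, 6])
    def test_matches_brute_force_on_small_instances(self, machine, n):
        aco = AcoParams(n_ants=12, n_iters=60, patience=25)
        for seed in range(50):
            rng = np.random.default_rng(seed)
            configs = self._random_configs(rng, n)
            start = cg.off_config()
            _, best = brute_force_sequence(configs, start, machine)
            _, cost = aco_sequence(configs, start, machine, aco, seed=seed)
            assert cost == pytest.approx(best, rel=1e-9)

    def test_reproducible_for_fixed_seed(self, machine):
        rng = np.random.default_rng(3)
        configs = self._random_configs(rng, 5)
        aco = AcoParams(n_ants=8, n_iters=30)
        a = aco_sequence(configs, cg.off_config(), machine, aco, seed=11)
        b = aco_sequence(configs, cg.off_config(), machine, aco, seed=11)
        assert a == b


def build_cp(rng, n_spots=16, index=0):
    """A control point mixing collimated edge spots and OFF-config spots."""
    spots = []
    configs = []
    for k in range(n_spots):
        x = float(rng.integers(-5, 6)) * 3.0
        y = float(rng.integers(-5, 6)) * 3.0
        cid = f"cp{index}_c{k}"
        if rng.random() < 0.5:  # collimated on one side
            configs.append(cg.TrimmerConfig(cid, 65.0, float(np.clip(x, -20, 65)),
                                            65.0, 65.0))
        else:
            configs.append(cg.off_config(cid))
        spots.append(cg.Spot(f"cp{index}_s{k}", x, y, 1.0, cid))
    return cg.ControlPoint(index=index, gantry_deg=0.0 + 2.8125 * index,
                           energy_mev=100.0, spots=tuple(spots),
                           configs=tuple(configs))


class TestGroupControlPoint:
    def test_group_size_one_keeps_collimated_configs(self, machine):
        rng = np.random.default_rng(0)
        cp = build_cp(rng)
        params = GroupingParams(target_mean_group_size=1.0, seed=0,
                                aco=AcoParams(n_ants=6, n_iters=20, patience=8))
        out = cg.group_control_point(cp, params, machine, cg.off_config())
        # every collimated spot keeps its own aperture; one OFF config total
        n_off = sum(1 for c in out.configs if c.is_off)
        assert n_off == 1
        n_col_before = sum(1 for c in cp.configs if not c.is_off)
        n_col_after = sum(1 for c in out.configs if not c.is_off)
        assert n_col_after == n_col_before

    def test_spots_keep_identity_mu_position(self, machine):
        rng = np.random.default_rng(1)
        cp = build_cp(rng)
        params = GroupingParams(target_mean_group_size=4.0, seed=1,
                                aco=AcoParams(n_ants=6, n_iters=20, patience=8))
        out = cg.group_control_point(cp, params, machine, cg.off_config())
        before = {(s.id, s.x, s.y, s.mu) for s in cp.spots}
        after = {(s.id, s.x, s.y, s.mu) for s in out.spots}
        assert before == after

    def test_no_spot_collimated_tighter_than_baseline(self, machine):
        rng = np.random.default_rng(2)
        cp = build_cp(rng)
        params = GroupingParams(target_mean_group_size=4.0, seed=2,
                                aco=AcoParams(n_ants=6, n_iters=20, patience=8))
        out = cg.group_control_point(cp, params, machine, cg.off_config())
        base = {s.id: cp.config_by_id(s.config_ref) for s in cp.spots}
        for s in out.spots:
            new = out.config_by_id(s.config_ref)
            old = base[s.id]
            assert all(nb >= ob - 1e-9 for nb, ob in zip(new.bars(), old.bars()))

    def test_grouped_trimmer_time_never_worse(self, machine):
        params = GroupingParams(target_mean_group_size=5.0,
                                aco=AcoParams(n_ants=6, n_iters=25, patience=8))
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cp = build_cp(rng)
            plan = cg.ArcPlan(control_points=(cp,))
            out = cg.group_control_point(cp, params, machine, cg.off_config(),
                                         seed=seed)
            gplan = cg.ArcPlan(control_points=(out,))
            assert (plan_bdt(gplan, machine).t_trimmer
                    <= plan_bdt(plan, machine).t_trimmer + 1e-9)


class TestGroupPlan:
    def test_all_uncollimated_collapses_to_single_off(self, machine):
        cps = []
        for i in range(3):
            spots = tuple(cg.Spot(f"cp{i}_s{k}", 3.0 * k, 0.0, 1.0, f"cp{i}_c{k}")
                          for k in range(4))
            configs = tuple(cg.off_config(f"cp{i}_c{k}") for k in range(4))
            cps.append(cg.ControlPoint(i, -10.0 + 10.0 * i, 100.0, spots, configs))
        plan = cg.ArcPlan(control_points=tuple(cps))
        params = GroupingParams(target_mean_group_size=4.0,
                                aco=AcoParams(n_ants=4, n_iters=10, patience=5))
        out, report = cg.group_plan(plan, params, machine)
        assert all(len(cp.configs) == 1 and cp.configs[0].is_off
                   for cp in out.control_points)
        assert plan_bdt(out, machine).t_trimmer == 0.0

    def test_unique_config_count_decreases(self, machine):
        rng = np.random.default_rng(4)
        cps = tuple(build_cp(rng, index=i) for i in range(4))
        plan = cg.ArcPlan(control_points=cps)
        params = GroupingParams(target_mean_group_size=4.0, seed=0,
                                aco=AcoParams(n_ants=6, n_iters=20, patience=8))
        out, report = cg.group_plan(plan, params, machine)
        assert report["configs_after"] < report["configs_before"]

    def test_achieved_mean_group_size_near_target(self, machine):
        # plans with plenty of collimated spots per control point
        rng = np.random.default_rng(5)
        cps = []
        for i in range(6):
            spots, configs = [], []
            for k in range(18):
                x = float(rng.integers(-6, 7)) * 3.0
                cid = f"cp{i}_c{k}"
                configs.append(cg.TrimmerConfig(cid, 65.0,
                                                float(np.clip(x, -20, 65)),
                                                65.0, 65.0))
                spots.append(cg.Spot(f"cp{i}_s{k}", x, 0.0, 1.0, cid))
            cps.append(cg.ControlPoint(i, 2.8125 * i, 100.0, tuple(spots),
                                       tuple(configs)))
        plan = cg.ArcPlan(control_points=tuple(cps))
        for target in (3.0, 6.0):
            params = GroupingParams(target_mean_group_size=target, seed=0,
                                    aco=AcoParams(n_ants=6, n_iters=20,
                                                  patience=8))
            _, report = cg.group_plan(plan, params, machine)
            assert abs(report["mean_group_size"] - target) <= 1.0
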