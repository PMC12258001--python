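"""Trimmer-configuration grouping and sequencing (the "Group" stage).

Baseline collimated arc plans give every spot its own trimmer
configuration, so the trimmers reposition before every spot and the
collimation pause dominates delivery time.  This stage

1. reassigns spots whose trimmers are far enough away to be *effectively
   uncollimated* to the single fully retracted OFF configuration,
2. merges the remaining collimated spots into groups of a user-chosen mean
   size, each group sharing the least-collimating envelope of its members'
   configurations (no spot is ever clipped more tightly than its own plan
   allowed), and
3. orders the resulting configurations within the control point to
   minimize total trimmer travel time, using an elitist ant-colony
   optimizer over visit orders (exact enumeration stays available as an
   oracle for small instances).

Spot monitor units and positions are never altered; only the apertures and
their delivery order change.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .machine_time import trimmer_move_time, trimmer_travel
from .plan_model import (ArcPlan, ControlPoint, MachineModel, Spot,
                         TRIMMER_OFF_MM, TrimmerConfig, off_config)

__all__ = [
    "AcoParams",
    "GroupingParams",
    "is_effectively_uncollimated",
    "shared_config",
    "sequence_cost",
    "brute_force_sequence",
    "aco_sequence",
    "group_control_point",
    "group_plan",
]


@dataclass(frozen=True)
class AcoParams:
    """Elitist ant-system parameters for configuration sequencing.

    ``alpha`` and ``beta`` weight pheromone versus visibility (inverse move
    time), ``rho`` is the evaporation rate, and the best-so-far ant deposits
    ``q / cost`` on its tour each iteration.  ``patience`` stops early after
    that many iterations without improvement.
    """

    n_ants: int = 20
    n_iters: int = 200
    alpha: float = 1.0
    beta: float = 2.0
    rho: float = 0.1
    q: float = 1.0
    patience: int = 50
    #: per-step probability of a uniformly random move (keeps rare
    #: optima reachable after the pheromone trail has converged)
    explore: float = 0.05

    def __post_init__(self):
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (0, 1)")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")


@dataclass(frozen=True)
class GroupingParams:
    """Knobs of the Group stage.

    ``target_mean_group_size`` is the desired mean number of collimated
    spots per shared configuration (efficiency plateaus around 6-10).
    A spot counts as effectively uncollimated when every bar edge is at
    least ``uncollimated_sigma_mult`` spot sigmas from the spot center
    (inclusive); with the default multiplier of 3 an unclipped Gaussian
    spot keeps ~99.7% of its fluence.  ``spot_sigma_mm`` is the in-air
    spot sigma used by that test.
    """

    target_mean_group_size: float = 8.0
    uncollimated_sigma_mult: float = 3.0
    spot_sigma_mm: float = 3.2
    aco: AcoParams = field(default_factory=AcoParams)
    seed: int = 0

    def __post_init__(self):
        if self.target_mean_group_size < 1:
            raise ValueError("target_mean_group_size must be >= 1")


def is_effectively_uncollimated(spot: Spot, config: TrimmerConfig,
                                sigma_mm: float, mult: float = 3.0) -> bool:
    """True iff every bar edge is >= mult*sigma from the spot center (inclusive)."""
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    margin = mult * sigma_mm - 1e-9
    x_lo, x_hi = config.window_x()
    y_lo, y_hi = config.window_y()
    return (spot.x - x_lo >= margin and x_hi - spot.x >= margin and
            spot.y - y_lo >= margin and y_hi - spot.y >= margin)


def shared_config(group: list[tuple[Spot, TrimmerConfig]],
                  config_id: str = "G") -> TrimmerConfig:
    """Least-collimating per-bar envelope of a group's configurations.

    Per bar the farthest-retracted member position is kept, so no spot in
    the group is clipped more tightly than its own configuration allowed.
    """
    if not group:
        raise ValueError("cannot build a shared config for an empty group")
    bars = np.array([c.bars() for _, c in group])
    env = bars.max(axis=0)
    return TrimmerConfig(config_id, *(float(v) for v in env))


# ---------------------------------------------------------------------------
# Configuration sequencing (open-path TSP from a fixed start)
# ---------------------------------------------------------------------------


def _move_time_matrix(configs: list[TrimmerConfig], start: TrimmerConfig,
                      machine: MachineModel) -> np.ndarray:
    """(n+1)x(n+1) move-time matrix; row/col 0 is the arrival state."""
    nodes = [start] + list(configs)
    n = len(nodes)
    t = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                travel = trimmer_travel(nodes[i], nodes[j], machine.trimmer_metric)
                t[i, j] = trimmer_move_time(travel, machine)
    return t


def sequence_cost(order: list[int], tmat: np.ndarray) -> float:
    """Total trimmer time of visiting configs in ``order`` from the start state."""
    cost = 0.0
    prev = 0
    for k in order:
        cost += tmat[prev, k + 1]
        prev = k + 1
    return cost


def brute_force_sequence(configs: list[TrimmerConfig], start: TrimmerConfig,
                         machine: MachineModel) -> tuple[list[int], float]:
    """Exhaustive optimal visit order; oracle for small instances."""
    tmat = _move_time_matrix(configs, start, machine)
    best, best_cost = None, math.inf
    for perm in itertools.permutations(range(len(configs))):
        c = sequence_cost(list(perm), tmat)
        if c < best_cost:
            best, best_cost = list(perm), c
    return best or [], best_cost if best is not None else 0.0


def _local_search(order: list[int], tmat: np.ndarray) -> tuple[list[int], float]:
    """2-opt segment reversal + single-config relocation to a local optimum."""
    best = sequence_cost(order, tmat)
    n = len(order)
    improved = True
    while improved:
        improved = False
        for i in range(n):
            for j in range(i + 1, n):
                cand = order[:i] + order[i:j + 1][::-1] + order[j + 1:]
                c = sequence_cost(cand, tmat)
                if c < best - 1e-15:
                    order, best, improved = cand, c, True
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                cand = list(order)
                cand.insert(j, cand.pop(i))
                c = sequence_cost(cand, tmat)
                if c < best - 1e-15:
                    order, best, improved = cand, c, True
    return order, best


def aco_sequence(configs: list[TrimmerConfig], start: TrimmerConfig,
                 machine: MachineModel, params: AcoParams,
                 seed: int) -> tuple[list[int], float]:
    """Ant-colony visit order minimizing total trimmer move time.

    Construction graph: configuration-visit order starting from the arrival
    trimmer state.  Visibility is the inverse move time (plus a small
    epsilon so zero-cost moves stay finite); pheromone follows an elitist
    ant system in which only the best-so-far tour deposits, with max-min
    bounds and occasional uniform exploration steps; every constructed tour
    is refined by 2-opt/relocation local search.  Deterministic for a fixed
    seed.
    """
    n = len(configs)
    if n == 0:
        return [], 0.0
    if n == 1:
        tmat = _move_time_matrix(configs, start, machine)
        return [0], float(tmat[0, 1])
    tmat = _move_time_matrix(configs, start, machine)
    eps = 1e-6
    eta = 1.0 / (eps + tmat)  # visibility, diagonal unused
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tau = np.ones_like(tmat)
    best_order: list[int] | None = None
    best_cost = math.inf
    stale = 0
    for _ in range(params.n_iters):
        improved = False
        for _ant in range(params.n_ants):
            prev = 0
            left = list(range(1, n + 1))
            order: list[int] = []
            cost = 0.0
            while left:
                w = (tau[prev, left] ** params.alpha) * (eta[prev, left] ** params.beta)
                tot = w.sum()
                if (not np.isfinite(tot) or tot <= 0
                        or rng.random() < params.explore):
                    pick = rng.integers(len(left))
                else:
                    pick = rng.choice(len(left), p=w / tot)
                nxt = left.pop(int(pick))
                cost += tmat[prev, nxt]
                order.append(nxt - 1)
                prev = nxt
            order, cost = _local_search(order, tmat)
            if cost < best_cost - 1e-15:
                best_cost, best_order = cost, order
                improved = True
        tau *= (1.0 - params.rho)
        if best_order is not None:
            deposit = params.q / (eps + best_cost)
            prev = 0
            for k in best_order:
                tau[prev, k + 1] += deposit
                prev = k + 1
            # pheromone bounds keep exploration alive (max-min ant system)
            tau_max = deposit / params.rho
            np.clip(tau, tau_max / (2.0 * (n + 1) ** 2), tau_max, out=tau)
        stale = 0 if improved else stale + 1
        if stale >= params.patience:
            break
    assert best_order is not None
    return best_order, float(best_cost)


# ---------------------------------------------------------------------------
# Group formation
# ---------------------------------------------------------------------------


def _merge_groups(groups: list[list[int]], bars: np.ndarray,
                  n_target: int) -> list[list[int]]:
    """Greedy agglomerative merging of collimated spots by envelope cost.

    ``bars`` holds each spot's own 4-bar configuration.  Merging two groups
    costs the total extra aperture opening the merged envelope imposes on
    the members of both; the cheapest pair is merged until ``n_target``
    groups remain.
    """
    env = [bars[g].max(axis=0) for g in groups]
    opening = [float((env[i] - bars[g]).sum()) for i, g in enumerate(groups)]
    while len(groups) > n_target:
        best, best_cost = None, math.inf
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                e = np.maximum(env[i], env[j])
                cost = float((e - bars[groups[i]]).sum() +
                             (e - bars[groups[j]]).sum()) \
                    - opening[i] - opening[j]
                if cost < best_cost:
                    best, best_cost = (i, j), cost
        i, j = best
        groups[i] = groups[i] + groups[j]
        env[i] = np.maximum(env[i], env[j])
        opening[i] = float((env[i] - bars[groups[i]]).sum())
        del groups[j], env[j], opening[j]
    return groups


def group_control_point(cp: ControlPoint, params: GroupingParams,
                        machine: MachineModel, prev_config: TrimmerConfig,
                        seed: int | None = None) -> ControlPoint:
    """Apply grouping to one control point.

    Effectively uncollimated spots join a single OFF group; collimated
    spots are agglomerated to roughly the target mean group size and each
    group gets the shared envelope configuration.  Configurations are then
    sequenced from ``prev_config`` (the trimmer state on arrival) to
    minimize total trimmer time; spots are reordered to follow their
    configuration but keep their id, MU and position.
    """
    if seed is None:
        seed = params.seed
    by_id = {c.id: c for c in cp.configs}
    pairs = [(s, by_id[s.config_ref]) for s in cp.spots]
    uncol = [p for p in pairs
             if is_effectively_uncollimated(p[0], p[1], params.spot_sigma_mm,
                                            params.uncollimated_sigma_mult)]
    col = [p for p in pairs if not
           is_effectively_uncollimated(p[0], p[1], params.spot_sigma_mm,
                                       params.uncollimated_sigma_mult)]

    groups: list[list[tuple[Spot, TrimmerConfig]]] = []
    if col:
        n_target = max(1, round(len(col) / params.target_mean_group_size))
        bars = np.array([c.bars() for _, c in col])
        idx_groups = _merge_groups([[i] for i in range(len(col))], bars, n_target)
        groups = [[col[i] for i in g] for g in idx_groups]

    configs: list[TrimmerConfig] = []
    members: list[list[Spot]] = []
    off_members: list[Spot] = [s for s, _ in uncol]
    for g in groups:
        env = shared_config(g, config_id=f"cp{cp.index}_g{len(configs)}")
        if env.is_off:
            off_members.extend(s for s, _ in g)
        else:
            configs.append(env)
            members.append([s for s, _ in g])
    if off_members:
        configs.append(off_config(f"cp{cp.index}_off"))
        members.append(off_members)

    order, _ = aco_sequence(configs, prev_config, machine, params.aco,
                            seed=seed * 100003 + cp.index)
    new_configs = tuple(configs[k] for k in order)
    new_spots = tuple(
        replace(s, config_ref=configs[k].id)
        for k in order for s in members[k]
    )
    return replace(cp, spots=new_spots, configs=new_configs)


def group_plan(plan: ArcPlan, params: GroupingParams,
               machine: MachineModel) -> tuple[ArcPlan, dict]:
    """Group every control point, threading the trimmer state across the arc.

    Returns the grouped plan and a small report: unique-configuration
    counts before/after and the achieved mean collimated group size.
    """
    new_cps = []
    prev = off_config()
    n_col_spots = 0
    n_col_groups = 0
    for cp in plan.control_points:
        g = group_control_point(cp, params, machine, prev)
        new_cps.append(g)
        if g.configs:
            prev = g.configs[-1]
        for c in g.configs:
            if not c.is_off:
                n_col_groups += 1
                n_col_spots += sum(1 for s in g.spots if s.config_ref == c.id)
    grouped = replace(plan, control_points=tuple(new_cps))
    report = {
        "configs_before": sum(len(cp.configs) for cp in plan.control_points),
        "configs_after": sum(len(cp.configs) for cp in grouped.control_points),
        "mean_group_size": (n_col_spots / n_col_groups) if n_col_groups else float("nan"),
    }
    return grouped, report
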