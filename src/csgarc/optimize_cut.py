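"""The "Cut" stage, spot-weight reoptimization, and the CSG pipeline.

Cut removes control points whose normalized MU weight falls below a
threshold (30% of the plan-average control-point weight by default); the
surviving spots are then reweighted to recover the dose objectives.  The
full Cut-Sort-Group pipeline chains the three delivery-time reduction
stages in order, reoptimizing spot weights after every stage that changes
plan geometry and renormalizing (but not reoptimizing) after grouping.

Reoptimization minimizes a convex quadratic built from per-structure
terms -- a uniform-dose target term, one-sided overdose/underdose
penalties and mean-dose penalties -- over nonnegative MU, by monotone
projected gradient descent with backtracking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dose_metrics import (DoseState, Phantom, influence_matrix,
                           normalize_to_prescription, quality_indices)
from .grouping import GroupingParams, group_plan
from .machine_time import BDTBreakdown, plan_bdt
from .plan_model import (ArcPlan, MachineModel, MU_FLOOR,
                         control_point_weights, remove_low_mu_spots)
from .swels import SwelsParams, sort_energies, window_capacity

__all__ = [
    "ObjectiveTerm",
    "Objectives",
    "default_objectives",
    "objective_value",
    "cut_control_points",
    "reoptimize_weights",
    "apply_mu",
    "CsgParams",
    "StageRecord",
    "PipelineResult",
    "csg_pipeline",
]


@dataclass(frozen=True)
class ObjectiveTerm:
    """One per-structure penalty.

    ``kind`` is ``uniform`` (quadratic around the goal), ``max`` (one-sided
    overdose), ``min`` (one-sided underdose) or ``mean`` (quadratic on the
    structure mean dose).  Penalties are averaged over the structure's
    voxels so weights are comparable across structure sizes.
    """

    structure: str
    kind: str
    weight: float
    goal_gy: float

    def __post_init__(self):
        if self.kind not in ("uniform", "max", "min", "mean"):
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.weight < 0:
            raise ValueError("objective weights must be nonnegative")


@dataclass(frozen=True)
class Objectives:
    terms: tuple[ObjectiveTerm, ...]

    def __post_init__(self):
        if not any(t.kind in ("uniform", "min") for t in self.terms):
            raise ValueError("need at least one target term")


def default_objectives(prescription_gy: float = 50.0) -> Objectives:
    """Target uniformity at prescription, with mild rind/OAR sparing."""
    return Objectives((
        ObjectiveTerm("PTV", "uniform", 1.0, prescription_gy),
        ObjectiveTerm("rind10mm", "max", 0.05, 0.6 * prescription_gy),
        ObjectiveTerm("OAR", "mean", 0.02, 0.0),
    ))


def _term_masks(objectives: Objectives, phantom: Phantom) -> list[np.ndarray]:
    masks = []
    for t in objectives.terms:
        if t.structure not in phantom.masks:
            raise ValueError(f"objective references unknown structure "
                             f"{t.structure!r}")
        m = np.flatnonzero(phantom.masks[t.structure].ravel())
        if m.size == 0 and t.kind in ("uniform", "min"):
            raise ValueError(f"target structure {t.structure!r} is empty")
        masks.append(m)
    return masks


def objective_value(dose: np.ndarray, objectives: Objectives,
                    phantom: Phantom) -> float:
    """Evaluate the composite quadratic objective at a dose distribution."""
    total = 0.0
    for t, vox in zip(objectives.terms, _term_masks(objectives, phantom)):
        if vox.size == 0:
            continue
        d = dose[vox]
        if t.kind == "uniform":
            total += t.weight * float(np.mean((d - t.goal_gy) ** 2))
        elif t.kind == "max":
            total += t.weight * float(np.mean(np.maximum(d - t.goal_gy, 0.0) ** 2))
        elif t.kind == "min":
            total += t.weight * float(np.mean(np.maximum(t.goal_gy - d, 0.0) ** 2))
        else:  # mean
            total += t.weight * float((np.mean(d) - t.goal_gy) ** 2)
    return total


def _eval_terms(dose_sub, terms, sub_masks):
    """Objective value and dose-space gradient on the objective voxels."""
    f = 0.0
    g = np.zeros_like(dose_sub)
    for t, vox in zip(terms, sub_masks):
        if vox.size == 0:
            continue
        d = dose_sub[vox]
        n = vox.size
        if t.kind == "uniform":
            r = d - t.goal_gy
            f += t.weight * float(r @ r) / n
            g[vox] += t.weight * 2.0 * r / n
        elif t.kind == "max":
            r = np.maximum(d - t.goal_gy, 0.0)
            f += t.weight * float(r @ r) / n
            g[vox] += t.weight * 2.0 * r / n
        elif t.kind == "min":
            r = np.maximum(t.goal_gy - d, 0.0)
            f += t.weight * float(r @ r) / n
            g[vox] -= t.weight * 2.0 * r / n
        else:  # mean
            r = float(np.mean(d)) - t.goal_gy
            f += t.weight * r * r
            g[vox] += t.weight * 2.0 * r / n
    return f, g


def reoptimize_weights(plan: ArcPlan, dose_state: DoseState,
                       objectives: Objectives, phantom: Phantom,
                       x0: np.ndarray | None = None,
                       max_iters: int = 1500, rel_tol: float = 1e-6,
                       callback=None) -> np.ndarray:
    """Nonnegative MU vector minimizing the dose objectives.

    Projected gradient descent with backtracking line search; the objective
    is monotone nonincreasing across iterations and iteration stops when
    its relative change drops below ``rel_tol``.  Only the voxels the
    objective terms reference enter the iteration (the influence matrix is
    sliced to them), so cost scales with the structures, not the grid.  The
    caller applies the result with :func:`apply_mu` (re-applying the
    deliverable-MU floor).
    """
    masks = _term_masks(objectives, phantom)
    union = np.unique(np.concatenate([m for m in masks if m.size] or
                                     [np.zeros(0, dtype=np.int64)]))
    pos = {v: i for i, v in enumerate(union)}
    sub_masks = [np.array([pos[v] for v in m], dtype=np.int64) for m in masks]
    A = dose_state.influence.tocsr()[union].tocsr()
    x = np.maximum(np.asarray(x0 if x0 is not None else dose_state.mu,
                              dtype=float), 0.0)
    At = A.T.tocsr()
    dose = np.asarray(A @ x).ravel()
    f, g_dose = _eval_terms(dose, objectives.terms, sub_masks)
    step = 1.0
    g_prev = None
    x_prev = None
    history: list[float] = []
    for _ in range(max_iters):
        g = np.asarray(At @ g_dose).ravel()
        if g_prev is not None:
            # Barzilai-Borwein spectral step, backtracked to stay monotone
            s = x - x_prev
            y = g - g_prev
            sy = float(s @ y)
            if sy > 1e-30:
                step = float(s @ s) / sy
        g_prev, x_prev = g, x
        while True:
            x_new = np.maximum(x - step * g, 0.0)
            dose_new = np.asarray(A @ x_new).ravel()
            f_new, g_dose_new = _eval_terms(dose_new, objectives.terms,
                                            sub_masks)
            dx = x_new - x
            armijo = f + float(g @ dx) + 0.5 / step * float(dx @ dx)
            if f_new <= armijo + 1e-15 or step < 1e-12:
                break
            step *= 0.5
        if callback is not None:
            callback(f_new)
        # spectral steps make tiny sawtooth progress; judge convergence on
        # the relative decrease over a 10-iteration window
        history.append(f_new)
        x, dose, f, g_dose = x_new, dose_new, f_new, g_dose_new
        if len(history) > 10:
            f_old = history[-11]
            if f_old - f_new <= rel_tol * max(f_old, 1e-30):
                break
    return x


def apply_mu(plan: ArcPlan, dose_state: DoseState, mu: np.ndarray,
             floor_mu: float = MU_FLOOR) -> ArcPlan:
    """Write an optimized MU vector back into a plan.

    Spots falling below the deliverable floor are removed and control
    points they empty are dropped (the standard plan filter re-applied).
    """
    lut = {key: float(v) for key, v in zip(dose_state.spot_ids, mu)}
    cps = tuple(
        replace(cp, spots=tuple(
            replace(s, mu=lut.get((cp.index, s.id), s.mu)) for s in cp.spots))
        for cp in plan.control_points
    )
    return remove_low_mu_spots(replace(plan, control_points=cps), floor_mu)


def cut_control_points(plan: ArcPlan, threshold: float = 0.30) -> ArcPlan:
    """Remove control points whose normalized weight is below ``threshold``.

    Weights are MU sums normalized to the plan average; order is preserved
    and indices reassigned.  Refuses to empty the plan entirely.
    """
    weights = control_point_weights(plan)
    keep = [cp for cp, w in zip(plan.control_points, weights) if w >= threshold]
    if not keep:
        raise ValueError(f"cut threshold {threshold:g} would remove every "
                         "control point")
    return replace(plan, control_points=tuple(keep)).reindexed()


# ---------------------------------------------------------------------------
# The full pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CsgParams:
    cut_threshold: float = 0.30
    swels: SwelsParams = field(default_factory=lambda: SwelsParams(25.0))
    grouping: GroupingParams = field(default_factory=GroupingParams)
    objectives: Objectives | None = None
    seed: int = 0
    #: iteration budget for the per-stage weight reoptimizations
    reopt_max_iters: int = 400


@dataclass(frozen=True)
class StageRecord:
    """Snapshot after one pipeline stage."""

    name: str
    n_control_points: int
    bdt: BDTBreakdown
    indices: object  # DoseIndices


@dataclass(frozen=True)
class PipelineResult:
    plan: ArcPlan
    stages: tuple[StageRecord, ...]
    grouping_report: dict

    def stage(self, name: str) -> StageRecord:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)


def _aperture_signature(plan: ArcPlan):
    """Dose-relevant content: each spot's MU, position and aperture window."""
    sig = []
    for cp in plan.control_points:
        by_id = {c.id: c for c in cp.configs}
        sig.append(frozenset(
            (s.id, s.x, s.y, s.mu, by_id[s.config_ref].bars())
            for s in cp.spots))
    return sig


def _record(name, plan, phantom, machine, dose=None) -> tuple[StageRecord, np.ndarray]:
    from .dose_metrics import compute_dose
    if dose is None:
        dose = compute_dose(plan, phantom)
    rec = StageRecord(name, plan.n_control_points, plan_bdt(plan, machine),
                      quality_indices(dose, phantom, plan.prescription_gy))
    return rec, dose


def csg_pipeline(plan: ArcPlan, phantom: Phantom, machine: MachineModel,
                 params: CsgParams) -> PipelineResult:
    """Run Cut -> Sort -> Group on a normalized baseline plan.

    Spot weights are reoptimized after Cut and after Sort whenever the
    stage actually changed the plan (spot lattices are regenerated for
    energy layers Sort remapped to new gantry angles); after Group only the
    D95 prescription normalization is re-applied -- the grouped apertures
    are taken as found.  Returns the final plan plus per-stage delivery
    times and quality indices.
    """
    objectives = params.objectives or default_objectives(plan.prescription_gy)
    stages = []
    rec, dose = _record("baseline", plan, phantom, machine)
    stages.append(rec)

    # --- Cut ---------------------------------------------------------------
    current = cut_control_points(plan, params.cut_threshold)
    if current.n_control_points != plan.n_control_points:
        state = influence_matrix(current, phantom)
        x = reoptimize_weights(current, state, objectives, phantom,
                               max_iters=params.reopt_max_iters)
        current = apply_mu(current, state, x)
        dose = state.dose(np.where(x >= MU_FLOOR, x, 0.0))
    rec, dose = _record("cut", current, phantom, machine, dose)
    stages.append(rec)

    # --- Sort --------------------------------------------------------------
    if window_capacity(params.swels) >= 2:
        sorted_plan = sort_energies(current, params.swels)
        if sorted_plan.energies() != current.energies():
            from .synthetic import regenerate_spots
            sorted_plan = regenerate_spots(sorted_plan, phantom)
            state = influence_matrix(sorted_plan, phantom)
            x = reoptimize_weights(sorted_plan, state, objectives, phantom,
                                   max_iters=params.reopt_max_iters)
            current = apply_mu(sorted_plan, state, x)
            dose = state.dose(np.where(x >= MU_FLOOR, x, 0.0))
        else:
            current = sorted_plan
    rec, dose = _record("sort", current, phantom, machine, dose)
    stages.append(rec)

    # --- Group -------------------------------------------------------------
    gparams = replace(params.grouping, seed=params.seed)
    grouped, greport = group_plan(current, gparams, machine)
    if _aperture_signature(grouped) != _aperture_signature(current):
        # apertures were relaxed: dose changed, re-pin D95 to prescription
        from .dose_metrics import compute_dose
        gdose = compute_dose(grouped, phantom)
        grouped, factor = normalize_to_prescription(grouped, gdose, phantom)
        dose = gdose * factor
    current = grouped
    rec, dose = _record("group", current, phantom, machine, dose)
    stages.append(rec)

    return PipelineResult(current, tuple(stages), greport)
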