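"""Beam-delivery-time (BDT) model for collimated step-and-shoot arcs.

Delivery of a discrete collimated arc is strictly sequential: the gantry
moves to a planned position and stops, the energy is switched if the layer
changed, then trimmer positioning and spot delivery alternate configuration
by configuration, after which the gantry moves on.  Total BDT therefore
decomposes exactly into four components -- gantry motion, energy switching,
trimmer (collimation) motion, and spot delivery -- and this module computes
each from machine kinematic parameters.

The same module houses the manual-intervention model used for conventional
few-field IMPT comparisons: a fixed pause between beams plus a larger pause
whenever the couch angle changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .plan_model import ArcPlan, ImptBeam, MachineModel, TrimmerConfig, off_config, validate_plan

__all__ = [
    "BDTBreakdown",
    "gantry_move_time",
    "energy_switch_time",
    "spot_time",
    "trimmer_travel",
    "trimmer_move_time",
    "plan_bdt",
    "impt_intervention_time",
    "IMPT_INTERBEAM_S",
    "IMPT_COUCH_KICK_S",
]

#: Manual-intervention pauses for IMPT delivery: between any two beams, and
#: additionally when a couch kick (couch-angle change) is required.
IMPT_INTERBEAM_S = 30.0
IMPT_COUCH_KICK_S = 120.0


@dataclass(frozen=True)
class BDTBreakdown:
    """Per-component delivery time in seconds; ``total`` is their exact sum."""

    t_gantry: float
    t_energy: float
    t_trimmer: float
    t_spot: float

    @property
    def total(self) -> float:
        return self.t_gantry + self.t_energy + self.t_trimmer + self.t_spot

    @property
    def total_min(self) -> float:
        return self.total / 60.0

    def as_dict(self) -> dict[str, float]:
        return {"t_gantry": self.t_gantry, "t_energy": self.t_energy,
                "t_trimmer": self.t_trimmer, "t_spot": self.t_spot,
                "total": self.total}


def gantry_move_time(distance_deg: float, machine: MachineModel) -> float:
    """Rest-to-rest time for a step-and-shoot gantry move of ``distance_deg``.

    Symmetric trapezoidal velocity profile with top speed ``v_max`` and
    acceleration ``a_max``: moves long enough to reach top speed
    (d >= v^2/a) take ``d/v + v/a`` seconds, shorter moves follow the
    triangular profile ``2*sqrt(d/a)``.  The two branches agree at the
    changeover distance.
    """
    if distance_deg < 0:
        raise ValueError("gantry move distance must be nonnegative")
    v, a = machine.v_max, machine.a_max
    if distance_deg >= v * v / a:
        return distance_deg / v + v / a
    return 2.0 * math.sqrt(distance_deg / a)


def energy_switch_time(e_from: float, e_to: float, machine: MachineModel) -> float:
    """Layer-switch pause: slow going up in energy, fast going down, 0 if equal."""
    if e_from <= 0 or e_to <= 0:
        raise ValueError("energies must be positive")
    if e_to > e_from:
        return machine.t_up
    if e_to < e_from:
        return machine.t_down
    return 0.0


def spot_time(mu: float, machine: MachineModel) -> float:
    """Time to deliver one spot: linear in MU plus a fixed scanning slew."""
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    return (machine.spot_slope * mu + machine.spot_slew) / 1000.0


def trimmer_travel(a: TrimmerConfig, b: TrimmerConfig,
                   metric: str = "max_bar") -> float:
    """Travel (mm) between two configurations.

    ``max_bar``: the four bars move simultaneously, so the largest single-bar
    excursion gates the pause.  ``sum_bars``: total travel of all bars, for
    sensitivity studies.
    """
    deltas = [abs(pb - pa) for pa, pb in zip(a.bars(), b.bars())]
    if metric == "max_bar":
        return max(deltas)
    if metric == "sum_bars":
        return sum(deltas)
    raise ValueError(f"unknown trimmer metric {metric!r}")


def trimmer_move_time(travel_mm: float, machine: MachineModel) -> float:
    """Collimation pause for a given trimmer travel, second-order polynomial.

    Zero travel means no reposition and no pause; otherwise
    ``c0 + c1*travel + c2*travel**2`` with the machine's coefficients.
    """
    if travel_mm < 0:
        raise ValueError("trimmer travel must be nonnegative")
    if travel_mm == 0:
        return 0.0
    c0, c1, c2 = machine.trimmer_poly
    t = c0 + c1 * travel_mm + c2 * travel_mm * travel_mm
    if t < 0:
        raise ValueError("trimmer time polynomial produced a negative time; "
                         "check trimmer_poly coefficients")
    return t


def plan_bdt(plan: ArcPlan, machine: MachineModel) -> BDTBreakdown:
    """Total BDT of an arc plan, broken into its four sequential components.

    Event order per control point: energy switch (none charged before the
    first control point), then alternating trimmer repositioning and spot
    delivery following the listed configuration order.  The trimmer state on
    arrival at a control point is the last configuration of the previous
    control point (fully retracted OFF before the first).  Gantry moves are
    rest-to-rest between consecutive planned angles and purely additive.
    """
    if plan.control_points:
        validate_plan(plan)
    t_gantry = t_energy = t_trimmer = t_spot = 0.0
    prev_energy: float | None = None
    prev_config: TrimmerConfig = off_config()
    prev_angle: float | None = None
    for cp in plan.control_points:
        if prev_angle is not None:
            t_gantry += gantry_move_time(abs(cp.gantry_deg - prev_angle), machine)
        prev_angle = cp.gantry_deg
        if prev_energy is not None:
            t_energy += energy_switch_time(prev_energy, cp.energy_mev, machine)
        prev_energy = cp.energy_mev
        for config, spots in cp.spots_by_config():
            travel = trimmer_travel(prev_config, config, machine.trimmer_metric)
            t_trimmer += trimmer_move_time(travel, machine)
            prev_config = config
            for s in spots:
                t_spot += spot_time(s.mu, machine)
    return BDTBreakdown(t_gantry, t_energy, t_trimmer, t_spot)


def impt_intervention_time(beams: Sequence[ImptBeam]) -> float:
    """Manual-intervention time (s) between the beams of an IMPT plan.

    Every transition between consecutive beams costs 30 s (alignment checks,
    re-imaging, readiness); a transition that changes the couch angle costs
    an additional 120 s couch kick.  A single beam needs no intervention.
    """
    if not beams:
        raise ValueError("need at least one beam")
    total = 0.0
    for prev, nxt in zip(beams, beams[1:]):
        total += IMPT_INTERBEAM_S
        if nxt.couch_deg != prev.couch_deg:
            total += IMPT_COUCH_KICK_S
    return total
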