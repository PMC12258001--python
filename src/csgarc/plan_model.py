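"""Domain model for collimated step-and-shoot proton arc plans.

An arc plan is an ordered sequence of *control points*: one gantry position
carrying a single energy layer, a set of pencil-beam spots (each with a
monitor-unit weight and a beam's-eye-view position) and the trimmer
configurations of a dynamic collimation system (DCS).  A trimmer
configuration is the position of four sliding bars -- two per lateral axis
-- whose medial edges shape the field around individual spots.

Conventions
-----------
* Gantry angles are degrees, IEC convention, stored in delivery order; a
  clockwise full arc runs from -180 to +180 with strictly increasing angle.
* Trimmer bar positions are signed distances (mm) of each bar's medial edge
  from the beam central axis in the beam's-eye view, positive meaning the
  bar is retracted away from the axis on its own side.  65 mm is the fully
  retracted "off" position; -20 mm is the permitted over-travel across the
  axis.
* Spot monitor units (MU) are dimensionless machine output; any *validated*
  plan carries only spots of at least 0.025 MU (lower-weight spots are not
  deliverable and are filtered out, along with control points they leave
  empty).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "TRIMMER_OFF_MM",
    "TRIMMER_MIN_MM",
    "MU_FLOOR",
    "PlanError",
    "PlanSchemaError",
    "PlanValidationError",
    "TrimmerConfig",
    "Spot",
    "ControlPoint",
    "ArcPlan",
    "MachineModel",
    "ImptBeam",
    "off_config",
    "read_plan",
    "write_plan",
    "plan_to_dict",
    "plan_from_dict",
    "validate_plan",
    "remove_low_mu_spots",
    "control_point_weights",
    "load_machine",
]

#: Fully retracted "off" trimmer position: 6.5 cm from the central axis.
TRIMMER_OFF_MM = 65.0
#: Permissive over-travel bound for a bar crossing the central axis.
TRIMMER_MIN_MM = -20.0
#: Minimum deliverable spot weight; lighter spots are excluded from plans.
MU_FLOOR = 0.025

#: Number of decimals kept by the canonical JSON serialization.
_CANON_DECIMALS = 6


class PlanError(Exception):
    """Base class for plan-related errors."""


class PlanSchemaError(PlanError):
    """A plan document does not conform to the JSON plan schema."""


class PlanValidationError(PlanError):
    """A structurally well-formed plan violates a domain invariant."""

    def __init__(self, failures: Sequence[str]):
        self.failures = list(failures)
        super().__init__("plan validation failed:\n  " + "\n  ".join(self.failures))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrimmerConfig:
    """One DCS trimmer configuration: four bar positions in beam's-eye view.

    ``x_neg``/``x_pos`` are the bars bounding the field on the negative and
    positive lateral (IEC X) side, ``y_neg``/``y_pos`` on the IEC Y axis.
    Each value is the signed distance of the bar's medial edge from the beam
    central axis on that bar's own side: the open field on x is the interval
    ``[-x_neg, +x_pos]`` in absolute beam's-eye-view coordinates.
    """

    id: str
    x_neg: float
    x_pos: float
    y_neg: float
    y_pos: float

    def bars(self) -> tuple[float, float, float, float]:
        return (self.x_neg, self.x_pos, self.y_neg, self.y_pos)

    @property
    def is_off(self) -> bool:
        return all(abs(b - TRIMMER_OFF_MM) < 1e-9 for b in self.bars())

    def window_x(self) -> tuple[float, float]:
        """Open interval on the x axis in absolute BEV coordinates (mm)."""
        return (-self.x_neg, self.x_pos)

    def window_y(self) -> tuple[float, float]:
        return (-self.y_neg, self.y_pos)


def off_config(config_id: str = "OFF") -> TrimmerConfig:
    """The canonical fully retracted configuration (all bars at 65 mm)."""
    return TrimmerConfig(config_id, TRIMMER_OFF_MM, TRIMMER_OFF_MM,
                         TRIMMER_OFF_MM, TRIMMER_OFF_MM)


@dataclass(frozen=True)
class Spot:
    """A single pencil-beam spot: BEV position (mm at isocenter) and MU."""

    id: str
    x: float
    y: float
    mu: float
    config_ref: str


@dataclass(frozen=True)
class ControlPoint:
    """One gantry position: a single energy layer, its spots and configs.

    ``configs`` is the delivery order of trimmer-configuration changes;
    spots are delivered grouped by configuration in that order.
    """

    index: int
    gantry_deg: float
    energy_mev: float
    spots: tuple[Spot, ...]
    configs: tuple[TrimmerConfig, ...]

    def config_by_id(self, config_id: str) -> TrimmerConfig:
        for c in self.configs:
            if c.id == config_id:
                return c
        raise KeyError(config_id)

    def mu_total(self) -> float:
        return sum(s.mu for s in self.spots)

    def spots_by_config(self) -> list[tuple[TrimmerConfig, list[Spot]]]:
        """Spots bucketed by configuration, in configuration delivery order."""
        buckets: dict[str, list[Spot]] = {c.id: [] for c in self.configs}
        for s in self.spots:
            buckets[s.config_ref].append(s)
        return [(c, buckets[c.id]) for c in self.configs]


@dataclass(frozen=True)
class ArcPlan:
    """An ordered step-and-shoot arc plan plus prescription metadata."""

    control_points: tuple[ControlPoint, ...]
    prescription_gy: float = 50.0
    #: normalization rule: prescription delivered to `d_quantile_pct` of the
    #: target at `level_pct` percent of the prescription (D95% = 100%).
    normalization: tuple[float, float] = (95.0, 100.0)
    arc_resolution_deg: float = 2.8125
    clockwise: bool = True

    @property
    def n_control_points(self) -> int:
        return len(self.control_points)

    def energies(self) -> list[float]:
        return [cp.energy_mev for cp in self.control_points]

    def gantry_angles(self) -> list[float]:
        return [cp.gantry_deg for cp in self.control_points]

    def reindexed(self) -> "ArcPlan":
        """Return a copy whose control points carry 0-based delivery indices."""
        cps = tuple(replace(cp, index=i) for i, cp in enumerate(self.control_points))
        return replace(self, control_points=cps)


@dataclass(frozen=True)
class MachineModel:
    """Every delivery-time parameter of the treatment machine.

    Defaults describe an IBA ProteusPLUS-class gantry with a DCS mounted on
    the nozzle: 6 deg/s maximum gantry speed, 0.6 deg/s^2 acceleration,
    6 s low-to-high and 0.8 s high-to-low energy switches, spot delivery at
    6.6 ms/MU plus 2.2 ms magnet slew.  ``trimmer_poly`` are second-order
    polynomial coefficients (c0, c1, c2) mapping trimmer travel (mm) to the
    programmed collimation pause (s); the shipped default is a documented
    configuration value (a full 65 mm throw takes about 0.9 s), not a fitted
    machine constant.
    """

    v_max: float = 6.0          # deg/s
    a_max: float = 0.6          # deg/s^2
    t_up: float = 6.0           # s, low-to-high energy switch
    t_down: float = 0.8         # s, high-to-low energy switch
    spot_slope: float = 6.6     # ms/MU
    spot_slew: float = 2.2      # ms
    trimmer_poly: tuple[float, float, float] = (0.3, 0.008, 2e-5)
    trimmer_metric: str = "max_bar"  # or "sum_bars"
    off_position_mm: float = TRIMMER_OFF_MM

    def __post_init__(self):
        if self.v_max <= 0 or self.a_max <= 0:
            raise ValueError("v_max and a_max must be positive")
        for name in ("t_up", "t_down", "spot_slope", "spot_slew"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.trimmer_metric not in ("max_bar", "sum_bars"):
            raise ValueError("trimmer_metric must be 'max_bar' or 'sum_bars'")


@dataclass(frozen=True)
class ImptBeam:
    """A static IMPT field; only the couch/gantry angles matter here."""

    gantry_deg: float
    couch_deg: float

    def __post_init__(self):
        if not (math.isfinite(self.gantry_deg) and math.isfinite(self.couch_deg)):
            raise ValueError("beam angles must be finite")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_plan(plan: ArcPlan, mu_floor: float = MU_FLOOR) -> None:
    """Check every ArcPlan invariant; raise PlanValidationError listing failures.

    Checks performed: at least the bar bounds on every trimmer configuration,
    resolvable spot->config references, one-energy-per-control-point (by
    construction), no empty control points, the deliverable-MU floor, and
    strict monotonicity of gantry angles in delivery order.
    """
    failures: list[str] = []
    for cp in plan.control_points:
        tag = f"control point {cp.index} (gantry {cp.gantry_deg:g} deg)"
        if cp.energy_mev <= 0:
            failures.append(f"{tag}: nonpositive energy {cp.energy_mev}")
        if not cp.spots:
            failures.append(f"{tag}: has no spots")
        config_ids = [c.id for c in cp.configs]
        if len(set(config_ids)) != len(config_ids):
            failures.append(f"{tag}: duplicate config ids")
        for c in cp.configs:
            for bar_name, v in zip(("x_neg", "x_pos", "y_neg", "y_pos"), c.bars()):
                if not (TRIMMER_MIN_MM - 1e-9 <= v <= TRIMMER_OFF_MM + 1e-9):
                    failures.append(
                        f"{tag}: config {c.id} bar {bar_name}={v:g} mm outside "
                        f"[{TRIMMER_MIN_MM:g}, {TRIMMER_OFF_MM:g}]")
        known = set(config_ids)
        for s in cp.spots:
            if s.config_ref not in known:
                failures.append(f"{tag}: spot {s.id} references unknown config "
                                f"{s.config_ref!r}")
            if s.mu < mu_floor - 1e-12:
                failures.append(f"{tag}: spot {s.id} mu={s.mu:g} below the "
                                f"{mu_floor:g} MU floor")
    angles = plan.gantry_angles()
    deltas = [b - a for a, b in zip(angles, angles[1:])]
    if plan.clockwise:
        if any(d <= 0 for d in deltas):
            failures.append("gantry angles not strictly increasing")
    else:
        if any(d >= 0 for d in deltas):
            failures.append("gantry angles not strictly decreasing")
    if failures:
        raise PlanValidationError(failures)


# ---------------------------------------------------------------------------
# JSON plan documents
# ---------------------------------------------------------------------------


def _canon(x: float) -> float:
    """Round to the canonical serialization precision (idempotent)."""
    return round(float(x), _CANON_DECIMALS)


def plan_to_dict(plan: ArcPlan) -> dict:
    return {
        "meta": {
            "prescription_gy": _canon(plan.prescription_gy),
            "normalization": {
                "d_quantile_pct": _canon(plan.normalization[0]),
                "level_pct": _canon(plan.normalization[1]),
            },
            "resolution_deg": _canon(plan.arc_resolution_deg),
            "clockwise": bool(plan.clockwise),
        },
        "control_points": [
            {
                "gantry_deg": _canon(cp.gantry_deg),
                "energy_mev": _canon(cp.energy_mev),
                "configs": [
                    {"id": c.id, "x_neg": _canon(c.x_neg), "x_pos": _canon(c.x_pos),
                     "y_neg": _canon(c.y_neg), "y_pos": _canon(c.y_pos)}
                    for c in cp.configs
                ],
                "spots": [
                    {"id": s.id, "x_mm": _canon(s.x), "y_mm": _canon(s.y),
                     "mu": _canon(s.mu), "config": s.config_ref}
                    for s in cp.spots
                ],
            }
            for cp in plan.control_points
        ],
    }


def _require(doc: dict, key: str, context: str):
    if key not in doc:
        raise PlanSchemaError(f"missing field {context}.{key}")
    return doc[key]


def plan_from_dict(doc: dict) -> ArcPlan:
    if not isinstance(doc, dict):
        raise PlanSchemaError("plan document must be a JSON object")
    meta = _require(doc, "meta", "$")
    norm = _require(meta, "normalization", "meta")
    cps_doc = _require(doc, "control_points", "$")
    cps = []
    for i, cp_doc in enumerate(cps_doc):
        ctx = f"control_points[{i}]"
        configs = tuple(
            TrimmerConfig(
                id=str(_require(c, "id", f"{ctx}.configs[{j}]")),
                x_neg=float(_require(c, "x_neg", f"{ctx}.configs[{j}]")),
                x_pos=float(_require(c, "x_pos", f"{ctx}.configs[{j}]")),
                y_neg=float(_require(c, "y_neg", f"{ctx}.configs[{j}]")),
                y_pos=float(_require(c, "y_pos", f"{ctx}.configs[{j}]")),
            )
            for j, c in enumerate(_require(cp_doc, "configs", ctx))
        )
        spots = tuple(
            Spot(
                id=str(_require(s, "id", f"{ctx}.spots[{j}]")),
                x=float(_require(s, "x_mm", f"{ctx}.spots[{j}]")),
                y=float(_require(s, "y_mm", f"{ctx}.spots[{j}]")),
                mu=float(_require(s, "mu", f"{ctx}.spots[{j}]")),
                config_ref=str(_require(s, "config", f"{ctx}.spots[{j}]")),
            )
            for j, s in enumerate(_require(cp_doc, "spots", ctx))
        )
        cps.append(ControlPoint(
            index=i,
            gantry_deg=float(_require(cp_doc, "gantry_deg", ctx)),
            energy_mev=float(_require(cp_doc, "energy_mev", ctx)),
            spots=spots,
            configs=configs,
        ))
    return ArcPlan(
        control_points=tuple(cps),
        prescription_gy=float(_require(meta, "prescription_gy", "meta")),
        normalization=(float(_require(norm, "d_quantile_pct", "meta.normalization")),
                       float(_require(norm, "level_pct", "meta.normalization"))),
        arc_resolution_deg=float(_require(meta, "resolution_deg", "meta")),
        clockwise=bool(meta.get("clockwise", True)),
    )


def read_plan(path: str | Path) -> ArcPlan:
    """Read and validate an arc plan from a canonical JSON document."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise PlanSchemaError(f"not valid JSON: {exc}") from exc
    plan = plan_from_dict(doc)
    validate_plan(plan)
    return plan


def write_plan(plan: ArcPlan, path: str | Path) -> None:
    """Validate, then serialize a plan to canonical JSON (stable round-trips)."""
    validate_plan(plan)
    doc = plan_to_dict(plan)
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Plan filters and bookkeeping
# ---------------------------------------------------------------------------


def remove_low_mu_spots(plan: ArcPlan, floor_mu: float = MU_FLOOR) -> ArcPlan:
    """Drop spots below the deliverable-MU floor and any emptied control points.

    Order is preserved and trimmer configurations no spot references any more
    are dropped with their spots.  Idempotent; an empty plan is a legal
    output.
    """
    new_cps = []
    for cp in plan.control_points:
        spots = tuple(s for s in cp.spots if s.mu >= floor_mu)
        if not spots:
            continue
        used = {s.config_ref for s in spots}
        configs = tuple(c for c in cp.configs if c.id in used)
        new_cps.append(replace(cp, spots=spots, configs=configs))
    return replace(plan, control_points=tuple(new_cps)).reindexed()


def control_point_weights(plan: ArcPlan) -> list[float]:
    """Per-control-point MU sums normalized to the plan-average sum.

    The returned sequence always averages to exactly 1 (up to floating
    point); a uniform plan maps to all-ones.
    """
    if not plan.control_points:
        raise ValueError("cannot compute weights of an empty plan")
    sums = [cp.mu_total() for cp in plan.control_points]
    mean = sum(sums) / len(sums)
    if mean <= 0:
        raise ValueError("plan has zero total MU")
    return [s / mean for s in sums]


# ---------------------------------------------------------------------------
# Machine-parameter files
# ---------------------------------------------------------------------------


def load_machine(path: str | Path) -> MachineModel:
    """Load a MachineModel from a YAML (or JSON) parameter file.

    The file carries any subset of the MachineModel fields; omitted fields
    keep their defaults.  ``trimmer_poly`` may be a 3-element list.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise PlanSchemaError("machine file must be a mapping")
    known = {f for f in MachineModel.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise PlanSchemaError(f"unknown machine parameter(s): {sorted(unknown)}")
    if "trimmer_poly" in doc:
        doc["trimmer_poly"] = tuple(float(c) for c in doc["trimmer_poly"])
    return MachineModel(**doc)
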