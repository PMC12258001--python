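"""Synthetic water phantom and baseline collimated arc plans.

Generates everything the rest of the package needs without patient data: a
spherical water phantom with a PTV, an eroded CTV, a 10 mm rind and an
adjacent OAR, plus a baseline single-arc plan with the structural
properties of a dynamically collimated step-and-shoot arc -- 129 equally
spaced gantry positions over a full clockwise arc, one energy layer per
control point, a 3 mm spot lattice covering the target's beam's-eye-view
projection with a 6 mm expansion, per-spot trimmer configurations with the
bars of out-of-target spots placed at 0 mm offset from the spot axis, spot
weights from the quadratic dose objectives, the 0.025 MU deliverability
filter and D95 prescription normalization.

Per-control-point energies cycle deterministically over target depth slabs
(a round-robin stand-in for per-angle energy selection), which yields the
non-monotone energy sequences the Sort stage exists to clean up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .dose_metrics import (EngineParams, Phantom, energy_to_range,
                           influence_matrix, normalize_to_prescription,
                           range_to_energy)
from .optimize_cut import (Objectives, apply_mu, default_objectives,
                           reoptimize_weights)
from .plan_model import (ArcPlan, ControlPoint, MachineModel, MU_FLOOR, Spot,
                         TRIMMER_MIN_MM, TRIMMER_OFF_MM, TrimmerConfig,
                         off_config, remove_low_mu_spots, validate_plan)

__all__ = [
    "PhantomSpec",
    "desk_scale_spec",
    "make_phantom",
    "make_baseline_plan",
    "regenerate_spots",
    "make_energy_sequence_fixture",
]

#: Depth fractions visited round-robin by the energy selection heuristic.
_DEPTH_SLABS = 8
_SLAB_STRIDE = 3  # coprime with _DEPTH_SLABS: visits all slabs, non-monotone


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic scene (all lengths mm).

    The phantom is a water sphere centered on the isocenter; the PTV an
    ellipsoid (equal radii give a sphere) at ``ptv_center``; the CTV is the
    PTV eroded by ``ctv_margin``; the rind is a ``rind_mm`` shell around
    the PTV; the OAR a sphere.  Defaults describe a cranial-scale scene:
    170 mm phantom radius, 20 mm PTV, one adjacent 12 mm OAR.
    """

    phantom_radius: float = 170.0
    ptv_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ptv_radii: tuple[float, float, float] = (20.0, 20.0, 20.0)
    oar_center: tuple[float, float, float] = (36.0, 0.0, 0.0)
    oar_radius: float = 12.0
    rind_mm: float = 10.0
    ctv_margin: float = 3.0
    spacing: float = 3.0


def desk_scale_spec() -> PhantomSpec:
    """A small scene for fast end-to-end runs: 33 mm phantom, 7.5 mm PTV."""
    return PhantomSpec(phantom_radius=33.0,
                       ptv_radii=(7.5, 7.5, 7.5),
                       oar_center=(13.5, 0.0, 0.0), oar_radius=6.0)


def _ellipsoid_mask(pts: np.ndarray, center, radii) -> np.ndarray:
    r = (pts - np.asarray(center)) / np.asarray(radii)
    return (r * r).sum(axis=1) <= 1.0


def make_phantom(spec: PhantomSpec,
                 engine: EngineParams | None = None) -> Phantom:
    """Voxelize the scene onto the 3 mm grid.

    Masks satisfy the structural invariants: PTV inside the external
    contour, rind = (PTV dilated by ``rind_mm``) minus PTV, disjoint from
    the PTV, everything clipped to the external sphere.  Deterministic for
    a fixed spec.
    """
    sp = spec.spacing
    n = 2 * math.ceil(spec.phantom_radius / sp) + 3
    shape = (n, n, n)
    origin = -sp * (n - 1) / 2.0
    idx = np.indices(shape).reshape(3, -1).T
    pts = origin + sp * idx

    external = (pts ** 2).sum(axis=1) <= spec.phantom_radius ** 2
    ptv = _ellipsoid_mask(pts, spec.ptv_center, spec.ptv_radii)
    if np.any(ptv & ~external):
        raise ValueError("PTV extends outside the phantom")
    if not np.any(ptv):
        raise ValueError("PTV mask is empty at this grid resolution")
    oar = _ellipsoid_mask(pts, spec.oar_center, (spec.oar_radius,) * 3) & external

    ptv3 = ptv.reshape(shape)
    ball_r = max(1, int(round(spec.rind_mm / sp)))
    ball = _ball_structure(ball_r)
    rind = ndimage.binary_dilation(ptv3, structure=ball) & ~ptv3
    rind &= external.reshape(shape)
    erode_r = max(1, int(round(spec.ctv_margin / sp)))
    ctv = ndimage.binary_erosion(ptv3, structure=_ball_structure(erode_r))
    if not ctv.any():
        ctv = ptv3.copy()  # margin exceeds target size: CTV degenerates to PTV

    density = external.astype(float).reshape(shape)
    masks = {
        "external": external.reshape(shape),
        "PTV": ptv3,
        "CTV": ctv,
        "rind10mm": rind,
        "OAR": oar.reshape(shape),
    }
    return Phantom(shape=shape, spacing=sp, density=density, masks=masks,
                   engine=engine or EngineParams())


def _ball_structure(r_vox: int) -> np.ndarray:
    z, y, x = np.ogrid[-r_vox:r_vox + 1, -r_vox:r_vox + 1, -r_vox:r_vox + 1]
    return x * x + y * y + z * z <= r_vox * r_vox


# ---------------------------------------------------------------------------
# Baseline plan construction
# ---------------------------------------------------------------------------


def _target_projection(phantom: Phantom, gantry_deg: float):
    """PTV projection in the BEV and its radiological depth extent."""
    from .dose_metrics import _cp_geometry
    active, wed, xb, yb = _cp_geometry(phantom, gantry_deg)
    in_ptv = phantom.masks["PTV"].ravel()[active]
    return xb[in_ptv], yb[in_ptv], wed[in_ptv]


def spot_lattice_for_cp(phantom: Phantom, gantry_deg: float,
                        spot_spacing: float = 3.0,
                        expansion: float = 6.0):
    """3 mm spot lattice covering the target BEV projection + expansion.

    Returns (positions (n,2) mm, in_target flags, projection centroid).
    A lattice cell is *in target* when a PTV voxel projects into it; the
    lattice includes every cell within ``expansion`` of an in-target cell.
    """
    xb, yb, _ = _target_projection(phantom, gantry_deg)
    ix = np.round(xb / spot_spacing).astype(np.int64)
    iy = np.round(yb / spot_spacing).astype(np.int64)
    occupied = set(zip(ix.tolist(), iy.tolist()))
    reach = int(math.ceil(expansion / spot_spacing))
    cells = {}
    for (cx, cy) in occupied:
        for dx in range(-reach, reach + 1):
            for dy in range(-reach, reach + 1):
                if math.hypot(dx, dy) * spot_spacing <= expansion + 1e-9:
                    cells.setdefault((cx + dx, cy + dy), False)
    for c in occupied:
        cells[c] = True
    keys = sorted(cells)
    pos = np.array([[kx * spot_spacing, ky * spot_spacing] for kx, ky in keys])
    in_target = np.array([cells[k] for k in keys])
    centroid = np.array([xb.mean(), yb.mean()])
    return pos, in_target, centroid


def _spot_config(x: float, y: float, in_target: bool, centroid: np.ndarray,
                 spacing: float, config_id: str) -> TrimmerConfig:
    """Per-spot baseline configuration.

    In-target spots are uncollimated (all bars OFF).  An out-of-target spot
    is trimmed at 0 mm offset -- the medial bar edge on the spot's own
    axis -- on the side(s) facing away from the target projection; the
    remaining bars stay OFF.  Bar positions are clipped to the hardware
    travel range.
    """
    if in_target:
        return off_config(config_id)
    bars = {"x_neg": TRIMMER_OFF_MM, "x_pos": TRIMMER_OFF_MM,
            "y_neg": TRIMMER_OFF_MM, "y_pos": TRIMMER_OFF_MM}
    tol = 0.25 * spacing
    dx, dy = x - centroid[0], y - centroid[1]
    trimmed = False
    if dx > tol:
        bars["x_pos"] = x
        trimmed = True
    elif dx < -tol:
        bars["x_neg"] = -x
        trimmed = True
    if dy > tol:
        bars["y_pos"] = y
        trimmed = True
    elif dy < -tol:
        bars["y_neg"] = -y
        trimmed = True
    if not trimmed:  # degenerate: sit on the centroid; trim the longer axis
        if abs(dx) >= abs(dy):
            bars["x_pos" if dx >= 0 else "x_neg"] = abs(x) if dx >= 0 else -x
        else:
            bars["y_pos" if dy >= 0 else "y_neg"] = abs(y) if dy >= 0 else -y
    clipped = {k: float(np.clip(v, TRIMMER_MIN_MM, TRIMMER_OFF_MM))
               for k, v in bars.items()}
    return TrimmerConfig(config_id, clipped["x_neg"], clipped["x_pos"],
                         clipped["y_neg"], clipped["y_pos"])


def _build_control_point(index: int, gantry_deg: float, energy_mev: float,
                         phantom: Phantom, spot_spacing: float,
                         expansion: float, mu0: float) -> ControlPoint:
    pos, in_target, centroid = spot_lattice_for_cp(phantom, gantry_deg,
                                                   spot_spacing, expansion)
    spots = []
    configs = []
    for k, ((x, y), it) in enumerate(zip(pos, in_target)):
        cid = f"cp{index}_c{k}"
        configs.append(_spot_config(float(x), float(y), bool(it), centroid,
                                    spot_spacing, cid))
        spots.append(Spot(id=f"cp{index}_s{k}", x=float(x), y=float(y),
                          mu=mu0, config_ref=cid))
    return ControlPoint(index=index, gantry_deg=gantry_deg,
                        energy_mev=energy_mev, spots=tuple(spots),
                        configs=tuple(configs))


def _cycle_energies(phantom: Phantom, angles: np.ndarray,
                    seed: int) -> list[float]:
    """One energy per angle: Bragg peak depths cycle over target slabs."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    slab_order = rng.permutation(_DEPTH_SLABS)
    energies = []
    for i, ang in enumerate(angles):
        _, _, wed = _target_projection(phantom, float(ang))
        dmin, dmax = float(wed.min()), float(wed.max())
        slab = slab_order[(i * _SLAB_STRIDE) % _DEPTH_SLABS]
        frac = (slab + 0.5) / _DEPTH_SLABS
        depth_mm = dmin + frac * (dmax - dmin)
        energies.append(range_to_energy(max(depth_mm, 1.0) / 10.0))
    return energies


def make_baseline_plan(phantom: Phantom, n_positions: int = 129,
                       spot_spacing: float = 3.0, expansion: float = 6.0,
                       machine: MachineModel | None = None,
                       objectives: Objectives | None = None,
                       seed: int = 0, prescription_gy: float = 50.0,
                       optimize: bool = True,
                       opt_max_iters: int = 400) -> ArcPlan:
    """Build a baseline collimated arc plan on the phantom.

    A full clockwise arc of ``n_positions`` equally spaced control points
    from -180 to +180 degrees inclusive (resolution 360/(n-1)); weights are
    optimized against the dose objectives, sub-0.025 MU spots and emptied
    control points removed, and the plan normalized to D95 = prescription.
    ``optimize=False`` skips the weight optimization (uniform weights,
    still filtered and normalized) for cheap structural fixtures.
    """
    if n_positions < 2:
        raise ValueError("need at least two arc positions")
    resolution = 360.0 / (n_positions - 1)
    angles = -180.0 + resolution * np.arange(n_positions)
    energies = _cycle_energies(phantom, angles, seed)
    mu0 = 1.0
    cps = tuple(
        _build_control_point(i, float(a), float(e), phantom, spot_spacing,
                             expansion, mu0)
        for i, (a, e) in enumerate(zip(angles, energies))
    )
    plan = ArcPlan(control_points=cps, prescription_gy=prescription_gy,
                   arc_resolution_deg=resolution, clockwise=True)
    state = influence_matrix(plan, phantom)
    if optimize:
        x = reoptimize_weights(plan, state,
                               objectives or default_objectives(prescription_gy),
                               phantom, max_iters=opt_max_iters)
    else:
        # uniform weights scaled to put the target near prescription
        dose = state.dose(np.ones_like(state.mu))
        in_ptv = phantom.masks["PTV"].ravel()
        scale = prescription_gy / max(float(np.median(dose[in_ptv])), 1e-9)
        x = np.full_like(state.mu, scale)
    plan = apply_mu(plan, state, x)
    if not plan.control_points:
        raise ValueError("no deliverable spots; check phantom/energy setup")
    dose = state.dose(np.where(x >= MU_FLOOR, x, 0.0))
    plan, _ = normalize_to_prescription(plan, dose, phantom)
    plan = remove_low_mu_spots(plan)
    validate_plan(plan)
    return plan


def regenerate_spots(plan: ArcPlan, phantom: Phantom,
                     spot_spacing: float = 3.0,
                     expansion: float = 6.0) -> ArcPlan:
    """Rebuild every control point's spot lattice and trimmer configs.

    Used after energy-layer sorting remaps layers to new gantry angles:
    spot positions and the 0 mm-offset collimation rule are re-derived at
    each angle while energies stay as sorted.  Existing MU are kept where a
    lattice position coincides with an old spot, otherwise seeded at the
    control point's mean MU, ready for reoptimization.
    """
    new_cps = []
    for cp in plan.control_points:
        old_mu = {(round(s.x, 3), round(s.y, 3)): s.mu for s in cp.spots}
        mean_mu = cp.mu_total() / max(len(cp.spots), 1)
        fresh = _build_control_point(cp.index, cp.gantry_deg, cp.energy_mev,
                                     phantom, spot_spacing, expansion, mean_mu)
        spots = tuple(
            replace(s, mu=old_mu.get((round(s.x, 3), round(s.y, 3)), mean_mu))
            for s in fresh.spots
        )
        new_cps.append(replace(fresh, spots=spots))
    return replace(plan, control_points=tuple(new_cps))


def make_energy_sequence_fixture(n: int, regime: str = "random",
                                 seed: int = 0) -> list[float]:
    """Reproducible energy sequences for sorting property tests.

    ``random``: i.i.d. draws from a clinical energy grid; ``sawtooth``:
    ascending runs of three that guarantee at least n/3 slow low-to-high
    transitions; ``descending``: strictly descending (zero up-jumps).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if regime == "descending":
        return list(np.linspace(160.0, 70.0, n))
    if regime == "sawtooth":
        base = [90.0, 115.0, 140.0]
        return [base[i % 3] + 2.0 * (i // 3 % 5) for i in range(n)]
    if regime == "random":
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        grid = np.arange(70.0, 161.0, 2.0)
        return list(rng.choice(grid, size=n))
    raise ValueError(f"unknown regime {regime!r}")
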