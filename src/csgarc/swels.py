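"""Sliding-Window Energy Layer Sorting (SWELS).

A step-and-shoot arc visits one energy layer per control point.  Because
low-to-high energy transitions are roughly an order of magnitude slower
than high-to-low ones, reordering the energy sequence toward descending
runs saves minutes of delivery time.  A global descending sort would move
layers to gantry angles far from where they were optimized; SWELS instead
sorts *within a sliding window* of consecutive control points so that no
layer ends farther from its original angle than the window size.

Mechanics (single left-to-right pass):

* the window grows from one control point up to its capacity
  ``floor(window_deg / resolution_deg)``, re-sorting its contents in
  descending energy order at every growth step;
* at capacity the window slides one index per step, re-sorting;
* if, after a slide, the energy at the window's last index exceeds the
  energy at its first index, the window jumps so that the last index
  becomes the new first index and regrows from there.

Each window sort is a *displacement-bounded* descending arrangement: a
layer whose accumulated displacement from its original control point has
reached capacity-1 is pinned rather than carried further.  An unconstrained
per-window sort can drag the lightest layer rightward indefinitely over
successive overlapping windows, which would break the guarantee the window
exists to provide; the bounded sort keeps every layer within the window of
its origin while still producing descending runs.

When a layer moves, everything it carries (spots, trimmer configurations)
moves with it to the new gantry angle: sorting permutes the energy layers
over the fixed set of planned gantry positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .plan_model import ArcPlan

__all__ = ["SwelsParams", "window_capacity", "sort_energies",
           "sort_permutation", "count_upjumps"]


@dataclass(frozen=True)
class SwelsParams:
    """Window size in degrees of arc, plus the plan's angular resolution.

    Studied window sizes are 10, 25 and 40 degrees; capacity is the window
    size divided by the resolution, and a capacity below 2 makes sorting a
    no-op.
    """

    window_deg: float
    resolution_deg: float = 2.8125


def window_capacity(params: SwelsParams) -> int:
    """Maximum number of consecutive control points inside one window."""
    if params.window_deg <= 0 or params.resolution_deg <= 0:
        raise ValueError("window and resolution must be positive")
    return math.floor(params.window_deg / params.resolution_deg)


def _bounded_desc_sort(order: list[int], energies: list[float],
                       s: int, e: int, cap: int) -> None:
    """Rearrange order[s..e] in descending energy, displacement-bounded.

    ``order[i]`` is the original index of the layer currently at slot i.
    A layer with original index o may only occupy slots in
    [o - (cap-1), o + (cap-1)].  Slots are filled left to right; at each
    slot any layer that has reached its rightmost legal slot must be placed,
    otherwise the highest-energy eligible layer is placed (original index
    breaks ties, keeping equal energies in original order).
    """
    window = order[s:e + 1]
    placed = [False] * len(window)
    out = []
    for slot in range(s, e + 1):
        must = None
        best = None
        for j, o in enumerate(window):
            if placed[j]:
                continue
            if o + (cap - 1) == slot:
                # deadline reached: this layer cannot move further right
                if must is None or energies[o] > energies[window[must]]:
                    must = j
            if o - (cap - 1) <= slot:
                if best is None:
                    best = j
                else:
                    b = window[best]
                    if (energies[o], -o) > (energies[b], -b):
                        best = j
        pick = must if must is not None else best
        if pick is None:  # no eligible layer; take leftmost-origin unplaced
            pick = min((j for j in range(len(window)) if not placed[j]),
                       key=lambda j: window[j])
        placed[pick] = True
        out.append(window[pick])
    order[s:e + 1] = out


def sort_permutation(energies: list[float], capacity: int) -> list[int]:
    """Return the SWELS permutation: result slot i holds layer ``perm[i]``.

    Pure sequence-level core of :func:`sort_energies`; useful for property
    checks on bare energy sequences.
    """
    n = len(energies)
    order = list(range(n))
    if capacity < 2 or n < 2:
        return order
    s = 0
    e = 0
    while True:
        _bounded_desc_sort(order, energies, s, e, capacity)
        if e == n - 1:
            return order
        if e - s + 1 < capacity:
            e += 1
        else:
            s += 1
            e += 1
            if energies[order[e]] > energies[order[s]]:
                # stop condition: regrow the window from the last index
                s = e


def sort_energies(plan: ArcPlan, params: SwelsParams) -> ArcPlan:
    """Reorder a plan's energy layers with SWELS.

    The multiset of energies is preserved; layer ``perm[i]`` (with its spots
    and trimmer configurations) is delivered at the i-th planned gantry
    angle.  No layer is displaced by ``window_capacity`` control points or
    more.
    """
    cap = window_capacity(params)
    perm = sort_permutation(plan.energies(), cap)
    cps = tuple(
        replace(plan.control_points[src], index=i,
                gantry_deg=plan.control_points[i].gantry_deg)
        for i, src in enumerate(perm)
    )
    return replace(plan, control_points=cps)


def count_upjumps(plan: ArcPlan | list[float]) -> int:
    """Number of slow low-to-high energy transitions between consecutive CPs.

    Equal consecutive energies count as neither an up- nor a down-jump.
    """
    energies = plan.energies() if isinstance(plan, ArcPlan) else list(plan)
    if not energies:
        raise ValueError("need at least one control point")
    return sum(1 for a, b in zip(energies, energies[1:]) if b > a)
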