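"""Consensus (Parkes) Error Grid zone assignment.

The consensus error grid partitions the (reference, predicted) glucose plane
into risk zones A-E, from clinically accurate (A) to dangerously misleading
(E). Zone boundaries are encoded from the published consensus breakpoint
coordinate tables (in mg/dL) for both the type 1 and the type 2 diabetes
variants of the grid. Boundaries are polylines; beyond the last tabulated
vertex each boundary continues with the slope of its final segment. Points
that fall exactly on a boundary take the lower-risk zone.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MMOL_TO_MGDL", "ceg_zone", "ceg_summary", "PARKES_BOUNDARIES"]

MMOL_TO_MGDL = 18.016

ZONES = ("A", "B", "C", "D", "E")

# Published consensus-grid breakpoints, mg/dL, (reference, predicted) vertices.
# "up" boundaries separate zones above the identity line (predicted too high),
# "low" boundaries below it. A point beyond boundary X_up / X_low is in zone X
# or worse.
PARKES_BOUNDARIES: dict[str, dict[str, tuple[tuple[float, float], ...]]] = {
    "type1": {
        "E_up": ((0, 150), (35, 155), (50, 550)),
        "D_up": ((0, 100), (25, 100), (50, 125), (80, 215), (125, 550)),
        "C_up": ((0, 60), (30, 60), (50, 80), (70, 110), (260, 550)),
        "B_up": ((0, 50), (30, 50), (140, 170), (280, 380), (430, 550)),
        "B_low": ((50, 0), (50, 30), (170, 145), (385, 300), (550, 450)),
        "C_low": ((120, 0), (120, 30), (260, 130), (550, 250)),
        "D_low": ((250, 0), (250, 40), (550, 150)),
    },
    "type2": {
        "E_up": ((0, 200), (35, 200), (50, 550)),
        "D_up": ((0, 80), (25, 80), (35, 90), (125, 550)),
        "C_up": ((0, 60), (30, 60), (280, 550)),
        "B_up": ((0, 50), (30, 50), (230, 330), (440, 550)),
        "B_low": ((50, 0), (50, 30), (90, 80), (330, 230), (550, 450)),
        "C_low": ((90, 0), (260, 130), (550, 250)),
        "D_low": ((250, 0), (250, 40), (410, 110), (550, 160)),
    },
}


def _boundary_y(vertices: tuple[tuple[float, float], ...], x: np.ndarray
                ) -> np.ndarray:
    """Boundary ordinate at reference value x; NaN where the boundary is absent.

    Leading vertical segments (repeated x) are collapsed to their upper vertex:
    the region to their left belongs to the safer zone. Past the last vertex
    the final segment's slope is extended.
    """
    vx = np.array([v[0] for v in vertices], dtype=float)
    vy = np.array([v[1] for v in vertices], dtype=float)
    vertical_start = len(vx) >= 2 and vx[0] == vx[1]
    # collapse a leading vertical segment to its upper vertex
    keep = np.concatenate((np.diff(vx) > 0, [True]))
    vx, vy = vx[keep], vy[keep]
    y = np.interp(x, vx, vy)
    # extend final slope beyond the last vertex
    if len(vx) >= 2:
        slope = (vy[-1] - vy[-2]) / (vx[-1] - vx[-2])
        beyond = x > vx[-1]
        y = np.where(beyond, vy[-1] + slope * (x - vx[-1]), y)
    if vertical_start:
        # the vertical segment itself is boundary: at x == vx[0] the safer
        # zone applies, so the region only exists strictly beyond it
        y = np.where(x <= vx[0], np.nan, y)
    else:
        y = np.where(x < vx[0], np.nan, y)
    return y


def ceg_zone(ref_mmol, pred_mmol, grid_variant: str = "type2"):
    """Assign consensus-error-grid zones to (reference, prediction) pairs.

    Inputs are in mmol/L and converted internally to mg/dL. Returns a zone
    label per point ('A'..'E'); scalars in give a scalar out. Boundary points
    take the lower-risk zone (comparisons beyond a boundary are strict).
    """
    if grid_variant not in PARKES_BOUNDARIES:
        raise ValueError(f"unknown grid variant: {grid_variant!r}")
    ref = np.atleast_1d(np.asarray(ref_mmol, dtype=float)) * MMOL_TO_MGDL
    pred = np.atleast_1d(np.asarray(pred_mmol, dtype=float)) * MMOL_TO_MGDL
    if np.any(ref <= 0) or np.any(pred <= 0):
        raise ValueError("glucose values must be positive")
    b = PARKES_BOUNDARIES[grid_variant]
    zone = np.full(ref.shape, "A", dtype="<U1")
    # above the identity line: worst zone whose boundary the point exceeds
    for name in ("B_up", "C_up", "D_up", "E_up"):
        y = _boundary_y(b[name], ref)
        above = ~np.isnan(y) & (pred > y)
        zone[above] = name[0]
    # below the identity line
    for name in ("B_low", "C_low", "D_low"):
        y = _boundary_y(b[name], ref)
        below = ~np.isnan(y) & (pred < y)
        zone[below] = name[0]
    if np.isscalar(ref_mmol) or np.asarray(ref_mmol).ndim == 0:
        return str(zone[0])
    return zone


def ceg_summary(ref_mmol, pred_mmol, grid_variant: str = "type2") -> dict[str, float]:
    """Percentage of points per zone; fractions sum to 100."""
    ref = np.asarray(ref_mmol, dtype=float)
    if ref.size == 0:
        raise ValueError("no points to summarize")
    zones = ceg_zone(ref_mmol, pred_mmol, grid_variant)
    zones = np.atleast_1d(zones)
    return {z: 100.0 * float(np.mean(zones == z)) for z in ZONES}
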