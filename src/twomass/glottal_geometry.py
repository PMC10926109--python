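"""Glottal channel geometry from the two-cylinder medial surface.

The medial surface of one fold is the convex envelope of two cylinders
(one per mass): the lower cylinder arc, the common external tangent line,
and the upper cylinder arc.  Each cylinder translates rigidly with its
mass displacement vector.  At rest the two cylinders touch the glottal
midline (y = 0) so the glottis is closed at the level of both masses:
the prephonatory glottal angle and the minimal glottal gap are both zero.

The channel half-width at a vertical station x is the y-coordinate of the
surface there; negative half-width means the fold has crossed the midline
and is in contact with its mirror-image contralateral fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mechanics import FoldState, ModelParams

__all__ = ["GlottalProfile", "GeometryError", "build_profile", "contact_depths"]

#: fallback half-width for stations not covered by any surface piece
#: (only reachable in pathological configurations)
_OPEN_HALF_WIDTH = 10e-3


class GeometryError(ValueError):
    """Degenerate cylinder configuration (no common external tangent)."""


@dataclass
class GlottalProfile:
    """Discretized glottal channel profile at one instant.

    ``x_grid`` runs inferior -> superior across the instantaneous fold
    thickness; ``half_width`` may be negative in contact.  ``area`` is the
    full-channel cross-section ``2 * half_width * L_g`` clipped at zero.
    """

    x_grid: np.ndarray
    half_width: np.ndarray
    area: np.ndarray
    min_area: float
    min_station: int
    entry_angle: float
    thickness: float
    #: vertical stations of the (displaced) mass centers
    x_mass1: float
    x_mass2: float
    #: half-width evaluated at each mass station
    hw_mass1: float
    hw_mass2: float
    #: midpoint of the tangent segment; stations below belong to mass 1
    x_split: float
    L_g: float


def _tangent_line(c1: np.ndarray, c2: np.ndarray, R1: float, R2: float):
    """Common external tangent below both circles.

    Returns ``(n, d, t1x, t2x)`` where the line is ``n . p = d`` with unit
    normal ``n`` pointing laterally (towards the circle centers) and
    ``t1x``/``t2x`` are the vertical stations of the tangency points.
    """
    delta = c2 - c1
    D = float(np.hypot(*delta))
    dR = R2 - R1
    if D <= abs(dR):
        raise GeometryError(
            f"no common tangent: centers {c1} / {c2} with radii {R1} / {R2} "
            "(one cylinder swallowed by the other)"
        )
    along = delta / D
    perp = np.array([-along[1], along[0]])
    cos_t = dR / D
    sin_t = np.sqrt(1.0 - cos_t * cos_t)
    for sign in (1.0, -1.0):
        n = cos_t * along + sign * sin_t * perp
        if n[1] > 0:  # normal must point lateral: circles above the line
            break
    else:  # pragma: no cover - unreachable for physically meaningful states
        raise GeometryError(f"no medial tangent for centers {c1} / {c2}")
    d = float(n @ c1) - R1
    t1 = c1 - R1 * n
    t2 = c2 - R2 * n
    return n, d, float(t1[0]), float(t2[0])


def _centers(state: FoldState, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    c1 = np.array([params.x_rest1 + state.r1[0], params.r_cyl1 + state.r1[1]])
    c2 = np.array([params.x_rest2 + state.r2[0], params.r_cyl2 + state.r2[1]])
    return c1, c2


def _envelope_half_width(x, c1, c2, R1, R2, n, d, t1x, t2x):
    """Half-width of the convex envelope at stations ``x`` (vectorized)."""
    x = np.asarray(x, dtype=float)
    hw = np.full(x.shape, np.inf)

    for c, R in ((c1, R1), (c2, R2)):
        dx = x - c[0]
        inside = np.abs(dx) <= R
        circ = np.where(inside, c[1] - np.sqrt(np.maximum(R * R - dx * dx, 0.0)), np.inf)
        hw = np.minimum(hw, circ)

    lo, hi = min(t1x, t2x), max(t1x, t2x)
    on_seg = (x >= lo) & (x <= hi)
    if n[1] > 0:
        line = (d - n[0] * x) / n[1]
        hw = np.where(on_seg, np.minimum(hw, line), hw)

    return np.where(np.isfinite(hw), hw, _OPEN_HALF_WIDTH)


def build_profile(state: FoldState, params: ModelParams, n_stations: int = 64) -> GlottalProfile:
    """Construct the glottal profile for the current mass positions.

    The surface is sampled at ``n_stations`` stations spanning the
    instantaneous vertical extent of the fold (bottom of the lower
    cylinder to top of the upper cylinder).  Mirror symmetry about the
    midline is assumed for the contralateral fold, so the full channel
    area at a station is ``2 * half_width * L_g``.
    """
    if n_stations < 8:
        raise ValueError("n_stations must be at least 8")
    c1, c2 = _centers(state, params)
    R1, R2 = params.r_cyl1, params.r_cyl2
    n, d, t1x, t2x = _tangent_line(c1, c2, R1, R2)

    x_lo = min(c1[0] - R1, c2[0] - R2)
    x_hi = max(c1[0] + R1, c2[0] + R2)
    x_grid = np.linspace(x_lo, x_hi, n_stations)
    hw = _envelope_half_width(x_grid, c1, c2, R1, R2, n, d, t1x, t2x)

    area = 2.0 * np.maximum(hw, 0.0) * params.L_g
    k_min = int(np.argmin(hw))
    hw_m1, hw_m2 = _envelope_half_width(
        np.array([c1[0], c2[0]]), c1, c2, R1, R2, n, d, t1x, t2x
    )

    # inferior-surface angle: slope of the common tangent w.r.t. the
    # vertical (flow) axis; zero at rest where the tangent lies on the midline
    entry_angle = float(np.arctan2(-n[0], n[1]))

    return GlottalProfile(
        x_grid=x_grid,
        half_width=hw,
        area=area,
        min_area=float(max(0.0, 2.0 * hw[k_min] * params.L_g)),
        min_station=k_min,
        entry_angle=entry_angle,
        thickness=float(x_hi - x_lo),
        x_mass1=float(c1[0]),
        x_mass2=float(c2[0]),
        hw_mass1=float(hw_m1),
        hw_mass2=float(hw_m2),
        x_split=0.5 * (t1x + t2x),
        L_g=params.L_g,
    )


def contact_depths(profile: GlottalProfile) -> tuple[float, float]:
    """Penetration depth (m) past the midline at each mass station.

    Zero when the glottis is open at that level; positive depth feeds the
    penalty contact force in the mechanics module.
    """
    return (max(0.0, -profile.hw_mass1), max(0.0, -profile.hw_mass2))


def _half_widths_scalar(
    r1x: float, r1y: float, r2x: float, r2y: float, params: ModelParams
) -> tuple[float, float]:
    """Half-width at the two mass stations, scalar math only.

    Hot path for the contact force inside Runge-Kutta stages; avoids any
    array allocation.  Mirrors :func:`build_profile` exactly at the two
    mass-center stations.
    """
    import math

    R1, R2 = params.r_cyl1, params.r_cyl2
    c1x, c1y = params.x_rest1 + r1x, R1 + r1y
    c2x, c2y = params.x_rest2 + r2x, R2 + r2y
    dx, dy = c2x - c1x, c2y - c1y
    D = math.hypot(dx, dy)
    dR = R2 - R1
    if D <= abs(dR):
        raise GeometryError(
            f"no common tangent: centers ({c1x}, {c1y}) / ({c2x}, {c2y}) "
            f"with radii {R1} / {R2}"
        )
    cos_t = dR / D
    sin_t = math.sqrt(1.0 - cos_t * cos_t)
    ax, ay = dx / D, dy / D  # unit vector along the center line
    px, py = -ay, ax
    nx, ny = cos_t * ax + sin_t * px, cos_t * ay + sin_t * py
    if ny <= 0:
        nx, ny = cos_t * ax - sin_t * px, cos_t * ay - sin_t * py
    if ny <= 0:
        raise GeometryError("no medial tangent")
    d = nx * c1x + ny * c1y - R1
    t1x, t2x = c1x - R1 * nx, c2x - R2 * nx
    lo, hi = (t1x, t2x) if t1x <= t2x else (t2x, t1x)

    out = []
    for x in (c1x, c2x):
        hw = math.inf
        for cx, cy, R in ((c1x, c1y, R1), (c2x, c2y, R2)):
            u = x - cx
            if abs(u) <= R:
                hw = min(hw, cy - math.sqrt(max(R * R - u * u, 0.0)))
        if lo <= x <= hi:
            hw = min(hw, (d - nx * x) / ny)
        out.append(hw if math.isfinite(hw) else _OPEN_HALF_WIDTH)
    return out[0], out[1]


def mass_half_widths(state: FoldState, params: ModelParams) -> tuple[float, float]:
    """Half-width at the two mass stations without building a full profile.

    Fast path used inside the Runge-Kutta stages, where only the contact
    depths are needed.
    """
    c1, c2 = _centers(state, params)
    R1, R2 = params.r_cyl1, params.r_cyl2
    n, d, t1x, t2x = _tangent_line(c1, c2, R1, R2)
    hw = _envelope_half_width(np.array([c1[0], c2[0]]), c1, c2, R1, R2, n, d, t1x, t2x)
    return float(hw[0]), float(hw[1])
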