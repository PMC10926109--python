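"""Quasi-steady Bernoulli glottal flow and surface pressure forces.

The glottal airflow is modeled as incompressible, quasi-steady flow
through the channel defined by the glottal profile: total pressure is
conserved from the subglottal side down to the flow-separation station
(the minimum-area station by default), beyond which the jet pressure
equals the supraglottal pressure.  The flow rate follows from requiring
the static pressure at separation to match the downstream pressure,
which gives the familiar orifice law ``U = A* sqrt(2 dP / rho)``.

Pressure forces on the two masses are obtained by integrating the static
pressure over the discretized medial surface; the surface element normal
supplies both the lateral (opening/closing) and the vertical force
components.  The vertical components are the per-mass "vertical forces"
used to diagnose acoustic entrainment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glottal_geometry import GlottalProfile
from .mechanics import ForcePair, ModelParams

__all__ = ["FlowSolution", "solve_flow", "solve_flow_loaded", "surface_forces"]

#: default air density (kg/m^3)
RHO_AIR = 1.2

#: minimum area used in Bernoulli denominators to avoid blow-up at closure
AREA_FLOOR = 1e-7


@dataclass
class FlowSolution:
    """Flow rate and per-station static pressure for one profile."""

    U: float
    separation_station: int
    pressure: np.ndarray
    p_sub: float
    p_sup: float


def _separation_station(profile: GlottalProfile, separation_ratio: float | None) -> int:
    """Station where the jet detaches.

    Default: the minimum-area station.  With ``separation_ratio`` set, the
    jet instead follows the diverging wall until the local area exceeds
    ``ratio * min_area`` (a common lumped-element separation criterion).
    """
    k = profile.min_station
    if separation_ratio is None:
        return k
    a_min = max(profile.area[k], AREA_FLOOR)
    for j in range(k, len(profile.area)):
        if profile.area[j] > separation_ratio * a_min:
            return j
    return len(profile.area) - 1


def _closed_pressure(profile: GlottalProfile, p_sub: float, p_sup: float) -> np.ndarray:
    """Hydrostatic pressure split during glottal closure.

    Subglottal pressure below the (first) contact station, supraglottal
    pressure above it; no flow.
    """
    contact = np.flatnonzero(profile.half_width <= 0.0)
    k = contact[0] if contact.size else profile.min_station
    p = np.full_like(profile.x_grid, p_sup)
    p[:k] = p_sub
    return p


def solve_flow(
    profile: GlottalProfile,
    p_sub: float,
    p_sup: float,
    rho: float = RHO_AIR,
    area_floor: float = AREA_FLOOR,
    separation_ratio: float | None = None,
) -> FlowSolution:
    """Bernoulli flow through the glottal profile for fixed end pressures.

    Upstream of the separation station the static pressure is
    ``p_sub - 0.5 rho (U / A(x))^2``; downstream it equals ``p_sup``.
    ``U`` is zero whenever the glottis is closed (min area at or below
    the area floor) or the driving pressure is non-positive.
    """
    if not (np.isfinite(p_sub) and np.isfinite(p_sup)):
        raise ValueError("end pressures must be finite")
    if rho <= 0:
        raise ValueError("rho must be positive")

    if profile.min_area <= area_floor:
        return FlowSolution(
            U=0.0,
            separation_station=profile.min_station,
            pressure=_closed_pressure(profile, p_sub, p_sup),
            p_sub=p_sub,
            p_sup=p_sup,
        )

    k_sep = _separation_station(profile, separation_ratio)
    a_sep = max(profile.area[k_sep], area_floor)
    dp = p_sub - p_sup
    U = a_sep * np.sqrt(2.0 * dp / rho) if dp > 0 else 0.0

    a_eff = np.maximum(profile.area, area_floor)
    p = p_sub - 0.5 * rho * (U / a_eff) ** 2
    p[k_sep + 1 :] = p_sup
    return FlowSolution(U=float(U), separation_station=k_sep, pressure=p, p_sub=p_sub, p_sup=p_sup)


def solve_flow_loaded(
    profile: GlottalProfile,
    p_sub_incident: float,
    p_sup_incident: float,
    z_sub: float,
    z_sup: float,
    rho: float = RHO_AIR,
    area_floor: float = AREA_FLOOR,
    separation_ratio: float | None = None,
) -> FlowSolution:
    """Glottal flow with acoustic loading by the two transmission lines.

    The instantaneous end pressures depend on the flow itself through the
    line characteristic impedances: ``p_sub = 2 f - z_sub U`` and
    ``p_sup = 2 b + z_sup U`` where ``f``/``b`` are the incident partial
    pressures arriving at the glottis.  Substituting into the Bernoulli
    balance yields a quadratic in U:

        (rho / 2 A*^2) U^2 + (z_sub + z_sup) U - 2 (f - b) = 0

    solved for the non-negative root.  This interactive coupling is what
    lets the tract acoustics feed back on the source.
    """
    if profile.min_area <= area_floor:
        return FlowSolution(
            U=0.0,
            separation_station=profile.min_station,
            pressure=_closed_pressure(profile, 2.0 * p_sub_incident, 2.0 * p_sup_incident),
            p_sub=2.0 * p_sub_incident,
            p_sup=2.0 * p_sup_incident,
        )

    k_sep = _separation_station(profile, separation_ratio)
    a_sep = max(profile.area[k_sep], area_floor)
    drive = 2.0 * (p_sub_incident - p_sup_incident)
    if drive <= 0:
        U = 0.0
    else:
        qa = 0.5 * rho / (a_sep * a_sep)
        qb = z_sub + z_sup
        U = (-qb + np.sqrt(qb * qb + 4.0 * qa * drive)) / (2.0 * qa)

    p_sub = 2.0 * p_sub_incident - z_sub * U
    p_sup = 2.0 * p_sup_incident + z_sup * U
    a_eff = np.maximum(profile.area, area_floor)
    p = p_sub - 0.5 * rho * (U / a_eff) ** 2
    p[k_sep + 1 :] = p_sup
    return FlowSolution(U=float(U), separation_station=k_sep, pressure=p, p_sub=p_sub, p_sup=p_sup)


def surface_forces(flow: FlowSolution, profile: GlottalProfile, params: ModelParams) -> ForcePair:
    """Pressure force vectors on the two masses (one fold).

    The medial surface is the curve ``y = h(x)``; a pressure ``p`` acting
    on the fluid side pushes the fold along the surface normal
    ``(-h'(x), 1) / sqrt(1 + h'^2)``, so per unit station length

        dF_y = L_g p dx            (lateral, positive = opening)
        dF_x = -L_g p h'(x) dx     (vertical, positive = superior)

    Stations at or below the tangent-segment midpoint are assigned to
    mass 1 (inferior portion: lower arc plus lower half of the tangent),
    the rest to mass 2.
    """
    from scipy.integrate import cumulative_trapezoid

    x = profile.x_grid
    h = profile.half_width
    p = flow.pressure
    dh_dx = np.gradient(h, x)

    # cumulative integrals so the mass-1/mass-2 split falls exactly at
    # x_split (interpolated) instead of snapping to a grid station
    cum_y = cumulative_trapezoid(p, x, initial=0.0)
    cum_x = cumulative_trapezoid(p * dh_dx, x, initial=0.0)
    split_y = float(np.interp(profile.x_split, x, cum_y))
    split_x = float(np.interp(profile.x_split, x, cum_x))

    F1 = params.L_g * np.array([-split_x, split_y])
    F2 = params.L_g * np.array([-(cum_x[-1] - split_x), cum_y[-1] - split_y])
    return ForcePair(F1, F2)
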