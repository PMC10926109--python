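"""Two-mass vocal fold mechanics.

Each vocal fold is lumped into a lower body mass (m1) and an upper cover
mass (m2).  Unlike the classic two-mass model, the spring/damper elements
act in both the medial-lateral (y) and superior-inferior (x) directions,
so each mass carries a 2-D displacement vector.  The vertical stiffness is
tied to the horizontal one through the ratio ``Q``: ``k_ix = Q * k_iy``.
Raising Q progressively restrains the vertical motion while leaving the
horizontal dynamics untouched.

Coordinate convention: ``x`` is vertical (inferior -> superior), ``y`` is
horizontal (medial -> lateral).  Displacement zero is the rest position,
in which the glottis is fully closed at the level of both masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelParams",
    "FoldState",
    "ForcePair",
    "InstabilityError",
    "damping_coefficients",
    "internal_forces",
    "contact_force",
    "contact_force_from_depths",
    "eom_rhs",
    "step",
]


class InstabilityError(RuntimeError):
    """Raised when the integrated displacement exceeds the safety bound."""


@dataclass(frozen=True)
class ModelParams:
    """Lumped mechanical and geometric constants of one vocal fold.

    Masses are in kg, stiffnesses in N/m, lengths in m.  The vertical
    spring constants are never stored: they are always derived as
    ``k_ix = Q * k_iy``.

    Attributes
    ----------
    m1, m2 : float
        Lower and upper element masses (defaults 0.17 g and 0.03 g).
    k1y, k2y : float
        Horizontal (medial-lateral) spring stiffnesses.
    kc : float
        Stiffness of the spring coupling the two masses.
    Q : float
        Vertical-to-horizontal stiffness ratio, ``k_ix = Q * k_iy``.
    zeta1, zeta2 : float
        Damping-ratio factors entering ``eta_i = zeta_i * 2 sqrt(m_i k_i)``.
    contact_stiffness_scale : float
        Multiplier on ``k_iy`` for the penalty spring during collision.
    contact_damping_scale : float
        Multiplier on the damping coefficients during collision (default 1,
        i.e. damping is unchanged by contact).
    r_cyl1, r_cyl2 : float
        Radii of the cylinders forming the medial surface of each mass.
    L_g : float
        Glottal span along the anterior-posterior direction.
    x_rest1, x_rest2 : float
        Rest vertical positions of the two cylinder centers.
    """

    m1: float = 0.17e-3
    m2: float = 0.03e-3
    k1y: float = 150.0
    k2y: float = 40.0
    kc: float = 20.0
    Q: float = 3.0
    zeta1: float = 0.1
    zeta2: float = 0.6
    contact_stiffness_scale: float = 3.0
    contact_damping_scale: float = 1.0
    r_cyl1: float = 2.0e-3
    r_cyl2: float = 1.0e-3
    L_g: float = 17.0e-3
    x_rest1: float = 0.0
    x_rest2: float = 3.0e-3

    def __post_init__(self) -> None:
        for name in ("m1", "m2", "k1y", "k2y", "Q"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.kc < 0:
            raise ValueError("kc must be non-negative")
        if self.r_cyl1 <= 0 or self.r_cyl2 <= 0:
            raise ValueError("cylinder radii must be strictly positive")
        if self.L_g <= 0:
            raise ValueError("L_g must be strictly positive")

    @property
    def k1x(self) -> float:
        return self.Q * self.k1y

    @property
    def k2x(self) -> float:
        return self.Q * self.k2y

    def with_Q(self, Q: float) -> "ModelParams":
        return replace(self, Q=Q)


def _vec2(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (2,):
        raise ValueError(f"expected a 2-vector (x, y), got shape {a.shape}")
    return a


@dataclass
class FoldState:
    """Displacements and velocities of the two masses of one fold.

    Vectors are ``(x, y)`` pairs; zero displacement is the rest (closed)
    position.  A negative half-width in the glottal profile derived from
    this state indicates collision with the contralateral fold.
    """

    r1: np.ndarray = field(default_factory=lambda: np.zeros(2))
    r2: np.ndarray = field(default_factory=lambda: np.zeros(2))
    v1: np.ndarray = field(default_factory=lambda: np.zeros(2))
    v2: np.ndarray = field(default_factory=lambda: np.zeros(2))
    t: float = 0.0

    def __post_init__(self) -> None:
        self.r1 = _vec2(self.r1)
        self.r2 = _vec2(self.r2)
        self.v1 = _vec2(self.v1)
        self.v2 = _vec2(self.v2)
        if not np.isfinite(self.to_vector()).all():
            raise ValueError("state must be finite")

    def to_vector(self) -> np.ndarray:
        """Pack as (r1x, r1y, r2x, r2y, v1x, v1y, v2x, v2y)."""
        return np.concatenate([self.r1, self.r2, self.v1, self.v2])

    @classmethod
    def from_vector(cls, vec: np.ndarray, t: float = 0.0) -> "FoldState":
        vec = np.asarray(vec, dtype=float)
        return cls(r1=vec[0:2], r2=vec[2:4], v1=vec[4:6], v2=vec[6:8], t=t)


@dataclass(frozen=True)
class ForcePair:
    """External force vectors (N) acting on the lower and upper mass."""

    F1: np.ndarray = field(default_factory=lambda: np.zeros(2))
    F2: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        object.__setattr__(self, "F1", _vec2(self.F1))
        object.__setattr__(self, "F2", _vec2(self.F2))

    def __add__(self, other: "ForcePair") -> "ForcePair":
        return ForcePair(self.F1 + other.F1, self.F2 + other.F2)


# ---------------------------------------------------------------------------
# element-wise coefficient vectors (x, y) per mass


def stiffness_vectors(params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Spring stiffness vectors ``k_i = (k_ix, k_iy)`` with ``k_ix = Q k_iy``."""
    k1 = np.array([params.k1x, params.k1y])
    k2 = np.array([params.k2x, params.k2y])
    return k1, k2


def damping_coefficients(params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Damping coefficient vectors ``eta_i = (eta_ix, eta_iy)`` in N s/m.

    ``eta_1 = 0.1 * 2 sqrt(m1 k1)`` and ``eta_2 = 0.6 * 2 sqrt(m2 k2)``
    element-wise, with the vertical stiffness ``k_ix = Q k_iy``.  Because
    of the square root, scaling Q by 4 doubles the vertical damping while
    leaving the horizontal one unchanged.
    """
    k1, k2 = stiffness_vectors(params)
    eta1 = params.zeta1 * 2.0 * np.sqrt(params.m1 * k1)
    eta2 = params.zeta2 * 2.0 * np.sqrt(params.m2 * k2)
    return eta1, eta2


def internal_forces(state: FoldState, params: ModelParams) -> ForcePair:
    """Spring, coupling and damper contribution to the net force.

    Returns the negated structural terms of the equations of motion, i.e.
    ``F_int,i = -(k_i o r_i + kc (r_i - r_j) + eta_i o v_i)`` where ``o``
    is the element-wise product.  At rest this is exactly zero, and for
    equal displacements of the two masses the coupling term vanishes.
    """
    k1, k2 = stiffness_vectors(params)
    eta1, eta2 = damping_coefficients(params)
    F1 = -(k1 * state.r1 + params.kc * (state.r1 - state.r2) + eta1 * state.v1)
    F2 = -(k2 * state.r2 + params.kc * (state.r2 - state.r1) + eta2 * state.v2)
    return ForcePair(F1, F2)


def contact_force_from_depths(depths: tuple[float, float], params: ModelParams) -> ForcePair:
    """Penalty contact force for given per-mass penetration depths (m).

    A linear penalty spring of stiffness ``contact_stiffness_scale * k_iy``
    pushes each penetrating mass back laterally (+y).  Depth <= 0 means no
    contact and contributes nothing.
    """
    d1, d2 = depths
    s = params.contact_stiffness_scale
    F1 = np.array([0.0, s * params.k1y * max(0.0, d1)])
    F2 = np.array([0.0, s * params.k2y * max(0.0, d2)])
    return ForcePair(F1, F2)


def contact_force(state: FoldState, profile, params: ModelParams) -> ForcePair:
    """Contact force from the instantaneous glottal profile.

    Convenience wrapper around :func:`contact_force_from_depths` using the
    penetration depths measured at each mass's vertical station.
    """
    from .glottal_geometry import contact_depths

    return contact_force_from_depths(contact_depths(profile), params)


def eom_rhs(state: FoldState, external: ForcePair, params: ModelParams) -> np.ndarray:
    """Time derivative of the packed state vector.

    ``external`` must already contain every non-structural force (aerodynamic
    surface force plus contact penalty); the spring/damper/coupling terms are
    added here.  Accelerations are element-wise per axis: the x and y
    dynamics only couple through the external forces and contact.
    """
    if not (np.isfinite(external.F1).all() and np.isfinite(external.F2).all()):
        raise ValueError("non-finite external force")
    fint = internal_forces(state, params)
    a1 = (external.F1 + fint.F1) / params.m1
    a2 = (external.F2 + fint.F2) / params.m2
    return np.concatenate([state.v1, state.v2, a1, a2])


def step(
    state: FoldState,
    dt: float,
    forces_callback,
    params: ModelParams,
    r_max: float = 20e-3,
) -> FoldState:
    """Advance the fold state by one explicit fourth-order Runge-Kutta step.

    Parameters
    ----------
    forces_callback : callable
        ``forces_callback(state) -> ForcePair`` returning the external
        (aerodynamic + contact) force for an intermediate state.  It is
        evaluated at every RK stage so position-dependent contact forces
        are handled consistently.
    r_max : float
        Instability guard: raise :class:`InstabilityError` if any mass
        displacement magnitude exceeds this bound after the step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")

    def rhs(vec: np.ndarray, t: float) -> np.ndarray:
        s = FoldState.from_vector(vec, t)
        return eom_rhs(s, forces_callback(s), params)

    y0 = state.to_vector()
    t0 = state.t
    k1 = rhs(y0, t0)
    k2 = rhs(y0 + 0.5 * dt * k1, t0 + 0.5 * dt)
    k3 = rhs(y0 + 0.5 * dt * k2, t0 + 0.5 * dt)
    k4 = rhs(y0 + dt * k3, t0 + dt)
    y1 = y0 + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    new = FoldState.from_vector(y1, t0 + dt)
    if max(np.linalg.norm(new.r1), np.linalg.norm(new.r2)) > r_max:
        raise InstabilityError(
            f"displacement exceeded {r_max * 1e3:.1f} mm at t = {new.t:.6f} s"
        )
    return new


def mechanical_energy(state: FoldState, params: ModelParams) -> float:
    """Total mechanical energy: kinetic + spring + coupling (J).

    Used by the conservation checks: with zero damping and no external
    forcing this quantity is an invariant of the motion.
    """
    k1, k2 = stiffness_vectors(params)
    kin = 0.5 * params.m1 * state.v1 @ state.v1 + 0.5 * params.m2 * state.v2 @ state.v2
    pot = 0.5 * (k1 * state.r1 @ state.r1 + k2 * state.r2 @ state.r2)
    d = state.r1 - state.r2
    pot += 0.5 * params.kc * d @ d
    return float(kin + pot)
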