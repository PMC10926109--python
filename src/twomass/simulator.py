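"""Coupled source-filter simulation loop and Q sweeps.

One fixed-step loop couples the four physical layers: at every acoustic
sample the glottal profile is rebuilt from the mass positions, the
tract-loaded Bernoulli flow is solved against the incident partial
pressures of both transmission lines, the resulting surface and contact
forces drive the two-mass mechanics (sub-stepped RK4), and the glottal
flow is injected back into the lines.  The far-field pressure at 160 mm
from the mouth is derived from the mouth outflow history afterwards.

The glottis starts closed at rest; the constant lung pressure (default
2000 Pa) opens the folds, and a tiny seeded velocity perturbation breaks
the symmetry of the start-up transient so runs are reproducible yet not
artificially symmetric.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glottal_flow, tract_acoustics
from .glottal_geometry import _half_widths_scalar, build_profile
from .glottal_flow import solve_flow_loaded, surface_forces
from .mechanics import (
    FoldState,
    InstabilityError,
    ModelParams,
    damping_coefficients,
    stiffness_vectors,
)
from .tract_acoustics import RadiationModel, build_tract, radiated_pressure, tract_step

__all__ = ["SimulationConfig", "SimulationResult", "run", "sweep_Q"]


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one coupled run.

    Defaults follow the study conditions: 150/175 mm sub-/supra-glottal
    ducts, 2000 Pa driving pressure, and the standard two-mass constants
    held in ``params``.  ``dt`` fixes the acoustic segment length to
    ``c * dt``; the mechanics is advanced with ``substeps`` RK4 sub-steps
    per acoustic sample.
    """

    params: ModelParams = field(default_factory=ModelParams)
    sub_length: float = 0.150
    sup_length: float = 0.175
    tract_area: float = 2.0e-4
    c: float = tract_acoustics.SPEED_OF_SOUND
    rho: float = glottal_flow.RHO_AIR
    loss: float = 0.002
    chamber_reflection: float = 0.8
    radiation: RadiationModel = field(default_factory=RadiationModel)
    p_lung: float = 2000.0
    duration: float = 0.5
    dt: float = 2.5e-5
    transient_discard: float = 0.1
    n_stations: int = 64
    substeps: int = 5
    area_floor: float = glottal_flow.AREA_FLOOR
    separation_ratio: float | None = None
    perturbation_v: float = 1.0e-4
    random_seed: int = 0
    decimate: int = 1
    r_bound: float = 20e-3

    def __post_init__(self) -> None:
        if not self.duration > self.transient_discard >= 0:
            raise ValueError("need duration > transient_discard >= 0")
        if self.dt <= 0 or self.substeps < 1 or self.decimate < 1:
            raise ValueError("dt, substeps and decimate must be positive")


@dataclass
class SimulationResult:
    """Synchronized time series of one run (transient removed, decimated).

    Displacement/velocity arrays have shape ``(n, 2)`` with columns
    ``(x, y)``; forces are the aerodynamic surface forces per mass, whose
    x-components are the per-mass vertical forces.
    """

    t: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    min_area: np.ndarray
    U: np.ndarray
    p_sub: np.ndarray
    p_sup: np.ndarray
    F1: np.ndarray
    F2: np.ndarray
    u_mouth: np.ndarray
    p_far: np.ndarray
    config: SimulationConfig

    @property
    def fs(self) -> float:
        return 1.0 / (self.config.dt * self.config.decimate)


def run(config: SimulationConfig) -> SimulationResult:
    """Run one coupled simulation; deterministic for a given config.

    A run that never starts oscillating (closure deadlock) is returned
    as-is — classifying it is the analysis layer's job.  Numerical
    instability (displacement beyond ``r_bound``) raises
    :class:`~twomass.mechanics.InstabilityError` with the step index.
    """
    p = config.params
    sub = build_tract(
        config.sub_length, config.tract_area, config.dt, config.c, config.rho,
        config.loss, far_reflection=config.chamber_reflection, far_pressure=config.p_lung,
    )
    sup = build_tract(
        config.sup_length, config.tract_area, config.dt, config.c, config.rho,
        config.loss, far_reflection=config.radiation.reflection,
    )

    # precomputed per-DOF coefficient vectors over (x1, y1, x2, y2)
    k1, k2 = stiffness_vectors(p)
    eta1, eta2 = damping_coefficients(p)
    kvec = np.concatenate([k1, k2])
    evec = np.concatenate([eta1, eta2])
    mvec = np.array([p.m1, p.m1, p.m2, p.m2])
    kc = p.kc
    ck1 = p.contact_stiffness_scale * p.k1y
    ck2 = p.contact_stiffness_scale * p.k2y
    cd = p.contact_damping_scale

    rng = np.random.default_rng(config.random_seed)
    y = np.zeros(8)  # (r1x, r1y, r2x, r2y, v1x, v1y, v2x, v2y)
    y[4:] = config.perturbation_v * rng.standard_normal(4)

    n_steps = int(round(config.duration / config.dt))
    rec = {name: np.zeros(n_steps) for name in (
        "min_area", "U", "p_sub", "p_sup", "u_mouth",
        "F1x", "F1y", "F2x", "F2y",
    )}
    traj = np.zeros((n_steps, 8))

    h_sub = config.dt / config.substeps
    r_bound = config.r_bound

    def rhs(yv: np.ndarray, fa1x: float, fa1y: float, fa2x: float, fa2y: float) -> np.ndarray:
        r = yv[:4]
        v = yv[4:]
        hw1, hw2 = _half_widths_scalar(r[0], r[1], r[2], r[3], p)
        f1y_c = ck1 * -hw1 if hw1 < 0.0 else 0.0
        f2y_c = ck2 * -hw2 if hw2 < 0.0 else 0.0
        damp = evec * v
        if cd != 1.0 and (hw1 < 0.0 or hw2 < 0.0):
            damp = damp.copy()
            if hw1 < 0.0:
                damp[0:2] *= cd
            if hw2 < 0.0:
                damp[2:4] *= cd
        fint = -(kvec * r) - damp
        fint[0] += -kc * (r[0] - r[2]) + fa1x
        fint[1] += -kc * (r[1] - r[3]) + fa1y + f1y_c
        fint[2] += -kc * (r[2] - r[0]) + fa2x
        fint[3] += -kc * (r[3] - r[1]) + fa2y + f2y_c
        out = np.empty(8)
        out[:4] = v
        out[4:] = fint / mvec
        return out

    for i in range(n_steps):
        state = FoldState.from_vector(y, t=i * config.dt)
        profile = build_profile(state, p, config.n_stations)
        flow = solve_flow_loaded(
            profile, sub.incident, sup.incident, sub.z0, sup.z0,
            rho=config.rho, area_floor=config.area_floor,
            separation_ratio=config.separation_ratio,
        )
        fa = surface_forces(flow, profile, p)
        fa1x, fa1y = fa.F1
        fa2x, fa2y = fa.F2

        for _ in range(config.substeps):
            s1 = rhs(y, fa1x, fa1y, fa2x, fa2y)
            s2 = rhs(y + 0.5 * h_sub * s1, fa1x, fa1y, fa2x, fa2y)
            s3 = rhs(y + 0.5 * h_sub * s2, fa1x, fa1y, fa2x, fa2y)
            s4 = rhs(y + h_sub * s3, fa1x, fa1y, fa2x, fa2y)
            y = y + (h_sub / 6.0) * (s1 + 2.0 * s2 + 2.0 * s3 + s4)
        if max(abs(y[0]), abs(y[1]), abs(y[2]), abs(y[3])) > r_bound:
            raise InstabilityError(f"displacement bound exceeded at step {i}")

        tract_step(sub, -flow.U)
        _, u_mouth = tract_step(sup, flow.U)

        traj[i] = y
        rec["min_area"][i] = profile.min_area
        rec["U"][i] = flow.U
        rec["p_sub"][i] = flow.p_sub
        rec["p_sup"][i] = flow.p_sup
        rec["u_mouth"][i] = u_mouth
        rec["F1x"][i], rec["F1y"][i] = fa1x, fa1y
        rec["F2x"][i], rec["F2y"][i] = fa2x, fa2y

    p_far = radiated_pressure(rec["u_mouth"], config.dt, config.radiation, config.rho, config.c)

    t_full = np.arange(n_steps) * config.dt
    keep = slice(int(round(config.transient_discard / config.dt)), None, config.decimate)
    return SimulationResult(
        t=t_full[keep],
        r1=traj[keep, 0:2],
        r2=traj[keep, 2:4],
        v1=traj[keep, 4:6],
        v2=traj[keep, 6:8],
        min_area=rec["min_area"][keep],
        U=rec["U"][keep],
        p_sub=rec["p_sub"][keep],
        p_sup=rec["p_sup"][keep],
        F1=np.column_stack([rec["F1x"][keep], rec["F1y"][keep]]),
        F2=np.column_stack([rec["F2x"][keep], rec["F2y"][keep]]),
        u_mouth=rec["u_mouth"][keep],
        p_far=p_far[keep],
        config=config,
    )


def sweep_Q(config: SimulationConfig, Q_list) -> pd.DataFrame:
    """Run one simulation per stiffness ratio and tabulate the measures.

    Columns: horizontal and vertical oscillation amplitudes per mass,
    SPL at the far-field point, fundamental frequency, regime label and
    subharmonic index.  A failed run (e.g. numerical instability) is
    recorded in its row's ``error`` column and the sweep continues.
    """
    from . import analysis

    rows = []
    for Q in Q_list:
        if Q <= 0:
            raise ValueError("Q values must be positive")
        cfg = dataclasses.replace(config, params=config.params.with_Q(Q))
        row: dict = {"Q": Q, "error": ""}
        try:
            res = run(cfg)
            fs = res.fs
            f0 = analysis.estimate_f0(res.r1[:, 1], fs)
            row.update(
                amp_y1=analysis.displacement_metrics(res.r1[:, 1]),
                amp_y2=analysis.displacement_metrics(res.r2[:, 1]),
                amp_x1=analysis.displacement_metrics(res.r1[:, 0]),
                amp_x2=analysis.displacement_metrics(res.r2[:, 0]),
                spl_db=analysis.spl(res.p_far, fs),
                f0_hz=f0 if f0 is not None else np.nan,
            )
            label = analysis.classify_regime(res.r1[:, 1], res.r2[:, 1], fs, f0)
            row["regime"] = label.label
            row["subharmonic_index"] = label.subharmonic_index
        except (InstabilityError, ValueError) as exc:
            row["error"] = str(exc)
            for key in ("amp_y1", "amp_y2", "amp_x1", "amp_x2", "spl_db",
                        "f0_hz", "subharmonic_index"):
                row[key] = np.nan
            row["regime"] = "failed"
        rows.append(row)
    return pd.DataFrame(rows).set_index("Q")
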