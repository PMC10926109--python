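"""Wave-reflection-analog (transmission-line) duct acoustics.

Each tract (the 150 mm subglottal duct and the 175 mm supraglottal duct)
is discretized into segments of length ``c * dt`` carrying forward and
backward partial pressure waves — the classic Kelly-Lochbaum scheme.
Total pressure is ``f + b`` and volume velocity ``(f - b) A / (rho c)``.

Index 0 is always the glottal end; ``f`` travels away from the glottis,
``b`` towards it.  Both lines take a positive input flow as flow INTO
the line at the glottal end (so the subglottal line is driven with
``-U`` when U flows out of it towards the glottis).

Far-end terminations: an open mouth is a frequency-independent
reflection coefficient (default -0.9) plus a monopole far-field model;
the inlet chamber is a soft constant-pressure reservoir with a positive
reflection coefficient and a transmission term that injects the lung
pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TractLine",
    "RadiationModel",
    "build_tract",
    "tract_step",
    "impedance_spectrum",
    "radiated_pressure",
]

SPEED_OF_SOUND = 343.0  # m/s
RHO_AIR = 1.2  # kg/m^3


@dataclass(frozen=True)
class RadiationModel:
    """Open-end termination and far-field sampling description.

    Only the frequency-independent ``reflection`` kind is implemented;
    the radiated pressure itself uses a simple-source (monopole)
    approximation evaluated at distance ``r_far`` from the mouth.
    """

    kind: str = "reflection"
    reflection: float = -0.9
    r_far: float = 0.160

    def __post_init__(self) -> None:
        if self.kind != "reflection":
            raise NotImplementedError(f"radiation model kind {self.kind!r} not supported")
        if abs(self.reflection) > 1.0:
            raise ValueError("|reflection| must not exceed 1")
        if self.r_far <= 0:
            raise ValueError("far-field distance must be positive")


@dataclass
class TractLine:
    """State of one discretized duct.

    ``far_reflection`` is the reflection coefficient at the non-glottal
    end; ``far_pressure`` (Pa), when non-zero, is a constant-pressure
    source behind that end transmitted with ``(1 - r) / 2`` so the duct
    settles to exactly that static pressure against a closed glottis.
    """

    n_seg: int
    seg_len: float
    area: float
    dt: float
    c: float = SPEED_OF_SOUND
    rho: float = RHO_AIR
    loss: float = 0.002
    far_reflection: float = -0.9
    far_pressure: float = 0.0
    requested_length: float = 0.0
    f_wave: np.ndarray = field(default_factory=lambda: np.zeros(0))
    b_wave: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.f_wave.size == 0:
            self.f_wave = np.zeros(self.n_seg)
        if self.b_wave.size == 0:
            self.b_wave = np.zeros(self.n_seg)

    @property
    def length(self) -> float:
        """Actual discretized length (may differ from requested by < 1 segment)."""
        return self.n_seg * self.seg_len

    @property
    def z0(self) -> float:
        """Characteristic impedance rho c / A (Pa s / m^3)."""
        return self.rho * self.c / self.area

    @property
    def incident(self) -> float:
        """Backward partial pressure arriving at the glottal end."""
        return float(self.b_wave[0])

    def pressure(self) -> np.ndarray:
        return self.f_wave + self.b_wave


def build_tract(
    length: float,
    area: float,
    dt: float,
    c: float = SPEED_OF_SOUND,
    rho: float = RHO_AIR,
    loss: float = 0.002,
    far_reflection: float = -0.9,
    far_pressure: float = 0.0,
) -> TractLine:
    """Discretize a duct of the given length into c*dt segments.

    The segment count is ``round(length / (c dt))`` and must be at least
    8 for the line to resolve its first quarter-wave resonance usefully.
    """
    if dt <= 0 or length <= 0 or area <= 0:
        raise ValueError("length, area and dt must be positive")
    n_seg = int(round(length / (c * dt)))
    if n_seg < 8:
        raise ValueError(
            f"discretization too coarse: {length=} m at dt={dt} s gives {n_seg} segments (< 8)"
        )
    return TractLine(
        n_seg=n_seg,
        seg_len=c * dt,
        area=area,
        dt=dt,
        c=c,
        rho=rho,
        loss=loss,
        far_reflection=far_reflection,
        far_pressure=far_pressure,
        requested_length=length,
    )


def tract_step(line: TractLine, u_in: float) -> tuple[float, float]:
    """Advance the line by one sample given the glottal-end inflow.

    Performs one Kelly-Lochbaum update in place: inject the source wave
    at the glottal end, propagate both rails one segment with the scalar
    loss factor, and apply the far-end termination.

    Returns
    -------
    (p_glottis, u_far_out) :
        Pressure seen by the glottis this step and the volume velocity
        delivered past the far end (mouth outflow for the supraglottal
        line).
    """
    z0 = line.z0
    decay = 1.0 - line.loss

    b0 = line.b_wave[0]
    f_inj = b0 + z0 * u_in  # source junction: u = (f - b)/z0
    p_glottis = f_inj + b0

    arriving_far = line.f_wave[-1] * decay
    r = line.far_reflection
    b_far = r * arriving_far
    if line.far_pressure != 0.0:
        # transmission chosen so the static pressure at a closed glottal
        # end settles to exactly far_pressure despite the per-segment loss
        # (forward path decays n times, the reflected path n - 1 times)
        d_rt = decay ** (2 * line.n_seg - 1)
        b_far += 0.5 * (1.0 - r * d_rt) / decay ** (line.n_seg - 1) * line.far_pressure
    u_far_out = (arriving_far - b_far) * line.area / (line.rho * line.c)

    line.f_wave[1:] = decay * line.f_wave[:-1]
    line.f_wave[0] = f_inj
    line.b_wave[:-1] = decay * line.b_wave[1:]
    line.b_wave[-1] = b_far

    return float(p_glottis), float(u_far_out)


def impedance_spectrum(line: TractLine, f_grid: np.ndarray) -> np.ndarray:
    """Input impedance magnitude of the discretized line vs. frequency.

    Frequency-domain transfer-matrix evaluation of the same segment
    chain: each segment contributes a lossy transmission-line two-port;
    the far termination is the load ``Z_L = Z0 (1 + r)/(1 - r)``.
    Resonances are the local maxima of the returned magnitude.
    """
    f_grid = np.asarray(f_grid, dtype=float)
    z0 = line.z0
    alpha = -np.log(max(1.0 - line.loss, 1e-12)) / line.seg_len
    k = 2.0 * np.pi * f_grid / line.c - 1j * alpha
    gamma = 1j * k * line.length  # uniform line: segments collapse into one

    r = line.far_reflection
    if np.isclose(r, 1.0):
        zl = np.inf
    else:
        zl = z0 * (1.0 + r) / (1.0 - r)

    t = np.tanh(gamma)
    if np.isinf(zl):
        z_in = z0 / t
    else:
        z_in = z0 * (zl + z0 * t) / (z0 + zl * t)
    return np.abs(z_in)


def resonance_frequencies(line: TractLine, f_max: float = 4000.0, n_points: int = 8192) -> np.ndarray:
    """Resonances of a line: local maxima of its input impedance magnitude."""
    from scipy.signal import find_peaks

    f_grid = np.linspace(1.0, f_max, n_points)
    mag = impedance_spectrum(line, f_grid)
    peaks, _ = find_peaks(mag)
    return f_grid[peaks]


def radiated_pressure(
    mouth_flow: np.ndarray,
    dt: float,
    radiation: RadiationModel,
    rho: float = RHO_AIR,
    c: float = SPEED_OF_SOUND,
) -> np.ndarray:
    """Far-field pressure from the mouth volume-velocity history.

    Simple-source approximation: ``p(t) = rho / (4 pi r) * dU/dt``
    evaluated with a centered finite difference and delayed by the
    propagation time ``r / c`` (rounded to whole samples).
    """
    u = np.asarray(mouth_flow, dtype=float)
    if u.size < 3:
        raise ValueError("mouth flow history must have at least 3 samples")
    dudt = np.gradient(u, dt)
    p = rho / (4.0 * np.pi * radiation.r_far) * dudt
    delay = int(round(radiation.r_far / (c * dt)))
    if delay > 0:
        p = np.concatenate([np.zeros(delay), p[:-delay] if delay < p.size else p[:0]])
        p = p[: u.size]
    return p
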