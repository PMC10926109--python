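"""Signal analyses for entrainment-regime characterization.

Extracts the standard voice measures from simulated (or stored) time
series: fundamental frequency, sound pressure level, Welch spectra, a
subharmonic index quantifying energy at half-integer multiples of F0,
the best rational p:q lock between F0 and a tract resonance, Poincare
section based regime classification (limit cycle vs torus/subharmonic),
and cycle-averaged displacement amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import scipy.signal

__all__ = [
    "SpectrumResult",
    "RegimeLabel",
    "estimate_f0",
    "spl",
    "spectrum",
    "subharmonic_index",
    "entrainment_ratio",
    "classify_regime",
    "displacement_metrics",
]

P_REF = 20e-6  # Pa, SPL reference

#: autocorrelation ratio above which a candidate half-period is preferred
#: over the full period (a weak subharmonic does not halve F0)
SUBHARMONIC_DOMINANCE = 0.95

#: amplitude below which a series is considered silent (relative to nothing
#: physical -- an absolute floor suited to displacements in meters and
#: pressures in pascals alike is impossible, so use a relative criterion)
_SILENT_REL = 1e-10


@dataclass
class SpectrumResult:
    """Welch magnitude spectrum in dB re an arbitrary reference."""

    frequency_hz: np.ndarray
    magnitude_db: np.ndarray
    power: np.ndarray  # linear PSD-integrated band powers, same grid
    nfft: int
    window: str
    fs: float

    @property
    def resolution(self) -> float:
        return self.frequency_hz[1] - self.frequency_hz[0]


@dataclass(frozen=True)
class RegimeLabel:
    """Classification of a vibratory regime with its evidence scores."""

    label: str  # silent | limit_cycle | torus_or_subharmonic | irregular
    n_clusters: int
    cluster_spread: float
    subharmonic_index: float


def _demean(series: np.ndarray) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    return x - x.mean()


def estimate_f0(series, fs: float, f_min: float = 30.0, f_max: float = 2000.0):
    """Fundamental frequency by autocorrelation peak with parabolic refinement.

    Returns the frequency of the PERIODIC frame: a weak subharmonic (for
    example 5% amplitude at F0/2) does not halve the estimate, but a
    dominant one does.  Returns ``None`` for silent or aperiodic input.
    """
    x = _demean(series)
    n = x.size
    if n < 16 or not np.any(np.abs(x) > _SILENT_REL * max(1.0, np.abs(series).max())):
        return None
    # biased autocorrelation via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec))[:n]
    if ac[0] <= 0:
        return None
    ac = ac / ac[0]

    lag_min = max(2, int(fs / f_max))
    lag_max = min(n - 2, int(fs / f_min))
    if lag_max <= lag_min:
        return None
    window = ac[lag_min : lag_max + 1]
    best = int(np.argmax(window)) + lag_min
    if ac[best] < 0.3:  # no periodicity worth reporting
        return None

    # prefer the half period while it is nearly as strong: a weak
    # subharmonic must not halve the reported F0
    while best // 2 >= lag_min:
        half = best // 2
        k = int(np.argmax(ac[max(lag_min, half - 2) : half + 3])) + max(lag_min, half - 2)
        if ac[k] >= SUBHARMONIC_DOMINANCE * ac[best]:
            best = k
        else:
            break

    if 1 <= best < n - 1:  # parabolic interpolation around the peak
        y0, y1, y2 = ac[best - 1], ac[best], ac[best + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        best = best + np.clip(delta, -0.5, 0.5)
    return float(fs / best)


def spl(series_pa, fs: float) -> float:
    """Sound pressure level 20 log10(rms / 20 uPa) of a mean-removed window."""
    x = _demean(series_pa)
    if x.size < int(0.05 * fs):
        raise ValueError("SPL needs a window of at least 50 ms")
    rms = np.sqrt(np.mean(x * x))
    if rms == 0.0:
        return -np.inf
    return float(20.0 * np.log10(rms / P_REF))


def spectrum(series, fs: float, nfft: int | None = None, window: str = "hann") -> SpectrumResult:
    """Welch-averaged magnitude spectrum (50% overlap).

    The default ``nfft`` targets a resolution of 5 Hz or better so that a
    90 Hz subharmonic comb is cleanly separated from the harmonics.
    """
    x = _demean(series)
    if nfft is None:
        nfft = int(2 ** np.ceil(np.log2(fs / 5.0)))
    if x.size < nfft:
        raise ValueError(f"series length {x.size} is shorter than nfft = {nfft}")
    f, pxx = scipy.signal.welch(x, fs=fs, window=window, nperseg=nfft, noverlap=nfft // 2)
    power = pxx * (f[1] - f[0])
    mag = 10.0 * np.log10(np.maximum(power, 1e-300))
    return SpectrumResult(frequency_hz=f, magnitude_db=mag, power=power, nfft=nfft, window=window, fs=fs)


def _peak_power(spec: SpectrumResult, f: float) -> float:
    """Band power collected within +-1 bin of the target frequency."""
    k = int(round(f / spec.resolution))
    lo, hi = max(0, k - 1), min(spec.power.size, k + 2)
    return float(spec.power[lo:hi].sum())


def subharmonic_index(spec: SpectrumResult, f0: float) -> float:
    """Power at half-integer multiples of F0 relative to integer harmonics.

    An index near zero indicates a purely harmonic spectrum; near one,
    subharmonics (period doubling / torus motion) as strong as the
    harmonics themselves.
    """
    if f0 < 2.0 * spec.resolution:
        raise ValueError(f"f0 = {f0} Hz is below twice the spectral resolution")
    f_nyq = spec.frequency_hz[-1]
    harm = sum(_peak_power(spec, k * f0) for k in range(1, int(f_nyq / f0) + 1))
    sub = sum(
        _peak_power(spec, (k + 0.5) * f0) for k in range(0, int(f_nyq / f0 - 0.5) + 1)
    )
    if harm <= 0:
        return np.inf if sub > 0 else 0.0
    return float(sub / harm)


def entrainment_ratio(f0: float, f_res: float, max_order: int = 8):
    """Best small-integer lock ratio p:q between F0 and a resonance.

    Minimizes ``|f0/f_res - p/q|`` over ``1 <= p, q <= max_order`` (ties
    go to the smallest denominator).  Also reports the residual and the
    difference tone ``min_k |f_res - k f0|`` — for the 2:5 lock between
    180 and 450 Hz this is the 90 Hz subharmonic.

    Returns
    -------
    (ratio, residual, difference_tone_hz)
    """
    if f0 <= 0 or f_res <= 0:
        raise ValueError("frequencies must be positive")
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    target = f0 / f_res
    best = None
    for q in range(1, max_order + 1):
        for pp in range(1, max_order + 1):
            err = abs(target - pp / q)
            key = (err, q, pp)
            if best is None or key < best[0]:
                best = (key, Fraction(pp, q))
    ratio = best[1]
    residual = float(abs(target - ratio))
    k = max(1, round(f_res / f0))
    difference = float(min(abs(f_res - kk * f0) for kk in (k - 1, k, k + 1) if kk >= 1))
    return ratio, residual, difference


def _poincare_section(y1: np.ndarray, y2: np.ndarray, v2: np.ndarray):
    """Section points (y2, v2) at upward zero crossings of y1."""
    s = _demean(y1)
    idx = np.flatnonzero((s[:-1] < 0) & (s[1:] >= 0))
    if idx.size == 0:
        return np.empty((0, 2))
    frac = -s[idx] / (s[idx + 1] - s[idx])
    pts = np.column_stack([
        y2[idx] + frac * (y2[idx + 1] - y2[idx]),
        v2[idx] + frac * (v2[idx + 1] - v2[idx]),
    ])
    return pts


def _cluster_count(pts: np.ndarray, rel_tol: float, scale: float) -> tuple[int, float]:
    """Single-linkage clustering at a distance threshold relative to the
    orbit scale (NOT the section scatter, which degenerates to zero for a
    limit cycle)."""
    if scale <= 0:
        return 1, 0.0
    z = pts / scale
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import pdist

    if len(z) < 3:
        return 1, 0.0
    labels = fcluster(linkage(pdist(z), method="single"), t=rel_tol, criterion="distance")
    n = int(labels.max())
    spread = float(
        np.mean([z[labels == c].std(axis=0).sum() for c in range(1, n + 1)])
    )
    return n, spread


def classify_regime(
    y1_series,
    y2_series,
    fs: float,
    f0: float | None,
    cluster_tol: float = 0.12,
    max_torus_clusters: int = 8,
    subharmonic_cutoff: float = 0.1,
) -> RegimeLabel:
    """Label the vibratory regime from a Poincare section.

    The section is taken at upward zero crossings of the mass-1 series;
    the (y2, dy2/dt) section points are clustered with a relative
    distance threshold.  One cluster means a limit cycle; a small number
    of tight clusters means period-n / subharmonic motion; many points
    forming a closed curve indicate a torus; anything else is irregular.
    The label is invariant to amplitude scaling and time shift.
    """
    y1 = np.asarray(y1_series, dtype=float)
    y2 = _demean(y2_series)
    scale = np.abs(_demean(y1)).max() if y1.size else 0.0
    if scale <= _SILENT_REL * max(1.0, np.abs(y1).max()):
        return RegimeLabel("silent", 0, 0.0, 0.0)

    v2 = np.gradient(y2, 1.0 / fs)
    pts = _poincare_section(y1, y2, v2)
    if len(pts) == 0:
        return RegimeLabel("silent", 0, 0.0, 0.0)
    if len(pts) < 10:
        return RegimeLabel("irregular", len(pts), 0.0, 0.0)

    # subharmonic evidence from the spectrum of the y2 series
    shi = 0.0
    if f0 is not None:
        try:
            spec = spectrum(y2, fs)
            shi = subharmonic_index(spec, f0)
        except ValueError:
            shi = 0.0

    orbit_scale = float(np.hypot(y2.std(), v2.std()))
    n, spread = _cluster_count(pts, cluster_tol, orbit_scale)
    tight = cluster_tol / 2.0
    if n == 1:
        if spread <= tight and shi < subharmonic_cutoff:
            return RegimeLabel("limit_cycle", n, spread, shi)
        # single-linkage chains a filled closed curve into one cluster
        if _is_closed_curve(pts) or shi >= subharmonic_cutoff:
            return RegimeLabel("torus_or_subharmonic", n, spread, shi)
        return RegimeLabel("irregular", n, spread, shi)
    if 2 <= n <= max_torus_clusters and spread <= tight:
        return RegimeLabel("torus_or_subharmonic", n, spread, shi)
    if _is_closed_curve(pts):
        return RegimeLabel("torus_or_subharmonic", n, spread, shi)
    return RegimeLabel("irregular", n, spread, shi)


def _is_closed_curve(pts: np.ndarray) -> bool:
    """Heuristic: do the section points trace a thin closed curve?

    Sort points by angle about the centroid and test whether the radius
    is a smooth single-valued function of angle (small local scatter
    relative to the mean radius) — true for a quasiperiodic torus
    section, false for a scattered (chaotic/noisy) cloud.
    """
    z = pts - pts.mean(axis=0)
    # normalize axes so the curve is roughly circular
    std = z.std(axis=0)
    if np.any(std == 0):
        return False
    z = z / std
    ang = np.arctan2(z[:, 1], z[:, 0])
    rad = np.hypot(z[:, 0], z[:, 1])
    order = np.argsort(ang)
    r_sorted = rad[order]
    local_jump = np.abs(np.diff(r_sorted))
    return float(np.median(local_jump)) < 0.15 * float(np.mean(rad))


def displacement_metrics(series) -> float:
    """Mean oscillation amplitude: cycle peak-to-peak averaged, halved.

    Cycles are delimited by upward zero crossings of the mean-removed
    series.  A constant (or effectively silent) series scores zero.
    """
    x = _demean(series)
    if x.size == 0 or np.abs(x).max() <= _SILENT_REL * max(1.0, np.abs(series).max()):
        return 0.0
    idx = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0))
    if idx.size < 2:
        return 0.0
    amps = [
        0.5 * (x[a:b].max() - x[a:b].min())
        for a, b in zip(idx[:-1], idx[1:])
        if b - a >= 2
    ]
    return float(np.mean(amps)) if amps else 0.0
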