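"""Synthetic test signals and CSV/WAV/config plumbing.

The fixture generator produces deterministic sinusoid mixtures (harmonic
combs, subharmonic mixtures, quasiperiodic pairs) so the whole analysis
layer can be exercised without running the physics.  The CSV schema is a
plain-text, full-precision round trip of :class:`SimulationResult`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io.wavfile

__all__ = [
    "FixtureSpec",
    "synth_signal",
    "write_timeseries_csv",
    "read_timeseries_csv",
    "write_wav",
    "read_wav",
    "SCHEMA_VERSION",
    "TIMESERIES_COLUMNS",
]

SCHEMA_VERSION = 1

#: required columns of the time-series CSV, in canonical order
TIMESERIES_COLUMNS = (
    "time", "r1x", "r1y", "r2x", "r2y", "v1x", "v1y", "v2x", "v2y",
    "min_area", "U", "p_sub", "p_sup",
    "F1x", "F1y", "F2x", "F2y", "u_mouth", "p_far",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic sum-of-sinusoids test signal description.

    ``components`` is a sequence of ``(frequency_hz, amplitude, phase)``
    triples; optional Gaussian noise of the given RMS is added from a
    seeded generator.
    """

    components: tuple = ()
    noise_rms: float = 0.0
    fs: float = 40000.0
    duration: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f, _a, _ph in self.components:
            if f >= self.fs / 2:
                raise ValueError(f"component at {f} Hz would alias at fs = {self.fs} Hz")
        if self.noise_rms < 0 or self.fs <= 0 or self.duration <= 0:
            raise ValueError("invalid fixture parameters")


def synth_signal(spec: FixtureSpec) -> np.ndarray:
    """Render the fixture: sum of sinusoids plus seeded Gaussian noise."""
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    x = np.zeros(n)
    for f, a, ph in spec.components:
        x += a * np.sin(2.0 * np.pi * f * t + ph)
    if spec.noise_rms > 0:
        rng = np.random.default_rng(spec.seed)
        x += spec.noise_rms * rng.standard_normal(n)
    return x


# ---------------------------------------------------------------------------
# time-series CSV


def _result_frame(result) -> pd.DataFrame:
    return pd.DataFrame({
        "time": result.t,
        "r1x": result.r1[:, 0], "r1y": result.r1[:, 1],
        "r2x": result.r2[:, 0], "r2y": result.r2[:, 1],
        "v1x": result.v1[:, 0], "v1y": result.v1[:, 1],
        "v2x": result.v2[:, 0], "v2y": result.v2[:, 1],
        "min_area": result.min_area, "U": result.U,
        "p_sub": result.p_sub, "p_sup": result.p_sup,
        "F1x": result.F1[:, 0], "F1y": result.F1[:, 1],
        "F2x": result.F2[:, 0], "F2y": result.F2[:, 1],
        "u_mouth": result.u_mouth, "p_far": result.p_far,
    })


def _config_to_json(config) -> str:
    d = dataclasses.asdict(config)
    return json.dumps(d, sort_keys=True)


def write_timeseries_csv(path, result) -> None:
    """Write a simulation result as plain CSV with a config header.

    Float columns use 17 significant digits so a write/read round trip
    is lossless at float64 precision.  The configuration is echoed in
    ``#``-prefixed header lines.
    """
    path = Path(path)
    df = _result_frame(result)
    with path.open("w") as fh:
        fh.write(f"# schema_version: {SCHEMA_VERSION}\n")
        if result.config is not None:
            fh.write(f"# config: {_config_to_json(result.config)}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_timeseries_csv(path):
    """Read a time-series CSV back into a :class:`SimulationResult`.

    Unknown extra columns are ignored; a missing required column raises
    an error naming it.  The embedded config (if present) is restored as
    a plain dict under ``result.config`` — reconstructing the dataclass
    is the caller's choice.
    """
    from .simulator import SimulationResult

    import io

    path = Path(path)
    config = None
    lines = path.read_text().splitlines(keepends=True)
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        if line.startswith("# config:"):
            config = json.loads(line[len("# config:"):])
    try:
        df = pd.read_csv(
            io.StringIO("".join(lines[body_start:])), float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc

    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    bad = df[list(TIMESERIES_COLUMNS)].isna().any(axis=1)
    if bad.any():
        # +2: 1-based line numbers plus the header row
        lineno = body_start + int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"malformed row at line {lineno} of {path}")

    def col2(a, b):
        return np.column_stack([df[a].to_numpy(), df[b].to_numpy()])

    return SimulationResult(
        t=df["time"].to_numpy(),
        r1=col2("r1x", "r1y"), r2=col2("r2x", "r2y"),
        v1=col2("v1x", "v1y"), v2=col2("v2x", "v2y"),
        min_area=df["min_area"].to_numpy(), U=df["U"].to_numpy(),
        p_sub=df["p_sub"].to_numpy(), p_sup=df["p_sup"].to_numpy(),
        F1=col2("F1x", "F1y"), F2=col2("F2x", "F2y"),
        u_mouth=df["u_mouth"].to_numpy(), p_far=df["p_far"].to_numpy(),
        config=config,
    )


# ---------------------------------------------------------------------------
# WAV export


def write_wav(series_pa, fs: float, path, normalize: bool = False) -> None:
    """Write a pressure series as a float32 RIFF WAV file.

    With ``normalize=True`` the series is peak-normalized to 0.9 and the
    applied gain recorded in a JSON sidecar next to the file, so the
    physical amplitude is recoverable.
    """
    x = np.asarray(series_pa, dtype=np.float64)
    if x.size == 0:
        raise ValueError("refusing to write an empty WAV file")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite samples")
    gain = 1.0
    if normalize:
        peak = np.abs(x).max()
        if peak > 0:
            gain = 0.9 / peak
    scipy.io.wavfile.write(str(path), int(round(fs)), (x * gain).astype(np.float32))
    sidecar = {"schema_version": SCHEMA_VERSION, "fs": fs, "normalized": normalize, "gain": gain}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, sort_keys=True))


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a WAV file back, undoing any recorded normalization gain."""
    fs, x = scipy.io.wavfile.read(str(path))
    gain = 1.0
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        gain = float(meta.get("gain", 1.0))
    return np.asarray(x, dtype=np.float64) / gain, float(fs)
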