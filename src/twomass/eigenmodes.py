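"""In-vacuo eigenmode analysis of the 4-DOF two-mass system.

The undamped, unforced equations of motion over the coordinates
``(x1, y1, x2, y2)`` form a generalized eigenproblem ``K phi = w^2 M phi``.
Because the springs act element-wise per axis, the stiffness matrix is
block diagonal over the two axes, so every mode is purely horizontal
(medial-lateral) or purely vertical; raising the vertical-to-horizontal
stiffness ratio Q shifts only the vertical-mode frequencies, producing a
crossover in the frequency-ordered mode list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .mechanics import ModelParams

__all__ = ["ModeSet", "assemble_system", "solve_modes", "mode_table"]

#: DOF ordering used throughout this module.
DOF_ORDER = ("x1", "y1", "x2", "y2")

_AXIS_TOL = 1e-9


@dataclass(frozen=True)
class ModeSet:
    """Natural frequencies and unit-normalized mode shapes of one fold.

    ``frequencies_hz`` is ascending; ``shapes[:, k]`` is the displacement
    pattern of mode ``k`` over ``(x1, y1, x2, y2)``.  ``labels[k]`` is
    ``"horizontal"`` when the x-components vanish (motion purely
    medial-lateral), ``"vertical"`` when the y-components vanish, and
    ``"mixed"`` otherwise.
    """

    frequencies_hz: np.ndarray
    shapes: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.frequencies_hz) != 4 or self.shapes.shape != (4, 4):
            raise ValueError("a ModeSet holds exactly four modes")
        if np.any(np.diff(self.frequencies_hz) < 0):
            raise ValueError("frequencies must be ascending")


def assemble_system(params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Mass and stiffness matrices of the undamped 4-DOF system.

    ``M = diag(m1, m1, m2, m2)`` and, per axis ``a``,
    ``K_a = [[k1a + kc, -kc], [-kc, k2a + kc]]`` with ``k_ix = Q k_iy``.
    Both matrices are symmetric positive definite for valid parameters.
    """
    M = np.diag([params.m1, params.m1, params.m2, params.m2])
    K = np.zeros((4, 4))
    for offset, (k1a, k2a) in ((0, (params.k1x, params.k2x)), (1, (params.k1y, params.k2y))):
        i, j = offset, offset + 2  # mass-1 and mass-2 DOF of this axis
        K[i, i] = k1a + params.kc
        K[j, j] = k2a + params.kc
        K[i, j] = K[j, i] = -params.kc
    return M, K


def _label(shape: np.ndarray) -> str:
    x_part = np.hypot(shape[0], shape[2])
    y_part = np.hypot(shape[1], shape[3])
    norm = np.linalg.norm(shape)
    if x_part <= _AXIS_TOL * norm:
        return "horizontal"
    if y_part <= _AXIS_TOL * norm:
        return "vertical"
    return "mixed"


def solve_modes(params: ModelParams) -> ModeSet:
    """Solve ``K phi = w^2 M phi`` and return the four natural modes.

    Frequencies are sorted ascending; on an exact frequency tie the
    horizontal mode is listed before the vertical one.  Shapes are
    normalized to unit Euclidean norm with a sign convention that makes
    the largest-magnitude component positive.
    """
    M, K = assemble_system(params)
    w2, V = scipy.linalg.eigh(K, M)
    f = np.sqrt(np.maximum(w2, 0.0)) / (2.0 * np.pi)

    labels = [_label(V[:, k]) for k in range(4)]
    rank = {"horizontal": 0, "vertical": 1, "mixed": 2}
    order = sorted(range(4), key=lambda k: (round(f[k], 9), rank[labels[k]]))

    shapes = np.empty((4, 4))
    for col, k in enumerate(order):
        v = V[:, k] / np.linalg.norm(V[:, k])
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        shapes[:, col] = v
    return ModeSet(
        frequencies_hz=f[order],
        shapes=shapes,
        labels=tuple(labels[k] for k in order),
    )


def mode_table(params: ModelParams, Q_list: Sequence[float]) -> pd.DataFrame:
    """Eigenfrequency table over a sweep of stiffness ratios.

    Rows are mode indices 1-4 (frequency-ordered), columns the Q values;
    entries in Hz.  ``df.to_csv(path)`` renders the table directly.
    """
    Q_list = list(Q_list)
    if not Q_list:
        raise ValueError("Q_list must be non-empty")
    if any(q <= 0 for q in Q_list):
        raise ValueError("all Q values must be positive")
    data = {q: solve_modes(params.with_Q(q)).frequencies_hz for q in Q_list}
    df = pd.DataFrame(data, index=pd.Index([1, 2, 3, 4], name="mode"))
    df.columns.name = "Q"
    return df


def lowest_vertical_mode_rank(params: ModelParams) -> int:
    """1-based frequency rank of the lowest vertical-labeled mode.

    Tracks the crossover: as Q grows the vertical modes stiffen and the
    lowest of them climbs past the second horizontal mode in the
    frequency-ordered list.
    """
    modes = solve_modes(params)
    for rank, label in enumerate(modes.labels, start=1):
        if label == "vertical":
            return rank
    raise ValueError("no vertical mode found (degenerate parameters?)")
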