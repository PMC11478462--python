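"""Phase-amplitude modulation: from ToF/amplitude to actuation signals.

The time-reversal chain is purely algebraic:

* focal phases  ``H_j = 2 pi (T_max - T_j) / T``  (latest arrival fires
  first when re-emitted, so all beams arrive in phase at the target);
* twin-trap phases ``M_j = H_j + pi/2 - pi * Heaviside(j - (n+1)/2)``:
  the left array half leads by +pi/2, the right half lags by -pi/2, putting
  a pi phase difference (the twin signature) between halves;
* amplitude coefficients ``W_j = A_max / A_j`` so every beam contributes
  the same pressure to the trap (min(W) = 1 at the strongest pathway);
* actuation ``Psi_j = theta * W_j * exp(i * phase_j)`` with theta the base
  emission pressure (1000 Pa by default; the field scales linearly in it).

Element index 1 is the minimum-lateral-coordinate end of the array after
pose rotation ("left"), fixing twin lobe laterality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModulationPatterns",
    "phase_from_tof",
    "twin_from_focal",
    "amplitude_coeffs",
    "actuation",
    "modulation_patterns",
]

DEFAULT_THETA_PA = 1000.0
TWO_PI = 2.0 * np.pi


def _heaviside_half(x: np.ndarray) -> np.ndarray:
    """Heaviside step with H(0) = 1/2 (centre element of odd arrays)."""
    return np.heaviside(x, 0.5)


def phase_from_tof(tof: np.ndarray, period: float) -> np.ndarray:
    """Focal-beam phase pattern H from per-element time of flight.

    ``H_j = 2 pi (T_max - T_j) / period`` wrapped into [0, 2 pi).  Adding a
    constant to every ToF leaves H unchanged (only differences matter).
    """
    if period <= 0:
        raise ValueError("period must be positive")
    t = np.asarray(tof, dtype=float)
    if t.size == 0:
        raise ValueError("empty ToF vector")
    h = TWO_PI * (t.max() - t) / period
    return np.mod(h, TWO_PI)


def twin_from_focal(h: np.ndarray, n: int | None = None) -> np.ndarray:
    """Twin-trap phase pattern M: +pi/2 on the left half, -pi/2 on the right.

    Uses 1-based element indices; ``M_j = H_j + pi/2 - pi H(j - (n+1)/2)``
    with H(0) = 1/2, so an odd array's centre element gets no shift.
    Wrapped into [0, 2 pi).
    """
    h = np.asarray(h, dtype=float)
    if n is None:
        n = h.size
    if h.size != n:
        raise ValueError(f"phase pattern must have length n={n}")
    j = np.arange(1, n + 1, dtype=float)
    m = h + np.pi / 2.0 - np.pi * _heaviside_half(j - (n + 1) / 2.0)
    return np.mod(m, TWO_PI)


def amplitude_coeffs(amplitude: np.ndarray) -> np.ndarray:
    """Wavefront-equalizing coefficients ``W_j = A_max / A_j``.

    ``W_j A_j`` is constant across elements, so with ``Psi_j = theta W_j``
    every beam delivers equal pressure to the target; the strongest pathway
    gets coefficient exactly 1.
    """
    a = np.asarray(amplitude, dtype=float)
    if a.size == 0:
        raise ValueError("empty amplitude vector")
    bad = np.flatnonzero(a <= 0)
    if bad.size:
        raise ValueError(f"non-positive amplitude at element {bad[0] + 1}")
    return a.max() / a


def actuation(phases: np.ndarray, w: np.ndarray | None = None,
              theta: float = DEFAULT_THETA_PA) -> np.ndarray:
    """Complex drive signals ``Psi_j = theta * W_j * exp(i * phase_j)``.

    ``w=None`` is phase-only modulation (W = 1 everywhere).
    """
    p = np.asarray(phases, dtype=float)
    if w is None:
        w = np.ones_like(p)
    w = np.asarray(w, dtype=float)
    if w.shape != p.shape:
        raise ValueError("phases and W must have matching length")
    return theta * w * np.exp(1j * p)


@dataclass(frozen=True)
class ModulationPatterns:
    """The full pattern set for one target: H, M, W and Psi."""

    h: np.ndarray              # focal phases, [0, 2 pi)
    m: np.ndarray              # twin phases, [0, 2 pi)
    w: np.ndarray              # amplitude coefficients, >= 1
    psi: np.ndarray            # complex actuation (focal or twin)
    theta: float               # base emission pressure, Pa
    period: float              # us
    trap: str                  # "focal" | "twin"
    am: bool                   # amplitude modulation applied?


def modulation_patterns(tof: np.ndarray, amplitude: np.ndarray,
                        period: float = 1.0, trap: str = "focal",
                        am: bool = True,
                        theta: float = DEFAULT_THETA_PA) -> ModulationPatterns:
    """Build all patterns for one target from its ToF/amplitude vectors."""
    if trap not in ("focal", "twin"):
        raise ValueError("trap must be 'focal' or 'twin'")
    h = phase_from_tof(tof, period)
    m = twin_from_focal(h)
    w = amplitude_coeffs(amplitude)
    phases = h if trap == "focal" else m
    psi = actuation(phases, w if am else None, theta)
    return ModulationPatterns(h=h, m=m, w=w, psi=psi, theta=theta,
                              period=period, trap=trap, am=am)
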