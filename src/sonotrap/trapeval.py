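"""Trap quality metrics on synthesized pressure fields.

Covers the four checks the workflow relies on: refocusing (distance from
the intended target to the field peak), lateral beam width (FWHM of the
intensity profile), the sequential-activation wavefront-uniformity test
(each added element should raise the normalized target pressure by exactly
1/n when amplitude modulation equalizes the wavefront), and the twin-trap
structure test (two lobes flanking a pressure well at the target).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from sonotrap.phantom import ArrayGeometry, TissueMap
from sonotrap.wavesim import FieldSynthesizer, PressureField, SimulationConfig

__all__ = [
    "TrapMetrics",
    "localization_error",
    "peak_position",
    "lateral_fwhm",
    "increment_uniformity",
    "twin_structure",
]


@dataclass
class TrapMetrics:
    """Flat container for the metrics the CLI serializes."""

    peak_position: tuple[float, float] | None = None
    localization_error: float | None = None
    fwhm_lateral: float | None = None
    increments: list[float] | None = None
    twin_control_points: list[tuple[float, float]] | None = None
    twin_contrast: float | None = None

    def as_dict(self) -> dict:
        out = {}
        for key, val in self.__dict__.items():
            if val is None:
                continue
            if isinstance(val, np.ndarray):
                val = val.tolist()
            out[key] = val
        return out


def _quadratic_offset(fm: float, f0: float, fp: float) -> float:
    """Sub-cell offset of a parabola through three equidistant samples."""
    denom = fm - 2.0 * f0 + fp
    if denom >= 0:  # not a local maximum; no refinement
        return 0.0
    return float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))


def peak_position(fld: PressureField, mask: np.ndarray | None = None
                  ) -> np.ndarray:
    """Position of the |p| maximum, refined by a local quadratic fit."""
    mag = fld.magnitude
    if mask is not None:
        mag = np.where(mask, mag, -np.inf)
    if np.ptp(mag[np.isfinite(mag)]) == 0:
        raise ValueError("flat field: no peak")
    i, j = np.unravel_index(np.argmax(mag), mag.shape)
    ny, nx = mag.shape
    di = dj = 0.0
    if 0 < i < ny - 1 and np.all(np.isfinite(mag[i - 1:i + 2, j])):
        di = _quadratic_offset(mag[i - 1, j], mag[i, j], mag[i + 1, j])
    if 0 < j < nx - 1 and np.all(np.isfinite(mag[i, j - 1:j + 2])):
        dj = _quadratic_offset(mag[i, j - 1], mag[i, j], mag[i, j + 1])
    x = fld.origin[0] + (j + 0.5 + dj) * fld.cell_size
    y = fld.origin[1] + (i + 0.5 + di) * fld.cell_size
    return np.array([x, y])


def localization_error(fld: PressureField, target,
                       mask: np.ndarray | None = None) -> float:
    """Euclidean distance (mm) from the target to the field |p| peak.

    Invariant under global field scaling; sub-cell refinement by a local
    quadratic fit around the arg-max cell.
    """
    peak = peak_position(fld, mask=mask)
    return float(np.linalg.norm(peak - np.asarray(target, dtype=float)))


def _profile(fld: PressureField, center, direction, span: float,
             n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """|p| sampled along a line segment centred on ``center``."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    s = np.linspace(-span / 2.0, span / 2.0, n_samples)
    pts = np.asarray(center, dtype=float)[None, :] + s[:, None] * d[None, :]
    return s, np.abs(fld.value_at(pts))


def lateral_fwhm(fld: PressureField, target, span: float,
                 direction=(1.0, 0.0), mode: str = "intensity",
                 n_samples: int = 801) -> float:
    """Full width at half maximum of the lateral profile through the peak.

    The profile is |p|^2 (acoustic intensity; ``mode="pressure"`` uses |p|)
    along ``direction`` through the profile maximum within a ``span``-wide
    window centred on the target.  Crossings are located by linear
    interpolation; a profile that does not drop below half maximum on both
    sides within the span is flagged as unresolved.
    """
    if mode not in ("intensity", "pressure"):
        raise ValueError("mode must be 'intensity' or 'pressure'")
    s, prof = _profile(fld, target, direction, span, n_samples)
    if mode == "intensity":
        prof = prof ** 2
    k = int(np.argmax(prof))
    if k == 0 or k == len(prof) - 1:
        raise ValueError("unresolved: profile maximum on the span boundary")
    half = prof[k] / 2.0
    left = right = None
    for i in range(k, 0, -1):
        if prof[i - 1] <= half:
            f = (prof[i] - half) / (prof[i] - prof[i - 1])
            left = s[i] - f * (s[i] - s[i - 1])
            break
    for i in range(k, len(prof) - 1):
        if prof[i + 1] <= half:
            f = (prof[i] - half) / (prof[i] - prof[i + 1])
            right = s[i] + f * (s[i + 1] - s[i])
            break
    if left is None or right is None:
        raise ValueError("unresolved: no half-maximum crossing within span")
    return float(right - left)


def increment_uniformity(synth: FieldSynthesizer | TissueMap,
                         patterns_psi: np.ndarray, target,
                         baseline: Sequence[int], added: Sequence[int],
                         array: ArrayGeometry | None = None,
                         cfg: SimulationConfig | None = None) -> np.ndarray:
    """Normalized target-pressure rise as elements are activated in turn.

    Starting from the ``baseline`` element set (1-based indices), each
    element of ``added`` is switched on cumulatively; the rise in
    |p(target)| after each addition is normalized by the all-n-active
    value.  With amplitude modulation the wavefront is uniform and every
    increment equals 1/n.

    ``synth`` may be a ready :class:`FieldSynthesizer` or a TissueMap (then
    ``array`` is required).  The target pressure is evaluated at the exact
    point, not on a grid.
    """
    if isinstance(synth, TissueMap):
        if array is None:
            raise ValueError("array geometry required when passing a TissueMap")
        synth = FieldSynthesizer(synth, array, cfg)
    n = synth.array.n
    psi = np.asarray(patterns_psi, dtype=complex)
    if psi.shape != (n,):
        raise ValueError(f"actuation must have length n={n}")
    baseline = [int(e) for e in baseline]
    added = [int(e) for e in added]
    all_named = baseline + added
    if len(set(all_named)) != len(all_named):
        raise ValueError("duplicate element in baseline/added")
    if any(e < 1 or e > n for e in all_named):
        raise ValueError(f"element indices must be in 1..{n}")
    transfer = synth.transfer_at(np.asarray(target, dtype=float)[None, :])[0]
    p_all = abs(transfer @ psi)
    if p_all == 0:
        raise ValueError("degenerate field: zero pressure at target")
    active = np.zeros(n, dtype=bool)
    for e in baseline:
        active[e - 1] = True
    prev = abs(transfer[active] @ psi[active]) if active.any() else 0.0
    increments = []
    for e in added:
        active[e - 1] = True
        cur = abs(transfer[active] @ psi[active])
        increments.append((cur - prev) / p_all)
        prev = cur
    return np.asarray(increments)


def twin_structure(fld: PressureField, target, wavelength: float,
                   direction=(1.0, 0.0), span: float | None = None,
                   n_samples: int = 1201) -> tuple[np.ndarray, float]:
    """Locate the two twin-trap lobes flanking the target.

    Scans the lateral |p| profile through the target, takes the strongest
    local maximum on each side, and checks the twin contract: the pressure
    at the target must be below both lobe peaks (a well between two walls).
    Returns the two control-point positions and the contrast
    ``|p(target)| / mean(lobe peaks)``.  Raises ``ValueError("no twin
    structure")`` when either lobe is missing or the target is not a well.
    """
    if span is None:
        span = 6.0 * wavelength
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    s, prof = _profile(fld, target, d, span, n_samples)
    p_target = prof[np.argmin(np.abs(s))]
    interior = slice(1, len(s) - 1)
    is_max = np.zeros(len(s), dtype=bool)
    is_max[interior] = (prof[1:-1] >= prof[:-2]) & (prof[1:-1] > prof[2:])
    lobes = []
    for side in (s < -0.25 * wavelength, s > 0.25 * wavelength):
        idx = np.flatnonzero(is_max & side)
        if idx.size == 0:
            raise ValueError("no twin structure: missing lobe")
        lobes.append(idx[np.argmax(prof[idx])])
    peaks = prof[lobes]
    if not np.all(p_target < peaks):
        raise ValueError("no twin structure: target is not a pressure well")
    ds = s[1] - s[0]
    points = []
    for k in lobes:
        off = _quadratic_offset(prof[k - 1], prof[k], prof[k + 1]) * ds
        points.append(np.asarray(target, float) + (s[k] + off) * d)
    contrast = float(p_target / peaks.mean())
    return np.stack(points), contrast
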