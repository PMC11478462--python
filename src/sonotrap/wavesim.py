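"""Geometric-acoustics forward model.

Three physical quantities drive the whole pipeline and are computed here:

* **first-arrival time of flight** through the heterogeneous speed map, as
  the viscosity solution of the eikonal equation ``|grad T| = 1/c`` solved
  by a Godunov upwind fast-sweeping method (numba-compiled);
* **arrival amplitude**, modelled as geometric spreading ``(r0/r)^s`` times
  frequency-scaled attenuation ``10^(-f * integral(alpha) / 20)`` along the
  straight source-receiver ray;
* **steady-state complex pressure fields** from a set of element actuation
  signals, superposing one eikonal phase map per element (transmission
  reciprocity keeps this at n solves per geometry).

The model reproduces exactly the quantities the surrogate training and the
trap metrics need (ToF, peak amplitude, interference structure); it is not a
full-wave solver and does not claim diffraction-accurate side lobes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from scipy.ndimage import map_coordinates

from sonotrap.phantom import ArrayGeometry, TissueMap

__all__ = [
    "SimulationConfig",
    "TofMap",
    "PressureField",
    "tof_map",
    "amplitude_at",
    "collect_sample",
    "peak_pick",
    "synth_field",
    "FieldSynthesizer",
]

#: conversion from dB to Np (20 log10 e)
_DB_PER_NP = 8.685889638065037


@dataclass(frozen=True)
class SimulationConfig:
    """Acoustic simulation constants.

    Attributes
    ----------
    frequency : float
        Operating frequency in MHz (default 1.0).
    c_water : float
        Reference sound speed in m/s defining the nominal wavelength.
    spreading_exponent : float
        Geometric-spreading power; 0.5 is cylindrical spreading in 2-D.
    reference_radius : float
        r0 in mm at which the source amplitude is defined.
    source_amplitude : float
        Emission pressure (Pa) of the point source used in data collection.
    """

    frequency: float = 1.0
    c_water: float = 1500.0
    spreading_exponent: float = 0.5
    reference_radius: float = 1.0
    source_amplitude: float = 1000.0
    directivity: bool = True
    directivity_sigma6_deg: float = 24.2
    directivity_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.c_water <= 0:
            raise ValueError("frequency and reference speed must be positive")
        if self.reference_radius <= 0:
            raise ValueError("reference_radius must be positive")

    @property
    def wavelength_water(self) -> float:
        """Nominal wavelength lambda = c_water / f, in mm."""
        return self.c_water / (self.frequency * 1e3)

    @property
    def period(self) -> float:
        """Wave period T = 1/f, in microseconds."""
        return 1.0 / self.frequency


@njit(cache=True)
def _fast_sweep(T, slowness, h, max_iter, tol):
    """Godunov upwind fast-sweeping solver for |grad T| = slowness.

    ``T`` holds initial values (large except near the source) and is updated
    in place; ``slowness`` is in time-units per mm, ``h`` the cell size in
    mm.  Four alternating sweep orderings per iteration; stops when the
    largest update falls below ``tol``.
    """
    ny, nx = T.shape
    for _ in range(max_iter):
        maxdiff = 0.0
        for sweep in range(4):
            if sweep == 0:
                i0, i1, di = 0, ny, 1
                j0, j1, dj = 0, nx, 1
            elif sweep == 1:
                i0, i1, di = 0, ny, 1
                j0, j1, dj = nx - 1, -1, -1
            elif sweep == 2:
                i0, i1, di = ny - 1, -1, -1
                j0, j1, dj = 0, nx, 1
            else:
                i0, i1, di = ny - 1, -1, -1
                j0, j1, dj = nx - 1, -1, -1
            for i in range(i0, i1, di):
                for j in range(j0, j1, dj):
                    a = 1e30
                    if j > 0 and T[i, j - 1] < a:
                        a = T[i, j - 1]
                    if j < nx - 1 and T[i, j + 1] < a:
                        a = T[i, j + 1]
                    b = 1e30
                    if i > 0 and T[i - 1, j] < b:
                        b = T[i - 1, j]
                    if i < ny - 1 and T[i + 1, j] < b:
                        b = T[i + 1, j]
                    f = slowness[i, j] * h
                    if abs(a - b) >= f:
                        tnew = (a if a < b else b) + f
                    else:
                        tnew = 0.5 * (a + b + math.sqrt(2.0 * f * f - (a - b) * (a - b)))
                    if tnew < T[i, j]:
                        d = T[i, j] - tnew
                        if d > maxdiff:
                            maxdiff = d
                        T[i, j] = tnew
        if maxdiff < tol:
            break
    return T


@njit(cache=True)
def _ray_integrals(atten, oy, ox, h, sy, sx, pts, step):
    """Midpoint line integrals of the attenuation grid, source -> points.

    Returns integral(alpha ds) in (dB/(cm*MHz)) * mm units for each point;
    nearest-cell sampling (the grids are piecewise constant).
    """
    ny, nx = atten.shape
    m = pts.shape[0]
    out = np.empty(m)
    for p in range(m):
        dx = pts[p, 0] - sx
        dy = pts[p, 1] - sy
        r = math.sqrt(dx * dx + dy * dy)
        if r == 0.0:
            out[p] = 0.0
            continue
        nsteps = int(r / step) + 1
        ds = r / nsteps
        acc = 0.0
        for q in range(nsteps):
            t = (q + 0.5) / nsteps
            x = sx + t * dx
            y = sy + t * dy
            j = int((x - ox) / h)
            i = int((y - oy) / h)
            if i < 0:
                i = 0
            elif i >= ny:
                i = ny - 1
            if j < 0:
                j = 0
            elif j >= nx:
                j = nx - 1
            acc += atten[i, j]
        out[p] = acc * ds
    return out


def element_response(array: ArrayGeometry, element_index: int, points,
                     cfg: SimulationConfig) -> np.ndarray:
    """Directional amplitude response of one element toward physical points.

    A Gaussian beam-spread model ``D(theta) = 2^(-(theta/sigma6)^2)``
    calibrated so the response is -6 dB (one half) at the configured
    half-spread angle ``cfg.directivity_sigma6_deg`` (default 24.2 deg, the
    elements' characterized beam spread), floored at
    ``cfg.directivity_floor``.  Unlike the signed piston pattern, this
    response is smooth and strictly positive, which keeps the
    amplitude-equalization inversion ``W = A_max / A`` well posed across
    the whole workspace (no nulls).

    The same factor multiplies the received amplitude in data collection
    and the transmitted amplitude in field synthesis (transducer
    reciprocity), so amplitude modulation cancels it exactly at the
    target.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    center = array.centers[element_index]
    rel = pts - center[None, :]
    r = np.linalg.norm(rel, axis=1)
    sin_th = np.where(r > 0, np.abs(rel @ array.axis) / np.where(r > 0, r, 1.0), 0.0)
    theta = np.degrees(np.arcsin(np.clip(sin_th, 0.0, 1.0)))
    d = 2.0 ** (-((theta / cfg.directivity_sigma6_deg) ** 2))
    return np.maximum(d, cfg.directivity_floor)


@dataclass
class TofMap:
    """First-arrival travel-time field (microseconds) from one source."""

    times: np.ndarray
    source: tuple[float, float]
    cell_size: float
    origin: tuple[float, float]

    def at(self, points) -> np.ndarray:
        """Bilinear interpolation of the travel time at physical points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ci = (pts[:, 1] - self.origin[1]) / self.cell_size - 0.5
        cj = (pts[:, 0] - self.origin[0]) / self.cell_size - 0.5
        return map_coordinates(self.times, [ci, cj], order=1, mode="nearest")


def tof_map(tissue_map: TissueMap, source: Sequence[float],
            max_iter: int = 60, tol: float = 1e-9,
            init_radius: int = 4) -> TofMap:
    """Solve the first-arrival travel-time field for a point source.

    The source neighbourhood (a few cells) is initialized with the exact
    local travel time to suppress the point-source singularity of the
    first-order upwind scheme; the fast-sweeping iteration then fills the
    rest of the grid.
    """
    if not tissue_map.contains_point(source):
        raise ValueError(f"source {tuple(source)} outside map")
    h = tissue_map.cell_size
    ny, nx = tissue_map.shape
    # slowness in us/mm: c in m/s == 1e-3 mm/us
    slowness = 1.0 / (tissue_map.speed_grid * 1e-3)
    T = np.full((ny, nx), 1e30)
    sx = float(source[0]) - tissue_map.origin[0]
    sy = float(source[1]) - tissue_map.origin[1]
    si = int(sy / h)
    sj = int(sx / h)
    si = min(max(si, 0), ny - 1)
    sj = min(max(sj, 0), nx - 1)
    c_src = tissue_map.speed_grid[si, sj] * 1e-3  # mm/us
    r_init = int(init_radius)  # cells of exact initialization at the source
    for i in range(max(0, si - r_init), min(ny, si + r_init + 1)):
        for j in range(max(0, sj - r_init), min(nx, sj + r_init + 1)):
            xc = (j + 0.5) * h
            yc = (i + 0.5) * h
            T[i, j] = math.hypot(xc - sx, yc - sy) / c_src
    _fast_sweep(T, slowness, h, max_iter, tol)
    return TofMap(times=T, source=(float(source[0]), float(source[1])),
                  cell_size=h, origin=tissue_map.origin)


def attenuation_db(tissue_map: TissueMap, source, points,
                   frequency_mhz: float, step: float | None = None) -> np.ndarray:
    """Attenuation in dB along straight rays from ``source`` to ``points``.

    The per-cell coefficient is in dB/(cm*MHz); the line integral (in mm) is
    scaled by the frequency and converted from cm to mm.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if step is None:
        step = tissue_map.cell_size / 2.0
    integ = _ray_integrals(
        tissue_map.atten_grid,
        tissue_map.origin[1], tissue_map.origin[0],
        tissue_map.cell_size,
        float(source[1]), float(source[0]),
        np.ascontiguousarray(pts), step)
    return integ * frequency_mhz / 10.0  # (dB/cm) * mm -> dB


def amplitude_at(tissue_map: TissueMap, source, receiver,
                 source_amplitude: float,
                 cfg: SimulationConfig | None = None) -> float:
    """Arrival pressure amplitude (Pa) at ``receiver`` for a point source.

    ``A = A0 (r0/r)^s 10^(-dB/20)`` with the attenuation integrated along
    the straight source-receiver segment.  Requires separation > r0.
    """
    cfg = cfg or SimulationConfig()
    for name, p in (("source", source), ("receiver", receiver)):
        if not tissue_map.contains_point(p):
            raise ValueError(f"{name} {tuple(p)} outside map")
    src = np.asarray(source, float)
    rec = np.asarray(receiver, float)
    r = float(np.linalg.norm(rec - src))
    if r == 0:
        raise ValueError("zero source-receiver separation")
    if r <= cfg.reference_radius:
        raise ValueError(
            f"separation {r} mm must exceed reference radius {cfg.reference_radius} mm")
    dB = attenuation_db(tissue_map, src, rec[None, :], cfg.frequency)[0]
    spread = (cfg.reference_radius / r) ** cfg.spreading_exponent
    return float(source_amplitude * spread * 10.0 ** (-dB / 20.0))


def collect_sample(tissue_map: TissueMap, array: ArrayGeometry, target,
                   cfg: SimulationConfig | None = None,
                   element_tof_maps: Sequence[TofMap] | None = None):
    """One time-reversal sample: per-element ToF and arrival amplitude.

    A point source at the target emits; the elements receive.  If
    ``element_tof_maps`` (one travel-time field per element, element centre
    as source) is provided, ToF is read there via reciprocity, so building a
    whole dataset costs ``n`` eikonal solves instead of one per sample.
    """
    from sonotrap.dataset import Sample  # local import avoids module cycle

    cfg = cfg or SimulationConfig()
    tgt = np.asarray(target, dtype=float)
    if not tissue_map.contains_point(tgt):
        raise ValueError(f"target {tuple(tgt)} outside map")
    if element_tof_maps is not None:
        if len(element_tof_maps) != array.n:
            raise ValueError("need one travel-time map per element")
        tof = np.array([tm.at(tgt)[0] for tm in element_tof_maps])
    else:
        tm = tof_map(tissue_map, tgt)
        tof = tm.at(array.centers)
    amp = np.array([
        amplitude_at(tissue_map, tgt, c, cfg.source_amplitude, cfg)
        for c in array.centers
    ])
    if cfg.directivity:
        amp = amp * np.array([
            element_response(array, j, tgt[None, :], cfg)[0]
            for j in range(array.n)])
    return Sample(target=tgt, tof=tof, amplitude=amp)


def peak_pick(waveform: np.ndarray, dt: float, t0: float = 0.0
              ) -> tuple[float, float]:
    """Global maximum of a sampled pressure trace and its timestamp.

    Ties are broken by the earliest sample.  An all-zero trace carries no
    arrival and is rejected.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size == 0:
        raise ValueError("empty waveform")
    if np.all(w == 0):
        raise ValueError("no arrival: all-zero trace")
    idx = int(np.argmax(w))  # argmax returns the first maximal sample
    return float(w[idx]), float(t0 + idx * dt)


@dataclass
class PressureField:
    """Complex steady-state pressure on a rectangular evaluation grid."""

    complex_pressure: np.ndarray     # (ny, nx), Pa
    cell_size: float                 # mm
    origin: tuple[float, float]      # mm, lower-left corner of the window

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.complex_pressure)

    @property
    def normalization(self) -> float:
        return float(np.abs(self.complex_pressure).max())

    @property
    def normalized(self) -> np.ndarray:
        """Magnitude scaled so the field maximum is 1 (NP display units)."""
        m = self.normalization
        if m == 0:
            raise ValueError("degenerate all-zero field")
        return np.abs(self.complex_pressure) / m

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.complex_pressure.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return x, y

    def value_at(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ci = (pts[:, 1] - self.origin[1]) / self.cell_size - 0.5
        cj = (pts[:, 0] - self.origin[0]) / self.cell_size - 0.5
        re = map_coordinates(self.complex_pressure.real, [ci, cj], order=1)
        im = map_coordinates(self.complex_pressure.imag, [ci, cj], order=1)
        return re + 1j * im


def save_field(fld: PressureField, path) -> None:
    """Persist a field raster: channels re/im/mag + window metadata."""
    np.savez(path,
             re=fld.complex_pressure.real,
             im=fld.complex_pressure.imag,
             mag=np.abs(fld.complex_pressure),
             cell_size_mm=fld.cell_size,
             origin_mm=np.asarray(fld.origin, dtype=float))


def load_field(path) -> PressureField:
    with np.load(path) as data:
        return PressureField(
            complex_pressure=data["re"] + 1j * data["im"],
            cell_size=float(data["cell_size_mm"]),
            origin=tuple(data["origin_mm"]))


class FieldSynthesizer:
    """Superposes per-element geometric-acoustics transfers into fields.

    Holds one travel-time field per element (reciprocity), so synthesizing
    any number of actuation patterns costs ``n`` eikonal solves in total.
    Per-window transfer matrices are cached, making repeated evaluations
    with different actuation vectors (e.g. sequential element activation)
    cheap.
    """

    def __init__(self, tissue_map: TissueMap, array: ArrayGeometry,
                 cfg: SimulationConfig | None = None,
                 directivity: bool | None = None):
        self.map = tissue_map
        self.array = array
        self.cfg = cfg or SimulationConfig()
        self.directivity = (self.cfg.directivity if directivity is None
                            else directivity)
        self._tof_maps: list[TofMap] | None = None
        self._window_cache: dict = {}

    @property
    def element_tof_maps(self) -> list[TofMap]:
        if self._tof_maps is None:
            self._tof_maps = [tof_map(self.map, c) for c in self.array.centers]
        return self._tof_maps

    def transfer_at(self, points) -> np.ndarray:
        """Complex transfer matrix (m points x n elements).

        ``p(x) = transfer @ psi``: each column carries the propagation
        phase ``exp(i 2 pi tof/T)``, spreading, attenuation and (optionally)
        the transmit directivity of that element.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cfg = self.cfg
        n = self.array.n
        out = np.empty((len(pts), n), dtype=complex)
        for j, center in enumerate(self.array.centers):
            rel = pts - center[None, :]
            r = np.linalg.norm(rel, axis=1)
            r_eff = np.maximum(r, cfg.reference_radius)
            spread = (cfg.reference_radius / r_eff) ** cfg.spreading_exponent
            dB = attenuation_db(self.map, center, pts, cfg.frequency)
            tof = self.element_tof_maps[j].at(pts)
            phase = 2.0 * np.pi * tof / cfg.period
            amp = spread * 10.0 ** (-dB / 20.0)
            if self.directivity:
                amp = amp * element_response(self.array, j, pts, cfg)
            out[:, j] = amp * np.exp(1j * phase)
        return out

    def point_pressure(self, psi: np.ndarray, points) -> np.ndarray:
        """Complex pressure at arbitrary physical points for actuation psi."""
        psi = np.asarray(psi, dtype=complex)
        if psi.shape != (self.array.n,):
            raise ValueError(f"actuation must have length n={self.array.n}")
        return self.transfer_at(points) @ psi

    def _window_transfer(self, region, cell_size):
        key = (tuple(np.round(region, 9)), round(cell_size, 9))
        if key not in self._window_cache:
            x0, x1, y0, y1 = region
            nx = max(2, int(round((x1 - x0) / cell_size)))
            ny = max(2, int(round((y1 - y0) / cell_size)))
            x = x0 + (np.arange(nx) + 0.5) * cell_size
            y = y0 + (np.arange(ny) + 0.5) * cell_size
            xx, yy = np.meshgrid(x, y)
            pts = np.column_stack([xx.ravel(), yy.ravel()])
            tr = self.transfer_at(pts).reshape(ny, nx, self.array.n)
            self._window_cache[key] = tr
        return self._window_cache[key]

    def field(self, psi: np.ndarray, region=None,
              cell_size: float | None = None) -> PressureField:
        """Synthesize the complex pressure field over a window.

        ``region`` is (x0, x1, y0, y1) in mm (default: the whole map);
        ``cell_size`` defaults to the map resolution.
        """
        psi = np.asarray(psi, dtype=complex)
        if psi.shape != (self.array.n,):
            raise ValueError(f"actuation must have length n={self.array.n}")
        if region is None:
            w, h = self.map.extent
            region = (self.map.origin[0], self.map.origin[0] + w,
                      self.map.origin[1], self.map.origin[1] + h)
        cell = cell_size if cell_size is not None else self.map.cell_size
        tr = self._window_transfer(tuple(region), cell)
        grid = tr @ psi
        return PressureField(complex_pressure=grid, cell_size=cell,
                             origin=(region[0], region[2]))


def synth_field(tissue_map: TissueMap, array: ArrayGeometry,
                actuation: np.ndarray, cfg: SimulationConfig | None = None,
                region=None, cell_size: float | None = None,
                directivity: bool = True,
                synthesizer: FieldSynthesizer | None = None) -> PressureField:
    """One-shot field synthesis for an actuation vector Psi.

    For repeated synthesis with the same geometry, build a
    :class:`FieldSynthesizer` once and call :meth:`FieldSynthesizer.field`.
    """
    synth = synthesizer or FieldSynthesizer(tissue_map, array, cfg,
                                            directivity=directivity)
    return synth.field(np.asarray(actuation, dtype=complex),
                       region=region, cell_size=cell_size)
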