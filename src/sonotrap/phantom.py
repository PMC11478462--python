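"""Layered tissue phantoms, phased-array placement and sampling workspace.

Geometry convention (used package-wide): continuous physical coordinates in
millimetres, origin at the lower-left corner of the map, ``x`` lateral and
``y`` depth into the body.  Grids are indexed row-major from the origin, so
``grid[i, j]`` is the cell whose centre is at
``origin + ((j + 0.5) * cell_size, (i + 0.5) * cell_size)``.

The phantom stands in for a segmented abdominal MR slice: horizontal layers
of water (coupling stand-off), skin, fat, muscle, liver and bone, each with
its own sound speed, mass density and attenuation coefficient.  Acoustic
property values for the tissue classes are not universal constants; the
defaults below are taken from standard tissue-property literature ranges and
are fully overridable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import j1

__all__ = [
    "TissueLayer",
    "TissueMap",
    "ArrayGeometry",
    "Workspace",
    "SamplingPlan",
    "DEFAULT_TISSUE_LAYERS",
    "DEFAULT_PHANTOM_LAYERS",
    "build_layered_phantom",
    "default_phantom",
    "place_array",
    "directivity_ratio",
    "solve_spread_half_angle",
    "workspace_bounds",
    "plan_samples",
]

#: First positive zero of the Bessel function J1 (first directivity null).
_J1_FIRST_ZERO = 3.8317059702075125


@dataclass(frozen=True)
class TissueLayer:
    """One homogeneous layer: name, thickness and acoustic properties."""

    name: str
    thickness_mm: float
    speed_mps: float
    density_kgm3: float
    atten_dbcmmhz: float


#: Default acoustic properties for the five tissue classes of the abdominal
#: slice (sound speed m/s, density kg/m3, attenuation dB/(cm*MHz)).  Values
#: are representative soft-tissue literature figures, not measurements.
DEFAULT_TISSUE_LAYERS: tuple[TissueLayer, ...] = (
    TissueLayer("skin", 2.0, 1615.0, 1090.0, 0.35),
    TissueLayer("fat", 8.0, 1450.0, 950.0, 0.48),
    TissueLayer("muscle", 15.0, 1580.0, 1050.0, 0.74),
    TissueLayer("liver", 55.0, 1595.0, 1060.0, 0.50),
    TissueLayer("bone", 10.0, 3198.0, 1990.0, 3.50),
)

#: Default full phantom stack: a 20 mm water coupling stand-off (the array
#: sits inside it) followed by the five tissue layers.
DEFAULT_PHANTOM_LAYERS: tuple[TissueLayer, ...] = (
    TissueLayer("water", 20.0, 1500.0, 1000.0, 0.0),
) + DEFAULT_TISSUE_LAYERS


@dataclass
class TissueMap:
    """Dense 2-D rasters of acoustic properties.

    Attributes
    ----------
    speed_grid, density_grid, atten_grid
        ``(ny, nx)`` arrays of sound speed (m/s), mass density (kg/m3) and
        attenuation coefficient (dB/(cm*MHz)).
    cell_size
        Grid spacing in mm (square cells).
    origin
        Physical coordinate of the lower-left corner of cell (0, 0), mm.
    layers
        The layer specification the map was built from (metadata only).
    frequency_mhz
        Operating frequency recorded with the map; used to check the
        cell-size-vs-wavelength contract.
    """

    speed_grid: np.ndarray
    density_grid: np.ndarray
    atten_grid: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    layers: tuple[TissueLayer, ...] = field(default_factory=tuple)
    frequency_mhz: float | None = None

    def __post_init__(self) -> None:
        self.speed_grid = np.ascontiguousarray(self.speed_grid, dtype=np.float64)
        self.density_grid = np.ascontiguousarray(self.density_grid, dtype=np.float64)
        self.atten_grid = np.ascontiguousarray(self.atten_grid, dtype=np.float64)
        if not (self.speed_grid.shape == self.density_grid.shape == self.atten_grid.shape):
            raise ValueError("speed, density and attenuation grids must share one shape")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if np.any(self.speed_grid <= 0) or np.any(self.density_grid <= 0):
            raise ValueError("sound speed and density must be positive everywhere")
        if np.any(self.atten_grid < 0):
            raise ValueError("attenuation must be non-negative everywhere")
        if self.frequency_mhz is not None:
            # mesh-resolution contract: cells no coarser than lambda/8 at the
            # operating frequency (lambda taken in the slowest medium).
            lam_min = self.speed_grid.min() / (self.frequency_mhz * 1e3)  # mm
            if self.cell_size > lam_min / 8 + 1e-12:
                raise ValueError(
                    f"cell_size {self.cell_size} mm exceeds lambda/8 = "
                    f"{lam_min / 8:.4f} mm at {self.frequency_mhz} MHz"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.speed_grid.shape

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the map in mm."""
        ny, nx = self.speed_grid.shape
        return (nx * self.cell_size, ny * self.cell_size)

    def contains_point(self, point: Sequence[float]) -> bool:
        x, y = float(point[0]), float(point[1])
        w, h = self.extent
        return (self.origin[0] <= x <= self.origin[0] + w
                and self.origin[1] <= y <= self.origin[1] + h)

    def value_at(self, grid: np.ndarray, point: Sequence[float]) -> float:
        """Nearest-cell lookup of one property grid at a physical point."""
        x, y = float(point[0]), float(point[1])
        j = int((x - self.origin[0]) / self.cell_size)
        i = int((y - self.origin[1]) / self.cell_size)
        ny, nx = grid.shape
        if not (0 <= i < ny and 0 <= j < nx):
            raise ValueError(f"point {(x, y)} outside map")
        return float(grid[i, j])

    def speed_at(self, point: Sequence[float]) -> float:
        return self.value_at(self.speed_grid, point)


def _coerce_layers(layer_spec: Iterable) -> list[TissueLayer]:
    layers: list[TissueLayer] = []
    for entry in layer_spec:
        if isinstance(entry, TissueLayer):
            layers.append(entry)
        elif isinstance(entry, dict):
            layers.append(TissueLayer(
                name=str(entry["name"]),
                thickness_mm=float(entry["thickness_mm"]),
                speed_mps=float(entry["speed_mps"]),
                density_kgm3=float(entry["density_kgm3"]),
                atten_dbcmmhz=float(entry["atten_dbcmmhz"]),
            ))
        else:
            name, thick, c, rho, att = entry
            layers.append(TissueLayer(str(name), float(thick), float(c),
                                      float(rho), float(att)))
    return layers


def build_layered_phantom(
    layer_spec: Iterable,
    cell_size: float,
    extent: tuple[float, float],
    origin: tuple[float, float] = (0.0, 0.0),
    frequency_mhz: float | None = 1.0,
) -> TissueMap:
    """Rasterize an ordered stack of horizontal layers into a TissueMap.

    Layers are stacked bottom-up from ``origin[1]``; layer boundaries use
    half-open intervals ``[top_of_previous, top_of_this)`` and a cell belongs
    to the layer containing its centre.  Depth beyond the last specified
    boundary is filled with the last layer.

    Parameters
    ----------
    layer_spec
        Ordered iterable of layers; each entry is a :class:`TissueLayer`, a
        mapping with keys ``name, thickness_mm, speed_mps, density_kgm3,
        atten_dbcmmhz``, or a 5-tuple in that order.
    cell_size
        Grid spacing in mm; must satisfy the lambda/8 resolution contract
        when ``frequency_mhz`` is given.
    extent
        (width, height) of the map in mm.
    """
    layers = _coerce_layers(layer_spec)
    if not layers:
        raise ValueError("layer_spec must contain at least one layer")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    for lay in layers:
        if lay.thickness_mm <= 0:
            raise ValueError(f"layer '{lay.name}': thickness must be positive")
        if lay.speed_mps <= 0 or lay.density_kgm3 <= 0:
            raise ValueError(f"layer '{lay.name}': speed and density must be positive")
        if lay.atten_dbcmmhz < 0:
            raise ValueError(f"layer '{lay.name}': attenuation must be non-negative")
    width, height = float(extent[0]), float(extent[1])
    total = sum(lay.thickness_mm for lay in layers)
    if total > height + 1e-9:
        raise ValueError(
            f"layer thicknesses sum to {total} mm > map height {height} mm")

    nx = int(round(width / cell_size))
    ny = int(round(height / cell_size))
    yc = (np.arange(ny) + 0.5) * cell_size  # depth of cell centres above origin
    tops = np.cumsum([lay.thickness_mm for lay in layers])
    # index of the layer owning each row; half-open [bottom, top) intervals,
    # rows beyond the last boundary take the last layer.
    idx = np.searchsorted(tops, yc, side="right")
    idx = np.minimum(idx, len(layers) - 1)

    speeds = np.array([lay.speed_mps for lay in layers])
    dens = np.array([lay.density_kgm3 for lay in layers])
    atts = np.array([lay.atten_dbcmmhz for lay in layers])
    speed = np.repeat(speeds[idx][:, None], nx, axis=1)
    density = np.repeat(dens[idx][:, None], nx, axis=1)
    atten = np.repeat(atts[idx][:, None], nx, axis=1)
    return TissueMap(speed, density, atten, cell_size, origin=origin,
                     layers=tuple(layers), frequency_mhz=frequency_mhz)


def default_phantom(cell_size: float = 0.18,
                    extent: tuple[float, float] = (120.0, 110.0)) -> TissueMap:
    """The default study phantom: water stand-off plus five tissue layers."""
    return build_layered_phantom(DEFAULT_PHANTOM_LAYERS, cell_size, extent)


def save_tissue_map(tissue_map: TissueMap, path) -> None:
    """Persist a phantom raster: channels speed/density/atten + metadata."""
    np.savez(
        path,
        speed=tissue_map.speed_grid,
        density=tissue_map.density_grid,
        atten=tissue_map.atten_grid,
        cell_size_mm=tissue_map.cell_size,
        origin_mm=np.asarray(tissue_map.origin, dtype=float),
        frequency_mhz=np.nan if tissue_map.frequency_mhz is None
        else tissue_map.frequency_mhz,
    )


def load_tissue_map(path) -> TissueMap:
    with np.load(path) as data:
        freq = float(data["frequency_mhz"])
        return TissueMap(
            speed_grid=data["speed"],
            density_grid=data["density"],
            atten_grid=data["atten"],
            cell_size=float(data["cell_size_mm"]),
            origin=tuple(data["origin_mm"]),
            frequency_mhz=None if math.isnan(freq) else freq,
        )


@dataclass(frozen=True)
class ArrayGeometry:
    """A linear phased array of ``n`` circular elements.

    ``centers`` holds the element centres in mm, ordered so element 1 is the
    minimum-lateral-coordinate end after pose rotation; ``normal`` is the
    unit broadside vector (perpendicular to the centre line, pointing into
    the workspace).
    """

    n: int
    element_diameter: float
    gap: float
    centers: np.ndarray        # (n, 2) mm
    pose_angle: float          # degrees
    normal: np.ndarray         # (2,) unit vector
    anchor: np.ndarray         # (2,) mm, rotation centre / array midpoint

    @property
    def pitch(self) -> float:
        return self.element_diameter + self.gap

    @property
    def axis(self) -> np.ndarray:
        """Unit vector along the element line, from element 1 to element n."""
        v = self.centers[-1] - self.centers[0]
        nrm = np.linalg.norm(v)
        if nrm == 0:  # single element: perpendicular to normal
            return np.array([self.normal[1], -self.normal[0]])
        return v / nrm

    @property
    def aperture_span(self) -> float:
        """Distance between the outer edges of the outer elements, mm."""
        return self.n * self.element_diameter + (self.n - 1) * self.gap

    @property
    def element_radius(self) -> float:
        return self.element_diameter / 2.0


def place_array(
    tissue_map: TissueMap,
    n: int,
    element_diameter: float,
    gap: float,
    anchor: Sequence[float],
    pose_angle: float,
) -> ArrayGeometry:
    """Place ``n`` collinear elements centred on ``anchor``, rotated by the
    pose angle (degrees, counter-clockwise from the x-axis)."""
    if n < 1:
        raise ValueError("need at least one element")
    if element_diameter <= 0 or gap < 0:
        raise ValueError("element_diameter must be positive and gap non-negative")
    a = math.radians(pose_angle)
    u = np.array([math.cos(a), math.sin(a)])
    normal = np.array([-math.sin(a), math.cos(a)])
    anchor = np.asarray(anchor, dtype=float)
    pitch = element_diameter + gap
    offsets = (np.arange(n) - (n - 1) / 2.0) * pitch
    centers = anchor[None, :] + offsets[:, None] * u[None, :]
    # element 1 = minimum lateral coordinate end (ties broken by y)
    if (centers[0, 0], centers[0, 1]) > (centers[-1, 0], centers[-1, 1]):
        centers = centers[::-1].copy()
    # footprint check: outer element edges must lie inside the map
    for sgn in (-1.0, 1.0):
        edge = anchor + sgn * (offsets[-1] + element_diameter / 2.0) * u
        if not tissue_map.contains_point(edge):
            raise ValueError(f"array footprint outside map at {tuple(edge)}")
    return ArrayGeometry(n=n, element_diameter=element_diameter, gap=gap,
                         centers=centers, pose_angle=pose_angle,
                         normal=normal, anchor=anchor)


def directivity_ratio(sigma_deg: float, element_radius_e: float,
                      wavelength: float) -> float:
    """Far-field pressure ratio p(r, sigma)/p(r) of a circular piston.

    Evaluates ``2 J1(k e sin sigma) / (k e sin sigma)`` with ``k = 2 pi /
    lambda``; the removable singularity at sigma = 0 returns the limit 1.
    """
    if element_radius_e <= 0 or wavelength <= 0:
        raise ValueError("element radius and wavelength must be positive")
    k = 2 * math.pi / wavelength
    x = k * element_radius_e * math.sin(math.radians(sigma_deg))
    if abs(x) < 1e-12:
        return 1.0
    return float(2.0 * j1(x) / x)


def solve_spread_half_angle(element_radius_e: float, wavelength: float,
                            ratio: float = 0.5) -> float:
    """Half beam-spread angle sigma (degrees) at a given pressure ratio.

    Solves ``2 J1(k e sin sigma)/(k e sin sigma) = ratio`` on (0, first
    null); ratio 0.5 is the -6 dB definition used to bound the workspace.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    k = 2 * math.pi / wavelength
    x_max = min(_J1_FIRST_ZERO, k * element_radius_e)  # sin sigma <= 1
    f = lambda x: 2.0 * j1(x) / x - ratio
    if f(x_max) > 0:
        raise ValueError("requested ratio not reached before the first null; "
                         "element too small for this wavelength")
    x_root = brentq(f, 1e-9, x_max)
    return math.degrees(math.asin(x_root / (k * element_radius_e)))


@dataclass(frozen=True)
class Workspace:
    """The sampling wedge between the two beam-spread boundary rays.

    The rays emanate from the two outer element centres at +/- sigma from
    the array normal; a point is inside iff it lies between the rays and its
    perpendicular distance from the array plane is within ``depth_range``.
    """

    half_angle: float                  # sigma, degrees
    ray_origins: np.ndarray            # (2, 2) outer element centres, mm
    ray_dirs: np.ndarray               # (2, 2) unit direction of l2, l3
    depth_range: tuple[float, float]   # (min, max) mm from array plane
    array: ArrayGeometry

    @property
    def boundary_lines(self) -> tuple[tuple[np.ndarray, np.ndarray], ...]:
        return ((self.ray_origins[0], self.ray_dirs[0]),
                (self.ray_origins[1], self.ray_dirs[1]))

    def contains(self, points) -> np.ndarray | bool:
        """Vectorized membership test; accepts one point or an (m, 2) array."""
        raw = np.asarray(points, dtype=float)
        pts = np.atleast_2d(raw)
        nrm = self.array.normal
        depth = (pts - self.array.anchor) @ nrm
        ok = (depth >= self.depth_range[0] - 1e-9) & (depth <= self.depth_range[1] + 1e-9)
        # l2 at the element-1 end: points must be on the +axis side of it;
        # l3 at the element-n end: points must be on the -axis side.
        axis = self.array.axis
        for origin, direction, sign in (
            (self.ray_origins[0], self.ray_dirs[0], +1.0),
            (self.ray_origins[1], self.ray_dirs[1], -1.0),
        ):
            rel = pts - origin
            cross = direction[0] * rel[:, 1] - direction[1] * rel[:, 0]
            # orient the test so the array axis direction is the inside side
            side = axis[0] * -direction[1] + axis[1] * direction[0]
            ok &= sign * np.sign(side) * cross >= -1e-9
        if raw.ndim == 1:
            return bool(ok[0])
        return ok


def workspace_bounds(array: ArrayGeometry, half_angle_sigma: float,
                     depth_range: tuple[float, float]) -> Workspace:
    """Build the wedge bounded by rays at +/- sigma from the array normal."""
    if not 0 < half_angle_sigma < 90:
        raise ValueError("half angle must lie in (0, 90) degrees")
    if depth_range[0] < 0 or depth_range[1] <= depth_range[0]:
        raise ValueError("depth_range must satisfy 0 <= min < max")
    s = math.radians(half_angle_sigma)
    nrm = array.normal
    axis = array.axis
    # ray at the element-1 end tilts away from the axis, at the element-n
    # end toward +axis, so the wedge opens with depth.
    d_lo = math.cos(s) * nrm - math.sin(s) * axis
    d_hi = math.cos(s) * nrm + math.sin(s) * axis
    origins = np.stack([array.centers[0], array.centers[-1]])
    dirs = np.stack([d_lo, d_hi])
    return Workspace(half_angle=half_angle_sigma, ray_origins=origins,
                     ray_dirs=dirs, depth_range=(float(depth_range[0]),
                                                 float(depth_range[1])),
                     array=array)


@dataclass(frozen=True)
class SamplingPlan:
    """Grid of target positions: columns parallel to the array normal."""

    density: float            # samples per mm (1/d)
    spacing: float            # d, mm
    targets: np.ndarray       # (m, 2) mm, column-major, increasing depth
    grid_index: np.ndarray    # (m, 2) integer (column, row) of each target

    def __len__(self) -> int:
        return len(self.targets)


def plan_samples(ws: Workspace, density: float,
                 column_direction: np.ndarray | None = None) -> SamplingPlan:
    """Lay a rectangular-by-column grid of targets over the workspace.

    Columns run parallel to the array normal (or ``column_direction``),
    spaced ``d = 1/density`` apart both along and across columns, clipped to
    the wedge.  Ordering is deterministic: column-major from the element-1
    side, increasing depth within each column.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    d = 1.0 / density
    arr = ws.array
    col_dir = arr.normal if column_direction is None else (
        np.asarray(column_direction, float) / np.linalg.norm(column_direction))
    lat_dir = arr.axis
    # lateral extent: wedge half-width at max depth, symmetric about anchor
    half_span = (arr.aperture_span / 2.0
                 + ws.depth_range[1] * math.tan(math.radians(ws.half_angle)))
    n_lat = int(math.floor(half_span / d))
    lat_offsets = np.arange(-n_lat, n_lat + 1) * d
    depths = np.arange(ws.depth_range[0],
                       ws.depth_range[1] + 1e-9, d)
    cols, rows = np.meshgrid(np.arange(len(lat_offsets)), np.arange(len(depths)),
                             indexing="ij")
    pts = (arr.anchor[None, :]
           + np.repeat(lat_offsets, len(depths))[:, None] * lat_dir[None, :]
           + np.tile(depths, len(lat_offsets))[:, None] * col_dir[None, :])
    keep = ws.contains(pts)
    targets = pts[keep]
    grid_index = np.stack([cols.ravel()[keep], rows.ravel()[keep]], axis=1)
    if len(targets) == 0:
        warnings.warn("workspace yields an empty sampling plan")
    return SamplingPlan(density=density, spacing=d, targets=targets,
                        grid_index=grid_index)
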