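"""Grid, calendar, tracer state containers and unit conversions.

Everything downstream (ecosystem, transport, diagnostics) operates on the
containers defined here.  Fields use the shape convention ``(nz, nlat, nlon)``
with layer index 0 at the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import xarray as xr

__all__ = [
    "Calendar",
    "Grid",
    "TracerState",
    "TRACER_NAMES",
    "DEFAULT_INTERFACES",
    "make_grid",
    "phosphorus_to_carbon",
    "total_phosphorus",
    "state_to_dataset",
]

#: The five phosphorus pools, in mmol P m^-3.
TRACER_NAMES = ("PO4", "PHY", "ZOO", "DET", "DOP")

#: Default layer interfaces (m).  120 m and 1080 m are exact interfaces,
#: the euphotic zone (above 120 m) spans exactly 2 layers, and spacing is
#: roughly geometric below 120 m.
DEFAULT_INTERFACES = (
    0.0, 50.0, 120.0, 220.0, 360.0, 550.0, 790.0, 1080.0,
    1420.0, 1810.0, 2250.0, 2740.0, 3280.0, 3870.0, 4510.0, 5200.0,
)

EARTH_RADIUS = 6.371e6  # m
CARBON_MOLAR_MASS = 12.011  # g mol^-1
REDFIELD_C_TO_P = 106.0

EXPORT_DEPTH = 120.0  # m, diagnostic export horizon
TRANSFER_DEPTH = 1080.0  # m, diagnostic transfer horizon


@dataclass(frozen=True)
class Calendar:
    """Idealized 360-day model calendar with 12 equal months."""

    year_length: int = 360
    months: int = 12
    dt: float = 0.5  # days per step

    def __post_init__(self) -> None:
        if self.year_length != self.months * 30:
            raise ValueError("calendar requires 12 x 30-day months")
        n = 30.0 / self.dt
        if abs(n - round(n)) > 1e-12 or self.dt <= 0:
            raise ValueError("dt must divide a 30-day month exactly")

    @property
    def month_length(self) -> float:
        return self.year_length / self.months

    @property
    def steps_per_year(self) -> int:
        return int(round(self.year_length / self.dt))

    def month_of(self, t: float) -> int:
        """Month index 0..11 for day-of-year ``t``."""
        return int((t % self.year_length) // self.month_length)


@dataclass
class Grid:
    """Regular latitude-longitude grid with 15 vertical layers.

    ``cell_volume`` is the geometric volume (area x thickness); dry cells are
    excluded through ``wet_mask`` rather than by zeroing volumes.
    """

    lat_centers: np.ndarray  # (nlat,) degrees North
    lon_centers: np.ndarray  # (nlon,) degrees East
    interfaces: np.ndarray   # (nz+1,) m, increasing from 0
    centers: np.ndarray      # (nz,) m
    thickness: np.ndarray    # (nz,) m
    cell_area: np.ndarray    # (nlat, nlon) m^2
    cell_volume: np.ndarray  # (nz, nlat, nlon) m^3
    n_wet: np.ndarray        # (nlat, nlon) wet layers per column
    wet_mask: np.ndarray     # (nz, nlat, nlon) bool
    depth_mask: np.ndarray   # (nlat, nlon) bool, bottom >= 1080 m
    wet_index: np.ndarray = field(init=False)  # (nz, nlat, nlon) int, -1 on dry
    n_cells: int = field(init=False)

    def __post_init__(self) -> None:
        idx = np.full(self.wet_mask.shape, -1, dtype=np.int64)
        idx[self.wet_mask] = np.arange(int(self.wet_mask.sum()))
        self.wet_index = idx
        self.n_cells = int(self.wet_mask.sum())

    # -- shape helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.wet_mask.shape

    @property
    def nz(self) -> int:
        return len(self.centers)

    @property
    def euphotic_layers(self) -> int:
        return int(self.euphotic_mask.sum())

    @property
    def euphotic_mask(self) -> np.ndarray:
        """(nz,) bool, layers wholly above the export depth."""
        return self.interfaces[1:] <= EXPORT_DEPTH + 1e-9

    def interface_index(self, depth: float) -> int:
        k = int(np.argmin(np.abs(self.interfaces - depth)))
        if abs(self.interfaces[k] - depth) > 1e-6:
            raise ValueError(f"{depth} m is not a layer interface")
        return k

    # -- wet-cell vector packing --------------------------------------
    def pack(self, fld: np.ndarray) -> np.ndarray:
        return np.asarray(fld)[self.wet_mask]

    def unpack(self, vec: np.ndarray) -> np.ndarray:
        out = np.zeros(self.shape, dtype=float)
        out[self.wet_mask] = vec
        return out

    @property
    def volume_vector(self) -> np.ndarray:
        return self.cell_volume[self.wet_mask]


def make_grid(
    n_lat: int,
    n_lon: int,
    interfaces=None,
    seafloor=5200.0,
    lat_extent: tuple[float, float] = (-90.0, 90.0),
) -> Grid:
    """Build a regular lat-lon grid with area-weighted cells.

    Parameters
    ----------
    n_lat, n_lon
        Number of latitude bands (even, >= 4) and longitude columns.
    interfaces
        16 strictly increasing layer interfaces starting at 0; must contain
        120 and 1080.  Defaults to :data:`DEFAULT_INTERFACES`.
    seafloor
        Scalar bottom depth (m) or ``(n_lat, n_lon)`` array.  A layer is wet
        when its bottom interface does not exceed the seafloor.
    """
    if n_lat < 4 or n_lat % 2:
        raise ValueError("n_lat must be even and >= 4")
    if n_lon < 1:
        raise ValueError("n_lon must be >= 1")
    ifc = np.asarray(DEFAULT_INTERFACES if interfaces is None else interfaces, dtype=float)
    if len(ifc) != 16:
        raise ValueError("expected 16 layer interfaces (15 layers)")
    if ifc[0] != 0 or np.any(np.diff(ifc) <= 0):
        raise ValueError("interfaces must increase strictly from 0")
    for required in (EXPORT_DEPTH, TRANSFER_DEPTH):
        if not np.any(np.isclose(ifc, required)):
            raise ValueError(f"interfaces must contain the {required:g} m horizon")

    lat_edges = np.linspace(lat_extent[0], lat_extent[1], n_lat + 1)
    lat_centers = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    lon_edges = np.linspace(0.0, 360.0, n_lon + 1)
    lon_centers = 0.5 * (lon_edges[:-1] + lon_edges[1:])

    dlam = np.deg2rad(np.diff(lon_edges))
    band = EARTH_RADIUS**2 * (np.sin(np.deg2rad(lat_edges[1:])) - np.sin(np.deg2rad(lat_edges[:-1])))
    cell_area = band[:, None] * dlam[None, :]

    centers = 0.5 * (ifc[:-1] + ifc[1:])
    thickness = np.diff(ifc)
    cell_volume = thickness[:, None, None] * cell_area[None, :, :]

    floor = np.broadcast_to(np.asarray(seafloor, dtype=float), (n_lat, n_lon))
    n_wet = np.searchsorted(ifc[1:], floor.ravel() + 1e-6, side="right").reshape(n_lat, n_lon)
    layer_idx = np.arange(len(centers))[:, None, None]
    wet_mask = layer_idx < n_wet[None, :, :]
    depth_mask = floor >= TRANSFER_DEPTH - 1e-6

    return Grid(
        lat_centers=lat_centers,
        lon_centers=lon_centers,
        interfaces=ifc,
        centers=centers,
        thickness=thickness,
        cell_area=cell_area,
        cell_volume=cell_volume,
        n_wet=n_wet.astype(np.int64),
        wet_mask=wet_mask,
        depth_mask=depth_mask,
    )


@dataclass
class TracerState:
    """Five tracer fields (mmol P m^-3) plus the model clock (days)."""

    PO4: np.ndarray
    PHY: np.ndarray
    ZOO: np.ndarray
    DET: np.ndarray
    DOP: np.ndarray
    time: float = 0.0

    @classmethod
    def zeros(cls, grid: Grid, time: float = 0.0) -> "TracerState":
        return cls(*(np.zeros(grid.shape) for _ in TRACER_NAMES), time=time)

    def tracers(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in TRACER_NAMES}

    def copy(self) -> "TracerState":
        return replace(self, **{k: v.copy() for k, v in self.tracers().items()})

    def validate(self, grid: Grid) -> None:
        for name, fld in self.tracers().items():
            wet = fld[grid.wet_mask]
            if np.any(~np.isfinite(wet)):
                raise ValueError(f"non-finite values in {name}")
            if np.any(wet < 0):
                raise ValueError(f"negative values in {name}")


def phosphorus_to_carbon(x):
    """Convert mmol P to g C using C:P = 106:1 (Redfield)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("phosphorus amount must be >= 0")
    out = x * REDFIELD_C_TO_P * CARBON_MOLAR_MASS * 1e-3
    return out if out.ndim else float(out)


def total_phosphorus(state: TracerState, grid: Grid) -> float:
    """Volume-weighted phosphorus inventory (mmol P) over all wet cells."""
    vol = grid.cell_volume
    wet = grid.wet_mask
    return float(sum(np.sum(fld[wet] * vol[wet]) for fld in state.tracers().values()))


def state_to_dataset(state: TracerState, grid: Grid) -> xr.Dataset:
    """CF-flavoured Dataset view of a state (NaN on dry cells)."""
    coords = {
        "depth": ("depth", grid.centers, {"units": "m", "positive": "down"}),
        "lat": ("lat", grid.lat_centers, {"units": "degrees_north"}),
        "lon": ("lon", grid.lon_centers, {"units": "degrees_east"}),
    }
    data = {}
    for name, fld in state.tracers().items():
        arr = np.where(grid.wet_mask, fld, np.nan)
        data[name] = (("depth", "lat", "lon"), arr, {"units": "mmol P m-3"})
    ds = xr.Dataset(data, coords=coords)
    ds.attrs["time_days"] = state.time
    return ds
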