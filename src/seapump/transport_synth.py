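"""Synthetic monthly transport operators.

Stand-in for offline transport-matrix circulation: 12 monthly sparse,
non-negative, mass-conserving operators over the wet cells of a grid.

Schemes
-------
``off``
    12 identity operators (the no-circulation limit).
``mixing_only``
    Seasonal vertical mixing over a latitude- and month-dependent mixed
    layer (deep in local winter, shallow in summer), plus a weak background
    vertical diffusivity connecting the whole column.
``overturning``
    ``mixing_only`` plus a prescribed meridional overturning loop per
    hemisphere (poleward at the surface, downwelling at high latitude,
    equatorward at depth, upwelling at low latitude), discretized upwind.

Each operator ``M`` satisfies, to machine precision, ``M 1 = 1`` (uniform
fields are untouched) and ``V^T M = V^T`` (volume-weighted mass is
conserved), with all entries non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .model_core import Grid, TracerState, TRACER_NAMES

__all__ = [
    "TransportOperator",
    "build_transport",
    "apply_transport",
    "write_transport_matrices",
    "read_transport_matrices",
    "validate_operator",
    "TransportFormatError",
]

_SCHEMES = ("off", "mixing_only", "overturning")


class TransportFormatError(ValueError):
    """Raised when an on-disk transport file is malformed."""


@dataclass
class TransportOperator:
    """One monthly redistribution operator over the wet-cell vector."""

    month: int                 # 1..12
    matrix: sp.csr_matrix      # (n_cells, n_cells)
    dt_matrix: float           # days the operator represents
    n_cells: int
    rate: sp.csr_matrix = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.rate = ((self.matrix - sp.identity(self.n_cells, format="csr"))
                     / self.dt_matrix).tocsr()


def validate_operator(op: TransportOperator, grid: Grid, tol: float = 1e-12) -> None:
    """Check non-negativity, uniform-field invariance and mass conservation."""
    m = op.matrix
    if m.shape != (grid.n_cells, grid.n_cells):
        raise ValueError("operator size does not match grid wet cells")
    if m.nnz and m.data.min() < -tol:
        raise ValueError("transport operator has negative entries")
    ones = np.ones(grid.n_cells)
    if np.max(np.abs(m @ ones - ones)) > 1e-10:
        raise ValueError("operator does not preserve uniform fields")
    vol = grid.volume_vector
    colsum = m.T @ vol
    if np.max(np.abs(colsum - vol) / vol) > 1e-10:
        raise ValueError("operator does not conserve volume-weighted mass")


def _mixed_layer_depth(lat: float, month: int, mld_min: float, mld_max: float) -> float:
    """Sinusoidal mixed-layer depth, deepest in local winter.

    Month centers sit at day (month + 0.5) * 30; Northern-Hemisphere winter
    is centered on day 0.  Amplitude scales linearly with |lat|/90 so the
    equator keeps a thin, steady mixed layer.
    """
    t_mid = (month + 0.5) * 30.0
    season = np.cos(2.0 * np.pi * t_mid / 360.0)
    if lat < 0:
        season = -season
    frac = 0.5 * (1.0 + season) * min(abs(lat) / 90.0, 1.0)
    return mld_min + (mld_max - mld_min) * frac


def _column_cells(grid: Grid, j: int, i: int) -> np.ndarray:
    return grid.wet_index[: grid.n_wet[j, i], j, i]


def _mixing_entries(grid: Grid, month: int, mld_min, mld_max, mixing_rate,
                    kv_background, dt_m):
    """COO triplets for mixing within the mixed layer + background diffusion."""
    rows, cols, vals = [], [], []
    diag = np.ones(grid.n_cells)
    vol = grid.volume_vector
    for j, lat in enumerate(grid.lat_centers):
        mld = _mixed_layer_depth(lat, month, mld_min, mld_max)
        for i in range(len(grid.lon_centers)):
            cells = _column_cells(grid, j, i)
            if len(cells) == 0:
                continue
            in_ml = cells[grid.centers[: len(cells)] <= mld]
            if len(in_ml) >= 2:
                v = vol[in_ml]
                vtot = v.sum()
                r = mixing_rate * dt_m
                for k in in_ml:
                    diag[k] -= r
                    rows.extend([k] * len(in_ml))
                    cols.extend(in_ml)
                    vals.extend(r * v / vtot)
            if kv_background > 0 and len(cells) >= 2:
                area = grid.cell_area[j, i]
                for p in range(len(cells) - 1):
                    upper, lower = cells[p], cells[p + 1]
                    dz_between = grid.centers[p + 1] - grid.centers[p]
                    q = kv_background / dz_between * area * dt_m  # m^3 per dt
                    for src, dst in ((upper, lower), (lower, upper)):
                        rows.append(dst)
                        cols.append(src)
                        vals.append(q / vol[dst])
                        diag[src] -= q / vol[src]
    return rows, cols, vals, diag


def _ring_path(grid: Grid, j_eq: int, j_pole: int, k_deep: int, i: int):
    """Closed cell loop in the (lat, depth) plane at longitude column ``i``."""
    step = 1 if j_pole > j_eq else -1
    path = [(0, j, i) for j in range(j_eq, j_pole + step, step)]
    path += [(k, j_pole, i) for k in range(1, k_deep + 1)]
    path += [(k_deep, j, i) for j in range(j_pole - step, j_eq - step, -step)]
    path += [(k, j_eq, i) for k in range(k_deep - 1, 0, -1)]
    return path


def _overturning_entries(grid: Grid, transport_fraction, k_deep, dt_m):
    """COO triplets for the meridional overturning rings (both hemispheres)."""
    rows, cols, vals = [], [], []
    diag = np.zeros(grid.n_cells)
    vol = grid.volume_vector
    nlat = len(grid.lat_centers)
    for i in range(len(grid.lon_centers)):
        for j_eq, j_pole in ((nlat // 2, nlat - 1), (nlat // 2 - 1, 0)):
            path = _ring_path(grid, j_eq, j_pole, k_deep, i)
            cells = []
            ok = True
            for (k, j, ii) in path:
                if k >= grid.n_wet[j, ii]:
                    ok = False
                    break
                cells.append(grid.wet_index[k, j, ii])
            if not ok or len(cells) < 2:
                continue
            q = transport_fraction * vol[cells].min() / dt_m  # m^3 day^-1
            for src, dst in zip(cells, cells[1:] + cells[:1]):
                rows.append(dst)
                cols.append(src)
                vals.append(q * dt_m / vol[dst])
                diag[src] -= q * dt_m / vol[src]
    return rows, cols, vals, diag


def build_transport(scheme: str, grid: Grid, *, mld_min: float = 50.0,
                    mld_max: float = 300.0, mixing_rate: float = 0.2,
                    kv_background: float = 5.0, transport_fraction: float = 0.02,
                    k_deep: int = 9, dt_matrix: float = 1.0,
                    validate: bool = True) -> list[TransportOperator]:
    """Build the 12 monthly operators for one of the synthetic schemes.

    ``mixing_rate`` is the homogenization rate (day^-1) toward the
    volume-weighted mixed-layer mean; ``kv_background`` a weak vertical
    diffusivity (m^2 day^-1); ``transport_fraction`` the fraction of the
    smallest ring-cell volume exchanged per ``dt_matrix`` by the
    overturning loop, which descends to layer index ``k_deep``.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown transport scheme {scheme!r}; choose from {_SCHEMES}")
    n = grid.n_cells
    ops = []
    for month in range(12):
        if scheme == "off":
            mat = sp.identity(n, format="csr")
        else:
            rows, cols, vals, diag = _mixing_entries(
                grid, month, mld_min, mld_max, mixing_rate, kv_background, dt_matrix)
            if scheme == "overturning":
                r2, c2, v2, d2 = _overturning_entries(
                    grid, transport_fraction, k_deep, dt_matrix)
                rows += r2
                cols += c2
                vals += v2
                diag = diag + d2
            if np.any(diag < 0):
                raise ValueError(
                    "transport too strong for dt_matrix: operator would go negative")
            rows += list(range(n))
            cols += list(range(n))
            vals += list(diag)
            mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        op = TransportOperator(month=month + 1, matrix=mat, dt_matrix=dt_matrix,
                               n_cells=n)
        if validate:
            validate_operator(op, grid)
        ops.append(op)
    return ops


def apply_transport(state: TracerState, op: TransportOperator,
                    grid: Grid) -> TracerState:
    """Apply one full operator to every tracer independently."""
    if op.n_cells != grid.n_cells:
        raise ValueError("operator was built for a different grid")
    new = state.copy()
    for name in TRACER_NAMES:
        vec = grid.pack(getattr(state, name))
        setattr(new, name, grid.unpack(op.matrix @ vec))
    return new


# ----------------------------------------------------------------------
# On-disk format: plain text, one header line, then 12 month blocks of
# coordinate triplets printed with full double precision (%.17g), so a
# write -> read round trip is bit-exact.
# ----------------------------------------------------------------------

_MAGIC = "seapump-transport v1"


def write_transport_matrices(path, ops: list[TransportOperator]) -> None:
    if len(ops) != 12:
        raise ValueError("expected 12 monthly operators")
    with open(path, "w") as fh:
        fh.write(f"# {_MAGIC}\n")
        fh.write(f"n_cells {ops[0].n_cells}\n")
        for op in ops:
            coo = op.matrix.tocoo()
            fh.write(f"month {op.month} nnz {coo.nnz} dt_matrix {op.dt_matrix!r}\n")
            for i, j, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{i} {j} {v:.17g}\n")


def read_transport_matrices(path, grid: Grid | None = None) -> list[TransportOperator]:
    """Load 12 operators; validates the conservation contract when a grid
    is supplied.  Malformed input raises :class:`TransportFormatError`
    naming the offending line."""
    ops = []
    with open(path) as fh:
        lines = fh.readlines()

    def fail(lineno, msg):
        raise TransportFormatError(f"{path}:{lineno + 1}: {msg}")

    if not lines or lines[0].strip() != f"# {_MAGIC}":
        fail(0, "missing format header")
    head = lines[1].split()
    if len(head) != 2 or head[0] != "n_cells":
        fail(1, "expected 'n_cells <int>'")
    n = int(head[1])
    pos = 2
    for _ in range(12):
        if pos >= len(lines):
            fail(len(lines) - 1, "truncated file: expected 12 month blocks")
        hdr = lines[pos].split()
        if len(hdr) != 6 or hdr[0] != "month" or hdr[2] != "nnz" or hdr[4] != "dt_matrix":
            fail(pos, "malformed month header")
        month, nnz, dt_m = int(hdr[1]), int(hdr[3]), float(hdr[5])
        if pos + 1 + nnz > len(lines):
            fail(len(lines) - 1, f"truncated file inside month {month} block")
        rows = np.empty(nnz, dtype=np.int64)
        cols = np.empty(nnz, dtype=np.int64)
        vals = np.empty(nnz)
        for k in range(nnz):
            parts = lines[pos + 1 + k].split()
            if len(parts) != 3:
                fail(pos + 1 + k, "expected 'row col value'")
            try:
                rows[k], cols[k], vals[k] = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError:
                fail(pos + 1 + k, "unparsable triplet")
        if rows.size and (rows.max() >= n or cols.max() >= n):
            fail(pos, f"index out of range for n_cells={n}")
        mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        op = TransportOperator(month=month, matrix=mat, dt_matrix=dt_m, n_cells=n)
        if grid is not None:
            try:
                validate_operator(op, grid)
            except ValueError as exc:
                raise TransportFormatError(
                    f"{path}: month {month} violates operator contract: {exc}") from exc
        ops.append(op)
        pos += 1 + nnz
    return ops
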