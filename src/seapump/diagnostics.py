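"""Annual diagnostics: transfer efficiency, global budgets, emergent-b fits,
layer-wise fractional transfer and run comparisons.

All global quantities are evaluated over columns whose seafloor reaches at
least 1080 m (the ``depth_mask``), which excludes shelves that would bias
the export-to-transfer comparison.  Carbon conversions use C:P = 106:1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attenuation import martin_te
from .integrate import AnnualCycleOutput
from .model_core import Grid, phosphorus_to_carbon

__all__ = ["FluxProfile", "AnnualDiagnostics", "te_local", "global_metrics",
           "fit_emergent_b", "fractional_transfer", "compare_runs",
           "global_flux_profile"]

#: TE is masked where annual F120 falls below this times its global mean.
TE_FLOOR_FRACTION = 1e-12


@dataclass
class FluxProfile:
    """Annual-mean flux versus interface depth at one location (or global)."""

    depths: np.ndarray          # (n,) m, increasing
    flux: np.ndarray            # (n,) mmol P m^-2 yr^-1
    location: object = "global"

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.flux = np.asarray(self.flux, dtype=float)
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must increase strictly")
        if np.any(self.flux < 0):
            raise ValueError("fluxes must be >= 0")

    @property
    def flux_gc(self) -> np.ndarray:
        """Carbon twin of the flux profile (g C m^-2 yr^-1)."""
        return phosphorus_to_carbon(self.flux)


@dataclass
class AnnualDiagnostics:
    pp_global: float            # Pg C yr^-1
    f120: float                 # Pg C yr^-1
    f1080: float                # Pg C yr^-1
    te_global: float
    te_map: np.ndarray          # (nlat, nlon), NaN where masked
    emergent_b_global: float
    emergent_b_residual: float
    fractional_transfer: pd.DataFrame  # per layer pair k = 3..14
    extras: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {"PP_global": self.pp_global, "F120": self.f120,
                "F1080": self.f1080, "TE_global": self.te_global,
                "emergent_b": self.emergent_b_global}


def te_local(f120: np.ndarray, f1080: np.ndarray) -> np.ndarray:
    """Elementwise annual transfer efficiency; NaN where export vanishes."""
    f120 = np.asarray(f120, dtype=float)
    f1080 = np.asarray(f1080, dtype=float)
    if f120.shape != f1080.shape:
        raise ValueError("flux maps must share a grid")
    floor = TE_FLOOR_FRACTION * max(float(np.nanmean(f120)), 1e-300)
    valid = f120 > floor
    out = np.full(f120.shape, np.nan)
    out[valid] = f1080[valid] / f120[valid]
    return out


def fit_emergent_b(profile: FluxProfile, z0: float = 120.0, z1: float = 1080.0):
    """Log-log least-squares attenuation exponent over ``[z0, z1]``.

    Returns ``(b, residual)`` where ``b`` is the negated slope of
    ``ln F`` against ``ln z`` (unweighted) and ``residual`` the RMS misfit
    of the regression in log space.  Non-positive fluxes inside the range
    are dropped; at least 3 usable interfaces are required.
    """
    sel = (profile.depths >= z0 - 1e-9) & (profile.depths <= z1 + 1e-9)
    z = profile.depths[sel]
    f = profile.flux[sel]
    good = f > 0
    if good.sum() < 3:
        raise ValueError("need >= 3 interfaces with positive flux in range")
    lz, lf = np.log(z[good]), np.log(f[good])
    coeffs, res = np.polyfit(lz, lf, 1), None
    pred = np.polyval(coeffs, lz)
    res = float(np.sqrt(np.mean((lf - pred) ** 2)))
    return float(-coeffs[0]), res


def fractional_transfer(profile: FluxProfile, b_model: float,
                        first_layer: int = 3, last_layer: int = 14) -> pd.DataFrame:
    """Diagnosed versus expected flux ratio between adjacent layers.

    For layer ``k`` the diagnosed ratio is the flux entering layer ``k``
    over the flux entering layer ``k - 1``; the expectation is the
    power-law ratio ``(z_k / z_{k-1})^-b`` of the same interface depths.
    ``profile`` must carry the fluxes at all interfaces involved
    (interfaces indexed from the surface, layer ``k`` is entered through
    interface ``k - 1``).  Zero-flux denominators yield NaN.
    """
    rows = []
    z = profile.depths
    f = profile.flux
    for k in range(first_layer, last_layer + 1):
        top_prev, top_this = k - 2, k - 1
        if top_this >= len(z):
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            diag = f[top_this] / f[top_prev] if f[top_prev] > 0 else np.nan
        expected = (z[top_this] / z[top_prev]) ** (-b_model) if z[top_prev] > 0 else np.nan
        rows.append({"layer": k, "z_upper": z[top_prev], "z_lower": z[top_this],
                     "diagnosed": diag, "expected": expected})
    return pd.DataFrame(rows)


def _annual_maps(output: AnnualCycleOutput):
    """Annual-mean F120/F1080 maps (mmol P m^-2 day^-1) and PP field."""
    f120 = output.monthly_f120.mean(axis=0)
    f1080 = output.monthly_f1080.mean(axis=0)
    pp = output.monthly_pp.mean(axis=0)
    iface = output.monthly_iface_flux.mean(axis=0)
    return f120, f1080, pp, iface


def global_flux_profile(output: AnnualCycleOutput) -> FluxProfile:
    """Area-weighted global annual-mean flux at every interface
    (mmol P m^-2 yr^-1), over deep-enough columns only."""
    grid = output.grid
    _, _, _, iface = _annual_maps(output)
    mask = grid.depth_mask
    area = grid.cell_area[mask]
    flux = np.array([np.sum(iface[k][mask] * area) / area.sum()
                     for k in range(len(grid.interfaces))])
    year = output.config.calendar.year_length
    # skip the zero-depth surface interface (log fits need z > 0)
    return FluxProfile(depths=grid.interfaces[1:], flux=flux[1:] * year,
                       location="global")


_PG_PER_MMOL_P = phosphorus_to_carbon(1.0) * 1e-15  # Pg C per mmol P


def global_metrics(output: AnnualCycleOutput, grid: Grid | None = None) -> AnnualDiagnostics:
    """The annual diagnostic suite for one converged run."""
    grid = grid or output.grid
    f120, f1080, pp, _ = _annual_maps(output)
    mask = grid.depth_mask
    area = grid.cell_area
    year = output.config.calendar.year_length

    f120_tot = float(np.sum(f120[mask] * area[mask])) * year * _PG_PER_MMOL_P
    f1080_tot = float(np.sum(f1080[mask] * area[mask])) * year * _PG_PER_MMOL_P
    colmask = mask[None, :, :] & grid.wet_mask
    pp_tot = float(np.sum((pp * grid.cell_volume)[colmask])) * year * _PG_PER_MMOL_P
    te_g = f1080_tot / f120_tot if f120_tot > 0 else np.nan

    te_map = te_local(f120, f1080)
    te_map[~mask] = np.nan

    profile = global_flux_profile(output)
    b_fit, resid = fit_emergent_b(profile)
    frac = fractional_transfer(profile, output.config.attenuation.b_ref)
    return AnnualDiagnostics(
        pp_global=pp_tot, f120=f120_tot, f1080=f1080_tot, te_global=te_g,
        te_map=te_map, emergent_b_global=b_fit, emergent_b_residual=resid,
        fractional_transfer=frac,
        extras={"converged": output.converged, "n_years": output.n_years,
                "martin_te_bref": martin_te(output.config.attenuation.b_ref)},
    )


def percent_change(a: float, b: float) -> float:
    """Percent change from ``a`` to ``b``."""
    return 100.0 * (b - a) / a


def compare_runs(diag_a: AnnualDiagnostics, diag_b: AnnualDiagnostics) -> pd.DataFrame:
    """Absolute values and percent changes of the headline scalars (a -> b),
    plus a TE-map percent-change field stashed in the ``pct_te_map`` attr."""
    if diag_a.te_map.shape != diag_b.te_map.shape:
        raise ValueError("runs use different grids")
    rows = []
    for key, va in diag_a.as_row().items():
        vb = diag_b.as_row()[key]
        rows.append({"metric": key, "a": va, "b": vb,
                     "pct_change": percent_change(va, vb)})
    table = pd.DataFrame(rows).set_index("metric")
    with np.errstate(divide="ignore", invalid="ignore"):
        table.attrs["pct_te_map"] = 100.0 * (diag_b.te_map - diag_a.te_map) / diag_a.te_map
    return table
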