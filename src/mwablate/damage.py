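"""Arrhenius thermal damage integral and ablation-zone morphology.

Thermal injury is modelled as a first-order rate process: the damage
integral alpha accumulates at rate A*exp(-dE/(R*T(t))) along each node's
temperature history, and the necrotic (destroyed-cell) fraction is
theta_d = 1 - exp(-alpha).  The contour theta_d = 1 - 1/e (alpha = 1) is
the conventional ablation-zone boundary.

The default kinetic parameters (A = 7.39e39 1/s, dE = 2.577e5 J/mol) are
the standard hepatic-tissue coagulation values widely reused in
interstitial ablation modelling; lung-specific kinetics remain an open
literature question, so both parameters are plainly overridable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import R as R_GAS

from .bioheat import TemperatureHistory
from .geometry import AxisymGrid

__all__ = [
    "ArrheniusParams",
    "DamageField",
    "damage_rate",
    "integrate_arrhenius",
    "necrotic_fraction_curve",
    "time_to_threshold",
    "zone_morphology",
]

#: theta_d at alpha = 1, the conventional ablation-zone threshold.
DEFAULT_ZONE_THRESHOLD = 1.0 - np.exp(-1.0)


@dataclass(frozen=True)
class ArrheniusParams:
    """First-order damage kinetics: rate = A * exp(-delta_E / (R T))."""

    A: float = 7.39e39  # frequency factor, 1/s
    delta_E: float = 2.577e5  # activation energy, J/mol
    R_gas: float = R_GAS  # 8.314462618 J/(mol K)

    def __post_init__(self) -> None:
        if self.A <= 0 or self.delta_E <= 0:
            raise ValueError("A and delta_E must be > 0")


def damage_rate(T, params: ArrheniusParams):
    """Damage accumulation rate (1/s) at absolute temperature ``T`` (K).

    Evaluated in log space, ``exp(ln A - dE/(R T))``, so the enormous
    frequency factor never overflows.
    """
    T = np.asarray(T, dtype=float)
    out = np.zeros_like(T)
    ok = np.isfinite(T)
    if np.any(T[ok] <= 0):
        raise ValueError("temperatures must be positive (kelvin)")
    out[ok] = np.exp(
        np.log(params.A) - params.delta_E / (params.R_gas * T[ok])
    )
    return out


@dataclass
class DamageField:
    """Nodal damage integral, necrotic fraction and zone morphology."""

    alpha: np.ndarray  # dimensionless, >= 0
    theta_d: np.ndarray  # in [0, 1], = 1 - exp(-alpha)
    zone_area: float = 0.0  # (r,z)-plane area of theta_d >= threshold, m^2
    zone_volume: float = 0.0  # revolved volume, m^3
    axial_extent: float = 0.0  # m
    radial_extent: float = 0.0  # m
    aspect_ratio: float = 0.0  # axial / radial


def integrate_arrhenius(
    history: TemperatureHistory, params: ArrheniusParams = ArrheniusParams()
) -> DamageField:
    """Trapezoidal integration of the damage rate over the stored history.

    Nodes outside the thermal domain (NaN in the snapshots) get alpha = 0.
    """
    if len(history.times) == 0:
        raise ValueError("empty temperature history")
    rates = np.array([damage_rate(f, params) for f in history.fields])
    alpha = np.trapezoid(rates, history.times, axis=0)
    alpha = np.where(np.isfinite(history.fields[-1]), alpha, 0.0)
    assert np.all(alpha >= 0.0)
    theta = -np.expm1(-alpha)
    return DamageField(alpha=alpha, theta_d=theta)


def necrotic_fraction_curve(
    history: TemperatureHistory,
    params: ArrheniusParams = ArrheniusParams(),
    probe=None,
) -> np.ndarray:
    """Necrotic fraction versus time at a probe point, shape (nt, 2).

    Uses the per-step probe trace when available (time resolution dt),
    otherwise falls back to the stored snapshots at the node nearest to
    ``probe`` = (r, z); ``probe=None`` uses the spatial-peak trace, an
    upper envelope of the pointwise damage.
    """
    if probe is not None and probe in history.probe_traces:
        t = history.peak_times
        T = history.probe_traces[probe]
    elif probe is None:
        t = history.peak_times
        T = history.peak_trace
    else:
        raise KeyError(
            f"no stored trace for probe {probe}; pass it to run_transient(probes=...)"
        )
    rate = damage_rate(T, params)
    alpha = np.concatenate(
        [[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(t))]
    )
    theta = -np.expm1(-alpha)
    return np.column_stack([t, theta])


def time_to_threshold(curve: np.ndarray, level: float = 0.99) -> float:
    """First time the necrotic-fraction curve reaches ``level`` (NaN if never).

    The crossing is interpolated linearly between samples.
    """
    t, theta = curve[:, 0], curve[:, 1]
    idx = np.nonzero(theta >= level)[0]
    if len(idx) == 0:
        return float("nan")
    i = int(idx[0])
    if i == 0:
        return float(t[0])
    f = (level - theta[i - 1]) / (theta[i] - theta[i - 1])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


def _extent_with_interpolation(coords, values, threshold):
    """Max coordinate of the threshold crossing along a sampled line."""
    above = values >= threshold
    if not np.any(above):
        return None
    last = int(np.nonzero(above)[0][-1])
    if last == len(values) - 1 or not np.isfinite(values[last + 1]):
        return coords[last]
    # linear interpolation between the last above-threshold node and the next
    v0, v1 = values[last], values[last + 1]
    f = (v0 - threshold) / (v0 - v1) if v0 > v1 else 0.0
    return coords[last] + f * (coords[last + 1] - coords[last])


def zone_morphology(
    field: DamageField,
    grid: AxisymGrid,
    threshold: float = DEFAULT_ZONE_THRESHOLD,
) -> tuple[float, float, float, float]:
    """Measure the ablation zone ``theta_d >= threshold``.

    Returns (zone_area, axial_extent, radial_extent, aspect_ratio) and also
    stores them (plus the revolved volume) on ``field``.  The area is the
    (r, z)-plane region area; extents are threshold-contour crossings found
    by linear interpolation along grid lines, so they resolve below the
    cell size.  An empty zone yields zeros.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    theta = np.nan_to_num(field.theta_d, nan=0.0)
    mask = theta >= threshold
    if not np.any(mask):
        field.zone_area = field.zone_volume = 0.0
        field.axial_extent = field.radial_extent = field.aspect_ratio = 0.0
        return (0.0, 0.0, 0.0, 0.0)

    r, z = grid.r_coords, grid.z_coords
    # radial extent: farthest threshold crossing over all axial lines
    radial = 0.0
    for j in range(len(z)):
        e = _extent_with_interpolation(r, theta[:, j], threshold)
        if e is not None:
            radial = max(radial, float(e))
    # axial extent: span of the zone along the axis direction
    z_lo, z_hi = np.inf, -np.inf
    for i in range(len(r)):
        col = theta[i, :]
        if not np.any(col >= threshold):
            continue
        hi = _extent_with_interpolation(z, col, threshold)
        lo = _extent_with_interpolation(-z[::-1], col[::-1], threshold)  # mirrored
        z_hi = max(z_hi, float(hi))
        z_lo = min(z_lo, float(-lo))
    axial = float(z_hi - z_lo)

    # area / revolved volume by corner counting (quarter-cell resolution)
    corners = (
        mask[:-1, :-1].astype(int)
        + mask[1:, :-1]
        + mask[:-1, 1:]
        + mask[1:, 1:]
    )
    frac = corners / 4.0
    area = float(np.sum(frac * grid.cell_areas()))
    volume = float(np.sum(frac * grid.revolved_cell_volumes()))

    aspect = axial / radial if radial > 0 else 0.0
    field.zone_area = area
    field.zone_volume = volume
    field.axial_extent = axial
    field.radial_extent = radial
    field.aspect_ratio = aspect
    return (area, axial, radial, aspect)
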