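"""Axisymmetric antenna/tissue geometry and structured grid generation.

The device is a thin interstitial coaxial antenna: inner conductor, PTFE
coax dielectric, outer conductor with a ring-shaped radiating slot, all
enclosed in a plastic catheter and short-circuited at the tip by a metal
cap.  The antenna is inserted along the symmetry axis of a cylindrical
tissue domain, so the problem is posed in (r, z) with z increasing from the
domain bottom (tissue below the antenna tip) toward the feed cable.

All lengths are SI metres internally; the reference dimensions follow the
thin monopole-slot design customary in interstitial microwave ablation
modelling (inner conductor radius 0.135 mm, dielectric 0.470 mm, outer
conductor 0.595 mm, catheter 0.895 mm, 1 mm slot centred 5.5 mm above the
short-circuited tip).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "Region",
    "AntennaGeometry",
    "DomainGeometry",
    "AxisymGrid",
    "build_default_geometry",
    "generate_grid",
    "geometry_to_config",
    "geometry_from_config",
    "save_geometry",
    "load_geometry",
]

MM = 1e-3


class Region(IntEnum):
    """Cell material labels on the axisymmetric grid."""

    TISSUE = 0
    COAX_DIELECTRIC = 1
    CATHETER = 2
    CONDUCTOR = 3
    SLOT = 4


@dataclass(frozen=True)
class AntennaGeometry:
    """Coaxial slot antenna cross-section (all radii/lengths in metres).

    ``tip_z`` is the axial position of the antenna tip in the domain frame;
    ``slot_center_offset`` is measured upward from the tip.  ``cap_length``
    is the thickness of the metal short closing the coax at the tip.
    """

    r_inner_conductor: float = 0.135 * MM
    r_dielectric: float = 0.470 * MM
    r_outer_conductor: float = 0.595 * MM
    r_catheter: float = 0.895 * MM
    slot_center_offset: float = 5.5 * MM
    slot_width: float = 1.0 * MM
    tip_z: float = 34.5 * MM
    cap_length: float = 0.5 * MM
    # the hygienic catheter is a closed sheath: its wall also covers the tip
    catheter_tip_cover: float = 0.3 * MM

    def __post_init__(self) -> None:
        r = (
            self.r_inner_conductor,
            self.r_dielectric,
            self.r_outer_conductor,
            self.r_catheter,
        )
        if not (0 < r[0] < r[1] < r[2] < r[3]):
            raise ValueError(f"antenna radii must be strictly nested, got {r}")
        if self.slot_width <= 0:
            raise ValueError("slot_width must be > 0")
        if self.cap_length < 0:
            raise ValueError("cap_length must be >= 0")
        if self.slot_center_offset - self.slot_width / 2 <= self.cap_length:
            raise ValueError("slot must lie above the tip cap")

    @property
    def slot_center_z(self) -> float:
        return self.tip_z + self.slot_center_offset

    @property
    def slot_z_range(self) -> tuple[float, float]:
        c = self.slot_center_z
        return (c - self.slot_width / 2, c + self.slot_width / 2)


@dataclass(frozen=True)
class DomainGeometry:
    """Cylindrical computational domain containing the antenna."""

    r_max: float = 30.0 * MM
    z_min: float = 0.0
    z_max: float = 80.0 * MM
    antenna: AntennaGeometry = field(default_factory=AntennaGeometry)

    def __post_init__(self) -> None:
        a = self.antenna
        if self.r_max < 10 * a.r_catheter:
            raise ValueError("r_max must be at least 10x the catheter radius")
        if not self.z_min < a.tip_z < self.z_max:
            raise ValueError("antenna tip must lie inside the domain")
        if a.slot_z_range[1] >= self.z_max:
            raise ValueError("slot must lie inside the domain")

    # -- material classification ----------------------------------------
    def interface_radii(self) -> np.ndarray:
        a = self.antenna
        return np.array(
            [
                a.r_inner_conductor,
                a.r_dielectric,
                a.r_outer_conductor,
                a.r_catheter,
            ]
        )

    def interface_heights(self) -> np.ndarray:
        a = self.antenna
        slot_lo, slot_hi = a.slot_z_range
        return np.array(
            [a.tip_z - a.catheter_tip_cover, a.tip_z, a.tip_z + a.cap_length, slot_lo, slot_hi]
        )

    def classify(self, r, z):
        """Material label at points (r, z); vectorized, returns int array."""
        a = self.antenna
        r = np.asarray(r, dtype=float)
        z = np.asarray(z, dtype=float)
        out = np.full(np.broadcast(r, z).shape, Region.TISSUE, dtype=np.int8)
        slot_lo, slot_hi = a.slot_z_range

        in_antenna_z = z >= a.tip_z
        in_cap_z = in_antenna_z & (z < a.tip_z + a.cap_length)
        above_cap = z >= a.tip_z + a.cap_length

        # closed catheter: side sleeve plus the sealed tip cover below the cap
        out[in_antenna_z & (r >= a.r_outer_conductor) & (r < a.r_catheter)] = (
            Region.CATHETER
        )
        out[
            (z >= a.tip_z - a.catheter_tip_cover)
            & (z < a.tip_z)
            & (r < a.r_catheter)
        ] = Region.CATHETER
        # metal short at the tip
        out[in_cap_z & (r < a.r_outer_conductor)] = Region.CONDUCTOR
        # coax cross-section above the cap
        out[above_cap & (r < a.r_inner_conductor)] = Region.CONDUCTOR
        out[above_cap & (r >= a.r_inner_conductor) & (r < a.r_dielectric)] = (
            Region.COAX_DIELECTRIC
        )
        outer = above_cap & (r >= a.r_dielectric) & (r < a.r_outer_conductor)
        in_slot_z = (z >= slot_lo) & (z < slot_hi)
        out[outer & ~in_slot_z] = Region.CONDUCTOR
        out[outer & in_slot_z] = Region.SLOT
        return out

    def revolved_region_volumes(self) -> dict:
        """Exact revolved volume (m^3) of each material region."""
        a = self.antenna

        def ann(r0, r1, z0, z1):
            return np.pi * (r1**2 - r0**2) * (z1 - z0)

        L = self.z_max - (a.tip_z + a.cap_length)  # coax length above cap
        slot_lo, slot_hi = a.slot_z_range
        vol = {}
        vol[Region.CATHETER] = ann(
            a.r_outer_conductor, a.r_catheter, a.tip_z, self.z_max
        ) + ann(0, a.r_catheter, a.tip_z - a.catheter_tip_cover, a.tip_z)
        vol[Region.COAX_DIELECTRIC] = ann(
            a.r_inner_conductor, a.r_dielectric, a.tip_z + a.cap_length, self.z_max
        )
        vol[Region.SLOT] = ann(a.r_dielectric, a.r_outer_conductor, slot_lo, slot_hi)
        vol[Region.CONDUCTOR] = (
            ann(0, a.r_outer_conductor, a.tip_z, a.tip_z + a.cap_length)
            + ann(0, a.r_inner_conductor, a.tip_z + a.cap_length, self.z_max)
            + ann(a.r_dielectric, a.r_outer_conductor, a.tip_z + a.cap_length, self.z_max)
            - vol[Region.SLOT]
        )
        total = np.pi * self.r_max**2 * (self.z_max - self.z_min)
        vol[Region.TISSUE] = total - sum(vol.values())
        return vol


def build_default_geometry() -> DomainGeometry:
    """Reference geometry: 30 mm x 80 mm tissue cylinder, slot at mid-height."""
    return DomainGeometry()


# -- geometry config round trip (lengths in millimetres) --------------------

_ANT_FIELDS = (
    "r_inner_conductor",
    "r_dielectric",
    "r_outer_conductor",
    "r_catheter",
    "slot_center_offset",
    "slot_width",
    "tip_z",
    "cap_length",
    "catheter_tip_cover",
)


def geometry_to_config(domain: DomainGeometry) -> dict:
    """Plain dict with all lengths in millimetres (config convention)."""
    ant = {f"{name}_mm": getattr(domain.antenna, name) / MM for name in _ANT_FIELDS}
    return {
        "r_max_mm": domain.r_max / MM,
        "z_min_mm": domain.z_min / MM,
        "z_max_mm": domain.z_max / MM,
        "antenna": ant,
    }


def geometry_from_config(config: dict) -> DomainGeometry:
    """Inverse of :func:`geometry_to_config`; missing keys use defaults."""
    ant_cfg = config.get("antenna", {})
    ant = AntennaGeometry(
        **{
            name: ant_cfg[f"{name}_mm"] * MM
            for name in _ANT_FIELDS
            if f"{name}_mm" in ant_cfg
        }
    )
    kwargs = {
        key: config[f"{key}_mm"] * MM
        for key in ("r_max", "z_min", "z_max")
        if f"{key}_mm" in config
    }
    return DomainGeometry(antenna=ant, **kwargs)


def save_geometry(domain: DomainGeometry, path) -> None:
    import yaml

    with open(path, "w") as f:
        yaml.safe_dump(geometry_to_config(domain), f, sort_keys=False)


def load_geometry(path) -> DomainGeometry:
    import yaml

    with open(path) as f:
        return geometry_from_config(yaml.safe_load(f))


# ---------------------------------------------------------------------------
# structured grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AxisymGrid:
    """Tensor-product grid in (r, z) with per-cell material labels.

    ``r_coords``/``z_coords`` are node coordinates (strictly increasing,
    ``r_coords[0] == 0`` on the symmetry axis); ``labels`` has shape
    ``(nr-1, nz-1)`` and conforms to every material interface.
    """

    r_coords: np.ndarray
    z_coords: np.ndarray
    labels: np.ndarray  # int8, cell-wise Region codes

    def __post_init__(self) -> None:
        r, z = self.r_coords, self.z_coords
        if r[0] != 0.0:
            raise ValueError("r_coords must start at the axis r = 0")
        if np.any(np.diff(r) <= 0) or np.any(np.diff(z) <= 0):
            raise ValueError("grid coordinates must be strictly increasing")
        if self.labels.shape != (len(r) - 1, len(z) - 1):
            raise ValueError("labels shape must be (nr-1, nz-1)")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.r_coords), len(self.z_coords))

    @property
    def n_nodes(self) -> int:
        return len(self.r_coords) * len(self.z_coords)

    @property
    def dr(self) -> np.ndarray:
        return np.diff(self.r_coords)

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.z_coords)

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_coords[:-1] + self.r_coords[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_coords[:-1] + self.z_coords[1:])

    def cell_areas(self) -> np.ndarray:
        """(r,z)-plane cell areas, shape (nr-1, nz-1)."""
        return np.outer(self.dr, self.dz)

    def revolved_cell_volumes(self) -> np.ndarray:
        """2*pi*r_c * area per cell (exact for the revolved annulus)."""
        ring = np.pi * (self.r_coords[1:] ** 2 - self.r_coords[:-1] ** 2)
        return np.outer(ring, self.dz)

    def max_aspect_ratio(self) -> float:
        a = np.outer(self.dr, 1.0 / self.dz)
        return float(max(a.max(), (1.0 / a).max()))


def _graded_axis(
    breakpoints: np.ndarray,
    fine_window: tuple[float, float],
    h_fine: float,
    h_coarse: float,
    growth: float = 0.3,
) -> np.ndarray:
    """1D graded point set containing every breakpoint exactly.

    Target spacing is ``h_fine`` inside ``fine_window``, growing linearly
    (at most ``growth`` per unit distance) to ``h_coarse`` far away.  Each
    breakpoint interval is marched independently and rescaled to land on its
    endpoints, so interfaces are represented exactly.
    """
    lo, hi = fine_window

    def h_at(x: float) -> float:
        d = max(0.0, lo - x, x - hi)
        return min(h_coarse, h_fine + growth * d)

    pts = [breakpoints[0]]
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        steps = []
        x = a
        while x < b:
            h = h_at(x)
            steps.append(h)
            x += h
        scale = (b - a) / sum(steps)
        xs = a + np.cumsum(steps) * scale
        xs[-1] = b  # exact endpoint
        pts.extend(xs.tolist())
    return np.array(pts)


def generate_grid(
    domain: DomainGeometry,
    target_h_fine: float = 0.1 * MM,
    target_h_coarse: float = 0.75 * MM,
    fine_halo: float = 5.0 * MM,
    max_aspect: float = 10.0,
) -> AxisymGrid:
    """Generate the conforming graded tensor grid for ``domain``.

    Spacing is at most ``target_h_fine`` within ``fine_halo`` of the slot
    and grades up to ``target_h_coarse`` at the domain edges; every material
    interface coordinate appears exactly among the grid lines.  The coarse
    target of each axis is capped so that no cell exceeds ``max_aspect``.
    """
    if not 0 < target_h_fine <= target_h_coarse:
        raise ValueError("need 0 < target_h_fine <= target_h_coarse")
    a = domain.antenna
    if target_h_fine > (domain.r_max / 4):
        raise ValueError("target_h_fine larger than the domain; grading infeasible")

    r_break = np.unique(
        np.concatenate([[0.0], domain.interface_radii(), [domain.r_max]])
    )
    z_break = np.unique(
        np.concatenate(
            [[domain.z_min], domain.interface_heights(), [domain.z_max]]
        )
    )
    slot_lo, slot_hi = a.slot_z_range
    r_window = (0.0, a.r_outer_conductor + fine_halo)
    z_window = (slot_lo - fine_halo, slot_hi + fine_halo)

    r = _graded_axis(r_break, r_window, target_h_fine, target_h_coarse)
    # cap the coarse spacing of each axis by the finest spacing of the other
    for _ in range(3):
        hz = min(target_h_coarse, max_aspect * np.diff(r).min() * 0.999)
        z = _graded_axis(z_break, z_window, min(target_h_fine, hz), hz)
        hr = min(target_h_coarse, max_aspect * np.diff(z).min() * 0.999)
        r_new = _graded_axis(r_break, r_window, min(target_h_fine, hr), hr)
        if len(r_new) == len(r) and np.allclose(r_new, r):
            r = r_new
            break
        r = r_new

    rc = 0.5 * (r[:-1] + r[1:])
    zc = 0.5 * (z[:-1] + z[1:])
    labels = domain.classify(rc[:, None], zc[None, :])
    return AxisymGrid(r, z, labels)
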