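"""Frequency-domain electromagnetic solver for the slot antenna.

In an axisymmetric, non-magnetic medium the magnetic field of the coaxial
antenna is purely azimuthal, H = H_phi(r, z) e_phi, and satisfies the scalar
curl-curl (Helmholtz) equation

    curl( eps_hat^-1 curl(H_phi e_phi) ) - k0^2 H_phi e_phi = 0,

with complex relative permittivity ``eps_hat = eps_r - j sigma/(omega eps0)``
(time convention ``exp(+j omega t)``).  Substituting v = r*H_phi reduces this
to a plain two-dimensional, self-adjoint problem on the (r, z) plane,

    div( a grad v ) + b v = 0,   a = 1/(eps_hat r),   b = k0^2 / r,

which is discretized here with a node-centered finite-volume scheme on the
structured conforming grid.  Radial face/volume integrals of 1/r are done in
closed form (log integrals), so the coaxial TEM mode ``v = const`` is exact
in the radial direction.  Boundary conditions:

* symmetry axis r = 0: v = 0 (exact for azimuthal fields),
* metal surfaces: perfect electric conductor, which is the natural
  (zero-flux) condition of the v-formulation,
* coax inlet: matched TEM port carrying the prescribed time-averaged power,
* outer tissue boundary: first-order scattering (Sommerfeld) condition.

Post-processing yields E = (curl H)/(j omega eps0 eps_hat), the resistive
heating density Q_ext = 1/2 sigma |E|^2 and SAR = Q_ext / rho.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.constants import epsilon_0 as EPS0, mu_0 as MU0, speed_of_light as C0

from .dielectrics import DielectricSample
from .geometry import AxisymGrid, Region

__all__ = [
    "CoaxPortSpec",
    "EMMaterialMap",
    "ComplexFieldSolution",
    "build_material_map",
    "assemble_helmholtz",
    "solve_field",
    "compute_sar_profile",
]

COAX_EPS_R = 2.03  # PTFE-like coax dielectric
CATHETER_EPS_R = 2.60  # plastic catheter


@dataclass(frozen=True)
class CoaxPortSpec:
    """Power-normalized TEM excitation of the coaxial feed.

    The travelling TEM mode has E_r = C/r, H_phi = C/(Z r); the amplitude C
    follows from the time-averaged power P = pi C^2 ln(r_out/r_in) / Z.
    """

    power_w: float
    frequency_hz: float
    r_in: float
    r_out: float
    coax_eps_r: float = COAX_EPS_R

    def __post_init__(self) -> None:
        if self.power_w <= 0:
            raise ValueError("power_w must be > 0")
        if not 0 < self.r_in < self.r_out:
            raise ValueError("need 0 < r_in < r_out")
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be > 0")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency_hz

    @property
    def wave_impedance(self) -> float:
        """Plane-wave impedance of the coax dielectric, ohm."""
        return float(np.sqrt(MU0 / (EPS0 * self.coax_eps_r)))

    @property
    def propagation_constant(self) -> float:
        return self.omega / C0 * float(np.sqrt(self.coax_eps_r))

    @property
    def mode_amplitude(self) -> float:
        """C (V) recovered from the prescribed port power."""
        Z = self.wave_impedance
        return float(
            np.sqrt(self.power_w * Z / (np.pi * np.log(self.r_out / self.r_in)))
        )

    @property
    def v_incident(self) -> float:
        """Incident value of v = r*H_phi (constant across the coax annulus)."""
        return self.mode_amplitude / self.wave_impedance

    def tem_power(self, amplitude: float) -> float:
        """Time-averaged TEM power carried by mode amplitude ``amplitude``."""
        return float(
            np.pi * amplitude**2 / self.wave_impedance
            * np.log(self.r_out / self.r_in)
        )


@dataclass
class EMMaterialMap:
    """Per-cell dielectric properties on the grid (mu_r = 1 everywhere)."""

    eps_r: np.ndarray  # (nr-1, nz-1)
    sigma: np.ndarray  # S/m
    is_conductor: np.ndarray  # bool

    def __post_init__(self) -> None:
        active = ~self.is_conductor
        if np.any(self.eps_r[active] < 1):
            raise ValueError("eps_r must be >= 1 in non-conductor cells")
        if np.any(self.sigma[active] < 0):
            raise ValueError("sigma must be >= 0")

    def complex_eps(self, omega: float) -> np.ndarray:
        """eps_hat = eps_r - j sigma/(omega eps0); conductors flagged as inf."""
        eps = self.eps_r - 1j * self.sigma / (omega * EPS0)
        return np.where(self.is_conductor, np.inf, eps)


def build_material_map(
    grid: AxisymGrid,
    tissue: DielectricSample,
    coax_eps_r: float = COAX_EPS_R,
    catheter_eps_r: float = CATHETER_EPS_R,
) -> EMMaterialMap:
    """Assign dielectric properties per region; the slot is filled with the
    coax dielectric."""
    lab = grid.labels
    eps = np.ones(lab.shape)
    sig = np.zeros(lab.shape)
    eps[lab == Region.TISSUE] = tissue.eps_r
    sig[lab == Region.TISSUE] = tissue.sigma
    eps[(lab == Region.COAX_DIELECTRIC) | (lab == Region.SLOT)] = coax_eps_r
    eps[lab == Region.CATHETER] = catheter_eps_r
    return EMMaterialMap(eps, sig, lab == Region.CONDUCTOR)


@dataclass
class HelmholtzSystem:
    """Assembled sparse system for v = r*H_phi (internal solver handle)."""

    grid: AxisymGrid
    mat: EMMaterialMap
    port: CoaxPortSpec
    matrix: sp.csc_matrix  # full (n_nodes x n_nodes)
    rhs: np.ndarray
    unknown: np.ndarray  # bool per node (flattened i*nz + j)
    v_known: np.ndarray  # prescribed values on ~unknown nodes
    port_node_idx: np.ndarray  # radial node indices of the port annulus


@dataclass
class ComplexFieldSolution:
    """Solved fields and derived heating quantities."""

    grid: AxisymGrid
    port: CoaxPortSpec
    v: np.ndarray  # (nr, nz) complex, v = r*H_phi
    H_phi: np.ndarray  # (nr, nz) complex nodal field, A/m
    E_r: np.ndarray  # (nr-1, nz-1) complex cell field, V/m
    E_z: np.ndarray
    Q_ext: np.ndarray  # W/m^3 per cell
    SAR: np.ndarray  # W/kg per cell (tissue only, 0 elsewhere)
    incident_power: float
    reflected_power: float
    absorbed_power: float
    boundary_outflow: float
    residual: float
    rho_tissue: float = 385.0

    def power_balance_error(self) -> float:
        """|incident - (reflected + absorbed + outflow)| / incident."""
        out = self.reflected_power + self.absorbed_power + self.boundary_outflow
        return abs(self.incident_power - out) / self.incident_power


def _radial_log_segments(r: np.ndarray):
    """Closed-form 1/r integrals over node half-cells.

    Returns (Lr, Ll): ``Lr[i]`` integrates 1/r over [r_i, r_{i+1/2}] (right
    half of node i inside cell i, zero on the axis where the node is
    Dirichlet anyway) and ``Ll[i]`` over [r_{i+1/2}, r_{i+1}] (left half of
    node i+1 inside cell i).
    """
    r_half = 0.5 * (r[:-1] + r[1:])
    with np.errstate(divide="ignore"):
        Lr = np.where(r[:-1] > 0, np.log(r_half / np.maximum(r[:-1], 1e-300)), 0.0)
    Ll = np.log(r[1:] / r_half)
    return Lr, Ll


def assemble_helmholtz(
    grid: AxisymGrid,
    mat: EMMaterialMap,
    port: CoaxPortSpec,
    forcing=None,
    dirichlet_boundary=None,
) -> HelmholtzSystem:
    """Assemble the sparse complex system for the azimuthal-field problem.

    ``forcing`` (test hook) is a callable f(r, z) making the assembled
    equation ``div(a grad v) + b v = f`` for manufactured-solution runs;
    ``dirichlet_boundary`` (test hook) is a callable g(r, z) that replaces
    the port/scattering conditions with v = g on the outer boundary.
    """
    r, z = grid.r_coords, grid.z_coords
    nr, nz = grid.shape
    NR, NZ = nr - 1, nz - 1
    dr, dz = grid.dr, grid.dz
    lab = grid.labels
    omega = port.omega
    k0 = omega / C0

    eps_hat = mat.complex_eps(omega)
    acell = np.where(mat.is_conductor, 0.0 + 0.0j, 1.0 / eps_hat)
    active_cell = ~mat.is_conductor

    if not np.any(active_cell):
        raise ValueError("assembly failed: domain contains no dielectric cells")

    rf = 0.5 * (r[:-1] + r[1:])  # radial face positions, (NR,)
    Lr, Ll = _radial_log_segments(r)

    rows, cols, vals = [], [], []

    def node(i, j):
        return i * nz + j

    # --- radial fluxes: edge between (i, j) and (i+1, j) ----------------
    hw = acell * (dz[None, :] / 2.0)  # per-cell half-face weight
    Ch = np.zeros((NR, nz), dtype=complex)
    Ch[:, 1:] += hw
    Ch[:, :-1] += hw
    Ch /= (rf * dr)[:, None]

    ii, jj = np.nonzero(Ch)
    p = node(ii, jj)
    q = node(ii + 1, jj)
    c = Ch[ii, jj]
    rows += [p, q, p, q]
    cols += [q, p, p, q]
    vals += [c, c, -c, -c]

    # --- axial fluxes: edge between (i, j) and (i, j+1) -----------------
    Cv = np.zeros((nr, NZ), dtype=complex)
    Cv[1:, :] += Ll[:, None] * acell
    Cv[:-1, :] += Lr[:, None] * acell
    Cv /= dz[None, :]

    ii, jj = np.nonzero(Cv)
    p = node(ii, jj)
    q = node(ii, jj + 1)
    c = Cv[ii, jj]
    rows += [p, q, p, q]
    cols += [q, p, p, q]
    vals += [c, c, -c, -c]

    # --- volume (mass) term k0^2/r over active quarter cells ------------
    m = active_cell.astype(float)
    B = np.zeros((nr, nz))
    q_lo = m * Lr[:, None] * (dz[None, :] / 2.0)
    q_hi = m * Ll[:, None] * (dz[None, :] / 2.0)
    B[:-1, :-1] += q_lo
    B[:-1, 1:] += q_lo
    B[1:, :-1] += q_hi
    B[1:, 1:] += q_hi
    B *= k0**2

    ii, jj = np.nonzero(B)
    p = node(ii, jj)
    rows.append(p)
    cols.append(p)
    vals.append(B[ii, jj].astype(complex))

    rhs = np.zeros(nr * nz, dtype=complex)
    port_idx = np.array([], dtype=int)

    if dirichlet_boundary is None:
        # --- matched TEM port on top-row coax-dielectric cells ----------
        top = lab[:, NZ - 1]
        port_cells = np.nonzero(top == Region.COAX_DIELECTRIC)[0]
        if len(port_cells) == 0:
            raise ValueError(
                "assembly failed: no coax-dielectric cells on the inlet "
                "boundary (zero-measure port)"
            )
        kc = port.propagation_constant
        v_inc = port.v_incident
        for ci in np.atleast_1d(port_cells):
            a = acell[ci, NZ - 1]
            for ni, seg in ((ci, Lr[ci]), (ci + 1, Ll[ci])):
                p = node(ni, nz - 1)
                rows.append(np.array([p]))
                cols.append(np.array([p]))
                vals.append(np.array([-1j * kc * a * seg]))
                rhs[p] += -2j * kc * a * seg * v_inc
        port_idx = np.unique(
            np.concatenate([port_cells, np.atleast_1d(port_cells) + 1])
        )

        # --- first-order scattering on the remaining open boundary ------
        k_cell = k0 * np.sqrt(
            np.where(mat.is_conductor, 1.0, eps_hat).astype(complex)
        )

        def robin(p, coeff):
            rows.append(np.array([p]))
            cols.append(np.array([p]))
            vals.append(np.array([-coeff]))

        # outer radius r = r_max
        for cj in range(NZ):
            if not active_cell[NR - 1, cj]:
                continue
            coeff = 1j * k_cell[NR - 1, cj] * acell[NR - 1, cj] / r[-1] * dz[cj] / 2
            robin(node(nr - 1, cj), coeff)
            robin(node(nr - 1, cj + 1), coeff)
        # bottom z = z_min and top z = z_max (excluding the port)
        for cj, jn in ((0, 0), (NZ - 1, nz - 1)):
            for ci in range(NR):
                if not active_cell[ci, cj]:
                    continue
                if jn == nz - 1 and lab[ci, cj] == Region.COAX_DIELECTRIC:
                    continue  # port handled above
                kac = 1j * k_cell[ci, cj] * acell[ci, cj]
                robin(node(ci, jn), kac * Lr[ci])
                robin(node(ci + 1, jn), kac * Ll[ci])

    # --- optional manufactured forcing ----------------------------------
    if forcing is not None:
        area = np.zeros((nr, nz))
        qa = m * np.outer(dr / 2.0, dz / 2.0)
        area[:-1, :-1] += qa
        area[:-1, 1:] += qa
        area[1:, :-1] += qa
        area[1:, 1:] += qa
        R, Z = np.meshgrid(r, z, indexing="ij")
        rhs += (np.asarray(forcing(R, Z), dtype=complex) * area).ravel()

    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nr * nz, nr * nz),
    ).tocsc()

    # --- unknown / known partition --------------------------------------
    act_node = np.zeros((nr, nz), dtype=bool)
    act_node[:-1, :-1] |= active_cell
    act_node[1:, :-1] |= active_cell
    act_node[:-1, 1:] |= active_cell
    act_node[1:, 1:] |= active_cell
    unknown = act_node.copy()
    unknown[0, :] = False  # axis Dirichlet v = 0
    v_known = np.zeros(nr * nz, dtype=complex)
    if dirichlet_boundary is not None:
        bnd = np.zeros((nr, nz), dtype=bool)
        bnd[-1, :] = bnd[:, 0] = bnd[:, -1] = True
        unknown &= ~bnd
        R, Z = np.meshgrid(r, z, indexing="ij")
        g = np.asarray(dirichlet_boundary(R, Z), dtype=complex)
        v_known[(bnd & act_node).ravel()] = g[bnd & act_node]

    return HelmholtzSystem(
        grid, mat, port, A, rhs, unknown.ravel(), v_known, port_idx
    )


def solve_field(system: HelmholtzSystem, rho_tissue: float = 385.0) -> ComplexFieldSolution:
    """Factorize and solve the assembled system; derive E, Q_ext and SAR.

    The relative residual of the linear solve is checked against 1e-10 and
    surfaced in the returned solution.
    """
    grid, mat, port = system.grid, system.mat, system.port
    nr, nz = grid.shape
    u = system.unknown
    A, b = system.matrix, system.rhs.copy()
    if np.any(system.v_known != 0):
        b -= A @ system.v_known

    Auu = A[u][:, u].tocsc()
    v = system.v_known.copy()
    lu = spla.splu(Auu)
    v[u] = lu.solve(b[u])

    bnorm = np.linalg.norm(b[u])
    res = np.linalg.norm(Auu @ v[u] - b[u]) / (bnorm if bnorm > 0 else 1.0)
    if res > 1e-8:
        raise RuntimeError(f"Helmholtz solve did not converge: residual {res:.3e}")

    v2d = v.reshape(nr, nz)
    r, dz, dr = grid.r_coords, grid.dz, grid.dr
    H = np.zeros_like(v2d)
    H[1:, :] = v2d[1:, :] / r[1:, None]
    # H_phi is odd in r; the axis value is exactly zero

    omega = port.omega
    eps_hat = mat.complex_eps(omega)
    with np.errstate(invalid="ignore"):
        inv_jwe = np.where(
            mat.is_conductor, 0.0, 1.0 / (1j * omega * EPS0 * eps_hat)
        )
    rc = grid.r_centers

    dv_dr = 0.5 * (
        (v2d[1:, :-1] - v2d[:-1, :-1]) + (v2d[1:, 1:] - v2d[:-1, 1:])
    ) / dr[:, None]
    E_z = dv_dr / rc[:, None] * inv_jwe
    dH_dz = 0.5 * (
        (H[:-1, 1:] - H[:-1, :-1]) + (H[1:, 1:] - H[1:, :-1])
    ) / dz[None, :]
    E_r = -dH_dz * inv_jwe

    Q = 0.5 * mat.sigma * (np.abs(E_r) ** 2 + np.abs(E_z) ** 2)
    Q[mat.is_conductor] = 0.0
    assert np.all(Q >= 0.0)
    tissue_mask = grid.labels == Region.TISSUE
    SAR = np.where(tissue_mask, Q / rho_tissue, 0.0)

    absorbed = float(np.sum(Q * grid.revolved_cell_volumes()))

    # reflected power: project the port-plane residual onto the TEM mode
    reflected = 0.0
    if len(system.port_node_idx) > 0:
        ip = system.port_node_idx
        rp = r[ip]
        v_ref = v2d[ip, -1] - port.v_incident
        ln_ratio = np.log(port.r_out / port.r_in)
        v_bar = np.trapezoid(v_ref / rp, rp) / ln_ratio
        reflected = float(
            np.pi * port.wave_impedance * abs(v_bar) ** 2 * ln_ratio
        )

    # Poynting outflow through the open outer boundary (diagnostic estimate
    # from boundary-adjacent cell fields)
    Hc = 0.25 * (H[:-1, :-1] + H[1:, :-1] + H[:-1, 1:] + H[1:, 1:])
    S_r = -0.5 * np.real(E_z * np.conj(Hc))
    S_z = 0.5 * np.real(E_r * np.conj(Hc))
    act = ~mat.is_conductor
    outflow = float(np.sum(S_r[-1, :] * act[-1, :] * 2 * np.pi * rc[-1] * dz))
    outflow += float(np.sum(-S_z[:, 0] * act[:, 0] * 2 * np.pi * rc * dr))
    top_open = act[:, -1] & (grid.labels[:, -1] != Region.COAX_DIELECTRIC)
    outflow += float(np.sum(S_z[:, -1] * top_open * 2 * np.pi * rc * dr))

    return ComplexFieldSolution(
        grid=grid,
        port=port,
        v=v2d,
        H_phi=H,
        E_r=E_r,
        E_z=E_z,
        Q_ext=Q,
        SAR=SAR,
        incident_power=port.power_w,
        reflected_power=reflected,
        absorbed_power=absorbed,
        boundary_outflow=outflow,
        residual=float(res),
        rho_tissue=rho_tissue,
    )


def compute_sar_profile(
    sol: ComplexFieldSolution, grid: AxisymGrid, r_probe: float
) -> np.ndarray:
    """SAR sampled along a line parallel to the antenna at radius ``r_probe``.

    Returns an array of shape (nz, 2) with columns (z in m, SAR in W/kg),
    one sample per axial grid line.
    """
    r = grid.r_coords
    if not r[0] < r_probe < r[-1]:
        raise ValueError(f"r_probe {r_probe} outside the grid")
    ic = int(np.searchsorted(r, r_probe) - 1)
    if np.any(grid.labels[ic, :] != Region.TISSUE):
        raise ValueError(
            f"probe radius {r_probe * 1e3:.3f} mm intersects the antenna; "
            "choose r_probe outside the catheter"
        )
    col = sol.SAR[ic, :]
    nz = grid.shape[1]
    prof = np.empty(nz)
    prof[0] = col[0]
    prof[-1] = col[-1]
    prof[1:-1] = 0.5 * (col[:-1] + col[1:])
    return np.column_stack([grid.z_coords, prof])
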