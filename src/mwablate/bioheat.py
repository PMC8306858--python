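"""Pennes bioheat solver on the axisymmetric grid.

Tissue temperature obeys

    rho c dT/dt = div(k grad T) + rho_b W_b c_b (T_b - T) + Q_ext + Q_m,

where the perfusion term models convective cooling by capillary blood
entering at body temperature T_b and Q_ext is the (fixed) electromagnetic
heating density from the EM solve.  Metabolic heating Q_m is zero by
default.  The thermal domain is the tissue region only: the antenna and
catheter are excluded with a zero-flux condition on their surfaces, the
symmetry axis is zero-flux, and the far boundary is held at T_b (body
bath).  Time stepping is backward Euler (unconditionally stable; the
operator is factorized once and reused), so the default dt = 1 s is a pure
accuracy choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import AxisymGrid, Region

__all__ = [
    "BioheatParams",
    "TemperatureHistory",
    "BioheatSystem",
    "step_temperature",
    "run_transient",
]


@dataclass(frozen=True)
class BioheatParams:
    """Thermal parameters for lung tissue and blood (SI units, kelvin)."""

    rho: float = 385.0  # tissue density, kg/m^3
    c: float = 3886.0  # tissue heat capacity, J/(kg K)
    k_thermal: float = 0.39  # tissue thermal conductivity, W/(m K)
    rho_b: float = 1060.0  # blood density, kg/m^3
    c_b: float = 3639.0  # blood heat capacity, J/(kg K)
    W_b: float = 0.0036  # blood perfusion rate, 1/s
    T_b: float = 310.15  # blood/body temperature, K (37 C)
    Q_m: float = 0.0  # metabolic heat, W/m^3

    def __post_init__(self) -> None:
        for name in ("rho", "c", "k_thermal", "rho_b", "c_b", "W_b", "T_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.Q_m < 0:
            raise ValueError("Q_m must be >= 0")

    @property
    def perfusion_coefficient(self) -> float:
        """rho_b * W_b * c_b, the volumetric perfusion heat-sink, W/(m^3 K)."""
        return self.rho_b * self.W_b * self.c_b


@dataclass
class TemperatureHistory:
    """Stored transient temperature solution.

    ``fields`` holds nodal temperature snapshots (NaN outside the thermal
    domain) at the times in ``times``; ``peak_times``/``peak_trace`` track
    the spatial maximum at every time step; ``probe_traces`` maps requested
    (r, z) probe points to per-step temperature arrays.
    """

    times: np.ndarray  # snapshot times, s
    fields: np.ndarray  # (n_snapshots, nr, nz), K
    peak_times: np.ndarray  # every step, s
    peak_trace: np.ndarray  # spatial max per step, K
    T_b: float
    probe_traces: dict = field(default_factory=dict)

    @property
    def final_field(self) -> np.ndarray:
        return self.fields[-1]

    @property
    def T_max_final(self) -> float:
        return float(self.peak_trace[-1])

    @property
    def saturation_time(self) -> float:
        """First time the peak trace reaches 95% of its final rise over T_b.

        The crossing is located by linear interpolation between time steps
        so the result is not quantized by dt.
        """
        rise = self.peak_trace[-1] - self.T_b
        if rise <= 1e-9:  # no heating beyond round-off
            return 0.0
        target = self.T_b + 0.95 * rise
        idx = np.nonzero(self.peak_trace >= target)[0]
        i = int(idx[0])
        if i == 0:
            return float(self.peak_times[0])
        t0, t1 = self.peak_times[i - 1], self.peak_times[i]
        v0, v1 = self.peak_trace[i - 1], self.peak_trace[i]
        f = (target - v0) / (v1 - v0) if v1 > v0 else 1.0
        return float(t0 + f * (t1 - t0))


class BioheatSystem:
    """Finite-volume discretization of the bioheat operator on tissue cells.

    Builds node volumes V (revolved measure), the conduction stiffness K and
    the perfusion lumped matrix P = rho_b W_b c_b V, restricted to unknown
    nodes (thermal nodes off the Dirichlet far boundary).
    """

    def __init__(
        self,
        grid: AxisymGrid,
        params: BioheatParams,
        dirichlet_values=None,
        thermal_regions=(Region.TISSUE,),
    ):
        self.grid = grid
        self.params = params
        r, z = grid.r_coords, grid.z_coords
        nr, nz = grid.shape
        dr, dz = grid.dr, grid.dz
        cell_ok = np.isin(grid.labels, thermal_regions)
        if not np.any(cell_ok):
            raise ValueError("no thermal cells in the grid")
        self.cell_mask = cell_ok
        m = cell_ok.astype(float)

        # exact radial moments: integral of r dr over node half-cells
        r_half = 0.5 * (r[:-1] + r[1:])
        Mlo = 0.5 * (r_half**2 - r[:-1] ** 2)  # right half of node i, cell i
        Mhi = 0.5 * (r[1:] ** 2 - r_half**2)  # left half of node i+1, cell i

        # node volumes (per radian; the 2*pi factor cancels throughout)
        V = np.zeros((nr, nz))
        q_lo = m * Mlo[:, None] * (dz[None, :] / 2.0)
        q_hi = m * Mhi[:, None] * (dz[None, :] / 2.0)
        V[:-1, :-1] += q_lo
        V[:-1, 1:] += q_lo
        V[1:, :-1] += q_hi
        V[1:, 1:] += q_hi
        self.node_volume = V

        k = params.k_thermal
        rows, cols, vals = [], [], []

        def node(i, j):
            return i * nz + j

        # radial conduction: k * r_f * dz_half / dr per half-face
        hw = m * (dz[None, :] / 2.0)
        Ch = np.zeros((nr - 1, nz))
        Ch[:, 1:] += hw
        Ch[:, :-1] += hw
        Ch *= k * (r_half / dr)[:, None]
        ii, jj = np.nonzero(Ch)
        p, q, c = node(ii, jj), node(ii + 1, jj), Ch[ii, jj]
        rows += [p, q, p, q]
        cols += [q, p, p, q]
        vals += [-c, -c, c, c]  # K is positive semi-definite: K = -div(k grad)

        # axial conduction: k * int(r dr) / dz per half-face
        Cv = np.zeros((nr, nz - 1))
        Cv[1:, :] += Mhi[:, None] * m
        Cv[:-1, :] += Mlo[:, None] * m
        Cv *= k / dz[None, :]
        ii, jj = np.nonzero(Cv)
        p, q, c = node(ii, jj), node(ii, jj + 1), Cv[ii, jj]
        rows += [p, q, p, q]
        cols += [q, p, p, q]
        vals += [-c, -c, c, c]

        n = nr * nz
        self.K = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()

        act = np.zeros((nr, nz), dtype=bool)
        act[:-1, :-1] |= cell_ok
        act[1:, :-1] |= cell_ok
        act[:-1, 1:] |= cell_ok
        act[1:, 1:] |= cell_ok
        self.active = act

        bnd = np.zeros((nr, nz), dtype=bool)
        bnd[-1, :] = bnd[:, 0] = bnd[:, -1] = True
        self.dirichlet = act & bnd
        self.unknown = (act & ~bnd).ravel()

        self.T_dirichlet = np.full(n, params.T_b)
        if dirichlet_values is not None:
            R, Z = np.meshgrid(r, z, indexing="ij")
            self.T_dirichlet = np.asarray(dirichlet_values(R, Z), float).ravel()

        self.P_diag = params.perfusion_coefficient * V.ravel()
        self.M_diag = params.rho * params.c * V.ravel()
        self._lu = None
        self._lu_dt = None

    # -- source handling -------------------------------------------------
    def integrate_source(self, Q_cells: np.ndarray) -> np.ndarray:
        """Nodal source vector from a per-cell heating density (W/m^3)."""
        grid = self.grid
        nr, nz = grid.shape
        dz = grid.dz
        r = grid.r_coords
        r_half = 0.5 * (r[:-1] + r[1:])
        Mlo = 0.5 * (r_half**2 - r[:-1] ** 2)
        Mhi = 0.5 * (r[1:] ** 2 - r_half**2)
        Qm = np.where(self.cell_mask, Q_cells, 0.0)
        S = np.zeros((nr, nz))
        q_lo = Qm * Mlo[:, None] * (dz[None, :] / 2.0)
        q_hi = Qm * Mhi[:, None] * (dz[None, :] / 2.0)
        S[:-1, :-1] += q_lo
        S[:-1, 1:] += q_lo
        S[1:, :-1] += q_hi
        S[1:, 1:] += q_hi
        return S.ravel()

    def initial_field(self) -> np.ndarray:
        T = np.full(self.grid.n_nodes, np.nan)
        T[self.active.ravel()] = self.params.T_b
        T[self.dirichlet.ravel()] = self.T_dirichlet[self.dirichlet.ravel()]
        return T

    def _factorize(self, dt: float):
        if self._lu is not None and self._lu_dt == dt:
            return
        n = self.grid.n_nodes
        A = (
            sp.diags(self.M_diag / dt + self.P_diag)
            + self.K
        ).tocsc()
        u = self.unknown
        self._A_full = A
        self._Auu = A[u][:, u].tocsc()
        self._Aud = A[u][:, ~u].tocsc()
        self._lu = spla.splu(self._Auu)
        self._lu_dt = dt

    def step(self, T: np.ndarray, dt: float, S: np.ndarray) -> np.ndarray:
        """One backward-Euler step; T is a flat nodal array (NaN outside)."""
        if not np.all(np.isfinite(T[self.active.ravel()])):
            raise FloatingPointError("non-finite temperature entering step")
        self._factorize(dt)
        u = self.unknown
        Tb_vec = self.params.T_b
        rhs = (
            self.M_diag[u] / dt * T[u]
            + self.P_diag[u] * Tb_vec
            + S[u]
            + self.params.Q_m * self.node_volume.ravel()[u]
        )
        T_known = np.where(self.dirichlet.ravel(), self.T_dirichlet, 0.0)
        rhs = rhs - self._Aud @ T_known[~u]
        T_new = T.copy()
        T_new[u] = self._lu.solve(rhs)
        if not np.all(np.isfinite(T_new[u])):
            raise FloatingPointError(
                f"bioheat step produced non-finite temperatures at dt={dt}"
            )
        return T_new

    def steady_state(self, S: np.ndarray) -> np.ndarray:
        """Direct steady solution of K T + P (T - T_b) = S."""
        n = self.grid.n_nodes
        A = (sp.diags(self.P_diag) + self.K).tocsc()
        u = self.unknown
        rhs = (
            self.P_diag[u] * self.params.T_b
            + S[u]
            + self.params.Q_m * self.node_volume.ravel()[u]
        )
        T_known = np.where(self.dirichlet.ravel(), self.T_dirichlet, 0.0)
        rhs = rhs - A[u][:, ~u] @ T_known[~u]
        T = self.initial_field()
        T[u] = spla.spsolve(A[u][:, u].tocsc(), rhs)
        return T

    def energy_balance_residual(
        self, T_old: np.ndarray, T_new: np.ndarray, dt: float, S: np.ndarray
    ) -> float:
        """Independent per-step energy audit.

        Recomputes storage change, conduction flux, perfusion and source
        integrals directly from the fields and returns the relative
        imbalance (should vanish for the implicit scheme up to round-off).
        """
        u = self.unknown
        d = self.dirichlet.ravel()
        storage = float(np.sum(self.M_diag[u] * (T_new[u] - T_old[u]) / dt))
        Tn = np.where(self.active.ravel(), np.nan_to_num(T_new), 0.0)
        conduction = float(np.sum((self.K @ Tn)[u] * 1.0))  # net outflow
        perfusion = float(np.sum(self.P_diag[u] * (self.params.T_b - T_new[u])))
        source = float(np.sum(S[u]))
        scale = max(abs(source), abs(storage), 1e-30)
        return abs(storage + conduction - perfusion - source) / scale


def step_temperature(
    grid: AxisymGrid,
    T: np.ndarray,
    dt: float,
    params: BioheatParams,
    Q_ext: np.ndarray,
) -> np.ndarray:
    """Convenience one-shot implicit step (builds the system each call).

    ``T`` is a (nr, nz) nodal field; ``Q_ext`` a per-cell heating density.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    sysm = BioheatSystem(grid, params)
    S = sysm.integrate_source(Q_ext)
    return sysm.step(np.asarray(T, float).ravel(), dt, S).reshape(grid.shape)


def run_transient(
    grid: AxisymGrid,
    params: BioheatParams,
    Q_ext: np.ndarray,
    duration: float,
    dt: float = 1.0,
    store_every: float = 5.0,
    probes=(),
    audit: bool = False,
) -> TemperatureHistory:
    """Advance the bioheat equation from T = T_b over ``[0, duration]``.

    ``Q_ext`` is the per-cell heating density held fixed for the whole run
    (one-way EM-to-thermal coupling).  Snapshots are stored every
    ``store_every`` seconds (plus the initial and final states); the spatial
    peak is tracked every step.  ``probes`` is a sequence of (r, z) points
    whose nearest-node temperature is recorded every step.
    """
    if duration < dt:
        raise ValueError("duration must be >= dt")
    sysm = BioheatSystem(grid, params)
    S = sysm.integrate_source(Q_ext)
    nr, nz = grid.shape

    probe_nodes = {}
    act = sysm.active
    for (rp, zp) in probes:
        ir = int(np.argmin(np.abs(grid.r_coords - rp)))
        iz = int(np.argmin(np.abs(grid.z_coords - zp)))
        if not act[ir, iz]:  # snap to nearest active node in the column
            ok = np.nonzero(act[:, iz])[0]
            ir = ok[np.argmin(np.abs(grid.r_coords[ok] - rp))]
        probe_nodes[(rp, zp)] = (ir, iz)

    n_steps = int(round(duration / dt))
    T = sysm.initial_field()
    times = [0.0]
    fields = [T.reshape(nr, nz).copy()]
    peak_t = [0.0]
    peak = [params.T_b]
    traces = {p: [params.T_b] for p in probes}
    next_store = store_every
    max_audit = 0.0

    u = sysm.unknown
    for n in range(1, n_steps + 1):
        t = n * dt
        T_new = sysm.step(T, dt, S)
        if audit:
            max_audit = max(
                max_audit, sysm.energy_balance_residual(T, T_new, dt, S)
            )
        T = T_new
        peak_t.append(t)
        peak.append(float(np.max(T[u])) if u.any() else params.T_b)
        for p, (ir, iz) in probe_nodes.items():
            traces[p].append(float(T.reshape(nr, nz)[ir, iz]))
        if t >= next_store - 1e-9 or n == n_steps:
            times.append(t)
            fields.append(T.reshape(nr, nz).copy())
            next_store += store_every

    hist = TemperatureHistory(
        times=np.array(times),
        fields=np.array(fields),
        peak_times=np.array(peak_t),
        peak_trace=np.array(peak),
        T_b=params.T_b,
        probe_traces={p: np.array(v) for p, v in traces.items()},
    )
    if audit:
        hist.max_energy_residual = max_audit  # type: ignore[attr-defined]
    return hist
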