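"""Analytic reference cases and synthetic histories for verification.

Every solver stage in this package can be checked without external data:

* the coax TEM mode gives closed-form E/H fields and a power round-trip for
  the electromagnetic solver,
* suppressing conduction reduces the bioheat equation to a scalar ODE with
  an exact exponential solution (perfusion-limited heating),
* manufactured-solution cases inject a forcing term so a chosen smooth
  field is the exact solution of the discrete operators,
* synthetic temperature histories (constant / ramp-plateau / noisy-plateau)
  exercise the damage integrator against constant-temperature closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.constants import epsilon_0 as EPS0

from .bioheat import BioheatParams, TemperatureHistory
from .em import CoaxPortSpec
from .geometry import AxisymGrid, Region

__all__ = [
    "AnalyticCase",
    "make_coax_tem_case",
    "make_perfusion_ode_case",
    "make_synthetic_history",
    "make_helmholtz_mms_case",
    "make_bioheat_mms_case",
    "uniform_tissue_grid",
    "coax_line_grid",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20210713


@dataclass
class AnalyticCase:
    """A named closed-form reference with its comparison tolerance."""

    name: str
    params: dict
    evaluate: Callable
    tolerance: float

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


# ---------------------------------------------------------------------------
# grids for analytic cases
# ---------------------------------------------------------------------------


def uniform_tissue_grid(r_max=0.02, z_max=0.04, nr=41, nz=61) -> AxisymGrid:
    """All-tissue uniform grid for operator-level tests."""
    r = np.linspace(0.0, r_max, nr)
    z = np.linspace(0.0, z_max, nz)
    labels = np.full((nr - 1, nz - 1), Region.TISSUE, dtype=np.int8)
    return AxisymGrid(r, z, labels)


def coax_line_grid(
    port: CoaxPortSpec, length=0.04, n_radial=12, n_axial=201
) -> AxisymGrid:
    """A pure coaxial line: inner conductor, dielectric annulus, outer wall.

    The port sits at z = length; the far end (z = 0) is left open so the
    scattering condition acts as a matched termination for the TEM mode.
    """
    r = np.concatenate(
        [
            np.linspace(0.0, port.r_in, 4),
            np.linspace(port.r_in, port.r_out, n_radial)[1:],
            [port.r_out * 1.15],  # outer-conductor wall
        ]
    )
    z = np.linspace(0.0, length, n_axial)
    labels = np.full((len(r) - 1, len(z) - 1), Region.CONDUCTOR, dtype=np.int8)
    rc = 0.5 * (r[:-1] + r[1:])
    labels[(rc > port.r_in) & (rc < port.r_out), :] = Region.COAX_DIELECTRIC
    return AxisymGrid(r, z, labels)


# ---------------------------------------------------------------------------
# closed-form cases
# ---------------------------------------------------------------------------


def make_coax_tem_case(port: CoaxPortSpec) -> AnalyticCase:
    """Exact travelling TEM mode of the coaxial feed.

    ``evaluate(r, zeta)`` returns (E_r, H_phi) at radius r and propagation
    distance zeta from the port; the case also exposes the amplitude/power
    round trip through ``params``.
    """
    C = port.mode_amplitude
    Z = port.wave_impedance
    k = port.propagation_constant

    def evaluate(r, zeta=0.0):
        r = np.asarray(r, dtype=float)
        phase = np.exp(-1j * k * np.asarray(zeta))
        E_r = C / r * phase
        H_phi = C / (Z * r) * phase
        return E_r, H_phi

    return AnalyticCase(
        name="coax_tem",
        params={
            "C": C,
            "Z": Z,
            "k": k,
            "power_roundtrip": port.tem_power(C),
            "port": port,
        },
        evaluate=evaluate,
        tolerance=1e-12,
    )


def make_perfusion_ode_case(params: BioheatParams, Q: float) -> AnalyticCase:
    """Conduction-free bioheat limit: rho c dT/dt = rho_b W_b c_b (T_b - T) + Q.

    Exact solution T(t) = T_b + (Q/P)(1 - exp(-P t / (rho c))) with
    P = rho_b W_b c_b; the steady temperature rise is Q/P and the rate
    constant P/(rho c) (about 9.3e-3 1/s, i.e. a ~108 s time constant, at
    the default lung/blood parameters).
    """
    if Q < 0:
        raise ValueError("Q must be >= 0")
    P = params.perfusion_coefficient
    tau_rate = P / (params.rho * params.c)

    def evaluate(t):
        t = np.asarray(t, dtype=float)
        return params.T_b + (Q / P) * (1.0 - np.exp(-tau_rate * t))

    return AnalyticCase(
        name="perfusion_ode",
        params={
            "Q": Q,
            "delta_T_steady": Q / P,
            "rate_constant": tau_rate,
            "bioheat": params,
        },
        evaluate=evaluate,
        tolerance=5e-3,
    )


def make_synthetic_history(
    profile: str,
    duration: float = 600.0,
    dt: float = 1.0,
    T_base: float = 310.15,
    T_plateau: float = 373.0,
    ramp_time: float = 120.0,
    noise_std: float = 0.5,
    seed: int = DEFAULT_SEED,
) -> TemperatureHistory:
    """Deterministic single-point temperature history for damage tests.

    Profiles: ``constant`` (T_base throughout), ``ramp-plateau`` (linear
    rise over ``ramp_time`` then plateau, emulating the source-dominated
    linear phase followed by perfusion-limited saturation) and
    ``noisy-plateau`` (ramp-plateau plus seeded Gaussian jitter).
    """
    t = np.arange(0.0, duration + dt / 2, dt)
    if profile == "constant":
        T = np.full_like(t, T_base)
    elif profile in ("ramp-plateau", "noisy-plateau"):
        T = T_base + (T_plateau - T_base) * np.clip(t / ramp_time, 0.0, 1.0)
        if profile == "noisy-plateau":
            rng = np.random.default_rng(seed)
            T = T + rng.normal(0.0, noise_std, size=t.shape)
    else:
        raise ValueError(f"unknown profile {profile!r}")

    fields = T[:, None, None]  # trivial 1x1 spatial grid
    return TemperatureHistory(
        times=t,
        fields=fields,
        peak_times=t,
        peak_trace=T.copy(),
        T_b=T_base,
        probe_traces={(0.0, 0.0): T.copy()},
    )


# ---------------------------------------------------------------------------
# manufactured solutions
# ---------------------------------------------------------------------------


def make_helmholtz_mms_case(
    eps_hat: complex, k0: float, r_max: float, z_max: float
) -> AnalyticCase:
    """Manufactured solution for the v = r*H_phi Helmholtz operator.

    Exact field v(r, z) = sin(pi r / R) sin(pi z / L) (zero on the axis and
    the outer boundary, matching homogeneous Dirichlet data); ``params``
    carries the forcing g = div(a grad v) + b v with a = 1/(eps_hat r),
    b = k0^2/r, to be injected through the assembler's test hook.
    """
    br = np.pi / r_max
    bz = np.pi / z_max

    def v_exact(r, z):
        return np.sin(br * r) * np.sin(bz * z)

    def forcing(r, z):
        r = np.asarray(r, dtype=float)
        safe_r = np.where(r > 0, r, np.nan)
        v = v_exact(r, z)
        v_r = br * np.cos(br * r) * np.sin(bz * z)
        lap = -(br**2 + bz**2) * v
        g = (lap / safe_r - v_r / safe_r**2) / eps_hat + k0**2 * v / safe_r
        return np.where(r > 0, g, 0.0)

    return AnalyticCase(
        name="helmholtz_mms",
        params={"forcing": forcing, "eps_hat": eps_hat, "k0": k0},
        evaluate=v_exact,
        tolerance=5e-2,
    )


def make_bioheat_mms_case(
    params: BioheatParams, r_max: float, z_max: float, delta_T: float = 20.0
) -> AnalyticCase:
    """Manufactured steady state of the bioheat operator.

    Exact field T(r, z) = T_b + dT cos(pi r / (2R)) sin(pi z / L): zero
    radial slope on the axis, T = T_b on the outer boundaries (matching the
    solver's default Dirichlet data).  ``params['Q_mms']`` is the heating
    density that makes this the steady solution.
    """
    br = np.pi / (2.0 * r_max)
    bz = np.pi / z_max
    k = params.k_thermal
    P = params.perfusion_coefficient

    def T_exact(r, z):
        return params.T_b + delta_T * np.cos(br * r) * np.sin(bz * z)

    def Q_mms(r, z):
        r = np.asarray(r, dtype=float)
        sz = np.sin(bz * np.asarray(z))
        # (1/r) d/dr(r dT/dr) = -dT [br^2 cos(br r) + br sin(br r)/r]
        sinc_term = br**2 * np.sinc(br * r / np.pi)  # = br sin(br r)/r
        lap = -delta_T * sz * (br**2 * np.cos(br * r) + sinc_term) \
            - bz**2 * delta_T * np.cos(br * r) * sz
        return -k * lap + P * (T_exact(r, z) - params.T_b)

    return AnalyticCase(
        name="bioheat_mms",
        params={"Q_mms": Q_mms, "bioheat": params, "delta_T": delta_T},
        evaluate=T_exact,
        tolerance=2e-2,
    )
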