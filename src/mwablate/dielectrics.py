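"""Frequency-dependent dielectric properties of lung tissue.

Lung tissue changes its microwave dielectric properties with the breathing
cycle: at end-inspiration (inflated) the alveoli are air-filled and both the
relative permittivity and the conductivity drop to roughly half of their
end-expiration (deflated) values.  This module supplies the three property
sets used throughout the package:

* ``inflated`` / ``deflated`` -- 4-term Cole-Cole dispersions (the standard
  Gabriel parameterization of measured tissue spectra),
* ``constant`` -- a frequency-independent baseline (eps_r = 20.5,
  sigma = 0.804 S/m) representing lung properties "regardless of
  respiration"; it coincides with the inflated-lung values at 2.45 GHz.

The engineering time convention ``exp(+j*omega*t)`` is used, so the complex
relative permittivity is ``eps_r - j*sigma/(omega*eps0)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.constants import epsilon_0 as EPS0

__all__ = [
    "TissueState",
    "ColeColeTerm",
    "ColeColeModel",
    "DielectricSample",
    "GABRIEL_LUNG_INFLATED",
    "GABRIEL_LUNG_DEFLATED",
    "CONSTANT_EPS_R",
    "CONSTANT_SIGMA",
    "FREQUENCY_BAND_HZ",
    "evaluate_cole_cole",
    "get_properties",
    "spectrum_table",
]

#: Supported frequency band for tissue property evaluation, Hz.
FREQUENCY_BAND_HZ = (0.5e9, 3.0e9)

#: Constant-baseline lung properties (applied at every frequency).
CONSTANT_EPS_R = 20.5
CONSTANT_SIGMA = 0.804  # S/m


class TissueState(str, Enum):
    """Breathing state selecting which dielectric property set applies."""

    INFLATED = "inflated"
    DEFLATED = "deflated"
    CONSTANT = "constant"


@dataclass(frozen=True)
class ColeColeTerm:
    """One relaxation pole of a Cole-Cole dispersion.

    Parameters
    ----------
    delta_eps : dimensionless dispersion magnitude (>= 0).
    tau_s : relaxation time in seconds (> 0).
    alpha : broadening exponent in [0, 1); alpha = 0 is a pure Debye pole.
    """

    delta_eps: float
    tau_s: float
    alpha: float

    def __post_init__(self) -> None:
        if self.delta_eps < 0:
            raise ValueError(f"delta_eps must be >= 0, got {self.delta_eps}")
        if self.tau_s <= 0:
            raise ValueError(f"tau_s must be > 0, got {self.tau_s}")
        if not 0 <= self.alpha < 1:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")


@dataclass(frozen=True)
class ColeColeModel:
    """Multi-term Cole-Cole dielectric dispersion with an ionic conductivity.

    eps_hat(omega) = eps_inf + sum_i delta_eps_i / (1 + (j*omega*tau_i)**(1-alpha_i))
                     + sigma_ionic / (j*omega*eps0)
    """

    eps_inf: float
    terms: tuple[ColeColeTerm, ...]
    sigma_ionic: float

    def __post_init__(self) -> None:
        if self.eps_inf < 1:
            raise ValueError(f"eps_inf must be >= 1, got {self.eps_inf}")
        if self.sigma_ionic < 0:
            raise ValueError(f"sigma_ionic must be >= 0, got {self.sigma_ionic}")
        object.__setattr__(self, "terms", tuple(self.terms))

    def complex_permittivity(self, frequency_hz):
        """Complex relative permittivity eps_hat = eps' - j*eps'' at ``frequency_hz``."""
        f = np.asarray(frequency_hz, dtype=float)
        if np.any(f <= 0):
            raise ValueError("frequency must be > 0")
        w = 2.0 * np.pi * f
        eps = np.full_like(f, self.eps_inf, dtype=complex)
        for t in self.terms:
            eps = eps + t.delta_eps / (1.0 + (1j * w * t.tau_s) ** (1.0 - t.alpha))
        eps = eps + self.sigma_ionic / (1j * w * EPS0)
        return eps

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "eps_inf": self.eps_inf,
            "sigma_ionic_s_per_m": self.sigma_ionic,
            "terms": [
                {"delta_eps": t.delta_eps, "tau_s": t.tau_s, "alpha": t.alpha}
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ColeColeModel":
        terms = tuple(
            ColeColeTerm(t["delta_eps"], t["tau_s"], t["alpha"]) for t in d["terms"]
        )
        return cls(d["eps_inf"], terms, d["sigma_ionic_s_per_m"])


@dataclass(frozen=True)
class DielectricSample:
    """Relative permittivity and conductivity at a single frequency."""

    frequency_hz: float
    eps_r: float
    sigma: float  # S/m

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be > 0")
        if self.eps_r < 1:
            raise ValueError(f"eps_r must be >= 1, got {self.eps_r}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    def complex_eps_r(self) -> complex:
        """eps_r - j*sigma/(omega*eps0) under the exp(+j*omega*t) convention."""
        w = 2.0 * np.pi * self.frequency_hz
        return self.eps_r - 1j * self.sigma / (w * EPS0)


# Gabriel-style 4-term Cole-Cole fits for lung tissue.  The inflated set
# evaluates to (eps_r, sigma) = (20.48, 0.804 S/m) at 2.45 GHz, matching the
# constant baseline above.
GABRIEL_LUNG_INFLATED = ColeColeModel(
    eps_inf=2.5,
    terms=(
        ColeColeTerm(18.0, 7.958e-12, 0.10),
        ColeColeTerm(500.0, 63.662e-9, 0.10),
        ColeColeTerm(2.5e5, 159.155e-6, 0.20),
        ColeColeTerm(4.0e7, 7.958e-3, 0.00),
    ),
    sigma_ionic=0.03,
)

GABRIEL_LUNG_DEFLATED = ColeColeModel(
    eps_inf=4.0,
    terms=(
        ColeColeTerm(45.0, 7.958e-12, 0.10),
        ColeColeTerm(1000.0, 159.155e-9, 0.10),
        ColeColeTerm(5.0e5, 159.155e-6, 0.20),
        ColeColeTerm(1.0e7, 15.915e-3, 0.00),
    ),
    sigma_ionic=0.20,
)

_STATE_MODELS = {
    TissueState.INFLATED: GABRIEL_LUNG_INFLATED,
    TissueState.DEFLATED: GABRIEL_LUNG_DEFLATED,
}


def evaluate_cole_cole(model: ColeColeModel, frequency_hz: float) -> DielectricSample:
    """Evaluate a Cole-Cole model at one frequency.

    Returns the real relative permittivity ``Re(eps_hat)`` and the total
    conductivity ``-omega*eps0*Im(eps_hat)`` (dielectric loss plus ionic).
    """
    eps_hat = complex(model.complex_permittivity(float(frequency_hz)))
    w = 2.0 * np.pi * float(frequency_hz)
    eps_r = eps_hat.real
    sigma = -w * EPS0 * eps_hat.imag
    if not (np.isfinite(eps_r) and np.isfinite(sigma)):
        raise FloatingPointError("Cole-Cole evaluation produced non-finite values")
    return DielectricSample(float(frequency_hz), eps_r, sigma)


def get_properties(
    state: TissueState | str,
    frequency_hz: float,
    models: dict | None = None,
) -> DielectricSample:
    """Dielectric properties of lung tissue in the given breathing state.

    ``constant`` returns (20.5, 0.804 S/m) at every supported frequency;
    ``inflated``/``deflated`` evaluate the shipped Cole-Cole dispersions
    (override via ``models``, a ``{TissueState: ColeColeModel}`` mapping).

    Raises
    ------
    ValueError
        If ``frequency_hz`` lies outside the supported band [0.5, 3] GHz.
    """
    state = TissueState(state)
    lo, hi = FREQUENCY_BAND_HZ
    if not lo <= frequency_hz <= hi:
        raise ValueError(
            f"frequency {frequency_hz:.4g} Hz outside supported band "
            f"[{lo:.3g}, {hi:.3g}] Hz"
        )
    if state is TissueState.CONSTANT:
        return DielectricSample(frequency_hz, CONSTANT_EPS_R, CONSTANT_SIGMA)
    table = dict(_STATE_MODELS)
    if models:
        table.update({TissueState(k): v for k, v in models.items()})
    return evaluate_cole_cole(table[state], frequency_hz)


def spectrum_table(frequencies_hz, states=tuple(TissueState)) :
    """Sampled spectra as a tidy DataFrame (frequency_hz, state, eps_r, sigma_s_per_m)."""
    import pandas as pd

    rows = []
    for state in states:
        state = TissueState(state)
        for f in np.asarray(frequencies_hz, dtype=float):
            s = get_properties(state, f)
            rows.append(
                {
                    "frequency_hz": f,
                    "state": state.value,
                    "eps_r": s.eps_r,
                    "sigma_s_per_m": s.sigma,
                }
            )
    return pd.DataFrame(rows)
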