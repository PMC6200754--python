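"""Dissipation rates, thermal occupation, and the decoherence-rate rule.

Each transition at angular frequency omega_q couples to the bosonic bath
with a cubic-frequency (free-space radiative) rate

    gamma_q = omega_q^3 |d|^2 / (3 eps0 pi hbar c^3),

where d is a transition dipole moment.  Spontaneous emission alone would be
astronomically slow at radio frequencies; what makes the channel relevant at
physiological temperature is the thermal occupation N(omega) = 1/(e^{hbar
omega / kB T} - 1), which at 300 K and MHz frequencies is ~1e5-1e6, so both
the emission (gamma_q (N+1)) and absorption (gamma_q N) dissipators are
thermally dominated.

The zero-frequency (decoherence) channel is assigned a rate gamma_D at
least ten times the largest dissipation rate in the run.

The default dipole moment is calibrated once so that the cubic law maps the
model's frequency window onto the rate window it is meant to produce:
gamma = 1e-3 s^-1 at omega/2pi = 1e8 Hz (see :func:`calibrate_dipole`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import c, epsilon_0, hbar, k as k_B, pi

from .eigenoperators import TransitionSet
from .hamiltonians import SystemSpec

__all__ = [
    "RateTable",
    "dissipation_rate",
    "planck_occupation",
    "calibrate_dipole",
    "DEFAULT_DIPOLE_CM",
    "build_rate_table",
]

_RATE_PREFACTOR = 1.0 / (3.0 * epsilon_0 * pi * hbar * c**3)


def dissipation_rate(omega: float | np.ndarray, d: float) -> float | np.ndarray:
    """Cubic-law rate gamma(omega) in s^-1; omega in rad/s, d in C m."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be nonnegative")
    out = omega**3 * _RATE_PREFACTOR * d**2
    return float(out) if out.ndim == 0 else out


def planck_occupation(omega: float | np.ndarray, temperature: float) -> float | np.ndarray:
    """Mean thermal boson number 1/(e^{hbar omega/kB T} - 1).

    omega in rad/s (the Boltzmann exponent is hbar*omega/kB*T; with
    hbar = 1 conventions this is the usual beta*omega).  omega = 0 is
    rejected: zero-frequency terms belong to the decoherence channel.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be positive (route omega=0 to decoherence)")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    x = hbar * omega / (k_B * temperature)
    out = 1.0 / np.expm1(x)
    return float(out) if out.ndim == 0 else out


def calibrate_dipole(gamma_at: float = 1e-3, omega_at_hz: float = 1e8) -> float:
    """Invert the cubic law for |d|: the dipole magnitude (C m) that yields
    ``gamma_at`` (s^-1) at ordinary frequency ``omega_at_hz`` (Hz)."""
    if gamma_at <= 0 or omega_at_hz <= 0:
        raise ValueError("anchor point must be positive")
    omega = 2 * pi * omega_at_hz
    return float(np.sqrt(gamma_at / (omega**3 * _RATE_PREFACTOR)))


#: default transition dipole (C m): anchored so gamma(2pi * 1e8 Hz) = 1e-3 s^-1
DEFAULT_DIPOLE_CM = calibrate_dipole()


@dataclass(frozen=True)
class RateTable:
    """Per-frequency dissipation rates and occupations, plus gamma_D."""

    omegas: np.ndarray  # rad/s, ascending, distinct
    gammas: np.ndarray  # s^-1
    n_thermal: np.ndarray  # dimensionless
    gamma_d: float  # s^-1
    temperature: float  # K
    dipole_moment: float  # C m

    def lookup(self, omega: float, rel_tol: float = 1e-6) -> tuple[float, float]:
        """(gamma_q, N_thermal) for the table frequency nearest ``omega``."""
        idx = int(np.argmin(np.abs(self.omegas - omega)))
        if abs(self.omegas[idx] - omega) > rel_tol * max(abs(omega), 1.0):
            raise KeyError(f"frequency {omega} not in rate table")
        return float(self.gammas[idx]), float(self.n_thermal[idx])


def build_rate_table(
    ts_list: list[TransitionSet] | TransitionSet,
    spec: SystemSpec,
    decoherence_factor: float = 10.0,
) -> RateTable:
    """Rates and occupations for every distinct frequency across the given
    transition sets, with gamma_D = decoherence_factor * max(gamma_q).

    ``decoherence_factor`` below 10 is rejected: the decoherence rate is
    taken to be at least ten times the largest dissipation rate.
    """
    if decoherence_factor < 10.0:
        raise ValueError("decoherence_factor must be >= 10")
    if isinstance(ts_list, TransitionSet):
        ts_list = [ts_list]
    freqs = np.concatenate([ts.frequencies for ts in ts_list if ts.transitions])
    if freqs.size == 0:
        raise ValueError("no transitions supplied")
    freqs = np.unique(freqs)
    d = spec.dipole_moment_cm if spec.dipole_moment_cm is not None else DEFAULT_DIPOLE_CM
    gammas = dissipation_rate(freqs, d)
    n_th = planck_occupation(freqs, spec.temperature_k)
    return RateTable(
        omegas=freqs,
        gammas=np.atleast_1d(gammas),
        n_thermal=np.atleast_1d(n_th),
        gamma_d=float(decoherence_factor * np.max(gammas)),
        temperature=spec.temperature_k,
        dipole_moment=d,
    )
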