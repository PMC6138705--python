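"""Closed-form electromagnetic references used to verify the solver.

These expressions never enter the time stepping; they serve as independent
oracles for the verification suite:

* the exact Hertzian-dipole near+far field in vacuum,
* the plane-wave attenuation constant of a lossy dielectric.
"""
from __future__ import annotations

import cmath
import math

import numpy as np
from scipy.constants import c as C0, epsilon_0, mu_0

from ..errors import DomainError

ETA0 = math.sqrt(mu_0 / epsilon_0)


def analytic_attenuation_constant(frequency: float, eps_r: float, sigma: float) -> float:
    """Plane-wave amplitude attenuation constant alpha (1/m).

    For a medium with permittivity eps = eps0 eps_r and conductivity sigma,

        alpha = omega sqrt(mu eps / 2) sqrt( sqrt(1 + (sigma/(omega eps))^2) - 1 ).
    """
    if frequency <= 0.0:
        raise DomainError("frequency must be positive")
    if eps_r < 1.0 or sigma < 0.0:
        raise DomainError("need eps_r >= 1 and sigma >= 0")
    omega = 2.0 * math.pi * frequency
    eps = epsilon_0 * eps_r
    loss_tan = sigma / (omega * eps)
    return omega * math.sqrt(mu_0 * eps / 2.0) * math.sqrt(math.sqrt(1.0 + loss_tan**2) - 1.0)


def analytic_phase_constant(frequency: float, eps_r: float, sigma: float) -> float:
    """Plane-wave phase constant beta (rad/m) of the same lossy medium."""
    omega = 2.0 * math.pi * frequency
    eps = epsilon_0 * eps_r
    loss_tan = sigma / (omega * eps)
    return omega * math.sqrt(mu_0 * eps / 2.0) * math.sqrt(math.sqrt(1.0 + loss_tan**2) + 1.0)


def complex_wavenumber(frequency: float, eps_r: float, sigma: float) -> complex:
    """k = omega sqrt(mu0 eps_c) with eps_c = eps0 eps_r - j sigma/omega.

    Independent route to (beta, alpha) = (Re k, -Im k) used to cross-check
    the closed forms above.
    """
    omega = 2.0 * math.pi * frequency
    eps_c = epsilon_0 * eps_r - 1j * sigma / omega
    k = omega * cmath.sqrt(mu_0 * eps_c)
    if k.imag > 0:
        k = -k
    return k


def hertzian_dipole_phasor(
    r: float, theta: float, current_moment: float, frequency: float
) -> tuple[complex, complex, complex]:
    """Phasor (E_r, E_theta, H_phi) of a z-directed Hertzian dipole in vacuum.

    ``current_moment`` is I0*dl in A*m; the ``exp(+j omega t)`` convention is
    used, so time-domain fields are ``Re(phasor * exp(j omega t))``.
    """
    if r <= 0.0:
        raise DomainError("observation point must be distinct from the dipole")
    k = 2.0 * math.pi * frequency / C0
    kr = k * r
    ikr = 1j * kr
    e_r = (
        ETA0 * current_moment * math.cos(theta) / (2.0 * math.pi * r**2)
        * (1.0 + 1.0 / ikr) * cmath.exp(-ikr)
    )
    e_t = (
        1j * ETA0 * k * current_moment * math.sin(theta) / (4.0 * math.pi * r)
        * (1.0 + 1.0 / ikr - 1.0 / kr**2) * cmath.exp(-ikr)
    )
    h_p = (
        1j * k * current_moment * math.sin(theta) / (4.0 * math.pi * r)
        * (1.0 + 1.0 / ikr) * cmath.exp(-ikr)
    )
    return e_r, e_t, h_p


def analytic_dipole_field(
    observation: np.ndarray | tuple[float, float, float],
    t: float,
    current_moment: float,
    frequency: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous (E, H) of a steady-state sinusoidal dipole at the origin.

    The dipole is z-directed with current ``I(t) = I0 sin(omega t)`` and
    moment ``current_moment = I0 * dl``.  Returns Cartesian field vectors at
    the observation point (metres) and time ``t`` (seconds).
    """
    obs = np.asarray(observation, dtype=float)
    r = float(np.linalg.norm(obs))
    if r == 0.0:
        raise DomainError("observation point must be distinct from the dipole")
    theta = math.acos(obs[2] / r)
    phi = math.atan2(obs[1], obs[0])
    e_r, e_t, h_p = hertzian_dipole_phasor(r, theta, current_moment, frequency)
    # I(t) = I0 sin(omega t) = Re(-j I0 exp(j omega t)); carry the -j here.
    omega = 2.0 * math.pi * frequency
    rot = -1j * cmath.exp(1j * omega * t)
    er_t = (e_r * rot).real
    et_t = (e_t * rot).real
    hp_t = (h_p * rot).real
    r_hat = obs / r
    t_hat = np.array(
        [
            math.cos(theta) * math.cos(phi),
            math.cos(theta) * math.sin(phi),
            -math.sin(theta),
        ]
    )
    p_hat = np.array([-math.sin(phi), math.cos(phi), 0.0])
    return er_t * r_hat + et_t * t_hat, hp_t * p_hat


def dipole_field_amplitude(
    observation: np.ndarray | tuple[float, float, float],
    current_moment: float,
    frequency: float,
) -> float:
    """Steady-state |E| amplitude envelope of the sinusoidal dipole."""
    obs = np.asarray(observation, dtype=float)
    r = float(np.linalg.norm(obs))
    if r == 0.0:
        raise DomainError("observation point must be distinct from the dipole")
    theta = math.acos(obs[2] / r)
    e_r, e_t, _ = hertzian_dipole_phasor(r, theta, current_moment, frequency)
    # E_r and E_theta are orthogonal polarizations; the peak of the elliptical
    # trajectory over a cycle:
    exx, eyy = abs(e_r), abs(e_t)
    ph = cmath.phase(e_t) - cmath.phase(e_r) if exx > 0 else 0.0
    # semi-major axis of the polarization ellipse
    s = exx**2 + eyy**2
    d = math.sqrt(
        (exx**2 - eyy**2) ** 2 + (2 * exx * eyy * math.cos(ph)) ** 2
    )
    return math.sqrt(0.5 * (s + d))
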