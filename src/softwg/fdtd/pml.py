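"""Perfectly-matched-layer coefficient profiles.

The absorber is the stretched-coordinate PML in its convolutional
(recursive-accumulator) form: each spatial derivative entering a curl inside
a boundary slab gains an auxiliary accumulator ``psi`` updated as
``psi <- b psi + c (d/dx)``, with ``b = exp(-sigma_pml dt / eps0)`` and
``c = b - 1`` (stretch factor kappa = 1, no complex-frequency shift).  The
PML conductivity is graded polynomially from zero at the interface to

    sigma_max = (order + 1) * (-ln r0) * eps0 * c0 / (2 * thickness * dx)

at the outer wall, the standard choice for a target normal-incidence
reflection ``r0``.  Electric-field accumulators sample the profile at
integer positions, magnetic ones at half-integer positions.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.constants import c as C0, epsilon_0

from .grid import PmlSpec


def _sigma_profile(positions: np.ndarray, n: int, npml: int, sigma_max: float, order: int):
    """PML conductivity at fractional cell positions along one axis."""
    sig = np.zeros_like(positions)
    if npml <= 0:
        return sig
    left = positions < npml
    sig[left] = sigma_max * ((npml - positions[left]) / npml) ** order
    right = positions > n - 1 - npml
    sig[right] = sigma_max * ((positions[right] - (n - 1 - npml)) / npml) ** order
    return sig


def cpml_coefficients(
    n: int, dx: float, dt: float, pml: PmlSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(b_e, c_e, b_h, c_h) recursion coefficients along an axis of n cells.

    Outside the slabs b = 1 and c = 0, so the accumulators stay identically
    zero there and the update reduces to the plain Yee scheme.
    """
    if pml.thickness == 0:
        ones = np.ones(n)
        zeros = np.zeros(n)
        return ones, zeros, ones.copy(), zeros.copy()
    sigma_max = (
        (pml.order + 1) * (-math.log(pml.r0)) * epsilon_0 * C0 / (2.0 * pml.thickness * dx)
    )
    pos_e = np.arange(n, dtype=float)
    pos_h = pos_e + 0.5
    sig_e = _sigma_profile(pos_e, n, pml.thickness, sigma_max, pml.order)
    sig_h = _sigma_profile(pos_h, n, pml.thickness, sigma_max, pml.order)
    b_e = np.exp(-sig_e * dt / epsilon_0)
    b_h = np.exp(-sig_h * dt / epsilon_0)
    c_e = np.where(sig_e > 0.0, b_e - 1.0, 0.0)
    c_h = np.where(sig_h > 0.0, b_h - 1.0, 0.0)
    return b_e, c_e, b_h, c_h
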