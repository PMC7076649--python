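"""Pressure-augmented dynamic free energy of a tagged particle.

The dynamic free energy (in kB T, displacements in units of d) is

    Fdyn(r) = - int_0^inf dq  q^2 [S(q)-1]^2 / (12 pi phi [1+S(q)])
                              * exp(-q^2 r^2 (S(q)+1) / (6 S(q)))
              - 3 ln(r)  +  P* r

The first (structural) term encodes caging by nearest neighbours, the
logarithm is the ideal delocalizing entropy, and the linear term is the
mechanical work P dV with dV ~ r d^2 done against the external pressure
P* (units kB T / d^3).  A local minimum at r_L (localization length) and
maximum at r_B (barrier position) exist only in sufficiently dense or
compressed states; their absence is reported as :class:`NoBarrierError`.

Derivatives of Fdyn are taken analytically under the integral sign; the
q-integral is a trapezoid on the structure grid (the integrand decays as
a Gaussian in q r and as [S-1]^2 at large q, so the tail beyond the grid
cutoff is negligible).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, NoBarrierError
from .structure import FluidState, StructureTables

#: lower edge of the displacement search window (units d)
R_MIN = 1e-3

#: barriers smaller than this (kB T) are treated as absent
FB_FLOOR = 1e-10


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Extrema and curvatures of the dynamic free-energy landscape."""

    phi: float
    pstar: float
    r_grid: np.ndarray = field(repr=False)
    f_of_r: np.ndarray = field(repr=False)
    r_loc: float        #: localization length r_L (units d)
    r_barrier: float    #: barrier position r_B (units d)
    f_barrier: float    #: local barrier F_B = F(r_B) - F(r_L) (kB T)
    k0: float           #: curvature at r_L (kB T / d^2), harmonic spring constant
    kb_curv: float      #: absolute curvature at r_B (kB T / d^2)

    @property
    def jump(self) -> float:
        """Jump distance dr = r_B - r_L (units d)."""
        return self.r_barrier - self.r_loc


def _integrand_weights(structure: StructureTables):
    """Per-q weight w(q) and Gaussian decay rate a(q) of the structural term."""
    q = structure.q_grid
    s = structure.s_of_q
    phi = structure.phi
    w = q**2 * (s - 1.0) ** 2 / (12.0 * np.pi * phi * (1.0 + s))
    a = q**2 * (s + 1.0) / (3.0 * s)  # exponent is -a r^2 / 2
    return q, w, a


def _structural_terms(r, structure: StructureTables, order: int = 0):
    """Trapezoid quadrature of the structural term and its r-derivatives.

    order 0: F_struct(r); 1: dF/dr; 2: d^2F/dr^2.  Vectorized over r.
    """
    q, w, a = _integrand_weights(structure)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    out = np.empty(r.shape)
    for lo in range(0, r.size, 2048):  # bound the (n_r, n_q) work array
        rb = r[lo : lo + 2048, None]
        e = np.exp(-0.5 * a[None, :] * rb**2)
        # the structural (caging) contribution is attractive: -int w exp(-a r^2/2)
        if order == 0:
            integ = -w[None, :] * e
        elif order == 1:
            integ = w[None, :] * a[None, :] * rb * e
        elif order == 2:
            integ = -w[None, :] * (a[None, :] ** 2 * rb**2 - a[None, :]) * e
        else:  # pragma: no cover
            raise ValueError(order)
        out[lo : lo + 2048] = np.trapezoid(integ, q, axis=1)
    return out


def dynamic_free_energy(r, state: FluidState, structure: StructureTables):
    """Fdyn(r) in kB T; ``r`` in units of d (scalar or array)."""
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r_arr <= 0):
        raise DomainError("displacement r must be > 0 (log divergence at 0)")
    out = _structural_terms(r_arr, structure) - 3.0 * np.log(r_arr) + state.pstar * r_arr
    return float(out[0]) if np.ndim(r) == 0 else out


def free_energy_gradient(r, state: FluidState, structure: StructureTables):
    """dFdyn/dr in kB T / d, analytic."""
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r_arr <= 0):
        raise DomainError("displacement r must be > 0")
    out = _structural_terms(r_arr, structure, order=1) - 3.0 / r_arr + state.pstar
    return float(out[0]) if np.ndim(r) == 0 else out


def free_energy_curvature(r, state: FluidState, structure: StructureTables):
    """d^2 Fdyn/dr^2 in kB T / d^2, analytic."""
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r_arr <= 0):
        raise DomainError("displacement r must be > 0")
    out = _structural_terms(r_arr, structure, order=2) + 3.0 / r_arr**2
    return float(out[0]) if np.ndim(r) == 0 else out


def locate_extrema(
    state: FluidState,
    structure: StructureTables,
    n_scan: int = 200,
) -> FreeEnergyProfile:
    """Locate the minimum/maximum pair of the dynamic free energy.

    Sign changes of the analytic gradient are bracketed on a log-spaced
    grid in [1e-3 d, r_cage] and refined by Brent's method; curvatures
    come from the analytic second derivative.

    Raises
    ------
    NoBarrierError
        If no interior minimum-maximum pair exists (fluid regime) or the
        barrier is degenerate (F_B < 1e-10 kB T).
    """
    if abs(structure.phi - state.phi) > 1e-9:
        raise DomainError("structure tables were computed at a different phi")
    r_scan = np.geomspace(R_MIN, structure.r_cage, n_scan)
    grad = free_energy_gradient(r_scan, state, structure)

    sign = np.sign(grad)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if flips.size < 2:
        raise NoBarrierError(state.phi, state.pstar)

    gfun = lambda x: free_energy_gradient(x, state, structure)
    roots = [brentq(gfun, r_scan[i], r_scan[i + 1], xtol=1e-12, rtol=1e-14) for i in flips[:2]]
    r_loc, r_barrier = roots
    if not (grad[flips[0]] < 0 < grad[flips[0] + 1]):
        # first flip must be a minimum (gradient - to +)
        raise NoBarrierError(state.phi, state.pstar)

    f_loc, f_bar = dynamic_free_energy(np.array([r_loc, r_barrier]), state, structure)
    f_barrier = f_bar - f_loc
    k0 = free_energy_curvature(r_loc, state, structure)
    kb = -free_energy_curvature(r_barrier, state, structure)
    if f_barrier < FB_FLOOR or k0 <= 0 or kb <= 0:
        raise NoBarrierError(state.phi, state.pstar, "degenerate landscape")

    f_grid = dynamic_free_energy(r_scan, state, structure)
    return FreeEnergyProfile(
        phi=state.phi,
        pstar=state.pstar,
        r_grid=r_scan,
        f_of_r=f_grid,
        r_loc=float(r_loc),
        r_barrier=float(r_barrier),
        f_barrier=float(f_barrier),
        k0=float(k0),
        kb_curv=float(kb),
    )
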