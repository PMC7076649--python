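"""Collective elastic barrier from cage dilation.

A cage-escape hop of amplitude dr dilates the first coordination shell
by a small amount dr_eff; continuum mechanics then gives a purely radial
displacement field u(r) = dr_eff (r_cage/r)^2 outside the cage.  Each
displaced particle sits in a harmonic well of spring constant K0 (the
curvature of the dynamic free energy at its localization length), and
summing K0 u^2 / 2 over the surroundings yields the collective elastic
barrier Fe.  With g(r) ~ 1 outside the cage the integral is elementary:

    Fe = 2 pi rho d^3 K0 dr_eff^2 r_cage^3   (kB T)

The local-nonlocal coupling ac that rescales Fe -> ac^2 Fe lives in the
kinetics layer; Fe returned here is bare.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.integrate import quad

from .errors import DomainError
from .structure import FluidState


@dataclass(frozen=True)
class ElasticBarrier:
    """Cage-expansion amplitude and the bare collective barrier."""

    delta_r_eff: float  #: cage expansion amplitude (units d)
    fe: float           #: bare elastic barrier (kB T)
    r_cage: float       #: cage radius used (units d)
    k0: float           #: harmonic spring constant used (kB T / d^2)


def cage_expansion_amplitude(r_cage: float, jump: float) -> float:
    """Amplitude of the cage-surface expansion driven by a hop of length ``jump``.

        dr_eff = (3 / r_cage^3) [ r_cage^2 jump^2 / 32
                                  - r_cage jump^3 / 192 + jump^4 / 3072 ]

    Valid in the harmonic regime jump <~ 6 r_cage where the bracket is
    non-negative.
    """
    if r_cage <= 0:
        raise DomainError(f"r_cage must be > 0, got {r_cage}")
    if jump < 0:
        raise DomainError(f"jump distance must be >= 0, got {jump}")
    if jump > 6.0 * r_cage:
        # the quartic bracket is positive-definite, so validity must be
        # enforced explicitly: hops larger than the cage itself are far
        # outside the small-dilation expansion
        raise DomainError(
            f"jump={jump:g} exceeds the harmonic regime for r_cage={r_cage:g}"
        )
    bracket = (
        r_cage**2 * jump**2 / 32.0
        - r_cage * jump**3 / 192.0
        + jump**4 / 3072.0
    )
    return 3.0 / r_cage**3 * bracket


def displacement_field(r, r_cage: float, delta_r_eff: float):
    """Radial elastic displacement u(r) = dr_eff (r_cage / r)^2, r >= r_cage."""
    if r_cage <= 0 or delta_r_eff < 0:
        raise DomainError("r_cage must be > 0 and delta_r_eff >= 0")
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < r_cage):
        raise DomainError("displacement field is undefined inside the cage (r < r_cage)")
    out = delta_r_eff * r_cage**2 / r_arr**2
    return out if out.ndim else float(out)


def elastic_barrier(
    state: FluidState,
    k0: float,
    delta_r_eff: float,
    r_cage: float,
    g_of_r=None,
    r_grid=None,
) -> float:
    """Bare collective elastic barrier Fe in kB T.

    By default uses the closed form ``2 pi rho d^3 K0 dr_eff^2 r_cage^3``
    (the g = 1 simplification of the shell sum, exact for the inverse-
    square field).  Passing tabulated ``g_of_r``/``r_grid`` reinstates
    g(r) under the integral (numerical quadrature to 200 r_cage) for
    sensitivity studies.
    """
    if k0 < 0 or delta_r_eff < 0 or r_cage <= 0:
        raise DomainError("k0, delta_r_eff must be >= 0 and r_cage > 0")
    rho = state.rho_reduced
    if g_of_r is None:
        return 2.0 * np.pi * rho * k0 * delta_r_eff**2 * r_cage**3
    from scipy.interpolate import interp1d

    g_interp = interp1d(r_grid, g_of_r, bounds_error=False, fill_value=1.0)
    integrand = lambda r: r**2 * g_interp(r) * 0.5 * k0 * (delta_r_eff * r_cage**2 / r**2) ** 2
    val, _ = quad(integrand, r_cage, 200.0 * r_cage, limit=400)
    return 4.0 * np.pi * rho * val


def build_elastic_barrier(state: FluidState, k0: float, jump: float, r_cage: float) -> ElasticBarrier:
    """Convenience wrapper: amplitude from the hop, then the closed-form Fe."""
    dre = cage_expansion_amplitude(r_cage, jump)
    if dre > 0.1 * r_cage:
        warnings.warn(
            f"delta_r_eff/r_cage = {dre / r_cage:.3f} > 0.1: harmonic "
            "treatment of the surroundings is marginal",
            stacklevel=2,
        )
    fe = elastic_barrier(state, k0, dre, r_cage)
    return ElasticBarrier(delta_r_eff=dre, fe=fe, r_cage=r_cage, k0=k0)
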