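"""Relaxation times, thermal mapping, Tg/Pg solvers and parameter fitting.

The structural (alpha) relaxation time follows Kramers' mean first-
passage rate over the total barrier -- local (F_B) plus collective
elastic rescaled by the local-nonlocal coupling (ac^2 Fe):

    tau_alpha / tau_s = 1 + (2 pi / sqrt(K0 KB)) exp(F_B + ac^2 Fe)

with curvatures in kB T / d^2 (the kB T / d^2 factor of the printed
prefactor is unity in reduced units).  The Johari-Goldstein beta process
is the same hop over the local barrier alone (Fe omitted), so
tau_beta <= tau_alpha always.  The short time scale tau_s measures
binary-collision-renormalized dynamics on the cage scale:

    tau_s = g(d)^2 tau_E [1 + (1/36 pi phi) int dq q^2 (S-1)^2/(S + b(q))]

with b(q) = 1/(1 - j0(q) + 2 j2(q)) and tau_E ~ 1e-13 s the Enskog time.

Temperature enters only through the linear thermal mapping

    T = T0 - (phi - phi0) / (beta phi0)

between hard-sphere volume fraction and laboratory temperature, with
beta the volume thermal expansion coefficient (glass/liquid value for
the alpha process at all pressures; a crystal-like value for the beta
process under compression, since an in-cage rattler expands like a
lattice vibration, not like a flowing liquid).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.constants import k as KB_J
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, least_squares
from scipy.special import spherical_jn

from .elastic import build_elastic_barrier
from .errors import ConfigurationError, DomainError, FitError, NoBarrierError, RangeError
from .free_energy import FreeEnergyProfile, locate_extrema
from .structure import (
    DEFAULT_NQ,
    DEFAULT_Q_MAX,
    FluidState,
    StructureTables,
    compute_structure,
    contact_value,
    structure_factor,
)

#: Enskog collision time for molecular amorphous materials (seconds)
TAU_E = 1e-13

LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# materials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialModel:
    """Per-drug constants of the thermal mapping and barrier coupling.

    Parameters
    ----------
    name : str
        Label.
    t0 : float
        Reference temperature of the thermal mapping (K).
    ac : float
        Local-nonlocal coupling; rescales the elastic barrier Fe -> ac^2 Fe.
    tg_threshold : float
        Relaxation time defining Tg / Pg (seconds).
    beta_glass : float
        Volume thermal expansion coefficient of the supercooled liquid /
        glass (1/K); ~12e-4 for organic materials.
    beta_crystal : float or None
        Crystal-state coefficient used for the beta-process mapping under
        compression; typically 2-4x smaller than ``beta_glass``.
    phi0 : float
        Characteristic volume fraction of the mapping.
    """

    name: str
    t0: float
    ac: float
    tg_threshold: float = 100.0
    beta_glass: float = 12e-4
    beta_crystal: float | None = None
    phi0: float = 0.5

    def __post_init__(self):
        if self.t0 <= 0 or self.ac < 0 or self.tg_threshold <= 0:
            raise DomainError("require t0 > 0, ac >= 0, tg_threshold > 0")
        if not (0 < self.phi0 < 0.64):
            raise DomainError("phi0 must lie in (0, 0.64)")
        if self.beta_crystal is not None and self.beta_crystal >= self.beta_glass:
            raise DomainError("beta_crystal must be smaller than beta_glass")


MATERIALS: dict[str, MaterialModel] = {
    "curcumin": MaterialModel("curcumin", t0=518.6, ac=1.0, tg_threshold=100.0),
    "glibenclamide": MaterialModel("glibenclamide", t0=525.0, ac=0.9, tg_threshold=1.0),
    "indomethacin": MaterialModel("indomethacin", t0=476.0, ac=1.5, tg_threshold=100.0),
}


def get_material(name_or_path: str) -> MaterialModel:
    """Look up a registry material or load one from a YAML config file."""
    if name_or_path in MATERIALS:
        return MATERIALS[name_or_path]
    path = Path(name_or_path)
    if path.exists():
        cfg = yaml.safe_load(path.read_text())
        if not isinstance(cfg, dict):
            raise ConfigurationError(f"malformed material config: {name_or_path}")
        try:
            return MaterialModel(**cfg)
        except TypeError as exc:
            raise ConfigurationError(f"bad material config fields: {exc}") from exc
    raise ConfigurationError(
        f"unknown material {name_or_path!r}; known: {sorted(MATERIALS)}"
    )


@dataclass(frozen=True)
class Timescales:
    """The hierarchy of relaxation times at one state point (seconds)."""

    tau_e: float
    tau_s: float
    tau_alpha: float
    tau_beta: float


# ---------------------------------------------------------------------------
# elementary kinetics
# ---------------------------------------------------------------------------

def _nonhydro_b(q):
    """b(q) = 1 / (1 - j0(q) + 2 j2(q)) of the binary-collision vertex."""
    return 1.0 / (1.0 - spherical_jn(0, q) + 2.0 * spherical_jn(2, q))


def short_time_scale(state: FluidState, structure: StructureTables | None = None) -> float:
    """tau_s / tau_E, the dimensionless short-time scale.

    If no structure tables are supplied, S(q) is evaluated analytically
    on the default wavevector grid (the cage radius is not needed here,
    so arbitrarily dilute states are allowed).
    """
    phi = state.phi
    if phi == 0.0:
        return 1.0
    if structure is not None:
        q, s = structure.q_grid, structure.s_of_q
    else:
        q = (DEFAULT_Q_MAX / DEFAULT_NQ) * np.arange(1, DEFAULT_NQ + 1)
        s = structure_factor(q, phi)
    b = _nonhydro_b(q)
    integral = np.trapezoid(q**2 * (s - 1.0) ** 2 / (s + b), q)
    return contact_value(phi) ** 2 * (1.0 + integral / (36.0 * np.pi * phi))


def _barrier_pieces(state: FluidState, structure: StructureTables):
    """(log10 tau_s [s], ln-prefactor, F_B, bare Fe) at one state point."""
    profile = locate_extrema(state, structure)
    eb = build_elastic_barrier(state, profile.k0, profile.jump, structure.r_cage)
    log10_tau_s = np.log10(TAU_E) + np.log10(short_time_scale(state, structure))
    ln_pref = np.log(2.0 * np.pi) - 0.5 * np.log(profile.k0 * profile.kb_curv)
    return log10_tau_s, ln_pref, profile.f_barrier, eb.fe, profile


def _compose_log10_tau(log10_tau_s, ln_pref, barrier):
    """log10 of tau_s (1 + prefactor e^barrier), overflow-safe."""
    return log10_tau_s + np.logaddexp(0.0, ln_pref + barrier) / LN10


def compute_timescales(
    state: FluidState, structure: StructureTables, material: MaterialModel
) -> Timescales:
    """All four relaxation times (seconds) at one state point."""
    lts, lp, fb, fe, _ = _barrier_pieces(state, structure)
    la = _compose_log10_tau(lts, lp, fb + material.ac**2 * fe)
    lb = _compose_log10_tau(lts, lp, fb)
    return Timescales(
        tau_e=TAU_E, tau_s=10.0**lts, tau_alpha=10.0**la, tau_beta=10.0**lb
    )


def alpha_time(state: FluidState, structure: StructureTables, material: MaterialModel) -> float:
    """Structural relaxation time tau_alpha in seconds."""
    return compute_timescales(state, structure, material).tau_alpha


def beta_time(state: FluidState, structure: StructureTables) -> float:
    """Johari-Goldstein beta relaxation time in seconds (no elastic term)."""
    lts, lp, fb, _, _ = _barrier_pieces(state, structure)
    return 10.0 ** _compose_log10_tau(lts, lp, fb)


# ---------------------------------------------------------------------------
# thermal mapping and unit conversion
# ---------------------------------------------------------------------------

def _mapping_coefficient(
    material: MaterialModel, which: str, pstar: float, override: float | None
) -> float:
    if override is not None:
        return override
    if which == "alpha":
        return material.beta_glass  # mapping held pressure-independent
    if which == "beta":
        if pstar > 0:
            if material.beta_crystal is None:
                raise ConfigurationError(
                    "beta-process mapping under compression needs beta_crystal"
                )
            return material.beta_crystal
        return material.beta_glass
    raise DomainError(f"which must be 'alpha' or 'beta', got {which!r}")


def thermal_map(
    phi: float,
    material: MaterialModel,
    which: str = "alpha",
    pstar: float = 0.0,
    expansion_coefficient: float | None = None,
) -> float:
    """Temperature (K) for a volume fraction: T = T0 - (phi - phi0)/(beta phi0)."""
    beta = _mapping_coefficient(material, which, pstar, expansion_coefficient)
    return material.t0 - (phi - material.phi0) / (beta * material.phi0)


def phi_from_temperature(
    temperature: float,
    material: MaterialModel,
    which: str = "alpha",
    pstar: float = 0.0,
    expansion_coefficient: float | None = None,
) -> float:
    """Inverse of :func:`thermal_map` (exact)."""
    beta = _mapping_coefficient(material, which, pstar, expansion_coefficient)
    return material.phi0 + beta * material.phi0 * (material.t0 - temperature)


def extract_diameter(pstar: float, p_si: float, temperature: float) -> float:
    """Molecular diameter d (nm) from P* d^3 = P / (kB T).

    Equating a theoretical reduced pressure ``pstar`` (kB T / d^3) with
    a laboratory pressure ``p_si`` (MPa) at temperature T fixes the only
    length scale of the hard-sphere model:
    d = (pstar kB T / P)^(1/3).
    """
    if pstar <= 0:
        raise DomainError("pstar must be > 0: no length scale is recoverable at P*=0")
    if p_si <= 0 or temperature <= 0:
        raise DomainError("pressure and temperature must be > 0")
    d_m = (pstar * KB_J * temperature / (p_si * 1e6)) ** (1.0 / 3.0)
    return d_m * 1e9


# ---------------------------------------------------------------------------
# isobar model: tau(phi) along one reduced pressure
# ---------------------------------------------------------------------------

class IsobarModel:
    """Material-independent barrier/timescale table along one isobar.

    Precomputes log10 tau_s, the Kramers ln-prefactor, F_B and the bare
    Fe on a volume-fraction grid at fixed reduced pressure, and exposes
    cubic-spline-smooth relaxation times for any material (which enters
    only through ac and the thermal mapping).
    """

    def __init__(
        self,
        pstar: float,
        phi_min: float = 0.50,
        phi_max: float = 0.623,
        n_phi: int = 50,
    ):
        self.pstar = float(pstar)
        phis = np.linspace(phi_min, phi_max, n_phi)
        rows = []
        for phi in phis:
            structure = compute_structure(phi)
            try:
                lts, lp, fb, fe, _ = _barrier_pieces(FluidState(phi, self.pstar), structure)
            except NoBarrierError:
                continue
            rows.append((phi, lts, lp, fb, fe))
        if len(rows) < 4:
            raise NoBarrierError(phi_min, self.pstar, "isobar window has no barrier regime")
        arr = np.array(rows)
        self.phi_grid = arr[:, 0]
        self._lts = CubicSpline(arr[:, 0], arr[:, 1])
        self._lp = CubicSpline(arr[:, 0], arr[:, 2])
        self._fb = CubicSpline(arr[:, 0], arr[:, 3])
        self._fe = CubicSpline(arr[:, 0], arr[:, 4])

    @property
    def phi_min(self) -> float:
        return float(self.phi_grid[0])

    @property
    def phi_max(self) -> float:
        return float(self.phi_grid[-1])

    def _check(self, phi):
        phi = np.asarray(phi, dtype=float)
        if np.any(phi < self.phi_min - 1e-12) or np.any(phi > self.phi_max + 1e-12):
            raise RangeError(
                f"phi outside tabulated isobar window [{self.phi_min:.4f}, {self.phi_max:.4f}]"
            )
        return phi

    def log10_tau_alpha(self, phi, ac: float):
        phi = self._check(phi)
        out = _compose_log10_tau(
            self._lts(phi), self._lp(phi), self._fb(phi) + ac**2 * self._fe(phi)
        )
        return float(out) if out.ndim == 0 else out

    def log10_tau_beta(self, phi):
        phi = self._check(phi)
        out = _compose_log10_tau(self._lts(phi), self._lp(phi), self._fb(phi))
        return float(out) if out.ndim == 0 else out

    def phi_at_log10_tau_alpha(self, target: float, ac: float) -> float:
        """Invert the (monotone) log10 tau_alpha(phi) relation."""
        lo, hi = self.phi_min, self.phi_max
        flo = self.log10_tau_alpha(lo, ac) - target
        fhi = self.log10_tau_alpha(hi, ac) - target
        if flo > 0 or fhi < 0:
            raise RangeError(
                f"target log10 tau = {target:g} outside reachable window "
                f"[{flo + target:.2f}, {fhi + target:.2f}]"
            )
        return brentq(lambda p: self.log10_tau_alpha(p, ac) - target, lo, hi, xtol=1e-12)


@lru_cache(maxsize=64)
def get_isobar(pstar: float, phi_min: float = 0.50, phi_max: float = 0.623, n_phi: int = 50) -> IsobarModel:
    """Memoized :class:`IsobarModel` constructor."""
    return IsobarModel(pstar, phi_min=phi_min, phi_max=phi_max, n_phi=n_phi)


# ---------------------------------------------------------------------------
# curves and transition solvers
# ---------------------------------------------------------------------------

def tau_curve_vs_temperature(
    material: MaterialModel,
    pstar: float = 0.0,
    phi_range: tuple[float, float] = (0.50, 0.623),
    n: int = 60,
    beta_coefficient: float | None = None,
) -> pd.DataFrame:
    """Table of (T, log10 tau_alpha, log10 tau_beta) along an isobar.

    ``temperature_K`` uses the alpha-process mapping (liquid expansion
    coefficient, pressure-independent); ``temperature_beta_K`` uses the
    beta-process mapping, which switches to ``beta_crystal`` under
    compression when the material defines it.  ``beta_coefficient``
    overrides the beta-mapping coefficient (e.g. to deliberately keep
    the unmodified liquid mapping at elevated pressure).
    """
    model = get_isobar(pstar, phi_min=phi_range[0], phi_max=phi_range[1])
    phis = np.linspace(model.phi_min, model.phi_max, n)
    if beta_coefficient is None and (pstar == 0 or material.beta_crystal is not None):
        beta_coeff = _mapping_coefficient(material, "beta", pstar, None)
    else:
        beta_coeff = beta_coefficient if beta_coefficient is not None else material.beta_glass
    return pd.DataFrame(
        {
            "phi": phis,
            "temperature_K": [thermal_map(p, material, "alpha") for p in phis],
            "log10_tau_alpha_s": model.log10_tau_alpha(phis, material.ac),
            "log10_tau_beta_s": model.log10_tau_beta(phis),
            "temperature_beta_K": [
                thermal_map(p, material, "beta", pstar, beta_coeff) for p in phis
            ],
        }
    )


def glass_transition_temperature(material: MaterialModel, pstar: float = 0.0) -> float:
    """Tg (K): temperature at which tau_alpha reaches the material threshold."""
    model = get_isobar(pstar)
    phi_g = model.phi_at_log10_tau_alpha(np.log10(material.tg_threshold), material.ac)
    return thermal_map(phi_g, material, "alpha")


def _log10_tau_alpha_state(phi: float, pstar: float, ac: float) -> float:
    """Direct (spline-free) log10 tau_alpha at a single state point."""
    structure = compute_structure(phi)
    lts, lp, fb, fe, _ = _barrier_pieces(FluidState(phi, pstar), structure)
    return _compose_log10_tau(lts, lp, fb + ac**2 * fe)


def glass_transition_pressure(
    material: MaterialModel, temperature: float, p_max: float = 12.0
) -> float:
    """Pg (kB T / d^3): reduced pressure at which tau_alpha reaches the threshold.

    The volume fraction is pinned by the (pressure-independent) alpha
    thermal mapping at the requested temperature; compression then slows
    the dynamics monotonically.
    """
    phi_t = phi_from_temperature(temperature, material, "alpha")
    if not (0 < phi_t < 0.64):
        raise DomainError(f"temperature {temperature} K maps to unphysical phi={phi_t:.3f}")
    target = np.log10(material.tg_threshold)

    def f(p):
        # once compressed past the point where the work term swallows the
        # free-energy maximum, the particle is permanently localized:
        # treat as infinitely slow so the bisection backs off
        try:
            return _log10_tau_alpha_state(phi_t, p, material.ac) - target
        except NoBarrierError:
            return np.inf

    try:
        f0 = _log10_tau_alpha_state(phi_t, 0.0, material.ac) - target
    except NoBarrierError as exc:
        raise RangeError(
            f"no activation barrier at T={temperature} K, P*=0; cannot bracket Pg"
        ) from exc
    if f0 >= 0:
        raise RangeError(
            f"already glassy at ambient pressure for T={temperature} K "
            f"(log10 tau_alpha = {f0 + target:.2f})"
        )
    lo, hi = 0.0, 0.25
    while f(hi) < 0:
        lo, hi = hi, 2.0 * hi
        if hi > p_max:
            raise RangeError(f"threshold unreachable below P* = {p_max}")
    for _ in range(60):  # plain bisection: f may be +inf on the glassy side
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9 * max(1.0, hi):
            break
    return 0.5 * (lo + hi)


def pressure_scan(
    material: MaterialModel, temperature: float, n: int = 13, span: float = 1.2
) -> pd.DataFrame:
    """Normalized isothermal compression curve (Fig.-3-style).

    Columns: pstar, p_over_pg, log10_tau_alpha_s; the scan covers
    P/Pg in (0, span].
    """
    pg = glass_transition_pressure(material, temperature)
    pstars = np.linspace(0.0, span * pg, n)
    rows = []
    for p in pstars:
        phi_t = phi_from_temperature(temperature, material, "alpha")
        rows.append(
            (p, p / pg, _log10_tau_alpha_state(phi_t, p, material.ac))
        )
    return pd.DataFrame(rows, columns=["pstar", "p_over_pg", "log10_tau_alpha_s"])


def beta_curve_vs_tg_over_t(
    material: MaterialModel,
    pstar: float,
    beta_coefficient: float | None = None,
    window: tuple[float, float] = (0.90, 1.0),
    n: int = 21,
    tg_ref: float | None = None,
) -> pd.DataFrame:
    """log10 tau_beta on a common Tg/T grid (ambient-pressure Tg).

    All curves share the ambient-pressure glass transition temperature as
    the normalization, so comparing pressures at fixed Tg/T compares them
    at fixed laboratory temperature.  ``beta_coefficient`` selects the
    expansion coefficient of the beta-process mapping (defaults to the
    material rule: liquid value at ambient pressure, crystal value under
    compression when defined).
    """
    if tg_ref is None:
        tg_ref = glass_transition_temperature(material, 0.0)
    model = get_isobar(pstar)
    phis = np.linspace(model.phi_min, model.phi_max, 160)
    if beta_coefficient is None:
        if pstar > 0 and material.beta_crystal is not None:
            beta_coefficient = material.beta_crystal
        else:
            beta_coefficient = material.beta_glass
    temps = np.array(
        [thermal_map(p, material, "beta", pstar, beta_coefficient) for p in phis]
    )
    x = tg_ref / temps
    y = model.log10_tau_beta(phis)
    order = np.argsort(x)
    xs = np.linspace(*window, n)
    ys = np.interp(xs, x[order], y[order], left=np.nan, right=np.nan)
    return pd.DataFrame({"tg_over_t": xs, "log10_tau_beta_s": ys})


def estimate_crystal_expansion(
    material: MaterialModel,
    pstar: float,
    window: tuple[float, float] = (0.90, 1.0),
    bounds: tuple[float, float] = (1e-4, 11.9e-4),
) -> float:
    """Crystal-state expansion coefficient that collapses a compressed
    beta curve onto the ambient one.

    Mirrors the experimental-comparison procedure of adjusting the
    beta-process mapping coefficient until tau_beta(T) becomes pressure
    insensitive; the result is an estimate of the crystal-state volume
    thermal expansion coefficient.
    """
    from scipy.optimize import minimize_scalar

    tg0 = glass_transition_temperature(material, 0.0)
    ref = beta_curve_vs_tg_over_t(material, 0.0, window=window, tg_ref=tg0)

    def spread(bc):
        cur = beta_curve_vs_tg_over_t(material, pstar, beta_coefficient=bc, window=window, tg_ref=tg0)
        return np.nanmax(np.abs(cur.log10_tau_beta_s.values - ref.log10_tau_beta_s.values))

    res = minimize_scalar(spread, bounds=bounds, method="bounded")
    return float(res.x)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Outcome of a (t0, ac) fit to a relaxation-time curve."""

    t0: float
    ac: float
    residual_norm: float
    n_obs: int
    n_starts: int
    success: bool
    message: str


def fit_material_parameters(
    observations,
    pstar: float = 0.0,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((350.0, 700.0), (0.1, 3.0)),
    ac_fixed: float | None = None,
    beta_glass: float = 12e-4,
    phi0: float = 0.5,
    n_starts: int = 5,
) -> FitResult:
    """Least-squares estimate of (T0, ac) from a (T, log10 tau_alpha) table.

    ``observations`` is an (n, 2) array or DataFrame with columns
    temperature_K, log10_tau_s.  The forward model maps each temperature
    to a volume fraction through the thermal mapping and evaluates the
    isobar's alpha relaxation time.  A deterministic multistart over
    ``n_starts`` points of the ac bound box guards against local minima;
    each start initializes T0 by inverting the observations through the
    model at the trial ac.
    """
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2 or obs.shape[0] < 5:
        raise FitError("need at least 5 observations with columns (temperature_K, log10_tau_s)")
    (t0_lo, t0_hi), (ac_lo, ac_hi) = bounds
    if not np.all(np.isfinite([t0_lo, t0_hi, ac_lo, ac_hi])):
        raise FitError("bounds must be finite")
    temps, logtaus = obs[:, 0], obs[:, 1]
    model = get_isobar(pstar)
    scale = beta_glass * phi0

    def phi_of(t0):
        return phi0 + scale * (t0 - temps)

    def residuals(params):
        t0, ac = params
        phi = phi_of(t0)
        clipped = np.clip(phi, model.phi_min, model.phi_max)
        penalty = 50.0 * np.abs(phi - clipped)  # keep least_squares smooth off-grid
        return model.log10_tau_alpha(clipped, ac) - logtaus + penalty

    def t0_init(ac):
        t0s = []
        for T, lt in zip(temps, logtaus):
            try:
                p = model.phi_at_log10_tau_alpha(lt, ac)
            except RangeError:
                continue
            t0s.append(T + (p - phi0) / scale)
        return float(np.clip(np.mean(t0s), t0_lo, t0_hi)) if t0s else 0.5 * (t0_lo + t0_hi)

    ac_starts = [ac_fixed] if ac_fixed is not None else list(np.linspace(ac_lo, ac_hi, n_starts))
    best = None
    for ac0 in ac_starts:
        if ac_fixed is not None:
            fun = lambda p: residuals((p[0], ac_fixed))
            res = least_squares(
                fun, x0=[t0_init(ac_fixed)], bounds=([t0_lo], [t0_hi]), x_scale=[100.0]
            )
            cand = (res.cost, float(res.x[0]), ac_fixed, res)
        else:
            res = least_squares(
                residuals,
                x0=[t0_init(ac0), ac0],
                bounds=([t0_lo, ac_lo], [t0_hi, ac_hi]),
                x_scale=[100.0, 1.0],
            )
            cand = (res.cost, float(res.x[0]), float(res.x[1]), res)
        if best is None or cand[0] < best[0]:
            best = cand
    cost, t0_hat, ac_hat, res = best
    if not res.success:
        raise FitError("fit did not converge", {"status": res.status, "message": res.message})
    return FitResult(
        t0=t0_hat,
        ac=ac_hat,
        residual_norm=float(np.linalg.norm(res.fun)),
        n_obs=obs.shape[0],
        n_starts=len(ac_starts),
        success=bool(res.success),
        message=str(res.message),
    )
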