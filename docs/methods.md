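# Methods

## Scope and assumptions

The package treats an amorphous molecular material as a one-component
hard-sphere fluid. All chemistry is compressed into three numbers: the
effective diameter *d* (the only length), the thermal-mapping reference
temperature T₀, and the local–nonlocal coupling a_c. The model assumes

- translational dynamics only (no rotational degrees of freedom);
- Percus–Yevick (PY) equilibrium structure — no attractions, no
  polydispersity, no site-resolved (RISM) structure;
- pressure acts solely as mechanical work P·ΔV(r) ≈ P r d² on the tagged
  particle's displacement, leaving the equilibrium structure at given Φ
  unchanged;
- the harmonic (small Δr_eff/r_cage) treatment of the medium outside the
  cage, with g(r) ≈ 1 there;
- a linear volume-fraction↔temperature mapping with a single expansion
  coefficient per process.

## Structure (PY hard spheres)

The direct correlation function inside the core is the Wertheim cubic;
its 3D Fourier transform is evaluated in closed form (moment integrals
of sin(qr) over the core), with a Taylor branch below q d = 0.2 to avoid
catastrophic cancellation. S(q) = 1/(1 − ρĈ(q)) therefore carries no
quadrature error; both branches agree with 40-digit arbitrary-precision
quadrature to better than 1e-10 relative.

g(r) is recovered by a type-I discrete sine transform. The working
wavevector grid is 2^13 uniform points on (0, 80/d] — sufficient for all
energy and timescale integrals, whose integrands carry Gaussian or
(S−1)² decay — but for the inverse transform the grid is extended
analytically (not zero-padded) to ~2560/d so that the sharp-cutoff
ringing that would otherwise corrupt the cage region (amplitude ~0.07 at
Φ = 0.55) is absent. The conjugate r-grid carries ≥ 2^13 points on
(0, 16 d]. Inside the core g is clamped to 0; the contact value is
always the analytic (1 + Φ/2)/(1 − Φ)².

The cage radius is the first local minimum of g(r) beyond the contact
peak, found by a windowed (±64 samples) discrete search refined with a
local cubic spline; the window makes the search immune to sub-grid
Gibbs wiggles at the core discontinuity. A minimum shallower than
g = 0.9 is reported as `NoCageError`: below Φ ≈ 0.27 the fluid has no
meaningful coordination cage. Volume fractions ≥ 0.64 (random close
packing) are rejected outright.

## Dynamic free energy and extrema

The structural integral and its first two r-derivatives are taken
analytically under the integral sign and evaluated by trapezoid
quadrature on the structure grid (r-blocks of 2048 bound the working
array). The extremum search brackets sign changes of the analytic
gradient on a 200-point log-spaced grid in [1e-3 d, r_cage] and refines
with Brent's method (xtol 1e-12); curvatures come from the analytic
second derivative. Degenerate landscapes (no minimum–maximum pair, or
F_B < 1e-10 k_BT) raise `NoBarrierError` carrying (Φ, P*): downstream
Kramers prefactors need strictly positive curvatures, so a zero barrier
is never silently returned. The ambient-pressure arrest onset lands
between Φ = 0.43 and 0.44 on the default grids.

Two regimes produce `NoBarrierError`: the dilute fluid (no minimum at
all) and strong over-compression, where the linear work term P* r
outgrows the structural decay before the cage edge and the maximum
disappears — the particle is then permanently localized. The P_g solver
treats the latter as "infinitely slow" when bracketing.

## Elastic barrier

Δr_eff follows the quartic bracket in (Δr, r_cage) exactly; the bracket
is positive-definite, so the harmonic-regime guard is an explicit
Δr ≤ 6 r_cage threshold rather than a sign test. F_e uses the closed
form 2πρd³K₀Δr_eff²r_cage³ (exact for the 1/r² field with g = 1); an
optional tabulated-g path integrates the shell sum numerically to
200 r_cage for sensitivity studies — note that truncation alone leaves a
1/200 deficit there, which is why the closed form is the default. The
coupling a_c multiplies F_e only at the kinetics layer (as a_c²F_e), so
the elastic module stays material-independent.

## Timescales and units

Internally everything is reduced (lengths in d, energies in k_BT,
pressure in k_BT/d³); in the Kramers prefactor
2π√(k_BT/d²)/√(K₀K_B) the k_BT/d² factor is unity, with curvatures in
k_BT/d². τ_E = 1e-13 s exactly. τ_s uses the binary-collision form with
b(q) = 1/(1 − j₀ + 2j₂) and the analytic contact value. Relaxation
times are composed in log space (`logaddexp`), so barriers of tens of
k_BT cannot overflow. SI conversion (MPa, nm) is confined to
`extract_diameter` and the CLI.

## Thermal mapping and solvers

T = T₀ − (Φ − Φ₀)/(βΦ₀) with β_glass = 12e-4 1/K and Φ₀ = 0.5 by
default. The α-process mapping is held pressure-independent. For the β
process under compression the coefficient switches to a crystal-like
value β_crystal (an in-cage rattler expands like a lattice vibration);
β_crystal must be set explicitly and must be smaller than β_glass.

`IsobarModel` precomputes log₁₀τ_s, the Kramers ln-prefactor, F_B and
bare F_e on a 50-point Φ grid (default [0.50, 0.623]) per reduced
pressure and interpolates each with a cubic spline; materials enter only
afterwards (a_c and the mapping), so one isobar serves every material.
T_g inverts the monotone log₁₀τ_α(Φ) spline by Brent bracketing;
P_g pins Φ through the mapping at the requested temperature and bisects
in P* (60-iteration cap, treating barrier-less over-compressed states as
infinitely slow). Both hit their thresholds to better than 1e-3 decades.

`fit_material_parameters` is a bounded least-squares fit of (T₀, a_c)
with a deterministic 5-point multistart over the a_c bound box; each
start initializes T₀ by inverting the observations through the model at
the trial a_c, which makes the noiseless fit exact to machine precision.
Off-grid Φ excursions during optimization are clipped with a smooth
penalty.

## Default materials

| material | T₀ (K) | a_c | T_g/P_g threshold |
|---|---|---|---|
| curcumin | 518.6 | 1.0 | 100 s |
| glibenclamide | 525.0 | 0.9 | 1 s |
| indomethacin | 476.0 | 1.5 | 100 s |

## β-curve comparison and the crystal coefficient

β-process curves at different pressures are compared on a common
T_g/T axis using the ambient-pressure T_g for every curve (a monotone
relabeling of the laboratory temperature axis). In this framing the
unmodified-mapping curves at P* = 0, 1.8, 2.6 are near-parallel, with
pairwise vertical offsets of ≈0.37 and ≈0.57 decades varying by only
6–8% across T_g/T ∈ [0.90, 1.0].

`estimate_crystal_expansion` adjusts the β-mapping coefficient of a
compressed curve until it collapses onto the ambient one. On this
package's numerics the collapse is excellent (< 0.12 decades residual
spread) at β_c ≈ 11.5e-4 and 11.2e-4 1/K for P* = 1.8 and 2.6 — only a
few percent below the liquid coefficient, because the work term P* r
shifts F_B by ≲1 k_BT at these pressures. Literature-style crystal
coefficients in the 4.7–4.8e-4 range over-correct by several decades
here; matching them would require pressure-induced β-time offsets far
larger than the printed dynamic free energy can produce. This residual
tension is a known limitation of the minimalist work-term treatment.

## What the synthetic fitting data emulate

Fit-recovery checks synthesize (T, log₁₀τ_α) curves from the forward
model itself: 25 points spanning 330–420 K (roughly τ_α from 10⁻⁹ s to
seconds, the span of broadband dielectric spectroscopy) with Gaussian
noise of 0.1 decades, a typical experimental scatter. Such data inherit
the model's own shape — they contain no secondary processes, no
conductivity wings, no temperature-dependent stretching — so passing
recovery tests demonstrates estimator consistency and identifiability of
(T₀, a_c), not correctness of the hard-sphere model for any real drug.
Under these conditions the estimator's sampling SD is ~1 K in T₀ and
~0.02 in a_c.

## Known limitations

- PY structure degrades above Φ ≈ 0.6 (g can dip slightly negative near
  the cage minimum at Φ = 0.62); the Φ ceiling of 0.64 is a guard, not
  an accuracy claim.
- The work term P r d² has no geometric prefactor; any O(1) factor would
  rescale the P* ↔ MPa correspondence and therefore the extracted
  diameters.
- Fixed P* along a curve: the model holds the reduced pressure constant
  while d may drift with T along a laboratory isobar. At fixed (P*, P)
  the identity d = (P* k_BT/P)^{1/3} gives d ∝ T^{+1/3}, consistent with
  the two extracted diameters (larger d at the lower-T, lower-P point).
- Electrostatics, H-bonding, and molecular shape enter only through T₀
  and a_c; deviations grow with compression.
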