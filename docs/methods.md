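# Methods

## The model

`slend` implements simplest-level electron nuclear dynamics (SLEND): a
time-dependent variational treatment of ion–molecule collisions and
electron-attachment dynamics in which

- the nuclei are classical point particles R_A(t), P_A(t), obtained as
  the zero-width limit of frozen narrow Gaussian wave packets (the
  packet widths are eliminated by the limit and never appear as state),
- the electrons are one complex, spin-unrestricted single determinant
  in the Thouless parametrization: the occupied molecular spin-orbitals
  of a fixed reference determinant, each mixed with the reference
  virtuals by complex coefficients z_ph(t),

    chi_h = phi_h + sum_p z_ph phi_p .

The reference orbitals come from a conventional UHF SCF at the initial
geometry; all electronic time dependence lives in z(t) and in the atomic
basis functions, which ride on the moving nuclei ("travelling" basis).
The Thouless chart covers every determinant not orthogonal to the
reference, which is what makes the working equations free of the
orthonormality constraints that destabilize naive orbital propagation.

## Equations of motion

Applying the time-dependent variational principle to the product trial
state gives a first-order (Pfaffian) Lagrangian.  Over the real
parameter vector y = (Re z, Im z, R, P) the Euler–Lagrange equations
take the antisymmetric linear form

    Omega(y) dy/dt = dE/dy ,      Omega = K + J ,

where J is the canonical nuclear symplectic block (from the P·dR/dt
term) and

    K_ij = -2 Im  d^2 ln S / dX'_i dX''_j |_(diagonal)

with S = <z', R', P' | z, R, P> the overlap of two Thouless states
(primes: bra copies of the parameters, set equal to the ket values after
differentiation).  These K blocks are exactly the generalized
non-adiabatic couplings C, C_X, C_XY of the method expressed in real
coordinates; regrouping the same system in (z, z*, R, P) recovers the
conventional four-block matrix form, and dz*/dt is the conjugate of
dz/dt by construction.  Omega is derived once from the Euler–Lagrange
route (so every sign and factor comes from a single derivation) and the
assembly *verifies antisymmetry numerically* every time (tolerance 1e-7
relative); an asymmetric K means inconsistent derivative blocks and
raises.

All ln S derivatives reduce to dense linear algebra over the per-spin
occupied metric M = D^H S_ao D, D = C_occ + C_virt z.  The energy is

    E_total = sum_A P_A^2/2M_A + <Psi|H_e|Psi>/<Psi|Psi> + V_NN ,

evaluated through the metric-normalized one-particle density
rho = D M^-1 D^H.  Analytic gradients (dE/dz*, dE/dR, dE/dP) follow by
the same matrix calculus; every block is validated against central
finite differences of ln S and E_total in the test suite at relative
1e-6.

Singularities of the Thouless chart (the state acquiring a node against
the reference) are physical, not numerical: the solver estimates the
condition of M and of the assembled Omega and *halts* with the estimate
rather than regularizing.  An optional re-anchoring control
(`PropagationControls.reanchor_threshold`, off by default) re-expresses
the state over a fresh reference with z = 0 when ||z|| grows past the
threshold; each event is logged in the trajectory metadata, and frames
recorded before an event store z over the reference current at that
time.

## Integrals and basis sets

Two independent in-repo integral routes exist, cross-checked against
each other in the tests:

- a numba-accelerated static-mode McMurchie–Davidson engine (s/p/d,
  values plus all center-derivative blocks used by the couplings and
  gradients), the production path for SCF and static dynamics;
- a pure-NumPy reference engine built on generalized "term lists"
  (linear combinations of power-shifted primitives) which additionally
  supports the travelling mode: each basis function carries the plane
  wave exp(i v_A · r) of its center's velocity.  The phase is absorbed
  into a complex shift of the Hermite product center; the MD recurrences
  are algebraic in that center and remain valid, with complex-argument
  Boys functions (erf closed form + stable recursions) in the Coulomb
  integrals.  Momentum derivatives (the C_P, C_PP blocks and dE/dP) are
  moment-raised integrals through the same machinery.

Static mode is the default below 10 keV collision energy, travelling
above (override with `etf_mode`); at zero momenta the travelling
integrals reduce exactly to the static ones (tested).  The travelling
route is substantially slower — it is the accuracy-first path for the
high-energy scenarios, not the desk-scale default.

Basis tables (STO-3G; 3-21G; 6-31G with the 6-31G*/6-31G** polarization
shells d=0.8 on C/N/O and p=1.1 on H/He) are plain-text files in
`electronic_structure/basis_data/`; their headers state the provenance.
Phosphorus ships for STO-3G only, reconstructed from the universal
STO→3G least-squares expansions and published Slater exponents (the
reconstruction procedure reproduces the published 1s/2sp expansions to
four decimals, and the recomputed 3s/3p contraction coefficients match
the published phosphorus values).  Every contracted Cartesian component
is normalized to unit self-overlap.

## Preparation of initial states

*Collisions.*  Beam along +x, impact parameter along +y, aim point
(target center of mass or a named atom) at the origin; the bare-proton
projectile starts at (-separation, b, 0) with momentum m·v x̂,
v = sqrt(2E/m).  Electrons are prepared on the target by a fragment
superposition: target and projectile UHF determinants are concatenated,
the occupied union is Löwdin-orthonormalized under the supersystem
overlap, and virtuals are rebuilt by projection.  The default initial
separation of 30 Bohr keeps the projectile–target basis overlap below
1e-8 for all shipped fixtures (checked at preparation; too-small
separations raise).

*Electron attachment.*  The simulation starts just after capture: the
extra electron is inserted into a selected canonical UHF virtual of the
neutral host (offset from the LUMO, per spin channel), which plays the
role of the metastable shape-resonant state; no orbital relaxation is
applied before propagation, and the nuclei start at rest.  True
resonance capture (a continuum electron) is outside the model — see
Limitations.

*Orientations.*  Uniform random rotations via unit quaternions from a
single seeded generator; every random draw in a run flows from the one
config seed.

## Time integration

Embedded Runge–Kutta 5(4) (scipy's RK45, stepped manually) on the
flattened real vector, one Pfaffian solve per right-hand-side
evaluation.  Defaults: rtol 1e-7, atol 1e-9, max step 5 a.u.  The total
energy is monitored along the run and drift beyond `energy_tol`
(default 1e-3 Hartree) aborts the trajectory; in practice desk-scale
runs conserve energy to 1e-8–1e-11 Hartree.  The Mulliken charge sum is
conserved *identically* in this formulation (tr(rho S_ao) = N_e is an
algebraic identity of the metric-normalized density), so total-charge
drift signals a genuine defect, not discretization error.  Trajectories
record per-frame diagnostics (energy, Mulliken charges, ||z||, step
size) plus the integrator's next trial step, which makes checkpoint
restarts bit-identical: RK45 is fully determined by (t, y, trial step).

Time reversal (P → -P, z → z*) is an exact symmetry of the equations
and is used as an integration oracle (forward + reversed propagation
recovers the initial state).

## Analysis layer

- *Fragments*: connected components under the covalent criterion
  |R_A - R_B| <= 1.2 (r_cov A + r_cov B) (closed boundary), with
  standard single-bond covalent radii; channel labels are canonical
  sorted multisets of fragment formulas, invariant under atom
  permutation and rigid rotation, with the projectile fragment flagged.
- *Electron-transfer probability*: the final Mulliken electron
  population on the projectile center, clipped to [0, N_e] — the
  fractional mean-field estimator.  It is isolated behind one function
  so alternative estimators can be swapped; a continuum-contamination
  flag fires when a configurable fraction of the projectile population
  sits in its most diffuse shell.
- *Cross sections*: sigma = 2 pi ∫ P(b) b db by trapezoid, with the
  |trapezoid - Simpson| difference as the quadrature error and the
  orientation-scatter standard errors propagated through the weights.
  The grid must reach a decayed tail (P(b_max) < 1e-4 by default) or
  the reduction refuses and reports the required extension.
- *Cluster scaling*: sigma(n) = c n^(2/3) by linear least squares in c
  (closed form), R^2 against the fitted curve; cross-checked against a
  general nonlinear least-squares fit.
- *Stored references*: the published water-monomer (experimental mean
  1.27 A^2 +/- 10.62%; SLEND/6-31G* 1.54; BGM 1.00; CDW-EIS 0.589) and
  proton–cytosine (experiment 2.3 +/- 0.5; CDW 1.9, units 1e-19 m^2)
  electron-transfer values, used only for signed-percentage-deviation
  reports; values only readable off plots are excluded on principle.

## Problem sizes used in the shipped tests

The full-fidelity cross-section campaigns behind the published
water-cluster numbers are cluster-scale (tens of thousands of
trajectories); this package reproduces the machinery, not the campaign.
The test suite exercises every code path at desk scale: H2+/H2 for the
derivative and reversibility oracles, a complete H+ + H2 collision at
1 keV (b = 1 Bohr) for the conservation suite, H2 + e- (sigma*
attachment — the textbook dissociative-attachment prototype) propagated
for 500+ a.u. for the charge-conservation check, a reduced-grid
H+ + H scan at 100 keV for the end-to-end cross-section pipeline, and
H3PO4 for phosphate-site attachment.  The expensive configurations
(6-31G* water at 100 keV with orientation averaging; cluster series)
are shipped as example configs and run through exactly the same code.

## What the fixtures do and do not represent

Diatomic and monomer fixtures use documented standard geometries.  The
water clusters are *synthetic idealized* structures built by rule from
the monomer (cyclic rings with alternating free hydrogens, stacked-ring
prism/cage hexamers, perturbed "asymmetric" variants); they realize the
isomer classes, not any particular published minimum, so
cluster-resolved observables from them are method demonstrations rather
than literature reproductions.  H3PO4 likewise uses idealized bonds and
angles.  The excised-nucleotide systems require a user-supplied XYZ
geometry (accepted everywhere a fixture name is) — their published
geometry is not redistributable from here.

## Numerical choices

- SCF: DIIS (8 vectors), core guess, |dE| < 1e-10 and RMS density
  change < 1e-8; non-convergence raises with the residuals.
- Overlap near-linear dependence warns below a smallest eigenvalue of
  1e-8; fragment-superposition occupied metrics below 1e-8 raise.
- EOM solves: LU with a 1-norm reciprocal-condition estimate; rcond
  below 1e-12 raises `SingularMetricError`.
- One-electron systems skip the two-electron tensor entirely (Coulomb
  and exchange of a single electron cancel identically).
- Degenerate electron-free systems (a bare proton) reduce exactly to
  classical free motion.

## Known limitations

- No true shape-resonance capture: attachment starts post-capture in a
  bound-orbital surrogate; a plane-wave continuum description is out of
  scope.
- The bound-state transfer estimator cannot separate capture into
  diffuse bound functions from slow ionization; values are flagged, not
  corrected (no continuum projection).
- No KSDFT propagation, no surface hopping, no nuclear quantum effects
  beyond the zero-width limit; nonrelativistic kinematics throughout
  (v/c ~ 0.015 at 100 keV).
- Travelling-mode dynamics uses the reference (slow) integral route;
  d-basis travelling trajectories are compute-hungry.
- Phosphorus is limited to STO-3G, matching the basis the
  phosphorus-bearing prototype calculations use.
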