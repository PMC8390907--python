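# Methods

`halosolv` reimplements, as a tested desk-scale pipeline, the analysis
chain used to study how halophilic and mesophilic proteins keep their
hydration shells in concentrated KCl: experimental electrolyte reference
quantities (Pitzer model), simulation-side activity derivatives
(Kirkwood-Buff theory on closed boxes), the optimization machinery for the
K⁺⋯carboxylate Lennard-Jones pair parameter, and solvation-shell
structure/dynamics observables.  It operates on synthetic configurations
and trajectories with known ground truth rather than on MD output; no MD
engine is ever launched.

## Pitzer reference (module `pitzer`)

For a 1:1 electrolyte at molality m (ionic strength I = m):

    ln γ± = f^γ(I) + B^γ(I)·m + (3/2)·C^φ·m²
    f^γ   = −A_φ [ √I/(1 + b√I) + (2/b) ln(1 + b√I) ]
    B^γ   = 2β⁰ + (2β¹/(α² I)) [ 1 − e^(−α√I)(1 + α√I − α²I/2) ]

with the conventional α = 2.0 and b = 1.2 (kg/mol)^½.  The molal activity
derivative a′^(b) = 1 + ∂ln γ±/∂ln b is differentiated **analytically**
(hand-derived, closed form); a central-difference cross-check (step 1e-4
in ln b, agreement required to 1e-6) lives in the test suite so the
algebra cannot silently rot.

The shipped potassium-acetate preset uses the Pitzer–Mayorga compilation
values β⁰ = 0.1587, β¹ = 0.3251, C^φ = −0.00660 kg²/mol², with the
standard 298 K Debye–Hückel slope A_φ = 0.392.  Temperature is fixed at
298 K; A_φ is an input, never derived from solvent theory.  Presets are
data and overridable.

Molal→molar conversion multiplies by the log-slope ∂ln b/∂ln ρ_s of the
salt number density, evaluated by central differences on a monotone
piecewise-cubic (PCHIP) interpolant of a mass-density table; extrapolation
outside the table is refused.  No measured density table for potassium
acetate ships with the package.  `synthetic_koac_density_curve` is a
**synthetic** stand-in constructed to carry a constant log-slope of 1.034
over b ∈ [0.1, 3] mol/kg — the behaviour implied by published molal/molar
derivative pairs for this salt; its absolute densities are plausible but
are not measurements, and nothing downstream treats them as such.  For a
1:1 electrolyte the salt-unit and indistinguishable-ion (cosolvent)
descriptions share activity coefficients and derivatives; activities
themselves differ by a factor of 2.

## Kirkwood-Buff analysis (module `kirkwood_buff`)

RDFs are estimated by a shell histogram with minimum-image distances, a
distinct-pair convention for identical species, and normalization by the
closed-box density N/V, so an uncorrelated (Poisson) configuration gives
g = 1 in expectation on every bin below half the box edge.  Default bin
widths: 0.05 Å for thermodynamic integrals, 0.02 Å for
parameterization-grade peak fitting.

The finite-size-corrected KB integral is

    G_ij(R) = ∫₀^{2R} [ f_ij·g_ij(r) − 1 ] · 4πr² · (1 − 3x/2 + x³/2) dr,

x = r/(2R), with R equal to a quarter of the box edge by default
(overridable for convergence studies).  The tail factor f_ij is the
reciprocal of the mean of g over the final 20 % of [0, 2R]; the window is
a package choice — it gives a stable mean without touching the structured
region — and is configurable.  Quadrature is trapezoidal on bin centers:
the RDF is piecewise-constant data and higher-order rules gain nothing;
the grid is closed with the exact endpoint values (the kernel weight is 1
at r = 0 and 0 at r = 2R).

Electroneutrality forces the cosolvent treatment: G_cc = (2G₊₋ + G₊₊ +
G₋₋)/4, G_cw = G₊w + G₋w, and a′_c = 1/(1 + ρ_c(G_cc − G_cw)) with ρ_c
the ion number density (both signs, total count over box volume).  A
non-positive denominator is rejected as thermodynamically invalid rather
than returned.

Replica analysis mirrors multi-run production protocols: each replica is
analyzed independently and the derivative reported as mean ± SEM over
replicas.  A SEM over three replicas has only two degrees of freedom, so
a ±3 SEM acceptance band on it fails for roughly 9 % of seed draws even
when the estimator is exact; the uncorrelated-limit tests therefore state
their seeds explicitly and this caveat applies to any reading of their
margins.

## Pair-parameter scan (module `parameter_scan`)

The 12-6 pair energy ε[(R_min/r)¹² − 2(R_min/r)⁶] (+ optional Coulomb with
the vacuum-permittivity constant in kcal·Å/mol·e² units) is evaluated
only; nothing is simulated.  Unlike-pair parameters come from
Lorentz–Berthelot rules (arithmetic mean of R_min, geometric mean of ε),
and the scanned quantity is a multiplicative factor f on the combination-
rule R_min; ε stays at its combination-rule value (dual optimization is a
non-goal).

First-peak positions are the mean of a Gaussian-plus-constant-baseline
least-squares fit.  The fit window runs from the left flank where g first
exceeds half the peak height to the first local minimum after the peak; a
5-bin moving average is used for window *detection* only, the fit sees raw
bins.  The baseline term exists because RDF peaks sit on a g ≈ 1
background.  Degenerate peaks — fewer than five informative bins, e.g. the
delta-like spikes of a zero-noise scripted system — fall back to the
intensity-weighted centroid of the window, which is what makes the
zero-noise scan-loop recovery exact to within half a bin.

Selection: a candidate survives if its activity derivative stays within a
relative band (default 0.07, i.e. ±7 %) of the reference at **every**
concentration, as a strict ≤ on unrounded values; among survivors the
winner minimizes the mean unsigned relative deviation |r_sim − r_cryst| /
r_cryst over the contact sites, ties broken toward smaller f.  Pair
overrides are exported in an R_min/ε (Å, kcal/mol) dialect and a σ/ε
dialect (σ = R_min·2^(−1/6), energies in kJ/mol), both round-trippable.

## Solvation-shell structure (module `solvation_structure`)

The proximal number density resolves solvent by distance to the protein
*surface*: ρ_X(r) = n̄_X(r)/(dr·SASA̅(r)) with dr = 0.05 Å shells,
left-closed right-open, water measured at its oxygen.  SASA(r) is the
area of the isosurface whose points lie exactly r from the nearest
non-hydrogen protein atom — the exposed area of the union of radius-r
spheres — sampled with a deterministic Fibonacci-spiral point set (default
960 points per atom) so results reproduce without a seed.  There is no
rolling probe and no per-atom van der Waals radius; that is deliberate
(the isosurface definition, not Shrake–Rupley SASA).  For a structureless
solvent this normalization cancels the protein's geometry exactly up to
O(dr²) curvature terms, giving a flat profile at the bulk density — the
key internal control.  SASA is evaluated per frame and averaged, with a
rigid-protein shortcut when coordinates do not move.

Strong water→protein hydrogen bonds: donor-oxygen⋯acceptor (N or O)
distance strictly below 3 Å and O_w–H⋯A angle at the hydrogen strictly
above 135°, maximized over the two hydrogens; each (water, acceptor) pair
contributes at most one bond.  The angle convention is genuinely
ambiguous in the geometric-criterion literature; the at-hydrogen form is
the default and an at-oxygen form (O–H bond vs. O⋯A vector, < 45°) is
selectable on the criterion object.  The surface density is σ_HB =
n̄_HB/SASA̅ with SASA evaluated at the first maximum of the hydration
layer, reported per Å² and per nm².

Residues are classified acidic (Asp, Glu), basic (Lys, Arg, plus His
under a titration flag), polar, or apolar, with a CSV-style override for
nonstandard names; composition metrics report counts, net charge (−1 per
acidic, +1 per basic) and per-SASA densities.  Correlations between peak
heights and surface composition use ordinary least squares plus Pearson r.

## Solvation-shell dynamics (module `solvation_dynamics`)

MSD(τ) uses every saved frame as a time origin (maximal averaging; origin
spacing is not a physical parameter here) and averages over the tagged
population.  Shell populations are tagged by proximal distance ≤ 4.5 Å at
the first analyzed frame and membership is fixed thereafter — members
that later leave the shell are retained, by definition.  The default
first-shell cutoff of 4.5 Å can be overridden per system from the first
minimum of ρ_X(r).

D comes from ordinary least squares of MSD = 6Dτ + C on the τ ∈ [20, 30]
ps window; C absorbs non-diffusive short-time motion and leaves the slope
unbiased.  Wrapped-coordinate MSD uses in-cell coordinates verbatim and
saturates below 3(L/2)² at long lag — the confinement signature — which
is harmless inside a short fit window; the unwrapped curve is always
retrievable for comparison.  D is Å²/ps internally and 10⁻⁵ cm²/s at
reporting boundaries.

## Synthetic data (module `synthetic`)

The generators define the study conditions:

- **Ideal solutions** place every molecule i.i.d. uniform per frame —
  the exact null model (all g ≡ 1, all G ≡ 0, a′_c ≡ 1).  The
  uncorrelated-limit checks use 500+500 ions with 500 waters in a 60 Å
  box over 200 frames per replica, three replicas: ion counts and box
  follow the solution-box scale of the study; the water count is a
  package choice (the a′_c = 1 limit is water-count independent) sized so
  the five pair RDFs stay desk-scale.
- **Paired solutions** script a known contact-ion-pair population:
  a chosen fraction of cation–anion pairs at Gaussian separation (mean
  2.8 Å, sd 0.1 Å in the recovery tests — the contact-pair distance scale
  for K⁺⋯carboxylate) with everything else uniform.  Note the fitted RDF
  peak sits ~2σ²/μ below the distance mode because of the 1/r² shell
  normalization (≈ 0.007 Å here), well inside the stated ±0.02 Å.
- **Brownian trajectories** draw Cartesian increments with variance
  2DΔt, so MSD = 6Dτ exactly; both wrapped and continuous coordinates are
  kept.  Recovery tests use D ∈ {0.05, 0.2, 0.5} Å²/ps (bracketing
  ion/water-like mobilities), 500 particles, 10⁴ steps of 0.1 ps, three
  seeds.
- **Toy protein systems** are rigid pseudo-proteins (five acidic sites
  with carboxylate-like oxygens, one basic N, one polar O, one apolar C
  on a widely spaced ring) with solvent placed at exact scripted
  distances and angles, plus a contact-site table carrying the scripted
  distances as r_cryst.  The five-site table is a scripted fixture; it
  emulates the *role* of cocrystallized-cation contact sites and never
  claims to be any deposited structure.

Water is a rigid 3-site molecule (O–H 0.9572 Å, H–O–H 104.52°, random
orientation) so hydrogen-bond geometry is exercisable; there is no
energetics anywhere.  A 0.5 Å minimum placement separation avoids
degenerate RDF bins (generators test statistics, not physics; the
resulting excluded-volume perturbation to KB integrals is ~0.5 Å³, far
below statistical noise).  All randomness flows from one root seed;
replica and stream seeds are spawned deterministically
(`replica_seeds`), so regeneration is bit-identical and replicas mimic
independent production runs.

What the generators deliberately do **not** emulate: force fields,
thermostats, real TIP3P water structure, correlated solvent shells, or
protein flexibility.  Passing tests therefore demonstrate that the
estimators are correct and unbiased on systems with known answers — not
that any force field is accurate.

## Numerical and degenerate-input choices

- Trapezoidal quadrature everywhere an integral meets binned data.
- Strict inequalities on both hydrogen-bond cutoffs.
- `fit_first_peak` refuses monotone RDFs ("no peak") rather than fitting
  a flank; an all-zero tail window or non-positive KB denominator raises.
- A single replica is an error for SEM-bearing pipelines (SEM reported as
  missing, never as zero).
- Seeds derived from a root stay below 2³¹.

## Problem sizes

Default test and demo sizes (200-frame replicas, ≤ 1000 ions, 10⁴-step
walks, 960 SASA points) were chosen once as the smallest systems on which
the statistical acceptance bands are comfortably resolved; they are stated
above and in the tests themselves.

## Known limitations

- The molar-scale potassium-acetate derivative depends on a measured
  density table the package does not ship; with the synthetic stand-in
  curve it reproduces the expected magnitude but is not an independent
  experimental number.
- The proximal-density normalization assumes shells thin enough that
  SASA(r_mid)·dr approximates the shell volume; at dr = 0.05 Å the error
  is O(10⁻⁴) relative for protein-scale curvatures.
- Wrapped-coordinate MSD conflates re-imaging jumps with diffusion at
  intermediate lag; the package reproduces that convention deliberately
  and exposes the unwrapped curve alongside.
- Three-replica SEMs are noisy (2 dof); margins quoted as multiples of
  such SEMs carry the ~9 % caveat noted above.
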