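# halosolv

Analysis toolkit for a question from halophile biophysics: proteins of
organisms that accumulate molar KCl in their cytoplasm are strongly
enriched in acidic amino acids, and one family of explanations holds that
this excess is needed to keep the protein hydrated when water activity is
low.  Testing that idea in molecular simulation requires a chain of
analyses that this package implements as a self-contained, seeded,
desk-scale pipeline:

- **Experimental reference**: mean molal activity coefficients of a 1:1
  electrolyte from the Pitzer ion-interaction model, the molal activity
  derivative a′^(b) = 1 + ∂ln γ±/∂ln b, and its conversion to the molar
  scale through the density log-slope ∂ln b/∂ln ρ_s.
- **Simulation-side observable**: Kirkwood-Buff integrals from closed-box
  RDFs with the finite-size kernel G(R) = ∫₀^{2R}[f·g(r) − 1]·4πr²·(1 −
  3x/2 + x³/2) dr and tail factor f, combined into the cosolvent activity
  derivative a′_c = 1/(1 + ρ_c(G_cc − G_cw)).
- **Pair-parameter optimization**: Lorentz-Berthelot combination rules, a
  scaling factor on the cation⋯carboxylate-oxygen R_min, Gaussian
  first-peak fitting of per-site RDFs, and selection of the factor that
  best matches crystal contact distances subject to a ±7 % band on the
  activity derivative.
- **Solvation-shell profiling**: proximal number densities ρ_X(r) =
  n̄_X(r)/(dr·SASA(r)) against the distance-r isosurface area, a
  geometric strong-hydrogen-bond census (O⋯A < 3 Å, O–H⋯A angle > 135°)
  and its surface density σ_HB = n̄_HB/SASA̅, and diffusion coefficients
  from MSD(τ) = 6Dτ + C fits on the 20–30 ps window for first-shell vs.
  bulk populations.

Everything runs on synthetic inputs with known ground truth — uniform
(Poisson) electrolyte boxes, scripted contact-ion-pair populations,
Brownian walks with prescribed D, and rigid toy proteins with solvent at
exact scripted geometries — so every estimator is tested against the
generator that produced its input.  No MD engine is involved; see
`docs/methods.md` for the model details and design choices.

## Worked example

Experimental reference derivatives for potassium acetate (the preset
carries the standard ion-interaction constants at 298 K):

```
$ halosolv pitzer --b 0.5 --b 1 --b 2
[
  {"b_s": 0.5, "gamma_molal": 0.749414118,  "a_prime_molal": 1.0143347098},
  {"b_s": 1.0, "gamma_molal": 0.7825041572, "a_prime_molal": 1.1229198146},
  {"b_s": 2.0, "gamma_molal": 0.909954807,  "a_prime_molal": 1.3344593421}
]
```

a′^(b) = 1 would be an ideal solution; the rise to 1.33 at 2 mol/kg is
the thermodynamic signature of ion-ion interactions that the simulation
side must reproduce.  From the library, a scripted contact-ion-pair
population is recovered by the RDF peak fitter:

```python
from halosolv import synthetic as syn, kirkwood_buff as kb, parameter_scan as ps

box = syn.BoxSpec(60.0)
roster = syn.SpeciesRoster.of(K=(300, "cation"), Cl=(300, "anion"))
traj = syn.gen_paired_solution(roster, box, cip_distance=2.8, paired_fraction=0.5,
                               peak_width=0.1, seed=42, n_frames=100)
rdf = kb.compute_rdf(traj, "K", "Cl", bin_width=0.02, r_max=15.0)
fit = ps.fit_first_peak(rdf)
print(f"first peak at {fit.r_sim:.3f} Å (sd {fit.sd:.3f} Å)")
```

prints

```
first peak at 2.795 Å (sd 0.100 Å)
```

— the generator's 2.8 Å / 0.1 Å ground truth, recovered through the
histogram → Gaussian-fit chain (the ~0.005 Å offset is the expected
2σ²/μ shift from the 1/r² shell normalization).

Other entry points: `halosolv kb` (replica trajectories → a′_c ± SEM),
`halosolv scan` (candidate manifest → selected scaling factor),
`halosolv shell` / `halosolv msd` (profiles and diffusion fits), and
`halosolv run --config FILE` for an end-to-end staged run with a JSON
report stamped by config hash and seed.

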