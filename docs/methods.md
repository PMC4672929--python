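# Methods

## Model

The membrane is a grand-canonical collection of independent sites.
One site is either empty (statistical weight 1) or occupied by one
receptor complex: `x` trimers of dimers (TDs, `3x` dimers), `x − 1`
linkers, and `x + 2` identical rest groups.  Complexes are two-state
(all dimers active or all inactive).  The free energy of a species
`S = (x, rest, linker composition)` is

    F_on(S)  = 3x f_on  + Σ_linkers (E_link + J) + R(S)
    F_off(S) = 3x f_off + Σ_linkers  E_link      + R(S)

with the single-dimer energies `f_on = Δε − ln(1 + c/K_on) + μ`,
`f_off = −ln(1 + c/K_off) + μ`.  Linker energies by scheme:

| scheme | full linker | CheW-only linker |
|---|---|---|
| BRIDGED (base) | μ_A₂ + 2μ_W | — |
| BRIDGED_PLUS_WONLY | μ_A₂ + 2μ_W | μ_W₂ + 2μ_W |
| SYMMETRIC | 2μ_A + 2μ_W | — |
| SYMMETRIC_PLUS_WONLY | 2μ_A + 2μ_W | μ_W₂ + 2μ_W |

Rest groups: R1 = 0, R2 = (x+2) μ_W, R3 = (x+2)(μ_W + μ_A₂) (R3 uses
2μ_A in the symmetric schemes).  Expression levels scale the
potentials per contained monomer: μ_W(i) = μ_W⁰ − ln i,
μ_A₂(j) = μ_A₂⁰ − ln j (monomer potential μ_A likewise), and
μ_W₂(i) = μ_W₂⁰ − 2 ln i since the central CheW₂ unit holds two
monomers.  `a_mult = 0` maps to μ_A₂ = +∞, removing all
CheA-containing species.

The activity `A = Σ P_S P_S^on n_A₂(S)` counts CheA₂ dimers in active
complexes, including those in R3 rest groups: rest-group kinases do
not couple TDs but do contribute to the measured signal.

### Design choices where the architecture was open

- **Sign convention of the expression scaling.**  The potentials are
  logarithms of dissociation constants over concentrations, so they
  *decrease* when expression rises.  This is the only convention under
  which more CheW produces larger complexes and higher cooperativity,
  the model's central qualitative behavior.
- **Mixed linkers.**  In the *_PLUS_WONLY schemes a complex may mix
  the two linker types; the `binom(x−1, k)` arrangements of `k` full
  linkers along the slots are counted as a single species with that
  multiplicity.  Because the slot contributions factorize, the
  partition function equals a closed form in which each slot
  contributes `e^{−E_A} + e^{−E_W}` independently — this closed form is
  asserted as a test oracle.
- **CheW-only linkers in the symmetric scheme** use μ_W₂ + 2μ_W with
  μ_W₂⁰ defaulting to 2μ_W⁰ when unspecified.  The default reproduces
  the plain `4μ_W` per-linker form (the central pair treated as two
  ordinary monomers) while keeping one uniform rule and the property
  that μ_W₂ → +∞ reduces any *_PLUS_WONLY scheme to its base scheme.
- **Rest groups in the symmetric scheme** are retained unchanged apart
  from μ_A₂ → 2μ_A, mirroring the treatment of the full linker.

## Density constraint

ρ(μ) = Σ 3x P_S is strictly decreasing in μ, so ρ(μ) = ρ_target has a
unique root.  It is found with Brent's method on a bracket expanded
geometrically from μ ∈ [−50, 50] kT up to |μ| ≤ 500 (beyond which
every species weight under- or overflows double precision and the
target is genuinely unreachable — e.g. ρ > 3 without CheA).  The root
is polished to machine precision in μ (`xtol = 1e−14`) and solutions
report the achieved density; convergence means |ρ − ρ_target| ≤ 1e−10.
Concentration sweeps warm-start each bracket at the previous root.
Boltzmann weights are always evaluated in log space relative to the
lowest free energy, so arbitrarily negative energies cannot overflow.

The constant-μ mode evaluates the same ensemble without the
constraint; the density then grows with ligand concentration toward
the packing limit `3 x_max` because larger complexes gain the most
binding free energy, which produces the characteristic bump in
normalized dose-response curves at high fixed μ.

## Dose-response and Hill analysis

All caption-value reproductions use 50 log-spaced concentrations from
0.001 to 1 mM; other grids are configurable.  Hill fits are ordinary
nonlinear least squares of `A₀ / (1 + (c/c_H)^{n_H})` on raw
(unnormalized) activities, initialized at A₀ = max activity, c_H = the
grid point nearest half-maximum, n_H = 2, with all parameters bounded
positive.  Comparisons with printed amplitudes require one unknown
signal scale per condition family; the scale is calibrated on the
family's lowest-amplitude curve and the remaining amplitudes are
predictions.

The classical single-complex MWC comparator
`Ǎ = (1 + exp[N(Δε + ln((1+c/K_off)/(1+c/K_on)))])^{−1}` is included;
its fitted n_H approaches the complex size N only when the transition
sits well inside K_off ≪ c ≪ K_on.

## Fitting

`FretFitModel` minimizes `Σ (s_family · A_model(c) − signal)²`.  The
scales enter linearly and are profiled in closed form
(`s = ΣA·y / ΣA²`, clipped at 0) at every objective evaluation.  The
remaining nonconvex problem uses multi-start local minimization:
Latin-hypercube start points inside the box bounds, ranked by
objective value, with L-BFGS-B refinement of the best six.  Defaults
(50 starts) are sized for interactive use; the ranking-then-refining
strategy spends local-optimization effort only where the objective
landscape is promising.  Fits are deterministic given the seed.
μ_W⁰, μ_A₂⁰ and ρ are mutually entangled (all shift complex-size
distributions), so fits share one parameter set across conditions and
by default estimate only `delta_eps`, `J` and `rho`; a per-family
density (ρ_W ≠ ρ_A) is optional.  One modification state per dataset;
confidence intervals are not produced — the nonlinearity of the model
makes linear-theory intervals unreliable, so only point estimates and
the per-start table are reported.

## Synthetic data

`generate_dataset` emulates a FRET dose-response experiment:
per-condition model curves on a log-spaced grid, an unknown
multiplicative signal scale, and additive homoscedastic Gaussian noise
(FRET ratio noise is approximately additive at these amplitudes).
It does not emulate photophysics, bleaching, CheY-P/CheZ readout
kinetics, adaptation, or concentration-dependent noise; passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to real
instrument systematics.

## Problem sizes and numerical notes

Test and acceptance runs use the published parameter sets directly
(12–30 species, x_max = 4).  Parameter-recovery checks use three
expression conditions on a 12-point grid with noise sd equal to 2% of
the maximal signal and 50 starts — sizes chosen to exercise the full
pipeline while keeping a complete run interactive.  Degenerate inputs
are handled explicitly: all-zero curves and <4-point curves are
rejected by the Hill fitter, unreachable densities raise a diagnostic
error carrying the bracket densities, and expression level 0 for CheA
is an exact limit rather than a small number.

## Known limitations

- Rest groups are symmetric (all x + 2 sites identical), as in the
  source model; asymmetric partial decoration is not enumerated.
- No spatial geometry: the hexagonal lattice motivates the linker
  architecture but sites are independent and structureless.
- Equilibrium only; assembly/insertion kinetics are out of scope.
- Joint fitting across modification states is not implemented (the
  forward model covers all states; fit them separately).
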