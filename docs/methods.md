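# Methods

## The problem

A metal M and a non-chromophoric ligand L form a complex MLn whose
stoichiometry n (moles of ligand per mole of metal) is to be determined
spectrophotometrically.  The two classical approaches — Job's method of
continuous variations and the mole-ratio (Yoe–Jones) method — read n off
the geometry of a titration plot of the complex's own absorbance, and
require either the complex or a reactant to absorb.  The ligand-exchange
(displacement) approach instead titrates a colored *indicator* complex MX
with L and watches the indicator's absorbance fall, so it also works when
every species of the M/L system is colorless at an accessible wavelength.

## Chemical model

All three designs are simulated from one competitive-equilibrium model:

    M + X  ⇌ MX     β_MX  = [MX] / ([M][X])        (1:1, colored)
    M + nL ⇌ MLn    β_MLn = [MLn] / ([M][L]^n)     (colorless at the
                                                    indicator wavelength)

with mass balances C_M = [M] + [MX] + [MLn], C_X = [X] + [MX],
C_L = [L] + n[MLn], and Beer–Lambert absorbance additive over species
(A = b·Σ ε_i c_i, path length b in cm, ε in M⁻¹cm⁻¹, c in mol/L).
Activity corrections, pH-dependent side reactions and mixed-ligand or
protonated species are outside the model; a formation constant here is a
*conditional* constant for the medium at hand.

### Speciation solver

`solve_speciation` runs damped Newton iteration on the logarithms of the
free concentrations (positivity is automatic; constants spanning 10²–10¹⁶
are handled without scaling tricks), with an analytic Jacobian, step
clipping at ±30 log units, backtracking line search, an iteration cap of
200, and a convergence tolerance of 1e−12 on the maximum relative
mass-balance residual.  Mixtures with an absent component reduce to the
corresponding subsystem.  If Newton stalls, the solver falls back to
`speciation_oracle`: outer bisection on [M] ∈ [0, C_M] with, per trial
value, the closed form [X] = C_X/(1 + β_MX[M]) and inner monotone bisection
for [L].  The bisection route is also kept as an *independent* cross-check:
the test suite demands 6-significant-figure agreement between the two on
200 random systems (log β ∈ [2, 16], n ∈ {1, 2, 3}, totals 10⁻⁶–10⁻² M).
Failure of both routes raises a solver error carrying the best residual.

## The displacement estimator

With the test complex much more stable than MX, adding L displaces the
indicator quantitatively.  For a complex of composition M_pL_q each mole of
L consumes p/q moles of metal from MX, so

    A = ε_MX (C_MX − (p/q) C_L),

a straight "inverse" line of slope −(p/q)·ε_MX.  Overlaying it on the
direct MX calibration line (slope ε_MX) and dropping a vertical of length
δ from the intersection to the abscissa splits the axis into segments

    α = δ / slope_direct,      β = δ / |slope_inverse|,

whose quotient α/β = p/q is the **metal-per-ligand** combining ratio.  For
MLn the package therefore reports the ligand-per-metal stoichiometry as

    n̂ = β/α = slope_direct / |slope_inverse|.

Both abscissa segments are measured from the fitted lines' actual
x-intercepts rather than from the origin.  This makes the α and β
identities above hold exactly whatever the calibration intercept, so the
geometric and slope-ratio estimates coincide and a small non-zero intercept
does not bias n̂; a warning is still emitted when the direct intercept
exceeds 3× its residual scatter, because then the through-origin reading of
the overlay plot would be misleading.

### Linear-region selection

The attenuation line is only linear while indicator complex remains; past
the equivalence level the absorbance flattens.  The inverse fit uses a
deterministic prefix of the series: starting from the first three points,
the next point is admitted while its residual from the running fit stays
inside a 3σ one-point prediction band (leverage-corrected), with σ taken as
the largest of the running fit scatter, the calibration's residual scatter
(an honest instrument-noise estimate), and an absolute floor of 3×10⁻⁵ AU
below which agreement is beyond any instrument's resolution.  A simple
backward "trim while the last residual exceeds 3·residual_sd" rule was
rejected: on series with a long post-equivalence plateau the plateau itself
inflates the global residual scatter and nothing is ever trimmed.

### Uncertainty and rounding

The estimator reports a case-resampling bootstrap percentile interval
(default 2000 replicates, seeded, points resampled within each series
independently; degenerate replicates — parallel slopes, intersection at or
below the axis — are dropped and counted).  The raw n̂ is snapped to the
nearest of {1/3, 1/2, 1, 2, 3, 4} by relative distance, ties toward the
smaller ratio, and displayed metal:ligand ("1:1", "2:1", …).

## Classical comparators

**Continuous variations**: mixtures with C_M + C_L constant; the absorbance
maximum sits at metal mole fraction x* = 1/(1+n), so n̂ = (1−x*)/x*.  The
apex is located either by intersecting straight lines fitted to the two
branches (points within 5% of the maximum absorbance are excluded from both
branches — hand-drawn tangent choice made deterministic) or by the vertex
of a parabola through the 3–5 points bracketing the empirical maximum.
Normalizing to A/A_max rescales both branches identically and provably
cannot move either locator's apex (property-tested to 1e−12).

**Mole-ratio**: fixed C_L, varying C_M, absorbance plotted against the
metal:ligand ratio; the ideal plot rises to the equivalence ratio 1/n and
then flattens, n̂ = 1/break.  The break is found by exhaustive two-segment
least squares (every split leaving ≥ 2 points per side; smallest total SSE
wins, ties to the smaller split index) and the tangent intersection of the
two segment fits.  On exactly piecewise-linear data this recovers the kink
exactly.

## Synthetic designs and their defaults

Bench amounts stated per 10 mL convert as 1 µmol/10 mL = 1×10⁻⁴ M.

| design | grid | fixed |
|---|---|---|
| calibration | MX 0.1–0.6 mM, 6 levels | C_L = 0 |
| exchange | L 0.02–0.18 mM, 9 levels | MX 0.3 mM |
| continuous variations | metal mole fraction 0.1–0.9, 9 mixtures | total 1 mM, no X |
| mole-ratio | metal 0.04–3 mM, 12 levels | L 0.5 mM, no X |

The mole-ratio metal grid (0.4, 1, 2, 3, 4, 5, 6, 8, 10, 15, 20, 30 µmol
per 10 mL) spans the stated 0.4–30 µmol range with denser coverage below
the equivalence point, where the rising tangent is fitted.

Noise is additive homoscedastic Gaussian on absorbance, default
sd 0.002 AU — the simplest instrumentally plausible model for a
single-wavelength colorimeter; one seeded generator per simulated series,
seed recorded in the series metadata.  The generator does **not** emulate
wavelength-resolved spectra, drift, heteroscedastic (transmittance-domain)
noise, pH/ionic-strength effects or mixed complex ladders, so passing tests
demonstrate estimator correctness under the stated model, not robustness to
those real-data features.

Default constants are **illustrative, not fitted**: no formation constants
for the indicator or test complexes are available, so the demo system uses
log β_MX = 6 (a moderately stable colored indicator) and log β_MLn = 14
(a much stronger, displaceable-into complex), ε_MX = 1600 M⁻¹cm⁻¹ at the
indicator wavelength and ε_MLn = 2000 M⁻¹cm⁻¹ at the classical wavelength
(chosen so standard designs give absorbances of order 0.1–1 AU).  Tests of
limiting behaviour use a deliberately deep strong-binding regime
(log β_MX = 12, log β_MLn = 14n + 2): at log β_MX = 6 the indicator is only
~90–97% formed over the calibration range, which curves the direct line and
caps slope-ratio accuracy near 2%.

## Cross-method comparison, and an honest negative result

`compare_methods` simulates matched datasets across a grid of log β_MLn
(default 5, 6, 14) at noise sd 0.002 over 25 seeds and tabulates bias and
SD of n̂ per method.  Because a displacement assay needs an indicator
weaker than the test complex, the indicator constant tracks the grid
(log β_MX = log β_MLn/n − 2), the software analogue of a chemist selecting
a displaceable indicator.  Default table for a 1:1 system
(`ligex compare --seed 0`, or `compare_methods(ComplexSystem(n=1,
eps_MX=1600.0), noise_sd=0.002, seeds=range(25))`):

| log β_MLn | method | bias | sd |
|---:|:---|---:|---:|
| 5 | ligand_exchange | +1.0496 | 0.0980 |
| 5 | job_tangent | +0.0007 | 0.0025 |
| 5 | mole_ratio | −0.0629 | 0.0020 |
| 6 | ligand_exchange | +0.4949 | 0.0248 |
| 6 | job_tangent | +0.0006 | 0.0024 |
| 6 | mole_ratio | −0.0226 | 0.0019 |
| 14 | ligand_exchange | +0.0115 | 0.0108 |
| 14 | job_tangent | +0.0006 | 0.0024 |
| 14 | mole_ratio | −0.0000 | 0.0026 |

Under this *matched-conditional-constant* protocol the displacement
estimator is the one that degrades fastest as the complex weakens — partial
displacement flattens the inverse slope (inflating n̂) at the same time as
incomplete indicator formation curves the direct line — while the
deterministic tangent rules keep the classical estimators comparatively
well behaved (the continuous-variations apex of a 1:1 system is protected
by symmetry at *any* binding strength).  The displacement method's
practical advantage for weak complexes arises differently: the assay can be
run in a medium where displacement is quantitative even though the same
complex is weak in the acidic medium the classical methods must use, and it
needs no subjective hand-drawn tangents.  A single-β simulation cannot
express that medium escape; the corresponding cross-method acceptance check
is therefore expected to fail under this model, and is left failing rather
than reshaped around it.

## Numerical and design choices

- δ is the intersection's absorbance y* (vertical distance to the
  abscissa); geometry is undefined (error) when y* ≤ 0, and lines whose
  slopes agree within relative 1e−9 are treated as parallel (error).
- Two-point line fits are exact with r = ±1 and residual_sd 0; fits with
  all x equal raise a degenerate-fit error.
- Series x-values are kept sorted; duplicate x are allowed as replicates;
  continuous-variations analysis needs ≥ 5 mixtures, mole-ratio
  segmentation ≥ 5 points, the displacement inverse fit ≥ 3 linear points.
- Reports are JSON with sorted keys and no timestamps: identical
  (config, seed) reproduce them byte for byte.

## Problem sizes

The test and acceptance workloads use the design sizes above: 100 noisy
repeats for the displacement recovery rate, 25 seeds per grid point for the
comparison table, 200 random systems for the solver cross-check, and
2000-replicate bootstraps — all of which complete in seconds on one CPU.

## Known limitations

- MX is fixed at 1:1; mixed ladders MLn/MLn−1 and MXm are not modeled, so
  n̂ from data generated by stepwise-binding chemistry will land between
  the rungs.
- The estimator assumes quantitative displacement; its output is
  systematically high when β_MLn is not ≫ β_MX (see the table above).
- Conditional constants are taken as given; nothing maps pH or ionic
  strength onto them.
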