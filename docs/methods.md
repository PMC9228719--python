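# Methods

## Model

A drug (1) and a carrier (2) form a 1:1 complex (3) with association constant
K = c₃/(c₁ᶠ c₂ᶠ) (mol⁻¹ dm³), where superscript f denotes free
concentrations.  The speciation of a composition (c1, c2) is the physical
root of the mass-action quadratic; the implementation uses the citardauq form
x = 2Kc1c2 / (b + √(b² − 4K²c1c2)), b = K(c1+c2)+1, which avoids subtractive
cancellation when K·c ≪ 1 (the weak-binding regime both case studies occupy).

The measurable ternary mutual-diffusion matrix follows from a dilute-solution
closure: the complex is in local equilibrium with the free species and its
independent cross-diffusion terms are neglected (D13 = D23 = 0).  Each matrix
coefficient is then an explicit combination of the three species
diffusivities weighted by the equilibrium factor
R = [(1 + K(c2−c1))² + 4Kc1]^(−1/2) (see the README for the four closed
forms).  Structural consequences the tests pin down:

- K = 0 gives an exactly diagonal matrix at every composition.
- In the tracer limit c1 → 0, D11 reduces to the fast-exchange average
  (1−f)·Dd + f·Dc with bound fraction f = Kc2/(1+Kc2).
- At c1 = c2, D12/D21 = (Dd − Dc)/(Db − Dc) exactly.
- At c2 = 0 the model forces D12 = 0 (no carrier, no coupling into its
  gradient); this matters for the fit quality discussion below.

Units everywhere: diffusivities 10⁻⁹ m² s⁻¹, concentrations mol dm⁻³, K
mol⁻¹ dm³.  The math core never converts units.

The complex diffusivity, when not measured, is estimated hydrodynamically:
radii proportional to 1/D, complex volume = sum of partner volumes, hence
Dc = (Dd⁻³ + Db⁻³)^(−1/3).  For the cyclodextrin system (1.050, 0.399) this
gives 0.392, within 1% of the tabulated 0.390; the residual discrepancy
reflects the unstated volume model behind the tabulated value, so the
estimator is documented as volume-additivity and checked at the 1% level.
For micellar carriers the complex diffusivity is instead pinned to the
micelle value (0.100) and treated as concentration-independent.

## Virtual instrument

Dispersion peaks are modelled by the standard two-mode profile in the
eigenbasis of the diffusion matrix (README equation).  Only the combination
D·tR/r² shapes a peak, so the unprinted retention time is a free nominal
default (7000 s for the default 3048.0 cm × 0.03220 cm tube, 5 s sampling);
every recovery test is tR-agnostic.

Mode weights: an injected excess (ΔC1, ΔC2) is decomposed on the eigenmodes
and projected on the detector sensitivity vector (1, ρ); ρ (the
refractive-index increment ratio of the two components) defaults to 1.0 and
is a required input for quantitative work.  The weight of the fast mode is
**not** confined to [0, 1]: counter-current coupling genuinely produces small
negative mode amplitudes (e.g. a carrier-only injection in the cyclodextrin
system has W1 ≈ −0.07).  The profile fitter therefore bounds W1 to a generous
[−2, 3] band rather than pinning it to [0, 1] — pinning would bias every
assembled cross coefficient by ~0.05·10⁻⁹ m² s⁻¹ and break the noiseless
pipeline identity.

Fitting is 7-parameter bounded Levenberg–Marquardt (lmfit) with moment-based
initialization (baseline from the trace edges, tR from the argmax, D scale
from the second moment) and a deterministic 8-point multi-start over
(W1, D1, D2) covering both mode-dominance extremes.  Fitted eigenvalues are
reported sorted descending with W1 attached to the larger one, removing the
label-exchange ambiguity.

Matrix assembly from two injections writes D = λ₂I + (λ₁−λ₂)Q with Q the
rank-1 spectral projector of the fast mode.  Each measured weight gives one
linear constraint sᵀQu = w·sᵀu; idempotency closes the system.  Because a
near-single-mode fit carries no label information, eigenvalues are pooled
across fits by clustering components on the largest relative gap (significant
components first, faint ones as a fallback when the detector is nearly blind
to a mode), and each fit's fast weight is re-expressed against the pooled
clusters.  With the canonical pure-component injection pair the inversion is
unique; for general independent excesses a quadratic can admit two
projectors and the one with the smaller off-diagonal norm is returned
(deterministic tie-break).  Inconsistent eigenvalue estimates (beyond 3
standard errors, or 1% when no errors are available) raise instead of
silently averaging.

## K estimation

The association constant is fitted by minimizing
Σ rows Σ coefficients [(D_obs − D_model(K))/σ]², with σ the per-cell standard
deviations of the table (class fallbacks 0.02 main / 0.05 cross when a cell
has none).  All four coefficients enter by default; a subset can be selected.
The 1-D objective is evaluated on a dense grid (K ∈ [0, 500], step 0.1) and
polished with bounded scalar minimization in the winning bracket — fully
deterministic and immune to local minima.  Species diffusivities are fixed
inputs taken from the binary-limit rows (D11 at X1 = 1, D22 at X1 = 0), as in
the source tables; they are not co-fitted.

For micellar carriers the fit uses only rows with c2 above the CMC
(0.0083 mol dm⁻³ for the surfactant studied): below the CMC the model's
"carrier" species — the micelle — does not exist, so those rows are reported
as diagnostics only.  The boundary c2 = CMC is assigned to the above-CMC
regime by convention.

Uncertainty: residual-resampling bootstrap.  Residuals at K̂ are pooled
within coefficient class (main/cross, matching the homoscedastic noise
model), resampled onto the fitted surface, and K refit per replicate (grid
stage only; the 0.1 grid resolution is far below the interval width);
the 95% interval is percentile-based and deterministic given a seed.  An
all-zero residual table yields a degenerate zero-width interval with a
warning.

### Fit results on the packaged tables

On the packaged measured tables the weighted least-squares optimum is much
smaller than the published constants (K̂ ≈ 0.3 instead of 10 for the
cyclodextrin system; K̂ ≈ 0 instead of 20 for the surfactant system).  This
is a property of the printed data, not of the optimizer: the closure forces
D12 = 0 at c2 = 0 while the tables report their largest |D12| exactly there,
and the constant-diffusivity assumption cannot reproduce the concentration
dependence of the binary-limit D11/D22 cells, whose small quoted SDs dominate
the objective with K-insensitive residuals.  No weighting variant examined
(unweighted, class-SD, single-coefficient, row subsets) recovers both
published values, so the published "best agreement" constants do not appear
to be a least-squares optimum of these tables.  The package reports the
optimum it computes; on *self-consistent* synthetic tables the same fit
recovers the generating K exactly (noiseless) and with median error well
inside 15% under table noise for K ∈ [5, 50].

## Solubilization diagnostics

Two-state fast exchange: a drug molecule diffuses either freely (D⁰, its
infinite-dilution diffusivity) or inside the carrier (Dc), so the tracer
coefficient interpolates linearly and s = (D⁰ − D11)/(D⁰ − Dc), clipped to
[0, 1] with a warning for noisy inputs.  On the surfactant fixtures this
gives 0.156 (c2 = 0.020) and 0.190 (c2 = 0.050).  The alternative route
s = Kc2/(1+Kc2) from a fitted constant is also provided (`bound_fraction`);
for the cyclodextrin system the two routes disagree with each other and with
the tabulated fractions (0.107/0.092), whose provenance is ambiguous — both
are reported, neither is forced to match.

Counter-transport ratios D12/D22 (mol of drug per mol of carrier) and
D21/D11 are reported per row; the maxima consider only rows with negative
cross coefficients, since only counter-current flows are counter-transport.

## Synthetic data

`generate_dtable` adds homoscedastic Gaussian noise per coefficient class
(defaults 0.02/0.05 · 10⁻⁹ m² s⁻¹, the reproducibility of the real tables)
to forward-model matrices on the verbatim composition grids of the two
studies; SD columns carry the class values actually used.
`generate_trace_set` runs each composition through the virtual instrument
(two pure-component injections by default).  Both are deterministic given a
seed; all randomness flows through explicitly passed `numpy` generators,
never global state.

What the generators deliberately do not emulate: baseline drift beyond the
linear term, temperature and flow fluctuations, injection-valve dead volume,
tube-coiling corrections, activity/electrostatic corrections for the ionic
surfactant, and any concentration dependence of the species diffusivities.
Passing recovery tests therefore demonstrate the correctness and
conditioning of the inference chain under the model's own assumptions, not
robustness to the systematic errors of real instruments — the fixture-table
fit results above show how much those assumptions matter on real data.

## Numerical choices and edge cases

- Speciation: citardauq quadratic root (no cancellation at small K·c).
- K optimization: fixed grid + bounded refinement; ties broken by the grid
  order (first minimum).
- Trace windows default to ±6σ of the slower mode around tR.
- DMatrix validation rejects non-real or non-positive eigenvalue pairs
  (unphysical diffusion); bootstrap pseudo-tables bypass this check, as
  resampled cells need not form a physical matrix.
- Degenerate (equal-eigenvalue) matrices are rejected with advice to treat
  the system as binary; binary (single-axis) injection pairs return a
  diagonal matrix by construction.
- Problem sizes used by the test suite: 10³–10⁴ draws for algebraic
  property checks, 40–200 replicates for Monte-Carlo recovery experiments,
  bootstrap 200–1000 resamples.

## Known limitations

- 1:1 stoichiometry only; no 1:2/2:1, no multi-solute (>2) diffusion.
- The D13 = D23 = 0 closure is baked in; the model inherits its X1 → 0
  behaviour (a nonzero D12 limit) even though physically D12 must vanish
  there — documented, not patched.
- Everything is isothermal at 298.15 K; no activity corrections.
- The micellar complex diffusivity is a constant; real micelle diffusivity
  varies with concentration.
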