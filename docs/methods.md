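# Methods

This note documents the models, estimators and numerical choices behind
`bistflux`, and what the synthetic data do and do not emulate.

## 1. Dye-dilution model and deconvolution

**Measurement model.**  A membrane-intercalating stain is fixed at the
moment of the substrate shift; each division halves a cell's dye content.
Working on the log₁₀ fluorescence axis (cytometers log-amplify, and the
measured distributions are log-normal-shaped), a population with growing
fraction α and growing-cell rate μ_g produces at time t a two-component
Gaussian mixture:

* non-growing component: mean m₀, SD s_ng, weight (1−α)/(α e^{μt}+1−α);
* growing component: mean m₀ − log₁₀(e)·μt (one halving per division,
  μt/ln2 divisions), SD s_g, weight α e^{μt}/(α e^{μt}+1−α).

A configurable fraction of non-growing cells (default 0.3) additionally
undergoes a single *reductive division* at t > 0 and sits one halving below
m₀.  Values below a detection floor (default log₁₀ a.u. = 1.0) are clipped.
Generator defaults: m₀ = 4.0, s_ng = s_g = 0.12 log₁₀ units, 20,000 events
per timepoint, sampling times spaced over ~1.6–4.8 divisions of the
growing pool (deeper, 2–7 divisions, for scenarios with α < 1%, whose
growing peak must clear the reductive shoulder before its small weight is
measurable).

**Estimator.**  Stage 1 fits each timepoint with a two-component Gaussian
mixture by EM (percentile initialization, relative log-likelihood
tolerance 1e-8, max 500 iterations, SD floor 0.01 with a `sd_clamped`
flag; the higher-mean component is labelled non-growing, with a
proximity-to-track guard should means cross).  EM that stalls because the
components coincide — always the case at t = 0 — marks the timepoint
unresolvable.  Stage 2 fits a single (α, μ_g, m₀) to the per-timepoint
weights and growing means by weighted least squares on a logit(α)/log(μ)
scale, weights from binomial and mean standard errors.  Excluded from
stage 2 are timepoints that are (i) unresolvable (component separation
< 1 pooled SD), (ii) shifted by the reductive rule (non-growing mean more
than half a halving from its reference), or (iii) *shoulder-overlapped*:
the fitted growing mean lies within 2 pooled SDs of the reductive shoulder
at m₀ − log₁₀2.  Rule (iii) matters: while the growing peak crosses the
shoulder, the mixture fit absorbs part of the shoulder into the growing
component and overstates its weight by up to ~0.03 in α.  Standard errors
come from the stage-2 Gauss–Newton Hessian by the delta method.  Boundary
cases are flagged, not clipped: an entirely diluted population returns
α = 1 with `alpha_at_upper_boundary`; a series with no resolvable second
component returns `upper_bound`.

An optional `global_likelihood` mode refines the two-stage estimate by
maximizing the joint raw-event likelihood across all timepoints, modelling
the non-growing side as its reductive doublet with a free fraction, so no
timepoint needs exclusion.  The two-stage fit remains the default: it
mirrors the per-distribution fitting procedure the measurement was
designed around and is numerically robust.

**Growth-curve route.**  N(t) = n₀[(1−α) + α e^{μt}] is fit to log counts
by Levenberg–Marquardt on (logit α, log μ, log n₀); a curve that never
rises 1.5× above its start raises "no growth detected".  The apparent lag
−ln(α)/μ is the time for the exponential branch to regain the inoculum
level — the package's restatement of lag as subpopulation arithmetic
rather than adaptation delay.

## 2. Kinetics

**Monod fit.**  Nonlinear least squares of μ_max·S/(K_S+S) with
multistarts around (max μ, median S) and positivity bounds; requires ≥ 3
distinct concentrations.  Generator defaults use μ_max = 0.34 h⁻¹ and
K_S = 0.5 g/l.

**Depletion MCMC.**  The model couples Monod growth dN/dt = μ(S)N with
per-cell uptake dS/dt = −q_max S/(K_u+S)·N·(MW·10⁻⁶), converting
nmol cell⁻¹ h⁻¹ (N in cells/ml) to g l⁻¹ h⁻¹ with the fumarate molar mass
116.07 g/mol.  Seven parameters (q_max, K_u, μ_max, K_S, n₀ and the two
noise scales) are sampled on the log scale with log-uniform priors
spanning ±2 decades around moment estimates; the q_max estimate uses the
whole-trace mass balance (substrate consumed over integrated cell-hours),
which is robust where an early-slope estimate is not.  The likelihood is
Gaussian on log counts and log substrate.  Sampling uses the emcee stretch
move (default 16 walkers × 2000 steps, 50% burn-in, thin 10), seeded from a
short Nelder–Mead posterior-mode search so that short chains start mixed;
acceptance outside (0.1, 0.6) triggers one re-run with a retuned stretch
parameter, and per-parameter split-R̂ (walkers as chains, via arviz) above
1.1 attaches a warning note.  The reported quantity is the per-draw
steady-state uptake q_max·S/(K_u+S) at the experiment's S₀, summarized by
median and central 95% interval — this combination is identified even
where q_max and K_u individually are ridge-correlated.

**Promoter activity and Cra activity.**  Batch: background-corrected GFP
differentiated by sliding-window linear regression (window 5), divided by
OD, averaged over the largest window where log OD is linear (R² > 0.99).
Chemostat: D·(GFP−bg)/OD averaged over the steady second half.  Cra
activity is 1 − PA_regulated/PA_deregulated with the ratio's propagated
standard error; values outside [0,1] are flagged, never clipped.  The
printed source formula lacks its operator; the subtraction is the only
reading under which occupancy rises as the repressed promoter's output
falls.

## 3. Flux-sensor circuit

State (E, F): lumped gluconeogenic "super-enzyme" abundance and FBP level.
With J = k_E·u·E·s/(K_s+s) and μ = Y·J:

    dF/dt = J − f_fbp·V_f · F/(K_F+F) · Jⁿ/(Jⁿ+K_Jⁿ) − μF
    dE/dt = β₀ + β₁/(1+(F/K_I)^h) − (δ+μ)E

The Jⁿ Hill factor is the flux-dependent (PEP feed-forward) activation of
Fbp, which inverts the flux–FBP relationship; FBP inhibition of Cra is the
(F/K_I)^h term.  Two negative links make the loop positive, enabling
bistability.  Growth dilution acts on both states (switchable for F via
`dilute_F`).  PEP is not an explicit state.

**Steady states.**  For fixed E, the F-nullcline's left side is strictly
increasing in F, so F*(E) is found by bisection on [0, 1/Y + K_F]; the
scalar residual g(E) = dE/dt|_{F*(E)} is scanned on a log grid (default
2000 points over 10⁻⁴–10³), sign changes polished by Brent's method, roots
deduplicated at 1e-6 relative, and classified by the analytic Jacobian
(stable iff all eigenvalue real parts < −1e-10).  At s = 0 the flux
vanishes, FBP dynamics are degenerate, and the single production/decay
balance point (E = (β₀+β₁)/δ, F = 0) is returned.  Bifurcation scans link
branches by nearest continuation, bisect count changes to locate folds,
and can be cross-checked against the degeneracy condition g = 0 ∧ ∂g/∂E
= 0 solved directly.

**Reference parameters** (`data/params_ref.yaml`): calibrated by
bifurcation scan to satisfy three structural requirements — a bistable
substrate window with fold points at both ends inside (0.01, 3) g/l
(final window ≈ 0.33–2.61 g/l), a high-branch growth rate Y·J at 2 g/l
equal to the Monod value 0.272 h⁻¹, and flux-sensor compensation: because
the high branch's FBP level sits on the steep flank of the Cra response
(K_I just below F_high, h = 6), a drop in E production is buffered — over
β₁ × 1.0 → 0.7 the high-branch flux moves < 8% while the watershed rises.
Two structural lessons from the calibration are recorded here as design
choices: the transport half-saturation K_s (5.2 g/l) must exceed the
growth Monod constant, otherwise uptake saturates before the low branch
can destabilize and no upper fold exists; and E removal must be dominated
by growth dilution rather than degradation (δ = 0.081 h⁻¹ ≪ Y·J_high),
which compresses the window's width to the observed substrate range.

## 4. Ensemble simulation

Cell-to-cell variability enters solely through the initial super-enzyme
abundance E₀ ~ lognormal (arithmetic-mean/CV parameterization, default CV
0.35).  Initial F is placed on its conditional nullcline (quasi-steady FBP
immediately after the shift, consistent with immediate gluconeogenic
substrate utilization).  When the circuit is bistable, a cell grows iff
E₀ exceeds the saddle's E (the watershed); cells within 1% of the
threshold are resolved by direct integration.  At monostable substrate
levels all cells adopt the single state's phenotype, counted as growing
iff its flux exceeds J = 0.3 — a floor placed in the gap between the
branches (low branch ≤ 0.23, high branch ≥ 0.41 in reference units), since
the non-growing branch carries nonzero basal flux.  The default mean E₀ is
1.15× the watershed at 2 g/l, which puts the simulated α(s) plateau near
0.6 at 2 g/l, mirroring the measured acetate saturation; α(s) is then an
emergent, increasing, saturating curve, zero below the lower fold.

Post-shift state-stabilizing regulation, stochastic phenotype switching
after commitment, and multi-enzyme noise are deliberately not modelled.

## 5. What the synthetic data do not emulate

No instrument optics (spectral compensation, doublets, gating) beyond a
detection floor; no cell-cycle/agent-based division timing (the halving
law acts on means); no dye bleaching; no acetate excretion/uptake
co-occurrence; no genome-scale flux estimation.  Passing tests therefore
demonstrate correctness of the estimators *under the stated measurement
model* and the qualitative structure of the circuit, not instrument-level
realism.

## 6. Problem sizes and seeds

Default analysis sizes — 20,000 events × 6 timepoints per cytometry series
(50,000 × 7 for the two small-α scenarios), 10-point depletion traces with
16 × 1250-step chains, ensembles of 10–50 thousand cells — were chosen so
each stage's Monte-Carlo error sits well inside the tolerance it is
checked against.  Every stochastic step takes an explicit integer seed and
is bit-reproducible; the acceptance script derives independent sub-seeds
from its single `--seed` argument via `numpy.random.SeedSequence`.
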