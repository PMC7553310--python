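# Methods

## The model

`isgdyn` implements a two-compartment (cytoplasm/nucleus, plus an
extracellular ligand pool) ordinary-differential-equation model of
IFNα-induced JAK/STAT signaling and the transcription of
interferon-stimulated genes (ISGs) in hepatoma cells.  All rate laws are
mass action; concentrations are in nM (promoter states in arbitrary
units) and time in hours.

The **core variant** (25 species, 45 kinetic parameters) contains:

- receptor activation lumped into a single step, `IFN + Rec -> ActRec`,
  with first-order inactivation, USP18-mediated sequestration of the
  active receptor (`ActRec + USP18 <-> RecUSP18`), receptor turnover and
  ligand decay;
- STAT1/STAT2 phosphorylation catalyzed by the active receptor and
  constitutive dephosphorylation;
- one-step synergistic assembly of the ISGF3 trimer
  (`pSTAT1 + pSTAT2 + IRF9 -> ISGF3`), nuclear import, nuclear
  dissociation and export of the subunits;
- ISGF3-driven transcription of ten nuclear mRNAs (the six antiviral
  transcripts IRF1, TRIM21, MX1, EIF2AK2, IFI6, IFITM3 and the pathway
  genes IRF9, SOCS1, USP18), first-order mRNA decay, translation of the
  pathway proteins and their turnover.

The **extended variant** (`core_feedback`; 30 species, 53 kinetic
parameters) adds an inducible transcriptional repressor: the IRF2
transcript is itself ISGF3-induced; IRF2 protein is translated, imported
into the nucleus and reversibly occupies a conserved pool of
transcription-factor binding sites (TFBS).  Transcription of the
repressed gene set (the six antiviral genes plus SOCS1) is multiplied by
the free-site fraction `TFBS_free / (TFBS_free + TFBS_IRF2)`.

Two deliberate deviations from pure mass action: (i) SOCS1 inhibits
receptor activation through the saturating factor `1/(1 + SOCS1/ki_socs1)`
— SOCS1 blocks JAK activity rather than being consumed; (ii) the
promoter-occupancy factor above.  The IRF2 degradation constant is shared
between the cytoplasmic and nuclear pools (parsimony; no
compartment-resolved data would distinguish them).

Conservation: the STAT1 and STAT2 moieties
(`STATc + pSTATc + STATn + ISGF3c + ISGF3n`) and the TFBS pool are
conserved exactly; `conservation_matrix` recovers these as the symbolic
left null space of the stoichiometric matrix, and simulated trajectories
keep them constant to better than 1e-6 relative.

### Key parameters and defaults

- Measured mRNA half-lives enter as fixed degradation constants
  `ln 2 / t_half`; the default class values are IRF1 0.75 h, TRIM21 1.5 h
  (short-lived), MX1 6 h, EIF2AK2 5.5 h (intermediate), IFI6 48 h,
  IFITM3 60 h (stable on the 24 h observation window).
- Free kinetic constants are bounded [1e-6, 1] (1/h or 1/(nM·h)), except
  the five translocation constants bounded [1e-6, 1e2]; sampling and
  optimization act on log10 values.  Values pinned at a bound are flagged
  as practically non-identifiable.
- IFNα doses in U/ml are converted to nM with a configurable factor
  (default 0.002 nM per U/ml — a placeholder; absolute ligand units only
  rescale `kact`).
- Initial pools (configurable): STAT1 100 nM (reference), STAT2 50 nM,
  IRF9 10 nM, receptor 1000 nM (non-limiting), TFBS total 1 a.u.
- Stimulation protocol: the system is first relaxed to its unstimulated
  steady state (dose 0, 300 h horizon), then the dose is added as an
  extracellular bolus at t = 0 and decays with `kdeg_ifn`; no re-addition.

### Reference parameterization

The committed reference kinetics (`isgdyn.reference`) were chosen once by
constraining the extended model to the qualitative physiology: a fast but
self-limiting activation pulse (ligand consumed by the large receptor
pool; long-lived active receptor sustaining a signaling tail), SOCS1 as
the fast negative feedback, USP18 as the slow one, and the repressor
occupancy rising from ~0.15 at 4 h to ~0.85 at 24 h.  Under these
kinetics the six antiviral transcripts peak on the observation grid at
4/4/8/8/12/12 h — matching their half-life classes — and the core variant
simulated with the same shared constants produces visibly more sustained
early/intermediate transcripts and SOCS1, which is exactly the structural
difference the model-comparison machinery is meant to detect.

## Simulation

The reaction network is lowered to flat index arrays and integrated with
LSODA (`scipy.integrate.odeint`); the right-hand side is JIT-compiled
with numba (pure-numpy fallback).  Default tolerances are rtol 1e-8 /
atol 1e-10 for `simulate`; the calibration objective integrates at rtol
1e-6 / atol 1e-9, which changes -2 log L by far less than the 0.01
convergence tolerance while roughly doubling throughput.  States are
clipped to zero at reporting; an excursion below -1e-6 nM raises an
integration error naming the parameter set.

## Likelihood and calibration

Observables are `scale × (sum of species)` with additive Gaussian noise,
one standard deviation per observable, fitted jointly with the kinetics:

    -2 log L = Σ [ (y − ŷ)² / σ² + log(2π σ²) ]

For the least-squares optimizer the log-term is carried as per-point
pseudo-residuals `sqrt(2 log(σ/σ_lo))` (σ_lo = the noise parameter's
lower bound), which preserves the exact optimum; reported objectives are
always the exact -2 log L.  Multistart calibration draws starts by Latin
hypercube sampling uniform in log10 over the free-parameter box and runs
bounded trust-region-reflective least squares (`x_scale='jac'`,
`tr_solver='exact'`, ftol = xtol = 1e-10, at most 500 residual
evaluations per start).  Jacobian scaling matters: without it the
optimizer reproducibly stalls hundreds of -2 log L units above the
optimum on this problem.  Starts whose final objective lies within 0.01
of the best are counted as converged to the same optimum (the waterfall
plateau).  Integration failures during a start yield a large finite
residual so the start is discarded gracefully.

### The discrimination study

`experiments.discrimination_experiment` reproduces the model-selection
logic on synthetic data: triplicate time courses of the six antiviral
transcripts plus SOCS1 mRNA on the grid {0,1,2,3,4,8,12,24} h at
500 U/ml, noise sd 10% of each observable's dynamic range.  Both
variants fit the per-gene transcription capacities, the SOCS1 mRNA decay
constant and one noise sd per observable; the extended variant
additionally fits `vmax_mIRF2`, `kdeg_mIRF2` and `koff_irf2`.  The
remaining feedback constants (translation, turnover, import, on-rate)
are held at reference values: transcript-only data constrain the
repressor branch solely through its occupancy time course, leaving those
constants structurally degenerate — freeing all eight produces a sloppy
valley of micro-optima with no reproducible waterfall plateau, while the
identifiable triple converges with several starts on one optimum.  The
ranking therefore compares models at Δdf = 3 (the structural difference
between the variants remains 8 parameters).

With feedback-generated data the AIC prefers the extended variant; with
core-generated data the extended variant recovers the core solution
(zero likelihood gain) and is penalized by 2Δdf, so no spurious
preference arises.

## Model ranking and prediction profiles

- `aic(k, log L) = 2k − 2 log L`; smaller is preferred.
- `lrt_statistic(Δdf, log L, α) = icdf_χ²(α, Δdf) − 2 log L`, with the
  quantile term zero at Δdf = 0; nestedness is checked by free-parameter
  name inclusion.
- Prediction profiles: for a species value at one time point, candidate
  predictions z are scanned outward from the best fit (adaptive doubling,
  then bisection to 1e-3 relative); at each z all free parameters are
  re-optimized under a quadratic penalty `λ(z(θ) − z)²` appended to the
  residuals, with λ = 1e6/σ_ref² (σ_ref = smallest fitted noise sd).  The
  band edge is where the data's -2 log L exceeds the optimum by
  χ²₀.₉₅,₁ = 3.8415.  On a linear-Gaussian toy model (prediction = the
  mean parameter, known σ) this construction reproduces the closed-form
  interval ±1.96 σ/√n, and its empirical coverage sits in the nominal
  range; non-converged inner optimizations flag the time point as
  widened.

## Curve-level procedures

- mRNA stability: `f(t) = d + a·2^(−t/t_half)` by bounded least squares
  (t_half on the log scale; start values d = min y, a = range,
  t_half = half the window).  A series is classified *stable* when it
  does not decrease, when the fitted half-life exceeds the observation
  window, or when the fitted decline over the window is smaller than
  twice the residual standard deviation (flat series would otherwise be
  assigned arbitrary short half-lives by noise-chasing fits).  The class
  boundary between short-lived and intermediate transcripts is 3.5 h —
  the midpoint of the gap between the generating ranges.
- Dose dependence: 4-parameter Hill `f(x) = d + a·x^b/(c^b + x^b)` with
  b > 0 and the EC50 c fitted on the log scale; `poor_fit` is flagged
  when the sigmoid explains less than half of the variance beyond a flat
  response.
- AUC: trapezoidal rule on the observed nodes.
- Smoothing: cubic smoothing spline minimizing
  `p·Σ(y−s)² + (1−p)·∫s″²` (p = 1 interpolates, p = 0 is the
  least-squares line; default p = 0.8), mapped onto
  `scipy.interpolate.make_smoothing_spline` via λ = (1−p)/p.
- qPCR arithmetic: `RQ = 2^−ΔΔCt`; reference-gene normalization is an
  element-wise ratio dropping samples with zero/missing reference.

## Expression classification

Genes are selected as upregulated when any time point has a paired
two-sided t-test p < 0.05 (treated vs untreated replicates) together
with an average linear fold change > 2 (computed as 2^(mean log2
difference)).  No multiple-testing correction is applied by default,
matching the stated selection rule; a Benjamini–Hochberg option exists.
Classification uses the time of maximal mean induction: early
(t_max ≤ 4 h), intermediate (t_max = 8 h), late (t_max ≥ 12 h); argmax
ties resolve to the earliest time, off-grid peaks snap to the nearest
boundary with a warning.  Heatmap order is t_max ascending, ties by the
1 h fold change descending.

## Synthetic data

The generators emulate the study design (500 U/ml, grid
{0,1,2,3,4,8,12,24} h, biological triplicates) with additive Gaussian
noise; the time-course noise sd defaults to 10% of each observable's
dynamic range, consistent with routine triplicate qRT-PCR scatter.
Decay series use the three class ranges (0.5–2 h, 5–7 h, stable ≡ flat)
over a 12 h chase in duplicate at sd 0.05; dose series use 0 plus eight
log-spaced doses (10–5000 U/ml) in triplicate at 5% amplitude noise.
The expression matrix builds per-gene induction from a first-order
transcript with class-drawn half-life driven by a stereotyped signal
pulse (activation 0.7 h, decay 6 h), peak fold changes log-uniform in
[4, 64], baselines uniform in [5, 10] log2 units, replicate noise sd 0.1
log2 units; genes whose noiseless peak would fall outside their class
window are redrawn, so the attached labels are exact by construction.
Default class split: 21 early / 27 intermediate / 5 late.

What the generators do **not** emulate: array-level probe effects and
normalization artifacts, replicate-correlated (batch) noise,
heteroscedasticity within an observable, partial transcription-inhibition
in chase experiments, and receptor-level dose nonlinearities in the dose
series (generated directly from the Hill law).  Passing tests therefore
demonstrate correctness of the estimators and the selection/ranking
machinery under the stated noise model, not robustness to those
real-data complications.

## Numerical choices and limitations

- Problem sizes used in the shipped studies: 25 multistart runs, 8 time
  points × 3 replicates × 7 observables (168 data points), 100 seeded
  repeats for class-recovery rates, 200 simulated datasets for band
  coverage — chosen so every analysis re-runs comfortably on one CPU.
- Degenerate inputs: zero-variance replicate pairs give p = 0 in the
  paired t-test (selected if the fold criterion holds); flat decay series
  return the stable class rather than a number; doses at 0 enter the Hill
  law as exact zeros.
- The pre-equilibration horizon (300 h) is finite; parameter draws with
  degradation constants near the 1e-6 bound may not be fully relaxed —
  such draws also fit poorly, so this only perturbs already-rejected
  starts.
- The prediction-profile scan assumes a unimodal profile in z; multimodal
  profiles would be reported too narrow (the widened flag catches inner
  non-convergence but not multimodality).
- SBML export covers structure (compartments, species, parameters,
  reactions with mass-action MathML); observables and parameter bounds
  are not part of the SBML document and live in the native JSON format.
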