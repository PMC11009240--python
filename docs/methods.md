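# Methods

## Mixing-ratio model and pSup

Sedimentation fractionation splits a lysate into Total (T), Supernatant (S)
and Pellet (P) fractions which are processed and measured separately, so
the measured peak areas of a protein do not obey conservation of mass.
Writing per-experiment mixing ratios α_S and α_P for the supernatant and
pellet samples, conservation is restored in expectation:

    T_i ≈ α_S S_i + α_P P_i.

The likelihood is lognormal on the total,
log(T_i) ~ Normal(log(α_S S_i + α_P P_i), σ), with S_i and P_i treated as
fixed covariates (no errors-in-variables). Priors are Gamma(1, 1) — i.e.
Exponential(1), mean 1, weakly favoring mixing ratios near unity — on α_S
and α_P, and half-Cauchy(0, 3) on σ. The half-Cauchy is the positive
truncation of a Cauchy(0, 3) scale prior, the standard choice for a scale
parameter that must be positive. The proportion in supernatant is

    pSup_i = α_S S_i / (α_S S_i + α_P P_i) ∈ [0, 1].

Point pSups plug in the posterior-mean mixing ratios; 95% intervals are the
2.5–97.5 percentiles of the per-draw pSup. Mixing ratios are fitted per
experiment (species × condition × replicate).

Decisions in the open parts of the design:

* **Fit set.** Only records with Total intensity strictly above the
  threshold (default 1) enter the mixing-ratio fit, since T is the modelled
  response; the column and threshold are configurable. Records with
  S = P = 0 are excluded from fitting, counted, and reported downstream as
  missing pSup — never as 0.5. The filter never removes proteins from pSup
  reporting.
* **Noise model.** A negative-binomial reading of the measurement noise is
  also defensible for count-like peak areas, so the generator supports both
  lognormal and gamma–Poisson (mean m, dispersion k, variance m + m²/k)
  noise; the inference follows the lognormal likelihood written above, and
  its robustness to the count-noise alternative is testable.
* **Sampler.** The posterior is three-dimensional and unimodal, so the fit
  uses adaptive random-walk Metropolis on log-parameters (with the log
  Jacobian), Robbins–Monro step-size adaptation toward 30% acceptance and a
  proposal covariance re-estimated from warmup history; adaptation freezes
  before retained draws. Defaults: 4 chains × 1000 warmup × 4000 retained
  draws, chosen so bulk ESS > 400 and split-R-hat < 1.01 hold robustly
  across seeds on a 2000-protein experiment (diagnostics via arviz); a fit
  takes about a second. Results carry a `converged` flag; downstream pSup
  computation refuses non-converged posteriors unless forced. A MAP
  backend (L-BFGS-B on log-parameters) provides fast point estimates and an
  optimizer-independent cross-check against exhaustive grid search in the
  tests.

## Synthetic fractionation data

The generator is the exact inverse of the inference model: latent true
pSup_i per protein (Beta-distributed per class and condition), latent
abundance A_i ~ lognormal(meanlog 8, sdlog 1.5) spanning a realistic
peak-area dynamic range, and

    S_i = A_i pSup_i / α_S,   P_i = A_i (1 − pSup_i) / α_P,
    T_i = A_i exp(ε_i),  ε_i ~ Normal(0, σ),

so the generative residual log T − log(α_S S + α_P P) is Normal(0, σ) by
construction. The default scenario has 30% "condensers" (basal pSup ~
Beta(20, 2), shocked ~ Beta(2, 20)) and 70% non-condensers (Beta(20, 2) in
both conditions), mimicking the observed geometry of proteome-wide
condensation: most proteins stay soluble, a class pellets sharply after
shock. The abundance distribution and class mixture are stand-ins chosen
once as plausible for DIA proteomics, not estimates from any dataset; they
are configurable. Zero intensities (pSup exactly 0 or 1) are allowed and
must be handled downstream.

What the generator does not emulate: peptide-to-protein roll-up,
missingness correlated with abundance, batch effects, and compositional
artifacts of DIA quantification. Passing recovery tests therefore shows
the estimator is correct under its own assumptions and robust to the
count-noise variant — not that real-data biases are absent.

Reference study conditions used by the tests and the acceptance script:
2000 proteins, α_S = 0.7, α_P = 1.4, σ = 0.1 (recovery, RMSE, coverage);
σ = 0.001 for the identifiability limit; a 10-protein instance for the
grid-search cross-check.

## Growth: rates and the cardinal temperature model

The maximum specific growth rate at one temperature is the slope of ln
OD₆₀₀ versus time over the contiguous window (≥ 4 points) maximizing the
linear fit R², ties broken toward longer then earlier windows — this
selects the exponential phase and ignores saturation. Rates are per hour;
times are minutes.

Growth rate versus temperature follows the cardinal temperature model with
inflection (Rosso form), zero at and outside (T_min, T_max) and equal to
μ_opt at T_opt. The fit is nonlinear least squares (weighted by provided
SEs) with the ordering constraint enforced by fitting positive gaps
(T_min, T_opt − T_min, T_max − T_opt); parameter SDs come from the fit
covariance mapped through this reparameterization. Initialization:
T_opt ← argmax μ, T_min ← min T − 5, T_max ← max T + 2. All-zero growth
curves are rejected as degenerate rather than fitted.

## Heat-shock-response curves

Flow-cytometry events are gated by removing cells above a configurable
quantile of the autofluorescence channel (floor of 5000 surviving cells),
normalized per cell as fluorescence / forward-scatter area (the simplest
size control; a regression-residual alternative would be a drop-in
replacement), and summarized as the mean statistic relative to mock-treated
cells.

The fold-change-versus-temperature curve (one point per temperature) is fit
with an amplitude-scaled skew-normal density whose peak height equals the
amplitude. Because a single symmetric start can stall in a poor local
optimum on skewed curves, the fit multi-starts over the shape parameter
(α₀ ∈ {0, −2, 2}) and keeps the lowest-cost solution. The temperature of
maximum response is the numeric mode (dense 0.01 °C grid; the skew-normal
mode has no closed form; exactly ξ in the symmetric case), and the reported
spread of the fit is the scale ω. Flat curves are rejected.

## DLS condensation onset (T_condense)

The monomer baseline is the mean hydrodynamic radius over all acquisitions
below 35 °C (at least 3 required). The onset is the lowest temperature at
which R_h exceeds baseline + k·SD for at least `run_length` consecutive
acquisitions, with k = 5, run_length = 2, and the baseline SD floored at 2%
of the baseline so a noiseless baseline cannot produce a zero threshold.
The sustained-exceedance rule guards against single-acquisition spikes.
Whether the original onset statistic used an SD-based or fractional-increase
threshold is not decidable from the baseline definition alone, so a
relative-increase variant (`method="relative"`) is provided; SD-based is
the default. Per-replicate onsets are averaged and their SD reported;
ramps with no sustained exceedance yield a missing onset, never an
extrapolated one. The detector is temperature-shift equivariant when the
baseline cutoff is shifted with the data.

Synthetic ramps use a flat baseline plus a linear post-onset rise; tests
use 2 nm/°C, a deliberately conservative slope — real condensation ramps
rise far more steeply, which would only make detection easier. With the
default threshold this geometry biases detection late by about 0.2 °C plus
grid quantization, within the 0.5 °C recovery target.

## HDX-MS

Peptide %D is 100·(m_t − m_undeut)/(m_sat − m_undeut), clipped to
[0, 100]; normalizing by the overnight-saturated control removes
back-exchange, and adding a constant to all three masses leaves %D
unchanged. Site profiles are unweighted means of all peptides covering a
residue, with each peptide's first residue (rapid back-exchange) and all
prolines (no amide proton) excluded from coverage — standard HDX practice,
configurable. Coverage is an explicit mask (NaN), never imputed. Δ%D is
condensate minus monomer, defined only where both states are covered:
positive means local unfolding or increased exposure in the condensate,
negative means new protection. A `min_confidence` flag filters peptides by
an upstream confidence column when present. Only unimodal (centroid)
uptake is supported; bimodal deconvolution is out of scope.

Cross-ortholog comparison aligns sequences globally (Needleman–Wunsch via
biopython's PairwiseAligner, BLOSUM62, gap open −11 / extend −1, first
optimal alignment kept for deterministic tie-breaking) and correlates
profiles over aligned, doubly covered, non-gap columns (≥ 20 required).
Significance is judged against a null of seeded random permutations of one
profile's columns ("shuffled sites"). The synthetic generator tiles
peptides (lengths 8–16, step 5) over a random proline-sparse sequence,
point-mutates orthologs (never to or from proline, keeping the coverage
mask comparable), and computes each peptide's %D as the mean of its covered
sites' true exchange fractions — so site aggregation, alignment, and
correlation can be validated round-trip. Tiling smears sharp features by up
to a peptide length; tests therefore assert rank agreement (Spearman ρ)
with truth and block-level means rather than pointwise equality.

## Cross-species aggregation

Ortholog maps are consumed, never computed; joins are inner joins
restricted to one-to-one pairs by default (one-to-many pairs dropped with a
warning, or expanded on request) so correlations never double-count. Class
summaries are means ± SE of point pSups; singleton classes report a missing
SE. Species × condition correlation matrices are squared Pearson
correlations, computed on class-mean vectors by default (matching how such
summaries are usually displayed) with a per-protein mode available, since
either granularity is defensible. TPM is counts/length normalized to sum
to 10⁶. Regulon summaries use the median log2 fold change per regulon
(robust to the heavy-tailed chaperone inductions, which reach 100–1000
fold), with the mean also reported and a 3-gene floor per regulon;
cross-species conservation of regulation is the Spearman ρ of regulon
medians.

## Pipeline, formats, determinism

All tables are TSV with schema-validated, typed columns; residue
coordinates are 1-based inclusive, temperatures °C, growth times minutes,
HDX timepoints seconds. Rejected rows are reported with 1-based line
numbers and the offending column. Output files carry a header comment with
the tool version, stage, and config digest. The YAML run config rejects
unknown keys and requires an explicit seed; every source of randomness in
the package flows from caller-supplied seeds (numpy `SeedSequence` spawning
per chain), so identical configs reproduce outputs bit for bit.

## Known limitations

* The mixing-ratio model ignores measurement error in S and P; when that
  error is large, pSup intervals understate uncertainty.
* The DLS onset statistic reports the first threshold crossing, which is
  biased late by (threshold − baseline)/slope for shallow onsets.
* Skew-normal fits need curvature on both flanks; curves truncated at the
  peak give poorly constrained ω and α.
* HDX site profiles inherit peptide-length smoothing; features narrower
  than the typical peptide cannot be localized.
* The synthetic generators validate correctness under stated noise models,
  not robustness to real-data artifacts (batch effects, informative
  missingness, compositionality).
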