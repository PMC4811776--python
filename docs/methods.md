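# Methods

`hierdcm` models directed interactions among six left lateral-prefrontal
regions — FPl, MFG, IFS, cMFG, IFJ, SFS, ordered rostral to caudal by
their MNI y-coordinates (48, 28, 20, 10, 6, 0 mm) — during a blocked
2x2x2 working-memory task, and relates the estimated dynamics to behavior
and trait cognitive ability. This note documents the model, the numerical
choices, the synthetic-data generator, and what the tests do and do not
establish.

## Task design and inputs

The design crosses *Stimulus Domain* (verbal, spatial) with *Contextual
Control* (low: Control, Delay; high: Restart, Dual) and *Temporal
Control* (low: Control, Restart; high: Delay, Dual). Each block has a pre
phase of the basic sequencing task (2-5 trials), a sub-task phase (3-5
trials), one return trial and a 1-2 trial post phase (7-13 trials per
block); Control blocks keep the same phase structure as a matched epoch
without a cue change. Under full counterbalancing, phase lengths are drawn
in complementary pairs per cell within each run (pre pairs sum to 7,
sub-task pairs to 8, post pairs to 3), so every run has an identical
trial count and every cell accumulates exactly 4 sub-task trials per
block on average. The default protocol — 2 sessions x 6 runs x 16 blocks
— therefore yields 192 blocks, 1920 trials, 160 trials per run, and 24
blocks / 96 sub-task trials per cell, exactly. When a run holds an odd
number of blocks per cell (e.g. 8-block runs), the unpaired block takes
the central lengths (3, 4, 1, 2) so the balance identities still hold.

Trial onset asynchrony is one TR (2 s) by default, aligning events to the
acquisition grid; the true inter-trial timing of such paradigms is rarely
critical at TR resolution and is configurable. The design translates into
seven DCM input channels: three driving channels (spatial stimuli -> SFS,
verbal stimuli -> IFJ, sub-task cues -> MFG) carrying one impulse per
trial onset (cue impulses at sub-task and return onsets of non-Control
blocks), and four 0/1 modulatory channels (Spatial, Verbal, Contextual,
Temporal) that are on exactly during the sub-task phases of blocks
loading the factor. Control blocks load no modulator; they are the
baseline.

**Impulse convention.** Driving impulses are unit-weight Dirac events
applied as instantaneous state increments `x += C w` at their onset bin,
rather than one-bin boxcars. A boxcar of fixed unit amplitude has an
integral proportional to the integration step, which would make simulated
BOLD depend on the grid; delta kicks make the forward model invariant to
the step (onsets fall on every admissible grid because the step divides
the trial asynchrony) and admit an exact matrix-exponential oracle. `C`
is therefore in units of state increment per event (Hz·s x 1/s of state,
effectively dimensionless per unit event).

## Generative model

Neural dynamics follow the bilinear state equation

    dx/dt = [A + Σ_j u_j(t) B(j)] x + C u(t)

with fixed connectivity `A` (strictly negative diagonal), per-factor
modulations `B(j)` active during sub-task epochs, and driving weights
`C`. Synaptic activity maps to BOLD through a standard balloon model
(vasodilatory signal s, inflow f, venous volume v, deoxyhemoglobin q; the
observation equation yields percent signal change with zero baseline).
Hemodynamic constants are the canonical literature values — signal decay
κ = 0.64 s⁻¹, autoregulation γ = 0.32 s⁻¹, transit time τ = 2 s,
stiffness α = 0.32, resting extraction E0 = 0.4, efficacy ε = 1, resting
volume fraction V0 = 0.04 — all configurable; no empirical values exist
for this paradigm and only the neural parameters are scientifically at
stake here, so they are held fixed during estimation as well.

**Integration.** The neural and hemodynamic states are advanced jointly
by fixed-step classical RK4 on a microtime grid (default TR/16 =
0.125 s), with driving kicks applied at bin starts and modulations
piecewise constant per bin. Joint integration matters: integrating the
hemodynamic chain separately against an interpolated neural trajectory
is only second-order accurate at the kick discontinuities and fails the
convergence requirement below. With the joint scheme, halving the default
step changes simulated BOLD by < 1e-5 (asserted in the tests). A
divergence guard aborts when |x| exceeds 1e6 or the balloon states leave
their physical domain (v ≤ 0), which doubles as a stability flag for
optimizer proposals. Sampling decimates the microtime BOLD to the TR
grid; observation noise is white Gaussian or stationary AR(1) with
configurable lag-1 autocorrelation, seeded.

## Estimation

The observation model is region-wise Gaussian,
`y_r = g_r(θ) + ε_r, ε_r ~ N(0, σ_r² I)`, with `g` the deterministic
forward model. Free parameters carry Gaussian shrinkage priors: A
off-diagonal N(0, 1/16), modulations N(0, 1), driving weights N(0, 1),
self-connections parameterized as `a_ii = -0.5 exp(θ_ii)` with
θ_ii ~ N(0, 1/16) (negativity enforced by construction), and per-region
log noise sd N(log 0.2, 1). The MAP is found on the penalized
log-likelihood with the full parameter vector (noise included).

**Derivatives and optimizer.** The integrator propagates forward-mode
tangents through the exact discrete RK4 scheme, so one pass returns the
simulated BOLD and its Jacobian with respect to every neural parameter to
machine precision (verified against finite differences); noise gradients
are analytic. The default optimizer (`method='auto'`) runs
Levenberg-Marquardt-damped Gauss-Newton from the prior mean (noise
initialized at 0.25x the raw data sd, which keeps the search out of an
"explain everything as noise" local optimum), plus — when `restarts > 1`
— one L-BFGS run from the same start and further Gauss-Newton runs from
jittered prior draws; the best penalized likelihood wins, ties broken by
lowest restart index. Fitting uses a coarser grid (default TR/4) than
simulation; the two differ by < 1e-3 percent signal, far below the noise
floors used anywhere in the package.

**Evidence.** Model evidence is a Laplace approximation at the MAP with
Gauss-Newton curvature `H = JᵀΣ⁻¹J + P₀` (plus the analytic noise
block): log-likelihood plus log-prior plus ½·d·log 2π − ½ log|H|.
Singular curvature is ridge-regularized with a warning. This is
deliberately not a full variational-Bayes free-energy scheme (out of
scope); at the high-SNR desk scales used here the Laplace evidence
separates generating from scrambled structures by hundreds of nats and
penalizes spurious parameters on null data, which the tests check.

Group inference on parameters is a one-sample t-test per free parameter
across subjects with Benjamini-Hochberg FDR; its type-I calibration is
verified on 1000 null cohorts.

## Model space and search

Candidates share the fixed graph (nine bidirectional pairs reconstructed
from the connections the analysis names: FPl-MFG, FPl-IFS, FPl-cMFG,
MFG-IFS, MFG-cMFG, cMFG-SFS, IFS-IFJ, SFS-IFJ, cMFG-IFS) and the driving
assignment, and vary only which directed edges each factor modulates:

* *Stimulus Domain*: dorsal (SFS-cMFG) and ventral (IFJ-IFS) pathways
  with yoked directionality (none / bottom-up / top-down / bidirectional),
  optionally adding bidirectional lateral modulation (SFS-IFJ, IFS-cMFG) —
  8 candidates;
* *Temporal Control*: FPl-MFG, 4 candidates;
* *Contextual Control*: contiguous scopes only — an upper section
  (FPl-MFG plus the rostral-to-mid edges), a lower section (the
  mid-to-caudal edges), or both — crossed with direction, plus none
  (10 candidates). Disjoint rostral+caudal scopes without mid-level edges
  are excluded by a stratum-interval check. The upper section includes
  FPl-MFG because the reference winning structure carries Contextual
  modulation there; within-level dorsal/ventral edges are not offered,
  keeping the candidate grid near the scale a per-factor iteration can
  compare meaningfully.

Random-effects Bayesian model selection fits a variational Dirichlet
posterior over population model frequencies (α0 = 1; responsibilities
proportional to exp(evidence + digamma terms), iterated to 1e-6) and
estimates exceedance probabilities — the probability that a model is more
frequent than every competitor — by Monte Carlo over Dirichlet samples
(default 1e5, seeded, chunked). With K models at identical evidences each
exceedance is 1/K; 99 flat models give 0.01, the uniform reference point.

The greedy search optimizes one factor at a time (Stimulus -> Temporal ->
Contextual), fits every candidate to every subject, selects by exceedance
probability, carries the winner forward, and cycles until a complete pass
changes no assignment (convergence; flagged after 10 cycles). Per-subject
evidences are cached by a canonical model key, so the confirming cycle
refits nothing, and candidate fits warm-start from the incumbent model's
posterior (shared parameters copied by label, new modulations starting at
the prior mean). Warm-started single-restart Gauss-Newton keeps a whole
n=12 search near one minute.

## Hierarchy metrics

Hierarchical strength of a region is mean efferent minus mean afferent
fixed-connection strength over its rostral/caudal connections;
dorsal/ventral pairs at the same level ({SFS, IFJ} caudal, {cMFG, IFS}
mid, with MFG and FPl each their own rostral level) are ignored. Negative
connections are zeroed before averaging by default (their meaning in this
contrast is unclear; the flag is exposed). Averages run over *present*
connections — entries exactly zero are treated as structurally absent,
while zeroed negatives still contribute 0 — so sparse hand-specified
matrices behave as written; estimated matrices always carry both
directions of every edge, for which the distinction is immaterial. With
zeroing off, transposing A negates every strength exactly (asserted).

A least-squares quadratic of strength on MNI y-position summarizes the
profile; the vertex position −b₁/(2b₂) locates the hierarchy's apex and
its height quantifies it. Curvature below 1e-12 (relative to the profile
scale) is flagged degenerate with no vertex — all-zero and strictly
linear profiles land there. Group tests (height > 0; position against the
rostral- and caudal-most y) mirror the reference analysis. Average and
total rostral/caudal connectivity per region are provided as magnitude
controls. The cost-threshold screen declares a region connected to an ROI
at cost c when its connectivity value reaches the (100−c)th percentile of
the ROI's reference distribution (everything qualifies at c = 100);
membership is monotone in cost by construction, and 18% is the
conventional mid-range default.

## Individual differences

Condition-wise measures are z-scored within subject (ddof = 1). Factors
are first principal components of standardized measure sets, sign-aligned
so higher scores mean more of the measured quantity (loadings flipped if
their sum is negative, or if an alignment vector is supplied), which
makes scores deterministic and order-invariant. Correlations are Pearson,
always accompanied by a Huber robust regression (IRLS, tuning constant
1.345) to limit high-leverage outliers. Partial correlations are Pearson
correlations of residuals after regressing controls (and optional subject
dummies) out of both variables, with degrees of freedom reduced
accordingly; a Spearman switch exists. The RT-gradient analysis regresses
Current RT (sub-task trials) and Future RT (return trials) on zone-wise
activation within each subject, submits the slopes to a zone x time
repeated-measures ANOVA, and reports pooled partial correlations with
subject dummies as a secondary view; near-identical Current and Future RT
are flagged collinear. Trait ability is regressed simultaneously on the
top-down, bottom-up and hierarchical-strength factors by OLS and Huber
fits, optionally after excluding subjects more than 2 SD below mean
ability.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with planted ground truth. Latent subject factors (top-down magnitude,
bottom-up magnitude, hierarchical asymmetry, trait ability) are drawn
from a planted correlation matrix (defaults: r(top-down, ability) = 0.5,
r(hierarchy, ability) = 0.5, r(top-down, bottom-up) = −0.5; positive
semidefiniteness is checked). Per subject:

* `A` is positive on the nine edges (base 0.10 Hz, entry noise sd 0.02,
  self −0.5) plus a mid-apex asymmetry: each directed entry gains
  ±κ_s/2 · (s(source) − s(target)) where s(y) = 1 − ((y−20)/30)² peaks in
  mid LPFC and κ_s scales with the subject's hierarchy latent — so
  efferent dominance, and hence the vertex height, peaks at mid LPFC by
  construction;
* modulations follow the reference winning structure: excitatory
  bottom-up SFS→cMFG and IFJ→IFS, excitatory Temporal FPl→MFG, and
  Contextual top-down effects that are inhibitory from FPl and excitatory
  from MFG, with magnitudes 0.25 ± 0.10 Hz scaled by the top-down /
  bottom-up latents (floored at 0.02) and entry noise sd 0.03;
* the five-test ability battery loads 0.75-0.85 on the ability latent
  (unit residuals), giving the inter-correlated structure the factor
  analysis presumes;
* condition RTs reproduce the control interaction (Delay 650 < Control
  720 < Restart 820 < Dual 950 ms on sub-task trials, with a distinct
  return-trial pattern), no stimulus-domain effect, subject intercept sd
  50 ms, cell noise sd 20 ms;
* zone activations load caudal on Current RT, rostral on Future RT and
  mid on both (0.8/0.8/0.5+0.5, noise sd 0.4), the plant for the
  RT-gradient analysis;
* BOLD is simulated per subject from these parameters under the blocked
  design (default noise sd 0.3% white) unless `simulate_bold=False`
  requests a factor-level cohort.

Any subject whose effective coupling would be unstable in an attainable
modulation state (margin 0.02 on the largest real eigenvalue) has
deviations shrunk geometrically toward the population mean on edge
entries and modulations only; every shrink is logged in the ground truth.
Recovery reports give per-parameter bias, RMSE and truth-estimate
correlation, plus negative controls.

**What the generator does not emulate**: scanner artifacts, motion,
physiological noise, hemodynamic variability across subjects or regions,
trial-level RT distributions, session effects, or the sex composition of
a real cohort. Passing tests therefore demonstrate the *internal*
consistency and calibration of the pipeline — that it recovers what it
assumes, controls its error rates, and identifies generating structures
at realistic SNR — not that real LPFC data satisfy the model.

## Problem sizes used by the validation suite

The validation suite runs at sizes a single CPU handles comfortably, as
a design choice: parameter recovery uses 2-node systems (600 scans at
TR 2 s, noise sd 0.1, 20 replicates; median |A error| < 0.05 Hz,
truth-estimate correlation > 0.9); model identification uses 10 cohorts
of 12 subjects with one 8-block run each at noise sd 0.05 (≥ 8/10
recoveries of the planted structure); null calibration uses 1000
factor-level replicates at n = 24; plant recovery uses one factor-level
cohort at n = 500. The same machinery scales to the full protocol — a
24-subject cohort with complete-design BOLD generates in about a second.

## Known limitations

* Evidence is Laplace/Gauss-Newton, not variational Bayes; absolute
  evidences are not comparable to SPM free energies, though rankings
  behave correctly in the tested regimes.
* Hemodynamics are fixed and homogeneous; real inter-regional
  hemodynamic variability would be absorbed into neural parameters.
* The estimation noise model is white (AR(1) is available in the
  generator but not in the likelihood), a simplification relative to
  autoregressive prewhitening in univariate pipelines.
* The greedy search explores the constrained space only; it inherits the
  usual greedy caveat that factor-wise winners need not be the global
  joint optimum, mitigated by the revisit cycles.
* The quadratic vertex is a summary, not a model: with strengths at six
  positions it can sit outside [0, 48] mm for noisy profiles; group
  statistics handle that by averaging over subjects, not by clipping.
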