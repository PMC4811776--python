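# hierdcm

Effective-connectivity modeling of the lateral prefrontal cortex (LPFC)
hierarchy, as a tested, reusable pipeline.

The scientific question is how six LPFC regions — FPl, MFG, IFS, cMFG,
IFJ, SFS, ordered rostral to caudal — influence one another while a
blocked 2x2x2 task manipulates *Stimulus Domain* (verbal, spatial),
*Contextual Control* and *Temporal Control*. The package is for
researchers who want to simulate, estimate and stress-test this style of
analysis end-to-end on synthetic cohorts with planted ground truth.

At its core is the bilinear dynamic causal model (DCM)

    dx/dt = [A + Σ_j u_j B(j)] x + C u

where `A` (Hz) is fixed inter-regional connectivity, `B(j)` the change in
connectivity induced by experimental factor j during sub-task epochs, and
`C` the sensitivity of regions to driving inputs (spatial stimuli → SFS,
verbal stimuli → IFJ, sub-task cues → MFG). Neural states map to BOLD
through a balloon-type hemodynamic model; parameters are estimated by MAP
under shrinkage priors with Laplace-approximate log evidence; candidate
modulation structures are compared by random-effects Bayesian model
selection (Dirichlet posterior over model frequencies, Monte-Carlo
exceedance probabilities) inside a constrained iterative greedy search.
Hierarchy is quantified per region as average efferent minus average
afferent fixed connectivity over rostral/caudal connections, summarized by
a quadratic vertex over MNI y-position; connectivity-derived factors are
related to behavior (Current/Future reaction-time gradients) and to a
trait cognitive-ability factor by correlation, Huber robust regression and
partial correlation.

## Worked example

Generate a 24-subject synthetic cohort at the default planted effect
structure (factor level, no BOLD), summarize its hierarchy, and relate the
connectivity factors to trait ability:

```python
from hierdcm.behavior import correlate_factors, first_eigenvariate_factor
from hierdcm.cohort import CohortConfig, generate_cohort
from hierdcm.hierarchy import vertex_fit

cohort = generate_cohort(CohortConfig(simulate_bold=False), seed=7)
td = first_eigenvariate_factor(cohort.modulations[cohort.topdown_columns].abs())
ab = first_eigenvariate_factor(cohort.ability)

strength = cohort.truth.strengths.mean()
vert = vertex_fit(strength)
print(strength.round(4))
print(f"vertex: y* = {vert.position:.1f} mm, height = {vert.height:.4f} Hz")
print(correlate_factors(td.scores, ab.scores))
```

Output:

```
FPl    -0.0452
MFG     0.0165
IFS     0.0261
cMFG    0.0169
IFJ    -0.0154
SFS    -0.0274
vertex: y* = 22.4 mm, height = 0.0240 Hz
top-down vs ability: r = 0.38 (p = 0.0653), robust t = 1.99
```

Reading the numbers: hierarchical strength (efferent minus afferent
connectivity, Hz) rises from the caudal regions (SFS, IFJ, negative =
net receivers) to the mid regions and falls again at FPl — an inverted-U
whose fitted apex sits at y* = 22.4 mm, i.e. in mid LPFC, with positive
height (the apex is a net sender). The top-down modulation factor
correlates r = 0.38 with the ability factor in this cohort — an
attenuated estimate of the planted latent correlation of 0.5 at n = 24,
which is why single-cohort p-values hover near threshold at this sample
size.

Full-pipeline use (simulate BOLD, fit DCMs, search the model space) goes
through `simulate_dataset`, `DCMEstimator` / `fit_dcm`, and
`GreedyModelSearch` / `greedy_search`; a thin CLI (`hierdcm design|synth|
fit|search|hierarchy|idiff`) wraps the same functions for shell use.

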