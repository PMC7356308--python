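# Methods

## Trajectory model

Pain ratings $y_{it}$ (0–10 numerical rating scale) at visit times $t$
(months since diagnosis: 0, 17/30.44 ≈ 0.56, 6, 12 by default) follow a
K-group finite mixture. Conditional on membership in group $j$, ratings are
independent across visits and normal around a polynomial mean curve
$\mu_j(t)=\sum_{p=0}^P \beta_{jp}(t-c)^p$ with a residual scale $\sigma$
shared across groups (the classic specification; a per-group scale is not
offered because the reference analyses report a single residual process).
The time polynomial is evaluated on months centered at the mid-span of the
schedule ($c = 6$ for the default visits) to reduce collinearity between
powers; the centering constant is stored on the model object so curves are
always reported on the original time axis.

**Censoring.** With the censored-normal option (the default for pain data),
an observation at a scale bound contributes tail mass instead of density:
$\Phi((0-\mu)/\sigma)$ at the floor, $\Phi((\mu-10)/\sigma)$ at the
ceiling. This is what lets a trajectory sit *at* zero pain — a plain normal
cannot produce the observed point mass at the floor. The plain-normal
variant is retained because it has closed-form M-steps and closed-form
single-group solutions, which the tests exploit.

**Fitting.** EM from multiple starts: one start from k-means on per-subject
trajectory vectors (per-visit mean-imputed), the rest from random Dirichlet
posteriors. Without censoring the M-step is exact weighted least squares
with $\sigma^2$ the weighted mean squared residual. With censoring the
expected complete-data log-likelihood is maximized numerically (L-BFGS with
analytic gradients over all $\beta_{jp}$ and $\log\sigma$, warm-started
from the current parameters); if the optimizer fails to improve the
objective the previous parameters are kept, so the generalized-EM
monotonicity guarantee — observed-data log-likelihood non-decreasing at
every iteration — holds in both variants and is asserted in tests.
Convergence: relative log-likelihood change below 1e-8 or 500 iterations;
default 20 starts (tests and the bundled examples use fewer since the
simulated likelihood surfaces here are benign); a mixing proportion
falling below 1e-6 aborts that start as degenerate. Groups are canonically
reordered by mean fitted level (ascending) so outputs are deterministic and
"group 0" is always the low-pain (transient) trajectory; hard assignment is
the posterior argmax with ties to the lower index.

**Selection and adequacy.** A scan over (K, order) cells picks the fit with
minimal BIC $= -2\ell + k\ln n$ where $k = K(P{+}1) + (K{-}1) + 1$ and $n$
counts subjects; ties break toward fewer parameters. The scan table also
carries the log-likelihood-scale convention $\ell - (k/2)\ln n$ used by
some trajectory software, but selection always uses the first form.
Adequacy per group: average posterior probability among assigned subjects
(AvePP > 0.70) and odds of correct classification
$[\mathrm{AvePP}/(1-\mathrm{AvePP})]/[\pi/(1-\pi)] > 5$.

## Composite vulnerability score

Each baseline endpoint is standardized against the pooled cohort — both
trajectory groups together — with the sample (n−1) SD, multiplied by its
vulnerable direction (+1 if a higher raw score marks more vulnerability),
and averaged within subject. The sample-SD choice is deliberate: applied to
the published group summaries it reproduces the published pooled-SD effect
size, which a population-SD reading would not at these group sizes. The
orientation (higher composite = more vulnerable) follows the vulnerability-
score usage; the classical average-z convention points the other way, and a
`flip_sign` option restores it. Subjects with fewer than a configurable
fraction of endpoints available (default 0.5) get a missing composite;
otherwise the mean of the available z-scores is used. Endpoint weighting,
factor analysis and time-to-event endpoints (log-rank scoring in the
classical composite construction) are out of scope — no such endpoint
exists in this battery.

The direction registry ships as a JSON resource covering the full baseline
battery (trail-making, FACT-COG, RAVLT, IPQ-R, HADS, cancer locus of
control, EORTC QLQ-C30, PSQI, EPICES); each entry's polarity rationale is
documented in `instruments.py`. Two genuinely debatable choices: the IPQ-R
personal-control/treatment-control/coherence subscales measure *positive*
beliefs and default to −1 (protective), and users can override any
direction via the same JSON schema.

## Effect sizes and power

Between-group comparisons use pooled-SD Cohen's d with the transient group
first, so a more vulnerable persistent group yields a negative d. The
default CI is the large-sample normal approximation
$d \pm z_{1-\alpha/2}\sqrt{(n_1{+}n_2)/(n_1 n_2) + d^2/(2(n_1{+}n_2))}$,
which reproduces the published interval from the published summaries; an
exact noncentral-t interval is available as an option, as is the Hedges
small-sample correction (off by default for the same reproduction reason).
Longitudinal visit-vs-baseline standardized differences reuse the pooled
two-sample formula over subjects observed at both visits; whether a paired
SD would be the better denominator is ambiguous and flagged in the
docstring. Power for the two-sided two-sample t-test uses the noncentral-t
distribution with noncentrality $d\sqrt{n_1 n_2/(n_1+n_2)}$, so the null
case returns exactly $\alpha$.

## Synthetic cohort generator

The generator emulates the study conditions: 89 subjects split 0.44/0.56
between a transient group (visit means 0, 1.46, 0.27, 0) and a persistent
group (0.86, 2.13, 2.23, 1.68); Gaussian residuals (SD 1.0) drawn
independently per visit given group — within-subject autocorrelation is
deliberately absent, matching the fitted model's conditional-independence
assumption; values clipped to [0, 10] and rounded to the 0.5 rating grid;
monotone dropout with retention 1, 1, 85/89, 73/89 across the four visits
(one uniform draw per subject, so missingness never reverses); and a
20-endpoint baseline battery with exchangeable correlation ρ = 0.3 *on the
direction-aligned scale* plus 5% item-level missingness completely at
random. The per-endpoint group shift is calibrated analytically: the
aligned composite has within-group SD $\sqrt{(1+(m-1)\rho)/m}$ and the
pooled standardization cancels, so $\delta = d\,\sqrt{(1+(m-1)\rho)/m}$
hits a target composite separation of d = 0.8 in the large-sample limit
(verified by simulation at n = 5000).

What the generator does *not* emulate: treatment schedules and their timing
relative to pain, within-subject residual correlation, informative dropout
(missingness is independent of pain given the retention schedule),
non-Gaussian endpoint distributions, and real instrument score ranges for
the synthetic battery (endpoints are standardized-scale Gaussians with
generic ids). Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the stated model, not robustness to the ways
real cohorts violate it.

## Pipeline

The primary analysis uses available observations without imputation — the
mixture likelihood handles unbalanced panels directly — and the LOCF pass
is a sensitivity analysis only, mirroring the reference design; a
complete-case restriction is not a default because it would discard a
fifth of the simulated cohort. Reports are plain JSON with sorted keys and
no timestamps, so a (config, seed) pair regenerates a byte-identical
report; wall-clock timings go to the run log only. The generator's
latent-group truth is written to a separate file the pipeline never reads.

## Problem sizes and numerical choices

Simulation-based tests use n = 300 for recovery and model-selection
replicates (20 replicates per regime) and n = 5000 for calibration checks
of the generator — sizes at which Monte-Carlo error is small relative to
the tolerances being asserted while the full suite stays fast. Model-
selection replicates run the plain-normal likelihood, whose closed-form
M-steps make scans cheap; recovery uses the censored likelihood with an
order-3 polynomial, which interpolates the four visit means exactly and so
makes "recovered curve vs generating curve" a sharp comparison. Two known
small biases: NRS rounding moves latent values near the floor into the
bound category slightly more often than the censored likelihood expects
(a downward shift of order 0.1–0.2 in near-floor visit means at SD 1), and
the k-means start can dominate random starts on well-separated data. Both
are visible in, and bounded by, the recovery tolerances. At the study's own
noise level the Bayes-optimal assignment accuracy is only ≈ 0.9, so
classification metrics sit near that ceiling by construction, not by
estimation error.
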