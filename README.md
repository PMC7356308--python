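# trajvuln

Tools for asking a simple clinical question with honest statistics: **at the
moment of a breast-cancer diagnosis, can a patient's psychosocial profile
predict whether her pain over the following year will be transient or
persistent?**

The package implements the full inference chain used to answer it:

1. **Latent pain trajectories.** Pain is rated on a 0–10 numerical scale at
   scheduled visits (diagnosis, after the first intervention, 6 and 12
   months). Group-based trajectory modeling (GBTM) fits a finite mixture of
   polynomial mean curves,

   $$y_{it} \mid (\text{group } j) \sim \mathcal N\!\Big(\textstyle\sum_p \beta_{jp}\,t^p,\ \sigma^2\Big),
   \qquad P(\text{group } j) = \pi_j,$$

   by multi-start EM, with an optional censored-normal likelihood that puts
   genuine probability mass at the scale bounds (a cohort reporting "0" pain
   at baseline is at the floor, not mid-scale). The number of groups and the
   polynomial order are chosen by BIC; adequacy is judged by the average
   posterior probability per assigned group (> 0.70) and the odds of correct
   classification, $\mathrm{OCC}_j = \frac{\mathrm{AvePP}_j/(1-\mathrm{AvePP}_j)}{\pi_j/(1-\pi_j)} > 5$.

2. **Composite psychosocial vulnerability.** Each baseline questionnaire
   subscore (cognition, emotion, quality of life, precariousness) is
   z-standardized against the pooled cohort, sign-aligned with a per-endpoint
   *vulnerable direction* registry, and averaged within subject — an
   average-z composite endpoint, oriented so higher = more vulnerable.

3. **Effect size between trajectories.** The composite is compared between
   the persistent- (PP) and transient-pain (TP) groups with a pooled-SD
   Cohen's d,

   $$d = \frac{m_1 - m_2}{s_\text{pooled}}, \qquad
   s^2_\text{pooled} = \frac{(n_1-1)s_1^2 + (n_2-1)s_2^2}{n_1+n_2-2},$$

   with a normal-approximation 95% CI, plus noncentral-t power for the
   two-sample t-test. A last-observation-carried-forward (LOCF) pass over the
   pain series repeats the whole analysis as a missing-data sensitivity check.

A synthetic-cohort generator reproduces the statistical structure this
analysis assumes — two latent trajectory groups in a 44/56 split with the
published mean pain curves, NRS granularity, monotone study dropout
(89 → 85 → 73 completers) and a correlated endpoint battery calibrated to a
composite separation of d ≈ 0.8 — so every stage is testable without
patient data.

## Worked example

```python
from trajvuln import (GroupSummary, cohens_d, d_confidence_interval,
                      odds_correct_classification, two_sample_power)

# published composite summaries: TP -0.14 +/- 0.26 (n=39), PP 0.12 +/- 0.36 (n=50)
s = GroupSummary(n1=39, n2=50, m1=-0.14, m2=0.12, s1=0.26, s2=0.36)
res = cohens_d(s)
lo, hi = d_confidence_interval(res.d, 39, 50)
print(f"d = {res.d:.3f}  (95% CI {lo:.2f} to {hi:.2f})")
print(f"OCC = {odds_correct_classification(0.851, 0.415):.2f}")
print(f"power = {two_sample_power(0.8, 50, 39):.3f}")
```

prints

```
d = -0.812  (95% CI -1.25 to -0.38)
OCC = 8.05
power = 0.959
```

— a large negative effect (the persistent-pain group is markedly more
vulnerable at baseline), classification odds 8× better than chance for the
first trajectory, and ample power at the achieved 50/39 group split.

Running the whole pipeline on a simulated study-sized cohort:

```python
from trajvuln import GeneratorConfig, GBTMOptions, PipelineConfig, run

cfg = PipelineConfig(generator=GeneratorConfig(seed=1),
                     gbtm=GBTMOptions(k_range=(1, 2, 3), order_range=(2, 3), n_starts=3),
                     seed=1)
rep = run(cfg)
```

selects a two-trajectory model (`K = 2`, sizes `{'TP': 24, 'PP': 65}`),
passes both adequacy checks (AvePP `[0.868, 0.954]`, OCC `[18.01, 7.57]`)
and finds `composite d = -0.54 (95% CI -1.01 to -0.06)` with a concordant
LOCF sensitivity result `d = -0.58 (95% CI -1.05 to -0.12)` — the direction
and rough magnitude of the separation survive at n = 89 despite assignment
noise.

The same stages are scriptable from a shell:

```bash
trajvuln simulate --seed 1 --out sim/
trajvuln gbtm --cohort sim/cohort.csv --k 2 --order 2 --censored --starts 20 --seed 1
trajvuln score --endpoints sim/endpoints.csv --registry sim/registry.json
trajvuln run --config config.json
```

## Layout

| module | contents |
| --- | --- |
| `trajvuln.cohort_io` | long-format pain cohorts, endpoint matrices, CSV/JSON I/O, LOCF |
| `trajvuln.synthetic` | study-structured cohort generator with latent-group truth |
| `trajvuln.instruments` | score ranges, categorical cutoffs, vulnerable-direction registry |
| `trajvuln.gbtm` | mixture likelihood, EM fitting, BIC scan, posterior diagnostics |
| `trajvuln.vulnerability` | pooled z-standardization and the average-z composite |
| `trajvuln.effects` | pooled-SD d, confidence intervals, noncentral-t power |
| `trajvuln.pipeline` / `trajvuln.cli` | one-config orchestration and the `trajvuln` command |

See `docs/methods.md` for modeling assumptions, defaults and limitations.
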