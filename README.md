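# serialdep

Serial dependence in orientation estimation: generative observer models,
synthetic adjustment-task experiments, the density-asymmetry bias-analysis
pipeline, and simulation-based power analysis.

## The problem

In orientation-adjustment tasks (rotate a bar to match a remembered Gabor
patch), reports are systematically attracted toward recently seen stimuli —
*serial dependence* (SD).  The bias is small (a few degrees), peaks at
intermediate stimulus differences (~35°), and its strength depends on how
precisely the previous and current items were encoded, which is exactly
what attention and memory prioritization manipulate.  This package
implements, end to end and without any data download, the computational
machinery used to study that question:

* **Bayesian observer** — per trial the observer measures the stimulus
  through wrapped-normal noise, `p(x|s) = f_WN(x; s, σ²)`, and holds a
  grid belief over orientation.  Consecutive stimuli are assumed related
  through a slow-change transition prior
  `p(s_t; s_{t-1}) = p_same · C(s_t; s_{t-1}, σ_s, γ) + (1−p_same) · U`,
  with `C ∝ exp(−|angle(s_t, s_{t-1})|^γ / 2σ_s²)`.  The prior for each
  trial is the previous posterior circularly convolved with that mixture;
  the response is the posterior circular mean.  Defaults: σ_s = 16.9°,
  γ = 2.6, p_same = 0.64, per-trial noise drawn from {6, 9, 12}°.
* **Demixing Model** — per trial the observer receives N = 100 bivariate
  measurements (orientation × a linear "temporal" dimension), each from
  the current or the previous source,
  `p(x_i|θ) = Σ_j π_j f_WN(x_i1; μ_1j, σ²_1j) · f_N(x_i2; μ_2j, σ²_2j)`,
  demixes them by maximum likelihood (multi-restart EM, Nelder–Mead
  polish) and reports the orientation mean of the component judged most
  recent (larger temporal mean).  Misattribution produces attraction with
  a non-monotonic dependence on the current item's noise.
* **Synthetic experiments** — seeded trial tables with the statistical
  structure of three designs: streaks of two sequential Gabors with a
  report-and-hold cue on a third of streaks (648 trials), and dual-stimulus
  pre-/post-cue designs with 75 % cue–report congruence (720 trials); a
  derivative-of-Gaussian (DoG) serial bias of configurable amplitude and
  width is planted toward the previous reported stimulus, plus optional
  cardinal bias and outliers.
* **Bias analysis** — per-participant cardinal-bias removal (two-harmonic
  regression on the doubled/quadrupled stimulus angle), outlier and
  participant exclusion, signed-bias computation, kernel-weighted
  density-asymmetry curves over dissimilarity 0–90°, per-degree t /
  repeated-measures-ANOVA tests with cluster reporting, and peak
  localization.
* **Power analysis** — Monte-Carlo power for the designs: simulate many
  datasets with a planted between-condition amplitude difference, fit
  per-participant DoG amplitudes, apply the design's test (paired t or
  repeated-measures ANOVA), count rejections.

All circular statistics live on the 180°-periodic orientation space
(doubled-angle representation internally); everything is driven by
explicit seeds.

## Worked example

```python
import serialdep as sd

# generate a streak-design experiment with a planted 2-deg bias at 35 deg
table = sd.generate_experiment(
    sd.DesignSpec.exp1(n_participants=18),
    profiles=sd.SDProfile(amplitude=2.0, width=35.0),
    noise=sd.NoiseSpec(response_sd=9.0),
    seed=401,
)
pre = sd.preprocess(table)
biases = sd.signed_bias(pre)
biases = biases[biases["role"] != "response3"]

curve = sd.density_asymmetry_curve(biases)
print(sd.peak_location(curve))
print(sd.mean_bias_test(biases)[["condition", "mean_asym", "t", "p"]])
```

prints

```
{'peak': 39.0, 'boundary': False, 'flat': False}
  condition  mean_asym         t             p
0       all   0.109085  9.083516  6.213700e-08
```

i.e. the pipeline recovers the planted bias: the curve peaks at 39°
(planted width 35°, within the smoothing bandwidth), and the mean density
asymmetry across the 18 simulated participants (0.11: errors fall toward
the previous stimulus 11 percentage points more often than away) is
highly significantly positive.  `examples/` contains one short script per capability
(observer simulation, demixing, generation, analysis, power).

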