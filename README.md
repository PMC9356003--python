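# myosynergy

Muscle-synergy analysis of motor control and phantom-limb perception after
transtibial amputation — for motor-neurophysiology and neuroprosthetics
researchers who want a tested, reusable implementation of the full analysis
chain, from multichannel EMG envelopes to population-level statistics.

The scientific question the pipeline addresses: how much of the
agonist-antagonist muscle strain (AMS) of an intact limb must a residual
limb preserve to retain natural motor control and limb perception?  Each
sensory-motor response variable y is related to the AMS degree
a ∈ [0, 1] by a first-order exponential response curve

    y = y∞ (1 − e^{−λ a}),    AMS_c = ln(20)/λ

whose critical degree AMS_c marks where the curve reaches 95% of its
asymptote.  Upstream of that statistic the package implements:

* **EMG processing** — 20 Hz zero-lag 4th-order Butterworth high-pass,
  full-wave rectification, 5 Hz low-pass, normalization to calibrated
  maxima (`myosynergy.emg`).
* **Synergy extraction** — multiplicative-update NMF,
  m(t) = Σ c_i(t) w_i + ε(t), with best-of-30-restarts selection, a
  VAF-plateau stopping rule and VAF > 0.95 model selection
  (`myosynergy.synergy`).
* **Naturalness** — muscle-synergy and synergy-activation similarity to
  the biologically intact reference via greedy scalar-product matching,
  leave-one-out for the reference group (`myosynergy.naturalness`).
* **Motor-intent decoding** — fixed-basis non-negative least squares into
  synergy space and angular decoding to the (α_INEV, α_PFDF) intent plane;
  activation margins φ_ij for movement decoupling (`myosynergy.decoding`).
* **Motor metrics** — 2-DoF controllability from diagonal velocity
  components, speed-accuracy motor-control performance and economy of
  motion, Fitts-style index of difficulty (`myosynergy.metrics`).
* **Perception** — psychometric (cumulative-Gaussian) fits of perceived vs
  intended phantom position and the limb-perception-capacity summary
  (`myosynergy.perception`).
* **Statistics** — AMS degree from fascicle-strain summaries, one-sided
  Kendall τ, exponential response fits with jackknife AMS_c, and the group
  test battery (`myosynergy.response`).
* **Synthetic cohort** — virtual limbs whose synergy corruption, intent
  trajectories and perception gain degrade along configured response
  curves, so the whole chain is testable without human recordings
  (`myosynergy.synthetic`).

Individual participant recordings of this kind are not publicly
available; the synthetic generator is therefore a first-class, tested
component and every stage is validated against it.  See
[docs/methods.md](docs/methods.md) for the model details and known
limitations.

## Worked example

```python
from myosynergy import CohortConfig, PipelineConfig, run_pipeline, render_report, results_summary

cfg = PipelineConfig(
    cohort=CohortConfig(discrete_reps=8, circle_cycles=4, speed_reps=2),
    nmf_restarts=8,
)
res = run_pipeline(cfg, seed=1)
print(res.table[["limb_id", "group", "ams_degree", "n_synergies",
                 "mss", "sas", "twodof", "lpc"]].head(4).round(3))
print(render_report(results_summary(res)))
```

prints the per-limb table (first rows)

```
limb_id group  ams_degree  n_synergies   mss   sas  twodof   lpc
  AMI-1   AMI        0.19            3 0.940 0.947   0.526 0.593
 BIO-A1 BIO-A        1.00            3 1.000 1.000   0.529   NaN
  AMI-2   AMI        0.30            3 0.989 0.989   0.549 0.745
 BIO-A2 BIO-A        1.00            3 1.000 0.999   0.523   NaN
```

and the response-curve report (excerpt)

```
AMS response-curve statistics (residual limbs, n = 14)

muscle synergy similarity: tau = 0.97, P = 7.01e-07; AMS_c = 0.20 +- 0.00 (jackknife), R^2 = 1.00
synergy activation similarity: tau = 0.95, P = 1.21e-06; AMS_c = 0.18 +- 0.00 (jackknife), R^2 = 0.97
limb perception capacity: tau = 0.97, P = 8.89e-07; AMS_c = 0.50 +- 0.00 (jackknife), R^2 = 0.99
```

Reading: every limb needed 3 synergies; similarity of each residual limb's
synergies to the intact reference rises steeply with its AMS degree, and
the fitted critical degree AMS_c ≈ 0.20 says that preserving ~20% of
intact-limb muscle strain already preserves 95% of natural synergy
structure, while limb perception requires far more (AMS_c ≈ 0.5–0.6).
`mss`/`sas` are muscle-synergy/synergy-activation similarity, `twodof` the
2-DoF controllability (noise-limited at this cohort's EMG noise level —
see the methods note), `lpc` the limb perception capacity (phantom limbs
only, hence NaN for intact limbs).

A command-line interface mirrors the stages
(`myosynergy simulate|preprocess|extract|naturalness|decode|metrics|perception|respond|run|report`),
reading and writing plain CSV/JSON/YAML artifacts in a workspace
directory:

```sh
myosynergy run --out ws --seed 1
myosynergy report --stats ws/stats.json
```

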