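# covertrace

Quantitative analysis of ocular deviation under monocular occlusion, as
recorded by video-oculography (VOG) during the cover test.

When one eye is covered, binocular fusion is interrupted and a latent
misalignment (heterophoria) — or the full extent of a manifest one
(heterotropia) — is revealed as the covered eye drifts to its fusion-free
position. Clinically this deviation is quantified with the alternate prism
cover test (APCT), which is examiner-dependent and gives no information
about *how* the eye moves behind the cover. An eye tracker that keeps
recording the occluded eye turns the cover test into a time-resolved
measurement: how large is the deviation, how fast does the eye move, how
long until it stabilizes, and does it transiently overshoot its final
position?

`covertrace` implements that analysis as a tested library:

- **Model.** The signed deviation signal (exodeviation negative) of a trial
  is fitted with a four-parameter logistic
  `f(t) = L0 + a / (1 + exp(−k(t − t0)))`, where `a` is the deviation angle
  (difference between the two asymptotes), and the trial statistics follow
  in closed form: peak deviation speed `b = |a|·k/4`, stabilization time
  `t* = t0 + ln(9)/k` (the time after occlusion onset to reach 90% of the
  deviation), and overshoot depth `d′ = max(0, |d − L0| − |a|)` with `d` the
  most extreme post-onset deviation of the lightly smoothed raw signal.
- **Simulator.** Seedable phoric traces (slow sigmoidal drift, optional
  overshoot transient, Gaussian noise, blink dropouts), tropic traces
  (saccadic refixation with corrective rebound-saccade), and cohorts whose
  deviation rate is coupled to deviation amplitude — with analytic ground
  truth attached to every trace.
- **Statistics.** Degree ↔ prism-diopter conversion (`PD = 100·tan θ`),
  Spearman rank correlation with an *exact* permutation p-value for small
  samples (full enumeration via dynamic programming up to n = 13), paired
  t comparison against the APCT, and a cohort summary.
- **Pipeline/CLI.** `covertrace simulate | fit | cohort | plot` tie the
  stages into one reproducible run (identical config + seed ⇒ byte-identical
  outputs).

## Worked example

Fit one simulated trial (a = −6°, k = 2/s, t0 = 1.5 s, 0.8° overshoot
transient, 0.2° measurement noise at 30 Hz):

```python
from covertrace import (PhoriaTraceParams, simulate_phoria_trace,
                        fit_logistic, compute_metrics)

trace = simulate_phoria_trace(PhoriaTraceParams(
    deviation_deg=-6.0, rate_per_s=2.0, midpoint_s=1.5,
    overshoot_amp_deg=0.8, noise_sd_deg=0.2, seed=42))
m = compute_metrics(trace, fit_logistic(trace))
print(m.angle_deg, m.angle_pd, m.peak_speed_deg_s,
      m.stabilization_time_s, m.overshoot_depth_deg, m.overshoot_category)
```

prints (rounded)

```
a  = -6.28 deg  ( -11.01 PD )
b  = 4.419 deg/s
t90= 2.208 s
d' = 1.264 deg  category: gt1
```

i.e. a 6.3° exodeviation drifting at a peak 4.4°/s, stabilized 2.2 s after
occlusion onset, with a measured overshoot of 1.3° (the generating
transient was 0.8°; the rest is the documented extreme-value noise floor of
the depth statistic — see `docs/methods.md`).

A full cohort run from the shell:

```sh
$ covertrace cohort --n-subjects 13 --seed 1 --out demo --no-figures
fitted 13 subjects; outputs in demo
stabilization time: 2.77 ± 0.49 s
angle vs speed rs=-0.940 (p=0.0000); angle vs stabilization rs=0.852 (p=0.0004); depth vs speed rs=0.940 (p=0.0000)
```

The signs are the clinically expected pattern: larger (more negative)
exodeviations drift faster, smaller ones take longer to stabilize, and
deeper overshoots accompany faster drifts. `demo/` contains the per-subject
`metrics.csv`, the cohort `summary.json`, the trace CSVs with ground-truth
sidecars, and a `manifest.json` that pins config, seed and versions.

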