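# streamconn

Functional and structural connectivity analysis of the two visual streams,
with a synthetic cohort generator that makes the entire pipeline testable
without any imaging data.

The package targets a common study design in visuomotor neuroscience:
two groups (here "gamers" and "nongamers"), resting/task BOLD time series
sampled at TR = 535 ms over four runs (3440 volumes), fourteen spherical
ROIs spanning the dorsal visual stream (DVS), ventral visual stream (VVS)
and the primary calcarine connections (VS), and per-connection anisotropy
metrics (FA, QA) from tractography exports. It provides:

* **Undirected functional connectivity (FC)** — pairwise Pearson correlation
  between voxel-averaged, detrended, z-normalized ROI series.
* **Directed connectivity (TGC)** — frequency-domain Granger causality on a
  bivariate VAR(p). With innovation covariance Σ and transfer function
  H(f) = (I − Σₖ Aₖ e^(−i2πfk/fs))⁻¹, the spectral matrix is S(f) = HΣH*
  and the causality from region 2 to region 1 is

      I₂→₁(f) = ln [ S₁₁(f) / (S₁₁(f) − (Σ₂₂ − Σ₁₂²/Σ₁₁) |H₁₂(f)|²) ]

  integrated over the analysis band f₁ = 0.05 Hz to f₂ = 0.9 Hz:

      F₂→₁ = (1/(f₂−f₁)) ∫ I₂→₁(f) df

* **Model-order selection** by minimizing the spectral difference between the
  VAR's parametric spectrum and a held-out Welch cross-spectral estimate
  (orders 2–20 scanned; order 6 is the packaged default).
* **Group statistics** — Wilcoxon rank-sum per connection with
  Holm–Bonferroni correction within each subsystem family (DVS, VVS, VS),
  and Spearman brain–behavior correlation of connectivity with response time.
* **Synthetic cohorts** — 28 gamers / 19 nongamers with VAR(6)-driven signals
  on the designated dorsal pair (L SOG → L SPL), response times linked
  negatively to the directed coupling (~190 ms group gap), and FA/QA tables
  with a group shift on the designated dorsal connection.

## Worked example

```python
import numpy as np
import streamconn as sc

cohort = sc.generate_cohort(sc.CohortConfig(seed=1))
ts = sc.simulate_subject_pair(cohort, "G03")          # 4 runs x 860 samples
fwd, rev = sc.directed_gc(
    ts.data.to_numpy(), order=6, fs=cohort.config.fs,
    band=(0.05, 0.9), run_lengths=ts.run_lengths, names=("L SOG", "L SPL"),
)
print(f"TGC L SOG->L SPL: {fwd.tgc:.4f}   reverse: {rev.tgc:.4f}")
x = ts.data.to_numpy()
print(f"FC: {sc.pearson_fc(x[:860, 0], x[:860, 1]):.3f}")
```

prints

```
TGC L SOG->L SPL: 0.1388   reverse: 0.0060
FC: 0.112
```

The directed influence runs from the superior occipital gyrus to the
superior parietal lobule (the designed direction); the reverse direction
sits at the estimation noise floor. The same quantities computed for every
subject and correlated with response time give the brain–behavior
relationship (negative: stronger coupling, faster responses).

The command-line pipeline runs end to end:

```bash
streamconn synth  -o data --seed 1
streamconn analyze --data data -o results
streamconn report --results results -o report
```

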