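# f1rotary

Analysis toolkit for single-molecule rotation assays of F1-ATPase — the
rotary motor whose γ shaft turns inside the α3β3 stator ring, advancing in
discrete steps separated by pauses (ATP-binding waits, catalytic waits, and
briefer sub-pauses). The package covers the full trace-to-kinetics
workflow used to characterise hybrid F1 complexes whose α, β and γ
subunits come from different species (thermophilic *Bacillus* PS3 "T",
*Paracoccus denitrificans* "P", bovine mitochondria "b"):

* **Rotary traces** (`f1rotary.trace`) — read/write delimited
  (time, angle) or (time, x, y) probe tables, convert centroids to
  unwrapped angles, and estimate bulk rotation rates.
* **Synthetic traces** (`f1rotary.simulate`) — a stepping-motor generator
  with 1–3 pauses per 120° repeat, exponential dwells, instantaneous
  steps and Gaussian angular noise, plus Michaelis–Menten rate datasets.
* **Change-point detection** (`f1rotary.changepoint`) — nonparametric
  pause-boundary detection: for a segment x₁…xₙ the statistic
  D = max(CUSUM) − min(CUSUM), with CUSUM(t) = Σ_{t'≤t}(x_{t'} − x̄), is
  calibrated by a permutation test; significant change points are placed
  by least-squares localisation and found recursively by binary
  segmentation. A cleanup pass merges adjacent intervals whose medians
  differ by less than A·(MAD_i + MAD_{i+1}), with A chosen from the
  squared-error sweep.
* **Pause analysis** (`f1rotary.pauses`) — interval histograms, the
  7-point and 40° filters, pause counting (3/6/9-stepper evidence), the
  angular distance ratio a/b between main and sub-pauses, and
  hierarchical clustering of mean ratios.
* **Kinetics** (`f1rotary.kinetics`) — Michaelis–Menten fits
  v(S) = V_max·S/(K_m + S), catalytic efficiency k_on = 3·V_max/K_m, and
  the nine-term quadratic composition model
  V_max/V̄ = a_α·V_α + a_β·V_β + a_γ·V_γ + a_αβ·V_α·V_β + a_αγ·V_α·V_γ +
  a_βγ·V_β·V_γ + a_αα·V_α² + a_ββ·V_β² + a_γγ·V_γ², where each variable is
  the genuine V_max of that subunit's origin divided by the mean V̄ of the
  three genuine values, with predictions over the 3×3×3 composition
  lattice and drop-one-term minimality checks.
* **Pipeline & CLI** (`f1rotary.pipeline`, `f1rotary` command) —
  end-to-end seeded runs from a single config.

## Worked example

```python
import f1rotary as f1
from f1rotary.simulate import MotorScheme, Pause
from f1rotary.pipeline import RunConfig, analyze_trace

# six-stepper with TF1 pause geometry: catalytic (main) dwell 10 ms at 80
# degrees per 120-degree repeat, 1 ms sub-pause at the binding angle
scheme = MotorScheme(
    pauses=(Pause(0.0, 1e-3, "binding"), Pause(80.0, 10e-3, "catalytic")),
    noise_sd=8.0,
)
trace = f1.simulate_trace(scheme, duration=5.0, fps=10_000, seed=3)
result = analyze_trace(trace, RunConfig(seed=3))
print(result.n_pauses_per_turn)                  # 6
print([round(p, 1) for p in result.peak_angles]) # [0.1, 80.0, 120.1, 199.9, 239.4, 320.1]
print(round(result.mean_ratio, 3))               # 0.508
```

The pipeline detects the change points, merges spurious ones (selected
merge factor A* = 2.0 here), drops intervals shorter than 7 frames and
non-progressive fluctuations, counts 6 pause clusters per turn, and
recovers the angular distance ratio a/b ≈ 0.5 — the signature of a
sub-pause 40° after each main pause (40°:80°). The same pipeline on a
midway sub-pause geometry returns ≈ 1.0 (60°:60°).

Fitting the quadratic composition model to the packaged table of measured
V_max values:

```python
from f1rotary import kinetics as kin
fit = kin.fit_quadratic(kin.load_reference_compositions())
print(round(fit.coefficients["a_ab"], 3))      # 0.469
print(round(kin.predict_vmax(fit, "TTP")))     # 288 rps
```

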