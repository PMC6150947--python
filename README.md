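# meshbench

Spatial benchmarking of MEG source-reconstruction algorithms against
systematically distorted cortical anatomy.

## The problem

Magnetoencephalography measures magnetic fields outside the head; inferring
the cortical currents behind them is ill-posed, and every inversion
algorithm closes the gap with a different prior on the source covariance.
Comparisons based on hand-picked tasks or simulations inherit the biases of
that choice. `meshbench` implements an alternative: use plentiful,
heterogeneous resting-state-like data, and ask each algorithm how small a
distortion of the cortical surface it can still reliably tell apart from
the true anatomy. An algorithm that genuinely uses the anatomy must get
worse when the anatomy is wrong; the distortion at its detection threshold
is a resolution figure in millimetres.

The pipeline: sensor data are partitioned into quasi-stationary network
states with a hidden Markov model (8 states on 40 PCA components, 200 ms
modal epochs, the 4 most-occupied states carried forward); each state
dataset is inverted — under a common empirical-Bayes machinery in which
**only** the source-covariance prior changes — onto every mesh of a
weighted-Fourier-series (WFS) library,

    f_L(ω) = Σ_{l≤L} Σ_m e^{−l(l+1)σ} f_lm S_lm(ω),    σ = 1e-4,

which spans smooth ovoids (L = 1) to the true surface (L = L_max = 50).
Model fit is scored by ten-fold held-out-channel cross-validation (CV%,
the percent of held-out sensor data explained) and by ReML free energy F;
both are normalized by the true-mesh value (ΔCV, ΔF ≤ 0). Group t-tests
(ΔCV) and Bayesian model comparison (ΔF) across subjects locate the
highest distinguishable harmonic (HDH), which is converted to mm as the
95th percentile of corresponding-vertex distances.

Four priors are built in: **MMN** (identity; classical minimum norm),
**LOR** (surface Green's-function smoothing; LORETA-like), **EBB**
(empirical Bayesian beamformer; variances from the sensor covariance),
and **MSP** (multiple sparse priors; 512 patch components with ARD
pruning). A synthetic-data module generates folded genus-0 cortices,
spherical-cap magnetometer arrays, Markov state-switching source activity,
power-calibrated sensor noise, and the channel-shuffling control, so the
whole benchmark runs without any recordings.

## Worked example

```python
from meshbench.config import RunConfig
from meshbench.cli import run_pipeline

cfg = RunConfig.tiny(seed=1)          # 642-vertex cortex, 64 channels,
out = run_pipeline(cfg)               # 2 states, +5 dB, 8 seed-subjects
for kind in ("EBB", "MMN"):
    res = out["per_kind"][kind]["result"]
    print(kind, "HDH:", res.hdh_cv, " mm: %.2f" % res.mm_mean,
          " true-mesh CV%%: %.1f" % out["per_kind"][kind]["true_cv"].mean())
```

prints (a few minutes on one CPU):

```
EBB HDH: 8  mm: 3.86  true-mesh CV%: 33.9
MMN HDH: 6  mm: 7.46  true-mesh CV%: 32.2
```

Read: with the beamformer prior the group can still distinguish the
order-8 mesh (3.9 mm from the truth at the 95th distance percentile) from
the true anatomy, while the minimum-norm prior loses track two harmonic
orders earlier (7.5 mm) — the beamformer both explains more held-out data
at the true mesh and is more sensitive to anatomical error, the same
ordering the benchmark is designed to expose. Group-mean ΔCV and ΔF rise
monotonically with harmonic order (Spearman ρ ≈ 0.9); shuffling channel
labels (`run_pipeline(cfg, n_shuffles=...)`) destroys and slightly
reverses that relationship, and at −20 dB SNR no harmonic remains
distinguishable.

A command-line interface exposes the same pipeline stage by stage
(`meshbench simulate|partition|library|invert|evaluate|all --config FILE
--out DIR [--tiny] [--prior ebb ...]`), communicating through GIfTI/TSV/
HDF5/JSON artifacts.

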