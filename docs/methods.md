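# Methods

## The benchmark in one paragraph

MEG source reconstruction is ill-posed: many source configurations explain
the same sensor data, and every inversion algorithm resolves the ambiguity
with a different prior on the source covariance. `meshbench` scores
algorithms by their *anatomical discrimination*: resting-state-like sensor
data are inverted onto a library of progressively distorted cortical
meshes, and an algorithm is better the smaller the mesh distortion it can
still reliably distinguish from the true anatomy. The distortion at the
threshold — the highest distinguishable harmonic (HDH) — is converted to
millimetres through corresponding-vertex distances, giving a spatial
resolution figure that does not depend on any particular cost function.

## Pipeline

1. **State partitioning.** Continuous data are band-passed 1–90 Hz with a
   48–52 Hz notch (both zero-phase 4th-order Butterworth), resampled to
   250 Hz, reduced by PCA to standardized component scores, and segmented
   by a Gaussian-observation hidden Markov model (full covariance per
   state, EM with restarts, Viterbi statepath). Non-overlapping 200 ms
   epochs are tagged with their modal state (ties to the lower index) and
   the most-occupied states are carried forward. Partitioning into
   quasi-stationary states matters because the Gaussian model underlying
   the inversion assumes stationarity within the inverted data.
2. **Mesh library.** The cortical surface (closed, genus 0) is mapped to
   the unit sphere (radial projection, with uniform-Laplacian inflation as
   fallback), each coordinate function is expanded in real orthonormal
   spherical harmonics by regularized least squares, and the surface is
   re-synthesized at orders L = 1..L_max with the weight
   `exp(-l(l+1)·sigma)` per degree (`sigma = 1e-4`). Vertex correspondence
   and face topology are preserved exactly, so per-vertex distances to the
   true mesh are well defined.
3. **Forward model.** Sarvas closed-form fields for current dipoles in a
   homogeneous conducting sphere, with sources at mesh vertices oriented
   along outward surface normals (units: mm, nAm, fT). Radial dipoles are
   exactly silent; the implementation returns exactly 0 for them,
   including a dipole at the centre. The gain interface accepts external
   matrices for users with realistic head models.
4. **Inversion.** Linear-Gaussian empirical Bayes: the sensor covariance
   is modelled as `Sigma_y = h0·Q_noise + sum_k h_k·L C_k L'`, with the
   source components C_k defining the algorithm — MMN (identity), LOR
   (surface heat-kernel smoothing `G G'`, `G = exp(s·A)` with A the
   row-normalized adjacency, s = 0.6 by default), EBB (diagonal beamformer
   powers `1/(l_i' Cy^-1 l_i)`, zero regularization, unit trace), MSP
   (rank-1 patch components `g_k g_k'` at farthest-point-sampled seed
   vertices, 512 by default). Hyperparameters are optimized on the log
   scale by Fisher-scored ReML with backtracking (the objective never
   decreases), under weak Gaussian hyperpriors (mean −32, variance 256 on
   the trace-normalized scale). Components collapsing 16 log-units below
   the leading one are pruned (ARD behaviour; only relevant for MSP).
   The reported free energy adds the Laplace volume term
   `K/2·log 2π − ½ log|H|` at the optimum and is rescaled to the data's
   original units.
5. **Scoring.** Per fold, a random 10% of channels are held out (folds are
   independent draws, not a partition), 16 temporal modes are computed on
   the retained channels (eigenvectors of the epoch-averaged temporal
   covariance), the model is fitted, MAP sources
   `J = Q_s L' Sigma_y^-1 Y` are projected through the held-out lead
   fields, and the prediction is scored as
   `CV% = 100·(1 − ‖Y − Ŷ‖²/‖Y‖²)` in sample space. CV% is averaged over
   10 folds and the dominant state datasets; free energy comes from
   full-channel fits and is summed over state datasets. Both metrics are
   normalized by subtracting the true-mesh value (ΔCV, ΔF), making
   ΔCV = 0 at the true mesh an identity.
6. **Group statistics.** Per harmonic: a two-sided one-sample t-test of
   ΔCV against zero across subjects, and random-effects Bayesian model
   comparison on ΔF (variational Dirichlet over model frequencies,
   exceedance probability by seeded Monte-Carlo). The HDH is the largest
   harmonic with p < alpha and mean Δ < 0; because that reading is
   ambiguous, the largest harmonic whose entire lower tail qualifies is
   also reported (`hdh_contiguous`). No multiplicity correction is
   applied, and the output says so. The HDH is converted to mm as the
   95th percentile (linear interpolation) of per-vertex distances between
   each subject's HDH mesh and their true mesh; since "mean distance" is
   an equally defensible summary, both are reported.

## Synthetic data

The generator emulates the statistical structure the benchmark relies on,
not MEG physics in detail:

* **Cortex** — an icosphere (radius 70 mm) radially perturbed by a random
  band-limited harmonic field (degrees 2..`fold_frequency`, coefficient
  amplitude ∝ degree, unit RMS) scaled by `fold_amplitude` (default
  5 mm): multi-scale folds with a controllable finest scale. A
  two-component option provides a two-ovoid stand-in for hemispheres.
* **Sensors** — quasi-uniform golden-angle layout on the upper cap of a
  120 mm sphere outside a 95 mm spherical conductor, radial pickup.
* **Activity** — a first-order Markov chain over `n_states` network
  states (mean dwell 200 ms, the scale of resting-state transitions);
  each state owns a few fixed vertices whose unit-variance Gaussian
  processes, band-passed to the 1–90 Hz analysis band and scaled in nAm,
  drive the sensors through the lead fields while the state is active.
* **Degradations** — white sensor noise calibrated on broadband power
  pooled over channels and samples (`10·log10(P_sig/P_noise)` equal to
  the requested dB; the power convention is an explicit choice), and
  channel shuffling, which permutes data rows under fixed labels and is
  invertible via the recorded permutation.

What it does **not** emulate: gradiometer pickup geometry, head movement,
physiological artifacts, 1/f spectra, spatially extended patches, or
inter-subject anatomical structure. Passing benchmarks on this generator
therefore demonstrates the machinery's correctness and the qualitative
behaviour of the priors (monotone improvement toward the true anatomy,
its reversal under shuffling, its collapse under noise) — not the
absolute millimetre figures one would obtain on human recordings, which
additionally depend on the real head model and data.

## Default parameters

| Parameter | Default | Meaning |
|---|---|---|
| `wfs.sigma` | 1e-4 | WFS smoothing bandwidth (dimensionless) |
| `wfs.L_max` | 50 | library harmonic orders 1..L_max |
| `hmm.K` | 8 | HMM states |
| `hmm.n_pca` | 40 | PCA components for the HMM (unit variance, zero mean) |
| `hmm.epoch_ms` | 200 | epoch length; 50 samples at 250 Hz |
| `hmm.n_dominant` | 4 | state datasets carried to inversion |
| `inversion.R` | 16 | orthonormal temporal modes |
| `inversion.msp_patches` | 512 | MSP patch components |
| `inversion.smooth_s` | 0.6 | heat-kernel extent for LOR/MSP (graph units) |
| `cv.n_folds` / `cv.holdout_frac` | 10 / 0.10 | cross-validation scheme |
| `stats.alpha` | 0.05 | per-harmonic significance level |
| `stats.bmc_draws` | 1e5 | Dirichlet Monte-Carlo draws |
| shuffle control | 10 repeats | per-subject label shuffles, ΔCV averaged |
| `sim.state_dwell_ms` | 200 | mean state dwell |
| `sim.fs` / `sim.duration_s` | 1200 Hz / 600 s | recording length |

## Problem sizes used by the test suite and acceptance script

The shipped suites run the complete pipeline at a desk-scale operating
point chosen once (`RunConfig.tiny()`): 642-vertex cortex with 5 mm folds
(band degrees 2–8), 64 channels, 2 states, 40 s at 600 Hz, L_max = 8,
R = 8, K = 2, 16 PCA components, 10 folds, 8 seeds treated as the subject
group, 4 shuffle repetitions per subject for the control, and a matched
-20 dB rerun for the noise-degradation check. The fold band tops out at
degree 8 so the L ≤ 8 library never saturates into an exact copy of the
truth. At this operating point EBB reliably discriminates finer
distortions than MMN (higher HDH, smaller mm bound) and both show
Spearman ρ > 0.8 monotonicity of group-mean ΔCV/ΔF in harmonic order.

## Numerical choices and edge cases

* **Spherical harmonics** are real, orthonormal and Condon–Shortley-free;
  coefficients are fitted by ridge-stabilized normal equations
  (ridge 1e-9 relative) on the vertex sampling. Because that sampling is
  not exactly uniform, truncation error is monotone in L only to ~1%.
* **ReML**: hyperparameters start at equal shares of the data trace;
  Newton steps are clipped to ±8 log-units and backtracked until the
  objective is non-decreasing (asserted to 1e-10 in tests);
  non-convergence returns the best iterate with a warning and a flag.
* **EBB** inverts the sensor covariance by symmetric eigendecomposition,
  clipping eigenvalues below `1e-12·λ_max` (a numerical pseudo-inverse;
  no diagonal loading). On exactly rank-deficient data the beamformer
  power estimate is degenerate — high-SNR data, not strictly noiseless
  data, is the supported regime.
* **Modal-state ties** go to the lower state index; dominance ties
  likewise. Empty state datasets are returned empty, not raised.
* **Degenerate statistics**: zero-variance t-tests return (0, 1) at zero
  mean and (±inf, 0) otherwise; an all-zero recording has no defined SNR
  and is rejected; `cv_percent` refuses an identically zero target.
* **Seeding**: every operation derives its generator from a single
  integer seed split by operation name, so fixtures are reproducible
  individually and pipelines bit-exactly (`fold_scores.tsv` reproduces
  across reruns of the same config).

## Known limitations

* The single-sphere forward model makes absolute mm estimates
  incomparable to those from realistic BEM head models; the benchmark's
  comparisons (between priors, SNRs, or datasets) are the meaningful
  output.
* The MSP optimizer is greedy ARD pruning over a fixed patch dictionary,
  not a search over random patch subsets; it inherits the known
  sensitivity to local optima.
* The spherical parameterization assumes a star-shaped-ish genus-0
  surface; heavily folded real pial surfaces may need many inflation
  iterations or an external parameterization.
* The HMM observes raw PCA scores with Gaussian state densities; spectral
  or envelope observation models are out of scope.
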