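# Methods

## Signal model

A dual-echo interleaved tag/control acquisition yields two series per
voxel: surround subtraction of the short-echo frames gives a
perfusion-weighted (ASL) series `A_t`, surround addition of the long-echo
frames a BOLD-weighted series `B_t` (at roughly twice the raw signal
level). Both are modeled as noisy observations of the same underlying flow
fluctuation: `A_t = f_t + eps_A`, `B_t = b_t + eps_B`, with the noiseless
components linked through the heuristic BOLD model on normalized flow
`x = f / f0`:

    db = M (1 - alpha_v - lam) * (x - 1) / x  =  k * g(x)

`M` (dimensionless, > 0) absorbs baseline deoxyhemoglobin content and
acquisition parameters; `alpha_v` (default 0.2, the literature value) is
the venous CBV/CBF power-law exponent; `lam` is the ratio of fractional
CMRO2 change to fractional CBF change. Because the model depends on the
three only through `k = M (1 - alpha_v - lam)`, a fit identifies `k` alone;
an epoch-wise fit with known `M` therefore constrains only the sum
`lam + alpha_v = 1 - k/M`. The Davis model
`db = M_d (1 - x^(alpha-beta) (1 + lam (x-1))^beta)` is provided for
comparison (defaults `alpha = 0.38`, `beta = 1.5`, conventional 3 T
values); in it `lam` and `M_d` cannot be lumped, but they are still jointly
non-identifiable in practice — two very different `(lam, M_d)` pairs trace
curves within 1e-3 of each other over the physiological flow range, a
property the test suite demonstrates explicitly.

## BCP estimation

For a candidate `k`, each measured pair `(A_t, B_t)` is projected to the
closest point on the curve `b = b0 (1 + k g(f/f0))` under the weighted
squared distance `w_A (A_t - f)^2 + w_B (B_t - b)^2`, with
inverse-noise-variance weights; the cost is the sum of projected distances
and is minimized over `k` by golden-section search. Numerical choices:

- **Projection.** The free coordinate `f` is restricted to
  `[f_floor * f0, f_cap * f0]` (defaults 0.05 and 5): `g` is singular at
  zero flow and physiological flow never vanishes. The minimizer is located
  by a 129-point grid over that interval followed by golden-section
  refinement inside the bracketing grid cell (48 iterations, final interval
  ~1e-11 of the range). The grid stage guards against the rare
  double-minimum geometry a concave curve can present; the refinement makes
  the projection at least as close as a dense 1e5-point search (tested).
  The projection minimizes *weighted distance in signal units*, which is
  the reading of the cost under which each time point's contribution is
  exactly its projected residual.
- **Search.** The probe point sits at the golden-section fraction
  `(3 - sqrt 5)/2 = 38.197%` of the current interval; termination when the
  bracket width is at most `tolerance` (default 0.001, interpreted as
  absolute width in `k` units), returning the bracket midpoint. The default
  initial bracket `[-0.1, 0.3]` contains `k = M (1 - alpha_v - lam)` for
  all plausible `M <= 0.2` and `lam` in `[0, 1]`, and admits negative `k`.
- **Unimodality.** The cost is assumed unimodal in `k` (the premise of a
  golden-section search); an optional 11-point diagnostic scan warns when
  the sampled profile is not.
- **Weights.** Only the `w_A / w_B` ratio affects `k_hat` (tested via scale
  equivariance); the weights come from CSF-voxel variances
  (`estimate_noise_weights`, sample variance with the n-1 denominator,
  averaged across voxels, one global pair per run). On noise-free synthetic
  runs the pipeline falls back to nominal weights built from the configured
  noise fractions, since a zero-variance CSF series is degenerate.
- **Degenerate inputs.** `k = 0` collapses the curve to the horizontal line
  `b = b0`, and the projection returns `(A_t, b0)`. Samples whose projected
  flow would leave the admissible range are clamped to its ends (at the
  reference single-voxel noise level this affects well under 1% of
  samples).

## Preprocessing conventions

Surround operations drop the first and last frames (no one-sided
endpoints; the paper-style three-point stencils are used only at interior
frames), shifting downstream time axes by one TR. Default parity is
tag-first, configurable. Any component linear in time cancels from the ASL
series and doubles in the BOLD series; a static-tissue fluctuation lasting
longer than a tag-control triplet never enters the ASL series. Baselines
`f0`, `b0` are means of the first 20 samples (task runs) or first 40
(calibration runs). Nuisance regression projects out demeaned confound
columns by ordinary least squares, preserving the series mean, and is
idempotent; CSF masks and nuisance regressor matrices are accepted as
inputs (tissue segmentation and physiological-trace processing are out of
scope).

## Calibration

Hypercapnia raises CBF without changing CMRO2 (`lam = 0`), so the
steady-state responses `df`, `db` (window means over baseline-normalized
series) invert the heuristic model for `M = db (1 + df)/((1 - alpha_v) df)`.
Averaging across runs/ROI happens before the inversion. `lam` then follows
either from steady-state task responses
(`lam = 1 - alpha_v - db (1 + df)/(M df)`, the traditional calibrated-BOLD
estimator) or from the BCP `k_hat` (`lam = 1 - alpha_v - k_hat / M`). On
noise-free data whose window is truly at steady state the two coincide up
to the golden-section tolerance (`tolerance / M` in `lam` units, ~0.009 at
defaults), and exactly as the tolerance shrinks — both facts are tested.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the reference study conditions: block design
60 s + 4 x (20 s on / 60 s off) + 30 s at TR 2.5 s (164 frames);
steady-state fractional CBF amplitude 0.46; `M = 0.11`, `alpha_v = 0.2`,
`lam = 0.35` (so `k_true = 0.0495`); ASL noise 36% of an f0 = 28
signal-unit baseline and BOLD noise 0.5% of a b0 = 11200 baseline (these
magnitudes mirror the reported acquisition scale; the gain is arbitrary).
The flow response is the stimulus boxcar convolved with a unit-sum gamma
density (order 3, time constant 1.2 s — a Boynton-family kernel chosen
here since only the gamma form, not its constants, is conventionally
fixed), peak-normalized; the fractional BOLD series is `k g(flow)`
pointwise. The hypercapnia run is modeled as 100 s rest plus 300 s of CO2
administration with `lam = 0` and flow amplitude 0.5.

Raw interleaved acquisitions place tag/control frames at
`static +/- perfusion/2` and the BOLD modulation at half scale on echo 2,
so the surround operations return the three-point-smoothed truth — exact
wherever the flow is locally constant. Noise is i.i.d. Gaussian per
modality; structured physiological noise exists only as optional sinusoidal
confounds for the regression tests, and correlated ASL/BOLD noise is not
generated by default. Consequently, passing tests show that the estimator
is accurate and precise *under white residual noise after nuisance
removal*; they do not probe motion, slice timing, label-relaxation physics,
spatially correlated noise, or BOLD transients (initial dip, dynamic
CBF/CBV/CMRO2 mismatch), all of which real data contain.

## Epochs and timing conventions

Frame `i` is stamped at `t = i * TR` from acquisition start. Epoch windows
are half-open `[start, end)` in seconds relative to stimulus onset
(transient-on `[0, 10)`, steady-state `[10, 20)`) or offset (transient-off
`[0, 10)`, undershoot `[12.5, 22.5)`); with the reference design each
epoch concatenates 4 samples per cycle, 16 in total. The half-open
convention avoids double counting and is what yields those counts. Note the
steady-state window opens at 10 s post-onset while the gamma response fully
saturates only by ~15 s, so "steady-state" window means sit within ~1e-3
of the plateau rather than exactly on it.

## Problem sizes used in tests and the acceptance script

Monte-Carlo checks use 100 seeded replicates per condition: ROI-scale fits
average 50 voxels (noise reduced by sqrt(50), matching the minimum ROI size
of the reference analysis), single-voxel fits use the raw noise level, and
noise-weight estimation draws 20 CSF voxels. These sizes give Monte-Carlo
standard errors comfortably below the decision thresholds (e.g. ~0.002 on
the ROI-scale mean lambda) while keeping the full suite fast. Observed
behaviour at these conditions: ROI-scale mean lambda bias ~0.003 (|bias|
threshold 0.05); single-voxel constrained-flow std drops from ~0.34 to
~0.17 (steady state) and ~0.36 to ~0.10 (undershoot) of baseline, with the
constrained series more precise than the measured one in 100/100
replicates and no detectable steady-state bias.

## Known limitations

- `k` is assumed constant over the analysis window; time-varying coupling
  appears only through epoch-wise refitting.
- The undershoot-window fit constrains `k` weakly because all model curves
  meet at the origin; near-baseline windows give imprecise `lam`.
- Errors-in-variables projection fitting is not guaranteed consistent as
  the window grows at fixed noise (incidental-parameters effect); at the
  reference noise levels the residual bias is below 0.01 in `lam` and is
  covered by the Monte-Carlo tests.
- `M` estimation is ROI-scale only, mirroring the precision limits of
  hypercapnia calibration; the interface does not offer voxel-wise `M`.
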