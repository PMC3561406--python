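# bcperf — BOLD-constrained perfusion estimation

`bcperf` jointly denoises arterial-spin-labeling (ASL) cerebral blood flow
(CBF) time series using the simultaneously acquired BOLD signal, and — given
a hypercapnia calibration — estimates the CMRO2/CBF coupling ratio λ. It is
aimed at researchers running simultaneous dual-echo ASL/BOLD fMRI who want
dynamic, quantitative flow estimates without assuming anything about the
stimulus timing.

## The problem and the model

ASL is directly proportional to CBF but very noisy; BOLD is far more
sensitive but relates to CBF nonlinearly and also depends on oxygen
metabolism and blood volume. Treating the two measured series
*A<sub>t</sub>* and *B<sub>t</sub>* as noisy windows into the same
underlying flow fluctuation, the package links them with a one-parameter
heuristic BOLD model on normalized flow *x = f / f₀*:

&nbsp;&nbsp;&nbsp;&nbsp;δb = M (1 − α_v − λ) · (x − 1)/x = **k** · g(x)

where *M* is a baseline-state scaling factor, *α_v* the venous CBV–CBF
power-law exponent (≈0.2), and λ = δ(CMRO2)/δ(CBF). BOLD-constrained
perfusion (BCP) estimation minimizes the errors-in-both-variables cost

&nbsp;&nbsp;&nbsp;&nbsp;C(k) = Σ<sub>t</sub> [ w_A (A<sub>t</sub> − f<sub>t</sub>)² + w_B (B<sub>t</sub> − b₀(1 + k·g(f<sub>t</sub>/f₀)))² ]

over the constrained flow trajectory (each point projected to the closest
point on the model curve under inverse-variance weights) and over *k* by
golden-section search (probe point at 38.197% of the interval, terminal
bracket width 0.001). The outputs are a denoised flow series *f̂* and the
fitted *k̂*. A hypercapnia experiment (CBF rises, CMRO2 does not, so λ = 0)
calibrates *M* via M = δb(1 + δf) / ((1 − α_v)·δf), after which
λ = 1 − α_v − k̂/M.

No public data accompany the method, so the package ships a first-class
synthetic-data generator reproducing the reference acquisition: TR 2.5 s,
60 s rest + 4 × (20 s flickering-checkerboard on / 60 s off) + 30 s rest
(164 frames), steady-state fractional CBF response 0.46, ASL noise 36% and
BOLD noise 0.5% of baseline, M = 0.11, α_v = 0.2, λ = 0.35.

## Worked example

Run the full synthetic pipeline (simulate → fit → calibrate):

```sh
$ bcperf pipeline --out-dir bcp_demo --seed 1
k_hat=0.0474335 M=0.1117 lambda_bcp=0.3755 lambda_traditional=0.3598
artifacts in bcp_demo
```

With ground truth k = 0.11·(1 − 0.2 − 0.35) = 0.0495 and λ = 0.35, this
seed's ROI-scale fit recovers k̂ = 0.0474 and, after hypercapnia
calibration (M̂ = 0.112), λ̂ = 0.376 by BCP versus 0.360 by the traditional
steady-state estimator — both within the Monte-Carlo spread of ≈0.02 (ROI
scale) around the true value. `bcp_demo/` contains the measured series
(`task_asl.csv`, `task_bold.csv`), the constrained fit
(`bcp_result.csv/.json`), the calibration report (`calibration.json`,
including per-epoch λ+α_v sums for the transient-on, steady-state,
transient-off and post-stimulus-undershoot windows), and a log of all
effective parameters.

The same machinery is available as a scikit-learn estimator:

```python
import numpy as np
from bcperf import BCPEstimator

est = BCPEstimator(var_asl=(0.36 * 28) ** 2, var_bold=(0.005 * 11200) ** 2)
est.fit(np.column_stack([asl, bold]))   # columns: ASL, BOLD signal units
est.k_hat_, est.f_hat_                  # fitted scale, denoised flow
```

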