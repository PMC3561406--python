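"""End-to-end pipeline: simulate -> preprocess -> fit -> calibrate.

Each stage is a plain function over the library; :func:`run_pipeline`
chains them according to a :class:`~bcperf.config.RunConfig` and writes
the artifacts (series CSVs, fit CSV/JSON, calibration JSON, log) to the
configured output directory.  Identical config and seed reproduce
byte-identical numeric outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .calibrate import estimate_M, lambda_bcp, lambda_traditional, steady_state_response
from .config import DEFAULT_EPOCH_DEFS, RunConfig
from .estimator import SearchSettings, fit_bcp, fit_epochs
from .models import PhysioParams, epoch_param_sum
from .preprocess import NoiseWeights, TimeSeriesPair, estimate_baselines, estimate_noise_weights
from .simulate import NoiseSpec, StimulusDesign, SyntheticTruth, simulate_measured_pair, simulate_roi_pair, simulate_truth
from . import io as bio

__all__ = ["epoch_windows_from_design", "run_pipeline", "task_design", "hypercapnia_design"]

log = logging.getLogger("bcperf")


def epoch_windows_from_design(
    design: StimulusDesign,
    definitions: dict[str, tuple[str, float, float]] | None = None,
) -> dict[str, np.ndarray]:
    """Per-epoch sample indices, concatenated across stimulus cycles.

    Windows are half-open ``[start, end)`` in seconds relative to the
    stimulus onset or offset of each cycle; frame ``i`` is stamped at
    ``i * tr``.  With the reference design each of the four default
    epochs collects 4 samples per cycle, 16 in total.
    """
    definitions = definitions or DEFAULT_EPOCH_DEFS
    t = np.arange(design.n_frames) * design.tr
    out: dict[str, np.ndarray] = {}
    for name, (anchor, start, end) in definitions.items():
        anchors = design.onsets_s if anchor == "onset" else design.offsets_s
        idx: list[np.ndarray] = []
        for a in anchors:
            if a + start < 0 or a + end > design.total_s:
                raise ValueError(
                    f"epoch {name!r} window [{a + start}, {a + end}) falls outside the run"
                )
            idx.append(np.nonzero((t >= a + start) & (t < a + end))[0])
        out[name] = np.concatenate(idx) if idx else np.array([], dtype=int)
    return out


def task_design(cfg: RunConfig) -> StimulusDesign:
    return StimulusDesign(
        pre_rest_s=cfg.pre_rest_s, n_cycles=cfg.n_cycles, on_s=cfg.on_s,
        off_s=cfg.off_s, post_rest_s=cfg.post_rest_s, tr=cfg.tr,
    )


def hypercapnia_design(cfg: RunConfig) -> StimulusDesign:
    """Calibration run: 100 s of rest then continuous CO2 administration.

    The baseline is the first ``baseline_n_calibration`` (default 40)
    frames, the steady-state window the last 40 frames of administration.
    """
    return StimulusDesign(
        pre_rest_s=100.0, n_cycles=1, on_s=300.0, off_s=0.0, post_rest_s=0.0, tr=cfg.tr
    )


def _simulate_csf(cfg: RunConfig, design: StimulusDesign, seed: int) -> NoiseWeights:
    """Noise weights from simulated CSF voxels (no flow response)."""
    flat = simulate_truth(design, PhysioParams(M=cfg.m_scale, alpha_v=cfg.alpha_v, lam=cfg.lam), amp=0.0)
    rng = np.random.default_rng(seed)
    n = flat.flow.size
    asl = rng.normal(0.0, cfg.sigma_asl_frac * cfg.f0, (cfg.n_csf_voxels, n))
    bold = cfg.b0 + rng.normal(0.0, cfg.sigma_bold_frac * cfg.b0, (cfg.n_csf_voxels, n))
    return estimate_noise_weights(asl, bold - bold.mean(axis=1, keepdims=True))


def _nominal_weights(cfg: RunConfig) -> NoiseWeights:
    """Weights from the configured noise fractions (noise-free fallback)."""
    return NoiseWeights.from_sigmas(
        max(cfg.sigma_asl_frac, 1e-6) * cfg.f0,
        max(cfg.sigma_bold_frac, 1e-6) * cfg.b0,
    )


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full synthetic pipeline and write artifacts.

    Returns a dict with the calibration report and artifact paths.
    """
    cfg.validate()
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(cfg, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out: Path) -> dict:
    params = PhysioParams(M=cfg.m_scale, alpha_v=cfg.alpha_v, lam=cfg.lam)
    log.info("seed=%d k_true=%.6g bracket=[%g, %g] tolerance=%g",
             cfg.seed, params.k, cfg.bracket_lo, cfg.bracket_hi, cfg.tolerance)
    design = task_design(cfg)
    truth = simulate_truth(design, params, amp=cfg.amp_task, seed=cfg.seed)

    noisy = cfg.sigma_asl_frac > 0 or cfg.sigma_bold_frac > 0
    task_noise = NoiseSpec(cfg.sigma_asl_frac, cfg.sigma_bold_frac,
                           cfg.drift_per_frame, seed=cfg.seed)
    pair = simulate_roi_pair(truth, n_voxels=cfg.n_roi_voxels,
                             f0=cfg.f0, b0=cfg.b0, noise=task_noise)
    pair.f0, pair.b0 = estimate_baselines(pair, cfg.baseline_n_task)

    # Noise weights: CSF-voxel variances when there is noise to measure.
    # Only the ASL/BOLD weight ratio matters for k_hat, and ROI averaging
    # scales both variances by the same 1/n_voxels factor.
    if noisy:
        weights = _simulate_csf(cfg, design, seed=cfg.seed + 1)
    else:
        weights = _nominal_weights(cfg)
    log.info("weights var_asl=%.6g var_bold=%.6g", weights.var_asl, weights.var_bold)

    settings = SearchSettings(cfg.bracket_lo, cfg.bracket_hi, cfg.tolerance,
                              cfg.f_floor, cfg.f_cap)
    result = fit_bcp(pair, weights, settings)
    log.info("k_hat=%.6g cost=%.6g n_evals=%d", result.k_hat, result.cost, result.n_evals)

    # Hypercapnia calibration (lam = 0 during CO2 by assumption).
    hc_design = hypercapnia_design(cfg)
    hc_params = PhysioParams(M=cfg.m_scale, alpha_v=cfg.alpha_v, lam=0.0)
    hc_truth = simulate_truth(hc_design, hc_params, amp=cfg.amp_hypercapnia,
                              seed=cfg.seed + 2)
    hc_noise = NoiseSpec(cfg.sigma_asl_frac, cfg.sigma_bold_frac,
                         cfg.drift_per_frame, seed=cfg.seed + 2)
    hc_pair = simulate_roi_pair(hc_truth, n_voxels=cfg.n_roi_voxels,
                                f0=cfg.f0, b0=cfg.b0, noise=hc_noise)
    hc_pair.f0, hc_pair.b0 = estimate_baselines(hc_pair, cfg.baseline_n_calibration)
    n_on_end = round((hc_design.pre_rest_s + hc_design.on_s) / cfg.tr)
    hc_window = np.arange(n_on_end - 40, n_on_end)
    hc = steady_state_response(hc_pair, hc_window)
    M = estimate_M(hc, alpha_v=cfg.alpha_v)
    log.info("hypercapnia df=%.4g db=%.4g M=%.4g", hc.df, hc.db, M)

    epochs = epoch_windows_from_design(design, cfg.epochs)
    vt = steady_state_response(pair, epochs["steady_state"])
    lam_trad = lambda_traditional(vt, M, alpha_v=cfg.alpha_v)
    lam_bcp = lambda_bcp(result, M, alpha_v=cfg.alpha_v)
    epoch_results = fit_epochs(pair, epochs, weights, settings)
    epoch_sums = {name: epoch_param_sum(r.k_hat, M) for name, r in epoch_results.items()}
    log.info("lambda_bcp=%.4g lambda_traditional=%.4g", lam_bcp, lam_trad)

    # artifacts
    bio.write_series(out / "task_asl.csv", pair.asl, cfg.tr)
    bio.write_series(out / "task_bold.csv", pair.bold, cfg.tr)
    bio.write_series(out / "truth_flow.csv", truth.flow, cfg.tr)
    bio.write_bcp_result(out / "bcp_result", pair, result, seed=cfg.seed)
    report = {
        "M": M,
        "alpha_v": cfg.alpha_v,
        "lambda_traditional": lam_trad,
        "lambda_bcp": lam_bcp,
        "k_hat": result.k_hat,
        "epoch_sums": epoch_sums,
        "steady_state": {"df": vt.df, "db": vt.db},
        "seed": cfg.seed,
    }
    bio.write_json(out / "calibration.json", report)
    cfg.to_yaml(out / "config_used.yaml")
    return {"report": report, "result": result, "pair": pair, "out_dir": out}
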