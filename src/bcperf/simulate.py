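"""Synthetic dual-echo ASL/BOLD data with known ground truth.

The generator emulates a block-design visual experiment: 60 s of rest,
four cycles of 20 s stimulus / 60 s rest, and a final 30 s of rest at
TR 2.5 s (164 frames).  The true flow response is the stimulus boxcar
convolved with a gamma-density hemodynamic response (order 3, time
constant 1.2 s), peak-normalized and scaled to a steady-state fractional
amplitude of 0.46; the true fractional BOLD series follows the heuristic
model pointwise.  Measured series add i.i.d. Gaussian noise at 36% of the
baseline ASL level and 0.5% of the baseline BOLD level, the group-mean
noise magnitudes of the experiment the defaults mirror.

All randomness flows from explicit seeds; no global RNG state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .models import PhysioParams, bold_from_flow
from .preprocess import RawAcquisition, TimeSeriesPair

__all__ = [
    "StimulusDesign",
    "SyntheticTruth",
    "NoiseSpec",
    "make_stimulus",
    "gamma_hrf",
    "simulate_truth",
    "simulate_measured_pair",
    "simulate_roi_pair",
    "simulate_raw_acquisition",
]


@dataclass(frozen=True)
class StimulusDesign:
    """Block-design timing in seconds; defaults are the reference protocol."""

    pre_rest_s: float = 60.0
    n_cycles: int = 4
    on_s: float = 20.0
    off_s: float = 60.0
    post_rest_s: float = 30.0
    tr: float = 2.5

    def __post_init__(self) -> None:
        if min(self.pre_rest_s, self.on_s, self.off_s, self.post_rest_s) < 0:
            raise ValueError("durations must be non-negative")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be non-negative")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if abs(self.total_s / self.tr - round(self.total_s / self.tr)) > 1e-9:
            raise ValueError("total duration must be an integer number of frames")

    @property
    def total_s(self) -> float:
        return self.pre_rest_s + self.n_cycles * (self.on_s + self.off_s) + self.post_rest_s

    @property
    def n_frames(self) -> int:
        return round(self.total_s / self.tr)

    @property
    def onsets_s(self) -> np.ndarray:
        """Stimulus onset times of each cycle."""
        return self.pre_rest_s + np.arange(self.n_cycles) * (self.on_s + self.off_s)

    @property
    def offsets_s(self) -> np.ndarray:
        """Stimulus offset (cessation) times of each cycle."""
        return self.onsets_s + self.on_s


@dataclass
class SyntheticTruth:
    """Ground-truth trajectories plus the parameters that generated them.

    ``flow`` is normalized to baseline 1; ``bold_frac`` satisfies
    ``bold_frac = k * g(flow)`` pointwise by construction.
    """

    flow: np.ndarray
    bold_frac: np.ndarray
    params: PhysioParams
    design: StimulusDesign
    seed: int | None
    amp: float


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise magnitudes as fractions of the baseline levels."""

    sigma_asl_frac: float = 0.36
    sigma_bold_frac: float = 0.005
    drift_per_frame: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_asl_frac < 0 or self.sigma_bold_frac < 0:
            raise ValueError("noise fractions must be non-negative")


def make_stimulus(design: StimulusDesign) -> np.ndarray:
    """Boxcar stimulus series, one 0/1 value per frame (frame i at i*tr)."""
    t = np.arange(design.n_frames) * design.tr
    stim = np.zeros(design.n_frames)
    for onset in design.onsets_s:
        stim[(t >= onset) & (t < onset + design.on_s)] = 1.0
    return stim


def gamma_hrf(tau_s: float = 1.2, n_order: int = 3, tr: float = 2.5) -> np.ndarray:
    """Discretized gamma-density hemodynamic response kernel.

    ``h(t) = (t/tau)**(n-1) exp(-t/tau) / (tau (n-1)!)`` sampled at the
    repetition time, truncated once the continuous density holds more than
    99.9% of its mass, and renormalized to unit sum so that convolving a
    constant series returns it unchanged.  The continuous mode sits at
    ``(n-1) * tau`` (2.4 s at the defaults).
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    if n_order < 1:
        raise ValueError("n_order must be at least 1")
    dist = stats.gamma(a=n_order, scale=tau_s)
    n_taps = max(2, math.ceil(dist.ppf(0.999) / tr) + 1)
    t = np.arange(n_taps) * tr
    h = dist.pdf(t)
    return h / h.sum()


def simulate_truth(
    design: StimulusDesign,
    params: PhysioParams,
    amp: float = 0.46,
    tau_s: float = 1.2,
    n_order: int = 3,
    seed: int | None = None,
) -> SyntheticTruth:
    """Noiseless flow and fractional BOLD trajectories for a design.

    ``flow = 1 + amp * r`` where ``r`` is the stimulus boxcar convolved
    with the gamma kernel and normalized to unit peak, so ``amp`` is the
    steady-state fractional CBF amplitude.  ``bold_frac = k * g(flow)``.
    """
    if amp <= -1:
        raise ValueError("amp must exceed -1 to keep flow positive")
    stim = make_stimulus(design)
    kernel = gamma_hrf(tau_s=tau_s, n_order=n_order, tr=design.tr)
    resp = np.convolve(stim, kernel)[: design.n_frames]
    peak = resp.max()
    if peak > 0:
        resp = resp / peak
    flow = 1.0 + amp * resp
    bold_frac = bold_from_flow(flow, params.k)
    return SyntheticTruth(
        flow=flow, bold_frac=np.asarray(bold_frac), params=params,
        design=design, seed=seed, amp=amp,
    )


def simulate_measured_pair(
    truth: SyntheticTruth,
    f0: float = 28.0,
    b0: float = 11200.0,
    noise: NoiseSpec | None = None,
) -> TimeSeriesPair:
    """Measured ASL/BOLD series: scaled truth plus Gaussian noise and drift.

    ``asl = f0*flow + N(0, (sigma_asl_frac*f0)**2)`` and
    ``bold = b0*(1 + bold_frac) + N(0, (sigma_bold_frac*b0)**2) + drift``.
    The baseline magnitudes default to the reference acquisition's scale
    (ASL baseline ~28 signal units, BOLD baseline ~11200 so that 0.5% is
    ~56 units); the gain is arbitrary.  Deterministic given ``noise.seed``.
    """
    if f0 <= 0 or b0 <= 0:
        raise ValueError("baselines f0 and b0 must be positive")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    n = truth.flow.size
    asl = f0 * truth.flow + rng.normal(0.0, noise.sigma_asl_frac * f0, n)
    bold = (
        b0 * (1.0 + truth.bold_frac)
        + rng.normal(0.0, noise.sigma_bold_frac * b0, n)
        + noise.drift_per_frame * np.arange(n)
    )
    return TimeSeriesPair(asl, bold, tr=truth.design.tr, f0=f0, b0=b0)


def simulate_roi_pair(
    truth: SyntheticTruth,
    n_voxels: int = 50,
    f0: float = 28.0,
    b0: float = 11200.0,
    noise: NoiseSpec | None = None,
) -> TimeSeriesPair:
    """ROI-scale pair: spatial average of ``n_voxels`` independent voxels.

    Voxels share the truth and differ only in noise, so averaging reduces
    the noise standard deviation by ``sqrt(n_voxels)``.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be at least 1")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    n = truth.flow.size
    asl = f0 * truth.flow + rng.normal(0.0, noise.sigma_asl_frac * f0, (n_voxels, n))
    bold = (
        b0 * (1.0 + truth.bold_frac)
        + rng.normal(0.0, noise.sigma_bold_frac * b0, (n_voxels, n))
        + noise.drift_per_frame * np.arange(n)
    )
    return TimeSeriesPair(
        asl.mean(axis=0), bold.mean(axis=0), tr=truth.design.tr, f0=f0, b0=b0
    )


def simulate_raw_acquisition(
    truth: SyntheticTruth,
    f0: float = 28.0,
    static_levels: tuple[float, float] = (5600.0, 5600.0),
    noise: NoiseSpec | None = None,
    parity: str = "tag-first",
) -> RawAcquisition:
    """Interleaved two-echo frame series consistent with the surround ops.

    Echo 1 alternates tag/control around a static level, offset by plus or
    minus half the instantaneous perfusion signal ``f0 * flow``; echo 2
    carries the BOLD modulation at half the output scale so that surround
    addition (which doubles constants) restores it.  A linear drift (both
    echoes) and i.i.d. Gaussian frame noise are added on top.

    At zero noise and drift, surround subtraction of echo 1 yields the
    three-point smoothed perfusion ``(p[t-1] + 2 p[t] + p[t+1]) / 4`` --
    exactly the perfusion wherever the flow is locally constant (rest and
    plateau frames) -- and surround addition of echo 2 likewise yields the
    smoothed BOLD series around baseline ``static2``.
    """
    if min(static_levels) <= 0:
        raise ValueError("static levels must be positive")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    n = truth.flow.size
    static1, static2 = static_levels
    perf = f0 * truth.flow
    idx = np.arange(n)
    is_tag = (idx % 2 == 0) if parity == "tag-first" else (idx % 2 == 1)
    sign = np.where(is_tag, -1.0, 1.0)
    drift = noise.drift_per_frame * idx
    echo1 = (
        static1 + sign * perf / 2.0 + drift
        + rng.normal(0.0, noise.sigma_asl_frac * f0, n)
    )
    echo2 = (
        (static2 / 2.0) * (1.0 + truth.bold_frac) + drift
        + rng.normal(0.0, noise.sigma_bold_frac * static2 / 2.0, n)
    )
    return RawAcquisition(echo1, echo2, tr=truth.design.tr, parity=parity)
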