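"""Preprocessing of interleaved dual-echo tag/control acquisitions.

Surround subtraction turns the first-echo frame series into a
perfusion-weighted (ASL) series; surround addition turns the second-echo
series into a BOLD-weighted series at roughly twice the raw signal level.
Both are sliding three-frame operations, so any component linear in time
cancels from the ASL series and simply doubles in the BOLD series, and a
static-tissue fluctuation lasting longer than a tag-control triplet is
preserved in the BOLD but eliminated from the ASL signal.

The first and last frames lack two neighbours and are dropped; downstream
time axes shift by one repetition time accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawAcquisition",
    "TimeSeriesPair",
    "NoiseWeights",
    "surround_subtract",
    "surround_add",
    "estimate_baselines",
    "regress_nuisance",
    "estimate_noise_weights",
    "extract_roi_series",
    "pair_from_raw",
]

_PARITIES = ("tag-first", "control-first")


@dataclass
class RawAcquisition:
    """Interleaved tag/control two-echo frame series.

    ``frames_echo1`` and ``frames_echo2`` are arrays whose last axis is
    time (shape ``(n_frames,)`` or ``(n_voxels, n_frames)``), in arbitrary
    scanner units.  ``parity`` states whether frame 0 is a tag or a control
    frame; tag and control frames then alternate strictly.
    """

    frames_echo1: np.ndarray
    frames_echo2: np.ndarray
    tr: float
    parity: str = "tag-first"

    def __post_init__(self) -> None:
        self.frames_echo1 = np.asarray(self.frames_echo1, dtype=float)
        self.frames_echo2 = np.asarray(self.frames_echo2, dtype=float)
        if self.frames_echo1.shape != self.frames_echo2.shape:
            raise ValueError("echo series must have identical shape")
        if self.parity not in _PARITIES:
            raise ValueError(f"parity must be one of {_PARITIES}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")


@dataclass
class TimeSeriesPair:
    """Aligned ASL- and BOLD-weighted series in raw signal units.

    ``f0`` and ``b0`` are the baseline-state levels of the two series,
    populated by :func:`estimate_baselines` (or known from simulation).
    """

    asl: np.ndarray
    bold: np.ndarray
    tr: float
    f0: float | None = None
    b0: float | None = None

    def __post_init__(self) -> None:
        self.asl = np.asarray(self.asl, dtype=float)
        self.bold = np.asarray(self.bold, dtype=float)
        if self.asl.shape != self.bold.shape or self.asl.ndim != 1:
            raise ValueError("asl and bold must be 1-D series of equal length")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.f0 is not None and self.f0 <= 0:
            raise ValueError("baseline f0 must be positive")
        if self.b0 is not None and self.b0 <= 0:
            raise ValueError("baseline b0 must be positive")

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, frame ``i`` stamped at ``i * tr``."""
        return np.arange(self.asl.size) * self.tr

    def subset(self, indices) -> "TimeSeriesPair":
        """Pair restricted to the given sample indices (baselines kept)."""
        idx = np.asarray(indices, dtype=int)
        return TimeSeriesPair(self.asl[idx], self.bold[idx], self.tr, self.f0, self.b0)


@dataclass(frozen=True)
class NoiseWeights:
    """Noise variances of the two measured series and their inverse weights."""

    var_asl: float
    var_bold: float

    def __post_init__(self) -> None:
        if self.var_asl <= 0 or self.var_bold <= 0:
            raise ValueError("noise variances must be strictly positive")

    @property
    def w_asl(self) -> float:
        return 1.0 / self.var_asl

    @property
    def w_bold(self) -> float:
        return 1.0 / self.var_bold

    @classmethod
    def from_sigmas(cls, sigma_asl: float, sigma_bold: float) -> "NoiseWeights":
        return cls(var_asl=sigma_asl**2, var_bold=sigma_bold**2)


def _tag_mask(parity: str, indices: np.ndarray) -> np.ndarray:
    if parity not in _PARITIES:
        raise ValueError(f"parity must be one of {_PARITIES}")
    even = indices % 2 == 0
    return even if parity == "tag-first" else ~even


def surround_subtract(series, parity: str = "tag-first") -> np.ndarray:
    """Perfusion-weighted series from interleaved first-echo frames.

    At each interior tag frame the frame is subtracted from the average of
    its two neighbouring control frames; at each interior control frame the
    average of the neighbouring tag frames is subtracted from the frame.
    Either way perfusion (control minus tag) comes out positive.  Endpoints
    are dropped, so the output is two frames shorter along time.
    """
    s = np.asarray(series, dtype=float)
    n = s.shape[-1]
    if n < 3:
        raise ValueError("surround subtraction needs at least 3 frames")
    neigh = 0.5 * (s[..., :-2] + s[..., 2:])
    mid = s[..., 1:-1]
    is_tag = _tag_mask(parity, np.arange(1, n - 1))
    return np.where(is_tag, neigh - mid, mid - neigh)


def surround_add(series) -> np.ndarray:
    """BOLD-weighted series: each interior frame plus its neighbour average.

    The output sits at roughly twice the raw signal level (a constant input
    ``c`` maps to ``2c``).  Endpoints are dropped.
    """
    s = np.asarray(series, dtype=float)
    if s.shape[-1] < 3:
        raise ValueError("surround addition needs at least 3 frames")
    return s[..., 1:-1] + 0.5 * (s[..., :-2] + s[..., 2:])


def pair_from_raw(raw: RawAcquisition, baseline_n: int | None = None) -> TimeSeriesPair:
    """Apply the surround operations to a raw acquisition.

    Optionally estimates baselines from the first ``baseline_n`` samples of
    the resulting series.
    """
    asl = surround_subtract(raw.frames_echo1, raw.parity)
    bold = surround_add(raw.frames_echo2)
    pair = TimeSeriesPair(asl, bold, raw.tr)
    if baseline_n is not None:
        pair.f0, pair.b0 = estimate_baselines(pair, baseline_n)
    return pair


def estimate_baselines(pair: TimeSeriesPair, n_points: int) -> tuple[float, float]:
    """Baseline levels as means of the first ``n_points`` samples.

    Task runs conventionally use the first 20 samples; hypercapnia
    calibration runs the first 40.
    """
    if n_points < 1 or n_points > pair.asl.size:
        raise ValueError("n_points must be between 1 and the series length")
    return float(pair.asl[:n_points].mean()), float(pair.bold[:n_points].mean())


def regress_nuisance(series, confounds) -> np.ndarray:
    """Remove nuisance regressors from a series, preserving its mean level.

    Fits ordinary least squares of the series on ``[intercept, confounds]``
    and subtracts the confound contribution only, so the temporal mean
    (the baseline level) is preserved.  The confound matrix must have one
    row per time point and full column rank after demeaning.
    """
    y = np.asarray(series, dtype=float)
    C = np.atleast_2d(np.asarray(confounds, dtype=float))
    if C.shape[0] != y.size:
        C = C.T
    if C.shape[0] != y.size:
        raise ValueError("confound matrix must have one row per time point")
    C_dm = C - C.mean(axis=0)
    design = np.column_stack([np.ones(y.size), C_dm])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("nuisance design is rank deficient")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - C_dm @ beta[1:]


def estimate_noise_weights(asl_csf, bold_csf) -> NoiseWeights:
    """Noise weights from CSF voxel series (no CBF-related fluctuations).

    ``asl_csf`` / ``bold_csf`` are ``(n_voxels, n_frames)`` arrays of
    surround-processed series from voxels with high CSF partial volume.
    The per-modality noise variance is the mean across voxels of the
    per-voxel sample variance (n-1 denominator); weights are reciprocals.
    One global weight pair per subject/run.
    """
    out = []
    for name, arr in (("ASL", asl_csf), ("BOLD", bold_csf)):
        a = np.atleast_2d(np.asarray(arr, dtype=float))
        if a.shape[1] < 2:
            raise ValueError(f"{name} CSF series need at least 2 samples")
        v = float(a.var(axis=1, ddof=1).mean())
        if v <= 0:
            raise ValueError(f"degenerate {name} CSF series: zero variance")
        out.append(v)
    return NoiseWeights(var_asl=out[0], var_bold=out[1])


def extract_roi_series(volume_series, mask) -> np.ndarray:
    """Spatial average over a region of interest, per time point.

    ``volume_series`` is ``(..., n_frames)`` with spatial axes leading
    (e.g. ``(x, y, z, t)`` or ``(n_voxels, t)``); ``mask`` is a matching
    boolean/nonzero array over the spatial axes.
    """
    vol = np.asarray(volume_series, dtype=float)
    m = np.asarray(mask) != 0
    if m.shape != vol.shape[:-1]:
        raise ValueError("mask shape must match the spatial axes of the series")
    if not m.any():
        raise ValueError("ROI mask selects no voxels")
    return vol[m].mean(axis=0)
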