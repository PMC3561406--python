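"""Closed-form models linking cerebral blood flow changes to the BOLD signal.

Two models are provided. The *heuristic* model lumps every physiological
modulator of the BOLD response -- the baseline-state scaling factor ``M``,
the venous blood-volume power-law exponent ``alpha_v`` and the CMRO2/CBF
coupling ratio ``lam`` -- into a single factor ``k`` multiplying a simple
nonlinear function of the normalized flow ``x = f / f0``::

    db = M (1 - alpha_v - lam) * (x - 1) / x  =  k * g(x)

The *Davis* model keeps the scaling factor and the coupling ratio separate::

    db = M_d * (1 - x**(alpha - beta) * (1 + lam * (x - 1))**beta)

Both curves pass through ``(1, 0)``: no flow change, no BOLD change.  All
model evaluations are defined on normalized flow; conversion from raw signal
units happens in the estimator layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhysioParams",
    "DavisParams",
    "flow_nonlinearity",
    "bold_from_flow",
    "k_from_params",
    "lam_from_k",
    "epoch_param_sum",
    "davis_bold_from_flow",
]


def _maybe_scalar(out: np.ndarray):
    return float(out) if out.ndim == 0 else out


def flow_nonlinearity(x):
    """Nonlinear flow term ``g(x) = (x - 1) / x`` of the heuristic model.

    Equivalently ``df / (1 + df)`` with ``df = x - 1``.  ``g`` is strictly
    increasing and concave on ``(0, inf)``, with ``g(1) = 0`` and
    ``g(x) -> 1`` as ``x -> inf``.

    Parameters
    ----------
    x : float or array_like
        Normalized flow ``f / f0``; must be strictly positive.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("normalized flow must be strictly positive")
    return _maybe_scalar((x - 1.0) / x)


def bold_from_flow(x, k):
    """Fractional BOLD change ``db = k * g(x)`` of the heuristic model."""
    return _maybe_scalar(np.asarray(k, dtype=float) * flow_nonlinearity(x))


def k_from_params(M: float, alpha_v: float, lam: float) -> float:
    """Lumped heuristic scale ``k = M * (1 - alpha_v - lam)``."""
    if M <= 0:
        raise ValueError("scaling factor M must be positive")
    return M * (1.0 - alpha_v - lam)


def lam_from_k(k: float, M: float, alpha_v: float) -> float:
    """CMRO2/CBF coupling ratio ``lam = 1 - alpha_v - k / M``.

    Exact inverse of :func:`k_from_params` for fixed ``M`` and ``alpha_v``.
    """
    if M <= 0:
        raise ValueError("scaling factor M must be positive")
    return 1.0 - alpha_v - k / M


def epoch_param_sum(k: float, M: float) -> float:
    """Sum ``lam + alpha_v = 1 - k / M`` identified by an epoch-wise fit.

    A fit of the heuristic model determines ``k`` only, so with a known
    ``M`` an epoch constrains the coupling ratio and the blood-volume
    exponent solely through their sum.
    """
    if M <= 0:
        raise ValueError("scaling factor M must be positive")
    return 1.0 - k / M


@dataclass(frozen=True)
class PhysioParams:
    """Baseline-state and coupling parameters of the heuristic BOLD model.

    Attributes
    ----------
    M : float
        Dimensionless BOLD scaling factor absorbing baseline deoxyhemoglobin
        content and acquisition parameters; must be positive.
    alpha_v : float
        Exponent of the venous CBV / CBF power law (literature value 0.2).
    lam : float
        Ratio of the fractional CMRO2 change to the fractional CBF change.
    """

    M: float = 0.11
    alpha_v: float = 0.2
    lam: float = 0.35

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ValueError("scaling factor M must be positive")

    @property
    def k(self) -> float:
        """Lumped scale ``M * (1 - alpha_v - lam)``."""
        return k_from_params(self.M, self.alpha_v, self.lam)

    @classmethod
    def from_k(cls, k: float, M: float, alpha_v: float) -> "PhysioParams":
        """Recover the coupling ratio from a fitted ``k`` and known M, alpha_v."""
        return cls(M=M, alpha_v=alpha_v, lam=lam_from_k(k, M, alpha_v))


@dataclass(frozen=True)
class DavisParams:
    """Parameters of the Davis BOLD model.

    ``alpha`` and ``beta`` default to conventional 3 T values (0.38, 1.5).
    """

    M_d: float = 0.1
    alpha: float = 0.38
    beta: float = 1.5
    lam: float = 0.35

    def __post_init__(self) -> None:
        if self.M_d <= 0:
            raise ValueError("Davis scaling factor M_d must be positive")
        if self.beta <= 0:
            raise ValueError("deoxyhemoglobin exponent beta must be positive")


def davis_bold_from_flow(x, p: DavisParams):
    """Fractional BOLD change under the Davis model.

    ``db = M_d * (1 - x**(alpha - beta) * m**beta)`` where
    ``m = 1 + lam * (x - 1)`` is the normalized CMRO2 implied by the
    coupling ratio.  Requires ``x > 0`` and ``m > 0``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("normalized flow must be strictly positive")
    m = 1.0 + p.lam * (x - 1.0)
    if np.any(m <= 0):
        raise ValueError("implied CMRO2 ratio 1 + lam*(x-1) must be positive")
    out = p.M_d * (1.0 - x ** (p.alpha - p.beta) * m**p.beta)
    return _maybe_scalar(out)
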