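"""Hypercapnia calibration and CMRO2/CBF coupling estimation.

Breathing CO2-enriched air raises cerebral blood flow without changing
oxygen metabolism, so the heuristic model with ``lam = 0`` can be inverted
for the scaling factor ``M`` from the steady-state hypercapnia responses::

    M = db * (1 + df) / ((1 - alpha_v) * df)

With ``M`` and an assumed ``alpha_v`` in hand, the coupling ratio for a
task run follows either from the steady-state responses directly
(traditional calibrated-BOLD analysis) or from the BCP-fitted ``k_hat``
(``lam = 1 - alpha_v - k_hat / M``).  On noise-free data whose steady-state
window is truly at steady state the two reduce to the same inversion.

``M`` estimation is ROI-scale only: single-voxel hypercapnia data lacks
the precision to support it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimator import BCPResult
from .models import lam_from_k
from .preprocess import TimeSeriesPair

__all__ = [
    "SteadyStateResponse",
    "steady_state_response",
    "estimate_M",
    "lambda_traditional",
    "lambda_bcp",
]


@dataclass(frozen=True)
class SteadyStateResponse:
    """Fractional steady-state CBF (``df``) and BOLD (``db``) responses."""

    df: float
    db: float
    n_samples: int

    def __post_init__(self) -> None:
        if 1.0 + self.df <= 0:
            raise ValueError("fractional CBF change must keep flow positive")


def steady_state_response(pair: TimeSeriesPair, windows) -> SteadyStateResponse:
    """Average fractional responses over the given sample windows.

    ``windows`` is a collection of sample indices (e.g. the last 40 frames
    of CO2 administration, or the last 10 s of each visual stimulus
    concatenated across cycles).
    """
    idx = np.asarray(windows, dtype=int).ravel()
    if idx.size == 0:
        raise ValueError("steady-state windows are empty")
    if pair.f0 is None or pair.b0 is None:
        raise ValueError("pair baselines f0/b0 must be populated")
    df = float(pair.asl[idx].mean() / pair.f0 - 1.0)
    db = float(pair.bold[idx].mean() / pair.b0 - 1.0)
    return SteadyStateResponse(df=df, db=db, n_samples=idx.size)


def estimate_M(hc: SteadyStateResponse, alpha_v: float = 0.2) -> float:
    """Scaling factor from hypercapnia responses, assuming ``lam = 0``."""
    if hc.df == 0:
        raise ValueError("degenerate calibration: zero hypercapnia CBF response")
    return hc.db * (1.0 + hc.df) / ((1.0 - alpha_v) * hc.df)


def lambda_traditional(vt: SteadyStateResponse, M: float, alpha_v: float = 0.2) -> float:
    """Coupling ratio from steady-state task responses (calibrated BOLD)."""
    if M <= 0:
        raise ValueError("scaling factor M must be positive")
    if vt.df == 0:
        raise ValueError("zero steady-state CBF response")
    return 1.0 - alpha_v - vt.db * (1.0 + vt.df) / (M * vt.df)


def lambda_bcp(result: BCPResult, M: float, alpha_v: float = 0.2) -> float:
    """Coupling ratio from a BCP-fitted ``k_hat`` and a calibrated ``M``."""
    return lam_from_k(result.k_hat, M, alpha_v)
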