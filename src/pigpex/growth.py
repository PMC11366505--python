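"""Gompertz body-weight curve for market pigs.

The growth model is the sigmoid BW(t) = A * exp(-b * exp(-k * t)) with
asymptotic mature weight ``A`` (kg), dimensionless shape ``b`` and rate
``k`` (per day), evaluated at age ``t`` in days.  The default parameters
(A = 217.4 kg, b = 4.6919, k = 0.0116/d) describe a modern commercial
crossbred pig reaching 7 kg at 27 days and 121.5 kg at the typical
marketing age of 180 days.

Age is continuous here; callers that need an integer-day grid (the
projection layer) impose it themselves.  The curve is neither clamped nor
extrapolation-guarded: validity of a BW for a given purpose is the
caller's concern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GompertzParams", "DEFAULT_GOMPERTZ", "gompertz_bw", "age_at_bw"]


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of the Gompertz growth curve.

    Attributes
    ----------
    asymptote_kg : float
        Mature body weight A (kg); upper bound of the curve.
    shape : float
        Dimensionless shape parameter b (displacement of the inflection).
    rate : float
        Growth-rate constant k (per day).
    """

    asymptote_kg: float = 217.4
    shape: float = 4.6919
    rate: float = 0.0116

    def __post_init__(self) -> None:
        for name in ("asymptote_kg", "shape", "rate"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


#: Default growth curve for a market pig (barrow/gilt average).
DEFAULT_GOMPERTZ = GompertzParams()


def gompertz_bw(params: GompertzParams, age_days):
    """Body weight (kg) at ``age_days`` under the Gompertz curve.

    Parameters
    ----------
    params : GompertzParams
    age_days : float or array-like
        Age in days; must be finite and non-negative.

    Returns
    -------
    float or ndarray
        BW = A * exp(-b * exp(-k * t)); strictly increasing in age and
        strictly below the asymptote for finite age.
    """
    age = np.asarray(age_days, dtype=float)
    if not np.all(np.isfinite(age)):
        raise ValueError("age_days must be finite")
    if np.any(age < 0):
        raise ValueError("age_days must be non-negative")
    bw = params.asymptote_kg * np.exp(-params.shape * np.exp(-params.rate * age))
    return float(bw) if np.isscalar(age_days) else bw


def age_at_bw(params: GompertzParams, bw_kg: float) -> float:
    """Age (days) at which the curve reaches ``bw_kg``.

    Closed-form inverse t = -ln(-ln(bw/A)/b)/k, defined for
    0 < bw_kg < asymptote.  Round-trips with :func:`gompertz_bw` to
    floating-point precision.
    """
    bw = float(bw_kg)
    if not np.isfinite(bw) or bw <= 0 or bw >= params.asymptote_kg:
        raise ValueError(
            f"bw_kg must lie strictly between 0 and the asymptote "
            f"({params.asymptote_kg} kg), got {bw_kg!r}"
        )
    return float(-np.log(-np.log(bw / params.asymptote_kg) / params.shape) / params.rate)
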