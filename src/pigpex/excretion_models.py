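"""Linear phosphorus-excretion prediction models.

Each model predicts a daily P excretion stream (fecal, urinary or total,
g/d) as an affine function of body weight (kg), feed intake (kg/d) and
dietary total-P concentration (% as-fed), their squares, and their
pairwise products.  Six published equations of this family ship as
package data (``load_published_models``); arbitrary models of the same
family can be constructed, serialized and refit.

Unit contract: BW in kg, FI in kg/d, diet P in percent as-fed (0.64
means 0.64 g P per 100 g feed).  This module never rescales inputs; a
reader that accepts FI in g/d must convert before calling.  Predictions
are returned unclamped — a model evaluated outside the BW/diet-P domain
it was fitted on can go negative, and the ``*_with_flag`` variant
reports whether the inputs sit inside that fitted domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import IO, Mapping, Union

import numpy as np

__all__ = [
    "Term",
    "ExcretionModel",
    "FITTED_BW_RANGE_KG",
    "FITTED_DIETP_RANGE_PCT",
    "evaluate",
    "evaluate_with_flag",
    "within_fitted_domain",
    "load_published_models",
    "save_models",
]


class Term(str, Enum):
    """Candidate regressor: a deterministic function of (BW, FI, diet P)."""

    BW = "BW"
    FI = "FI"
    DIETP = "DIETP"
    BW_SQ = "BW_SQ"
    FI_SQ = "FI_SQ"
    DIETP_SQ = "DIETP_SQ"
    BWxFI = "BWxFI"
    BWxDIETP = "BWxDIETP"
    FIxDIETP = "FIxDIETP"


#: Inputs each term draws on; used to detect missing inputs up front.
TERM_INPUTS: Mapping[Term, frozenset] = {
    Term.BW: frozenset({"bw"}),
    Term.FI: frozenset({"fi"}),
    Term.DIETP: frozenset({"dietp"}),
    Term.BW_SQ: frozenset({"bw"}),
    Term.FI_SQ: frozenset({"fi"}),
    Term.DIETP_SQ: frozenset({"dietp"}),
    Term.BWxFI: frozenset({"bw", "fi"}),
    Term.BWxDIETP: frozenset({"bw", "dietp"}),
    Term.FIxDIETP: frozenset({"fi", "dietp"}),
}


def term_value(term: Term, bw=None, fi=None, dietp=None):
    """Numeric value of one regressor given the raw covariates."""
    if term is Term.BW:
        return bw
    if term is Term.FI:
        return fi
    if term is Term.DIETP:
        return dietp
    if term is Term.BW_SQ:
        return bw * bw
    if term is Term.FI_SQ:
        return fi * fi
    if term is Term.DIETP_SQ:
        return dietp * dietp
    if term is Term.BWxFI:
        return bw * fi
    if term is Term.BWxDIETP:
        return bw * dietp
    if term is Term.FIxDIETP:
        return fi * dietp
    raise ValueError(f"unknown term {term!r}")  # pragma: no cover


#: BW and diet-P domain the published equations were fitted on.
FITTED_BW_RANGE_KG = (7.0, 121.5)
FITTED_DIETP_RANGE_PCT = (0.40, 0.64)

_RESPONSES = ("fecal", "urinary", "total")


@dataclass(frozen=True)
class ExcretionModel:
    """An affine P-excretion model: intercept + sum(coef * term value).

    ``rmse`` (g/d) and ``r2`` carry the fit statistics of the model's
    original estimation; ``fit_n`` the number of observations, if known.
    """

    name: str
    response: str
    intercept: float
    coefficients: Mapping[Term, float]
    rmse: float = float("nan")
    r2: float = float("nan")
    fit_n: int | None = None

    def __post_init__(self) -> None:
        if self.response not in _RESPONSES:
            raise ValueError(f"response must be one of {_RESPONSES}, got {self.response!r}")
        coefs = {Term(k): float(v) for k, v in self.coefficients.items()}
        object.__setattr__(self, "coefficients", coefs)
        if not np.isnan(self.rmse) and self.rmse < 0:
            raise ValueError("rmse must be non-negative")
        if not np.isnan(self.r2) and not (0.0 <= self.r2 <= 1.0):
            raise ValueError("r2 must lie in [0, 1]")

    @property
    def terms(self) -> tuple[Term, ...]:
        return tuple(self.coefficients)

    def requires_fi(self) -> bool:
        return any("fi" in TERM_INPUTS[t] for t in self.coefficients)

    def requires_bw(self) -> bool:
        return any("bw" in TERM_INPUTS[t] for t in self.coefficients)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "response": self.response,
            "intercept": self.intercept,
            "coefficients": {t.value: c for t, c in self.coefficients.items()},
            "rmse": self.rmse,
            "r2": self.r2,
        }
        if self.fit_n is not None:
            d["fit_n"] = self.fit_n
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExcretionModel":
        required = {"name", "response", "intercept", "coefficients"}
        missing = required - set(d)
        if missing:
            raise ValueError(f"model record missing fields: {sorted(missing)}")
        try:
            coefs = {Term(k): float(v) for k, v in dict(d["coefficients"]).items()}
        except ValueError as exc:
            raise ValueError(f"bad coefficient entry in model {d.get('name')!r}: {exc}") from exc
        return cls(
            name=str(d["name"]),
            response=str(d["response"]),
            intercept=float(d["intercept"]),
            coefficients=coefs,
            rmse=float(d.get("rmse", float("nan"))),
            r2=float(d.get("r2", float("nan"))),
            fit_n=int(d["fit_n"]) if d.get("fit_n") is not None else None,
        )


def _check_inputs(model: ExcretionModel, bw, fi, dietp) -> None:
    provided = {"bw": bw, "fi": fi, "dietp": dietp}
    needed = set().union(*(TERM_INPUTS[t] for t in model.coefficients)) if model.coefficients else set()
    for key in needed:
        val = provided[key]
        if val is None:
            pretty = {"bw": "bw_kg", "fi": "fi_kg_d", "dietp": "diet_p_pct"}[key]
            raise ValueError(f"model {model.name!r} requires input {pretty}")
        if not np.all(np.isfinite(np.asarray(val, dtype=float))):
            raise ValueError(f"non-finite value for input {key!r}")
    if dietp is not None and np.any(np.asarray(dietp, dtype=float) < 0):
        raise ValueError("diet_p_pct must be non-negative")


def evaluate(model: ExcretionModel, bw_kg=None, fi_kg_d=None, diet_p_pct=None):
    """Predicted excretion (g/d) for the given covariates.

    Inputs may be scalars or broadcastable arrays.  Raises if an input a
    model term needs is absent or non-finite.  No clamping: values can
    be negative outside the fitted domain.
    """
    _check_inputs(model, bw_kg, fi_kg_d, diet_p_pct)
    out = model.intercept
    for term, coef in model.coefficients.items():
        out = out + coef * term_value(term, bw=bw_kg, fi=fi_kg_d, dietp=diet_p_pct)
    return out


def within_fitted_domain(bw_kg=None, diet_p_pct=None):
    """True where the covariates lie inside the published fitting domain."""
    ok = True
    if bw_kg is not None:
        bw = np.asarray(bw_kg, dtype=float)
        ok = ok & (bw >= FITTED_BW_RANGE_KG[0]) & (bw <= FITTED_BW_RANGE_KG[1])
    if diet_p_pct is not None:
        dp = np.asarray(diet_p_pct, dtype=float)
        ok = ok & (dp >= FITTED_DIETP_RANGE_PCT[0]) & (dp <= FITTED_DIETP_RANGE_PCT[1])
    return ok


def evaluate_with_flag(model: ExcretionModel, bw_kg=None, fi_kg_d=None, diet_p_pct=None):
    """Like :func:`evaluate`, but also return an in-domain validity flag."""
    value = evaluate(model, bw_kg=bw_kg, fi_kg_d=fi_kg_d, diet_p_pct=diet_p_pct)
    return value, within_fitted_domain(bw_kg=bw_kg, diet_p_pct=diet_p_pct)


Source = Union[str, Path, IO[str], None]


def load_published_models(source: Source = None) -> dict[str, ExcretionModel]:
    """Load the shipped (or a user-supplied) set of excretion models.

    With no argument, returns the six published equations: Eq1–Eq3
    predict fecal/urinary/total P from BW and diet P; Eq4–Eq6 from FI
    and diet P.  A path or open text handle to a JSON file of the same
    schema may be passed instead.
    """
    if source is None:
        text = resources.files("pigpex.data").joinpath("published_models.json").read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed model file: {exc}") from exc
    return {name: ExcretionModel.from_dict(rec) for name, rec in raw.items()}


def save_models(models: Mapping[str, ExcretionModel], path: Union[str, Path]) -> None:
    """Serialize a model map to JSON (inverse of :func:`load_published_models`)."""
    Path(path).write_text(
        json.dumps({name: m.to_dict() for name, m in models.items()}, indent=1) + "\n"
    )
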