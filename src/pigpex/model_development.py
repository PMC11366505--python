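"""Statistical pipeline for developing P-excretion prediction equations.

The pipeline mirrors how equations of this family are built from
balance-trial data:

1. screen daily urinary-P values for gross outliers per experiment with
   a Tukey-type fence at quartile +/- k * IQR (default k = 3);
2. inspect Pearson correlations among BW, FI, diet P and the excretion
   streams to pick plausible predictors;
3. expand each record into the candidate design (BW, FI, diet P, their
   squares and pairwise products);
4. forward-stepwise ordinary least squares: at each step the candidate
   with the smallest coefficient p-value enters if below ``alpha_enter``
   (SAS-style SLENTRY); after each entry, included terms whose p-value
   has risen to ``alpha_stay`` or above are removed, largest first
   (SLSTAY).  Setting ``alpha_stay=1`` gives pure forward selection.
   The intercept is always estimated and never removed.

Records travel as a pandas DataFrame with the ``BalanceRecord`` column
schema; a row-wise dataclass view is provided for construction and
validation of individual observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .excretion_models import ExcretionModel, Term, TERM_INPUTS, evaluate, term_value

__all__ = [
    "BalanceRecord",
    "BALANCE_COLUMNS",
    "ALL_CANDIDATE_TERMS",
    "records_to_frame",
    "validate_balance_frame",
    "iqr_outlier_mask",
    "iqr_outlier_filter",
    "filter_urinary_outliers",
    "correlation_matrix",
    "expand_terms",
    "StepwiseResult",
    "forward_stepwise",
    "fit_metrics",
]

logger = logging.getLogger(__name__)

BALANCE_COLUMNS = (
    "pig_id",
    "experiment",
    "period",
    "diet_id",
    "bw_kg",
    "fi_kg_d",
    "diet_p_pct",
    "p_intake_g_d",
    "fecal_p_g_d",
    "urinary_p_g_d",
    "total_p_g_d",
)

#: Full candidate set: main effects, squares, pairwise interactions.
ALL_CANDIDATE_TERMS: tuple[Term, ...] = tuple(Term)

#: Covariate-family candidate sets for guided selection: equations are
#: developed per family (BW + diet P, or FI + diet P) so the resulting
#: model needs only the inputs its users can actually supply.
BW_DIETP_TERMS: tuple[Term, ...] = (
    Term.BW, Term.DIETP, Term.BW_SQ, Term.DIETP_SQ, Term.BWxDIETP,
)
FI_DIETP_TERMS: tuple[Term, ...] = (
    Term.FI, Term.DIETP, Term.FI_SQ, Term.DIETP_SQ, Term.FIxDIETP,
)

_TERM_FIELD = {"bw": "bw_kg", "fi": "fi_kg_d", "dietp": "diet_p_pct"}


@dataclass(frozen=True)
class BalanceRecord:
    """One pig x period observation from a total-collection balance trial.

    ``bw_kg`` is the period-mean body weight (mean of initial and final
    BW of the period); intake and excretion are daily rates over the
    collection window.
    """

    pig_id: str
    experiment: str
    period: int
    diet_id: str
    bw_kg: float
    fi_kg_d: float
    diet_p_pct: float
    p_intake_g_d: float
    fecal_p_g_d: float
    urinary_p_g_d: float
    total_p_g_d: float

    def __post_init__(self) -> None:
        for name in ("bw_kg", "fi_kg_d", "diet_p_pct", "p_intake_g_d",
                     "fecal_p_g_d", "urinary_p_g_d", "total_p_g_d"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")
        if abs(self.total_p_g_d - (self.fecal_p_g_d + self.urinary_p_g_d)) > 1e-6:
            raise ValueError("total_p_g_d must equal fecal_p_g_d + urinary_p_g_d")


def records_to_frame(records: Iterable[BalanceRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=list(BALANCE_COLUMNS))


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


def validate_balance_frame(df: pd.DataFrame, intake_rtol: float = 0.02) -> None:
    """Check the balance-record invariants on a whole table.

    Raises on missing columns, negative rates, or a total that is not
    the sum of the fecal and urinary streams.  A P intake farther than
    ``intake_rtol`` (relative) from FI x diet P x 10 logs a warning —
    measured intake may legitimately differ from the product.
    """
    missing = set(BALANCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"balance table missing columns: {sorted(missing)}")
    num = df[list(BALANCE_COLUMNS[4:])].to_numpy(dtype=float)
    if not np.all(np.isfinite(num)):
        raise ValueError("balance table contains non-finite values")
    if np.any(num < 0):
        raise ValueError("balance table contains negative masses or rates")
    resid = df["total_p_g_d"] - (df["fecal_p_g_d"] + df["urinary_p_g_d"])
    if np.any(np.abs(resid) > 1e-6):
        raise ValueError("total_p_g_d != fecal_p_g_d + urinary_p_g_d")
    expected = df["fi_kg_d"] * df["diet_p_pct"] * 10.0
    off = np.abs(df["p_intake_g_d"] - expected) > intake_rtol * np.maximum(expected, 1e-12)
    if off.any():
        logger.warning(
            "%d records have P intake deviating >%g%% from FI x dietP x 10",
            int(off.sum()), 100 * intake_rtol,
        )


# ---------------------------------------------------------------------------
# Outlier screening


def iqr_outlier_mask(values, k: float = 3.0) -> np.ndarray:
    """Boolean mask of values beyond quartile +/- k * IQR (strict).

    Quartiles use linear interpolation between order statistics.  With
    the default k = 3 this is a very conservative fence that only gross
    errors cross.  Requires at least 4 values.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if v.size < 4:
        raise ValueError(f"need at least 4 values to estimate quartiles, got {v.size}")
    if k <= 0:
        raise ValueError("k must be positive")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v < q1 - k * iqr) | (v > q3 + k * iqr)


def iqr_outlier_filter(values, k: float = 3.0):
    """Split indices into (kept, flagged) by the IQR fence."""
    mask = iqr_outlier_mask(values, k=k)
    idx = np.arange(mask.size)
    return idx[~mask], idx[mask]


def filter_urinary_outliers(
    records, k: float = 3.0, column: str = "urinary_p_g_d"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the IQR fence to daily urinary P within each experiment.

    Returns ``(kept, flagged)`` DataFrames.  Screening is per
    experiment because the urinary-P scale differs severalfold between
    growth stages.
    """
    df = _as_frame(records)
    flagged_parts = []
    for _, grp in df.groupby("experiment", sort=False):
        mask = iqr_outlier_mask(grp[column].to_numpy(), k=k)
        flagged_parts.append(grp.loc[mask])
    flagged = (
        pd.concat(flagged_parts) if flagged_parts else df.iloc[0:0]
    )
    kept = df.drop(index=flagged.index)
    return kept, flagged


# ---------------------------------------------------------------------------
# Correlation screening


def correlation_matrix(records, variables: Sequence[str]):
    """Pearson r and two-sided p-values among the named columns.

    Returns ``(r, p)`` DataFrames, symmetric with unit diagonal.  For a
    zero-variance column the off-diagonal r and p are NaN (flagged, not
    fatal).  p-values come from the exact t transform with n - 2 df.
    """
    df = _as_frame(records)
    n = len(df)
    if n < 3:
        raise ValueError(f"need at least 3 records for correlations, got {n}")
    x = df[list(variables)].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.asarray(r, dtype=float)
    for i, s in enumerate(sd):
        if s == 0:
            r[i, :] = np.nan
            r[:, i] = np.nan
    np.fill_diagonal(r, 1.0)
    # t transform: t = r * sqrt((n-2)/(1-r^2)), df = n - 2
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        rr = np.clip(r, -1.0, 1.0)
        t = rr * np.sqrt((n - 2) / np.maximum(1.0 - rr**2, np.finfo(float).tiny))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    p[np.isnan(r)] = np.nan
    cols = list(variables)
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


# ---------------------------------------------------------------------------
# Design expansion


def expand_terms(records, candidates: Sequence[Term] = ALL_CANDIDATE_TERMS) -> pd.DataFrame:
    """Design matrix of candidate-term values, one column per term.

    Units follow the model contract: BW kg, FI kg/d, diet P % as-fed.
    Raises if a record field a term needs is absent, naming the term.
    """
    df = _as_frame(records)
    out = {}
    for term in candidates:
        term = Term(term)
        kwargs = {}
        for inp in TERM_INPUTS[term]:
            col = _TERM_FIELD[inp]
            if col not in df.columns:
                raise ValueError(f"term {term.value} requires missing field {col!r}")
            kwargs[inp] = df[col].to_numpy(dtype=float)
        out[term.value] = np.asarray(term_value(term, **kwargs), dtype=float)
    return pd.DataFrame(out, index=df.index)


# ---------------------------------------------------------------------------
# OLS core (normal equations; small designs, thousands of refits)

#: Relative SSE below which a fit is numerically perfect: entry stops,
#: since further p-values would be artifacts of floating-point residue.
_PERFECT_FIT_RTOL = 1e-12


@dataclass
class _OLSFit:
    coefs: np.ndarray       # includes intercept first
    std_errors: np.ndarray  # same order
    p_values: np.ndarray    # same order
    sse: float
    sst: float
    n: int
    p: int                  # estimated parameters incl. intercept

    @property
    def r2(self) -> float:
        return 1.0 - self.sse / self.sst if self.sst > 0 else np.nan

    @property
    def rmse(self) -> float:
        return float(np.sqrt(self.sse / (self.n - self.p)))


def _ols(y: np.ndarray, X: np.ndarray) -> _OLSFit | None:
    """Least squares with intercept prepended; None if rank-deficient."""
    n = y.size
    Z = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    p = Z.shape[1]
    if n <= p:
        return None
    if np.linalg.matrix_rank(Z) < p:
        return None
    coefs, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ coefs
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    sigma2 = sse / (n - p)
    XtX_inv = np.linalg.inv(Z.T @ Z)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coefs / se, np.inf * np.sign(coefs))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
    return _OLSFit(coefs=coefs, std_errors=se, p_values=pvals, sse=sse, sst=sst, n=n, p=p)


@dataclass
class StepwiseResult:
    """Outcome of a forward-stepwise selection.

    ``trace`` records every decision: one dict per event with keys
    step, candidate, p_value, action (entered/removed/skipped/stopped).
    """

    selected_terms: list[Term]
    intercept: float
    coefficients: dict[Term, float]
    p_values: dict[Term, float]
    rmse: float
    r2: float
    n: int
    std_errors: dict[Term, float] = field(default_factory=dict)
    intercept_se: float = float("nan")
    trace: list[dict] = field(default_factory=list)

    def to_model(self, response: str, name: str = "fitted") -> ExcretionModel:
        """Package the selected fit as an evaluable excretion model."""
        resp = {"fecal_p_g_d": "fecal", "urinary_p_g_d": "urinary", "total_p_g_d": "total"}.get(
            response, response
        )
        return ExcretionModel(
            name=name,
            response=resp,
            intercept=self.intercept,
            coefficients=dict(self.coefficients),
            rmse=self.rmse,
            r2=self.r2 if 0.0 <= self.r2 <= 1.0 else float("nan"),
            fit_n=self.n,
        )

    def to_dict(self) -> dict:
        return {
            "selected_terms": [t.value for t in self.selected_terms],
            "intercept": self.intercept,
            "coefficients": {t.value: c for t, c in self.coefficients.items()},
            "p_values": {t.value: p for t, p in self.p_values.items()},
            "std_errors": {t.value: s for t, s in self.std_errors.items()},
            "intercept_se": self.intercept_se,
            "rmse": self.rmse,
            "r2": self.r2,
            "n": self.n,
            "trace": self.trace,
        }


def forward_stepwise(
    records,
    response: str,
    candidates: Sequence[Term] = ALL_CANDIDATE_TERMS,
    alpha_enter: float = 0.05,
    alpha_stay: float = 0.05,
) -> StepwiseResult:
    """Forward-stepwise OLS term selection with p-value entry/stay rules.

    At each step every remaining candidate is tried one at a time on
    top of the current model; the candidate with the smallest
    coefficient p-value enters if that p-value is below ``alpha_enter``
    (ties broken by larger partial R-square, then candidate order).
    After each entry, any included term whose p-value is at or above
    ``alpha_stay`` is removed, largest first, refitting after each
    removal.  The intercept is always retained.  A candidate that makes
    the design rank-deficient is skipped with a logged warning.  If no
    candidate ever enters, the result is the intercept-only model.
    """
    df = _as_frame(records)
    if response not in df.columns:
        raise ValueError(f"response column {response!r} not in records")
    candidates = [Term(c) for c in candidates]
    if len(df) <= len(candidates) + 1:
        raise ValueError(
            f"need more records ({len(df)}) than candidates + 1 ({len(candidates) + 1})"
        )
    y = df[response].to_numpy(dtype=float)
    design = expand_terms(df, candidates)
    X_full = {t: design[t.value].to_numpy() for t in candidates}

    included: list[Term] = []
    trace: list[dict] = []
    step = 0

    def fit(terms: Sequence[Term]) -> _OLSFit | None:
        X = np.column_stack([X_full[t] for t in terms]) if terms else np.empty((y.size, 0))
        return _ols(y, X)

    current = fit(included)
    while True:
        step += 1
        remaining = [t for t in candidates if t not in included]
        if not remaining:
            break
        best = None  # (p_value, -r2, order_index, term, fit)
        for order, cand in enumerate(remaining):
            trial = fit(included + [cand])
            if trial is None:
                logger.warning("skipping rank-deficient candidate %s", cand.value)
                trace.append(
                    {"step": step, "candidate": cand.value, "p_value": None, "action": "skipped"}
                )
                continue
            p_cand = float(trial.p_values[-1])
            key = (p_cand, -trial.r2, order)
            if best is None or key < best[0]:
                best = (key, cand, trial)
        if best is None:
            break
        (p_best, _, _), cand, trial = best
        if p_best >= alpha_enter:
            trace.append(
                {"step": step, "candidate": cand.value, "p_value": p_best, "action": "stopped"}
            )
            break
        included.append(cand)
        current = trial
        trace.append(
            {"step": step, "candidate": cand.value, "p_value": p_best, "action": "entered"}
        )
        # backward purge at alpha_stay (skipped when alpha_stay >= 1: pure forward)
        while alpha_stay < 1.0 and len(included) > 0:
            pv = current.p_values[1:]  # term p-values (intercept exempt)
            worst = int(np.argmax(pv))
            if pv[worst] < alpha_stay:
                break
            removed = included.pop(worst)
            trace.append(
                {
                    "step": step,
                    "candidate": removed.value,
                    "p_value": float(pv[worst]),
                    "action": "removed",
                }
            )
            current = fit(included)
        # numerically perfect fit: nothing left to explain.  t-based
        # p-values are floating-point artifacts here, so redundant terms
        # are pruned exactly instead: drop any term whose removal keeps
        # the fit perfect, then stop.
        def _perfect(f: _OLSFit) -> bool:
            return f.sse <= _PERFECT_FIT_RTOL * max(f.sst, np.finfo(float).tiny)

        if _perfect(current):
            pruned = True
            while pruned and len(included) > 1:
                pruned = False
                for t in list(included):
                    trial = fit([u for u in included if u is not t])
                    if trial is not None and _perfect(trial):
                        included.remove(t)
                        current = trial
                        trace.append(
                            {"step": step, "candidate": t.value, "p_value": None,
                             "action": "removed"}
                        )
                        pruned = True
                        break
            trace.append(
                {"step": step, "candidate": None, "p_value": None, "action": "stopped"}
            )
            break

    final = current if current is not None else fit([])
    assert final is not None
    coefs = {t: float(final.coefs[i + 1]) for i, t in enumerate(included)}
    pvals = {t: float(final.p_values[i + 1]) for i, t in enumerate(included)}
    ses = {t: float(final.std_errors[i + 1]) for i, t in enumerate(included)}
    return StepwiseResult(
        selected_terms=list(included),
        intercept=float(final.coefs[0]),
        coefficients=coefs,
        p_values=pvals,
        rmse=final.rmse,
        r2=float(final.r2),
        n=final.n,
        std_errors=ses,
        intercept_se=float(final.std_errors[0]),
        trace=trace,
    )


def fit_metrics(records, model: ExcretionModel, response: str) -> dict:
    """Goodness of fit of an existing model on a record table.

    R-square is 1 - SSE/SST; RMSE is sqrt(SSE/(n - p)) with p the
    number of estimated parameters including the intercept.  A constant
    response (SST = 0) yields NaN R-square.
    """
    df = _as_frame(records)
    if len(df) < 3:
        raise ValueError(f"need at least 3 records, got {len(df)}")
    y = df[response].to_numpy(dtype=float)
    pred = evaluate(
        model,
        bw_kg=df["bw_kg"].to_numpy(dtype=float) if model.requires_bw() else None,
        fi_kg_d=df["fi_kg_d"].to_numpy(dtype=float) if model.requires_fi() else None,
        diet_p_pct=df["diet_p_pct"].to_numpy(dtype=float),
    )
    pred = np.broadcast_to(np.asarray(pred, dtype=float), y.shape)
    sse = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    p = 1 + len(model.coefficients)
    return {
        "r2": 1.0 - sse / sst if sst > 0 else float("nan"),
        "rmse": float(np.sqrt(sse / (len(df) - p))),
        "n": len(df),
    }
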