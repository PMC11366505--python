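"""Synthetic phosphorus balance-trial data.

Emulates a series of total-collection experiments on growing pigs so
the whole modelling pipeline — outlier screening, correlation analysis,
stepwise model development — can be exercised end to end without the
(unpublished) raw trial data.

The default design mirrors four experiments at body-weight centers of
roughly 15, 30, 50 and 80 kg: 12 pigs x 2 periods each, three diets per
experiment in a balanced allocation, daily feed allowance set as a
fixed percentage of (experiment- or period-) initial BW, and responses
generated from a pair of "truth" excretion models plus homoscedastic
Gaussian residuals at the models' published residual SDs.  Urinary
values occasionally receive a multiplicative gross-error spike so the
outlier screen has something realistic to find.

What this generator does NOT emulate: the Latin-square crossover
correlation structure (records are independent given the design), the
right-skew of real urinary-P residuals (a lognormal option exists, off
by default), or assay error in diet-P concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd
import yaml

from .excretion_models import ExcretionModel, evaluate, load_published_models
from .model_development import BALANCE_COLUMNS

__all__ = [
    "ExperimentDesign",
    "TrialDesign",
    "GeneratorConfig",
    "default_trial_design",
    "default_generator_config",
    "generate",
    "summarize",
    "write_balance_csv",
    "read_balance_csv",
]

PERIOD_DAYS = 9  # 5 d adaptation + 4 d collection


@dataclass(frozen=True)
class ExperimentDesign:
    """One balance experiment: pigs, periods, BW span, feeding level, diets."""

    label: str
    n_pigs: int
    initial_bw_mean_kg: float
    initial_bw_sd_kg: float
    final_bw_mean_kg: float
    feed_allowance_frac_of_bw: float
    diet_p_levels_pct: tuple[float, ...]
    periods: int = 2
    allowance_basis: str = "period_initial"  # or "experiment_initial"
    final_bw_sd_kg: float | None = None  # None: no inter-pig gain variation

    def __post_init__(self) -> None:
        if self.n_pigs <= 0 or self.periods <= 0:
            raise ValueError(f"{self.label}: n_pigs and periods must be positive")
        if self.n_pigs % len(self.diet_p_levels_pct) != 0:
            raise ValueError(
                f"{self.label}: n_pigs ({self.n_pigs}) must be divisible by the "
                f"number of diets ({len(self.diet_p_levels_pct)})"
            )
        if not (0.0 < self.feed_allowance_frac_of_bw < 0.1):
            raise ValueError(
                f"{self.label}: feed_allowance_frac_of_bw must lie in (0, 0.1)"
            )
        if self.initial_bw_sd_kg < 0 or self.initial_bw_mean_kg <= 0:
            raise ValueError(f"{self.label}: bad initial BW parameters")
        if self.final_bw_mean_kg <= self.initial_bw_mean_kg:
            raise ValueError(f"{self.label}: final BW must exceed initial BW")
        if self.allowance_basis not in ("period_initial", "experiment_initial"):
            raise ValueError(f"{self.label}: unknown allowance_basis {self.allowance_basis!r}")
        if self.final_bw_sd_kg is not None and self.final_bw_sd_kg < self.initial_bw_sd_kg:
            raise ValueError(f"{self.label}: final_bw_sd_kg must be >= initial_bw_sd_kg")
        object.__setattr__(self, "diet_p_levels_pct", tuple(float(x) for x in self.diet_p_levels_pct))

    @property
    def daily_gain_kg_d(self) -> float:
        return (self.final_bw_mean_kg - self.initial_bw_mean_kg) / (self.periods * PERIOD_DAYS)

    @property
    def gain_sd_kg(self) -> float:
        """Inter-pig SD of total experiment gain.

        Chosen so that initial- and final-BW dispersions jointly match
        the design: Var(final) = Var(initial) + Var(gain) under
        independent gain, hence sd = sqrt(final_sd^2 - initial_sd^2).
        """
        if self.final_bw_sd_kg is None:
            return 0.0
        return float(np.sqrt(self.final_bw_sd_kg**2 - self.initial_bw_sd_kg**2))


@dataclass(frozen=True)
class TrialDesign:
    experiments: tuple[ExperimentDesign, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "experiments", tuple(self.experiments))
        if not self.experiments:
            raise ValueError("trial design needs at least one experiment")

    @property
    def n_records(self) -> int:
        return sum(e.n_pigs * e.periods for e in self.experiments)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "TrialDesign":
        return cls(tuple(ExperimentDesign(**rec) for rec in data["experiments"]))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "TrialDesign":
        return cls.from_mapping(yaml.safe_load(Path(path).read_text()))


def default_trial_design() -> TrialDesign:
    """Four experiments at ~15/30/50/80 kg, 24 records each (96 total)."""
    text = resources.files("pigpex.data").joinpath("default_trial_design.yaml").read_text()
    data = yaml.safe_load(text)
    for rec in data["experiments"]:
        rec["diet_p_levels_pct"] = tuple(rec["diet_p_levels_pct"])
    return TrialDesign.from_mapping(data)


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything that determines a synthetic dataset, seed included.

    Residual SDs default to the published RMSEs of the BW-based fecal
    and urinary equations (0.656 and 0.194 g/d), which the truth models
    also default to, so refitting generated data is a faithful
    parameter-recovery exercise.
    """

    design: TrialDesign
    fecal_truth: ExcretionModel
    urinary_truth: ExcretionModel
    residual_sd_fecal: float = 0.656
    residual_sd_urinary: float = 0.194
    outlier_rate: float = 0.01
    outlier_scale: float = 10.0
    fi_jitter_frac: float = 0.05
    urinary_distribution: str = "gaussian"  # or "lognormal"
    fecal_floor_g_d: float = 0.05
    urinary_floor_g_d: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd_fecal < 0 or self.residual_sd_urinary < 0:
            raise ValueError("residual SDs must be non-negative")
        if not (0.0 <= self.outlier_rate <= 1.0):
            raise ValueError("outlier_rate must lie in [0, 1]")
        if self.outlier_scale <= 1.0:
            raise ValueError("outlier_scale must exceed 1")
        if self.urinary_distribution not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown urinary_distribution {self.urinary_distribution!r}")
        if not (0.0 <= self.fi_jitter_frac < 0.5):
            raise ValueError("fi_jitter_frac must lie in [0, 0.5)")


def default_generator_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Default config: published design, truth models Eq1/Eq2."""
    published = load_published_models()
    base = dict(
        design=default_trial_design(),
        fecal_truth=published["Eq1"],
        urinary_truth=published["Eq2"],
        seed=seed,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def _noise(rng: np.random.Generator, mean: np.ndarray, sd: float, kind: str) -> np.ndarray:
    """Additive residual around `mean`; lognormal matches mean/sd moments."""
    if sd == 0:
        return mean
    if kind == "gaussian":
        return mean + rng.normal(0.0, sd, size=mean.shape)
    # lognormal with the same mean and sd as the target stream
    m = np.maximum(mean, 1e-6)
    sigma2 = np.log1p((sd / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2))


def generate(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one synthetic balance dataset as a BalanceRecord table.

    Fully deterministic given ``config.seed``; each experiment draws
    from its own sub-stream spawned from the master seed, so any single
    experiment can be regenerated in isolation.
    """
    frames = []
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(len(config.design.experiments))
    for exp, ss in zip(config.design.experiments, streams):
        rng = np.random.default_rng(ss)
        n_diets = len(exp.diet_p_levels_pct)
        bw0 = rng.normal(exp.initial_bw_mean_kg, exp.initial_bw_sd_kg, size=exp.n_pigs)
        total_days = exp.periods * PERIOD_DAYS
        mean_span = exp.final_bw_mean_kg - exp.initial_bw_mean_kg
        # per-pig daily gain: mean span plus inter-pig variation (if designed),
        # truncated at a small positive floor so every pig grows
        spans = rng.normal(mean_span, exp.gain_sd_kg, size=exp.n_pigs)
        spans = np.maximum(spans, 0.1 * mean_span)
        gains = spans / total_days
        rows = []
        for pig in range(exp.n_pigs):
            gain = gains[pig]
            for period in range(1, exp.periods + 1):
                diet_idx = (pig + period - 1) % n_diets
                diet_p = exp.diet_p_levels_pct[diet_idx]
                period_start_bw = bw0[pig] + (period - 1) * PERIOD_DAYS * gain
                bw_mid = period_start_bw + PERIOD_DAYS * gain / 2.0
                basis_bw = bw0[pig] if exp.allowance_basis == "experiment_initial" else period_start_bw
                fi = exp.feed_allowance_frac_of_bw * basis_bw
                fi *= 1.0 + rng.uniform(-config.fi_jitter_frac, config.fi_jitter_frac)
                p_intake = fi * diet_p * 10.0
                fecal_mu = max(
                    float(evaluate(config.fecal_truth, bw_kg=bw_mid, fi_kg_d=fi, diet_p_pct=diet_p)),
                    0.0,
                )
                urinary_mu = max(
                    float(evaluate(config.urinary_truth, bw_kg=bw_mid, fi_kg_d=fi, diet_p_pct=diet_p)),
                    0.0,
                )
                fecal = float(
                    _noise(rng, np.asarray(fecal_mu), config.residual_sd_fecal, "gaussian")
                )
                urinary = float(
                    _noise(
                        rng,
                        np.asarray(urinary_mu),
                        config.residual_sd_urinary,
                        config.urinary_distribution,
                    )
                )
                fecal = max(fecal, config.fecal_floor_g_d)
                urinary = max(urinary, config.urinary_floor_g_d)
                if rng.random() < config.outlier_rate:
                    urinary *= config.outlier_scale
                rows.append(
                    {
                        "pig_id": f"{exp.label}-P{pig + 1:02d}",
                        "experiment": exp.label,
                        "period": period,
                        "diet_id": f"{exp.label}-D{diet_idx + 1}",
                        "bw_kg": bw_mid,
                        "fi_kg_d": fi,
                        "diet_p_pct": diet_p,
                        "p_intake_g_d": p_intake,
                        "fecal_p_g_d": fecal,
                        "urinary_p_g_d": urinary,
                        "total_p_g_d": fecal + urinary,
                    }
                )
        frames.append(pd.DataFrame(rows))
    df = pd.concat(frames, ignore_index=True)
    return df[list(BALANCE_COLUMNS)]


_SUMMARY_FIELDS = (
    ("bw_kg", "Body weight (kg)"),
    ("fi_kg_d", "Feed intake (kg/d)"),
    ("p_intake_g_d", "P intake (g/d)"),
    ("fecal_p_g_d", "Fecal P excretion (g/d)"),
    ("urinary_p_g_d", "Urinary P excretion (g/d)"),
    ("total_p_g_d", "Total P excretion (g/d)"),
)


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Per-experiment N/mean/min/max/SD/CV table for the core streams.

    SD is the sample SD (ddof=1); CV = 100 * SD / mean.  Single-record
    groups report SD = CV = 0.
    """
    if len(records) == 0:
        raise ValueError("no records to summarize")
    rows = []
    for exp, grp in records.groupby("experiment", sort=False):
        for col, label in _SUMMARY_FIELDS:
            v = grp[col].to_numpy(dtype=float)
            sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
            mean = float(v.mean())
            rows.append(
                {
                    "experiment": exp,
                    "item": label,
                    "n": v.size,
                    "mean": mean,
                    "min": float(v.min()),
                    "max": float(v.max()),
                    "sd": sd,
                    "cv": 100.0 * sd / mean if mean != 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def write_balance_csv(records: pd.DataFrame, path: Union[str, Path], seed: int | None = None) -> None:
    """Write records as CSV; the generating seed goes in a header comment."""
    path = Path(path)
    with path.open("w") as fh:
        if seed is not None:
            fh.write(f"# pigpex synthetic balance records; seed={seed}\n")
        records.to_csv(fh, index=False)


def read_balance_csv(path: Union[str, Path], fi_units: str = "kg_d") -> pd.DataFrame:
    """Read a balance-record CSV (comment lines ignored).

    ``fi_units``: 'kg_d' (native) or 'g_d' — the latter divides the FI
    column by 1000 on ingest, keeping the in-memory unit contract.
    """
    df = pd.read_csv(path, comment="#")
    missing = set(BALANCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"balance CSV missing columns: {sorted(missing)}")
    if fi_units == "g_d":
        df = df.assign(fi_kg_d=df["fi_kg_d"] / 1000.0)
    elif fi_units != "kg_d":
        raise ValueError(f"fi_units must be 'kg_d' or 'g_d', got {fi_units!r}")
    return df[list(BALANCE_COLUMNS)]
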