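"""Exposure metrics and model-performance statistics.

The common data currency is a tidy observation table (a pandas DataFrame)
with one row per measured concentration:

    group              dose-group identifier
    species            e.g. 'monkey', 'rabbit'
    route              'iv' or 'sc'
    dose_nmol_per_kg   molar dose normalised to body weight
    time_days          sampling time since first dose
    analyte            'drug' or 'soluble-target'
    conc_nM            measured concentration (NaN when censored)
    censored           True when below the quantification limit

Metrics: trapezoidal AUC to the last measurable point, the symmetric mean
absolute percentage error between observed and simulated AUCs (bounded
0-200%), the absolute average fold error across paired concentrations
(>= 1), dose-normalised AUC for dose-proportionality assessment, and a local
sensitivity sweep reporting signed percent changes of 30-day drug exposure.
"""

from __future__ import annotations

from collections.abc import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .model import Regimen
from .parameters import ModelParameters
from .simulate import SimulationResult, simulate

__all__ = [
    "OBSERVATION_COLUMNS",
    "validate_observations",
    "auc_last",
    "smape",
    "aafe",
    "dose_normalized_auc",
    "local_sensitivity",
]

OBSERVATION_COLUMNS = (
    "group",
    "species",
    "route",
    "dose_nmol_per_kg",
    "time_days",
    "analyte",
    "conc_nM",
    "censored",
)


def validate_observations(table: pd.DataFrame) -> pd.DataFrame:
    """Check an observation table's schema and invariants; returns it unchanged."""
    missing = set(OBSERVATION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    if (table["time_days"] < 0).any():
        raise ValueError("observation times must be >= 0")
    uncensored = table.loc[~table["censored"].astype(bool)]
    if not (uncensored["conc_nM"] > 0).all():
        raise ValueError("non-censored concentrations must be > 0")
    if table.loc[table["censored"].astype(bool), "conc_nM"].notna().any():
        raise ValueError("censored records must carry no concentration")
    bad = set(table["analyte"].unique()) - {"drug", "soluble-target"}
    if bad:
        raise ValueError(f"unknown analyte(s): {sorted(bad)}")
    return table


def auc_last(times: np.ndarray, concentrations: np.ndarray) -> float:
    """Linear-trapezoid AUC from the first to the last measurable point (day*nM)."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    keep = np.isfinite(c)
    t, c = t[keep], c[keep]
    if len(t) < 2:
        raise ValueError("auc_last needs at least 2 non-censored points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(c, t))


def smape(auc_sim: float, auc_obs: float) -> float:
    """Symmetric mean absolute percentage error between two AUCs, percent.

    Bounded by 0 (identical) and 200 (one value zero).
    """
    if auc_sim < 0 or auc_obs < 0:
        raise ValueError("AUCs must be non-negative")
    denom = 0.5 * (auc_sim + auc_obs)
    if denom == 0:
        raise ValueError("smape undefined when both AUCs are zero")
    return abs(auc_sim - auc_obs) / denom * 100.0


def aafe(predicted: Iterable[float], observed: Iterable[float]) -> float:
    """Absolute average fold error, 10**mean(|log10(pred/obs)|); >= 1."""
    p = np.asarray(list(predicted), dtype=float)
    o = np.asarray(list(observed), dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError("aafe needs non-empty paired values")
    if np.any(p <= 0) or np.any(o <= 0):
        raise ValueError("aafe needs strictly positive concentrations")
    return float(10.0 ** np.mean(np.abs(np.log10(p / o))))


def dose_normalized_auc(result: SimulationResult, dose_per_kg: float) -> float:
    """Free-drug AUC over the full simulated grid divided by the molar dose/kg."""
    if dose_per_kg <= 0:
        raise ValueError("dose_per_kg must be > 0")
    return float(np.trapezoid(result.free_drug, result.times)) / dose_per_kg


def _auc_0_to(result: SimulationResult, t_end: float) -> float:
    mask = result.times <= t_end
    return float(np.trapezoid(result.free_drug[mask], result.times[mask]))


def local_sensitivity(
    params: ModelParameters,
    regimen: Regimen,
    param_name: str,
    values: Iterable[float],
    couplings: Mapping[str, Callable[[float], float]] | None = None,
    horizon_days: float = 30.0,
) -> pd.DataFrame:
    """Signed percent change of drug AUC(0-30 days) as one parameter is swept.

    ``couplings`` maps dependent parameter names to functions of the swept
    value, applied before each simulation (e.g. keeping the membrane-target
    baseline proportional to the soluble baseline).  Simulation failures at
    individual sweep values are recorded as NaN; the sweep proceeds.
    """
    ref = simulate(params, regimen)
    auc_ref = _auc_0_to(ref, horizon_days)
    rows = []
    for v in values:
        if v <= 0:
            raise ValueError("sweep values must be positive")
        updates = {param_name: float(v)}
        if couplings:
            for dep, fn in couplings.items():
                updates[dep] = float(fn(v))
        try:
            res = simulate(params.with_updates(**updates), regimen)
            pct = (_auc_0_to(res, horizon_days) - auc_ref) / auc_ref * 100.0
        except Exception:
            pct = float("nan")
        rows.append({"parameter": param_name, "value": float(v), "pct_change_auc": pct})
    return pd.DataFrame(rows)
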