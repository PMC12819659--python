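"""Multi-start nonlinear least-squares estimation of the TMDD parameters.

The estimation problem is naive-pooled: per-group mean concentration-time
data for both analytes, all dose groups at once, with the objective

    SSR = sum over observations of (log10 y_obs - log10 y_pred)**2.

Each of ``n_starts`` starting points — sampled log-uniformly within
per-parameter initial ranges — is refined by damped Gauss-Newton on the
log10-transformed parameters (finite-difference Jacobian, rank-revealing
least-squares step, step-halving line search).  The cloud of terminal SSR
values then drives the diagnostics: an elbow cut on the sorted SSR curve
plus iterative Grubbs outlier removal selects the accepted cluster, and a
binned approximate profile likelihood over all terminal sets classifies
each parameter as identifiable or not.

The log10 parameterization enforces positivity; the initial ranges bound
sampling only, not the subsequent iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import odeint

from .model import (
    Regimen,
    apply_dose,
    initial_state,
    pack_params,
    rhs_stacked,
    rhs_stacked_jacobian,
)
from .parameters import ModelParameters

__all__ = [
    "OPTIMIZED_PARAMETERS",
    "DEFAULT_RANGES",
    "FitProblem",
    "FitResult",
    "ssr",
    "sample_starts",
    "fit_multistart",
    "accept_sets",
    "profile_identifiability",
]

PRED_FLOOR_NM = 1e-12

#: the fifteen optimized parameters, in canonical vector order
OPTIMIZED_PARAMETERS = (
    "CL_D",
    "V2",
    "V3",
    "k01",
    "k02",
    "k12",
    "k_deg_m",
    "k_deg_s",
    "k_el_CM",
    "k_el_CS",
    "k_el_MG1113",
    "k_loss",
    "k_on",
    "mTFPI_base",
    "sTFPI_base",
)

#: published initial sampling ranges (min, max), typically 1e-2 to 1e2
#: of a base value
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "CL_D": (0.002755, 27.55),
    "V2": (0.00157, 15.7),
    "V3": (0.001047, 10.47),
    "k01": (0.01, 100.0),
    "k02": (0.01, 100.0),
    "k12": (0.01, 100.0),
    "k_deg_m": (0.01, 100.0),
    "k_deg_s": (0.025, 250.0),
    "k_el_CM": (0.01, 100.0),
    "k_el_CS": (0.00259, 25.9),
    "k_el_MG1113": (0.0005359, 5.359),
    "k_loss": (0.01, 100.0),
    "k_on": (0.01435, 143.5),
    "mTFPI_base": (0.01, 100.0),
    "sTFPI_base": (0.009768, 97.68),
}


def ssr(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Sum of squared base-10 log residuals between paired concentrations.

    Non-positive predictions are floored at 1e-12 nM so the objective stays
    finite (a floored prediction contributes a huge but finite residual).
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError("observed and predicted must be paired")
    if np.any(o <= 0):
        raise ValueError("observed concentrations must be > 0 (drop censored)")
    p = np.maximum(p, PRED_FLOOR_NM)
    r = np.log10(o) - np.log10(p)
    return float(r @ r)


@dataclass(frozen=True)
class FitProblem:
    """Observations, regimens, fixed parameters, ranges and optimizer settings."""

    observations: pd.DataFrame                   # mean table, tidy schema
    regimens: dict[str, Regimen]                 # group id -> regimen
    fixed: dict[str, float]                      # BW, KD
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    n_starts: int = 1000
    n_iterations: int = 100
    seed: int = 0
    sim_rtol: float = 1e-5
    sim_atol: float = 1e-8

    def __post_init__(self) -> None:
        obs = self.observations
        groups = set(obs["group"].unique())
        missing = groups - set(self.regimens)
        if missing:
            raise ValueError(f"no regimen for observed group(s): {sorted(missing)}")
        for name, (lo, hi) in self.ranges.items():
            if not (0 < lo <= hi):
                raise ValueError(f"range for {name} must satisfy 0 < min <= max")
        if set(self.ranges) != set(OPTIMIZED_PARAMETERS):
            raise ValueError("ranges must cover exactly the optimized parameters")
        for key in ("BW", "KD"):
            if key not in self.fixed:
                raise ValueError(f"fixed parameters must include {key}")

    def parameters_from_vector(self, x_log10: np.ndarray) -> ModelParameters:
        values = dict(self.fixed)
        for name, xl in zip(OPTIMIZED_PARAMETERS, x_log10):
            values[name] = 10.0**xl
        return ModelParameters.from_dict(values)


def sample_starts(problem: FitProblem, n: int, seed: int) -> np.ndarray:
    """``n`` starting points, log10-uniform within each parameter's range.

    Returns an (n, 15) array of log10 values in canonical parameter order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo = np.log10([problem.ranges[k][0] for k in OPTIMIZED_PARAMETERS])
    hi = np.log10([problem.ranges[k][1] for k in OPTIMIZED_PARAMETERS])
    return lo + (hi - lo) * rng.random((n, len(OPTIMIZED_PARAMETERS)))


def _split_observations(
    problem: FitProblem,
) -> list[tuple[str, Regimen, np.ndarray, dict[str, np.ndarray]]]:
    """Pre-index uncensored observations per group for fast residual evaluation."""
    out = []
    obs = problem.observations
    obs = obs.loc[~obs["censored"].astype(bool)]
    for gid, gdf in obs.groupby("group", sort=False):
        regimen = problem.regimens[gid]
        per_analyte = {}
        for analyte, adf in gdf.groupby("analyte", sort=False):
            adf = adf.sort_values("time_days")
            per_analyte[analyte] = (
                adf["time_days"].to_numpy(),
                adf["conc_nM"].to_numpy(),
            )
        out.append((gid, regimen, per_analyte))
    return out


class _Objective:
    """log10-residual vector as a function of the log10 parameter vector.

    All dose groups share one parameter set, so they are integrated as a
    single stacked (block-diagonal) system: one stiff solve per residual
    evaluation instead of one per group.
    """

    _ANALYTE_STATE = {"drug": 2, "soluble-target": 4}

    def __init__(self, problem: FitProblem):
        self.problem = problem
        self.groups = _split_observations(problem)
        n_groups = len(self.groups)

        # shared output grid and segmentation across all groups' dose events
        obs_times: set[float] = set()
        bounds: set[float] = {0.0}
        horizon = 0.0
        for _, regimen, per_analyte in self.groups:
            for times, _ in per_analyte.values():
                obs_times.update(float(t) for t in times)
            bounds.update(e.time for e in regimen.events)
            horizon = max(horizon, regimen.horizon)
        bounds.add(horizon)
        self._bounds = sorted(bounds)
        self._grid = np.array(sorted(obs_times | bounds))

        # per-group dose bookkeeping: (segment-start time -> events)
        self._events: list[dict[float, list]] = []
        for _, regimen, _ in self.groups:
            ev: dict[float, list] = {}
            for e in regimen.events:
                ev.setdefault(e.time, []).append(e)
            self._events.append(ev)

        # residual extraction plan: (group index, state index, grid rows, log10 obs)
        self._plan = []
        n_res = 0
        for g, (_, _, per_analyte) in enumerate(self.groups):
            for analyte, (times, conc) in per_analyte.items():
                rows = np.searchsorted(self._grid, times)
                self._plan.append(
                    (g, self._ANALYTE_STATE[analyte], rows, np.log10(conc))
                )
                n_res += len(times)
        self.n_residuals = n_res
        self._n_groups = n_groups

    def _solve(self, params: ModelParameters) -> np.ndarray | None:
        """Stacked trajectories on the shared grid, or None on failure."""
        pv = pack_params(params)
        y = np.empty(8 * self._n_groups)
        for g in range(self._n_groups):
            y[8 * g : 8 * (g + 1)] = initial_state(params)
        out = np.empty((len(self._grid), 8 * self._n_groups))
        grid = self._grid
        for a, b in zip(self._bounds[:-1], self._bounds[1:]):
            for g, ev in enumerate(self._events):
                for e in ev.get(a, []):
                    y[8 * g : 8 * (g + 1)] = apply_dose(
                        y[8 * g : 8 * (g + 1)], e, params
                    )
            mask = (grid >= a) & (grid <= b)
            t_seg = np.unique(np.concatenate(([a], grid[mask], [b])))
            sol, info = odeint(
                rhs_stacked,
                y,
                t_seg,
                args=(pv,),
                Dfun=rhs_stacked_jacobian,
                rtol=self.problem.sim_rtol,
                atol=self.problem.sim_atol,
                mxstep=5000,  # hopeless parameter regions must fail fast
                full_output=True,
            )
            if info["message"] != "Integration successful.":
                return None
            row_of = {t: i for i, t in enumerate(t_seg)}
            sel = grid[mask & (grid < b)] if b != self._bounds[-1] else grid[mask]
            for t in sel:
                out[np.searchsorted(grid, t)] = sol[row_of[t]]
            y = sol[-1]
        return out

    def residuals(self, x_log10: np.ndarray) -> np.ndarray:
        try:
            params = self.problem.parameters_from_vector(x_log10)
        except (ValueError, OverflowError):
            return np.full(self.n_residuals, np.inf)
        traj = self._solve(params)
        if traj is None:
            return np.full(self.n_residuals, np.inf)
        chunks = []
        for g, state_idx, rows, log_obs in self._plan:
            pred = np.maximum(traj[rows, 8 * g + state_idx], PRED_FLOOR_NM)
            chunks.append(log_obs - np.log10(pred))
        return np.concatenate(chunks)

    def ssr(self, x_log10: np.ndarray) -> float:
        r = self.residuals(x_log10)
        if not np.all(np.isfinite(r)):
            return np.inf
        return float(r @ r)


def _gauss_newton(
    objective: _Objective,
    x0: np.ndarray,
    max_iter: int,
    fd_step: float = 1e-4,
    ftol: float = 1e-9,
    xtol: float = 1e-8,
    max_halvings: int = 10,
    stall_iters: int = 3,
    stall_ftol: float = 1e-4,
    jac_refresh: int = 2,
) -> tuple[np.ndarray, float, int]:
    """Damped Gauss-Newton on log10 parameters; SSR is non-increasing.

    The step solves the linearised least-squares problem with a
    rank-revealing ``lstsq`` (flat directions get zero step) and is halved
    until the SSR decreases; failure to decrease with a fresh Jacobian
    terminates the start, as does a run of ``stall_iters`` iterations with
    relative improvement below ``stall_ftol``.

    The finite-difference Jacobian is recomputed every ``jac_refresh``
    iterations and kept current in between by Broyden rank-1 secant
    updates; a line-search failure on a secant Jacobian forces a fresh one
    before giving up.
    """
    x = x0.copy()
    r = objective.residuals(x)
    if not np.all(np.isfinite(r)):
        return x, np.inf, 0
    f = float(r @ r)
    n = len(x)
    stalled = 0
    J: np.ndarray | None = None
    fresh = False

    def fd_jacobian() -> np.ndarray:
        Jn = np.empty((len(r), n))
        for j in range(n):
            xp = x.copy()
            xp[j] += fd_step
            rp = objective.residuals(xp)
            if not np.all(np.isfinite(rp)):
                rp = r  # flat in a direction that breaks the simulation
            Jn[:, j] = (rp - r) / fd_step
        return Jn

    for it in range(1, max_iter + 1):
        if J is None or (it - 1) % jac_refresh == 0:
            J = fd_jacobian()
            fresh = True
        step, *_ = np.linalg.lstsq(J, -r, rcond=1e-10)
        if not np.all(np.isfinite(step)) or np.linalg.norm(step) == 0:
            return x, f, it
        # cap outrageous steps (log10 space: 4 decades at once is plenty)
        norm = np.linalg.norm(step)
        if norm > 4.0:
            step *= 4.0 / norm
        improved = False
        alpha = 1.0
        for _ in range(max_halvings):
            x_new = x + alpha * step
            r_new = objective.residuals(x_new)
            f_new = float(r_new @ r_new) if np.all(np.isfinite(r_new)) else np.inf
            if f_new < f:
                improved = True
                break
            alpha *= 0.5
        if not improved:
            if not fresh:
                J = None  # retry this iterate with a fresh Jacobian
                continue
            return x, f, it
        s = alpha * step
        if np.all(np.isfinite(r_new)):
            J = J + np.outer(r_new - r - J @ s, s) / (s @ s)
            fresh = False
        dx = np.max(np.abs(s))
        df = f - f_new
        x, r, f = x_new, r_new, f_new
        if df < ftol * max(f, 1.0) and dx < xtol:
            return x, f, it
        stalled = stalled + 1 if df < stall_ftol * max(f, 1.0) else 0
        if stalled >= stall_iters:
            return x, f, it
    return x, f, max_iter


@dataclass(frozen=True)
class FitResult:
    """All terminal parameter sets, the accepted cluster, and diagnostics."""

    problem: FitProblem
    log10_sets: np.ndarray        # (n_terminal, 15), sorted by SSR
    ssrs: np.ndarray              # aligned, ascending
    iterations: np.ndarray        # Gauss-Newton iterations per start
    accepted: np.ndarray          # boolean mask over the sorted sets
    threshold: float              # max accepted SSR
    n_failed: int                 # starts whose refinement never produced a finite SSR

    @property
    def rank1(self) -> ModelParameters:
        """The minimum-SSR accepted parameter set."""
        idx = int(np.flatnonzero(self.accepted)[0])
        return self.problem.parameters_from_vector(self.log10_sets[idx])

    @property
    def rank1_ssr(self) -> float:
        return float(self.ssrs[np.flatnonzero(self.accepted)[0]])

    def parameter_sets(self, accepted_only: bool = True) -> np.ndarray:
        """Linear-scale parameter sets, shape (n, 15)."""
        sets = self.log10_sets[self.accepted] if accepted_only else self.log10_sets
        return 10.0**sets

    def summary(self) -> pd.DataFrame:
        """Per-parameter rank-1 / median / min / max over the accepted sets,
        plus the identifiability label."""
        acc = self.parameter_sets(accepted_only=True)
        rank1 = acc[0]
        rows = []
        for j, name in enumerate(OPTIMIZED_PARAMETERS):
            _, label = profile_identifiability(self, name)
            rows.append(
                {
                    "parameter": name,
                    "rank1": rank1[j],
                    "median": float(np.median(acc[:, j])),
                    "min": float(acc[:, j].min()),
                    "max": float(acc[:, j].max()),
                    "identifiability": label,
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        # log10 values rounded to 6 decimals (far below fit resolution)
        # keep the all-sets artifact compact
        return {
            "parameters": list(OPTIMIZED_PARAMETERS),
            "fixed": self.problem.fixed,
            "log10_sets": np.round(self.log10_sets, 6).tolist(),
            "ssrs": [float(f"{v:.6g}") for v in self.ssrs],
            "accepted": self.accepted.astype(bool).tolist(),
            "threshold": self.threshold,
            "seed": self.problem.seed,
            "n_starts": self.problem.n_starts,
            "n_iterations": self.problem.n_iterations,
            "n_failed": self.n_failed,
        }


def fit_multistart(problem: FitProblem, verbose: bool = False) -> FitResult:
    """Refine every sampled start and assemble the accepted cluster.

    Individual start failures (integration breakdown everywhere) are
    recorded and excluded; they never abort the fit.
    """
    if problem.observations["group"].nunique() < 2:
        raise ValueError("fitting needs observations from at least 2 dose groups")
    objective = _Objective(problem)
    starts = sample_starts(problem, problem.n_starts, problem.seed)
    terminal, ssrs, iters = [], [], []
    n_failed = 0
    for i, x0 in enumerate(starts):
        x, f, it = _gauss_newton(objective, x0, problem.n_iterations)
        if np.isfinite(f):
            terminal.append(x)
            ssrs.append(f)
            iters.append(it)
        else:
            n_failed += 1
        if verbose and (i + 1) % 20 == 0:
            print(f"  start {i + 1}/{len(starts)}: best SSR {min(ssrs):.3g}")
    if not terminal:
        raise RuntimeError("every start failed; check the problem setup")
    order = np.argsort(ssrs)
    log10_sets = np.asarray(terminal)[order]
    ssrs_sorted = np.asarray(ssrs)[order]
    threshold, accepted = accept_sets(ssrs_sorted)
    return FitResult(
        problem=problem,
        log10_sets=log10_sets,
        ssrs=ssrs_sorted,
        iterations=np.asarray(iters)[order],
        accepted=accepted,
        threshold=threshold,
        n_failed=n_failed,
    )


def _grubbs_max_outlier(values: np.ndarray, alpha: float) -> int | None:
    """Index of the maximum if Grubbs' one-sided test rejects it, else None."""
    n = len(values)
    if n < 3:
        return None
    mean, sd = values.mean(), values.std(ddof=1)
    if sd == 0:
        return None
    idx = int(np.argmax(values))
    g = (values[idx] - mean) / sd
    t = stats.t.ppf(1 - alpha / n, n - 2)
    g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
    return idx if g > g_crit else None


def accept_sets(
    sorted_ssrs: np.ndarray, alpha: float = 0.05
) -> tuple[float, np.ndarray]:
    """Elbow cut on the sorted SSR curve followed by Grubbs outlier removal.

    The elbow is the interior index maximizing the second difference of the
    min-max normalized sorted log10-SSR curve (SSR spans orders of
    magnitude across terminal sets, so the sudden-increase structure lives
    on the log scale; values are floored three decades below the best SSR
    so solver-precision jitter among near-perfect fits cannot masquerade as
    an elbow).  Sets up to and including the elbow are kept, then
    one-at-a-time Grubbs at ``alpha`` prunes high outliers from the kept
    SSRs.  Returns (threshold, accepted mask).
    """
    s = np.asarray(sorted_ssrs, dtype=float)
    n = len(s)
    if np.any(np.diff(s) < 0):
        raise ValueError("SSRs must be sorted ascending")
    if n < 10:
        warnings.warn("fewer than 10 terminal sets; acceptance keeps all")
        mask = np.ones(n, dtype=bool)
        return float(s[mask].max()), mask

    mask = np.ones(n, dtype=bool)
    floor = max(s[0], 1e-12) * 1e-3
    y = np.log10(np.maximum(s, floor))
    span = y[-1] - y[0]
    if span > 0:
        y = (y - y[0]) / span
        # second difference on the normalized curve (x spacing is uniform)
        d2 = y[2:] - 2 * y[1:-1] + y[:-2]
        elbow = int(np.argmax(d2)) + 1
        if d2.max() > 1e-12:
            mask[:] = False
            mask[: elbow + 1] = True

    kept = np.flatnonzero(mask)
    if len(kept) < 3:
        warnings.warn("fewer than 3 sets below the elbow; keeping all sets")
        mask = np.ones(n, dtype=bool)
        return float(s.max()), mask

    while True:
        idx = _grubbs_max_outlier(s[mask], alpha)
        if idx is None:
            break
        mask[np.flatnonzero(mask)[idx]] = False
        if mask.sum() < 3:
            break
    return float(s[mask].max()), mask


def profile_identifiability(
    fit: FitResult,
    param_name: str,
    n_bins: int = 20,
    delta_ssr_crit: float = 3.84,
) -> tuple[pd.DataFrame, str]:
    """Approximate profile likelihood for one parameter from the terminal cloud.

    The log10 values of the parameter across *all* terminal sets are binned;
    the profile is the minimum SSR per bin.  A parameter is labelled
    ``non-identifiable`` when the profile is flat (range below
    ``delta_ssr_crit``, a chi-square(1, 0.95) heuristic on the SSR scale)
    over a span of at least two decades, or when it shows two or more
    separated local minima below the acceptance threshold; otherwise
    ``identifiable``.
    """
    if param_name not in OPTIMIZED_PARAMETERS:
        raise KeyError(f"unknown optimized parameter {param_name!r}")
    j = OPTIMIZED_PARAMETERS.index(param_name)
    x = fit.log10_sets[:, j]
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:
        profile = pd.DataFrame(
            {"log10_value": [lo], "min_ssr": [float(fit.ssrs.min())]}
        )
        return profile, "identifiable"
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    centers, mins = [], []
    for b in range(n_bins):
        sel = which == b
        if not sel.any():
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        mins.append(float(fit.ssrs[sel].min()))
    profile = pd.DataFrame({"log10_value": centers, "min_ssr": mins})

    mins_arr = np.asarray(mins)
    span = centers[-1] - centers[0]
    flat = span >= 2.0 and (mins_arr.max() - mins_arr.min()) < delta_ssr_crit

    # separated local minima below the acceptance threshold
    n_minima = 0
    last_min_pos = -10
    for i in range(len(mins_arr)):
        left = mins_arr[i - 1] if i > 0 else np.inf
        right = mins_arr[i + 1] if i < len(mins_arr) - 1 else np.inf
        if mins_arr[i] <= fit.threshold and mins_arr[i] <= left and mins_arr[i] <= right:
            if i - last_min_pos > 1:
                n_minima += 1
            last_min_pos = i

    label = "non-identifiable" if (flat or n_minima >= 2) else "identifiable"
    return profile, label
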