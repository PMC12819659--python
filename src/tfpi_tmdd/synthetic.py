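"""Study-like synthetic observation tables generated from known parameters.

The real animal concentration data behind the model are not publicly
deposited, so every pipeline stage is exercised against synthetic tables
simulated from a known ("truth") parameter set under the published study
designs: monkey single doses (i.v./s.c. 17.2, 34.4, 68.8 nmol/kg at 3.5 kg)
and rabbit single doses (i.v. 2.75/17.2/34.4, s.c. 17.2/34.4/68.8/137.6
nmol/kg at 2.5 kg) with the printed rabbit sampling schedules.

The monkey sampling schedule was never printed; the surrogate used here is
the rabbit schedule augmented with the intensive early sampling times
(5, 15, 30, 60 min) and extended to 42 days so the soluble-target rebound
window is observed.

Noise is multiplicative log-normal per observation (median-preserving,
``exp(sigma * z)`` with ``sigma**2 = ln(1 + CV**2)``); values below the
lower limit of quantification are flagged censored and carry no
concentration, mimicking below-calibration ELISA readouts being treated as
missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import OBSERVATION_COLUMNS, validate_observations
from .model import DoseEvent, Regimen, mg_per_kg_to_nmol
from .parameters import DRUG_MW_KDA, ModelParameters
from .simulate import multiple_dose_regimen, simulate

__all__ = [
    "StudyDesign",
    "DoseGroup",
    "generate",
    "group_means",
    "monkey_design",
    "rabbit_design",
    "human_regimens",
    "MONKEY_BW_KG",
    "RABBIT_BW_KG",
    "HUMAN_BW_KG",
]

MONKEY_BW_KG = 3.5
RABBIT_BW_KG = 2.5
HUMAN_BW_KG = 70.0

#: printed rabbit sampling schedules (days post-dose)
RABBIT_IV_SCHEDULE = (
    0.00347, 0.0104, 0.0208, 0.0417, 0.167, 0.333, 0.5,
    1.0, 2.0, 3.0, 4.0, 5.0, 7.0,
)
RABBIT_SC_SCHEDULE = (
    0.0104, 0.0208, 0.0417, 0.167, 0.5, 1.0, 2.0, 3.0, 5.0, 14.0, 21.0,
)

# Monkey surrogate: rabbit schedule + 5/15/30/60 min early points, out to 42 d.
MONKEY_IV_SCHEDULE = RABBIT_IV_SCHEDULE + (10.0, 14.0, 21.0, 28.0, 35.0, 42.0)
MONKEY_SC_SCHEDULE = tuple(
    sorted(set(RABBIT_SC_SCHEDULE) | {0.00347} | {10.0, 28.0, 35.0, 42.0})
)


@dataclass(frozen=True)
class DoseGroup:
    route: str                 # 'iv' or 'sc'
    dose_nmol_per_kg: float
    n_animals: int = 1

    def __post_init__(self) -> None:
        if self.route not in ("iv", "sc"):
            raise ValueError(f"route must be 'iv' or 'sc', got {self.route!r}")
        if self.dose_nmol_per_kg <= 0 or self.n_animals < 1:
            raise ValueError("dose must be > 0 and n_animals >= 1")


@dataclass(frozen=True)
class StudyDesign:
    """Species, dose groups, per-route sampling schedule, noise and censoring."""

    species: str
    body_weight: float
    groups: tuple[DoseGroup, ...]
    schedule: dict[str, tuple[float, ...]]       # route -> sampling days
    noise_cv: float = 0.15
    lloq_nM: dict[str, float] = field(
        default_factory=lambda: {"drug": 0.0, "soluble-target": 0.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for route, times in self.schedule.items():
            t = tuple(float(x) for x in times)
            if list(t) != sorted(t) or len(set(t)) != len(t):
                raise ValueError(f"{route} schedule must be strictly increasing")

    def regimen(self, group: DoseGroup) -> Regimen:
        times = self.schedule[group.route]
        amount = group.dose_nmol_per_kg * self.body_weight
        return Regimen(
            body_weight=self.body_weight,
            events=(DoseEvent(0.0, group.route, amount),),
            horizon=max(times),
            observation_times=times,
        )


def monkey_design(
    noise_cv: float = 0.15,
    lloq_nM: dict[str, float] | None = None,
    n_animals: int = 3,
    seed: int = 0,
) -> StudyDesign:
    """The monkey single-dose study: i.v. and s.c. at 17.2/34.4/68.8 nmol/kg."""
    doses = (17.2, 34.4, 68.8)
    groups = tuple(
        DoseGroup(route, d, n_animals) for route in ("iv", "sc") for d in doses
    )
    return StudyDesign(
        species="monkey",
        body_weight=MONKEY_BW_KG,
        groups=groups,
        schedule={"iv": MONKEY_IV_SCHEDULE, "sc": MONKEY_SC_SCHEDULE},
        noise_cv=noise_cv,
        lloq_nM=lloq_nM or {"drug": 0.0, "soluble-target": 0.0},
        seed=seed,
    )


def rabbit_design(
    noise_cv: float = 0.15,
    lloq_nM: dict[str, float] | None = None,
    n_animals: int = 3,
    seed: int = 0,
) -> StudyDesign:
    """The rabbit single-dose study with its printed sampling schedules."""
    groups = tuple(
        [DoseGroup("iv", d, n_animals) for d in (2.75, 17.2, 34.4)]
        + [DoseGroup("sc", d, n_animals) for d in (17.2, 34.4, 68.8, 137.6)]
    )
    return StudyDesign(
        species="rabbit",
        body_weight=RABBIT_BW_KG,
        groups=groups,
        schedule={"iv": RABBIT_IV_SCHEDULE, "sc": RABBIT_SC_SCHEDULE},
        noise_cv=noise_cv,
        lloq_nM=lloq_nM or {"drug": 0.0, "soluble-target": 0.0},
        seed=seed,
    )


def human_regimens(
    n_doses: int = 1, horizon: float | None = None
) -> dict[str, Regimen]:
    """Phase-I human regimens: s.c. 0.5/1.7/3.3 mg/kg and i.v. 3.3 mg/kg.

    ``n_doses`` > 1 gives the weekly (Q7d) repeated-dose versions.  The
    default single-dose horizon is 30 days (the exposure window used for
    sensitivity analyses).
    """
    combos = [("sc", 0.5), ("sc", 1.7), ("sc", 3.3), ("iv", 3.3)]
    if horizon is None:
        horizon = 30.0 if n_doses == 1 else 7.0 * n_doses
    out = {}
    for route, mgkg in combos:
        amount = mg_per_kg_to_nmol(mgkg, HUMAN_BW_KG, DRUG_MW_KDA)
        out[f"{route}_{mgkg}mgkg"] = multiple_dose_regimen(
            amount, route, 7.0, n_doses, HUMAN_BW_KG, horizon=horizon
        )
    return out


def generate(design: StudyDesign, truth: ModelParameters) -> pd.DataFrame:
    """Simulate every dose group from ``truth`` and emit a noisy, censored table.

    One record per animal, sampling time and analyte.  Reproducible under
    ``design.seed``.  Use :func:`group_means` to obtain the per-group mean
    table that mean-data fitting consumes.
    """
    rng = np.random.default_rng(design.seed)
    sigma = float(np.sqrt(np.log1p(design.noise_cv**2)))
    rows = []
    for group in design.groups:
        regimen = design.regimen(group)
        res = simulate(truth, regimen, grid_density=0.0)
        times = np.asarray(design.schedule[group.route])
        gid = f"{design.species}_{group.route}_{group.dose_nmol_per_kg:g}"
        for analyte in ("drug", "soluble-target"):
            clean = res.at_times(times, analyte)
            lloq = design.lloq_nM.get(analyte, 0.0)
            for animal in range(group.n_animals):
                if design.noise_cv > 0:
                    noisy = clean * np.exp(sigma * rng.standard_normal(len(times)))
                else:
                    noisy = clean.copy()
                for t, c in zip(times, noisy):
                    censored = bool(c < lloq)
                    rows.append(
                        {
                            "group": gid,
                            "species": design.species,
                            "route": group.route,
                            "dose_nmol_per_kg": group.dose_nmol_per_kg,
                            "animal": animal,
                            "time_days": float(t),
                            "analyte": analyte,
                            "conc_nM": float("nan") if censored else float(c),
                            "censored": censored,
                        }
                    )
    table = pd.DataFrame(rows)
    validate_observations(table)
    return table


def group_means(table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean over animals per (group, time, analyte).

    Censored records are excluded from the mean; a point where every animal
    is censored stays censored in the mean table.
    """
    validate_observations(table)
    keys = ["group", "species", "route", "dose_nmol_per_kg", "time_days", "analyte"]
    agg = (
        table.groupby(keys, sort=False)
        .agg(conc_nM=("conc_nM", "mean"), censored=("censored", "all"))
        .reset_index()
    )
    agg.loc[agg["censored"], "conc_nM"] = float("nan")
    return agg[list(OBSERVATION_COLUMNS)]
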