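"""State, derivatives, dosing and unit conversion for the two-target TMDD model.

The antibody distributes over a depot/transit absorption chain (amounts, nmol)
and central/peripheral compartments (concentrations, nM).  In the central
compartment it binds reversibly to two target pools — circulating soluble
TFPI-alpha and an equivalent central-compartment representation of
membrane-bound TFPI — forming two complexes that are cleared by first-order
internalization.  Targets turn over by zero-order synthesis and first-order
degradation; binding, complexes and targets are confined to the central
compartment, and only free drug exchanges with the periphery.

State ordering used throughout:

    0 A_depot   nmol   s.c. injection depot
    1 A_transit nmol   transit (lymphatic-surrogate) compartment
    2 C2        nM     central free drug
    3 C3        nM     peripheral free drug
    4 Cs        nM     free soluble target
    5 Cm        nM     free membrane target (central-equivalent)
    6 C2_CS     nM     drug/soluble-target complex
    7 C2_CM     nM     drug/membrane-target complex
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import ModelParameters

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


__all__ = [
    "N_STATES",
    "STATE_NAMES",
    "DoseEvent",
    "Regimen",
    "pack_params",
    "rhs",
    "rhs_jacobian",
    "rhs_stacked",
    "rhs_stacked_jacobian",
    "derivatives",
    "initial_state",
    "apply_dose",
    "mg_per_kg_to_nmol",
]

N_STATES = 8
STATE_NAMES = (
    "A_depot",
    "A_transit",
    "C2_MG1113",
    "C3_MG1113",
    "Cs",
    "Cm",
    "C2_CS",
    "C2_CM",
)

# indices into the packed kernel parameter vector
_IDX = dict(
    k01=0, k02=1, k12=2, k_loss=3, k_el=4, CL_D=5, V2=6, V3=7,
    k_on=8, k_off=9, k_deg_s=10, k_deg_m=11, k_el_CS=12, k_el_CM=13,
    k_syn_s=14, k_syn_m=15,
)


def pack_params(p: ModelParameters) -> np.ndarray:
    """Flatten a parameter set into the float vector the ODE kernel consumes."""
    v = np.empty(16)
    v[0] = p.k01
    v[1] = p.k02
    v[2] = p.k12
    v[3] = p.k_loss
    v[4] = p.k_el_MG1113
    v[5] = p.CL_D
    v[6] = p.V2
    v[7] = p.V3
    v[8] = p.k_on
    v[9] = p.k_off
    v[10] = p.k_deg_s
    v[11] = p.k_deg_m
    v[12] = p.k_el_CS
    v[13] = p.k_el_CM
    v[14] = p.k_syn_s
    v[15] = p.k_syn_m
    return v


@njit(cache=True)
def rhs(y, t, pv):  # noqa: ARG001 - autonomous system, t required by LSODA
    k01 = pv[0]; k02 = pv[1]; k12 = pv[2]; k_loss = pv[3]
    k_el = pv[4]; CL_D = pv[5]; V2 = pv[6]; V3 = pv[7]
    k_on = pv[8]; k_off = pv[9]; k_deg_s = pv[10]; k_deg_m = pv[11]
    k_el_CS = pv[12]; k_el_CM = pv[13]; k_syn_s = pv[14]; k_syn_m = pv[15]

    A, T, C2, C3, Cs, Cm, CCS, CCM = y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7]

    dy = np.empty(8)
    dy[0] = -(k01 + k02 + k_loss) * A
    dy[1] = k01 * A - k12 * T
    dy[2] = (
        (k02 * A + k12 * T) / V2
        - k_el * C2
        - (CL_D / V2) * (C2 - C3)
        - k_on * C2 * (Cs + Cm)
        + k_off * (CCS + CCM)
    )
    dy[3] = (CL_D / V3) * (C2 - C3)
    dy[4] = k_syn_s - k_deg_s * Cs - k_on * C2 * Cs + k_off * CCS
    dy[5] = k_syn_m - k_deg_m * Cm - k_on * C2 * Cm + k_off * CCM
    dy[6] = k_on * C2 * Cs - (k_off + k_el_CS) * CCS
    dy[7] = k_on * C2 * Cm - (k_off + k_el_CM) * CCM
    return dy


@njit(cache=True)
def rhs_jacobian(y, t, pv):  # noqa: ARG001
    """Analytic Jacobian of ``rhs``; keeps the stiff solver's steps large."""
    k01 = pv[0]; k02 = pv[1]; k12 = pv[2]; k_loss = pv[3]
    k_el = pv[4]; CL_D = pv[5]; V2 = pv[6]; V3 = pv[7]
    k_on = pv[8]; k_off = pv[9]; k_deg_s = pv[10]; k_deg_m = pv[11]
    k_el_CS = pv[12]; k_el_CM = pv[13]

    C2, Cs, Cm = y[2], y[4], y[5]

    J = np.zeros((8, 8))
    J[0, 0] = -(k01 + k02 + k_loss)
    J[1, 0] = k01
    J[1, 1] = -k12
    J[2, 0] = k02 / V2
    J[2, 1] = k12 / V2
    J[2, 2] = -k_el - CL_D / V2 - k_on * (Cs + Cm)
    J[2, 3] = CL_D / V2
    J[2, 4] = -k_on * C2
    J[2, 5] = -k_on * C2
    J[2, 6] = k_off
    J[2, 7] = k_off
    J[3, 2] = CL_D / V3
    J[3, 3] = -CL_D / V3
    J[4, 2] = -k_on * Cs
    J[4, 4] = -k_deg_s - k_on * C2
    J[4, 6] = k_off
    J[5, 2] = -k_on * Cm
    J[5, 5] = -k_deg_m - k_on * C2
    J[5, 7] = k_off
    J[6, 2] = k_on * Cs
    J[6, 4] = k_on * C2
    J[6, 6] = -(k_off + k_el_CS)
    J[7, 2] = k_on * Cm
    J[7, 5] = k_on * C2
    J[7, 7] = -(k_off + k_el_CM)
    return J


@njit(cache=True)
def rhs_stacked(y, t, pv):
    """RHS for several independent copies of the system sharing one
    parameter set (stacked dose groups); y has length 8 * n_groups."""
    n = y.shape[0] // 8
    dy = np.empty(8 * n)
    for g in range(n):
        dy[8 * g : 8 * (g + 1)] = rhs(y[8 * g : 8 * (g + 1)], t, pv)
    return dy


@njit(cache=True)
def rhs_stacked_jacobian(y, t, pv):
    n = y.shape[0] // 8
    J = np.zeros((8 * n, 8 * n))
    for g in range(n):
        J[8 * g : 8 * (g + 1), 8 * g : 8 * (g + 1)] = rhs_jacobian(
            y[8 * g : 8 * (g + 1)], t, pv
        )
    return J


def derivatives(state: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Time derivative (per day) of each state under the TMDD system."""
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATES,):
        raise ValueError(f"state must have shape ({N_STATES},), got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state passed to derivatives")
    return rhs(y, 0.0, pack_params(params))


def initial_state(params: ModelParameters) -> np.ndarray:
    """Pre-dose steady state: no drug, targets at their baselines.

    Because synthesis rates are defined as k_deg * baseline, this state is an
    exact fixed point of the drug-free system.
    """
    y0 = np.zeros(N_STATES)
    y0[4] = params.sTFPI_base
    y0[5] = params.mTFPI_base
    return y0


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: time (days), route ('iv' or 'sc'), amount (nmol)."""

    time: float
    route: str
    amount: float

    def __post_init__(self) -> None:
        if self.route not in ("iv", "sc"):
            raise ValueError(f"route must be 'iv' or 'sc', got {self.route!r}")
        if not self.amount > 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")


@dataclass(frozen=True)
class Regimen:
    """Dosing events plus body weight, horizon and optional sampling times."""

    body_weight: float
    events: tuple[DoseEvent, ...]
    horizon: float
    observation_times: tuple[float, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        times = [e.time for e in events]
        if times != sorted(times):
            raise ValueError("dose events must be sorted by time")
        if events and self.horizon < events[-1].time:
            raise ValueError("horizon must cover the last dose event")
        if self.observation_times is not None:
            obs = tuple(float(t) for t in self.observation_times)
            object.__setattr__(self, "observation_times", obs)


def apply_dose(
    state: np.ndarray, event: DoseEvent, params: ModelParameters
) -> np.ndarray:
    """Apply an instantaneous dose: i.v. into central (nmol/L = nM), s.c. into depot."""
    y = np.array(state, dtype=float)
    if event.route == "iv":
        y[2] += event.amount / params.V2
    elif event.route == "sc":
        y[0] += event.amount
    else:  # unreachable through DoseEvent, kept for raw-tuple callers
        raise ValueError(f"unknown route {event.route!r}")
    return y


def mg_per_kg_to_nmol(dose_mgkg: float, bw: float, mw_kda: float) -> float:
    """Convert a mg/kg dose to nmol for a given body weight and molecular weight.

    With bw = 1 this returns the per-kg molar dose (nmol/kg).
    """
    if mw_kda <= 0:
        raise ValueError("molecular weight must be > 0")
    if dose_mgkg < 0 or bw <= 0:
        raise ValueError("dose must be >= 0 and body weight > 0")
    return dose_mgkg * bw / mw_kda * 1000.0
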