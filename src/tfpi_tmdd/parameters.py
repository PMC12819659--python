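"""Model parameterization for the two-target anti-TFPI antibody TMDD model.

A single species' parameter set combines fixed quantities (body weight, the
equilibrium dissociation constant ``KD``) with the fifteen optimized
disposition, absorption, binding and target-turnover constants.  Derived
rates (``k_off``, the target synthesis rates) are always recomputed from the
stored fields so that the steady-state relationships

    k_off   = k_on * KD
    k_syn_s = k_deg_s * sTFPI_base
    k_syn_m = k_deg_m * mTFPI_base

can never drift out of sync with the primary parameters.

Units follow the conventions of small-molecule-free antibody PK modelling:
time in days, concentrations in nM, amounts in nmol, volumes in L, so the
association rate ``k_on`` carries 1/(nM*day).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

__all__ = [
    "ModelParameters",
    "monkey_rank1",
    "MONKEY_RANK1_PATH",
    "DRUG_MW_KDA",
    "STFPI_MW_KDA",
]

#: Molecular weights used for mg <-> nmol conversion (kDa = mg/umol / 1000).
DRUG_MW_KDA = 145.36
STFPI_MW_KDA = 35.0

# Fields that may legitimately be zero (direct depot->central absorption and
# depot loss are structurally near-zero for lymphatically absorbed antibodies).
_NONNEGATIVE_OK = {"k02", "k_loss"}


@dataclass(frozen=True)
class ModelParameters:
    """One species' full parameterization of the two-target TMDD model."""

    BW: float            # body weight, kg
    KD: float            # equilibrium dissociation constant, nM
    CL_D: float          # intercompartmental clearance, L/day
    V2: float            # central volume, L
    V3: float            # peripheral volume, L
    k01: float           # depot -> transit rate, 1/day
    k02: float           # depot -> central rate, 1/day
    k12: float           # transit -> central rate, 1/day
    k_loss: float        # depot elimination rate, 1/day
    k_el_MG1113: float   # central free-drug elimination rate, 1/day
    k_on: float          # association rate, 1/(nM*day)
    k_deg_s: float       # free soluble-target degradation rate, 1/day
    k_deg_m: float       # free membrane-target degradation rate, 1/day
    k_el_CS: float       # drug/soluble-target complex elimination, 1/day
    k_el_CM: float       # drug/membrane-target complex elimination, 1/day
    sTFPI_base: float    # baseline free soluble target, nM
    mTFPI_base: float    # baseline free membrane target, nM

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v == v and abs(v) != float("inf")):  # NaN / inf guard
                raise ValueError(f"{f.name} must be finite, got {v!r}")
            if f.name in _NONNEGATIVE_OK:
                if v < 0:
                    raise ValueError(f"{f.name} must be >= 0, got {v!r}")
            elif v <= 0:
                raise ValueError(f"{f.name} must be > 0, got {v!r}")

    # -- derived rates (never stored) -----------------------------------
    @property
    def k_off(self) -> float:
        """Dissociation rate, 1/day (k_on * KD)."""
        return self.k_on * self.KD

    @property
    def k_syn_s(self) -> float:
        """Zero-order soluble-target synthesis rate, nM/day."""
        return self.k_deg_s * self.sTFPI_base

    @property
    def k_syn_m(self) -> float:
        """Zero-order membrane-target synthesis rate, nM/day."""
        return self.k_deg_m * self.mTFPI_base

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        missing = known - set(mapping)
        if missing:
            raise KeyError(f"missing parameter name(s): {sorted(missing)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def with_updates(self, **kwargs: float) -> "ModelParameters":
        """Return a copy with some fields replaced (validation re-runs)."""
        return replace(self, **kwargs)


MONKEY_RANK1_PATH = Path(__file__).parent / "data" / "monkey_rank1.yaml"


def monkey_rank1() -> ModelParameters:
    """The packaged rank-1 cynomolgus-monkey parameter set.

    Rank 1 denotes the minimum-SSR member of the accepted multi-start
    solutions of the original monkey fit; it is the default input for
    allometric extrapolation to rabbit and human.
    """
    return ModelParameters.from_yaml(MONKEY_RANK1_PATH)
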