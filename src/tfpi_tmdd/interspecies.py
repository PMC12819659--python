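"""Allometric translation of a fitted monkey parameter set to other species.

Power-law scaling by body-weight ratio with the standard exponents for
antibody PK: 0.75 for clearance, 1.0 for volumes, and -0.25 for first-order
rate constants.  Binding parameters (KD, k_on) are conserved across species
because the target's binding domain is highly homologous.  The soluble-target
baseline comes from species-specific literature measurements; the
membrane-target baseline is transferred via the monkey's membrane-to-soluble
baseline ratio, since both pools derive from the same gene by alternative
splicing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ModelParameters

__all__ = [
    "SpeciesProfile",
    "RABBIT",
    "HUMAN",
    "allometric_scale",
    "set_mtfpi_baseline",
]

EXP_CLEARANCE = 0.75
EXP_RATE = -0.25
EXP_VOLUME = 1.0

#: fields scaled with the rate-constant exponent
RATE_FIELDS = (
    "k01",
    "k02",
    "k12",
    "k_deg_m",
    "k_deg_s",
    "k_el_CM",
    "k_el_CS",
    "k_el_MG1113",
    "k_loss",
)


@dataclass(frozen=True)
class SpeciesProfile:
    """Target species: name, representative body weight, and (for species
    other than the source) the literature soluble-target baseline in nM."""

    name: str
    body_weight: float
    sTFPI_base_literature: float | None = None

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")


RABBIT = SpeciesProfile("rabbit", 2.5, sTFPI_base_literature=1.114)
HUMAN = SpeciesProfile("human", 70.0, sTFPI_base_literature=2.3)


def set_mtfpi_baseline(
    sTFPI_base_target: float, monkey_params: ModelParameters
) -> float:
    """Membrane-target baseline via the monkey membrane/soluble ratio."""
    if sTFPI_base_target <= 0:
        raise ValueError("target soluble baseline must be > 0")
    if monkey_params.sTFPI_base <= 0:
        raise ValueError("monkey soluble baseline must be > 0")
    return sTFPI_base_target * monkey_params.mTFPI_base / monkey_params.sTFPI_base


def allometric_scale(
    params_monkey: ModelParameters, target: SpeciesProfile
) -> ModelParameters:
    """Scale a source parameter set to a target species by body weight.

    Baselines: if the profile carries a literature soluble baseline it is
    adopted and the membrane baseline is set by the source ratio; otherwise
    the source baselines are kept (the identity case, target BW = source BW,
    then returns the source set unchanged).
    """
    ratio = target.body_weight / params_monkey.BW
    updates: dict[str, float] = {
        "BW": target.body_weight,
        "CL_D": params_monkey.CL_D * ratio**EXP_CLEARANCE,
        "V2": params_monkey.V2 * ratio**EXP_VOLUME,
        "V3": params_monkey.V3 * ratio**EXP_VOLUME,
    }
    for name in RATE_FIELDS:
        updates[name] = getattr(params_monkey, name) * ratio**EXP_RATE
    # k02 / k_loss may be exactly zero; a zero stays zero under scaling

    if target.sTFPI_base_literature is not None:
        updates["sTFPI_base"] = target.sTFPI_base_literature
        updates["mTFPI_base"] = set_mtfpi_baseline(
            target.sTFPI_base_literature, params_monkey
        )
    elif target.body_weight != params_monkey.BW:
        raise ValueError(
            f"species profile {target.name!r} needs a literature soluble-target "
            "baseline to scale to a different body weight"
        )
    return params_monkey.with_updates(**updates)
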