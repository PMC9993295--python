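"""Allometric (power-law) scaling of adult drug doses to children.

Metabolic quantities such as drug clearance relate to body weight by a
power law, Y = alpha * BW^b, with b ~ 3/4 for clearance-type quantities.
Because the maintenance dose at steady state is proportional to clearance,
the paediatric dose can be extrapolated from the adult dose as

    dose_child = dose_adult * (BW_child / BW_ref)^0.75

anchored at a reference adult weight (70 kg by convention).  Inverting the
relation gives the body weight at which a child needs exactly a given
dose,

    BW = BW_ref * (dose_child / dose_adult)^(1/0.75)

which is what turns a discrete tablet formulary into weight-band
boundaries (see :mod:`allodose.bands`).

This module holds the closed-form scaling operations plus the formulary
model: the dispensable dose steps of a fixed-dose-combination product and
the policies for rounding a continuous scaled dose onto them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

from .errors import ConfigError, DomainError

__all__ = [
    "ScalingModel",
    "Formulary",
    "FormularyStep",
    "RoundingPolicy",
    "power_scale",
    "allometric_dose",
    "weight_for_dose",
    "round_to_formulary",
]

_ROUNDING_MODES = ("nearest", "ceil", "floor")
_TIE_RULES = ("lower", "higher")


@dataclass(frozen=True)
class ScalingModel:
    """Power-law scaling model Y(BW) = adult_value * (BW / ref)^exponent.

    Parameters
    ----------
    adult_value
        The adult quantity being scaled down: a dose in mg, or a
        clearance in L/h — the units carry through unchanged.
    reference_weight_kg
        Adult anchor weight; 70 kg by convention.
    exponent
        Allometric exponent in (0, 2]; 0.75 for clearance/dose, 1.0
        recovers linear per-kg scaling, 0.25 suits time-related
        quantities such as heart rate.
    """

    adult_value: float
    reference_weight_kg: float = 70.0
    exponent: float = 0.75

    def __post_init__(self) -> None:
        if not self.adult_value > 0:
            raise DomainError(f"adult_value must be > 0, got {self.adult_value}")
        if not self.reference_weight_kg > 0:
            raise DomainError(
                f"reference_weight_kg must be > 0, got {self.reference_weight_kg}"
            )
        if not 0 < self.exponent <= 2:
            raise DomainError(f"exponent must lie in (0, 2], got {self.exponent}")

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingModel":
        return cls(
            adult_value=float(d.get("adult_dose_mg", d.get("adult_value"))),
            reference_weight_kg=float(d.get("reference_weight_kg", 70.0)),
            exponent=float(d.get("exponent", 0.75)),
        )

    def to_dict(self) -> dict:
        return {
            "adult_dose_mg": self.adult_value,
            "reference_weight_kg": self.reference_weight_kg,
            "exponent": self.exponent,
        }


class FormularyStep(NamedTuple):
    """One dispensable dose: mg of the index drug plus a tablet-count label."""

    dose_mg: float
    label: str


@dataclass(frozen=True)
class Formulary:
    """Ordered dispensable dose steps of a fixed-dose-combination product.

    Doses are expressed in mg of the index drug (for the ABC/3TC 2:1 FDC,
    the abacavir component); the co-formulated component follows the
    fixed ratio and needs no separate bookkeeping.  ``unit_strength_mg``
    is the mg content of one dispersible tablet, so a step's tablet count
    is ``dose_mg / unit_strength_mg``.
    """

    drug_label: str
    unit_strength_mg: float
    steps: tuple[FormularyStep, ...]
    adult_dose_mg: float

    def __post_init__(self) -> None:
        if not self.steps:
            raise ConfigError("formulary must contain at least one step")
        steps = tuple(FormularyStep(float(d), str(lab)) for d, lab in self.steps)
        object.__setattr__(self, "steps", steps)
        doses = [s.dose_mg for s in steps]
        if any(d <= 0 for d in doses):
            raise ConfigError("formulary step doses must be positive")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ConfigError(
                "formulary steps must be strictly increasing with no duplicates"
            )
        if not self.unit_strength_mg > 0:
            raise ConfigError("unit_strength_mg must be positive")
        if self.adult_dose_mg != doses[-1]:
            raise ConfigError(
                f"adult_dose_mg ({self.adult_dose_mg}) must equal the largest "
                f"step ({doses[-1]})"
            )

    def tablets(self, dose_mg: float) -> float:
        """Tablet-equivalents of ``dose_mg`` in units of one dispersible tablet."""
        return dose_mg / self.unit_strength_mg

    @classmethod
    def from_dict(cls, d: dict) -> "Formulary":
        return cls(
            drug_label=str(d.get("drug_label", "")),
            unit_strength_mg=float(d["unit_strength_mg"]),
            steps=tuple(FormularyStep(float(s[0]), str(s[1])) for s in d["steps"]),
            adult_dose_mg=float(d["adult_dose_mg"]),
        )

    def to_dict(self) -> dict:
        return {
            "drug_label": self.drug_label,
            "unit_strength_mg": self.unit_strength_mg,
            "adult_dose_mg": self.adult_dose_mg,
            "steps": [[s.dose_mg, s.label] for s in self.steps],
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "Formulary":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class RoundingPolicy:
    """How a continuous scaled dose maps onto discrete formulary steps.

    ``nearest`` minimises the absolute deviation (exact midpoints broken
    by ``tie_rule``); ``ceil`` takes the smallest step at or above the
    dose (never underdosing, the convention used for band construction);
    ``floor`` is symmetric.  ``cap_at_adult`` clamps the result at the
    adult step.
    """

    mode: str = "nearest"
    tie_rule: str = "lower"
    cap_at_adult: bool = True

    def __post_init__(self) -> None:
        if self.mode not in _ROUNDING_MODES:
            raise ConfigError(f"mode must be one of {_ROUNDING_MODES}, got {self.mode!r}")
        if self.tie_rule not in _TIE_RULES:
            raise ConfigError(
                f"tie_rule must be one of {_TIE_RULES}, got {self.tie_rule!r}"
            )


def power_scale(model: ScalingModel, weight_kg: float) -> float:
    """Scale ``model.adult_value`` to a body weight: Y * (BW/ref)^b.

    Strictly increasing in weight; returns the adult value exactly at the
    reference weight.
    """
    if not weight_kg > 0:
        raise DomainError(f"weight_kg must be > 0, got {weight_kg}")
    if weight_kg == model.reference_weight_kg:
        return float(model.adult_value)
    return model.adult_value * (weight_kg / model.reference_weight_kg) ** model.exponent


def allometric_dose(
    model: ScalingModel, weight_kg: float, cap_at_adult: bool = True
) -> float:
    """Paediatric dose at ``weight_kg`` under the allometric model.

    With ``cap_at_adult`` (the default) children heavier than the
    reference weight receive the adult dose rather than an extrapolated
    super-adult dose.
    """
    dose = power_scale(model, weight_kg)
    if cap_at_adult:
        return min(dose, model.adult_value)
    return dose


def weight_for_dose(model: ScalingModel, paediatric_dose_mg: float) -> float:
    """Body weight at which the allometric dose equals ``paediatric_dose_mg``.

    Exact inverse of :func:`allometric_dose` on (0, adult_value]; used to
    convert formulary steps into weight-band boundaries.
    """
    if not 0 < paediatric_dose_mg <= model.adult_value:
        raise DomainError(
            f"dose must lie in (0, {model.adult_value}], got {paediatric_dose_mg}"
        )
    return model.reference_weight_kg * (
        paediatric_dose_mg / model.adult_value
    ) ** (1.0 / model.exponent)


def round_to_formulary(
    dose_mg: float,
    formulary: Formulary,
    policy: RoundingPolicy | None = None,
) -> FormularyStep:
    """Round a continuous dose onto a dispensable formulary step.

    Returns the chosen ``FormularyStep``; always a member of
    ``formulary.steps``.
    """
    if policy is None:
        policy = RoundingPolicy()
    if not dose_mg > 0:
        raise DomainError(f"dose_mg must be > 0, got {dose_mg}")
    steps = formulary.steps
    tol = 1e-9 * max(1.0, abs(dose_mg))

    if policy.mode == "nearest":
        best = min(abs(s.dose_mg - dose_mg) for s in steps)
        candidates = [s for s in steps if abs(s.dose_mg - dose_mg) <= best + tol]
        step = candidates[0] if policy.tie_rule == "lower" else candidates[-1]
    elif policy.mode == "ceil":
        step = next((s for s in steps if s.dose_mg >= dose_mg - tol), steps[-1])
    else:  # floor
        below = [s for s in steps if s.dose_mg <= dose_mg + tol]
        step = below[-1] if below else steps[0]

    if policy.cap_at_adult and step.dose_mg > formulary.adult_dose_mg:
        step = next(s for s in steps if s.dose_mg == formulary.adult_dose_mg)
    return step
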