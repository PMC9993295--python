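"""Weight-band dosing tables: construction, lookup and (de)serialisation.

A weight-band table maps ordered weight intervals to dispensable doses.
Two tables matter here: the WHO-style paediatric dosage chart (fixed
published bands) and the table derived from the allometric model by
inverting the dose equation at each formulary step.  Band edges are
expressed at a finite weight resolution (0.1 kg, matching how clinical
weights are recorded); a weight is quantised to that resolution before
lookup, which makes the tables total even at printed boundaries.

Construction follows the round-up ("ceil") convention: the upper edge of
band *k* is the exact body weight whose allometric dose equals step
*k*'s dose, so every child inside the band needs at most that step.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

from .errors import ConfigError, DomainError, TableValidationError
from .scaling import Formulary, ScalingModel, weight_for_dose

__all__ = [
    "WeightBand",
    "WeightBandTable",
    "LookupResult",
    "build_allometric_bands",
    "lookup_dose",
    "parse_table",
    "serialize_table",
    "format_band_table",
]


def _to_units(x: float, resolution: float) -> int:
    """Quantise a weight to integer resolution units, half away from zero."""
    return int(math.floor(x / resolution + 0.5))


def _from_units(u: int, resolution: float) -> float:
    return round(u * resolution, 10)


@dataclass(frozen=True)
class WeightBand:
    """One row of a dosing table: [lower_kg, upper_kg] -> dose_mg.

    Both edges are inclusive at the table's resolution; ``upper_kg`` is
    ``None`` for the open-topped (adult) band.
    """

    lower_kg: float
    upper_kg: float | None
    dose_mg: float
    label: str

    def __post_init__(self) -> None:
        if self.upper_kg is not None and not self.lower_kg < self.upper_kg:
            raise TableValidationError(
                f"band lower edge {self.lower_kg} must be below upper edge "
                f"{self.upper_kg}"
            )
        if not self.dose_mg > 0:
            raise TableValidationError(f"band dose must be positive, got {self.dose_mg}")

    def render(self) -> str:
        """Printable weight interval, e.g. '<=8.2', '8.3-14.1', '>=35.5'."""
        if self.lower_kg <= 0:
            return f"<={self.upper_kg:g}"
        if self.upper_kg is None:
            return f">={self.lower_kg:g}"
        return f"{self.lower_kg:g}-{self.upper_kg:g}"


@dataclass(frozen=True)
class WeightBandTable:
    """Ordered, gap-free, dose-monotone list of weight bands."""

    bands: tuple[WeightBand, ...]
    resolution_kg: float = 0.1
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        self._validate()

    def _validate(self) -> None:
        bands = self.bands
        if not bands:
            raise TableValidationError("table must contain at least one band")
        if self.resolution_kg < 0:
            raise TableValidationError("resolution_kg must be non-negative")
        bad: list[int] = []
        msgs: list[str] = []
        for i, b in enumerate(bands[:-1]):
            if b.upper_kg is None:
                bad.append(i)
                msgs.append(f"row {i}: only the last band may be unbounded")
        for i in range(1, len(bands)):
            prev, cur = bands[i - 1], bands[i]
            if prev.upper_kg is None:
                continue
            if self.resolution_kg > 0:
                gap = _to_units(cur.lower_kg, self.resolution_kg) - _to_units(
                    prev.upper_kg, self.resolution_kg
                )
                if gap != 1:
                    bad.append(i)
                    msgs.append(
                        f"row {i}: lower edge {cur.lower_kg} does not follow "
                        f"{prev.upper_kg} by one {self.resolution_kg} kg step"
                        if gap > 1
                        else f"row {i}: band overlaps or touches previous "
                        f"(lower {cur.lower_kg} vs upper {prev.upper_kg})"
                    )
            elif cur.lower_kg != prev.upper_kg:
                bad.append(i)
                msgs.append(
                    f"row {i}: bands must be contiguous at zero resolution"
                )
            if cur.dose_mg < prev.dose_mg:
                bad.append(i)
                msgs.append(
                    f"row {i}: dose {cur.dose_mg} decreases from {prev.dose_mg}"
                )
        if bad:
            raise TableValidationError("; ".join(msgs), rows=sorted(set(bad)))

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "resolution_kg": self.resolution_kg,
            "bands": [
                {
                    "lower_kg": b.lower_kg,
                    "upper_kg": b.upper_kg,
                    "dose_mg": b.dose_mg,
                    "label": b.label,
                }
                for b in self.bands
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WeightBandTable":
        try:
            bands = tuple(
                WeightBand(
                    lower_kg=float(row["lower_kg"]),
                    upper_kg=None if row["upper_kg"] is None else float(row["upper_kg"]),
                    dose_mg=float(row["dose_mg"]),
                    label=str(row["label"]),
                )
                for row in d["bands"]
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise TableValidationError(f"malformed band row: {exc}") from exc
        return cls(
            bands=bands,
            resolution_kg=float(d.get("resolution_kg", 0.1)),
            source=str(d.get("source", "")),
        )


class LookupResult(NamedTuple):
    """Dose resolved for one weight, with the band that supplied it.

    ``out_of_range`` flags weights below the table's minimum (mapped to
    the first band) or above a bounded last band (mapped to the last).
    """

    dose_mg: float
    label: str
    band: WeightBand
    out_of_range: bool


def build_allometric_bands(
    model: ScalingModel,
    formulary: Formulary,
    resolution_kg: float = 0.1,
) -> WeightBandTable:
    """Derive a weight-band table from the scaling model and a formulary.

    For each step below the adult dose, the band's upper edge is the
    exact allometric weight for that dose, rounded to the table
    resolution; the band receives that step (round-up convention: a
    child at or below the edge needs at most this dose).  Weights above
    the last finite edge map to the adult step.
    """
    if len(formulary.steps) < 2:
        raise ConfigError("band construction needs a formulary with >= 2 steps")
    if not resolution_kg > 0:
        raise ConfigError("resolution_kg must be positive")

    edge_units = [
        _to_units(weight_for_dose(model, s.dose_mg), resolution_kg)
        for s in formulary.steps[:-1]
    ]
    if any(b <= a for a, b in zip(edge_units, edge_units[1:])):
        raise ConfigError(
            "formulary steps too close: band edges collapse at this resolution"
        )

    bands = []
    lower = 0.0
    for step, u in zip(formulary.steps[:-1], edge_units):
        upper = _from_units(u, resolution_kg)
        bands.append(WeightBand(lower, upper, step.dose_mg, step.label))
        lower = _from_units(u + 1, resolution_kg)
    adult = formulary.steps[-1]
    bands.append(WeightBand(lower, None, adult.dose_mg, adult.label))
    return WeightBandTable(
        bands=tuple(bands), resolution_kg=resolution_kg, source="allometric"
    )


def lookup_dose(table: WeightBandTable, weight_kg: float) -> LookupResult:
    """Resolve the dose for a weight, quantised to the table resolution.

    Total by construction: weights below the first band map to it (and
    above a bounded last band map to it) with ``out_of_range`` set.
    """
    if not weight_kg > 0:
        raise DomainError(f"weight_kg must be > 0, got {weight_kg}")
    res = table.resolution_kg
    first, last = table.bands[0], table.bands[-1]

    if res > 0:
        w = _to_units(weight_kg, res)
        lo = lambda b: _to_units(b.lower_kg, res)  # noqa: E731
        hi = lambda b: math.inf if b.upper_kg is None else _to_units(b.upper_kg, res)  # noqa: E731
    else:
        w = weight_kg
        lo = lambda b: b.lower_kg  # noqa: E731
        hi = lambda b: math.inf if b.upper_kg is None else b.upper_kg  # noqa: E731

    if w < lo(first):
        return LookupResult(first.dose_mg, first.label, first, True)
    for band in table.bands:
        if lo(band) <= w <= hi(band):
            return LookupResult(band.dose_mg, band.label, band, False)
    return LookupResult(last.dose_mg, last.label, last, True)


def parse_table(source: str | Path | dict) -> WeightBandTable:
    """Read a weight-band table from a JSON file, JSON text, or dict.

    Validates every structural invariant; errors name the offending rows.
    """
    if isinstance(source, dict):
        return WeightBandTable.from_dict(source)
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise TableValidationError(f"not valid JSON: {exc}") from exc
    return WeightBandTable.from_dict(payload)


def serialize_table(table: WeightBandTable, path: str | Path | None = None) -> str:
    """Serialise a table to JSON (round-trips losslessly via parse_table)."""
    text = json.dumps(table.to_dict(), indent=1)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def format_band_table(
    table: WeightBandTable, unit_strength_mg: float | None = None
) -> str:
    """Render a table as aligned plain text, one band per row."""
    header = f"{'Body weight (kg)':<18} {'Dose (mg)':>10} {'Label':>8}"
    if unit_strength_mg:
        header += f" {'Tablets':>8}"
    lines = [f"# source: {table.source}" if table.source else "# weight-band table",
             header]
    for b in table.bands:
        line = f"{b.render():<18} {b.dose_mg:>10g} {b.label:>8}"
        if unit_strength_mg:
            line += f" {b.dose_mg / unit_strength_mg:>8g}"
        lines.append(line)
    return "\n".join(lines)
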