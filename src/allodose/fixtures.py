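"""Loaders for the data shipped with the package.

Everything the pipeline needs at its defaults — the 600 mg / 70 kg /
0.75 scaling model, the six-step ABC/3TC formulary, the WHO-style
dosage chart, the allometrically derived reference band table, and the
89-child cohort specification — is packaged as JSON so no network or
external file is ever required.
"""

from __future__ import annotations

import json
from importlib.resources import files

from .bands import WeightBandTable
from .cohort import CohortSpec
from .errors import ConfigError
from .scaling import Formulary, ScalingModel

__all__ = [
    "load_default_model",
    "load_default_formulary",
    "load_reference_band_table",
    "load_who_table",
    "load_who_chart",
    "load_default_cohort_spec",
]


def _read(name: str) -> dict:
    return json.loads(files("allodose.data").joinpath(name).read_text())


def load_default_model() -> ScalingModel:
    """Adult 600 mg, 70 kg reference, exponent 3/4."""
    return ScalingModel.from_dict(_read("model.json"))


def load_default_formulary() -> Formulary:
    """ABC/3TC dispersible-tablet steps {120, 180, 240, 300, 360, 600} mg."""
    return Formulary.from_dict(_read("formulary.json"))


def load_reference_band_table() -> WeightBandTable:
    """The packaged allometrically derived band table (six bands)."""
    return WeightBandTable.from_dict(_read("allometric_bands.json"))


def load_who_chart() -> dict:
    """The raw WHO-style dosage chart, all drugs."""
    return _read("who_dosage_chart.json")


def load_who_table(drug: str = "ABC/3TC") -> WeightBandTable:
    """One drug's column of the WHO-style chart as a band table."""
    chart = load_who_chart()
    try:
        entry = chart["drugs"][drug]
    except KeyError:
        raise ConfigError(
            f"no such drug in the packaged chart: {drug!r}; "
            f"available: {sorted(chart['drugs'])}"
        )
    return WeightBandTable.from_dict(
        {
            "source": f"{chart['source']} ({drug})",
            "resolution_kg": chart["resolution_kg"],
            "bands": entry["bands"],
        }
    )


def load_default_cohort_spec() -> CohortSpec:
    """The 11-stratum, n=89, ages 2-12 reference cohort specification."""
    return CohortSpec.from_dict(_read("cohort_spec.json"))
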