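"""Study constants: reference doses, molar masses, serving sizes.

All risk–benefit arithmetic in this package is driven by a single
:class:`StudyConfig` object so that every constant (molar masses, the EFSA
adequate Se intake, the two mercury reference doses, portion conventions)
is explicit, validated and overridable from a YAML/JSON file.

Two mercury reference doses deliberately coexist and are never
interchangeable:

* ``rfd_hg_jecfa`` (0.23 µg/kg-BW/day, FAO/WHO JECFA) — used for the
  hazard quotient;
* ``rfd_hg_epa`` (0.0001 mg/kg/day, US EPA) — used for consumption limits
  (CR_lim / CR_mm), together with ``rfd_se_epa`` for the selenium limits.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

#: Taiwan MOHW-style exchange serving sizes, g/serving. The fish (35 g) and
#: egg (60 g) values are anchored by the published portion-limit results;
#: the remainder are conventional exchange portions and only affect
#: serving-denominated outputs for those categories.
DEFAULT_SERVING_SIZES: dict[str, float] = {
    "Eggs": 60.0,
    "Fish": 35.0,
    "Marine fish": 35.0,
    "Freshwater fish": 35.0,
    "Shellfish": 35.0,
    "Meat and meat products": 35.0,
    "Milk and dairy products": 240.0,
    "Leafy vegetables": 100.0,
    "Non-leafy vegetables": 100.0,
    "Fruits": 100.0,
    "Grains and related products": 20.0,
    "Legumes and related products": 20.0,
    "Rice": 20.0,
}


class StudyConfig(BaseModel):
    """Constants of the dietary risk–benefit assessment.

    Defaults reproduce the preschool-cohort study conditions: AI_Se of 20
    µg/day, default body weight 13.87 kg, 30.44 days/month, US EPA fish
    meal size 65 g, hair-Hg exposure cutoff 1 µg/g.
    """

    model_config = ConfigDict(validate_assignment=True)

    molar_mass_se: float = Field(78.971, description="g/mol")
    molar_mass_hg: float = Field(200.59, description="g/mol")
    ai_se: float = Field(20.0, description="adequate Se intake, µg/day")
    rfd_hg_jecfa: float = Field(0.23, description="JECFA Hg RfD, µg/kg-BW/day (HQ)")
    rfd_hg_epa: float = Field(0.0001, description="US EPA Hg RfD, mg/kg/day (CR_lim)")
    rfd_se_epa: float = Field(0.005, description="US EPA Se RfD, mg/kg/day (CR_lim)")
    days_per_month: float = Field(30.44, description="T, days/month")
    epa_meal_size: float = Field(0.065, description="US EPA child fish meal, kg/meal")
    default_bw: float = Field(13.87, description="default child body weight, kg")
    hair_cutoff: float = Field(1.0, description="hair-Hg high/low cutoff, µg/g")
    serving_sizes: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_SERVING_SIZES),
        description="exchange serving size per category, g/serving",
    )
    mdl_se: float = Field(0.00003, description="Se method detection limit, mg/kg")
    mdl_hg: float = Field(0.000009, description="Hg method detection limit, mg/kg")
    nondetect_fraction: float = Field(
        0.5, description="fraction of the MDL substituted for nondetects"
    )

    @field_validator(
        "molar_mass_se",
        "molar_mass_hg",
        "ai_se",
        "rfd_hg_jecfa",
        "rfd_hg_epa",
        "rfd_se_epa",
        "epa_meal_size",
        "default_bw",
        "hair_cutoff",
        "mdl_se",
        "mdl_hg",
    )
    @classmethod
    def _strictly_positive(cls, v: float, info) -> float:
        if v <= 0:
            raise ValueError(f"{info.field_name} must be strictly positive, got {v}")
        return v

    @field_validator("days_per_month")
    @classmethod
    def _days_in_month_range(cls, v: float) -> float:
        if not 28.0 < v < 32.0:
            raise ValueError(f"days_per_month must lie in (28, 32), got {v}")
        return v

    @field_validator("serving_sizes")
    @classmethod
    def _servings_nonnegative(cls, v: dict[str, float]) -> dict[str, float]:
        for category, size in v.items():
            if size < 0:
                raise ValueError(
                    f"serving_sizes[{category!r}] must be nonnegative, got {size}"
                )
        return v

    @field_validator("nondetect_fraction")
    @classmethod
    def _fraction_in_unit_interval(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"nondetect_fraction must lie in [0, 1], got {v}")
        return v

    def serving_size(self, category: str) -> float:
        try:
            return self.serving_sizes[category]
        except KeyError:
            raise KeyError(f"no serving size configured for category {category!r}") from None


def load_config(path: str | Path | None = None) -> StudyConfig:
    """Load a :class:`StudyConfig` from a YAML or JSON file.

    Absent keys fall back to the study defaults; an empty file yields the
    default configuration. Serving-size overrides are merged on top of the
    defaults rather than replacing the whole map.
    """
    if path is None:
        return StudyConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text(encoding="utf-8"))
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file must contain a mapping, got {type(data).__name__}")
    overrides = data.pop("serving_sizes", None)
    config = StudyConfig(**data)
    if overrides:
        merged = dict(DEFAULT_SERVING_SIZES)
        merged.update(overrides)
        config.serving_sizes = merged
    return config
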