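"""Domain record types and the controlled food-category vocabulary."""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

#: The 11 food categories of the survey panel (closed vocabulary).
CATEGORIES: tuple[str, ...] = (
    "Eggs",
    "Fish",
    "Fruits",
    "Grains and related products",
    "Leafy vegetables",
    "Legumes and related products",
    "Meat and meat products",
    "Milk and dairy products",
    "Non-leafy vegetables",
    "Rice",
    "Shellfish",
)

#: Fish sub-groups, reported alongside the pooled fish category.
FISH_SUBCATEGORIES: tuple[str, ...] = ("Marine fish", "Freshwater fish")

_CANONICAL = {label.lower(): label for label in CATEGORIES + FISH_SUBCATEGORIES}


def canonical_category(label: str, allow_subcategory: bool = False) -> str:
    """Resolve a category label case-insensitively against the vocabulary.

    Raises ``ValueError`` listing the allowed labels for anything outside
    the closed vocabulary, so typos never fragment categories silently.
    """
    resolved = _CANONICAL.get(label.strip().lower())
    allowed = CATEGORIES + (FISH_SUBCATEGORIES if allow_subcategory else ())
    if resolved is None or resolved not in allowed:
        raise ValueError(
            f"unknown food category {label!r}; allowed labels: {', '.join(allowed)}"
        )
    return resolved


class FoodSample(BaseModel):
    """One analyzed food item (concentrations in mg/kg wet weight)."""

    model_config = ConfigDict(frozen=True)

    sample_id: str
    category: str
    subcategory: Optional[str] = None  # Marine fish / Freshwater fish
    feeding_habit: Optional[str] = None
    se_conc: float = Field(ge=0, description="Se, mg/kg ww")
    hg_conc: float = Field(ge=0, description="THg, mg/kg ww")
    se_nondetect: bool = False
    hg_nondetect: bool = False

    @field_validator("category")
    @classmethod
    def _known_category(cls, v: str) -> str:
        return canonical_category(v)

    @field_validator("subcategory")
    @classmethod
    def _known_subcategory(cls, v: Optional[str]) -> Optional[str]:
        if v is None or v == "":
            return None
        resolved = _CANONICAL.get(v.strip().lower())
        if resolved not in FISH_SUBCATEGORIES:
            raise ValueError(
                f"unknown subcategory {v!r}; allowed: {', '.join(FISH_SUBCATEGORIES)}"
            )
        return resolved

    @model_validator(mode="after")
    def _subcategory_only_for_fish(self) -> "FoodSample":
        if self.subcategory is not None and self.category != "Fish":
            raise ValueError("subcategory labels apply only to the Fish category")
        return self


class ChildRecord(BaseModel):
    """Demographic, anthropometric and hair-Hg fields for one child."""

    model_config = ConfigDict(frozen=True)

    child_id: str
    sex: Literal["male", "female"]
    age: float = Field(description="years")
    weight: float = Field(gt=0, description="kg")
    height: float = Field(gt=0, description="cm")
    hair_hg: float = Field(gt=0, description="µg/g")
    income_band: str
    parity: int = Field(ge=1)
    age_at_measurement: float = Field(description="years")

    @field_validator("age", "age_at_measurement")
    @classmethod
    def _preschool_age(cls, v: float, info) -> float:
        if not 0.0 <= v < 7.0:
            raise ValueError(f"{info.field_name} must lie in [0, 7) years, got {v}")
        return v


class IntakeRecord(BaseModel):
    """FFQ-derived daily intake of one food category by one child."""

    model_config = ConfigDict(frozen=True)

    child_id: str
    category: str
    intake_rate: float = Field(ge=0, description="g/day")

    @field_validator("category")
    @classmethod
    def _known_category(cls, v: str) -> str:
        return canonical_category(v, allow_subcategory=True)
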