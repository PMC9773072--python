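"""Nutrient vector arithmetic and the canonical nutrient/unit schema.

All intake bookkeeping in this package flows through :class:`NutrientVector`,
a fixed-length, unit-annotated vector of daily amounts: total energy plus the
19 nutrients assessed against the Chinese dietary reference intakes (DRIs)
for preschool children. Units are fixed per nutrient (column header names are
canonical); no unit inference is ever performed on input files.
"""

from __future__ import annotations

from typing import Iterator, Mapping

import numpy as np

#: Canonical nutrient order. Every composition table, supplement file and
#: intake vector uses exactly these column names.
NUTRIENTS: tuple[str, ...] = (
    "energy",
    "carbohydrate",
    "protein",
    "fat",
    "fiber",
    "dha",
    "calcium",
    "iron",
    "zinc",
    "iodine",
    "potassium",
    "vitamin_a",
    "vitamin_b1",
    "vitamin_b2",
    "vitamin_b3",
    "vitamin_b6",
    "vitamin_b9",
    "vitamin_b12",
    "vitamin_c",
    "vitamin_d",
)

#: Unit of each component, per day (or per 100 g for composition entries).
UNITS: dict[str, str] = {
    "energy": "kcal",
    "carbohydrate": "g",
    "protein": "g",
    "fat": "g",
    "fiber": "g",
    "dha": "mg",
    "calcium": "mg",
    "iron": "mg",
    "zinc": "mg",
    "iodine": "ug",
    "potassium": "mg",
    "vitamin_a": "ug RAE",
    "vitamin_b1": "mg",
    "vitamin_b2": "mg",
    "vitamin_b3": "mg NE",
    "vitamin_b6": "mg",
    "vitamin_b9": "ug DFE",
    "vitamin_b12": "ug",
    "vitamin_c": "mg",
    "vitamin_d": "ug",
}

_INDEX: dict[str, int] = {name: i for i, name in enumerate(NUTRIENTS)}

#: Energy density of fat, kcal per gram (Atwater factor).
KCAL_PER_G_FAT = 9.0


class NegativeComponentError(ValueError):
    """A nutrient amount that must be non-negative is negative."""


class NutrientVector:
    """Energy plus 19 nutrient amounts; closed under addition and scaling.

    Parameters
    ----------
    values
        Sequence of 20 floats in :data:`NUTRIENTS` order, or a mapping from
        nutrient name to amount (missing names default to 0).
    validate
        If true (default) reject negative components.
    """

    __slots__ = ("values",)

    def __init__(self, values=None, *, validate: bool = True) -> None:
        if values is None:
            arr = np.zeros(len(NUTRIENTS))
        elif isinstance(values, Mapping):
            arr = np.zeros(len(NUTRIENTS))
            for name, amount in values.items():
                if name not in _INDEX:
                    raise KeyError(f"unknown nutrient {name!r}")
                arr[_INDEX[name]] = float(amount)
        else:
            arr = np.asarray(values, dtype=float).copy()
            if arr.shape != (len(NUTRIENTS),):
                raise ValueError(
                    f"expected {len(NUTRIENTS)} components, got shape {arr.shape}"
                )
        if validate and (arr < 0).any():
            bad = [NUTRIENTS[i] for i in np.flatnonzero(arr < 0)]
            raise NegativeComponentError(f"negative nutrient amount(s): {bad}")
        self.values = arr

    # -- named access --------------------------------------------------
    def __getattr__(self, name: str) -> float:
        try:
            return float(self.values[_INDEX[name]])
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> float:
        return float(self.values[_INDEX[name]])

    def as_dict(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(NUTRIENTS, self.values)}

    def __iter__(self) -> Iterator[float]:
        return iter(self.values.tolist())

    # -- algebra -------------------------------------------------------
    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector(self.values + other.values, validate=False)

    def __sub__(self, other: "NutrientVector") -> "NutrientVector":
        # May go transiently negative (dairy removal); callers clip/check.
        return NutrientVector(self.values - other.values, validate=False)

    def __mul__(self, scalar: float) -> "NutrientVector":
        return NutrientVector(self.values * float(scalar), validate=False)

    __rmul__ = __mul__

    def clipped(self, rel_tol: float = 1e-9) -> "NutrientVector":
        """Clip tiny negative rounding residue to zero.

        A component more negative than ``rel_tol`` times the vector magnitude
        indicates an internal bookkeeping error and raises.
        """
        scale = max(float(np.abs(self.values).max()), 1.0)
        if (self.values < -rel_tol * scale).any():
            bad = [NUTRIENTS[i] for i in np.flatnonzero(self.values < -rel_tol * scale)]
            raise NegativeComponentError(
                f"component(s) {bad} negative beyond numerical tolerance"
            )
        return NutrientVector(np.clip(self.values, 0.0, None), validate=False)

    def isclose(self, other: "NutrientVector", rel: float = 1e-9, abs_: float = 1e-12) -> bool:
        return bool(np.allclose(self.values, other.values, rtol=rel, atol=abs_))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, NutrientVector) and bool(
            np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        nonzero = {k: round(v, 4) for k, v in self.as_dict().items() if v}
        return f"NutrientVector({nonzero})"


def zeros() -> NutrientVector:
    return NutrientVector()
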