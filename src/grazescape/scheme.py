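"""Land-cover nomenclature for the savanna woodland–grassland gradient.

The classification stratifies the forest-to-grassland gradient into four
25%-woody-cover interval classes (CDW, ODW, DG, CG) that carry integer
grassiness modifiers 1–4, plus non-gradient classes (anthropogenic, bare,
water) that carry none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

__all__ = ["LandCoverClass", "ClassScheme", "DEFAULT_SCHEME", "GRADIENT_ABBREVS"]

#: Gradient classes in decreasing woody-cover order; modifiers are 1..4.
GRADIENT_ABBREVS = ("CDW", "ODW", "DG", "CG")

_EXPECTED_INTERVALS = {
    "CDW": (75.0, 100.0),
    "ODW": (50.0, 75.0),
    "DG": (25.0, 50.0),
    "CG": (0.0, 25.0),
}
_EXPECTED_MODIFIERS = {"CDW": 1, "ODW": 2, "DG": 3, "CG": 4}


@dataclass(frozen=True)
class LandCoverClass:
    """One land-cover class: integer raster code, names, and gradient role.

    ``woody_cover`` is the (low, high) percentage interval for gradient
    classes, ``None`` otherwise. ``grassiness_modifier`` is the ×1…×4 weight
    used by the grassiness index, ``None`` for non-gradient classes.
    """

    code: int
    label: str
    abbrev: str
    woody_cover: Optional[Tuple[float, float]] = None
    grassiness_modifier: Optional[int] = None


class ClassScheme:
    """Ordered land-cover class list with code/abbreviation lookup.

    Enforces unique codes and, whenever the four gradient classes are
    present, their fixed modifiers (CDW=1, ODW=2, DG=3, CG=4) and contiguous
    woody-cover intervals (75–100 / 50–75 / 25–50 / 0–25 %).
    """

    def __init__(self, classes: Iterable[LandCoverClass]):
        classes = tuple(classes)
        codes = [c.code for c in classes]
        if len(set(codes)) != len(codes):
            raise ValueError("class codes must be unique")
        self._classes = classes
        self._by_code = {c.code: c for c in classes}
        self._by_abbrev = {c.abbrev: c for c in classes}
        for abbrev in GRADIENT_ABBREVS:
            cls = self._by_abbrev.get(abbrev)
            if cls is None:
                continue
            if cls.grassiness_modifier != _EXPECTED_MODIFIERS[abbrev]:
                raise ValueError(
                    f"{abbrev} must carry grassiness modifier "
                    f"{_EXPECTED_MODIFIERS[abbrev]}, got {cls.grassiness_modifier}"
                )
            if cls.woody_cover != _EXPECTED_INTERVALS[abbrev]:
                raise ValueError(
                    f"{abbrev} woody-cover interval must be "
                    f"{_EXPECTED_INTERVALS[abbrev]}, got {cls.woody_cover}"
                )
        for c in classes:
            if c.abbrev not in GRADIENT_ABBREVS and c.grassiness_modifier is not None:
                raise ValueError(
                    f"non-gradient class {c.abbrev} must not carry a modifier"
                )

    @property
    def classes(self) -> Tuple[LandCoverClass, ...]:
        return self._classes

    @property
    def codes(self) -> Tuple[int, ...]:
        return tuple(c.code for c in self._classes)

    @property
    def abbrevs(self) -> Tuple[str, ...]:
        return tuple(c.abbrev for c in self._classes)

    @property
    def gradient_classes(self) -> Tuple[LandCoverClass, ...]:
        return tuple(
            self._by_abbrev[a] for a in GRADIENT_ABBREVS if a in self._by_abbrev
        )

    def by_code(self, code: int) -> LandCoverClass:
        try:
            return self._by_code[code]
        except KeyError:
            raise KeyError(f"unknown land-cover code {code}") from None

    def by_abbrev(self, abbrev: str) -> LandCoverClass:
        try:
            return self._by_abbrev[abbrev]
        except KeyError:
            raise KeyError(f"unknown land-cover abbreviation {abbrev!r}") from None

    def code_of(self, abbrev: str) -> int:
        return self.by_abbrev(abbrev).code

    def modifier(self, code: int) -> Optional[int]:
        return self.by_code(code).grassiness_modifier

    def __contains__(self, code: int) -> bool:
        return code in self._by_code

    def __len__(self) -> int:
        return len(self._classes)

    def __iter__(self):
        return iter(self._classes)


#: Default nine-class nomenclature for the Kruger savanna study area.
DEFAULT_SCHEME = ClassScheme(
    [
        LandCoverClass(1, "Closed deciduous woodland", "CDW", (75.0, 100.0), 1),
        LandCoverClass(2, "Open deciduous woodland", "ODW", (50.0, 75.0), 2),
        LandCoverClass(3, "Discontinuous grassland", "DG", (25.0, 50.0), 3),
        LandCoverClass(4, "Continuous grassland", "CG", (0.0, 25.0), 4),
        LandCoverClass(5, "Agriculture", "AG"),
        LandCoverClass(6, "Built-up", "BU"),
        LandCoverClass(7, "Closed coniferous woodland", "CCW"),
        LandCoverClass(8, "Bare ground", "BA"),
        LandCoverClass(9, "Water", "W"),
    ]
)
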