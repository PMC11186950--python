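"""ESC risk-item catalogue: item codes, severities, and predicates.

The ESC-2022 cardio-oncology baseline risk proforma is a checklist of
clinical items, each graded M1 (1 point), M2 (2 points), H or VH. The
checklist itself is guideline data and varies by drug class, so it ships
as an editable YAML file rather than code; :func:`default_catalogue`
loads the packaged VEGF-inhibitor catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import yaml

__all__ = ["CatalogueItem", "EscItemCatalogue", "default_catalogue", "load_catalogue"]

SEVERITIES = ("M1", "M2", "H", "VH")
#: Numeric points of the moderate grades; H/VH are tier triggers, not points.
MODERATE_POINTS = {"M1": 1, "M2": 2}


class CatalogueError(ValueError):
    pass


@dataclass(frozen=True)
class CatalogueItem:
    code: str
    label: str
    severity: str
    field: str
    age_min: Optional[int] = None
    age_max: Optional[int] = None

    def applies(self, profile) -> bool:
        """Evaluate this item's predicate on a profile."""
        if self.field == "age":
            ok = profile.age >= (self.age_min or 0)
            if self.age_max is not None:
                ok = ok and profile.age <= self.age_max
            return ok
        if self.field == "extra":
            return bool(profile.extra_items.get(self.code, False))
        return bool(getattr(profile, self.field))


class EscItemCatalogue:
    """Ordered collection of catalogue items with unique codes."""

    def __init__(self, items: list[CatalogueItem]):
        codes = [it.code for it in items]
        if len(set(codes)) != len(codes):
            raise CatalogueError("item codes must be unique")
        for it in items:
            if it.severity not in SEVERITIES:
                raise CatalogueError(
                    f"item {it.code!r}: severity {it.severity!r} not in {SEVERITIES}"
                )
        self.items = list(items)
        self._by_code = {it.code: it for it in items}

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def extra_item_codes(self) -> set[str]:
        return {it.code for it in self.items if it.field == "extra"}


def _parse(doc: dict) -> EscItemCatalogue:
    items = []
    for code, entry in doc["items"].items():
        items.append(
            CatalogueItem(
                code=code,
                label=str(entry.get("label", code)),
                severity=str(entry["severity"]),
                field=str(entry.get("field", code)),
                age_min=entry.get("age_min"),
                age_max=entry.get("age_max"),
            )
        )
    return EscItemCatalogue(items)


def load_catalogue(path) -> EscItemCatalogue:
    """Load a catalogue from a YAML file (keys: item_code -> entry)."""
    with open(path) as fh:
        return _parse(yaml.safe_load(fh))


def default_catalogue() -> EscItemCatalogue:
    """The packaged VEGF-inhibitor item catalogue."""
    text = resources.files("macerisk.data").joinpath("esc_items.yaml").read_text()
    return _parse(yaml.safe_load(text))
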