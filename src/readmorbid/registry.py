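"""Canonical comorbidity category registry.

Two summary measures are supported:

* ``charlson`` — the 17-category Charlson Comorbidity Index (CCI).  Each
  category carries two integer weights: the original scheme (values 1, 2, 3
  or 6) and the Quan 12-item update, in which five categories receive weight
  0 and the remainder weights in {1, 2, 4, 6}.
* ``elixhauser`` — the 31-category Elixhauser Method (EM).  The categories
  are unweighted; they enter regression models as separate indicators.

The registry ships as an editable YAML resource (``data/categories.yml``)
and also declares the default severity-hierarchy rules (e.g. metastatic
solid tumour supersedes any-malignancy) applied before index computation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import yaml

MEASURES = ("charlson", "elixhauser")

CHARLSON_WEIGHTS_ORIGINAL = frozenset({1, 2, 3, 6})
CHARLSON_WEIGHTS_QUAN = frozenset({0, 1, 2, 4, 6})


@dataclass(frozen=True)
class CategoryDef:
    """One comorbidity category of a summary measure."""

    category_id: str
    display_name: str
    measure: str
    weight_original: int | None = None  # charlson only
    weight_quan: int | None = None  # charlson only

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure: {self.measure!r}")
        if self.measure == "charlson":
            if self.weight_original not in CHARLSON_WEIGHTS_ORIGINAL:
                raise ValueError(
                    f"{self.category_id}: original weight {self.weight_original} "
                    f"not in {sorted(CHARLSON_WEIGHTS_ORIGINAL)}"
                )
            if self.weight_quan not in CHARLSON_WEIGHTS_QUAN:
                raise ValueError(
                    f"{self.category_id}: Quan weight {self.weight_quan} "
                    f"not in {sorted(CHARLSON_WEIGHTS_QUAN)}"
                )


@dataclass(frozen=True)
class HierarchyRule:
    """When ``severe_category`` is flagged, ``superseded_category`` is cleared."""

    severe_category: str
    superseded_category: str
    measure: str


@dataclass(frozen=True)
class CategoryRegistry:
    """The full category universe for both measures plus hierarchy rules."""

    categories: tuple[CategoryDef, ...]
    hierarchy: tuple[HierarchyRule, ...]

    def for_measure(self, measure: str) -> tuple[CategoryDef, ...]:
        _check_measure(measure)
        return tuple(c for c in self.categories if c.measure == measure)

    def category_ids(self, measure: str) -> tuple[str, ...]:
        return tuple(c.category_id for c in self.for_measure(measure))

    def hierarchy_rules(self, measure: str) -> tuple[HierarchyRule, ...]:
        _check_measure(measure)
        return tuple(r for r in self.hierarchy if r.measure == measure)

    def charlson_weights(self, scheme: str = "original") -> dict[str, int]:
        if scheme not in ("original", "quan"):
            raise ValueError(f"unknown weight scheme: {scheme!r}")
        attr = "weight_original" if scheme == "original" else "weight_quan"
        return {c.category_id: getattr(c, attr) for c in self.for_measure("charlson")}

    def validate(self) -> None:
        n_ch = len(self.for_measure("charlson"))
        n_em = len(self.for_measure("elixhauser"))
        if n_ch != 17:
            raise ValueError(f"charlson registry has {n_ch} categories, expected 17")
        if n_em != 31:
            raise ValueError(f"elixhauser registry has {n_em} categories, expected 31")
        n_quan = sum(c.weight_quan > 0 for c in self.for_measure("charlson"))
        if n_quan != 12:
            raise ValueError(
                f"{n_quan} charlson categories carry a positive Quan weight, expected 12"
            )
        for measure in MEASURES:
            ids = self.category_ids(measure)
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate category ids in {measure} registry")
            for rule in self.hierarchy_rules(measure):
                for cat in (rule.severe_category, rule.superseded_category):
                    if cat not in ids:
                        raise ValueError(
                            f"hierarchy rule references unknown {measure} category {cat!r}"
                        )


def _check_measure(measure: str) -> None:
    if measure not in MEASURES:
        raise ValueError(f"unknown measure: {measure!r} (expected one of {MEASURES})")


def load_registry(path: str | Path | None = None) -> CategoryRegistry:
    """Load a category registry from YAML (default: the packaged registry)."""
    if path is None:
        text = (
            importlib.resources.files("readmorbid") / "data" / "categories.yml"
        ).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    cats: list[CategoryDef] = []
    for measure in MEASURES:
        for row in raw[measure]:
            cats.append(
                CategoryDef(
                    category_id=row["id"],
                    display_name=row["name"],
                    measure=measure,
                    weight_original=row.get("weight_original"),
                    weight_quan=row.get("weight_quan"),
                )
            )
    rules: list[HierarchyRule] = []
    for measure, rows in (raw.get("hierarchy") or {}).items():
        for row in rows or []:
            rules.append(HierarchyRule(row["severe"], row["superseded"], measure))
    reg = CategoryRegistry(categories=tuple(cats), hierarchy=tuple(rules))
    reg.validate()
    return reg


@lru_cache(maxsize=1)
def default_registry() -> CategoryRegistry:
    """The packaged registry (cached; treat as immutable)."""
    return load_registry(None)
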