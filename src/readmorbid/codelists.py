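"""Load, validate, merge and query comorbidity code lists.

A code list maps clinical terminology codes (Read codes: opaque,
case-sensitive tokens) to the categories of one summary measure.  Files are
comma-delimited UTF-8 with a header naming at least ``code``, ``term`` and
``category``; terms frequently contain commas and brackets, so the usual
spreadsheet quoting convention applies.

Matching is exact and case-sensitive and no hierarchy expansion is
performed: the lists are expected to be fully exploded already.  Duplicates
are identical (code, category) pairs and are collapsed on load; the same
code appearing under two *different* categories of one measure is retained
and merely reported, since e.g. a tumour code can legitimately serve two
categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .registry import CategoryRegistry, default_registry, _check_measure

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("code", "term", "category")


class CodelistSchemaError(ValueError):
    """The file does not conform to the code-list schema."""


@dataclass(frozen=True)
class CodeEntry:
    """One terminology code mapped to one comorbidity category."""

    code: str
    term: str
    category: str
    measure: str


@dataclass
class CodeList:
    """All (code, category) mappings for one summary measure."""

    measure: str
    entries: list[CodeEntry]
    registry: CategoryRegistry = field(default_factory=default_registry, repr=False)

    def __post_init__(self) -> None:
        _check_measure(self.measure)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def category_ids(self) -> tuple[str, ...]:
        return self.registry.category_ids(self.measure)

    def lookup(self, code: str) -> set[str]:
        """Categories the (trimmed, case-sensitive) code maps to; may be empty."""
        return self._index().get(code.strip(), set())

    def _index(self) -> dict[str, set[str]]:
        if not hasattr(self, "_code_index"):
            idx: dict[str, set[str]] = {}
            for e in self.entries:
                idx.setdefault(e.code, set()).add(e.category)
            self._code_index = idx
        return self._code_index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.code, e.term, e.category) for e in self.entries],
            columns=list(MANDATORY_COLUMNS),
        )

    def pair_set(self) -> set[tuple[str, str]]:
        return {(e.code, e.category) for e in self.entries}


@dataclass
class ValidationReport:
    """Outcome of the logic check over one code list."""

    duplicate_pairs: list[tuple[str, str]]
    unknown_categories: list[str]
    empty_codes: int
    cross_category_codes: list[str]  # informational, not a violation
    entry_count: int
    per_category_counts: dict[str, int]

    @property
    def ok(self) -> bool:
        return not (self.duplicate_pairs or self.unknown_categories or self.empty_codes)


@dataclass
class DiscrepancyReport:
    """Codes present in a strict subset of the merged lists, per category.

    These are the items that would require human adjudication when
    independently screened lists are reconciled.
    """

    by_category: dict[str, list[str]]

    @property
    def empty(self) -> bool:
        return not any(self.by_category.values())


def lookup(codelist: CodeList, code: str) -> set[str]:
    """Exact-match category lookup (module-level convenience)."""
    return codelist.lookup(code)


def load_codelist(
    path: str | Path,
    measure: str,
    registry: CategoryRegistry | None = None,
) -> CodeList:
    """Read a delimited code-list file into a deduplicated :class:`CodeList`.

    Duplicate (code, category) rows are collapsed to one entry (the first
    term wins); the collapse count is logged.  Codes are preserved verbatim
    apart from whitespace trimming — Read codes are case-sensitive.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    CodelistSchemaError
        If a mandatory column is missing or a row's category is not in the
        measure's declared category set.
    """
    _check_measure(measure)
    registry = registry or default_registry()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"code list file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CodelistSchemaError(
            f"{path}: missing mandatory column(s) {missing}; found {list(df.columns)}"
        )
    known = set(registry.category_ids(measure))
    entries: list[CodeEntry] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for i, row in enumerate(df.itertuples(index=False)):
        code = str(row.code).strip()
        category = str(row.category).strip()
        if not code:
            raise CodelistSchemaError(f"{path}: row {i + 2}: empty code")
        if category not in known:
            raise CodelistSchemaError(
                f"{path}: row {i + 2}: category {category!r} is not a "
                f"{measure} category"
            )
        key = (code, category)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        entries.append(CodeEntry(code, str(row.term), category, measure))
    if n_dup:
        logger.info("%s: collapsed %d duplicate (code, category) rows", path, n_dup)
    return CodeList(measure=measure, entries=entries, registry=registry)


def write_codelist(codelist: CodeList, path: str | Path) -> None:
    """Write a code list back to CSV (round-trips with :func:`load_codelist`)."""
    codelist.to_frame().to_csv(path, index=False)


def validate_codelist(codelist: CodeList) -> ValidationReport:
    """Run the logic check: enumerate every invariant violation.

    A list produced by :func:`load_codelist` yields zero duplicates and zero
    unknown categories; ``cross_category_codes`` is informational only.
    """
    known = set(codelist.category_ids)
    seen: set[tuple[str, str]] = set()
    duplicates: list[tuple[str, str]] = []
    unknown: list[str] = []
    empty = 0
    per_cat: dict[str, int] = {}
    by_code: dict[str, set[str]] = {}
    for e in codelist.entries:
        key = (e.code, e.category)
        if key in seen:
            duplicates.append(key)
        seen.add(key)
        if e.category not in known:
            unknown.append(e.category)
        if not e.code.strip():
            empty += 1
        per_cat[e.category] = per_cat.get(e.category, 0) + 1
        by_code.setdefault(e.code, set()).add(e.category)
    cross = sorted(c for c, cats in by_code.items() if len(cats) > 1)
    return ValidationReport(
        duplicate_pairs=duplicates,
        unknown_categories=sorted(set(unknown)),
        empty_codes=empty,
        cross_category_codes=cross,
        entry_count=len(codelist.entries),
        per_category_counts=per_cat,
    )


def merge_codelists(lists: list[CodeList]) -> tuple[CodeList, DiscrepancyReport]:
    """Set-union merge of independently compiled lists for one measure.

    The merged list contains the union of (code, category) pairs.  The
    discrepancy report lists, per category, codes present in a strict subset
    of the inputs — the items that screeners would reconcile by discussion.
    Merging is idempotent, commutative and associative.
    """
    if not lists:
        raise ValueError("merge_codelists requires at least one list")
    measures = {cl.measure for cl in lists}
    if len(measures) > 1:
        raise ValueError(f"cannot merge lists of mixed measures: {sorted(measures)}")
    measure = lists[0].measure
    merged: dict[tuple[str, str], CodeEntry] = {}
    presence: dict[tuple[str, str], int] = {}
    for cl in lists:
        for key in cl.pair_set():
            presence[key] = presence.get(key, 0) + 1
        for e in cl.entries:
            merged.setdefault((e.code, e.category), e)
    n_lists = len(lists)
    by_category: dict[str, list[str]] = {}
    if n_lists > 1:
        for (code, category), n in presence.items():
            if n < n_lists:
                by_category.setdefault(category, []).append(code)
        for codes in by_category.values():
            codes.sort()
    entries = sorted(merged.values(), key=lambda e: (e.category, e.code))
    out = CodeList(measure=measure, entries=entries, registry=lists[0].registry)
    return out, DiscrepancyReport(by_category=by_category)
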