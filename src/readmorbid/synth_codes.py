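"""Deterministic generator of *synthetic* Read-style code lists.

The published Charlson and Elixhauser Read-code resources comprise 5832 and
7156 deduplicated (code, category) rows respectively, but the underlying
terminology tables cannot be redistributed with this package.  This module
builds stand-in lists of exactly that scale: opaque, case-sensitive,
Read-shaped tokens (5-character stem + ``00`` termination) partitioned
across the registry's categories.  The construction is deterministic — no
RNG — so every build of the package carries byte-identical lists.

The synthetic codes exercise everything downstream code cares about
(case-sensitive exact matching, CSV quoting of terms containing commas,
category lookup, deduplication) while carrying no clinical meaning.
"""

from __future__ import annotations

import string
from pathlib import Path

from .codelists import CodeEntry, CodeList, write_codelist
from .registry import CategoryRegistry, default_registry

#: Published sizes of the two code-list resources (deduplicated rows).
CHARLSON_N_CODES = 5832
ELIXHAUSER_N_CODES = 7156

_STEM_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits
# Disjoint prefix alphabets keep the two measures' code universes disjoint,
# so an event generated for one measure can never flag a category of the
# other via an accidental token collision.
_PREFIXES = {
    "charlson": string.ascii_uppercase,
    "elixhauser": string.ascii_lowercase + string.digits,
}


def _encode_stem(i: int) -> str:
    """Four base-62 characters; mixed case makes matching case-significant."""
    chars = []
    for _ in range(4):
        i, r = divmod(i, len(_STEM_ALPHABET))
        chars.append(_STEM_ALPHABET[r])
    return "".join(reversed(chars))


def _category_sizes(n_codes: int, n_categories: int) -> list[int]:
    base, extra = divmod(n_codes, n_categories)
    return [base + (1 if i < extra else 0) for i in range(n_categories)]


def build_synthetic_codelist(
    measure: str,
    n_codes: int | None = None,
    registry: CategoryRegistry | None = None,
) -> CodeList:
    """Build the synthetic code list for one measure.

    ``n_codes`` defaults to the published resource size for the measure.
    Codes are unique within a measure and allocated near-evenly across its
    categories; every third term contains a comma to exercise CSV quoting.
    """
    registry = registry or default_registry()
    if n_codes is None:
        n_codes = CHARLSON_N_CODES if measure == "charlson" else ELIXHAUSER_N_CODES
    cat_ids = registry.category_ids(measure)
    sizes = _category_sizes(n_codes, len(cat_ids))
    entries: list[CodeEntry] = []
    serial = 0
    prefixes = _PREFIXES[measure]
    for cat_idx, (cat, size) in enumerate(zip(cat_ids, sizes)):
        prefix = prefixes[cat_idx % len(prefixes)]
        display = registry.for_measure(measure)[cat_idx].display_name
        for j in range(size):
            code = f"{prefix}{_encode_stem(serial)}00"
            if j % 3 == 0:
                term = f"Synthetic term, {display} (variant {j})"
            else:
                term = f"Synthetic {display} term {j}"
            entries.append(CodeEntry(code=code, term=term, category=cat, measure=measure))
            serial += 1
    return CodeList(measure=measure, entries=entries, registry=registry)


def write_synthetic_codelists(
    out_dir: str | Path, registry: CategoryRegistry | None = None
) -> dict[str, Path]:
    """Write charlson.csv and elixhauser.csv under ``out_dir``; return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for measure in ("charlson", "elixhauser"):
        cl = build_synthetic_codelist(measure, registry=registry)
        path = out_dir / f"{measure}.csv"
        write_codelist(cl, path)
        paths[measure] = path
    return paths
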