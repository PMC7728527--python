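"""Anonymization operators for source values.

Four operator families cover the default de-identification strategy:

* **masking** — replace a suffix of the value with a fill character, keeping a
  short disclosing prefix (``"1234567890"`` with a 5-character prefix becomes
  ``"12345*****"``);
* **removal** — erase the entire value (the canonical removal token is the
  empty string, which round-trips unambiguously through CSV);
* **partial removal** — for postal addresses: drop the street/building part
  entirely and keep only a short leading region prefix of the zip code;
* **whole-value redaction** — for free-text fields where token-level NLP
  de-identification is out of scope, the entire value is erased (a caller may
  plug in a smarter redactor).

Masking also induces the generalization hierarchies used by the lattice
search: level *i* of a field's hierarchy masks the last *i* characters of
every value, and the top level collapses every value to a single suppression
token.

Aggregation (mean/median replacement) and pseudonymization-by-encryption are
registered as named operator slots for deployments that need them, but are
not part of the default strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

from .errors import ConfigError

#: Canonical removal token: the empty string.
REMOVED = ""

#: Default fill character for masking.
MASK_CHAR = "*"

#: Default number of leading zip/postal characters retained by partial removal.
ZIP_PREFIX = 3

#: Default disclosing prefix for long identifiers (the 10-digit key example
#: keeps 5) and for short coded values.
KEEP_PREFIX_LONG = 5
KEEP_PREFIX_CODE = 1


def mask_value(value, keep_prefix: int = KEEP_PREFIX_LONG, mask_char: str = MASK_CHAR) -> str:
    """Mask the suffix of ``value``, keeping at most ``keep_prefix`` leading characters.

    The output always has the same length as the stringified input.  If the
    value is no longer than the prefix it is masked entirely, so a short value
    is never disclosed in full.
    """
    if keep_prefix < 0:
        raise ConfigError("keep_prefix must be >= 0")
    s = value if isinstance(value, str) else ("" if value is None else str(value))
    if len(s) <= keep_prefix:
        return mask_char * len(s)
    return s[:keep_prefix] + mask_char * (len(s) - keep_prefix)


def remove_value(value=None) -> str:
    """Erase the entire value; returns the canonical removal token."""
    return REMOVED


def nlp_redact(value=None, redactor: Callable[[str], str] | None = None) -> str:
    """Redact a free-text value.

    By default the whole value is replaced with the removal token.  Passing a
    ``redactor`` substitutes a user-supplied function (e.g. a clinical NLP
    de-identifier) for the default whole-value erasure.
    """
    if redactor is not None:
        s = value if isinstance(value, str) else ("" if value is None else str(value))
        return redactor(s)
    return REMOVED


def partial_remove_address(
    address_1,
    address_2,
    zip_prefix: int = ZIP_PREFIX,
    mask_char: str = MASK_CHAR,
) -> tuple:
    """Partially remove a postal address.

    The street/building line (``address_1``) is erased entirely; the
    zip/postal line (``address_2``) keeps its first ``zip_prefix`` characters
    with the remainder masked, e.g. ``"02841"`` -> ``"028**"``.  ``None``
    inputs pass through as ``None`` in the second position.
    """
    a2 = None
    if address_2 is not None:
        s = address_2 if isinstance(address_2, str) else str(address_2)
        a2 = s[:zip_prefix] + mask_char * max(0, len(s) - zip_prefix)
    return REMOVED, a2


@dataclass(frozen=True)
class Hierarchy:
    """A suffix-masking generalization hierarchy for one field.

    Level 0 is the identity.  Level ``i`` keeps the first
    ``max(len(v) - i, 0)`` characters of a value and appends ``i`` fill
    characters, so generalization is a monotone coarsening: values equal at
    level ``i`` stay equal at every deeper level.  The top level
    (``max_level`` = length of the longest value seen when the hierarchy was
    built) maps every value to the same full-suppression token.
    """

    field: str
    max_level: int
    mask_char: str = MASK_CHAR
    values: tuple = field(default_factory=tuple)  # build-time value set, for export

    def apply(self, value, level: int) -> str:
        if not 0 <= level <= self.max_level:
            raise ConfigError(
                f"level {level} outside [0, {self.max_level}] for field {self.field!r}"
            )
        s = value if isinstance(value, str) else ("" if value is None else str(value))
        if level == 0:
            return s
        return s[: max(len(s) - level, 0)] + self.mask_char * level

    def level_table(self, level: int) -> list:
        """(value, generalized value) pairs for one level over the build-time
        value set — the layout common anonymization tools import."""
        return [(v, self.apply(v, level)) for v in self.values]


def build_masking_hierarchy(values: Iterable, mask_char: str = MASK_CHAR, field_name: str = "") -> Hierarchy:
    """Build the suffix-masking hierarchy for a set of observed values.

    The number of levels equals the length of the longest value, so the top
    level suppresses every value to ``mask_char * max_len``.
    """
    vals = tuple(sorted({v if isinstance(v, str) else ("" if v is None else str(v)) for v in values}))
    if not vals:
        raise ConfigError("cannot build a hierarchy from an empty value set")
    max_len = max(len(v) for v in vals)
    return Hierarchy(field=field_name, max_level=max_len, mask_char=mask_char, values=vals)


def export_hierarchy_csv(hierarchy: Hierarchy, directory) -> list:
    """Write one two-column CSV (value, generalized value) per level.

    Files are named ``<field>_level<i>.csv`` — the layout common
    anonymization tools accept for imported hierarchies.  Returns the paths.
    """
    import csv as _csv
    from pathlib import Path

    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for lvl in range(hierarchy.max_level + 1):
        p = out / f"{hierarchy.field or 'field'}_level{lvl}.csv"
        with open(p, "w", newline="", encoding="utf-8") as fh:
            w = _csv.writer(fh)
            w.writerow(["value", "generalized"])
            w.writerows(hierarchy.level_table(lvl))
        paths.append(p)
    return paths


# Named operator slots.  "aggregate" and "pseudonymize" are available for
# deployment-specific strategies; the default rule set uses the first four.
OPERATORS: dict = {
    "mask": mask_value,
    "remove": remove_value,
    "partial_remove": partial_remove_address,
    "nlp_redact": nlp_redact,
    "keep": lambda value=None: value,
}


def register_operator(name: str, fn: Callable) -> None:
    """Register or replace a named transformation operator."""
    OPERATORS[name] = fn
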