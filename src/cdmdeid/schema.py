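"""Schema registry: OMOP-CDM v5.3.1 tables and per-field de-identification rules.

Every covered CDM table is registered with its ordered column list, and every
column resolves to exactly one :class:`FieldRule` giving its disclosure
classification and the transformation applied to it:

* ``identifier`` — directly identifying; always removed.
* ``raw`` — institutional source values (the ``*_source_value`` convention);
  treated as quasi-identifiers during privacy-model enforcement.
* ``quasi_identifier`` — identifying in combination (addresses, geocodes,
  provider registry numbers).
* ``sensitive`` — clinical content protected by l-diversity / t-closeness
  rather than transformed.
* ``insensitive`` — surrogate keys and other non-disclosing columns.

The curated rules ship as a versioned YAML document bundled with the package
(``data/cdm_v531.yaml``); deployments may override individual rules via the
run configuration.  Fields without a curated rule fall back to conservative
name-based defaults: any ``*_source_value`` is masked, concept ids and
surrogate keys are kept as insensitive, and numeric clinical values and dates
are kept as sensitive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import yaml

from .errors import ConfigError, UnregisteredTableError

CLASSIFICATIONS = frozenset(
    {"identifier", "quasi_identifier", "raw", "sensitive", "insensitive"}
)
ACTIONS = frozenset({"remove", "mask", "partial_remove", "nlp_redact", "keep"})

# Foreign keys that can be linked back to the institutional database and are
# therefore deleted outright: the person source key and the provider registry
# identifiers/name.
LINKABLE_KEYS = frozenset(
    {
        ("PERSON", "person_source_value"),
        ("PROVIDER", "npi"),
        ("PROVIDER", "dea"),
        ("PROVIDER", "provider_name"),
    }
)

# Numeric clinical fields kept as sensitive data (protected by the privacy
# model, not transformed).
_NUMERIC_CLINICAL = frozenset(
    {
        "quantity",
        "refills",
        "days_supply",
        "value_as_number",
        "range_low",
        "range_high",
        "year_of_birth",
        "month_of_birth",
        "day_of_birth",
        "survey_version_number",
        "amount_allowed",
    }
)
_NUMERIC_CLINICAL_PREFIXES = ("total_", "paid_")

# Default patterns that flag retained content as identifier-like: long
# all-digit identifiers (resident registration / account numbers) and e-mail
# addresses.  Deployments may extend the list.
DEFAULT_IDENTIFIER_PATTERNS = (
    r"^\d{9,}$",
    r"^[^@\s]+@[^@\s]+\.[^@\s]+$",
)


@dataclass(frozen=True)
class FieldRule:
    """Classification and transformation directive for one CDM field."""

    table: str
    field: str
    classification: str
    action: str

    def __post_init__(self):
        if self.classification not in CLASSIFICATIONS:
            raise ConfigError(f"unknown classification {self.classification!r}")
        if self.action not in ACTIONS:
            raise ConfigError(f"unknown action {self.action!r}")
        if self.classification == "identifier" and self.action != "remove":
            raise ConfigError(
                f"{self.table}.{self.field}: identifier fields must be removed"
            )

    @property
    def is_quasi(self) -> bool:
        """Raw and quasi-identifier fields enter privacy-model enforcement."""
        return self.classification in ("raw", "quasi_identifier")


def default_rule(table: str, field: str) -> FieldRule:
    """Conservative fallback rule for a field without a curated entry."""
    if "source_value" in field:
        return FieldRule(table, field, "raw", "mask")
    if field.endswith("_concept_id") or field.endswith("_id") or field.endswith("_domain_id"):
        return FieldRule(table, field, "insensitive", "keep")
    if field in _NUMERIC_CLINICAL or field.startswith(_NUMERIC_CLINICAL_PREFIXES):
        return FieldRule(table, field, "sensitive", "keep")
    if "date" in field or "time" in field:
        return FieldRule(table, field, "sensitive", "keep")
    return FieldRule(table, field, "insensitive", "keep")


class SchemaRegistry:
    """Registry of covered CDM tables, their columns, and field rules.

    Lookup is total over registered tables: every (table, field) pair
    resolves to exactly one rule, curated or defaulted.
    """

    def __init__(self, tables: Mapping[str, list], rules: Iterable[FieldRule], version: str = ""):
        self.version = version
        self.tables: dict = {t.upper(): [c.lower() for c in cols] for t, cols in tables.items()}
        self._rules: dict = {}
        for rule in rules:
            key = (rule.table.upper(), rule.field.lower())
            if key in self._rules:
                raise ConfigError(f"duplicate rule for {key[0]}.{key[1]}")
            self._rules[key] = rule

    @classmethod
    def bundled(cls) -> "SchemaRegistry":
        """Load the curated v5.3.1 registry shipped with the package."""
        text = resources.files("cdmdeid").joinpath("data/cdm_v531.yaml").read_text("utf-8")
        doc = yaml.safe_load(text)
        rules = [
            FieldRule(r["table"].upper(), r["field"].lower(), r["classification"], r["action"])
            for r in doc["rules"]
        ]
        tables = {t: spec["columns"] for t, spec in doc["tables"].items()}
        return cls(tables, rules, version=doc.get("version", ""))

    def with_overrides(self, overrides: Iterable[Mapping]) -> "SchemaRegistry":
        """A copy of the registry with per-deployment rule overrides applied.

        Each override is a mapping with table, field, classification, action.
        """
        merged = dict(self._rules)
        for o in overrides:
            rule = FieldRule(
                o["table"].upper(), o["field"].lower(), o["classification"], o["action"]
            )
            merged[(rule.table, rule.field)] = rule
        reg = SchemaRegistry.__new__(SchemaRegistry)
        reg.version = self.version
        reg.tables = self.tables
        reg._rules = merged
        return reg

    # -- lookup ------------------------------------------------------------

    def _check_table(self, table: str) -> str:
        t = table.upper()
        if t not in self.tables:
            raise UnregisteredTableError(table)
        return t

    def columns(self, table: str) -> list:
        return list(self.tables[self._check_table(table)])

    def classify_field(self, table: str, field: str) -> FieldRule:
        """The rule for one field: the curated entry when present, otherwise
        the name-based default."""
        t = self._check_table(table)
        f = field.lower()
        rule = self._rules.get((t, f))
        if rule is not None:
            return rule
        return default_rule(t, f)

    def rules_for(self, table: str) -> list:
        """Rules for every registered column of a table, in schema order."""
        t = self._check_table(table)
        return [self.classify_field(t, f) for f in self.tables[t]]

    def quasi_identifiers_for(self, table: str) -> list:
        """Columns entering privacy-model enforcement, in schema order.

        Raw/quasi-identifier fields whose action is not outright removal;
        removed fields carry no information to generalize.
        """
        return [
            r.field for r in self.rules_for(table) if r.is_quasi and r.action != "remove"
        ]

    def raw_fields_for(self, table: str) -> list:
        """All raw/quasi-identifier columns, including ones slated for
        removal — the combination an attacker sees before anonymization."""
        return [r.field for r in self.rules_for(table) if r.is_quasi]

    def sensitive_fields_for(self, table: str) -> list:
        """Columns classified as sensitive clinical data, in schema order."""
        return [r.field for r in self.rules_for(table) if r.classification == "sensitive"]

    # -- post-hoc content check --------------------------------------------

    def validate_intentional_fields(
        self, dataset: Mapping, patterns: Iterable[str] = DEFAULT_IDENTIFIER_PATTERNS
    ) -> list:
        """Scan retained (non-removed) columns for identifier-like content.

        Intentionally stored fields (e.g. SURVEY_CONDUCT responses) are kept,
        but a retained field whose content matches an identifier pattern —
        long all-digit IDs, e-mail addresses — must not be used, and is
        flagged here.  Returns a list of violation records
        ``{"table", "field", "n_matching", "pattern"}``; an empty list is a
        pass.  Report-only: nothing is modified.
        """
        compiled = [re.compile(p) for p in patterns]
        violations = []
        for name, df in dataset.items():
            t = name.upper()
            if t not in self.tables:
                continue
            for col in df.columns:
                rule = self.classify_field(t, col)
                if rule.action == "remove":
                    continue
                values = df[col].dropna().astype(str)
                values = values[values != ""]
                if values.empty:
                    continue
                for pat in compiled:
                    n = int(values.str.fullmatch(pat.pattern).sum())
                    if n > 0:
                        violations.append(
                            {"table": t, "field": col, "n_matching": n, "pattern": pat.pattern}
                        )
                        break
        return violations
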