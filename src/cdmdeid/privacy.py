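"""Equivalence-class partitioning and the k-anonymity, l-diversity and
t-closeness predicates.

Records are grouped into equivalence classes on the exact tuple of
(transformed) quasi-identifier values; a class of size *s* carries a
per-record prosecutor re-identification risk of ``1/s``.

* **k-anonymity** holds when every class has at least *k* records, bounding
  the identification probability by ``1/k``.
* **l-diversity** (distinct variant) additionally requires at least *l*
  distinct sensitive values per class, defending against homogeneity attacks
  where a uniform sensitive value leaks despite a large class.
* **t-closeness** requires the sensitive-value distribution of every class to
  lie within earth-mover's distance *t* of the global distribution, defending
  against skewness attacks.  For categorical sensitive domains the ground
  distance is uniform, making the EMD the total-variation distance; for
  ordered (numeric) domains the 1-D EMD over the sorted domain is normalized
  by the domain span so the result stays in [0, 1].
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

#: In-memory marker for a missing value inside a grouping key or sensitive
#: tally.  Nulls form their own category: they can never silently merge with a
#: real value or inflate diversity.
NULL_MARKER = "␀"  # ␀


@dataclass(frozen=True)
class EquivalenceClass:
    """Records sharing one transformed quasi-identifier tuple."""

    key: tuple
    row_indices: tuple
    sensitive_counts: Mapping = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.row_indices)

    @property
    def risk(self) -> float:
        """Prosecutor per-record re-identification risk, 1/|class|."""
        return 1.0 / self.size

    def distinct_sensitive(self, sensitive_field: str) -> int:
        if sensitive_field not in self.sensitive_counts:
            raise ConfigError(f"sensitive field {sensitive_field!r} not tabulated")
        return len(self.sensitive_counts[sensitive_field])


@dataclass
class PrivacyConfig:
    """Privacy model choice and parameters.

    Defaults follow the strategy's reference configuration: the minimum
    k-anonymity criterion k=3, with the conservative l=5 / t=0.1 for the
    stronger models.  ``risk_threshold`` is the prosecutor-risk cutoff above
    which a record counts as "at risk" (default 20%); ``suppression_limit``
    caps the fraction of rows the lattice search may discard.
    """

    model: str = "k_anonymity"
    k: int = 3
    l: int = 5
    t: float = 0.1
    risk_threshold: float = 0.2
    suppression_limit: float = 1.0
    sensitive_field: object = None  # str, or mapping table -> str, or None (auto)
    ground: str = "categorical"

    def __post_init__(self):
        if self.model not in ("k_anonymity", "l_diversity", "t_closeness"):
            raise ConfigError(f"unknown privacy model {self.model!r}")
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.l < 1:
            raise ConfigError("l must be >= 1")
        if not 0.0 <= self.t <= 1.0:
            raise ConfigError("t must lie in [0, 1]")
        if not 0.0 < self.risk_threshold <= 1.0:
            raise ConfigError("risk_threshold must lie in (0, 1]")
        if not 0.0 <= self.suppression_limit <= 1.0:
            raise ConfigError("suppression_limit must lie in [0, 1]")
        if self.ground not in ("categorical", "ordered"):
            raise ConfigError(f"unknown ground distance {self.ground!r}")

    def sensitive_for(self, table: str):
        if isinstance(self.sensitive_field, Mapping):
            return self.sensitive_field.get(table.upper())
        return self.sensitive_field


def _key_series(df: pd.DataFrame, col: str) -> pd.Series:
    s = df[col]
    if s.dtype != object:
        s = s.astype(object)
    return s.where(pd.notna(s), NULL_MARKER)


def partition(
    records: pd.DataFrame,
    quasi_identifiers: Sequence[str],
    sensitive_fields: Sequence[str] = (),
) -> list:
    """Partition rows into equivalence classes on the exact QI tuple.

    Nulls form their own category.  An empty QI list yields a single class
    holding every row (the empty tuple key).  Row indices are positional.
    ``sensitive_fields`` are tabulated per class for the diversity/closeness
    predicates.
    """
    for col in list(quasi_identifiers) + list(sensitive_fields):
        if col not in records.columns:
            raise ConfigError(f"unknown column {col!r}")
    n = len(records)
    if n == 0:
        return []
    sens_arrays = {f: _key_series(records, f).to_numpy() for f in sensitive_fields}

    def make_class(key: tuple, positions: np.ndarray) -> EquivalenceClass:
        counts = {
            f: dict(Counter(arr[positions])) for f, arr in sens_arrays.items()
        }
        return EquivalenceClass(key=key, row_indices=tuple(int(i) for i in positions),
                                sensitive_counts=counts)

    if not quasi_identifiers:
        return [make_class((), np.arange(n))]

    key_arrays = [_key_series(records, c).to_numpy() for c in quasi_identifiers]
    grouped: dict = {}
    for pos in range(n):
        key = tuple(arr[pos] for arr in key_arrays)
        grouped.setdefault(key, []).append(pos)
    # insertion order = first-appearance order of each key
    return [make_class(key, np.array(positions)) for key, positions in grouped.items()]


def satisfies_k(classes: Iterable[EquivalenceClass], k: int) -> bool:
    """True iff every equivalence class holds at least k records."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    return all(c.size >= k for c in classes)


def satisfies_l(classes: Iterable[EquivalenceClass], sensitive_field: str, l: int) -> bool:
    """Distinct l-diversity: every class has >= l distinct sensitive values."""
    if l < 1:
        raise ConfigError("l must be >= 1")
    return all(c.distinct_sensitive(sensitive_field) >= l for c in classes)


def _align(class_dist, global_dist):
    """Align the two distributions and validate normalization."""
    if isinstance(class_dist, Mapping) != isinstance(global_dist, Mapping):
        raise ConfigError("distributions must both be mappings or both sequences")
    if isinstance(class_dist, Mapping):
        if set(class_dist) != set(global_dist):
            raise ConfigError("distributions are over different value domains")
        domain = sorted(class_dist, key=_order_key)
        p = np.array([float(class_dist[v]) for v in domain])
        q = np.array([float(global_dist[v]) for v in domain])
    else:
        p = np.asarray(class_dist, dtype=float)
        q = np.asarray(global_dist, dtype=float)
        if p.shape != q.shape:
            raise ConfigError("distributions are over different value domains")
    for vec in (p, q):
        if vec.ndim != 1 or len(vec) == 0:
            raise ConfigError("distributions must be non-empty 1-D vectors")
        if (vec < -1e-12).any() or not math.isclose(vec.sum(), 1.0, abs_tol=1e-9):
            raise ConfigError("distribution does not sum to 1")
    return p, q


def _order_key(v):
    try:
        return (0, float(v))
    except (TypeError, ValueError):
        return (1, str(v))


def distribution_distance(class_dist, global_dist, ground: str = "categorical") -> float:
    """Earth-mover's distance between two distributions over one domain.

    ``categorical`` ground: all distinct values are equally far apart, so the
    EMD reduces to the total-variation distance ``0.5 * sum |p - q|``.
    ``ordered`` ground: 1-D EMD over the sorted domain, normalized by the
    number of unit steps so the result lies in [0, 1].  Mappings are aligned
    by key (numeric order when the keys parse as numbers); sequences are
    assumed pre-aligned on a shared, ordered domain.
    """
    p, q = _align(class_dist, global_dist)
    if ground == "categorical":
        return float(0.5 * np.abs(p - q).sum())
    if ground == "ordered":
        m = len(p)
        if m == 1:
            return 0.0
        return float(np.abs(np.cumsum(p - q)[:-1]).sum() / (m - 1))
    raise ConfigError(f"unknown ground distance {ground!r}")


def _class_and_global_dists(classes: Sequence[EquivalenceClass], sensitive_field: str):
    """Per-class and global sensitive distributions over the shared domain."""
    totals: Counter = Counter()
    for c in classes:
        if sensitive_field not in c.sensitive_counts:
            raise ConfigError(f"sensitive field {sensitive_field!r} not tabulated")
        totals.update(c.sensitive_counts[sensitive_field])
    domain = sorted(totals, key=_order_key)
    n = sum(totals.values())
    global_dist = np.array([totals[v] / n for v in domain])
    per_class = []
    for c in classes:
        counts = c.sensitive_counts[sensitive_field]
        per_class.append(np.array([counts.get(v, 0) / c.size for v in domain]))
    return per_class, global_dist


def satisfies_t(
    classes: Sequence[EquivalenceClass],
    sensitive_field: str,
    t: float,
    ground: str = "categorical",
) -> bool:
    """t-closeness: every class distribution within distance t of the global
    distribution over all retained records."""
    if not 0.0 <= t <= 1.0:
        raise ConfigError("t must lie in [0, 1]")
    classes = list(classes)
    if not classes:
        return True
    per_class, global_dist = _class_and_global_dists(classes, sensitive_field)
    return all(
        distribution_distance(p, global_dist, ground) <= t + 1e-12 for p in per_class
    )


def class_diagnostics(
    classes: Sequence[EquivalenceClass],
    sensitive_field: str | None = None,
    ground: str = "categorical",
) -> pd.DataFrame:
    """Class-level diagnostic table: key, size, risk, and (when a sensitive
    field is tabulated) distinct sensitive count and distance to the global
    distribution."""
    rows = []
    dists = None
    if sensitive_field is not None and classes:
        per_class, global_dist = _class_and_global_dists(classes, sensitive_field)
        dists = [distribution_distance(p, global_dist, ground) for p in per_class]
    for i, c in enumerate(classes):
        row = {"class_key": "|".join(map(str, c.key)), "size": c.size, "risk": c.risk}
        if sensitive_field is not None:
            row["distinct_sensitive"] = c.distinct_sensitive(sensitive_field)
            row["distance_to_global"] = dists[i] if dists else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
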