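"""Seeded generator of OMOP-CDM-shaped tables with controllable re-identifiability.

The generator emulates the situation the de-identification strategy targets:
clinical tables whose ``*_source_value`` columns hold institutional codes
that are mostly repeated (large equivalence classes) but occasionally rare or
unique.  Controls:

* **qi_cardinalities / skew** — per-field coded-domain size and Zipf
  exponent, so marginal code frequencies are realistically head-heavy;
* **planted_class_sizes** — equivalence classes of exact sizes planted on
  the quasi-identifier tuple, using reserved codes disjoint from the coded
  domains, so tests and calibrations can rely on the exact class-size
  spectrum regardless of seed (``planted_unique`` is the special case of
  planting that many singletons);
* **min_background_class_size** — non-planted quasi-identifier tuples whose
  class falls below this floor are merged into the modal background tuple,
  so the only rare combinations are the planted ones.

Codes are short alphanumerics (3–8 characters) so suffix-masking hierarchies
have non-trivial depth.  Clinical plausibility is a non-goal: concept ids,
dates and quantities are filler with the right shapes, and event tables link
to PERSON by uniformly drawn person_id foreign keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .schema import SchemaRegistry

_CODE_ALPHABET = np.array(list("ABCDEFGHJKLMNPQRSTUVWXYZ0123456789"))
_RESERVED_PREFIX = "#U"  # planted codes; '#' is outside the code alphabet

DEFAULT_CARDINALITY = 8
DEFAULT_SKEW = 1.2


@dataclass
class GeneratorConfig:
    """Configuration for the synthetic CDM generator."""

    n_persons: int = 200
    tables: Sequence[str] = ("PERSON",)
    qi_cardinalities: Mapping[str, int] = dc_field(default_factory=dict)
    skew: float = DEFAULT_SKEW
    planted_unique: int = 0
    planted_class_sizes: Sequence[int] = ()
    rows_per_person: float = 3.0
    min_background_class_size: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_persons < 0 or self.planted_unique < 0:
            raise ConfigError("counts must be >= 0")
        if self.rows_per_person < 0:
            raise ConfigError("rows_per_person must be >= 0")
        if any(s < 1 for s in self.planted_class_sizes):
            raise ConfigError("planted class sizes must be >= 1")
        if self.min_background_class_size < 1:
            raise ConfigError("min_background_class_size must be >= 1")
        names = {t.upper() for t in self.tables}
        if names - {"PERSON"} and "PERSON" not in names:
            raise ConfigError("emitting an event table requires PERSON")

    @property
    def all_planted_sizes(self) -> list:
        return list(self.planted_class_sizes) + [1] * self.planted_unique


def _codes(rng: np.random.Generator, n: int, length: int) -> list:
    """n distinct alphanumeric codes of the given length."""
    out: list = []
    seen = set()
    while len(out) < n:
        c = "".join(rng.choice(_CODE_ALPHABET, size=length))
        if c not in seen:
            seen.add(c)
            out.append(c)
    return out


def _zipf_probs(m: int, s: float) -> np.ndarray:
    ranks = np.arange(1, m + 1, dtype=float)
    p = ranks**-s
    return p / p.sum()


def _fill_qi_columns(
    df: pd.DataFrame,
    qis: Sequence[str],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> None:
    """Draw coded quasi-identifier columns, plant exact-size classes, and
    floor the background class sizes."""
    n = len(df)
    sizes = config.all_planted_sizes
    planted_total = sum(sizes)
    if planted_total > n:
        raise ConfigError(
            f"planted class sizes need {planted_total} rows but the table has {n}"
        )
    for q in qis:
        m = config.qi_cardinalities.get(q, DEFAULT_CARDINALITY)
        if m < 1:
            raise ConfigError(f"cardinality for {q!r} must be >= 1")
        length = int(rng.integers(3, 9))
        domain = _codes(rng, m, length)
        draws = rng.choice(m, size=n, p=_zipf_probs(m, config.skew))
        df[q] = [domain[i] for i in draws]

    if not qis:
        return

    # plant exact-size classes on reserved, mutually distinct tuples
    positions = rng.choice(n, size=planted_total, replace=False)
    cursor = 0
    planted_rows = []
    for j, s in enumerate(sizes):
        rows = positions[cursor : cursor + s]
        cursor += s
        planted_rows.extend(rows)
        for q in qis:
            df.loc[df.index[rows], q] = f"{_RESERVED_PREFIX}{j:05d}"

    # floor background class sizes so rare tuples are only the planted ones
    background = np.setdiff1d(np.arange(n), np.array(planted_rows, dtype=int))
    if background.size == 0:
        return
    floor = config.min_background_class_size
    keys = pd.Series(
        list(zip(*(df[q].to_numpy()[background] for q in qis))), index=background
    )
    counts = keys.value_counts()
    big = counts[counts >= floor]
    small_keys = set(counts[counts < floor].index)
    if not small_keys:
        return
    if big.empty:
        if background.size < floor:
            raise ConfigError(
                "too few background rows to satisfy min_background_class_size"
            )
        modal = keys.iloc[0]
    else:
        modal = big.index[0]
    move = keys[keys.isin(small_keys)].index
    for q, val in zip(qis, modal):
        df.loc[df.index[move], q] = val


def _fill_column(
    df: pd.DataFrame,
    table: str,
    col: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> None:
    n = len(df)
    base = np.datetime64("2015-01-01")
    if col == "person_source_value":
        df[col] = [f"{i:010d}" for i in rng.permutation(n) + 1_000_000_000]
    elif col in ("sig", "note_text", "value_as_string", "note_title"):
        df[col] = [f"free text {int(v)}" for v in rng.integers(0, 1000, size=n)]
    elif col == "address_1":
        df[col] = [f"{int(v)} Main St" for v in rng.integers(1, 999, size=n)]
    elif col in ("address_2", "zip"):
        df[col] = [f"{int(v):05d}" for v in rng.integers(0, 99999, size=n)]
    elif col in ("latitude", "longitude"):
        df[col] = np.round(rng.uniform(-90, 90, size=n), 4)
    elif col.endswith("_source_concept_id"):
        df[col] = 0
    elif col.endswith("_concept_id"):
        df[col] = rng.integers(1000, 1100, size=n)
    elif "datetime" in col:
        offs = rng.integers(0, 1500, size=n)
        df[col] = [str(base + np.timedelta64(int(o), "D")) + " 00:00:00" for o in offs]
    elif "date" in col or col == "measurement_time":
        offs = rng.integers(0, 1500, size=n)
        df[col] = [str(base + np.timedelta64(int(o), "D")) for o in offs]
    elif col in ("quantity", "refills", "days_supply", "value_as_number",
                 "range_low", "range_high"):
        df[col] = rng.integers(1, 50, size=n)
    elif col in ("year_of_birth",):
        df[col] = rng.integers(1930, 2010, size=n)
    elif col in ("month_of_birth",):
        df[col] = rng.integers(1, 13, size=n)
    elif col in ("day_of_birth",):
        df[col] = rng.integers(1, 29, size=n)
    else:
        df[col] = ""


def generate(config: GeneratorConfig, registry: SchemaRegistry | None = None) -> dict:
    """Generate the configured tables as DataFrames keyed by CDM table name.

    Deterministic per seed: the same configuration yields byte-identical
    tables.  Every table carries the exact registered column set; the planted
    class-size spectrum is exact by construction.
    """
    registry = registry or SchemaRegistry.bundled()
    rng = np.random.default_rng(config.seed)
    out: dict = {}
    for name in config.tables:
        t = name.upper()
        columns = registry.columns(t)
        if t == "PERSON":
            n = config.n_persons
        else:
            n = int(rng.poisson(config.rows_per_person, config.n_persons).sum())
        df = pd.DataFrame(index=range(n))
        qis = [q for q in registry.quasi_identifiers_for(t)
               if q in columns and registry.classify_field(t, q).action == "mask"]
        pk = columns[0]
        df[pk] = np.arange(1, n + 1)
        if "person_id" in columns and t != "PERSON":
            df["person_id"] = rng.integers(1, config.n_persons + 1, size=n)
        elif t == "PERSON":
            df["person_id"] = np.arange(1, n + 1)
        _fill_qi_columns(df, qis, config, rng)
        for col in columns:
            if col not in df.columns:
                _fill_column(df, t, col, config, rng)
        out[t] = df[columns].astype(str)
    return out


def summarize(tables: Mapping) -> pd.DataFrame:
    """Per-table value counts (rows x cols), the layout of a database census."""
    rows = [
        {
            "table": name,
            "n_rows": len(df),
            "n_cols": df.shape[1],
            "n_values": int(len(df) * df.shape[1]),
        }
        for name, df in tables.items()
    ]
    return pd.DataFrame(rows, columns=["table", "n_rows", "n_cols", "n_values"])
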