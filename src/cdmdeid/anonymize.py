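"""End-to-end anonymization: field rules, lattice search, suppression.

The strategy runner mirrors a configuration → exploration → risk-analysis
flow.  Per table:

1. oversized tables are down-sampled to the analysis cell budget;
2. the pre-anonymization prosecutor risk is measured on the raw
   source-value quasi-identifier combination;
3. field rules are applied (removal, partial address removal, free-text
   redaction; maskable fields stay at hierarchy level 0 for the lattice to
   generalize);
4. the full cross-product lattice of per-field generalization levels is
   enumerated exhaustively and the feasible node of minimal information loss
   is chosen — a node is feasible when, after discarding equivalence classes
   that violate the configured privacy model, the discarded fraction stays
   within the suppression limit;
5. violating classes are suppressed (whole rows) and the post-anonymization
   risk is measured on the retained records.

Information loss at a node is the mean relative generalization level over
the quasi-identifiers plus the suppressed row fraction, weighted 1:1; ties
break toward the lexicographically smallest level vector, so the search is
deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InfeasibleModelError
from .privacy import (
    EquivalenceClass,
    PrivacyConfig,
    _class_and_global_dists,
    distribution_distance,
    partition,
    satisfies_k,
    satisfies_l,
    satisfies_t,
)
from .risk import RiskReport, prosecutor_risk
from .schema import SchemaRegistry
from .transforms import (
    REMOVED,
    Hierarchy,
    build_masking_hierarchy,
    nlp_redact,
    partial_remove_address,
)

#: ARX-style analysis budget: rows x cols may not exceed 2^32 - 1.
MAX_ANALYSIS_CELLS = 2**32 - 1


@dataclass(frozen=True)
class LatticeNode:
    """One point of the generalization lattice: a level per quasi-identifier."""

    levels: tuple
    loss: float = 0.0
    feasible: bool = False
    suppressed_fraction: float = 0.0


@dataclass
class AnonymizationResult:
    """Transformed tables plus the choices and diagnostics behind them."""

    tables: dict
    chosen_nodes: dict
    suppressed: dict  # table -> {"count": int, "fraction": float}
    classes: dict  # table -> final equivalence classes
    reports: dict  # table -> {"before": RiskReport, "after": RiskReport}
    config: PrivacyConfig


def apply_field_rules(dataset: Mapping, registry: SchemaRegistry) -> dict:
    """Apply the per-field de-identification rules to every table.

    Removal blanks the whole column (schema preserved, values erased);
    partial removal erases address lines and keeps a short zip prefix;
    free-text redaction erases the value.  Maskable fields are left at
    generalization level 0 — the lattice search decides their depth.
    Sensitive and insensitive fields pass through untouched.  Columns the
    registry does not know are retained unchanged (insensitive by default).
    """
    out = {}
    for name, df in dataset.items():
        t = name.upper()
        registry.columns(t)  # raises UnregisteredTableError for unknown tables
        df = df.copy()
        for col in df.columns:
            rule = registry.classify_field(t, col)
            if rule.action == "remove":
                df[col] = REMOVED
            elif rule.action == "nlp_redact":
                df[col] = df[col].map(lambda v: nlp_redact(v))
            elif rule.action == "partial_remove":
                if col.lower() == "address_2":
                    df[col] = df[col].map(
                        lambda v: partial_remove_address(None, v)[1]
                    )
                else:
                    df[col] = REMOVED
        out[t] = df
    return out


def generalize(
    df: pd.DataFrame,
    quasi_identifiers: Sequence[str],
    hierarchies: Mapping[str, Hierarchy],
    levels: Sequence[int],
) -> pd.DataFrame:
    """Full-domain global recoding: every cell of QI *i* generalized to
    ``levels[i]`` of its hierarchy."""
    df = df.copy()
    for q, lvl in zip(quasi_identifiers, levels):
        if lvl:
            h = hierarchies[q]
            df[q] = df[q].map(lambda v: h.apply(v, lvl))
    return df


def violating_classes(
    classes: Sequence[EquivalenceClass],
    config: PrivacyConfig,
    sensitive_field: str | None = None,
) -> list:
    """Classes that violate the configured model (one pass).

    For t-closeness the global distribution is taken over the classes as
    given, so repeated suppress/recheck rounds converge to a fixed point.
    """
    if config.model == "k_anonymity":
        return [c for c in classes if c.size < config.k]
    if sensitive_field is None:
        raise ConfigError(f"{config.model} requires a sensitive field")
    if config.model == "l_diversity":
        return [c for c in classes if c.distinct_sensitive(sensitive_field) < config.l]
    # t_closeness
    classes = list(classes)
    if not classes:
        return []
    per_class, global_dist = _class_and_global_dists(classes, sensitive_field)
    return [
        c
        for c, p in zip(classes, per_class)
        if distribution_distance(p, global_dist, config.ground) > config.t + 1e-12
    ]


def suppress_violating_classes(
    dataset: pd.DataFrame,
    classes: Sequence[EquivalenceClass],
    config: PrivacyConfig,
    sensitive_field: str | None = None,
):
    """Drop whole rows of classes violating the model.

    Returns ``(retained dataframe, suppressed row count)``; the count is the
    sum of the violating class sizes.  One pass: for t-closeness, suppression
    shifts the global distribution, so callers loop until no class violates.
    """
    bad = violating_classes(classes, config, sensitive_field)
    if not bad:
        return dataset, 0
    drop = np.concatenate([np.asarray(c.row_indices) for c in bad])
    keep = np.setdiff1d(np.arange(len(dataset)), drop)
    return dataset.iloc[keep].reset_index(drop=True), int(len(drop))


def _enforce(
    df: pd.DataFrame,
    quasi_identifiers: Sequence[str],
    config: PrivacyConfig,
    sensitive_field: str | None,
):
    """Suppress until the retained classes satisfy the model (fixed point).

    Returns ``(retained df, final classes, total suppressed)``.
    """
    sens = [sensitive_field] if sensitive_field else []
    total = 0
    while True:
        classes = partition(df, quasi_identifiers, sens)
        bad = violating_classes(classes, config, sensitive_field)
        if not bad:
            return df, classes, total
        df, n = suppress_violating_classes(df, classes, config, sensitive_field)
        total += n


def _satisfied(classes, config, sensitive_field):
    if config.model == "k_anonymity":
        return satisfies_k(classes, config.k)
    if config.model == "l_diversity":
        return satisfies_l(classes, sensitive_field, config.l)
    return satisfies_t(classes, sensitive_field, config.t, config.ground)


def search_lattice(
    dataset: pd.DataFrame,
    quasi_identifiers: Sequence[str],
    hierarchies: Mapping[str, Hierarchy],
    config: PrivacyConfig,
    sensitive_field: str | None = None,
) -> LatticeNode:
    """Exhaustively enumerate the generalization lattice and return the
    feasible node of minimal information loss.

    Raises :class:`InfeasibleModelError` when no node satisfies the model
    within the suppression limit (the caller may raise the limit).
    """
    for q in quasi_identifiers:
        if q not in hierarchies:
            raise ConfigError(f"no hierarchy for quasi-identifier {q!r}")
    max_levels = [hierarchies[q].max_level for q in quasi_identifiers]
    n = len(dataset)
    best: LatticeNode | None = None
    best_key = None
    for levels in itertools.product(*(range(m + 1) for m in max_levels)):
        gen = generalize(dataset, quasi_identifiers, hierarchies, levels)
        _, classes, suppressed = _enforce(gen, quasi_identifiers, config, sensitive_field)
        frac = suppressed / n if n else 0.0
        feasible = frac <= config.suppression_limit + 1e-12
        gen_loss = (
            float(np.mean([lvl / m if m else 0.0 for lvl, m in zip(levels, max_levels)]))
            if max_levels
            else 0.0
        )
        loss = gen_loss + frac
        if feasible:
            key = (loss, levels)
            if best_key is None or key < best_key:
                best_key = key
                best = LatticeNode(levels, loss=loss, feasible=True, suppressed_fraction=frac)
    if best is None:
        raise InfeasibleModelError(
            "no feasible transformation: every lattice node exceeds the "
            f"suppression limit {config.suppression_limit:g}"
        )
    return best


def sample_for_analysis(
    dataset: pd.DataFrame, max_cells: int = MAX_ANALYSIS_CELLS, seed: int = 0
) -> pd.DataFrame:
    """Uniform row sample (without replacement) for tables whose rows x cols
    exceed the analysis cell budget; identity otherwise.  Reproducible from
    ``seed``; retained rows keep their original order."""
    n, cols = dataset.shape
    if cols and max_cells < cols:
        raise ConfigError("max_cells smaller than a single row")
    if n * cols <= max_cells or cols == 0:
        return dataset
    target = max_cells // cols
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=target, replace=False))
    return dataset.iloc[keep].reset_index(drop=True)


def _auto_sensitive(registry: SchemaRegistry, table: str, df: pd.DataFrame) -> str | None:
    for f in registry.sensitive_fields_for(table):
        if f in df.columns:
            return f
    return None


def run_strategy(
    dataset: Mapping,
    registry: SchemaRegistry,
    config: PrivacyConfig,
    seed: int = 0,
    max_cells: int = MAX_ANALYSIS_CELLS,
) -> AnonymizationResult:
    """Run the full de-identification strategy over every table.

    Each table is processed independently: sample → before-risk on the raw
    source-value quasi-identifiers → field rules → lattice search →
    suppression → after-risk.  Returns the anonymized tables together with
    paired before/after risk reports, the chosen lattice node and the
    suppression statistics per table.
    """
    tables, nodes, suppressed, all_classes, reports = {}, {}, {}, {}, {}
    for name in dataset:
        t = name.upper()
        df = dataset[name]
        registry.columns(t)
        df = sample_for_analysis(df, max_cells, seed)
        raw_qis = [c for c in registry.raw_fields_for(t) if c in df.columns]
        before = prosecutor_risk(partition(df, raw_qis), config.risk_threshold)

        if len(df) == 0:
            tables[t] = df.copy()
            nodes[t] = None
            suppressed[t] = {"count": 0, "fraction": 0.0}
            all_classes[t] = []
            reports[t] = {"before": before, "after": prosecutor_risk([], config.risk_threshold)}
            continue

        transformed = apply_field_rules({t: df}, registry)[t]
        qis = [c for c in registry.quasi_identifiers_for(t) if c in df.columns]
        sensitive = None
        if config.model in ("l_diversity", "t_closeness"):
            sensitive = config.sensitive_for(t) or _auto_sensitive(registry, t, df)
            if sensitive is None:
                raise ConfigError(
                    f"{config.model} requires a sensitive field but table {t} has none"
                )
        hierarchies = {
            q: build_masking_hierarchy(transformed[q], field_name=q) for q in qis
        }
        node = search_lattice(transformed, qis, hierarchies, config, sensitive)
        gen = generalize(transformed, qis, hierarchies, node.levels)
        final_df, final_classes, n_sup = _enforce(gen, qis, config, sensitive)

        tables[t] = final_df
        nodes[t] = node
        suppressed[t] = {"count": n_sup, "fraction": n_sup / len(df)}
        all_classes[t] = final_classes
        reports[t] = {
            "before": before,
            "after": prosecutor_risk(final_classes, config.risk_threshold),
        }
    return AnonymizationResult(
        tables=tables,
        chosen_nodes=nodes,
        suppressed=suppressed,
        classes=all_classes,
        reports=reports,
        config=config,
    )
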