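"""Field-rule application, lattice search, suppression, strategy runner."""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdmdeid import (
    GeneratorConfig,
    InfeasibleModelError,
    PrivacyConfig,
    UnregisteredTableError,
    apply_field_rules,
    build_masking_hierarchy,
    generate,
    partition,
    run_strategy,
    sample_for_analysis,
    search_lattice,
    suppress_violating_classes,
)
from cdmdeid.anonymize import generalize
from cdmdeid.errors import ConfigError


class TestApplyFieldRules:
    def test_person_key_removed(self, registry):
        df = pd.DataFrame({"person_source_value": ["1234567890"],
                           "gender_source_value": ["M"]})
        out = apply_field_rules({"PERSON": df}, registry)["PERSON"]
        assert out["person_source_value"].tolist() == [""]
        assert out["gender_source_value"].tolist() == ["M"]  # level 0 = identity

    def test_location_geocodes_removed_address_partial(self, registry):
        df = pd.DataFrame({"latitude": ["37.5"], "longitude": ["127.0"],
                           "address_1": ["12 Main St"], "address_2": ["02841"]})
        out = apply_field_rules({"LOCATION": df}, registry)["LOCATION"]
        assert out["latitude"].tolist() == [""]
        assert out["longitude"].tolist() == [""]
        assert out["address_1"].tolist() == [""]
        assert out["address_2"].tolist() == ["028**"]

    def test_free_text_redacted(self, registry):
        df = pd.DataFrame({"sig": ["take 1 tab PO qd"], "quantity": ["30"]})
        out = apply_field_rules({"DRUG_EXPOSURE": df}, registry)["DRUG_EXPOSURE"]
        assert out["sig"].tolist() == [""]
        assert out["quantity"].tolist() == ["30"]  # sensitive data untouched

    def test_empty_table_schema_preserved(self, registry):
        df = pd.DataFrame(columns=["person_source_value", "gender_source_value"])
        out = apply_field_rules({"PERSON": df}, registry)["PERSON"]
        assert list(out.columns) == list(df.columns) and len(out) == 0

    def test_unknown_table_rejected(self, registry):
        with pytest.raises(UnregisteredTableError):
            apply_field_rules({"NOT_A_TABLE": pd.DataFrame()}, registry)


def _mask(value: str, level: int) -> str:
    # independent re-statement of suffix masking for the oracle
    return value[: max(len(value) - level, 0)] + "*" * level


def brute_force_search(df, qis, hierarchies, k, suppression_limit):
    """Independent exhaustive lattice enumeration for the k-model: plain
    loops and Counters, minimal (loss, levels) among feasible nodes."""
    max_levels = [hierarchies[q].max_level for q in qis]
    n = len(df)
    best = None
    for levels in itertools.product(*(range(m + 1) for m in max_levels)):
        tuples = [
            tuple(_mask(str(df[q].iloc[i]), lv) for q, lv in zip(qis, levels))
            for i in range(n)
        ]
        counts = Counter(tuples)
        suppressed = sum(c for c in counts.values() if c < k)
        frac = suppressed / n if n else 0.0
        if frac > suppression_limit + 1e-12:
            continue
        gen_loss = sum(lv / m if m else 0.0 for lv, m in zip(levels, max_levels)) / len(qis)
        key = (gen_loss + frac, levels)
        if best is None or key < best:
            best = key
    return best


class TestSearchLattice:
    def _hier(self, df, qis):
        return {q: build_masking_hierarchy(df[q], field_name=q) for q in qis}

    def test_identity_chosen_when_already_uniform(self):
        df = pd.DataFrame({"a": ["XX"] * 5, "b": ["YY"] * 5})
        node = search_lattice(df, ["a", "b"], self._hier(df, ["a", "b"]),
                              PrivacyConfig(k=3, suppression_limit=0.0))
        assert node.levels == (0, 0) and node.loss == 0.0

    def test_full_suppression_node_when_k_unreachable(self):
        # two 1-character QIs, every level-0 class of size 1, k = 3: only the
        # top node (1, 1) collapses all rows into one class without suppression
        df = pd.DataFrame({"a": list("ABCD"), "b": list("EFGH")})
        node = search_lattice(df, ["a", "b"], self._hier(df, ["a", "b"]),
                              PrivacyConfig(k=3, suppression_limit=0.0))
        assert node.levels == (1, 1)

    def test_infeasible_raises(self):
        # unique single-character QI, k=3, no suppression allowed: even the
        # top level collapses to one class -- so make each value distinct at
        # every level by using k larger than n
        df = pd.DataFrame({"a": ["A", "B", "C"]})
        with pytest.raises(InfeasibleModelError):
            search_lattice(df, ["a"], self._hier(df, ["a"]),
                           PrivacyConfig(k=5, suppression_limit=0.0))

    def test_missing_hierarchy_rejected(self):
        df = pd.DataFrame({"a": ["A"]})
        with pytest.raises(ConfigError):
            search_lattice(df, ["a"], {}, PrivacyConfig())

    @given(st.data())
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_matches_brute_force_enumeration(self, data):
        n = data.draw(st.integers(min_value=1, max_value=25))
        codes1 = st.sampled_from(["A1", "B2", "C3"])
        codes2 = st.sampled_from(["XX1", "YY2"])
        df = pd.DataFrame({
            "q1": data.draw(st.lists(codes1, min_size=n, max_size=n)),
            "q2": data.draw(st.lists(codes2, min_size=n, max_size=n)),
        })
        k = data.draw(st.integers(min_value=1, max_value=4))
        limit = data.draw(st.sampled_from([0.0, 0.25, 1.0]))
        hier = self._hier(df, ["q1", "q2"])
        cfg = PrivacyConfig(k=k, suppression_limit=limit)
        expected = brute_force_search(df, ["q1", "q2"], hier, k, limit)
        if expected is None:
            with pytest.raises(InfeasibleModelError):
                search_lattice(df, ["q1", "q2"], hier, cfg)
        else:
            node = search_lattice(df, ["q1", "q2"], hier, cfg)
            assert node.levels == expected[1]
            assert node.loss == pytest.approx(expected[0])


class TestSuppression:
    def test_small_classes_discarded(self):
        df = pd.DataFrame({"q": ["a"] * 2 + ["b"] * 3 + ["c"] * 4})
        classes = partition(df, ["q"])
        out, n = suppress_violating_classes(df, classes, PrivacyConfig(k=3))
        assert n == 2 and len(out) == 7 and "a" not in set(out["q"])

    def test_compliant_classes_untouched(self):
        df = pd.DataFrame({"q": ["a"] * 3 + ["b"] * 3})
        classes = partition(df, ["q"])
        out, n = suppress_violating_classes(df, classes, PrivacyConfig(k=3))
        assert n == 0 and out is df

    def test_t_closeness_removes_distant_class(self):
        # global x:y = 7:3; class "a" is all-x (distance 0.3), class "b" is
        # 5x:3y (distance 0.075) -- only "a" violates t = 0.1
        df = pd.DataFrame({"q": ["a"] * 2 + ["b"] * 8,
                           "s": ["x"] * 2 + ["x"] * 5 + ["y"] * 3})
        classes = partition(df, ["q"], ["s"])
        cfg = PrivacyConfig(model="t_closeness", t=0.1)
        out, n = suppress_violating_classes(df, classes, cfg, sensitive_field="s")
        assert n == 2 and set(out["q"]) == {"b"}

    @given(st.lists(st.integers(min_value=1, max_value=8), min_size=1, max_size=12))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_suppressed_count_monotone_in_k(self, sizes):
        """With the transformation fixed, raising k can only discard more."""
        df = pd.DataFrame({"q": [f"c{i}" for i, s in enumerate(sizes) for _ in range(s)]})
        classes = partition(df, ["q"])
        counts = [suppress_violating_classes(df, classes, PrivacyConfig(k=k))[1]
                  for k in range(1, 10)]
        assert counts == sorted(counts)


class TestSampleForAnalysis:
    def test_identity_within_budget(self):
        df = pd.DataFrame(np.zeros((10, 5)))
        assert sample_for_analysis(df, 2**32 - 1, seed=1) is df

    def test_downsampled_to_cell_budget(self):
        df = pd.DataFrame(np.arange(1000).reshape(100, 10))
        out = sample_for_analysis(df, 500, seed=1)
        assert len(out) == 50  # floor(500 / 10)

    def test_budget_below_one_row_rejected(self):
        df = pd.DataFrame(np.zeros((2, 10)))
        with pytest.raises(ConfigError):
            sample_for_analysis(df, 5, seed=1)

    def test_reproducible_and_order_preserving(self):
        df = pd.DataFrame({"x": np.arange(100), "y": np.arange(100)})
        a = sample_for_analysis(df, 40, seed=9)
        b = sample_for_analysis(df, 40, seed=9)
        assert a.equals(b)
        assert (np.diff(a["x"].to_numpy()) > 0).all()


def _drug_config(**kw):
    return GeneratorConfig(
        n_persons=80, tables=("PERSON", "DRUG_EXPOSURE"), rows_per_person=3.0,
        qi_cardinalities={"drug_source_value": 6, "route_source_value": 3,
                          "dose_unit_source_value": 2}, seed=kw.pop("seed", 11), **kw)


class TestRunStrategy:
    def test_planted_unique_gives_100_before(self, registry):
        data = generate(GeneratorConfig(n_persons=60, planted_unique=2, seed=5))
        res = run_strategy(data, registry, PrivacyConfig(k=3))
        assert res.reports["PERSON"]["before"].highest_risk == 100.0

    def test_k_anonymity_risk_ceiling(self, registry):
        data = generate(_drug_config())
        res = run_strategy(data, registry, PrivacyConfig(model="k_anonymity", k=3))
        for table, pair in res.reports.items():
            after = pair["after"]
            if after.n_records:
                assert after.highest_risk <= 100.0 / 3 + 1e-9
            assert res.suppressed[table]["fraction"] <= 1.0

    def test_l_diversity_risk_ceiling(self, registry):
        data = generate(_drug_config(seed=13))
        cfg = PrivacyConfig(model="l_diversity", l=3,
                            sensitive_field={"DRUG_EXPOSURE": "quantity",
                                             "PERSON": "year_of_birth"})
        res = run_strategy(data, registry, cfg)
        after = res.reports["DRUG_EXPOSURE"]["after"]
        if after.n_records:
            assert after.highest_risk <= 100.0 / 3 + 1e-9

    def test_t_closeness_classes_within_t(self, registry):
        from cdmdeid import satisfies_t

        data = generate(_drug_config(seed=17))
        cfg = PrivacyConfig(model="t_closeness", t=0.3,
                            sensitive_field={"DRUG_EXPOSURE": "quantity",
                                             "PERSON": "year_of_birth"})
        res = run_strategy(data, registry, cfg)
        classes = res.classes["DRUG_EXPOSURE"]
        if classes:
            assert satisfies_t(classes, "quantity", 0.3)

    def test_empty_table_zeroed_report(self, registry):
        df = pd.DataFrame(columns=registry.columns("PERSON"))
        res = run_strategy({"PERSON": df}, registry, PrivacyConfig(k=3))
        assert res.reports["PERSON"]["after"].n_records == 0
        assert len(res.tables["PERSON"]) == 0

    def test_deterministic_under_fixed_seed(self, registry):
        data = generate(_drug_config())
        r1 = run_strategy(data, registry, PrivacyConfig(k=3), seed=2)
        r2 = run_strategy(data, registry, PrivacyConfig(k=3), seed=2)
        for t in r1.tables:
            assert r1.tables[t].equals(r2.tables[t])
            assert r1.chosen_nodes[t] == r2.chosen_nodes[t]
            assert r1.reports[t]["after"] == r2.reports[t]["after"]
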