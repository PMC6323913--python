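"""Assignment engine: step/property semantics, ordering, reports."""

import numpy as np
import pytest

from conftest import (
    fixed_point_states,
    make_prop,
    make_step,
    table_from_pairs,
)
from genprops.assign import (
    evaluate_all,
    evaluate_property,
    evaluate_step,
    long_report,
    protein_report,
    summary_report,
)
from genprops.matches import MatchTable, parse_interproscan_tsv
from genprops.model import (
    GraphCycleError,
    PropertyRegistry,
    PropertyType,
    ResultState,
)
from genprops.synthetic import FixtureConfig, make_matches, make_registry, random_feasible_states


def prop_with_required(accession="GenProp0001", n_required=3, threshold=0, n_optional=0):
    steps = [make_step(i + 1, [f"IPR{i:06d}"]) for i in range(n_required)]
    steps += [
        make_step(n_required + j + 1, [f"IPR{900 + j:06d}"], required=False)
        for j in range(n_optional)
    ]
    return make_prop(accession, threshold=threshold, steps=steps)


def table_matching_steps(prop, indices):
    """Table matching the given step positions (one protein per evidence)."""
    pairs = []
    for i, step in enumerate(prop.steps):
        if i in indices:
            pairs.append((f"prot{i}", step.evidences[0].accession))
    return table_from_pairs(pairs)


class TestEvaluateStep:
    def test_interpro_evidence_lists_matching_proteins(self):
        step = make_step(1, ["IPR000001"])
        table = table_from_pairs([("p1", "IPR000001"), ("p2", "IPR000001")])
        result = evaluate_step(step, table, {})
        assert result.matched
        assert result.matched_by == (("IPR000001", ("p1", "p2")),)

    def test_any_evidence_line_suffices(self):
        step = make_step(1, ["IPR000001", "IPR000002"])
        table = table_from_pairs([("p1", "IPR000002")])
        result = evaluate_step(step, table, {})
        assert result.matched
        assert result.matched_by[0][0] == "IPR000002"

    def test_genprop_evidence_requires_yes_unless_flagged(self):
        step = make_step(1, ["GenProp0002"])
        table = MatchTable(label="empty")
        sub_partial = {
            "GenProp0002": evaluate_property(
                prop_with_required("GenProp0002", 2, 0), table_matching_steps(
                    prop_with_required("GenProp0002", 2, 0), {0}), {})
        }
        assert sub_partial["GenProp0002"].state is ResultState.PARTIAL
        assert not evaluate_step(step, table, sub_partial).matched
        flagged = evaluate_step(step, table, sub_partial, partial_counts=True)
        assert flagged.matched
        assert flagged.matched_by == (("GenProp0002", ()),)

    def test_unresolved_genprop_evidence_is_programming_error(self):
        step = make_step(1, ["GenProp0002"])
        with pytest.raises(KeyError):
            evaluate_step(step, MatchTable(label="x"), {})

    def test_signature_fallback_behind_flag(self):
        from genprops.model import Evidence, Step
        step = Step(number=1, id="s1", required=True,
                    evidences=(Evidence("IPR000001", ("PF00001",)),))
        table = MatchTable(label="t", signature_matches={"p1": {"PF00001"}})
        assert not evaluate_step(step, table, {}).matched
        assert evaluate_step(step, table, {}, use_signatures=True).matched


class TestEvaluateProperty:
    @pytest.mark.parametrize(
        "matched, expected",
        [(3, ResultState.YES), (2, ResultState.PARTIAL), (1, ResultState.NO),
         (0, ResultState.NO)],
    )
    def test_three_required_threshold_one(self, matched, expected):
        prop = prop_with_required(n_required=3, threshold=1)
        table = table_matching_steps(prop, set(range(matched)))
        result = evaluate_property(prop, table, {})
        assert result.state is expected
        assert result.required_matched == matched
        assert result.required_total == 3

    def test_optional_steps_never_change_state(self):
        prop = prop_with_required(n_required=2, threshold=0, n_optional=1)
        # both required matched, optional not -> YES
        table = table_matching_steps(prop, {0, 1})
        assert evaluate_property(prop, table, {}).state is ResultState.YES
        # only the optional matched -> still NO
        table = table_matching_steps(prop, {2})
        result = evaluate_property(prop, table, {})
        assert result.state is ResultState.NO
        assert result.step_results[2].matched

    def test_zero_steps_is_no_with_warning(self):
        prop = make_prop("GenProp0001")
        with pytest.warns(UserWarning, match="no steps"):
            assert evaluate_property(prop, MatchTable(label="x"), {}).state is ResultState.NO

    def test_all_optional_property_never_yes(self):
        steps = [make_step(1, ["IPR000001"], required=False)]
        prop = make_prop("GenProp0001", steps=steps)
        table = table_from_pairs([("p1", "IPR000001")])
        assert evaluate_property(prop, table, {}).state is ResultState.NO

    def test_threshold_boundary_exhaustive_small(self):
        for r in range(1, 7):
            for t in range(0, r):
                prop = prop_with_required(n_required=r, threshold=t)
                for m in range(0, r + 1):
                    state = evaluate_property(
                        prop, table_matching_steps(prop, set(range(m))), {}
                    ).state
                    if m == r:
                        assert state is ResultState.YES
                    elif m > t:
                        assert state is ResultState.PARTIAL
                    else:
                        assert state is ResultState.NO


class TestEvaluateAll:
    def test_metapath_partial_from_mixed_children(self, two_leaf_registry):
        # leaf A fully matched -> YES; leaf B unmatched -> NO
        table = table_from_pairs([("p1", "IPR900001"), ("p2", "IPR900002")])
        results = evaluate_all(two_leaf_registry, table)
        assert results["GenProp0001"].state is ResultState.YES
        assert results["GenProp0002"].state is ResultState.NO
        # metapath: 2 required, threshold 0, 1 matched -> PARTIAL
        assert results["GenProp0010"].state is ResultState.PARTIAL

    def test_empty_table_gives_all_no(self, two_leaf_registry):
        results = evaluate_all(two_leaf_registry, MatchTable(label="empty"))
        assert {r.state for r in results.values()} == {ResultState.NO}

    def test_every_property_gets_exactly_one_result(self, two_leaf_registry):
        results = evaluate_all(two_leaf_registry, MatchTable(label="empty"))
        assert sorted(results) == two_leaf_registry.accessions()

    def test_cycle_aborts_with_path(self):
        a = make_prop("GenProp0001", ptype=PropertyType.METAPATH,
                      steps=[make_step(1, ["GenProp0002"])])
        b = make_prop("GenProp0002", ptype=PropertyType.METAPATH,
                      steps=[make_step(1, ["GenProp0001"])])
        with pytest.raises(GraphCycleError) as err:
            evaluate_all(PropertyRegistry([a, b]), MatchTable(label="x"))
        assert set(err.value.cycle) >= {"GenProp0001", "GenProp0002"}

    def test_dangling_evidence_rejected(self):
        a = make_prop("GenProp0001", ptype=PropertyType.METAPATH,
                      steps=[make_step(1, ["GenProp0099"])])
        with pytest.raises(KeyError, match="GenProp0099"):
            evaluate_all(PropertyRegistry([a]), MatchTable(label="x"))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_fixed_point_oracle_on_random_inputs(self, seed):
        """Topological evaluation equals brute-force fixed-point iteration."""
        rng = np.random.default_rng(seed)
        registry = make_registry(FixtureConfig(seed=seed))
        evidence = sorted(registry.evidence_accessions())
        chosen = [a for a in evidence if rng.random() < 0.4]
        table = table_from_pairs([(f"p_{a}", a) for a in chosen])
        results = evaluate_all(registry, table)
        oracle = fixed_point_states(registry, table)
        assert {a: r.state for a, r in results.items()} == oracle

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_added_matches(self, seed):
        """Adding matches can only promote states (NO -> PARTIAL -> YES)."""
        rng = np.random.default_rng(seed)
        registry = make_registry(FixtureConfig(seed=seed))
        evidence = sorted(registry.evidence_accessions())
        base = [a for a in evidence if rng.random() < 0.3]
        extra = base + [a for a in evidence if rng.random() < 0.3]
        small = evaluate_all(registry, table_from_pairs([(f"p_{a}", a) for a in base]))
        large = evaluate_all(registry, table_from_pairs([(f"p_{a}", a) for a in extra]))
        for acc in registry.accessions():
            assert large[acc].state >= small[acc].state


@pytest.fixture
def single_yes_results(two_leaf_registry):
    """Leaf A YES (both steps), everything else NO."""
    table = table_from_pairs([("p1", "IPR900001"), ("p2", "IPR900002")])
    registry = PropertyRegistry([two_leaf_registry["GenProp0001"]])
    return registry, evaluate_all(registry, table)


class TestReports:
    def test_summary_one_row_per_property(self, single_yes_results):
        registry, results = single_yes_results
        lines = summary_report(results, registry).splitlines()
        assert lines[0] == "accession\tname\tstate"
        assert len(lines) == 2
        assert lines[1].startswith("GenProp0001\t") and lines[1].endswith("\tYES")

    def test_long_adds_one_row_per_step(self, single_yes_results):
        registry, results = single_yes_results
        lines = long_report(results, registry).splitlines()
        assert len(lines) == 1 + 3  # header + property row + 2 step rows
        assert lines[2].split("\t")[1] == "1"
        assert lines[2].endswith("MATCHED")

    def test_protein_report_rows_equal_matched_evidence_proteins(self, single_yes_results):
        registry, results = single_yes_results
        lines = protein_report(results, registry).splitlines()
        assert lines[0] == "protein\tproperty\tstep\tevidence"
        assert lines[1:] == [
            "p1\tGenProp0001\t1\tIPR900001",
            "p2\tGenProp0001\t2\tIPR900002",
        ]

    def test_all_no_results_give_empty_protein_report(self, two_leaf_registry):
        results = evaluate_all(two_leaf_registry, MatchTable(label="empty"))
        assert protein_report(results, two_leaf_registry).splitlines()[1:] == []

    def test_state_strings_are_exact(self, two_leaf_registry):
        table = table_from_pairs([("p1", "IPR900001"), ("p2", "IPR900002")])
        results = evaluate_all(two_leaf_registry, table)
        report = summary_report(results, two_leaf_registry, include_categories=True)
        states = {line.split("\t")[2] for line in report.splitlines()[1:]}
        assert states == {"YES", "PARTIAL", "NO"}

    def test_categories_excluded_by_default(self, two_leaf_registry):
        results = evaluate_all(two_leaf_registry, MatchTable(label="empty"))
        default = summary_report(results, two_leaf_registry)
        assert "GenProp0100" not in default
        included = summary_report(results, two_leaf_registry, include_categories=True)
        assert "GenProp0100" in included

    def test_empty_results_rejected(self, two_leaf_registry):
        with pytest.raises(ValueError):
            summary_report({}, two_leaf_registry)


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", range(10))
    def test_planted_state_vectors_recovered(self, seed):
        registry = make_registry(FixtureConfig(seed=seed))
        planted = random_feasible_states(registry, seed=seed + 500)
        tsv = make_matches(registry, planted, seed=seed + 900, label="px")
        table = parse_interproscan_tsv(tsv, "px")
        results = evaluate_all(registry, table)
        assert {a: r.state for a, r in results.items()} == planted
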