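"""Model parsing, writing, SIF conversion, terminals, and verification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortpbn.model_io import (BooleanNetwork, ModelParseError,
                                SignedInteractionTable,
                                UnsupportedFeatureError, identify_terminals,
                                parse_bnet, parse_sbml_qual_subset, to_sif,
                                verify_structure, write_bnet)
from conftest import random_network


# ---------------------------------------------------------------------------
# .bnet parsing
# ---------------------------------------------------------------------------

class TestParseBnet:
    def test_single_identity_node_is_input(self):
        net = parse_bnet("targets, factors\nA, A")
        assert net.nodes == ["A"]
        assert net.rules["A"] == "A"

    def test_negative_loop_truth_tables(self, negation_loop):
        # A's rule is !B: output 1 when B=0; B's rule is A: identity
        assert negation_loop.truth_table("A") == (1, 0)
        assert negation_loop.truth_table("B") == (0, 1)

    @pytest.mark.parametrize("text,match", [
        ("targets, factors\nA, !C\n", "undeclared"),
        ("targets, factors\nA, B\nA, 1\nB, 0\n", "duplicate"),
        ("targets, factors\nA, \n", "empty rule"),
        ("A, A\n", "header"),
    ])
    def test_malformed_files_raise(self, text, match):
        with pytest.raises(ModelParseError, match=match):
            parse_bnet(text)

    def test_error_names_offending_line_and_symbol(self):
        with pytest.raises(ModelParseError) as err:
            parse_bnet("targets, factors\nA, A\nB, A & C\n")
        assert "line 3" in str(err.value) and "'C'" in str(err.value)

    def test_identifiers_are_case_preserving(self):
        net = parse_bnet("targets, factors\nFoo, Foo\nbar, !Foo")
        assert net.nodes == ["Foo", "bar"]

    def test_constant_rules_allowed(self):
        net = parse_bnet("targets, factors\nA, 1\nB, A")
        assert net.truth_table("A") == (1,)


class TestWriteBnet:
    def test_identity_net_contains_rule_line(self):
        net = BooleanNetwork(nodes=["A"], rules={"A": "A"})
        assert "A, A" in write_bnet(net)

    @pytest.mark.parametrize("seed", range(100))
    def test_roundtrip_preserves_truth_tables(self, seed):
        """parse(write(net)) must reproduce every node's truth table."""
        net = random_network(seed, n_nodes=4 + seed % 5)
        back = parse_bnet(write_bnet(net))
        assert back.nodes == net.nodes
        for node in net.nodes:
            assert back.truth_table(node) == net.truth_table(node)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.recursive(
        st.sampled_from([("var", "A"), ("var", "B"), ("const", 0),
                         ("const", 1)]),
        lambda kids: st.one_of(
            st.tuples(st.just("not"), kids),
            st.tuples(st.just("and"), kids, kids),
            st.tuples(st.just("or"), kids, kids)),
        max_leaves=8))
    def test_expression_format_parse_roundtrip(self, ast):
        """format -> parse preserves the truth table of arbitrary rule ASTs."""
        from itertools import product
        from cohortpbn.model_io import (evaluate_expression,
                                        format_expression, parse_expression)
        back = parse_expression(format_expression(ast))
        for a, b in product((0, 1), repeat=2):
            env = {"A": a, "B": b}
            assert evaluate_expression(back, env) == \
                evaluate_expression(ast, env)

    def test_roundtrip_mixed_operator_rule(self):
        net = parse_bnet("targets, factors\nA, A\nB, A\nC, (A | !B) & !(B & A)")
        back = parse_bnet(write_bnet(net))
        assert back.truth_table("C") == net.truth_table("C")


# ---------------------------------------------------------------------------
# SBML-qual subset
# ---------------------------------------------------------------------------

_QUAL_TEMPLATE = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:qual="http://www.sbml.org/sbml/level3/version1/qual/version1"
      level="3" version="1" qual:required="true">
  <model id="toy">
    <qual:listOfQualitativeSpecies>
      {species}
    </qual:listOfQualitativeSpecies>
    <qual:listOfTransitions>
      {transitions}
    </qual:listOfTransitions>
  </model>
</sbml>
"""


def _species(sid, max_level=1):
    return (f'<qual:qualitativeSpecies qual:id="{sid}" '
            f'qual:maxLevel="{max_level}" qual:constant="false"/>')


def _transition(target, mathml):
    return f"""<qual:transition qual:id="tr_{target}">
      <qual:listOfOutputs>
        <qual:output qual:qualitativeSpecies="{target}"
                     qual:transitionEffect="assignmentLevel"/>
      </qual:listOfOutputs>
      <qual:listOfFunctionTerms>
        <qual:defaultTerm qual:resultLevel="0"/>
        <qual:functionTerm qual:resultLevel="1">
          <math xmlns="http://www.w3.org/1998/Math/MathML">{mathml}</math>
        </qual:functionTerm>
      </qual:listOfFunctionTerms>
    </qual:transition>"""


class TestParseSbmlQual:
    def test_minimal_two_species_model(self):
        xml = _QUAL_TEMPLATE.format(
            species=_species("A") + _species("B"),
            transitions=_transition("B", "<ci>A</ci>"))
        net = parse_sbml_qual_subset(xml)
        assert set(net.nodes) == {"A", "B"}
        assert net.rules["B"] == "A"
        assert net.rules["A"] == "A"  # no incoming transition -> input

    def test_boolean_logic_with_thresholds(self):
        math = ("<apply><and/>"
                "<apply><eq/><ci>A</ci><cn>1</cn></apply>"
                "<apply><not/><apply><geq/><ci>B</ci><cn>1</cn></apply></apply>"
                "</apply>")
        xml = _QUAL_TEMPLATE.format(
            species=_species("A") + _species("B") + _species("C"),
            transitions=_transition("C", math))
        net = parse_sbml_qual_subset(xml)
        assert net.truth_table("C") == parse_bnet(
            "targets, factors\nA, A\nB, B\nC, A & !B").truth_table("C")

    def test_multilevel_species_rejected(self):
        xml = _QUAL_TEMPLATE.format(species=_species("A", max_level=2),
                                    transitions="")
        with pytest.raises(UnsupportedFeatureError, match="maxLevel"):
            parse_sbml_qual_subset(xml)

    def test_empty_model_rejected(self):
        xml = _QUAL_TEMPLATE.format(species="", transitions="")
        with pytest.raises(ModelParseError, match="empty model"):
            parse_sbml_qual_subset(xml)

    def test_non_boolean_math_rejected_with_construct_name(self):
        xml = _QUAL_TEMPLATE.format(
            species=_species("A") + _species("B"),
            transitions=_transition(
                "B", "<apply><plus/><ci>A</ci><cn>1</cn></apply>"))
        with pytest.raises(UnsupportedFeatureError, match="plus"):
            parse_sbml_qual_subset(xml)


# ---------------------------------------------------------------------------
# SIF export
# ---------------------------------------------------------------------------

class TestToSif:
    def test_negated_literal_is_inhibitory(self):
        net = parse_bnet("targets, factors\nA, A\nB, !A")
        assert to_sif(net) == [("A", "inhibitory", "B")]

    def test_mixed_parity_regulator_emits_two_rows(self):
        net = parse_bnet("targets, factors\nA, A\nC, A | !A")
        rows = to_sif(net)
        assert ("A", "stimulatory", "C") in rows
        assert ("A", "inhibitory", "C") in rows
        assert len(rows) == 2

    def test_identity_input_emits_no_rows(self):
        net = parse_bnet("targets, factors\nA, A")
        assert to_sif(net) == []

    @pytest.mark.parametrize("seed", range(30))
    def test_sign_matches_sensitivity_analysis_on_monotone_rules(self, seed):
        """For single-parity regulators, flipping the regulator ON in every
        context must move the rule output in the sign's direction."""
        net = random_network(seed, n_nodes=5)
        from itertools import product
        for src, sign, tgt in to_sif(net):
            signs = {s for s2, s, t in to_sif(net) if (s2, t) == (src, tgt)}
            if len(signs) > 1:
                continue  # non-monotone in this regulator
            others = [v for v in net.regulators(tgt) if v != src]
            deltas = set()
            for bits in product((0, 1), repeat=len(others)):
                ctx = dict(zip(others, bits))
                lo = net.evaluate(tgt, {**ctx, src: 0})
                hi = net.evaluate(tgt, {**ctx, src: 1})
                deltas.add(hi - lo)
            if sign == "stimulatory":
                assert -1 not in deltas
            else:
                assert 1 not in deltas


# ---------------------------------------------------------------------------
# Terminals
# ---------------------------------------------------------------------------

class TestIdentifyTerminals:
    def test_prkn_shaped_fixture_terminals(self, prkn_shape):
        inputs, outputs = identify_terminals(prkn_shape)
        assert set(inputs) == {"ATXN3", "BAG4", "FBXW7", "GABARAPL1",
                               "TIMM17A", "ULK1", "VPS13C"}
        assert set(outputs) == {"Apoptosis", "Mitophagy",
                                "PRKN_ubiquitinated", "PINK1_accumulation"}

    def test_isolated_node_is_both_input_and_output(self):
        net = parse_bnet("targets, factors\nA, A")
        assert identify_terminals(net) == (["A"], ["A"])

    def test_chain_has_head_input_tail_output(self, chain3):
        inputs, outputs = identify_terminals(chain3)
        assert inputs == ["A"] and outputs == ["C"]

    @pytest.mark.parametrize("seed", range(20))
    def test_invariant_under_node_reordering(self, seed):
        net = random_network(seed, n_nodes=6)
        order = list(net.nodes)[::-1]
        shuffled = BooleanNetwork(nodes=order,
                                  rules={n: net.rules[n] for n in order})
        assert set(identify_terminals(net)[0]) == \
            set(identify_terminals(shuffled)[0])
        assert set(identify_terminals(net)[1]) == \
            set(identify_terminals(shuffled)[1])


# ---------------------------------------------------------------------------
# Structural verification
# ---------------------------------------------------------------------------

class TestVerifyStructure:
    def test_sign_mismatch_reported(self):
        net = parse_bnet("targets, factors\nA, A\nB, !A")
        ref = SignedInteractionTable([("A", "B", "stimulatory")])
        report = verify_structure(net, ref)
        assert report.summary["sign_mismatches"] == 1
        assert report.sign_mismatches[0][:2] == ("A", "B")

    def test_identical_edges_give_clean_report(self):
        net = parse_bnet("targets, factors\nA, A\nB, !A\nC, B")
        ref = SignedInteractionTable([("A", "B", "inhibitory"),
                                      ("B", "C", "stimulatory")])
        report = verify_structure(net, ref)
        assert report.summary == {"sign_matches": 2, "sign_mismatches": 0,
                                  "direction_conflicts": 0,
                                  "missing_in_reference": 0,
                                  "missing_in_network": 0,
                                  "unknown_reference_ids": 0}

    def test_reversed_reference_edge_is_direction_conflict(self):
        net = parse_bnet("targets, factors\nA, A\nB, A")
        ref = SignedInteractionTable([("B", "A", "stimulatory")])
        report = verify_structure(net, ref)
        assert report.direction_conflicts == [("A", "B")]

    def test_unknown_reference_ids_reported_not_errored(self):
        net = parse_bnet("targets, factors\nA, A\nB, A")
        ref = SignedInteractionTable([("X", "Y", "stimulatory")])
        report = verify_structure(net, ref)
        assert report.unknown_reference_ids == ["X", "Y"]
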