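"""Boolean network model I/O: BoolNet-style rule files, a strict SBML-qual
subset, SIF export, terminal-node identification, and structural verification
against a signed-interaction reference.

Rules are Boolean expressions over node identifiers using ``!`` (NOT),
``&`` (AND), ``|`` (OR), parentheses, and the constants ``0``/``1``.
Identifiers are matched exactly (case-preserving, no normalisation) so that
naming discrepancies between a model and a reference table surface instead of
being silently reconciled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

from lxml import etree

__all__ = [
    "BooleanNetwork",
    "BooleanExpressionError",
    "ModelParseError",
    "UnsupportedFeatureError",
    "SignedInteractionTable",
    "StructureReport",
    "parse_expression",
    "parse_bnet",
    "write_bnet",
    "parse_sbml_qual_subset",
    "to_sif",
    "write_sif",
    "identify_terminals",
    "verify_structure",
    "read_signed_table",
]

STIMULATORY = "stimulatory"
INHIBITORY = "inhibitory"


class BooleanExpressionError(ValueError):
    """Malformed Boolean rule expression."""


class ModelParseError(ValueError):
    """Malformed model file (bad header, duplicate/undeclared nodes, ...)."""


class UnsupportedFeatureError(ModelParseError):
    """Model uses a construct outside the supported Boolean subset."""


# ---------------------------------------------------------------------------
# Boolean expression AST
#
# Node kinds: ("var", name) | ("const", 0 or 1) | ("not", x)
#             | ("and", a, b, ...) | ("or", a, b, ...)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(?P<ident>[A-Za-z_][A-Za-z0-9_.:\-]*)"
                       r"|(?P<const>[01])"
                       r"|(?P<op>[!&|()]))")


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise BooleanExpressionError(
                f"unexpected character {text[pos]!r} in rule {text!r}")
        pos = m.end()
        if m.lastgroup == "ident":
            tokens.append(("ident", m.group("ident")))
        elif m.lastgroup == "const":
            tokens.append(("const", m.group("const")))
        else:
            tokens.append(("op", m.group("op")))
    return tokens


def parse_expression(text: str) -> tuple:
    """Parse a Boolean rule into an AST tuple.

    Grammar: expr := term ('|' term)* ; term := factor ('&' factor)* ;
    factor := '!' factor | '(' expr ')' | identifier | '0' | '1'.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise BooleanExpressionError("empty rule")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, None)

    def expect_op(op: str) -> None:
        nonlocal pos
        kind, val = peek()
        if kind != "op" or val != op:
            raise BooleanExpressionError(
                f"expected {op!r} at token {pos} in {text!r}")
        pos += 1

    def factor() -> tuple:
        nonlocal pos
        kind, val = peek()
        if kind == "op" and val == "!":
            pos += 1
            return ("not", factor())
        if kind == "op" and val == "(":
            pos += 1
            node = expr()
            expect_op(")")
            return node
        if kind == "ident":
            pos += 1
            return ("var", val)
        if kind == "const":
            pos += 1
            return ("const", int(val))
        raise BooleanExpressionError(
            f"unexpected token at position {pos} in {text!r}")

    def term() -> tuple:
        parts = [factor()]
        while peek() == ("op", "&"):
            expect_op("&")
            parts.append(factor())
        return parts[0] if len(parts) == 1 else ("and", *parts)

    def expr() -> tuple:
        parts = [term()]
        while peek() == ("op", "|"):
            expect_op("|")
            parts.append(term())
        return parts[0] if len(parts) == 1 else ("or", *parts)

    node = expr()
    if pos != len(tokens):
        raise BooleanExpressionError(f"trailing tokens in rule {text!r}")
    return node


def expression_variables(ast: tuple) -> set[str]:
    kind = ast[0]
    if kind == "var":
        return {ast[1]}
    if kind == "const":
        return set()
    if kind == "not":
        return expression_variables(ast[1])
    out: set[str] = set()
    for child in ast[1:]:
        out |= expression_variables(child)
    return out


def evaluate_expression(ast: tuple, values: Mapping[str, int]) -> int:
    kind = ast[0]
    if kind == "var":
        return int(values[ast[1]])
    if kind == "const":
        return ast[1]
    if kind == "not":
        return 1 - evaluate_expression(ast[1], values)
    if kind == "and":
        return int(all(evaluate_expression(c, values) for c in ast[1:]))
    if kind == "or":
        return int(any(evaluate_expression(c, values) for c in ast[1:]))
    raise BooleanExpressionError(f"unknown AST node {kind!r}")


def format_expression(ast: tuple) -> str:
    """Render an AST back to rule text (fully parenthesised where needed)."""
    kind = ast[0]
    if kind == "var":
        return ast[1]
    if kind == "const":
        return str(ast[1])
    if kind == "not":
        inner = format_expression(ast[1])
        if ast[1][0] in ("and", "or"):
            inner = f"({inner})"
        return f"!{inner}"
    if kind == "and":
        parts = []
        for c in ast[1:]:
            s = format_expression(c)
            if c[0] == "or":
                s = f"({s})"
            parts.append(s)
        return " & ".join(parts)
    if kind == "or":
        return " | ".join(format_expression(c) for c in ast[1:])
    raise BooleanExpressionError(f"unknown AST node {kind!r}")


def _literal_signs(ast: tuple, negated: bool, acc: dict[str, set[str]]) -> None:
    kind = ast[0]
    if kind == "var":
        acc.setdefault(ast[1], set()).add(
            INHIBITORY if negated else STIMULATORY)
    elif kind == "not":
        _literal_signs(ast[1], not negated, acc)
    elif kind in ("and", "or"):
        for child in ast[1:]:
            _literal_signs(child, negated, acc)
    # constants contribute nothing


# ---------------------------------------------------------------------------
# BooleanNetwork
# ---------------------------------------------------------------------------

@dataclass
class BooleanNetwork:
    """A Boolean model: ordered unique nodes, one update rule per node.

    Every identifier referenced by a rule must be a declared node. An input
    node carries the identity self-rule ``node = node`` or a constant.
    """

    nodes: list[str]
    rules: dict[str, str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._asts: dict[str, tuple] = {}
        self.validate()

    # -- validation / derived views -------------------------------------
    def validate(self) -> None:
        if len(self.nodes) != len(set(self.nodes)):
            dupes = {n for n in self.nodes if self.nodes.count(n) > 1}
            raise ModelParseError(f"duplicate node identifiers: {sorted(dupes)}")
        for n in self.nodes:
            if not n:
                raise ModelParseError("empty node identifier")
        declared = set(self.nodes)
        if set(self.rules) != declared:
            missing = declared - set(self.rules)
            extra = set(self.rules) - declared
            raise ModelParseError(
                f"rules/nodes mismatch (missing rules: {sorted(missing)}, "
                f"undeclared rule targets: {sorted(extra)})")
        self._asts = {}
        for node in self.nodes:
            ast = parse_expression(self.rules[node])
            unknown = expression_variables(ast) - declared
            if unknown:
                raise ModelParseError(
                    f"rule for {node!r} references undeclared node(s) "
                    f"{sorted(unknown)}")
            self._asts[node] = ast

    def ast(self, node: str) -> tuple:
        return self._asts[node]

    def regulators(self, node: str) -> set[str]:
        """Nodes the rule of `node` depends on (may include `node` itself)."""
        return expression_variables(self._asts[node])

    def truth_table(self, node: str) -> tuple[int, ...]:
        """Rule output over all assignments of its regulators (sorted order)."""
        regs = sorted(self.regulators(node))
        rows = []
        for bits in product((0, 1), repeat=len(regs)):
            rows.append(evaluate_expression(
                self._asts[node], dict(zip(regs, bits))))
        return tuple(rows)

    def evaluate(self, node: str, state: Mapping[str, int]) -> int:
        return evaluate_expression(self._asts[node], state)


# ---------------------------------------------------------------------------
# BoolNet-style .bnet files
# ---------------------------------------------------------------------------

def parse_bnet(text: str) -> BooleanNetwork:
    """Parse BoolNet-style rule text: a ``targets, factors`` header followed
    by one ``target, rule`` line per node."""
    lines = [ln for ln in text.splitlines()]
    body: list[tuple[int, str]] = []
    header_seen = False
    for i, raw in enumerate(lines, start=1):
        ln = raw.strip()
        if not ln or ln.startswith("#"):
            continue
        if not header_seen:
            cols = [c.strip().lower() for c in ln.split(",")]
            if cols[:2] != ["targets", "factors"]:
                raise ModelParseError(
                    f"line {i}: expected header 'targets, factors', got {ln!r}")
            header_seen = True
            continue
        body.append((i, ln))
    if not header_seen:
        raise ModelParseError("missing 'targets, factors' header")
    if not body:
        raise ModelParseError("no rules after header")

    nodes: list[str] = []
    rules: dict[str, str] = {}
    for i, ln in body:
        if "," not in ln:
            raise ModelParseError(f"line {i}: expected 'target, rule'")
        target, rule = ln.split(",", 1)
        target = target.strip()
        rule = rule.strip()
        if not target:
            raise ModelParseError(f"line {i}: empty target")
        if not rule:
            raise ModelParseError(f"line {i}: empty rule for {target!r}")
        if target in rules:
            raise ModelParseError(f"line {i}: duplicate target {target!r}")
        nodes.append(target)
        rules[target] = rule

    declared = set(nodes)
    for i, ln in body:
        target = ln.split(",", 1)[0].strip()
        try:
            ast = parse_expression(rules[target])
        except BooleanExpressionError as exc:
            raise ModelParseError(f"line {i}: {exc}") from exc
        unknown = expression_variables(ast) - declared
        if unknown:
            raise ModelParseError(
                f"line {i}: rule for {target!r} references undeclared "
                f"node(s) {sorted(unknown)}")
    return BooleanNetwork(nodes=nodes, rules=rules)


def write_bnet(net: BooleanNetwork) -> str:
    """Serialise to BoolNet rule text; round-trips truth tables exactly."""
    lines = ["targets, factors"]
    for node in net.nodes:
        lines.append(f"{node}, {format_expression(net.ast(node))}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SBML-qual (strict Boolean subset)
# ---------------------------------------------------------------------------

_QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
_MATH_NS = "http://www.w3.org/1998/Math/MathML"


def _qual(tag: str) -> str:
    return f"{{{_QUAL_NS}}}{tag}"


def _math(tag: str) -> str:
    return f"{{{_MATH_NS}}}{tag}"


def _mathml_to_ast(el) -> tuple:
    tag = etree.QName(el).localname
    if tag == "math":
        children = [c for c in el if isinstance(c.tag, str)]
        if len(children) != 1:
            raise UnsupportedFeatureError("math element must hold one expression")
        return _mathml_to_ast(children[0])
    if tag == "ci":
        return ("var", (el.text or "").strip())
    if tag == "cn":
        val = (el.text or "").strip()
        if val not in ("0", "1"):
            raise UnsupportedFeatureError(
                f"non-Boolean constant <cn>{val}</cn>")
        return ("const", int(val))
    if tag == "true":
        return ("const", 1)
    if tag == "false":
        return ("const", 0)
    if tag != "apply":
        raise UnsupportedFeatureError(f"unsupported MathML construct <{tag}>")

    children = [c for c in el if isinstance(c.tag, str)]
    op = etree.QName(children[0]).localname
    args = [_mathml_to_ast(c) for c in children[1:]]
    if op == "and":
        return ("and", *args) if len(args) > 1 else args[0]
    if op == "or":
        return ("or", *args) if len(args) > 1 else args[0]
    if op == "not":
        if len(args) != 1:
            raise UnsupportedFeatureError("<not> takes one argument")
        return ("not", args[0])
    if op in ("eq", "geq"):
        if len(args) != 2:
            raise UnsupportedFeatureError(f"<{op}> takes two arguments")
        var, thr = args
        if var[0] != "var" or thr[0] != "const":
            raise UnsupportedFeatureError(
                f"<{op}> must compare a species to a 0/1 constant")
        if thr[1] == 1:
            return var
        # eq(x, 0) == NOT x at Boolean levels; geq(x, 0) is always true
        return ("not", var) if op == "eq" else ("const", 1)
    if op in ("lt", "leq"):
        if len(args) != 2 or args[0][0] != "var" or args[1][0] != "const":
            raise UnsupportedFeatureError(
                f"<{op}> must compare a species to a 0/1 constant")
        var, thr = args
        if op == "lt" and thr[1] == 1:
            return ("not", var)
        if op == "leq" and thr[1] == 0:
            return ("not", var)
        raise UnsupportedFeatureError(f"non-Boolean threshold in <{op}>")
    raise UnsupportedFeatureError(f"unsupported MathML operator <{op}>")


def parse_sbml_qual_subset(xml: str | bytes) -> BooleanNetwork:
    """Parse an SBML-qual document restricted to Boolean (max level 1) models.

    One network node per qualitative species; each transition must carry a
    single function term with result level 1 (default term level 0), whose
    MathML compiles to a Boolean rule. Species without incoming transitions
    become inputs with the identity self-rule.
    """
    if isinstance(xml, str):
        xml = xml.encode()
    try:
        root = etree.fromstring(xml)
    except etree.XMLSyntaxError as exc:
        raise ModelParseError(f"invalid XML: {exc}") from exc

    species_els = root.findall(f".//{_qual('qualitativeSpecies')}")
    if not species_els:
        raise ModelParseError("empty model: no qualitative species")

    nodes: list[str] = []
    for sp in species_els:
        sid = sp.get(_qual("id")) or sp.get("id")
        if not sid:
            raise ModelParseError("qualitativeSpecies without id")
        max_level = sp.get(_qual("maxLevel")) or sp.get("maxLevel")
        if max_level is not None and int(max_level) > 1:
            raise UnsupportedFeatureError(
                f"species {sid!r} has maxLevel={max_level}; only Boolean "
                f"(maxLevel 1) models are supported")
        nodes.append(sid)

    rules: dict[str, str] = {}
    for tr in root.findall(f".//{_qual('transition')}"):
        outputs = tr.findall(f".//{_qual('output')}")
        if len(outputs) != 1:
            raise UnsupportedFeatureError(
                "transitions must have exactly one output species")
        target = (outputs[0].get(_qual("qualitativeSpecies"))
                  or outputs[0].get("qualitativeSpecies"))
        if target not in set(nodes):
            raise ModelParseError(
                f"transition output references unknown species {target!r}")
        if target in rules:
            raise ModelParseError(
                f"species {target!r} is the output of multiple transitions")

        fterms = tr.findall(f".//{_qual('functionTerm')}")
        dterms = tr.findall(f".//{_qual('defaultTerm')}")
        for dt in dterms:
            lvl = dt.get(_qual("resultLevel")) or dt.get("resultLevel")
            if lvl is not None and int(lvl) != 0:
                raise UnsupportedFeatureError(
                    f"default term with resultLevel {lvl} (only 0 supported)")
        active = []
        for ft in fterms:
            lvl = int(ft.get(_qual("resultLevel")) or ft.get("resultLevel") or 0)
            if lvl == 1:
                active.append(ft)
            elif lvl != 0:
                raise UnsupportedFeatureError(
                    f"function term with resultLevel {lvl} on {target!r}")
        if len(active) != 1:
            raise UnsupportedFeatureError(
                f"transition for {target!r} must carry exactly one "
                f"resultLevel-1 function term")
        math_el = active[0].find(_math("math"))
        if math_el is None:
            raise UnsupportedFeatureError(
                f"function term for {target!r} has no MathML body")
        ast = _mathml_to_ast(math_el)
        unknown = expression_variables(ast) - set(nodes)
        if unknown:
            raise ModelParseError(
                f"rule for {target!r} references unknown species "
                f"{sorted(unknown)}")
        rules[target] = format_expression(ast)

    for sid in nodes:
        rules.setdefault(sid, sid)  # no incoming transition -> input
    name_el = root.find(".//{*}model")
    meta = {"name": name_el.get("id")} if name_el is not None else {}
    return BooleanNetwork(nodes=nodes, rules=rules, metadata=meta)


# ---------------------------------------------------------------------------
# SIF export
# ---------------------------------------------------------------------------

def to_sif(net: BooleanNetwork) -> list[tuple[str, str, str]]:
    """Edge list (source, sign, target); sign from literal-occurrence parity.

    A regulator appearing only un-negated in a rule is stimulatory, only
    negated inhibitory, and both parities yield two rows. Identity self-rules
    (input nodes) emit no row.
    """
    rows: list[tuple[str, str, str]] = []
    for target in net.nodes:
        ast = net.ast(target)
        if ast == ("var", target):  # identity input rule
            continue
        signs: dict[str, set[str]] = {}
        _literal_signs(ast, False, signs)
        for regulator in sorted(signs):
            for sign in sorted(signs[regulator]):
                rows.append((regulator, sign, target))
    return rows


def write_sif(net: BooleanNetwork) -> str:
    return "".join(f"{s}\t{sign}\t{t}\n" for s, sign, t in to_sif(net))


# ---------------------------------------------------------------------------
# Terminal nodes
# ---------------------------------------------------------------------------

def identify_terminals(net: BooleanNetwork) -> tuple[list[str], list[str]]:
    """(inputs, outputs): inputs depend on no other node; outputs feed none."""
    referenced_by_others: set[str] = set()
    for node in net.nodes:
        referenced_by_others |= net.regulators(node) - {node}
    inputs = [n for n in net.nodes if not (net.regulators(n) - {n})]
    outputs = [n for n in net.nodes if n not in referenced_by_others]
    return inputs, outputs


# ---------------------------------------------------------------------------
# Structural verification
# ---------------------------------------------------------------------------

@dataclass
class SignedInteractionTable:
    """Reference edges (regulator, target, sign) from a curated sign database."""

    rows: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        seen = set()
        for reg, tgt, sign in self.rows:
            if sign not in (STIMULATORY, INHIBITORY):
                raise ValueError(
                    f"sign must be '{STIMULATORY}' or '{INHIBITORY}', "
                    f"got {sign!r}")
            if (reg, tgt) in seen:
                raise ValueError(f"duplicate reference pair ({reg!r}, {tgt!r})")
            seen.add((reg, tgt))

    def pairs(self) -> dict[tuple[str, str], str]:
        return {(r, t): s for r, t, s in self.rows}


def read_signed_table(text: str) -> SignedInteractionTable:
    """TSV with columns regulator, target, sign (header optional)."""
    rows = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if [p.lower() for p in parts[:3]] == ["regulator", "target", "sign"]:
            continue
        if len(parts) < 3:
            raise ValueError(f"expected 3 columns, got {ln!r}")
        rows.append((parts[0], parts[1], parts[2]))
    return SignedInteractionTable(rows=rows)


@dataclass
class StructureReport:
    """Edge-by-edge comparison of a network against a signed reference."""

    sign_matches: list[tuple[str, str, str]]
    sign_mismatches: list[tuple[str, str, str, str]]  # (src, tgt, net, ref)
    direction_conflicts: list[tuple[str, str]]  # network (src, tgt), ref reversed
    missing_in_reference: list[tuple[str, str, str]]
    missing_in_network: list[tuple[str, str, str]]
    unknown_reference_ids: list[str]

    @property
    def summary(self) -> dict[str, int]:
        return {
            "sign_matches": len(self.sign_matches),
            "sign_mismatches": len(self.sign_mismatches),
            "direction_conflicts": len(self.direction_conflicts),
            "missing_in_reference": len(self.missing_in_reference),
            "missing_in_network": len(self.missing_in_network),
            "unknown_reference_ids": len(self.unknown_reference_ids),
        }

    def to_text(self) -> str:
        lines = ["category\tsource\ttarget\tdetail"]
        for s, t, sign in self.sign_matches:
            lines.append(f"match\t{s}\t{t}\t{sign}")
        for s, t, net_sign, ref_sign in self.sign_mismatches:
            lines.append(f"sign_mismatch\t{s}\t{t}\tnetwork={net_sign},reference={ref_sign}")
        for s, t in self.direction_conflicts:
            lines.append(f"direction_conflict\t{s}\t{t}\treference_has_reversed")
        for s, t, sign in self.missing_in_reference:
            lines.append(f"missing_in_reference\t{s}\t{t}\t{sign}")
        for s, t, sign in self.missing_in_network:
            lines.append(f"missing_in_network\t{s}\t{t}\t{sign}")
        for ident in self.unknown_reference_ids:
            lines.append(f"unknown_reference_id\t{ident}\t\t")
        return "\n".join(lines) + "\n"


def verify_structure(net: BooleanNetwork,
                     ref: SignedInteractionTable) -> StructureReport:
    """Compare the network's SIF edges against a signed reference table.

    Report-only: every network edge is classified as a sign match, a sign
    mismatch, a direction conflict (the reference holds the reversed edge),
    or absent from the reference; reference edges absent from the network are
    listed symmetrically. Reference rows naming identifiers outside the
    network vocabulary are reported separately, never errored.
    """
    known = set(net.nodes)
    unknown_ids = sorted({i for r, t, _ in ref.rows for i in (r, t)} - known)
    usable = {(r, t): s for r, t, s in ref.rows
              if r in known and t in known}

    net_edges: dict[tuple[str, str], set[str]] = {}
    for s, sign, t in to_sif(net):
        net_edges.setdefault((s, t), set()).add(sign)

    matches, mismatches, conflicts = [], [], []
    missing_in_ref = []
    for (s, t), signs in sorted(net_edges.items()):
        if (s, t) in usable:
            ref_sign = usable[(s, t)]
            if ref_sign in signs:
                matches.append((s, t, ref_sign))
            else:
                mismatches.append((s, t, "/".join(sorted(signs)), ref_sign))
        elif (t, s) in usable and (t, s) not in net_edges:
            conflicts.append((s, t))
        else:
            for sign in sorted(signs):
                missing_in_ref.append((s, t, sign))

    missing_in_net = []
    for (r, t), sign in sorted(usable.items()):
        if (r, t) not in net_edges and (t, r) not in net_edges:
            missing_in_net.append((r, t, sign))

    return StructureReport(
        sign_matches=matches,
        sign_mismatches=mismatches,
        direction_conflicts=conflicts,
        missing_in_reference=missing_in_ref,
        missing_in_network=missing_in_net,
        unknown_reference_ids=unknown_ids,
    )
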