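"""Knowledge-base model for Dynamic Uncertain Causality Graphs (DUCG).

A DUCG knowledge base is a directed acyclic graph of multi-state variables.
Root causes (diseases) are ``B``-type variables with prior distributions;
manifestations (symptoms, signs, tests) are ``X``-type consequences whose
state 0 is the normal state.  Uncertain causality from a parent onto a child
is a weighted functional event ``F = (r_i / r) * A`` where ``A`` carries a
strength matrix ``a[k][j]`` (probability that the parent in state ``j``
independently causes child state ``k``) and the per-parent weights ``r``
normalise the influence of multiple parents (``r = sum_i r_i``).

Risk factors act on disease incidence through a special machinery: a logic
gate (``SG``) maps risk-factor state combinations to gate states via an
ordered specification table, and an ``SA`` factor vector rescales the raw
disease prior per gate state, producing the conditional root ``BX`` whose
prior is what inference actually uses.

Each disease is authored as one :class:`SubDUCG`; sub-graphs are merged into
a :class:`CompleteDUCG` by unifying shared variables and taking the union of
their incoming links.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

from .logic import Expr, ExpressionError, parse_expr

PROB_TOL = 1e-9
PRIOR_TOL = 1e-12

#: Variable kinds: B disease root, BX conditional root, X manifestation,
#: SX gold-standard manifestation, SG logic gate, D default cause,
#: C organisational classifier (no probabilistic role).
KINDS = ("B", "BX", "X", "SX", "SG", "D", "C")

ROOT_KINDS = ("B", "D")
OBSERVABLE_KINDS = ("X", "SX")

_ID_RE = re.compile(r"^(BX|SX|SG|B|X|D|C|RG)(\d+)$")


class KBError(Exception):
    """Base class for knowledge-base errors."""


class KBParseError(KBError):
    """A KB file violates the schema; ``location`` names the offending field."""

    def __init__(self, message: str, location: str = ""):
        self.location = location
        super().__init__(f"{location}: {message}" if location else message)


class KBValidationError(KBError):
    """A structurally parsed KB fails semantic validation."""

    def __init__(self, findings: Sequence["Finding"]):
        self.findings = list(findings)
        lines = "; ".join(str(f) for f in self.findings)
        super().__init__(f"knowledge base invalid: {lines}")


class MergeConflictError(KBError):
    """Two sub-DUCGs declare irreconcilable elements."""


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``level`` is ``"error"`` or ``"warning"``."""

    level: str
    code: str
    message: str

    def __str__(self) -> str:
        return f"[{self.level}:{self.code}] {self.message}"


def parse_var_id(var_id: str) -> tuple[str, int]:
    """Split an id like ``BX23`` into kind prefix and numeric index."""
    m = _ID_RE.match(var_id)
    if m is None:
        raise KBParseError(f"malformed variable id {var_id!r}")
    return m.group(1), int(m.group(2))


def var_index(var_id: str) -> int:
    """Numeric index of a variable id, used for deterministic tie-breaks."""
    return parse_var_id(var_id)[1]


@dataclass(frozen=True)
class Variable:
    """A named multi-state node.  ``prior`` is required iff kind is B or D."""

    id: str
    kind: str
    n_states: int
    label: str = ""
    prior: tuple[float, ...] | None = None


@dataclass(frozen=True)
class CausalLink:
    """Weighted functional event from ``parent`` onto ``child``.

    ``strength[k][j]`` is the probability that the parent in state ``j``
    causes child state ``k``; row 0 (the normal state) is implied residual
    mass and must be all zeros.  ``weight_r`` is the per-parent causal
    intensity ``r_i``; ratios ``r_i / sum r`` are always computed over the
    parents present in the graph at hand.
    """

    child: str
    parent: str
    weight_r: float
    strength: tuple[tuple[float, ...], ...]

    def a(self, k: int, j: int) -> float:
        return self.strength[k][j]

    @property
    def n_child_states(self) -> int:
        return len(self.strength)

    @property
    def n_parent_states(self) -> int:
        return len(self.strength[0])


def strength_matrix(
    n_child_states: int,
    n_parent_states: int,
    rows: Mapping[int, Sequence[float]],
) -> tuple[tuple[float, ...], ...]:
    """Build a full strength matrix from sparse abnormal-state rows.

    Unspecified rows (including row 0) are zero; columns for parent state 0
    default to zero unless explicitly authored.
    """
    out = [[0.0] * n_parent_states for _ in range(n_child_states)]
    for k, row in rows.items():
        if not 1 <= int(k) < n_child_states:
            raise KBParseError(
                f"strength row for child state {k} out of range 1..{n_child_states - 1}"
            )
        if len(row) != n_parent_states:
            raise KBParseError(
                f"strength row for state {k} has {len(row)} entries, "
                f"expected {n_parent_states}"
            )
        out[int(k)] = [float(v) for v in row]
    return tuple(tuple(r) for r in out)


@dataclass(frozen=True)
class LogicGateSpec:
    """Ordered logic specification table (LGS) of an SG gate.

    Rows are ``(gate state, expression)`` pairs evaluated first-match-wins;
    when no row matches, the remnant state holds.
    """

    gate: str
    rows: tuple[tuple[int, Expr], ...]
    remnant_state: int = 0

    def parents(self) -> tuple[str, ...]:
        vs: set[str] = set()
        for _, expr in self.rows:
            vs |= expr.variables()
        return tuple(sorted(vs, key=var_index))

    def evaluate(self, states: Mapping[str, int]) -> int:
        for state, expr in self.rows:
            if expr.evaluate(states):
                return state
        return self.remnant_state


@dataclass(frozen=True)
class SAFactor:
    """Per-gate-state multiplicative factors on a disease prior (SA event).

    ``factors[g]`` rescales the abnormal prior mass of ``disease`` when the
    gate realises state ``g``; the remnant state's factor is 1 so that an
    absent risk profile leaves the prior unchanged.
    """

    disease: str
    bx: str
    gate: str
    factors: tuple[float, ...]


def _canon_links(links: Iterable[CausalLink]) -> tuple[CausalLink, ...]:
    return tuple(
        sorted(links, key=lambda l: (var_index(l.child), var_index(l.parent), l.child, l.parent))
    )


def _canon_sa(sa: Iterable[SAFactor]) -> tuple[SAFactor, ...]:
    return tuple(sorted(sa, key=lambda s: var_index(s.disease)))


@dataclass
class SubDUCG:
    """One disease module: variables, links, gates and SA factors."""

    name: str
    variables: dict[str, Variable]
    links: tuple[CausalLink, ...]
    gates: dict[str, LogicGateSpec]
    sa_factors: tuple[SAFactor, ...]

    def __post_init__(self) -> None:
        self.variables = dict(
            sorted(self.variables.items(), key=lambda kv: (var_index(kv[0]), kv[0]))
        )
        self.links = _canon_links(self.links)
        self.gates = dict(sorted(self.gates.items(), key=lambda kv: var_index(kv[0])))
        self.sa_factors = _canon_sa(self.sa_factors)

    def disease_roots(self) -> list[str]:
        return [v.id for v in self.variables.values() if v.kind == "B"]


@dataclass
class CompleteDUCG:
    """Merged knowledge base; ``provenance`` maps each variable id to the
    names of the sub-DUCGs that contributed it."""

    name: str
    variables: dict[str, Variable]
    links: tuple[CausalLink, ...]
    gates: dict[str, LogicGateSpec]
    sa_factors: tuple[SAFactor, ...]
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.variables = dict(
            sorted(self.variables.items(), key=lambda kv: (var_index(kv[0]), kv[0]))
        )
        self.links = _canon_links(self.links)
        self.gates = dict(sorted(self.gates.items(), key=lambda kv: var_index(kv[0])))
        self.sa_factors = _canon_sa(self.sa_factors)
        self.provenance = {
            k: tuple(sorted(v))
            for k, v in sorted(self.provenance.items(), key=lambda kv: kv[0])
        }

    def disease_roots(self) -> list[str]:
        return [v.id for v in self.variables.values() if v.kind == "B"]


KnowledgeBase = SubDUCG | CompleteDUCG


# ---------------------------------------------------------------------------
# Graph views
# ---------------------------------------------------------------------------

def causal_digraph(kb: KnowledgeBase) -> nx.DiGraph:
    """Directed graph over causal links only (parent -> child)."""
    g = nx.DiGraph()
    g.add_nodes_from(kb.variables)
    g.add_edges_from((l.parent, l.child) for l in kb.links)
    return g


def structural_digraph(kb: KnowledgeBase) -> nx.DiGraph:
    """Causal links plus gate wiring (risk factor -> SG -> BX <- B)."""
    g = causal_digraph(kb)
    for gate in kb.gates.values():
        for p in gate.parents():
            g.add_edge(p, gate.gate)
    for sa in kb.sa_factors:
        g.add_edge(sa.disease, sa.bx)
        g.add_edge(sa.gate, sa.bx)
    return g


def parents_of(kb: KnowledgeBase, child: str) -> list[CausalLink]:
    return [l for l in kb.links if l.child == child]


def sa_for_disease(kb: KnowledgeBase, disease: str) -> SAFactor | None:
    for sa in kb.sa_factors:
        if sa.disease == disease:
            return sa
    return None


def effective_root(kb: KnowledgeBase, disease: str) -> str:
    """The root variable that carries a disease's causal links: its BX if a
    risk-factor triple exists, else the B variable itself."""
    sa = sa_for_disease(kb, disease)
    return sa.bx if sa is not None else disease


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_CPT_EXHAUSTIVE_CAP = 4096
_CPT_SAMPLES = 512


def validate_kb(kb: KnowledgeBase) -> list[Finding]:
    """Semantic validation; returns findings (errors and warnings).

    Errors: malformed ids, missing/invalid priors, dangling references,
    cycles, CPT overflow (joint abnormal mass above 1 for some parent-state
    combination), SA remnant factor differing from 1, gate inconsistencies.
    Warnings: unreachable variables, diseases without manifestations.
    """
    findings: list[Finding] = []
    err = lambda code, msg: findings.append(Finding("error", code, msg))
    warn = lambda code, msg: findings.append(Finding("warning", code, msg))

    for v in kb.variables.values():
        try:
            prefix, _ = parse_var_id(v.id)
        except KBParseError:
            err("bad-id", f"variable id {v.id!r} is not of the form <kind><index>")
            continue
        if prefix == "RG":
            err("rg-unsupported", f"{v.id}: RG-type variables are not supported")
            continue
        if v.kind not in KINDS:
            err("bad-kind", f"{v.id}: unknown kind {v.kind!r}")
            continue
        if prefix != v.kind:
            err("kind-mismatch", f"{v.id}: id prefix disagrees with kind {v.kind}")
        if v.n_states < 2:
            err("bad-states", f"{v.id}: n_states must be >= 2, got {v.n_states}")
        if v.kind in ROOT_KINDS:
            if v.prior is None:
                err("missing-prior", f"{v.id}: {v.kind}-type variable requires a prior")
            else:
                if len(v.prior) != v.n_states:
                    err("bad-prior", f"{v.id}: prior length {len(v.prior)} != n_states")
                elif any(p < 0 for p in v.prior):
                    err("bad-prior", f"{v.id}: negative prior mass")
                elif abs(sum(v.prior) - 1.0) > PRIOR_TOL:
                    err("prior-mass", f"{v.id}: prior sums to {sum(v.prior)!r}, not 1")
        elif v.prior is not None:
            err("spurious-prior", f"{v.id}: {v.kind}-type variable must not carry a prior")

    if not any(v.kind == "B" for v in kb.variables.values()):
        err("no-disease", "a knowledge base must contain at least one B-type disease root")

    by_child: dict[str, list[CausalLink]] = {}
    seen_pairs: set[tuple[str, str]] = set()
    for l in kb.links:
        if l.child not in kb.variables:
            err("dangling-ref", f"link references undeclared child {l.child}")
            continue
        if l.parent not in kb.variables:
            err("dangling-ref", f"link references undeclared parent {l.parent}")
            continue
        child, parent = kb.variables[l.child], kb.variables[l.parent]
        if (l.child, l.parent) in seen_pairs:
            err("duplicate-link", f"duplicate link {l.parent} -> {l.child}")
        seen_pairs.add((l.child, l.parent))
        if child.kind not in OBSERVABLE_KINDS:
            err("bad-link", f"{l.parent} -> {l.child}: {child.kind}-type cannot be a link child")
        if parent.kind in ("SG", "C"):
            err("bad-link", f"{l.parent} -> {l.child}: {parent.kind}-type cannot be a link parent")
        if l.weight_r <= 0:
            err("bad-weight", f"{l.parent} -> {l.child}: weight r must be positive")
        if len(l.strength) != child.n_states or any(
            len(row) != parent.n_states for row in l.strength
        ):
            err(
                "bad-strength",
                f"{l.parent} -> {l.child}: strength shape "
                f"{len(l.strength)}x{len(l.strength[0])} does not match state counts",
            )
            continue
        if any(v != 0.0 for v in l.strength[0]):
            err("bad-strength", f"{l.parent} -> {l.child}: row for child state 0 must be zero")
        if any(not 0.0 <= a <= 1.0 for row in l.strength for a in row):
            err("bad-strength", f"{l.parent} -> {l.child}: strengths must lie in [0, 1]")
        for j in range(parent.n_states):
            col = sum(l.strength[k][j] for k in range(1, child.n_states))
            if col > 1.0 + PROB_TOL:
                # One causation draw per (parent, state): its outcome
                # probabilities over child states must not exceed 1.
                err(
                    "strength-overflow",
                    f"{l.parent} -> {l.child}: column for parent state {j} "
                    f"sums to {col:.6g} > 1",
                )
        by_child.setdefault(l.child, []).append(l)

    for gate_id, gate in kb.gates.items():
        gv = kb.variables.get(gate_id)
        if gv is None:
            err("dangling-ref", f"gate table references undeclared gate {gate_id}")
            continue
        if gv.kind != "SG":
            err("bad-gate", f"{gate_id}: gate table attached to {gv.kind}-type variable")
        for state, _ in gate.rows:
            if not 0 <= state < gv.n_states:
                err("bad-gate", f"{gate_id}: row state {state} out of range")
            if state == gate.remnant_state:
                err("bad-gate", f"{gate_id}: remnant state {state} also appears as a row")
        for p in gate.parents():
            if p not in kb.variables:
                err("dangling-ref", f"gate {gate_id} references undeclared {p}")

    for sa in kb.sa_factors:
        for ref, want in ((sa.disease, "B"), (sa.bx, "BX"), (sa.gate, "SG")):
            v = kb.variables.get(ref)
            if v is None:
                err("dangling-ref", f"SA factor references undeclared {ref}")
            elif v.kind != want:
                err("bad-sa", f"SA factor expects {want}-type for {ref}, found {v.kind}")
        gate = kb.gates.get(sa.gate)
        gv = kb.variables.get(sa.gate)
        if gv is not None and len(sa.factors) != gv.n_states:
            err("bad-sa", f"SA for {sa.disease}: factor count != gate state count")
        elif (
            gate is not None
            and gate.remnant_state < len(sa.factors)
            and sa.factors[gate.remnant_state] != 1.0
        ):
            err("sa-remnant", f"SA for {sa.disease}: remnant-state factor must be 1")
        if any(f < 0 for f in sa.factors):
            err("bad-sa", f"SA for {sa.disease}: factors must be non-negative")
        bxv, bv = kb.variables.get(sa.bx), kb.variables.get(sa.disease)
        if bxv is not None and bv is not None and bxv.n_states != bv.n_states:
            err("bad-sa", f"{sa.bx} and {sa.disease} disagree on state count")

    g = structural_digraph(kb)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        err("cycle", "cycle detected: " + " -> ".join(e[0] for e in cycle))
        return findings  # downstream checks assume a DAG

    findings.extend(_check_cpt_overflow(kb, by_child))

    if isinstance(kb, SubDUCG) and len(kb.disease_roots()) > 1:
        err("multi-root", f"sub-DUCG {kb.name!r} declares more than one disease root")

    causal = causal_digraph(kb)
    for d in kb.disease_roots():
        root = effective_root(kb, d)
        desc = nx.descendants(causal, root)
        if not any(kb.variables[x].kind in OBSERVABLE_KINDS for x in desc):
            warn("no-manifestations", f"disease {d} has no manifestations")
    for v in kb.variables.values():
        if v.kind in ("C",):
            continue
        if g.degree(v.id) == 0:
            warn("unreachable", f"variable {v.id} is disconnected")
    return findings


def _check_cpt_overflow(
    kb: KnowledgeBase, by_child: dict[str, list[CausalLink]]
) -> list[Finding]:
    # For each child and joint parent-state assignment the abnormal mass
    # sum_{k>=1} sum_i (r_i/r) a_i[k][j_i] must stay <= 1, or the residual
    # normal-state probability would be negative.
    out: list[Finding] = []
    rng = np.random.default_rng(0)
    for child, links in by_child.items():
        r_total = sum(l.weight_r for l in links)
        sizes = [kb.variables[l.parent].n_states for l in links]
        n_combo = int(np.prod(sizes))
        if n_combo <= _CPT_EXHAUSTIVE_CAP:
            combos: Iterable[tuple[int, ...]] = np.ndindex(*sizes)  # type: ignore[assignment]
        else:
            combos = (
                tuple(int(rng.integers(0, s)) for s in sizes) for _ in range(_CPT_SAMPLES)
            )
        worst = 0.0
        for combo in combos:
            mass = sum(
                (l.weight_r / r_total) * l.a(k, j)
                for l, j in zip(links, combo)
                for k in range(1, len(l.strength))
            )
            worst = max(worst, mass)
        if worst > 1.0 + PROB_TOL:
            out.append(
                Finding(
                    "error",
                    "cpt-overflow",
                    f"{child}: joint abnormal mass {worst:.6g} exceeds 1 for some "
                    "parent-state combination",
                )
            )
    return out


def assert_valid(kb: KnowledgeBase) -> KnowledgeBase:
    errors = [f for f in validate_kb(kb) if f.level == "error"]
    if errors:
        raise KBValidationError(errors)
    return kb


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_subgraphs(parts: Sequence[SubDUCG]) -> CompleteDUCG:
    """Merge sub-DUCGs into one complete DUCG.

    Shared variables (identical ids) must agree on kind, state count and
    prior; their incoming links are unioned.  The result is order-independent
    and re-validated.
    """
    if not parts:
        raise MergeConflictError("cannot merge an empty list of sub-DUCGs")
    variables: dict[str, Variable] = {}
    provenance: dict[str, list[str]] = {}
    origin: dict[str, str] = {}
    links: dict[tuple[str, str], tuple[CausalLink, str]] = {}
    gates: dict[str, tuple[LogicGateSpec, str]] = {}
    sa_map: dict[str, tuple[SAFactor, str]] = {}

    for part in sorted(parts, key=lambda p: p.name):
        for vid, v in part.variables.items():
            if vid in variables:
                prev = variables[vid]
                if (prev.kind, prev.n_states, prev.prior) != (v.kind, v.n_states, v.prior):
                    raise MergeConflictError(
                        f"variable {vid} conflicts between sub-DUCGs "
                        f"{origin[vid]!r} and {part.name!r}"
                    )
                if not prev.label and v.label:
                    variables[vid] = replace(prev, label=v.label)
            else:
                variables[vid] = v
                origin[vid] = part.name
            provenance.setdefault(vid, []).append(part.name)
        for l in part.links:
            key = (l.child, l.parent)
            if key in links:
                prev, src = links[key]
                if prev != l:
                    raise MergeConflictError(
                        f"link {l.parent} -> {l.child} conflicts between "
                        f"{src!r} and {part.name!r}"
                    )
            else:
                links[key] = (l, part.name)
        for gid, gate in part.gates.items():
            if gid in gates and gates[gid][0] != gate:
                raise MergeConflictError(
                    f"gate {gid} conflicts between {gates[gid][1]!r} and {part.name!r}"
                )
            gates.setdefault(gid, (gate, part.name))
        for sa in part.sa_factors:
            if sa.disease in sa_map and sa_map[sa.disease][0] != sa:
                raise MergeConflictError(
                    f"SA factor for {sa.disease} conflicts between "
                    f"{sa_map[sa.disease][1]!r} and {part.name!r}"
                )
            sa_map.setdefault(sa.disease, (sa, part.name))

    merged = CompleteDUCG(
        name="+".join(sorted(p.name for p in parts)),
        variables=variables,
        links=tuple(l for l, _ in links.values()),
        gates={gid: g for gid, (g, _) in gates.items()},
        sa_factors=tuple(sa for sa, _ in sa_map.values()),
        provenance={k: tuple(v) for k, v in provenance.items()},
    )
    assert_valid(merged)
    return merged


# ---------------------------------------------------------------------------
# Risk-factor prior rescaling
# ---------------------------------------------------------------------------

def compute_bx_prior(
    kb: KnowledgeBase,
    disease: str,
    risk_evidence: Mapping[str, int] | None = None,
) -> np.ndarray:
    """Prior of a disease's conditional root (BX) under observed risk factors.

    The disease's SG gate is evaluated on the risk evidence (unobserved risk
    factors default to state 0); the SA factor ``f`` for the realised gate
    state scales every abnormal prior mass, the result is clipped/renormalised
    so total abnormal mass never exceeds 1, and the normal state takes the
    residual.  A disease without a BX/SG/SA triple passes its raw prior
    through unchanged.
    """
    v = kb.variables.get(disease)
    if v is None or v.kind != "B":
        raise KBError(f"{disease} is not a B-type disease root in this KB")
    assert v.prior is not None
    prior = np.asarray(v.prior, dtype=float)
    sa = sa_for_disease(kb, disease)
    if sa is None:
        return prior
    gate = kb.gates[sa.gate]
    observations = dict(risk_evidence or {})
    gate_state = gate.evaluate(observations)
    f = sa.factors[gate_state]
    abnormal = prior[1:] * f
    total = abnormal.sum()
    if total > 1.0:
        abnormal = abnormal / total
        total = 1.0
    out = np.empty_like(prior)
    out[0] = 1.0 - total
    out[1:] = abnormal
    return out


# ---------------------------------------------------------------------------
# On-disk format
# ---------------------------------------------------------------------------

def _require(mapping: Mapping, key: str, loc: str):
    if key not in mapping:
        raise KBParseError(f"missing required field {key!r}", loc)
    return mapping[key]


def subducg_from_dict(doc: Mapping, name: str = "") -> SubDUCG:
    """Build a (not yet validated) SubDUCG from a parsed YAML/JSON document."""
    if not isinstance(doc, Mapping):
        raise KBParseError("document must be a mapping")
    kb_name = str(doc.get("name", name or "kb"))
    variables: dict[str, Variable] = {}
    raw_vars = doc.get("variables", [])
    if not isinstance(raw_vars, list):
        raise KBParseError("must be a list", "variables")
    for i, rv in enumerate(raw_vars):
        loc = f"variables[{i}]"
        if not isinstance(rv, Mapping):
            raise KBParseError("variable entry must be a mapping", loc)
        vid = str(_require(rv, "id", loc))
        kind = str(rv.get("kind", ""))
        if not kind:
            try:
                kind = parse_var_id(vid)[0]
            except KBParseError as e:
                raise KBParseError(str(e), loc) from None
        if kind == "RG":
            raise KBParseError(
                f"{vid}: RG-type variables are not supported by this engine", loc
            )
        n_states = int(_require(rv, "states", loc))
        prior = rv.get("prior")
        if prior is not None:
            try:
                prior = tuple(float(p) for p in prior)
            except (TypeError, ValueError):
                raise KBParseError("prior must be a list of numbers", f"{loc}.prior")
        if vid in variables:
            raise KBParseError(f"duplicate variable id {vid}", loc)
        variables[vid] = Variable(
            id=vid, kind=kind, n_states=n_states, label=str(rv.get("label", "")), prior=prior
        )

    links: list[CausalLink] = []
    for i, rl in enumerate(doc.get("links", []) or []):
        loc = f"links[{i}]"
        if not isinstance(rl, Mapping):
            raise KBParseError("link entry must be a mapping", loc)
        child = str(_require(rl, "child", loc))
        parent = str(_require(rl, "parent", loc))
        weight = float(rl.get("weight", 1.0))
        raw_strength = _require(rl, "strength", loc)
        cv, pv = variables.get(child), variables.get(parent)
        if cv is None:
            raise KBParseError(f"link child {child} is not declared", loc)
        if pv is None:
            raise KBParseError(f"link parent {parent} is not declared", loc)
        if not isinstance(raw_strength, Mapping):
            raise KBParseError("strength must map child state -> row", f"{loc}.strength")
        try:
            strength = strength_matrix(
                cv.n_states, pv.n_states, {int(k): v for k, v in raw_strength.items()}
            )
        except KBParseError as e:
            raise KBParseError(str(e), f"{loc}.strength") from None
        links.append(CausalLink(child=child, parent=parent, weight_r=weight, strength=strength))

    gates: dict[str, LogicGateSpec] = {}
    for i, rg in enumerate(doc.get("gates", []) or []):
        loc = f"gates[{i}]"
        gid = str(_require(rg, "gate", loc))
        rows: list[tuple[int, Expr]] = []
        for j, rr in enumerate(_require(rg, "rows", loc)):
            try:
                rows.append((int(_require(rr, "state", loc)), parse_expr(str(_require(rr, "expr", loc)))))
            except ExpressionError as e:
                raise KBParseError(str(e), f"{loc}.rows[{j}].expr") from None
        if gid in gates:
            raise KBParseError(f"duplicate gate table for {gid}", loc)
        gates[gid] = LogicGateSpec(
            gate=gid, rows=tuple(rows), remnant_state=int(rg.get("remnant", 0))
        )

    sa_factors: list[SAFactor] = []
    for i, rs in enumerate(doc.get("sa_factors", []) or []):
        loc = f"sa_factors[{i}]"
        sa_factors.append(
            SAFactor(
                disease=str(_require(rs, "disease", loc)),
                bx=str(_require(rs, "bx", loc)),
                gate=str(_require(rs, "gate", loc)),
                factors=tuple(float(f) for f in _require(rs, "factors", loc)),
            )
        )

    return SubDUCG(
        name=kb_name,
        variables=variables,
        links=tuple(links),
        gates=gates,
        sa_factors=tuple(sa_factors),
    )


def kb_to_dict(kb: KnowledgeBase) -> dict:
    """Serialise a KB to the on-disk document structure (round-trip safe)."""
    doc: dict = {"name": kb.name, "variables": []}
    for v in kb.variables.values():
        rv: dict = {"id": v.id, "kind": v.kind, "states": v.n_states}
        if v.label:
            rv["label"] = v.label
        if v.prior is not None:
            rv["prior"] = list(v.prior)
        doc["variables"].append(rv)
    doc["links"] = [
        {
            "child": l.child,
            "parent": l.parent,
            "weight": l.weight_r,
            "strength": {k: list(row) for k, row in enumerate(l.strength) if k >= 1},
        }
        for l in kb.links
    ]
    doc["gates"] = [
        {
            "gate": g.gate,
            "rows": [{"state": s, "expr": str(e)} for s, e in g.rows],
            "remnant": g.remnant_state,
        }
        for g in kb.gates.values()
    ]
    doc["sa_factors"] = [
        {"disease": s.disease, "bx": s.bx, "gate": s.gate, "factors": list(s.factors)}
        for s in kb.sa_factors
    ]
    return doc


def _read_doc(path: Path) -> Mapping:
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            return json.loads(text)
        return yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as e:
        raise KBParseError(f"cannot parse {path.name}: {e}") from None


def load_subducg(path: str | Path) -> SubDUCG:
    """Load and validate a single sub-DUCG file (YAML or JSON)."""
    path = Path(path)
    sub = subducg_from_dict(_read_doc(path), name=path.stem)
    assert_valid(sub)
    return sub


def load_kb(path: str | Path) -> CompleteDUCG:
    """Load a knowledge base from a file or a directory of sub-graphs.

    A directory must contain ``index.yaml`` listing its sub-graph files (or,
    failing that, every ``*.yaml``/``*.json`` in sorted order is taken); the
    parts are validated individually and merged.  A single file holding one
    disease module is promoted to a complete DUCG; a single file holding
    several disease roots is loaded as a complete DUCG directly.
    """
    path = Path(path)
    if path.is_dir():
        index = path / "index.yaml"
        if index.exists():
            idx = _read_doc(index)
            files = [path / f for f in _require(idx, "subgraphs", "index.yaml")]
        else:
            files = sorted(
                p for p in path.iterdir() if p.suffix.lower() in (".yaml", ".yml", ".json")
            )
        if not files:
            raise KBParseError(f"no sub-DUCG files found under {path}")
        return merge_subgraphs([load_subducg(f) for f in files])
    doc = _read_doc(path)
    sub = subducg_from_dict(doc, name=path.stem)
    if len(sub.disease_roots()) == 1:
        return merge_subgraphs([sub])
    kb = CompleteDUCG(
        name=sub.name,
        variables=sub.variables,
        links=sub.links,
        gates=sub.gates,
        sa_factors=sub.sa_factors,
        provenance={vid: (sub.name,) for vid in sub.variables},
    )
    assert_valid(kb)
    return kb


def save_kb(kb: KnowledgeBase, path: str | Path) -> None:
    """Write a KB to YAML (default) or JSON, chosen by file extension."""
    path = Path(path)
    doc = kb_to_dict(kb)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
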