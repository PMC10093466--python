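"""Per-hypothesis graphic interpretation of a diagnosis.

For each hypothesis the observed evidence partitions into *explained*
abnormal evidence (a causal path exists from the hypothesis root — or a
D-type default cause — to the observation), *isolated* abnormal evidence
(no such path; it penalises the hypothesis through the leak factor), and
*negative* normal evidence on manifestations the hypothesis is linked to
(it reduces the hypothesis's conditional probability through residual
normal-state mass).  Observed risk factors feeding the disease's logic gate
are reported separately because they act on the prior, not through causal
links.  The partition depends only on graph structure and the evidence,
never on numeric parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import islice

import networkx as nx

from . import kb_model as km
from .inference import DecomposedView, Evidence, Hypothesis, reachable_from_causes


@dataclass(frozen=True)
class Interpretation:
    hypothesis: Hypothesis
    explained: tuple[str, ...]
    isolated: tuple[str, ...]
    negative: tuple[str, ...]
    risk_factors: tuple[str, ...]
    #: evidence var -> enumerated causal paths (root .. evidence), shortest first
    paths: dict[str, tuple[tuple[str, ...], ...]]
    observed: tuple[tuple[str, int], ...]

    def to_dict(self) -> dict:
        return {
            "hypothesis": {"disease": self.hypothesis.disease, "state": self.hypothesis.state},
            "explained": list(self.explained),
            "isolated": list(self.isolated),
            "negative": list(self.negative),
            "risk_factors": list(self.risk_factors),
            "paths": {v: [list(p) for p in ps] for v, ps in self.paths.items()},
            "observed": {v: s for v, s in self.observed},
        }


def interpret(view: DecomposedView, ev: Evidence, path_cap: int = 10) -> Interpretation:
    """Classify the evidence for one hypothesis and enumerate causal paths."""
    kb = view.kb
    g = view.causal_graph()
    reach = reachable_from_causes(view)

    abnormal = ev.abnormal
    explained = tuple(sorted((v for v in abnormal if v in reach), key=km.var_index))
    isolated = tuple(sorted((v for v in abnormal if v not in reach), key=km.var_index))

    root_reach = (nx.descendants(g, view.root) | {view.root}) if view.root in g else set()
    negative = tuple(
        sorted((v for v in ev.normal if v in root_reach), key=km.var_index)
    )

    sa = km.sa_for_disease(kb, view.hypothesis.disease)
    gate_parents = set(kb.gates[sa.gate].parents()) if sa and sa.gate in kb.gates else set()
    risk_factors = tuple(
        sorted((v for v in ev.as_dict() if v in gate_parents), key=km.var_index)
    )

    paths: dict[str, tuple[tuple[str, ...], ...]] = {}
    for v in explained:
        found: list[tuple[str, ...]] = []
        for source in [view.root] + sorted(
            (x.id for x in kb.variables.values() if x.kind == "D"), key=km.var_index
        ):
            if source not in g or not nx.has_path(g, source, v):
                continue
            found.extend(
                tuple(p) for p in islice(nx.all_simple_paths(g, source, v), path_cap)
            )
        found.sort(key=lambda p: (len(p), p))
        paths[v] = tuple(found[:path_cap])

    return Interpretation(
        hypothesis=view.hypothesis,
        explained=explained,
        isolated=isolated,
        negative=negative,
        risk_factors=risk_factors,
        paths=paths,
        observed=ev.observations,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_STYLES = {
    "root": 'shape=doublecircle, style=filled, fillcolor="#f4cccc"',
    "explained": 'style=filled, fillcolor="#d9ead3"',
    "isolated": 'style="filled,dashed", fillcolor="#eeeeee"',
    "negative": 'style=filled, fillcolor="#cfe2f3"',
    "risk": 'style=filled, fillcolor="#fce5cd"',
    "internal": "",
}


def _dot_id(name: str) -> str:
    return f'"{name}"'


def render(interp: Interpretation, format: str = "text") -> str:
    """Render an interpretation as a stable text report, DOT graph, or JSON."""
    if format == "text":
        return _render_text(interp)
    if format == "dot":
        return _render_dot(interp)
    if format == "json":
        return json.dumps(interp.to_dict(), indent=2)
    raise ValueError(f"unknown render format {format!r} (expected text, dot, or json)")


def _render_text(interp: Interpretation) -> str:
    obs = dict(interp.observed)
    lines = [f"hypothesis: {interp.hypothesis}"]

    def block(title: str, items: tuple[str, ...]) -> None:
        lines.append(f"{title}:" + ("" if items else " (none)"))
        for v in items:
            lines.append(f"  {v} = {obs.get(v)}")

    block("explained abnormal evidence", interp.explained)
    block("isolated abnormal evidence", interp.isolated)
    block("negative (normal) evidence", interp.negative)
    block("risk factors", interp.risk_factors)
    lines.append("causal paths:" + ("" if interp.paths else " (none)"))
    for v in interp.explained:
        for p in interp.paths.get(v, ()):
            lines.append("  " + " -> ".join(p))
    return "\n".join(lines) + "\n"


def _render_dot(interp: Interpretation) -> str:
    obs = dict(interp.observed)
    nodes: dict[str, str] = {}
    edges: set[tuple[str, str]] = set()
    root = None
    for v, ps in interp.paths.items():
        for p in ps:
            root = p[0]
            for a, b in zip(p, p[1:]):
                edges.add((a, b))
            for n in p:
                nodes.setdefault(n, "internal")
    if root is not None:
        nodes[root] = "root"
    for v in interp.explained:
        nodes[v] = "explained"
    for v in interp.negative:
        nodes.setdefault(v, "negative")
    for v in interp.risk_factors:
        nodes.setdefault(v, "risk")

    out = ["digraph interpretation {", "  rankdir=LR;"]
    out.append(f"  label={_dot_id('hypothesis ' + str(interp.hypothesis))};")
    for n in sorted(nodes, key=km.var_index):
        style = _STYLES[nodes[n]]
        label = n if n not in obs else f"{n}={obs[n]}"
        attrs = f"label={_dot_id(label)}"
        if style:
            attrs += ", " + style
        out.append(f"  {_dot_id(n)} [{attrs}];")
    if interp.isolated:
        out.append("  subgraph cluster_isolated {")
        out.append('    label="isolated evidence"; style=dashed;')
        for v in interp.isolated:
            out.append(
                f"    {_dot_id(v)} [label={_dot_id(f'{v}={obs.get(v)}')}, "
                f"{_STYLES['isolated']}];"
            )
        out.append("  }")
    for a, b in sorted(edges):
        out.append(f"  {_dot_id(a)} -> {_dot_id(b)};")
    out.append("}")
    return "\n".join(out) + "\n"
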