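"""Brute-force exact probability computation on small DUCG views.

The oracle makes the weighted-mixture semantics of the causal calculus
explicit: for every child it enumerates the parent-selection event (child
``n`` draws its cause from parent ``i`` with probability ``r_i / r``) and,
given the selected parent's state ``j``, the categorical outcome of the
causation draw (child state ``k`` with probability ``a[k][j]``, normal with
the residual).  Root states are enumerated from their priors.  Summing every
joint outcome consistent with the hypothesis and the evidence yields
``zeta = Pr{H, E}`` with no factorisation shortcuts, which is what the
inference engine is verified against.

The oracle is deliberately naive; enumeration is refused (never silently
truncated) above a configurable atomic-event cap.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from . import kb_model as km
from .inference import DecomposedView, Evidence

DEFAULT_CAP = 20


class OracleCapExceeded(RuntimeError):
    """The KB is too large for brute-force enumeration."""


def atomic_event_count(kb: km.KnowledgeBase) -> int:
    """Number of atomic events: root states plus functional (A) events,
    counted as nonzero strength entries."""
    n = sum(
        v.n_states for v in kb.variables.values() if v.kind in ("B", "D")
    )
    n += sum(
        1 for l in kb.links for row in l.strength for a in row if a != 0.0
    )
    return n


def _toposort(kb: km.KnowledgeBase, nodes: set[str]) -> list[str]:
    # Kahn's algorithm with deterministic (index-sorted) tie-breaking,
    # independent of declaration order.
    children: dict[str, list[str]] = {v: [] for v in nodes}
    indeg: dict[str, int] = {v: 0 for v in nodes}
    for l in kb.links:
        if l.parent in nodes and l.child in nodes:
            children[l.parent].append(l.child)
            indeg[l.child] += 1
    ready = sorted((v for v in nodes if indeg[v] == 0), key=km.var_index)
    order: list[str] = []
    while ready:
        v = ready.pop(0)
        order.append(v)
        for c in sorted(children[v], key=km.var_index):
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
        ready.sort(key=km.var_index)
    if len(order) != len(nodes):
        raise km.KBError("cycle encountered during oracle enumeration")
    return order


def _reachable(kb: km.KnowledgeBase, sources: Sequence[str]) -> set[str]:
    children: dict[str, list[str]] = {}
    for l in kb.links:
        children.setdefault(l.parent, []).append(l.child)
    seen = set()
    stack = [s for s in sources if s in kb.variables]
    while stack:
        v = stack.pop()
        if v in seen:
            continue
        seen.add(v)
        stack.extend(children.get(v, []))
    return seen


def world_probability(
    kb: km.KnowledgeBase,
    root_assignment: Mapping[str, int],
    ev: Mapping[str, int],
    leak: float = 0.0,
) -> float:
    """``Pr{E | roots fixed as given}`` by full enumeration.

    Observed abnormal variables not reachable from any abnormal-fixed root
    or D-type default contribute the factor ``leak`` and are excluded from
    the network, mirroring the engine's isolated-evidence convention.
    """
    sources = [v for v, s in root_assignment.items() if s != 0]
    sources += [v.id for v in kb.variables.values() if v.kind == "D"]
    reach = _reachable(kb, sources)
    isolated = [v for v, s in ev.items() if s != 0 and v not in reach]
    obs = {v: s for v, s in ev.items() if v not in isolated}

    nodes = {
        v.id
        for v in kb.variables.values()
        if v.kind not in ("SG", "C") and v.id not in root_assignment
    } | set(root_assignment)
    order = _toposort(kb, nodes)
    links_by_child: dict[str, list[km.CausalLink]] = {}
    for l in kb.links:
        links_by_child.setdefault(l.child, []).append(l)

    def options(vid: str, assignment: dict[str, int]) -> list[tuple[int, float]]:
        if vid in root_assignment:
            return [(root_assignment[vid], 1.0)]
        var = kb.variables[vid]
        links = links_by_child.get(vid)
        if links:
            r_total = sum(l.weight_r for l in links)
            opts: list[tuple[int, float]] = []
            for l in links:  # selection event, enumerated explicitly
                w = l.weight_r / r_total
                j = assignment[l.parent]
                residual = 1.0
                for k in range(1, l.n_child_states):
                    a = l.a(k, j)
                    residual -= a
                    if a > 0.0:
                        opts.append((k, w * a))
                if residual > 0.0:
                    opts.append((0, w * residual))
            return opts
        if var.kind == "D":
            assert var.prior is not None
            return [(s, p) for s, p in enumerate(var.prior) if p > 0.0]
        return [(0, 1.0)]  # exogenous context variable

    def recurse(idx: int, assignment: dict[str, int], acc: float) -> float:
        if acc == 0.0:
            return 0.0
        if idx == len(order):
            return acc
        vid = order[idx]
        want = obs.get(vid)
        total = 0.0
        for state, p in options(vid, assignment):
            if want is not None and state != want:
                continue
            assignment[vid] = state
            total += recurse(idx + 1, assignment, acc * p)
            del assignment[vid]
        return total

    return (leak ** len(isolated)) * recurse(0, {}, 1.0)


def enumerate_zeta(
    view: DecomposedView,
    ev: Evidence,
    leak: float = 0.01,
    cap: int = DEFAULT_CAP,
) -> float:
    """Exact ``zeta = Pr{H, E}`` on a decomposed view by enumeration."""
    kb = view.kb
    n = atomic_event_count(kb)
    if n > cap:
        raise OracleCapExceeded(
            f"{n} atomic events exceed the enumeration cap of {cap}"
        )
    prior_mass = float(view.prior[view.hypothesis.state])
    roots = {view.root: view.hypothesis.state}
    roots.update(view.fixed_roots)
    return prior_mass * world_probability(kb, roots, ev.as_dict(), leak=leak)


# Backwards-friendly alias matching the operation name.
enumerate_joint = enumerate_zeta
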