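"""Symbolic backward expansion of evidence events into sums of products.

An evidence event on a consequence variable expands recursively against the
causal chain: ``X_nk = sum_i sum_j (r_i / r) A_nk;ij V_ij`` until only root
events remain.  A product term is a multiset of atomic events

* :class:`RootEvent` — a root (or exogenous terminal) variable in a state,
* :class:`SelectorEvent` — "child n draws its cause from parent i", carrying
  the exact rational weight ``r_i / r``,
* :class:`CausationEvent` — the virtual causation ``A_nk;ij`` with its
  strength ``a[k][j]``,

with the algebra of the calculus applied on multiplication: duplicate events
absorb idempotently; two states of one root variable are mutually exclusive;
two selectors for the same child naming different parents are mutually
exclusive (a child draws its cause once); and two causation events for the
same (child, parent, parent state) producing different child states are
mutually exclusive (one draw of the causation).  Normal-state events
(state 0) expand as one minus the sum of the abnormal-state expansions,
which introduces signed terms whose cancellations rely on exactly those
rules — no stronger state-consistency may be imposed.  Under them the
probability of a sum of products — coefficient times the product of
independent atom probabilities, summed — is exact, and is cross-checked
against both the generative evaluator and the brute-force oracle in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import reduce
from typing import Iterable, Mapping

from . import kb_model as km
from .kb_model import KnowledgeBase


@dataclass(frozen=True)
class RootEvent:
    var: str
    state: int

    def __str__(self) -> str:
        return f"{self.var},{self.state}"


@dataclass(frozen=True)
class SelectorEvent:
    """Weight event: child selects this parent as its cause (prob r_i / r)."""

    child: str
    parent: str
    ratio: Fraction

    def __str__(self) -> str:
        return f"r[{self.child};{self.parent}]={self.ratio}"


@dataclass(frozen=True)
class CausationEvent:
    """Virtual functional event ``A``: parent in state j causes child state k."""

    child: str
    child_state: int
    parent: str
    parent_state: int
    prob: float

    def __str__(self) -> str:
        return f"A[{self.child},{self.child_state};{self.parent},{self.parent_state}]"


Atom = RootEvent | SelectorEvent | CausationEvent


def _consistent(events: frozenset[Atom]) -> bool:
    root_states: dict[str, int] = {}
    selectors: dict[str, str] = {}
    draws: dict[tuple[str, str, int], int] = {}
    for e in events:
        if isinstance(e, RootEvent):
            if root_states.setdefault(e.var, e.state) != e.state:
                return False
        elif isinstance(e, SelectorEvent):
            if selectors.setdefault(e.child, e.parent) != e.parent:
                return False
        else:
            key = (e.child, e.parent, e.parent_state)
            if draws.setdefault(key, e.child_state) != e.child_state:
                return False
    return True


@dataclass(frozen=True)
class Term:
    """A signed product of atomic events."""

    coeff: int
    events: frozenset[Atom]

    def weight(self) -> Fraction:
        """Accumulated rational r-ratio factor of this term."""
        return self.coeff * reduce(
            lambda acc, e: acc * e.ratio,
            (e for e in self.events if isinstance(e, SelectorEvent)),
            Fraction(1),
        )

    def probability(self, root_prior) -> float:
        p = float(self.coeff)
        for e in self.events:
            if isinstance(e, RootEvent):
                p *= root_prior(e.var, e.state)
            elif isinstance(e, SelectorEvent):
                p *= float(e.ratio)
            else:
                p *= e.prob
        return p


@dataclass(frozen=True)
class SumOfProducts:
    terms: tuple[Term, ...]

    @classmethod
    def zero(cls) -> "SumOfProducts":
        return cls(terms=())

    @classmethod
    def one(cls) -> "SumOfProducts":
        return cls(terms=(Term(1, frozenset()),))

    @classmethod
    def of(cls, *atoms: Atom, coeff: int = 1) -> "SumOfProducts":
        return cls(terms=(Term(coeff, frozenset(atoms)),)).normalised()

    def normalised(self) -> "SumOfProducts":
        acc: dict[frozenset[Atom], int] = {}
        for t in self.terms:
            if t.coeff == 0 or not _consistent(t.events):
                continue
            acc[t.events] = acc.get(t.events, 0) + t.coeff
        terms = tuple(
            Term(c, ev)
            for ev, c in sorted(
                acc.items(), key=lambda kv: sorted(str(a) for a in kv[0])
            )
            if c != 0
        )
        return SumOfProducts(terms=terms)

    def __add__(self, other: "SumOfProducts") -> "SumOfProducts":
        return SumOfProducts(terms=self.terms + other.terms).normalised()

    def __sub__(self, other: "SumOfProducts") -> "SumOfProducts":
        return self + other.scale(-1)

    def scale(self, c: int) -> "SumOfProducts":
        return SumOfProducts(
            terms=tuple(Term(t.coeff * c, t.events) for t in self.terms)
        ).normalised()

    def __mul__(self, other: "SumOfProducts") -> "SumOfProducts":
        out: list[Term] = []
        for a in self.terms:
            for b in other.terms:
                events = a.events | b.events  # duplicate events absorb
                if _consistent(events):
                    out.append(Term(a.coeff * b.coeff, events))
        return SumOfProducts(terms=tuple(out)).normalised()

    def probability(self, root_prior) -> float:
        """Numeric value given ``root_prior(var, state)`` for terminal events."""
        return sum(t.probability(root_prior) for t in self.terms)

    def __str__(self) -> str:
        if not self.terms:
            return "0"
        parts = []
        for t in self.terms:
            atoms = " * ".join(sorted(str(e) for e in t.events)) or "1"
            sign = "-" if t.coeff < 0 else "+"
            mag = abs(t.coeff)
            parts.append(f"{sign} {'' if mag == 1 else f'{mag} * '}{atoms}")
        return " ".join(parts).lstrip("+ ")


def expand(kb: KnowledgeBase, var: str, state: int) -> SumOfProducts:
    """Expand an event ``(var, state)`` into a sum of products of root
    events, selector weights, and causation events.

    Terminates at variables with no incoming links (B/BX/D roots and
    exogenous context variables), which remain as bare :class:`RootEvent`
    atoms.  Normal-state events (state 0) on linked variables are expanded
    as one minus the sum of the abnormal expansions.
    """
    if var not in kb.variables:
        raise km.KBError(f"unknown variable {var}")
    cache: dict[tuple[str, int], SumOfProducts] = {}

    def rec(v: str, s: int) -> SumOfProducts:
        key = (v, s)
        if key in cache:
            return cache[key]
        links = km.parents_of(kb, v)
        if not links:
            result = SumOfProducts.of(RootEvent(v, s))
        elif s == 0:
            result = SumOfProducts.one()
            for k in range(1, kb.variables[v].n_states):
                result = result - rec(v, k)
        else:
            r_total = sum(l.weight_r for l in links)
            result = SumOfProducts.zero()
            for l in links:
                ratio = Fraction(l.weight_r) / Fraction(r_total)
                for j in range(l.n_parent_states):
                    a = l.a(s, j)
                    if a == 0.0:
                        continue
                    base = SumOfProducts.of(
                        SelectorEvent(v, l.parent, ratio),
                        CausationEvent(v, s, l.parent, j, a),
                    )
                    result = result + base * rec(l.parent, j)
        cache[key] = result
        return result

    return rec(var, state)


def expansion_probability(
    kb: KnowledgeBase,
    events: Iterable[tuple[str, int]],
    condition: Mapping[str, int] | None = None,
) -> float:
    """Probability of a conjunction of events via symbolic expansion.

    ``condition`` fixes terminal variables (e.g. the hypothesis root and the
    fixed-normal other roots): a conditioned root event has probability 1
    when it matches the condition and 0 otherwise; unconditioned roots use
    their priors, and exogenous terminals default to the normal state.
    """
    condition = dict(condition or {})
    sop = SumOfProducts.one()
    for var, state in events:
        sop = sop * expand(kb, var, state)

    def root_prior(var: str, state: int) -> float:
        if var in condition:
            return 1.0 if condition[var] == state else 0.0
        v = kb.variables[var]
        if v.prior is not None:
            return v.prior[state]
        return 1.0 if state == 0 else 0.0

    return sop.probability(root_prior)
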