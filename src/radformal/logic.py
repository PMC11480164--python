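"""Modal mu-calculus formulas and a fixpoint model checker for patient chains.

Concrete syntax::

    phi ::= tt | ff | X | phi and phi | phi or phi | not phi
          | <a> phi | [a] phi | min X . phi | max X . phi
          | presence(a) | absence(a) | ( phi )

``a`` is an action name or the wildcard ``-`` (any action).  Precedence is
``not`` > ``and`` > ``or``; modalities and fixpoints bind like ``not`` except
that a fixpoint body extends as far right as possible.  ``presence(a)`` is the
macro ``min X . (<a>tt or <->X)`` (the action occurs somewhere on the series)
and ``absence(a)`` its negation.

Evaluation uses standard semantics over a finite labeled transition system:
diamond/box quantify over matching transitions and min/max fixpoints are
computed by Kleene iteration from the empty / full state set, converging in at
most ``n_states`` rounds per fixpoint on the lattice of state sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .formal_model import PatientLTS

__all__ = [
    "Formula",
    "TT",
    "FF",
    "Var",
    "Not",
    "And",
    "Or",
    "Diamond",
    "Box",
    "Mu",
    "Nu",
    "WILDCARD",
    "FormulaSyntaxError",
    "MonotonicityError",
    "parse_formula",
    "formula_to_text",
    "presence",
    "absence",
    "free_variables",
    "check_monotone",
    "CheckResult",
    "evaluate",
]

WILDCARD = "-"


class Formula:
    """Base class for AST nodes; subclasses are frozen dataclasses."""

    def __str__(self) -> str:
        return formula_to_text(self)


@dataclass(frozen=True)
class TT(Formula):
    pass


@dataclass(frozen=True)
class FF(Formula):
    pass


@dataclass(frozen=True)
class Var(Formula):
    name: str


@dataclass(frozen=True)
class Not(Formula):
    sub: Formula


@dataclass(frozen=True)
class And(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True)
class Or(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True)
class Diamond(Formula):
    action: str  # action name or WILDCARD
    sub: Formula


@dataclass(frozen=True)
class Box(Formula):
    action: str
    sub: Formula


@dataclass(frozen=True)
class Mu(Formula):
    var: str
    body: Formula


@dataclass(frozen=True)
class Nu(Formula):
    var: str
    body: Formula


def presence(action: str) -> Formula:
    """``min X . (<a>tt or <->X)`` — the action occurs somewhere on the trace."""
    return Mu("X", Or(Diamond(action, TT()), Diamond(WILDCARD, Var("X"))))


def absence(action: str) -> Formula:
    return Not(presence(action))


_PRESENCE_RE = None  # structural, not textual: see match_presence


def match_presence(phi: Formula) -> Optional[str]:
    """If ``phi`` is the presence macro for some action, return that action."""
    if (
        isinstance(phi, Mu)
        and isinstance(phi.body, Or)
        and isinstance(phi.body.left, Diamond)
        and isinstance(phi.body.left.sub, TT)
        and isinstance(phi.body.right, Diamond)
        and phi.body.right.action == WILDCARD
        and phi.body.right.sub == Var(phi.var)
    ):
        return phi.body.left.action
    return None


# ---------------------------------------------------------------------------
# parsing


class FormulaSyntaxError(ValueError):
    """Syntax error with source position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class MonotonicityError(ValueError):
    """A fixpoint variable occurs under an odd number of negations."""


_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z0-9_]+)|(?P<sym>[<>\[\]().-]))")

_KEYWORDS = {"tt", "ff", "and", "or", "not", "min", "max", "presence", "absence"}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise FormulaSyntaxError(f"unexpected character {stripped[0]!r}", pos)
        if m.group("name") is not None:
            tokens.append(("name", m.group("name"), m.start("name")))
        else:
            tokens.append(("sym", m.group("sym"), m.start("sym")))
        pos = m.end()
    tokens.append(("eof", "", len(text)))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str, value: str | None = None):
        k, v, p = self.next()
        if k != kind or (value is not None and v != value):
            want = value if value is not None else kind
            raise FormulaSyntaxError(f"expected {want!r}, found {v or 'end of input'!r}", p)
        return v

    def parse(self) -> Formula:
        phi = self.parse_or()
        k, v, p = self.peek()
        if k != "eof":
            raise FormulaSyntaxError(f"unexpected trailing input {v!r}", p)
        return phi

    def parse_or(self) -> Formula:
        phi = self.parse_and()
        while self.peek()[:2] == ("name", "or"):
            self.next()
            phi = Or(phi, self.parse_and())
        return phi

    def parse_and(self) -> Formula:
        phi = self.parse_unary()
        while self.peek()[:2] == ("name", "and"):
            self.next()
            phi = And(phi, self.parse_unary())
        return phi

    def parse_action(self) -> str:
        k, v, p = self.next()
        if k == "sym" and v == WILDCARD:
            return WILDCARD
        if k == "name":
            return v
        raise FormulaSyntaxError(f"expected action name or '-', found {v!r}", p)

    def parse_unary(self) -> Formula:
        k, v, p = self.peek()
        if (k, v) == ("name", "not"):
            self.next()
            return Not(self.parse_unary())
        if (k, v) == ("sym", "<"):
            self.next()
            act = self.parse_action()
            self.expect("sym", ">")
            return Diamond(act, self.parse_unary())
        if (k, v) == ("sym", "["):
            self.next()
            act = self.parse_action()
            self.expect("sym", "]")
            return Box(act, self.parse_unary())
        if (k, v) in (("name", "min"), ("name", "max")):
            self.next()
            var = self._variable()
            self.expect("sym", ".")
            body = self.parse_or()  # fixpoint body extends maximally right
            return Mu(var, body) if v == "min" else Nu(var, body)
        return self.parse_atom()

    def _variable(self) -> str:
        k, v, p = self.next()
        if k != "name" or v in _KEYWORDS:
            raise FormulaSyntaxError(f"expected variable name, found {v!r}", p)
        return v

    def parse_atom(self) -> Formula:
        k, v, p = self.next()
        if (k, v) == ("name", "tt"):
            return TT()
        if (k, v) == ("name", "ff"):
            return FF()
        if (k, v) in (("name", "presence"), ("name", "absence")):
            self.expect("sym", "(")
            act = self.parse_action()
            self.expect("sym", ")")
            return presence(act) if v == "presence" else absence(act)
        if (k, v) == ("sym", "("):
            phi = self.parse_or()
            self.expect("sym", ")")
            return phi
        if k == "name" and v not in _KEYWORDS:
            return Var(v)
        raise FormulaSyntaxError(f"unexpected token {v or 'end of input'!r}", p)


def parse_formula(text: str) -> Formula:
    """Parse concrete syntax into an AST, expanding macros and rejecting
    non-monotone fixpoints."""
    phi = _Parser(text).parse()
    check_monotone(phi)
    return phi


def formula_to_text(phi: Formula) -> str:
    """Deterministic concrete syntax; ``parse_formula`` inverts it."""

    def render2(f: Formula, level: int) -> str:
        # level: 0 = or-context, 1 = and-context, 2 = unary/atom context
        if isinstance(f, TT):
            return "tt"
        if isinstance(f, FF):
            return "ff"
        if isinstance(f, Var):
            return f.name
        if isinstance(f, Not):
            return f"not {render2(f.sub, 2)}"
        if isinstance(f, Diamond):
            return f"<{f.action}> {render2(f.sub, 2)}"
        if isinstance(f, Box):
            return f"[{f.action}] {render2(f.sub, 2)}"
        if isinstance(f, (Mu, Nu)):
            kw = "min" if isinstance(f, Mu) else "max"
            s = f"{kw} {f.var} . {render2(f.body, 0)}"
            return f"({s})"  # always parenthesize: body extent is maximal
        if isinstance(f, And):
            s = f"{render2(f.left, 1)} and {render2(f.right, 2)}"
            return s if level <= 1 else f"({s})"
        if isinstance(f, Or):
            s = f"{render2(f.left, 0)} or {render2(f.right, 1)}"
            return s if level == 0 else f"({s})"
        raise TypeError(f"unknown node {f!r}")

    return render2(phi, 0)


# ---------------------------------------------------------------------------
# static checks


def free_variables(phi: Formula, bound: frozenset[str] = frozenset()) -> set[str]:
    if isinstance(phi, Var):
        return set() if phi.name in bound else {phi.name}
    if isinstance(phi, (TT, FF)):
        return set()
    if isinstance(phi, Not):
        return free_variables(phi.sub, bound)
    if isinstance(phi, (Diamond, Box)):
        return free_variables(phi.sub, bound)
    if isinstance(phi, (And, Or)):
        return free_variables(phi.left, bound) | free_variables(phi.right, bound)
    if isinstance(phi, (Mu, Nu)):
        return free_variables(phi.body, bound | {phi.var})
    raise TypeError(f"unknown node {phi!r}")


def check_monotone(phi: Formula) -> None:
    """Reject formulas where a fixpoint variable occurs under odd negation."""

    def walk(f: Formula, polarity: dict[str, bool]) -> None:
        if isinstance(f, Var):
            if f.name in polarity and not polarity[f.name]:
                raise MonotonicityError(
                    f"fixpoint variable {f.name!r} occurs under a negation"
                )
        elif isinstance(f, Not):
            walk(f.sub, {v: not p for v, p in polarity.items()})
        elif isinstance(f, (Diamond, Box)):
            walk(f.sub, polarity)
        elif isinstance(f, (And, Or)):
            walk(f.left, polarity)
            walk(f.right, polarity)
        elif isinstance(f, (Mu, Nu)):
            walk(f.body, {**polarity, f.var: True})

    walk(phi, {})


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class CheckResult:
    """Outcome of checking a formula against one patient chain."""

    satisfied: bool
    satisfying_states: frozenset[int]
    witness: Optional[list[str]] = None
    fixpoint_iterations: int = 0  # max Kleene rounds used by any one fixpoint

    def __post_init__(self) -> None:
        assert self.satisfied == (0 in self.satisfying_states)


class _Evaluator:
    """Semantics over a chain, with boolean state vectors and a cache for
    closed subformulas (presence atoms recur across a rule's conjuncts)."""

    def __init__(self, lts: PatientLTS):
        self.n = lts.n_states
        trace = lts.trace()
        names = sorted(set(trace))
        self.code = {a: i for i, a in enumerate(names)}
        self.labels = np.array([self.code[a] for a in trace], dtype=np.int64)
        self.cache: dict[int, np.ndarray] = {}
        self._closed_memo: dict[int, bool] = {}
        self.max_iters = 0

    def _is_closed(self, phi: Formula) -> bool:
        memo = self._closed_memo.get(id(phi))
        if memo is None:
            memo = not free_variables(phi)
            self._closed_memo[id(phi)] = memo
        return memo

    def _match(self, action: str) -> np.ndarray:
        if action == WILDCARD:
            return np.ones(self.n - 1, dtype=bool)
        c = self.code.get(action)
        if c is None:
            return np.zeros(self.n - 1, dtype=bool)
        return self.labels == c

    def sat(self, phi: Formula, env: dict[str, np.ndarray]) -> np.ndarray:
        # a closed subformula's satisfying set is env-independent: cache it so
        # repeated atoms inside Kleene loops cost one evaluation
        if self._is_closed(phi):
            res = self.cache.get(id(phi))
            if res is None:
                res = self._sat(phi, env)
                self.cache[id(phi)] = res
            return res
        return self._sat(phi, env)

    def _sat(self, phi: Formula, env: dict[str, np.ndarray]) -> np.ndarray:
        n = self.n
        if isinstance(phi, TT):
            return np.ones(n, dtype=bool)
        if isinstance(phi, FF):
            return np.zeros(n, dtype=bool)
        if isinstance(phi, Var):
            if phi.name not in env:
                raise ValueError(f"free variable {phi.name!r} at evaluation")
            return env[phi.name]
        if isinstance(phi, Not):
            return ~self.sat(phi.sub, env)
        if isinstance(phi, And):
            return self.sat(phi.left, env) & self.sat(phi.right, env)
        if isinstance(phi, Or):
            return self.sat(phi.left, env) | self.sat(phi.right, env)
        if isinstance(phi, Diamond):
            s = self.sat(phi.sub, env)
            out = np.zeros(n, dtype=bool)
            out[:-1] = self._match(phi.action) & s[1:]
            return out
        if isinstance(phi, Box):
            s = self.sat(phi.sub, env)
            out = np.ones(n, dtype=bool)  # terminal state: vacuously true
            out[:-1] = ~self._match(phi.action) | s[1:]
            return out
        if isinstance(phi, (Mu, Nu)):
            start = np.zeros(n, dtype=bool) if isinstance(phi, Mu) else np.ones(n, dtype=bool)
            x = start
            for rounds in range(1, n + 2):
                nxt = self.sat(phi.body, {**env, phi.var: x})
                if np.array_equal(nxt, x):
                    break
                x = nxt
            else:  # pragma: no cover - Kleene bound on a finite lattice
                raise RuntimeError("fixpoint failed to converge within state bound")
            self.max_iters = max(self.max_iters, rounds)
            return x
        raise TypeError(f"unknown node {phi!r}")


def _witness(lts: PatientLTS, phi: Formula, sat0) -> Optional[list[str]]:
    """Shortest action prefix reaching the first occurrence of a satisfied
    presence atom — the retraceable explanation for a positive call."""
    trace = lts.trace()
    best: Optional[int] = None

    def scan(f: Formula) -> None:
        nonlocal best
        act = match_presence(f)
        if act is not None:
            if act == WILDCARD and trace:
                idx = 0
            elif act in trace:
                idx = trace.index(act)
            else:
                return
            if best is None or idx < best:
                best = idx
            return
        for child in getattr(f, "__dict__", {}).values():
            if isinstance(child, Formula):
                scan(child)

    scan(phi)
    if best is None:
        return None
    return trace[: best + 1]


def evaluate(lts: PatientLTS, formula: Formula) -> CheckResult:
    """Model-check a closed, monotone formula against one patient chain."""
    fv = free_variables(formula)
    if fv:
        raise ValueError(f"formula has free variables: {sorted(fv)}")
    check_monotone(formula)
    ev = _Evaluator(lts)
    sat = ev.sat(formula, {})
    states = frozenset(int(i) for i in np.flatnonzero(sat))
    satisfied = bool(sat[0])
    witness = _witness(lts, formula, sat) if satisfied else None
    return CheckResult(
        satisfied=satisfied,
        satisfying_states=states,
        witness=witness,
        fixpoint_iterations=ev.max_iters,
    )
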