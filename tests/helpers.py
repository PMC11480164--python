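"""Shared test utilities: an independent trace-enumeration semantics oracle and
a random generator of monotone formulas.

The oracle works directly on the action trace with plain Python sets and naive
fixpoint iteration — a separate route from the package's vectorized checker.
"""

from __future__ import annotations

import random

from radformal.logic import (
    FF,
    TT,
    And,
    Box,
    Diamond,
    Formula,
    Mu,
    Not,
    Nu,
    Or,
    Var,
    WILDCARD,
)


def oracle_states(trace: list[str], phi: Formula, env=None) -> set[int]:
    """Satisfying states of ``phi`` over the chain 0..len(trace) by recursion."""
    env = env or {}
    n = len(trace)
    all_states = set(range(n + 1))
    if isinstance(phi, TT):
        return set(all_states)
    if isinstance(phi, FF):
        return set()
    if isinstance(phi, Var):
        return set(env[phi.name])
    if isinstance(phi, Not):
        return all_states - oracle_states(trace, phi.sub, env)
    if isinstance(phi, And):
        return oracle_states(trace, phi.left, env) & oracle_states(trace, phi.right, env)
    if isinstance(phi, Or):
        return oracle_states(trace, phi.left, env) | oracle_states(trace, phi.right, env)
    if isinstance(phi, Diamond):
        sub = oracle_states(trace, phi.sub, env)
        return {
            s
            for s in range(n)
            if (phi.action == WILDCARD or trace[s] == phi.action) and (s + 1) in sub
        }
    if isinstance(phi, Box):
        sub = oracle_states(trace, phi.sub, env)
        out = set()
        for s in all_states:
            if s == n or not (phi.action == WILDCARD or trace[s] == phi.action):
                out.add(s)  # no matching transition: vacuously true
            elif (s + 1) in sub:
                out.add(s)
        return out
    if isinstance(phi, (Mu, Nu)):
        x = set() if isinstance(phi, Mu) else set(all_states)
        while True:
            nxt = oracle_states(trace, phi.body, {**env, phi.var: x})
            if nxt == x:
                return x
            x = nxt
    raise TypeError(f"unknown node {phi!r}")


def oracle_satisfied(trace: list[str], phi: Formula) -> bool:
    return 0 in oracle_states(trace, phi)


def random_monotone_formula(
    rng: random.Random,
    alphabet: list[str],
    depth: int,
    scope: tuple[str, ...] = (),
) -> Formula:
    """Random monotone formula of bounded depth.

    Negation is only ever applied to closed subformulas, so every fixpoint body
    is syntactically monotone in its bound variable.
    """
    act = lambda: rng.choice(alphabet + [WILDCARD])
    if depth <= 0:
        choices = ["tt", "ff"] + (["var"] * 2 if scope else [])
        pick = rng.choice(choices)
        if pick == "tt":
            return TT()
        if pick == "ff":
            return FF()
        return Var(rng.choice(scope))
    pick = rng.choice(
        ["and", "or", "diamond", "box", "mu", "nu", "not_closed", "leaf"]
    )
    if pick == "leaf":
        return random_monotone_formula(rng, alphabet, 0, scope)
    if pick == "and":
        return And(
            random_monotone_formula(rng, alphabet, depth - 1, scope),
            random_monotone_formula(rng, alphabet, depth - 1, scope),
        )
    if pick == "or":
        return Or(
            random_monotone_formula(rng, alphabet, depth - 1, scope),
            random_monotone_formula(rng, alphabet, depth - 1, scope),
        )
    if pick == "diamond":
        return Diamond(act(), random_monotone_formula(rng, alphabet, depth - 1, scope))
    if pick == "box":
        return Box(act(), random_monotone_formula(rng, alphabet, depth - 1, scope))
    if pick == "not_closed":
        # closed subformula: generate with empty scope
        return Not(random_monotone_formula(rng, alphabet, depth - 1, ()))
    var = f"X{len(scope)}"
    body = random_monotone_formula(rng, alphabet, depth - 1, scope + (var,))
    return Mu(var, body) if pick == "mu" else Nu(var, body)


def random_trace(rng: random.Random, alphabet: list[str], max_len: int = 30) -> list[str]:
    return [rng.choice(alphabet) for _ in range(rng.randint(1, max_len))]
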