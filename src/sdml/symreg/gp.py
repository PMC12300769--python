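"""Genetic-programming symbolic regression over protected expression trees.

A population of prefix expression trees (function set: +, -, *, protected
division, protected natural log, sqrt(|x|), sin, abs, and the square/cube
power primitives; terminals: features and ephemeral constants) evolves under
tournament selection with subtree crossover, subtree mutation and
reproduction. Fitness is training RMSE plus a parsimony pressure proportional
to tree size, so bloat is penalized. The best-of-run individual is returned
as an :class:`~sdml.symreg.equation.Equation`; expressions that happen to be
sums of primitive products are flattened into the term list, otherwise the
equation carries the expression tree itself.
"""

from __future__ import annotations

import numpy as np

from ..data import FeatureTable
from .equation import (
    Equation,
    Factor,
    Term,
    evaluate_expr,
    expr_size,
    expr_to_text,
)

_BINARY = ("add", "sub", "mul", "div")
_UNARY = ("ln", "sqrt", "sin", "abs", "square", "cube")
_MAX_NODES = 64


def _random_tree(rng, variables, depth, full):
    if depth == 0 or (not full and rng.random() < 0.3):
        if rng.random() < 0.8:
            return ("var", variables[rng.integers(0, len(variables))])
        return ("const", float(np.round(rng.uniform(-2.0, 2.0), 3)))
    if rng.random() < 0.75:
        op = _BINARY[rng.integers(0, len(_BINARY))]
        return (op, _random_tree(rng, variables, depth - 1, full),
                _random_tree(rng, variables, depth - 1, full))
    op = _UNARY[rng.integers(0, len(_UNARY))]
    return (op, _random_tree(rng, variables, depth - 1, full))


def _subtrees(node, path=()):
    yield node, path
    if node[0] in ("const", "var"):
        return
    for i, child in enumerate(node[1:], start=1):
        yield from _subtrees(child, path + (i,))


def _replace(node, path, new):
    if not path:
        return new
    i = path[0]
    children = list(node)
    children[i] = _replace(node[i], path[1:], new)
    return tuple(children)


def _crossover(a, b, rng):
    sa = list(_subtrees(a))
    sb = list(_subtrees(b))
    _, pa = sa[rng.integers(0, len(sa))]
    sub, _ = sb[rng.integers(0, len(sb))]
    child = _replace(a, pa, sub)
    return child if expr_size(child) <= _MAX_NODES else a


def _mutate(node, variables, rng):
    subs = list(_subtrees(node))
    _, path = subs[rng.integers(0, len(subs))]
    child = _replace(node, path, _random_tree(rng, variables, int(rng.integers(1, 4)), False))
    return child if expr_size(child) <= _MAX_NODES else node


def _fitness(node, df, y, parsimony):
    try:
        pred = evaluate_expr(node, df)
    except FloatingPointError:
        return np.inf
    if not np.all(np.isfinite(pred)):
        return np.inf
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    return rmse + parsimony * expr_size(node)


def fit_gp(
    train: FeatureTable,
    pop: int = 2000,
    gens: int = 100,
    seed: int = 0,
    parsimony: float = 0.001,
    tournament: int = 20,
    p_crossover: float = 0.7,
    p_mutation: float = 0.2,
) -> Equation:
    """Evolve an equation for the training target.

    ``gens = 0`` returns the best random individual. The run never raises on
    budget exhaustion; the incumbent is always returned.
    """
    if train.n_rows < 30:
        raise ValueError("fit_gp requires at least 30 rows")
    rng = np.random.default_rng(seed)
    df = train.data
    y = train.y.to_numpy(float)
    variables = train.feature_names

    population = [
        _random_tree(rng, variables, 2 + int(rng.integers(0, 3)), bool(rng.integers(0, 2)))
        for _ in range(pop)
    ]
    fits = np.array([_fitness(ind, df, y, parsimony) for ind in population])

    def tourney():
        idx = rng.integers(0, len(population), size=tournament)
        return population[idx[np.argmin(fits[idx])]]

    best_idx = int(np.argmin(fits))
    best, best_fit = population[best_idx], fits[best_idx]
    for _gen in range(gens):
        nxt = [best]  # elitism
        while len(nxt) < pop:
            r = rng.random()
            if r < p_crossover:
                nxt.append(_crossover(tourney(), tourney(), rng))
            elif r < p_crossover + p_mutation:
                nxt.append(_mutate(tourney(), variables, rng))
            else:
                nxt.append(tourney())
        population = nxt
        fits = np.array([_fitness(ind, df, y, parsimony) for ind in population])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best, best_fit = population[gen_best], fits[gen_best]

    pred = evaluate_expr(best, df)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = float(1.0 - np.sum((y - pred) ** 2) / ss_tot) if ss_tot > 0 else None
    eq = Equation(method="gp", expression=expr_to_text(best), fit_r2=r2)
    flattened = _try_flatten(best)
    if flattened is not None:
        terms, intercept = flattened
        eq.terms, eq.intercept, eq.expression = terms, intercept, None
    return eq


# ------------------------------------------------------- optional flattening

_UNARY_TO_TRANSFORM = {"sqrt": "sqrt_abs", "ln": "ln_abs", "sin": "sin", "abs": "abs"}


def _try_flatten(node) -> tuple[list[Term], float] | None:
    """Flatten sums of primitive products into equation terms, if possible."""
    addends = _collect_addends(node, +1.0)
    if addends is None:
        return None
    terms: list[Term] = []
    intercept = 0.0
    for sign, sub in addends:
        parsed = _parse_product(sub)
        if parsed is None:
            return None
        coef, factors = parsed
        if not factors:
            intercept += sign * coef
        else:
            terms.append(Term(tuple(factors), sign * coef))
    return terms, intercept


def _collect_addends(node, sign):
    if node[0] == "add":
        left = _collect_addends(node[1], sign)
        right = _collect_addends(node[2], sign)
        return None if left is None or right is None else left + right
    if node[0] == "sub":
        left = _collect_addends(node[1], sign)
        right = _collect_addends(node[2], -sign)
        return None if left is None or right is None else left + right
    if node[0] == "neg":
        return _collect_addends(node[1], -sign)
    return [(sign, node)]


def _parse_product(node):
    if node[0] == "const":
        return float(node[1]), []
    if node[0] == "mul":
        a = _parse_product(node[1])
        b = _parse_product(node[2])
        if a is None or b is None:
            return None
        return a[0] * b[0], a[1] + b[1]
    factor = _parse_factor(node)
    return (1.0, [factor]) if factor is not None else None


def _parse_factor(node):
    if node[0] == "var":
        return Factor(node[1])
    if node[0] == "square" and node[1][0] == "var":
        return Factor(node[1][1], power=2)
    if node[0] == "cube" and node[1][0] == "var":
        return Factor(node[1][1], power=3)
    if node[0] in _UNARY_TO_TRANSFORM and node[1][0] == "var":
        return Factor(node[1][1], transform=_UNARY_TO_TRANSFORM[node[0]])
    return None
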