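"""Serializable symbolic equations with protected evaluation.

An :class:`Equation` is a sum of terms plus an intercept; each term is a
coefficient times a product of primitive factors, a factor being a transform
of one feature raised to a power (``(transform(x))**power``). Equations that
do not flatten into that grammar (notably evolved expression trees) carry a
prefix-notation expression instead; both forms round-trip through JSON to an
identical evaluator.

All operators are protected so that any finite input row yields a finite
prediction: logarithms see ``|x| + eps``, square roots see ``|x|``, and
negative powers floor the base magnitude at eps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_EPS = 1e-6

TRANSFORMS = ("identity", "sqrt_abs", "ln_abs", "exp_decay", "sin", "abs")


def _apply_transform(tag: str, x: np.ndarray) -> np.ndarray:
    if tag == "identity":
        return x
    if tag == "sqrt_abs":
        return np.sqrt(np.abs(x))
    if tag == "ln_abs":
        return np.log(np.abs(x) + _EPS)
    if tag == "exp_decay":
        return np.exp(-0.005 * x)
    if tag == "sin":
        return np.sin(x)
    if tag == "abs":
        return np.abs(x)
    raise ValueError(f"unknown transform {tag!r}")


def _protected_power(base: np.ndarray, power: float) -> np.ndarray:
    if power == 1:
        return base
    if power < 0 or power != int(power):
        safe = np.where(np.abs(base) < _EPS, np.sign(base) * _EPS + (base == 0) * _EPS, base)
        if power != int(power):
            return np.abs(safe) ** power
        return safe ** power
    return base ** power


@dataclass(frozen=True)
class Factor:
    feature: str
    power: float = 1.0
    transform: str = "identity"

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        x = df[self.feature].to_numpy(float)
        return _protected_power(_apply_transform(self.transform, x), self.power)

    def label(self) -> str:
        core = self.feature if self.transform == "identity" else f"{self.transform}({self.feature})"
        return core if self.power == 1 else f"{core}^{self.power:g}"


@dataclass(frozen=True)
class Term:
    factors: tuple[Factor, ...]
    coefficient: float

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        out = np.full(len(df), self.coefficient)
        for f in self.factors:
            out = out * f.evaluate(df)
        return out

    def label(self) -> str:
        return " * ".join(f.label() for f in self.factors) if self.factors else "1"


class EvaluationError(KeyError):
    """A feature required by the equation is missing from the data."""


# ----------------------------------------------------------- expression AST
# Prefix-notation trees for equations that are not sums of primitive factors:
# ("const", v) | ("var", name) | (op, child, ...) with protected operators.

UNARY_OPS = {
    "log10": lambda a: np.log10(np.abs(a) + _EPS),
    "ln": lambda a: np.log(np.abs(a) + _EPS),
    "sqrt": lambda a: np.sqrt(np.abs(a)),
    "sin": np.sin,
    "abs": np.abs,
    "neg": np.negative,
    "square": lambda a: a * a,
    "cube": lambda a: a * a * a,
}
BINARY_OPS = {
    "add": np.add,
    "sub": np.subtract,
    "mul": np.multiply,
    "div": lambda a, b: a / np.where(np.abs(b) < _EPS, np.where(b < 0, -_EPS, _EPS), b),
    "powi": lambda a, k: _protected_power(a, float(k)),
}


def evaluate_expr(node: tuple, df: pd.DataFrame) -> np.ndarray:
    op = node[0]
    if op == "const":
        return np.full(len(df), float(node[1]))
    if op == "var":
        if node[1] not in df.columns:
            raise EvaluationError(f"feature {node[1]!r} missing from data")
        return df[node[1]].to_numpy(float)
    if op == "powi":
        return BINARY_OPS["powi"](evaluate_expr(node[1], df), node[2])
    if op in UNARY_OPS:
        return UNARY_OPS[op](evaluate_expr(node[1], df))
    if op in BINARY_OPS:
        return BINARY_OPS[op](evaluate_expr(node[1], df), evaluate_expr(node[2], df))
    raise ValueError(f"unknown operator {op!r}")


def expr_to_text(node: tuple) -> str:
    op = node[0]
    if op == "const":
        return repr(float(node[1]))
    if op == "var":
        return node[1]
    if op == "powi":
        return f"(powi {expr_to_text(node[1])} {int(node[2])})"
    return "(" + " ".join([op, *[expr_to_text(c) for c in node[1:]]]) + ")"


def expr_from_text(text: str) -> tuple:
    tokens = text.replace("(", " ( ").replace(")", " ) ").split()
    pos = 0

    def parse() -> tuple:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        if tok == "(":
            op = tokens[pos]
            pos += 1
            children = []
            while tokens[pos] != ")":
                children.append(parse())
            pos += 1
            if op == "powi":
                return ("powi", children[0], int(children[1][1]))
            return (op, *children)
        try:
            return ("const", float(tok))
        except ValueError:
            return ("var", tok)

    node = parse()
    if pos != len(tokens):
        raise ValueError("trailing tokens in expression text")
    return node


def expr_features(node: tuple) -> set[str]:
    if node[0] == "var":
        return {node[1]}
    if node[0] == "const":
        return set()
    out: set[str] = set()
    for c in node[1:]:
        if isinstance(c, tuple):
            out |= expr_features(c)
    return out


def expr_size(node: tuple) -> int:
    if node[0] in ("const", "var"):
        return 1
    return 1 + sum(expr_size(c) for c in node[1:] if isinstance(c, tuple))


# ----------------------------------------------------------------- equation

@dataclass
class Equation:
    terms: list[Term] = field(default_factory=list)
    intercept: float = 0.0
    fit_r2: float | None = None
    method: str = "hsie"               # gp | mftec | hsie | fixture
    expression: str | None = None      # prefix text, used when terms are empty

    def required_features(self) -> set[str]:
        feats: set[str] = set()
        for t in self.terms:
            feats |= {f.feature for f in t.factors}
        if self.expression is not None:
            feats |= expr_features(expr_from_text(self.expression))
        return feats

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        missing = self.required_features() - set(df.columns)
        if missing:
            raise EvaluationError(f"features missing from data: {sorted(missing)}")
        if self.expression is not None and not self.terms:
            return evaluate_expr(expr_from_text(self.expression), df) + self.intercept
        out = np.full(len(df), self.intercept)
        for t in self.terms:
            out = out + t.evaluate(df)
        return out

    def to_text(self) -> str:
        if self.expression is not None and not self.terms:
            return f"{self.expression} + {self.intercept:g}"
        parts = [f"{self.intercept:+.6g}"]
        parts += [f"{t.coefficient:+.6g}*{t.label()}" for t in self.terms]
        return " ".join(parts)

    # ------------------------------------------------------- serialization
    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "intercept": self.intercept,
                "fit_r2": self.fit_r2,
                "expression": self.expression,
                "terms": [
                    {
                        "coefficient": t.coefficient,
                        "factors": [
                            {"feature": f.feature, "power": f.power, "transform": f.transform}
                            for f in t.factors
                        ],
                    }
                    for t in self.terms
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Equation":
        d = json.loads(text)
        terms = [
            Term(
                factors=tuple(Factor(**f) for f in t["factors"]),
                coefficient=t["coefficient"],
            )
            for t in d["terms"]
        ]
        return cls(
            terms=terms,
            intercept=d["intercept"],
            fit_r2=d["fit_r2"],
            method=d["method"],
            expression=d["expression"],
        )


def evaluate_equation(eq: Equation, table) -> tuple[np.ndarray, float | None]:
    """Vectorized predictions plus R^2 against the target when present."""
    df = table.data if hasattr(table, "data") else table
    pred = eq.predict(df)
    r2 = None
    target = getattr(table, "target_name", None)
    if target is not None and target in df.columns:
        y = df[target].to_numpy(float)
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot > 0:
            r2 = float(1.0 - np.sum((y - pred) ** 2) / ss_tot)
    return pred, r2


# ------------------------------------------------------------ demo fixtures

def printed_equation_demo(which: int = 3) -> Equation:
    """The two published evolved equations, under a documented parse.

    The typeset source is ambiguous, so these are demo fixtures only: base-10
    logarithms act on absolute-value-protected arguments and exponents bind to
    the immediately preceding variable. They are illustrations of the
    equation format, not reference values.
    """
    if which == 3:
        # log10(0.05 - logKow^9 + pKa^8 + MW)
        expr = ("log10",
                ("add", ("sub", ("const", 0.05), ("powi", ("var", "logKow"), 9)),
                 ("add", ("powi", ("var", "pKa"), 8), ("var", "MW"))))
    elif which == 4:
        # MW + sin(sin(MW + -0.519 + logKow^6)) + log10(0.05 - sin(MW - pKa^8))
        expr = ("add",
                ("add", ("var", "MW"),
                 ("sin", ("sin", ("add", ("add", ("var", "MW"), ("const", -0.519)),
                                  ("powi", ("var", "logKow"), 6))))),
                ("log10", ("sub", ("const", 0.05),
                           ("sin", ("sub", ("var", "MW"),
                                    ("powi", ("var", "pKa"), 8))))))
    else:
        raise ValueError("which must be 3 or 4")
    return Equation(method="fixture", expression=expr_to_text(expr))
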