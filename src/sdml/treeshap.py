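"""Path-dependent Shapley values for sklearn decision-tree ensembles.

Implements the polynomial-time tree traversal that keeps, for each feature on
the current root-to-node path, the proportion of coalitions in which the
feature is present (``one``) or absent (``zero``), together with the Shapley
coalition weights, extending and unwinding the path as the recursion descends.
Expectations over absent features follow the tree's own cover (the training
sample counts stored at each node), i.e. path-dependent expectations.

Guarantees, used directly by the tests: additivity (base value plus the
per-row attributions equals the model prediction) and the null player
property (a feature never used in a split receives exactly zero).
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor


class _Path:
    """Parallel arrays for the unique-path state (d, zero, one, weight)."""

    __slots__ = ("d", "z", "o", "w")

    def __init__(self):
        self.d: list[int] = []
        self.z: list[float] = []
        self.o: list[float] = []
        self.w: list[float] = []

    def copy(self) -> "_Path":
        p = _Path()
        p.d = self.d.copy()
        p.z = self.z.copy()
        p.o = self.o.copy()
        p.w = self.w.copy()
        return p


def _extend(m: _Path, pz: float, po: float, pi: int) -> None:
    l = len(m.d)
    m.d.append(pi)
    m.z.append(pz)
    m.o.append(po)
    m.w.append(1.0 if l == 0 else 0.0)
    for i in range(l - 1, -1, -1):
        m.w[i + 1] += po * m.w[i] * (i + 1) / (l + 1)
        m.w[i] = pz * m.w[i] * (l - i) / (l + 1)


def _unwind(m: _Path, i: int) -> None:
    l = len(m.d) - 1
    n = m.w[l]
    if m.o[i] != 0:
        for j in range(l - 1, -1, -1):
            t = m.w[j]
            m.w[j] = n * (l + 1) / ((j + 1) * m.o[i])
            n = t - m.w[j] * m.z[i] * (l - j) / (l + 1)
    else:
        for j in range(l - 1, -1, -1):
            m.w[j] = m.w[j] * (l + 1) / (m.z[i] * (l - j))
    for j in range(i, l):
        m.d[j] = m.d[j + 1]
        m.z[j] = m.z[j + 1]
        m.o[j] = m.o[j + 1]
    m.d.pop()
    m.z.pop()
    m.o.pop()
    m.w.pop()


def _unwound_sum(m: _Path, i: int) -> float:
    """Sum of the path weights after unwinding entry i, without mutating."""
    l = len(m.d) - 1
    total = 0.0
    if m.o[i] != 0:
        n = m.w[l]
        for j in range(l - 1, -1, -1):
            t = n * (l + 1) / ((j + 1) * m.o[i])
            total += t
            n = m.w[j] - t * m.z[i] * (l - j) / (l + 1)
    else:
        for j in range(l - 1, -1, -1):
            total += m.w[j] * (l + 1) / (m.z[i] * (l - j))
    return total


def shap_values_tree(tree, x: np.ndarray) -> np.ndarray:
    """Shapley attributions of one sklearn ``tree_`` structure for one row."""
    t = tree.tree_ if hasattr(tree, "tree_") else tree
    left, right = t.children_left, t.children_right
    feature, threshold = t.feature, t.threshold
    value = t.value[:, 0, 0]
    cover = t.weighted_n_node_samples
    phi = np.zeros(len(x))

    def recurse(j: int, m: _Path, pz: float, po: float, pi: int) -> None:
        m = m.copy()
        _extend(m, pz, po, pi)
        if left[j] < 0:  # leaf
            for i in range(1, len(m.d)):
                w = _unwound_sum(m, i)
                phi[m.d[i]] += w * (m.o[i] - m.z[i]) * value[j]
            return
        d = feature[j]
        hot, cold = (left[j], right[j]) if x[d] <= threshold[j] else (right[j], left[j])
        iz, io = 1.0, 1.0
        for k in range(1, len(m.d)):
            if m.d[k] == d:
                iz, io = m.z[k], m.o[k]
                _unwind(m, k)
                break
        rj = cover[j]
        recurse(hot, m, iz * cover[hot] / rj, io, d)
        recurse(cold, m, iz * cover[cold] / rj, 0.0, d)

    recurse(0, _Path(), 1.0, 1.0, -1)
    return phi


def expected_value_tree(tree) -> float:
    """Cover-weighted mean leaf value — the tree's path-dependent base value."""
    t = tree.tree_ if hasattr(tree, "tree_") else tree
    leaves = t.children_left < 0
    w = t.weighted_n_node_samples[leaves]
    return float(np.sum(t.value[leaves, 0, 0] * w) / w.sum())


def shap_values_model(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    """(phi matrix, base value) for a sklearn tree model or ensemble."""
    X = np.asarray(X, dtype=float)
    if isinstance(model, DecisionTreeRegressor):
        phi = np.array([shap_values_tree(model, x) for x in X])
        return phi, expected_value_tree(model)
    if isinstance(model, RandomForestRegressor):
        phis = np.zeros((len(X), X.shape[1]))
        base = 0.0
        for est in model.estimators_:
            phis += np.array([shap_values_tree(est, x) for x in X])
            base += expected_value_tree(est)
        k = len(model.estimators_)
        return phis / k, base / k
    if isinstance(model, GradientBoostingRegressor):
        lr = model.learning_rate
        init = float(model.init_.predict(X[:1])[0])
        phis = np.zeros((len(X), X.shape[1]))
        base = init
        for stage in model.estimators_[:, 0]:
            phis += lr * np.array([shap_values_tree(stage, x) for x in X])
            base += lr * expected_value_tree(stage)
        return phis, base
    raise TypeError(f"unsupported model type for the tree tier: {type(model).__name__}")
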