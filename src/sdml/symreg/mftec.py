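"""Select-then-construct equation building with a stacked linear architecture.

Stage 1 keeps the top-m features by composite importance score, so every
derived term is built from variables already known to matter. Stage 2
constructs three blocks of derived columns: the linear block (the features
themselves), the interaction block (pairwise products) and the transform
block (sqrt(|x|), ln(|x|+eps), squares, and an exp(-0.005 x) first-order
decay for time-like features). Stage 3 fits an L1/L2-penalized (elastic-net)
linear model per block on standardized columns and combines the three block
predictions with a non-negative least-squares meta-layer (a free intercept is
realized as a +/- column pair so the weights stay non-negative). The stack is
then flattened algebraically into a single equation whose predictions equal
the stacked pipeline's exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.linear_model import ElasticNetCV

from ..data import FeatureTable
from ..features import FeatureScore, select_features
from .equation import Equation, Factor, Term

_EPS = 1e-6


def _is_time_like(name: str) -> bool:
    return "time" in name.lower()


def _build_blocks(df: pd.DataFrame, feats: list[str]):
    """Return (columns dict per block) keyed by Term descriptors."""
    linear = {Term((Factor(f),), 1.0): df[f].to_numpy(float) for f in feats}
    inter = {}
    for i, a in enumerate(feats):
        for b in feats[i + 1:]:
            inter[Term((Factor(a), Factor(b)), 1.0)] = (
                df[a].to_numpy(float) * df[b].to_numpy(float)
            )
    transf = {}
    for f in feats:
        x = df[f].to_numpy(float)
        transf[Term((Factor(f, transform="sqrt_abs"),), 1.0)] = np.sqrt(np.abs(x))
        transf[Term((Factor(f, transform="ln_abs"),), 1.0)] = np.log(np.abs(x) + _EPS)
        transf[Term((Factor(f, power=2),), 1.0)] = x * x
        if _is_time_like(f):
            transf[Term((Factor(f, transform="exp_decay"),), 1.0)] = np.exp(-0.005 * x)
    return [linear, inter, transf]


def fit_mftec(
    train: FeatureTable,
    scores: list[FeatureScore],
    m: int = 8,
    seed: int = 0,
    return_details: bool = False,
):
    """Fit the stacked select-then-construct model and flatten it.

    Returns a single polynomial-with-transforms equation; its ``fit_r2`` is
    the training R^2 of the flattened (= stacked) predictor.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    m = min(m, len(scores))
    feats = select_features(scores, m)
    feats = [f for f in feats if f in train.data.columns]
    y = train.y.to_numpy(float)
    blocks = _build_blocks(train.data, feats)

    block_preds = []
    flat: dict[Term, float] = {}
    flat_intercepts = []
    fitted_blocks = []
    for block in blocks:
        terms = [t for t, col in block.items() if np.ptp(col) > 0]
        if not terms:
            fitted_blocks.append(None)
            continue
        D = np.column_stack([block[t] for t in terms])
        mu, sd = D.mean(axis=0), D.std(axis=0)
        sd = np.where(sd > 1e-12, sd, 1.0)
        Z = (D - mu) / sd
        if np.ptp(y) == 0:
            coef = np.zeros(Z.shape[1])
            intercept = float(y[0])
        else:
            net = ElasticNetCV(l1_ratio=[0.1, 0.5, 0.9], cv=5, random_state=seed,
                               max_iter=5000)
            net.fit(Z, y)
            coef, intercept = net.coef_, float(net.intercept_)
        pred = Z @ coef + intercept
        block_preds.append(pred)
        fitted_blocks.append((terms, coef, mu, sd, intercept))

    if not block_preds:
        eq = Equation(terms=[], intercept=float(y.mean()), fit_r2=0.0, method="mftec")
        return (eq, np.full(len(y), y.mean())) if return_details else eq

    # non-negative meta-combiner; the +/- ones pair realizes a free intercept
    P = np.column_stack(block_preds + [np.ones(len(y)), -np.ones(len(y))])
    w, _ = nnls(P, y)
    block_w = w[:-2]
    meta_intercept = float(w[-2] - w[-1])

    intercept = meta_intercept
    bi = 0
    for fb in fitted_blocks:
        if fb is None:
            continue
        terms, coef, mu, sd, b_int = fb
        wb = block_w[bi]
        bi += 1
        if wb == 0:
            continue
        intercept += wb * (b_int - float(np.sum(coef * mu / sd)))
        for t, c, s in zip(terms, coef, sd):
            if c != 0:
                flat[t] = flat.get(t, 0.0) + wb * c / s

    eq_terms = [Term(t.factors, c) for t, c in flat.items() if abs(c) > 0]
    eq = Equation(terms=eq_terms, intercept=float(intercept), method="mftec")
    pred = eq.predict(train.data)
    ss_tot = np.sum((y - y.mean()) ** 2)
    eq.fit_r2 = float(1.0 - np.sum((y - pred) ** 2) / ss_tot) if ss_tot > 0 else None
    if return_details:
        stacked_pred = P[:, :-2] @ block_w + meta_intercept
        return eq, stacked_pred
    return eq
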