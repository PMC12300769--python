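"""Construct-then-select sparse equations over a high-order dictionary.

The dictionary contains every monomial of the chosen features up to
``max_order`` (default 3), plus per-feature transforms (sqrt(|x|),
ln(|x|+eps)) and protected pairwise ratios. Logarithms and ratio denominators
are only admitted for features whose observed magnitude stays bounded away
from zero, since a protected log or division evaluated near the floor turns
into a spike on unseen rows and poisons the fit. Columns are standardized and
an L1-regularized path with 5-fold cross-validated penalty choice (the
one-standard-error rule, favoring the sparsest penalty within one SE of the
CV optimum) selects the support; an unpenalized least-squares refit on the
raw selected columns then yields coefficients on the original scale (a
"relaxed" fit), with near-zero refit coefficients pruned and the model refit
once more. With ``max_order = 1`` the dictionary reduces to the plain
features, so the result is ordinary least squares.
"""

from __future__ import annotations

from itertools import combinations, combinations_with_replacement

import numpy as np
from sklearn.linear_model import LassoCV

from ..data import FeatureTable
from .equation import Equation, Factor, Term

_EPS = 1e-6
HARD_CAP = 20_000


class DictionaryOverflowError(ValueError):
    """The interaction dictionary exceeds the hard cap; use fewer features."""


def _dictionary(df, feats: list[str], max_order: int) -> dict[Term, np.ndarray]:
    cols: dict[Term, np.ndarray] = {}
    arrs = {f: df[f].to_numpy(float) for f in feats}
    for order in range(1, max_order + 1):
        for combo in combinations_with_replacement(feats, order):
            counts: dict[str, int] = {}
            for f in combo:
                counts[f] = counts.get(f, 0) + 1
            term = Term(tuple(Factor(f, power=p) for f, p in sorted(counts.items())), 1.0)
            val = np.ones(len(df))
            for f, p in counts.items():
                val = val * arrs[f] ** p
            cols[term] = val
    if max_order >= 2:
        # a log or reciprocal is only safe when the column never approaches 0
        away = {
            f: np.abs(arrs[f]).min() > 0.05 * max(np.std(arrs[f]), 1e-12)
            for f in feats
        }
        for f in feats:
            x = arrs[f]
            cols[Term((Factor(f, transform="sqrt_abs"),), 1.0)] = np.sqrt(np.abs(x))
            if away[f]:
                cols[Term((Factor(f, transform="ln_abs"),), 1.0)] = np.log(np.abs(x) + _EPS)
            if "time" in f.lower():
                # first-order absorption-kinetics decay and its interactions
                kin = np.exp(-0.005 * x)
                cols[Term((Factor(f, transform="exp_decay"),), 1.0)] = kin
                for g in feats:
                    if g != f:
                        cols[Term((Factor(f, transform="exp_decay"), Factor(g)), 1.0)] = (
                            kin * arrs[g]
                        )
        for a, b in combinations(feats, 2):
            for num, den in ((a, b), (b, a)):
                if not away[den]:
                    continue
                term = Term((Factor(num), Factor(den, power=-1)), 1.0)
                d = arrs[den]
                safe = np.where(np.abs(d) < _EPS, np.where(d < 0, -_EPS, _EPS), d)
                cols[term] = arrs[num] / safe
    if len(cols) > HARD_CAP:
        raise DictionaryOverflowError(
            f"dictionary has {len(cols)} columns (cap {HARD_CAP}); reduce features or order"
        )
    return cols


def fit_hsie(
    train: FeatureTable,
    max_order: int = 3,
    seed: int = 0,
    features: list[str] | None = None,
    prune_rel: float = 1e-6,
) -> Equation:
    """Sparse high-order equation for the training target."""
    if train.n_rows < 40:
        raise ValueError("fit_hsie requires at least 40 rows")
    feats = features if features is not None else train.feature_names
    y = train.y.to_numpy(float)
    cols = _dictionary(train.data, feats, max_order)
    terms = [t for t, v in cols.items() if np.ptp(v) > 1e-12 and np.isfinite(v).all()]
    if not terms or np.ptp(y) == 0:
        return Equation(terms=[], intercept=float(y.mean()), fit_r2=0.0, method="hsie")
    D = np.column_stack([cols[t] for t in terms])
    mu, sd = D.mean(axis=0), D.std(axis=0)
    sd = np.where(sd > 1e-300, sd, 1.0)
    Z = (D - mu) / sd

    lasso = LassoCV(cv=5, random_state=seed, max_iter=20_000, alphas=60)
    lasso.fit(Z, y)
    # one-SE rule: sparsest penalty whose CV error is within one standard
    # error of the best, then the coefficients at that penalty
    mse = lasso.mse_path_.mean(axis=1)
    se = lasso.mse_path_.std(axis=1) / np.sqrt(lasso.mse_path_.shape[1])
    best = int(np.argmin(mse))
    within = np.flatnonzero(mse <= mse[best] + se[best])
    alpha_1se = float(lasso.alphas_[within.min()])  # alphas_ descend
    if alpha_1se > lasso.alpha_:
        from sklearn.linear_model import Lasso

        refit = Lasso(alpha=alpha_1se, max_iter=20_000).fit(Z, y)
        coef_sel = refit.coef_
    else:
        coef_sel = lasso.coef_
    support = np.flatnonzero(np.abs(coef_sel) > 1e-10)
    if len(support) == 0:
        return Equation(terms=[], intercept=float(y.mean()), fit_r2=0.0, method="hsie")

    def _ols(idx: np.ndarray):
        A = np.column_stack([np.ones(len(y)), D[:, idx]])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        return beta[0], beta[1:]

    intercept, coefs = _ols(support)
    # prune refit coefficients that are numerically zero on the standardized
    # scale, then refit once on the reduced support
    std_mag = np.abs(coefs) * sd[support]
    keep = std_mag > prune_rel * max(std_mag.max(), 1e-300)
    if keep.sum() < len(support):
        support = support[keep]
        if len(support) == 0:
            return Equation(terms=[], intercept=float(y.mean()), fit_r2=0.0, method="hsie")
        intercept, coefs = _ols(support)

    eq_terms = [Term(terms[j].factors, float(c)) for j, c in zip(support, coefs)]
    eq = Equation(terms=eq_terms, intercept=float(intercept), method="hsie")
    pred = eq.predict(train.data)
    ss_tot = np.sum((y - y.mean()) ** 2)
    eq.fit_r2 = float(1.0 - np.sum((y - pred) ** 2) / ss_tot)
    return eq
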