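"""A compact tree-structured Parzen estimator for hyperparameter search.

Each trial's proposal depends only on the trials before it and on a
per-trial RNG derived from (seed, trial index), so a longer budget replays a
shorter one exactly — the incumbent objective is non-increasing in budget for
a fixed seed.

After a random start-up phase the observed trials are split into a "good"
quantile and the rest; numeric parameters get one Parzen (Gaussian-mixture)
density per group in the transformed space (log for log-uniform scales), and
candidates drawn from the good density are ranked by the density ratio
l(x)/g(x). Categorical parameters use smoothed empirical frequencies.
Conditional parameters are sampled only when their activation predicate over
the partially built configuration holds, so logically incompatible
combinations never occur.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

UNIFORM = "uniform"
LOGUNIFORM = "loguniform"
INT = "int"
CHOICE = "choice"


@dataclass
class Param:
    name: str
    kind: str
    low: float | None = None
    high: float | None = None
    choices: list | None = None
    # sampled only when this predicate over the partial config holds
    condition: Callable[[dict], bool] | None = None

    def transform(self, v: float) -> float:
        return math.log(v) if self.kind == LOGUNIFORM else float(v)

    def inverse(self, t: float) -> float:
        v = math.exp(t) if self.kind == LOGUNIFORM else t
        lo, hi = self.low, self.high
        v = min(max(v, lo), hi)
        return int(round(v)) if self.kind == INT else v

    def sample_uniform(self, rng: np.random.Generator):
        if self.kind == CHOICE:
            return self.choices[rng.integers(0, len(self.choices))]
        if self.kind == LOGUNIFORM:
            return math.exp(rng.uniform(math.log(self.low), math.log(self.high)))
        v = rng.uniform(self.low, self.high)
        return int(round(v)) if self.kind == INT else v


@dataclass
class Trial:
    params: dict
    value: float


def _parzen_logpdf(x: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    diff = (x[:, None] - centers[None, :]) / sigma
    log_components = -0.5 * diff**2 - math.log(sigma * math.sqrt(2 * math.pi))
    m = log_components.max(axis=1, keepdims=True)
    return (m.squeeze(1) + np.log(np.exp(log_components - m).mean(axis=1)))


class TPESampler:
    """Sequential sampler over a list of :class:`Param` definitions."""

    def __init__(self, space: list[Param], seed: int = 0,
                 n_startup: int = 10, gamma: float = 0.25, n_candidates: int = 24):
        self.space = space
        self.seed = seed
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates
        self.trials: list[Trial] = []

    def _rng(self, trial_index: int) -> np.random.Generator:
        return np.random.default_rng((self.seed * 1000003 + trial_index) % (2**31))

    def suggest(self) -> dict:
        t = len(self.trials)
        rng = self._rng(t)
        params: dict = {}
        finished = [tr for tr in self.trials if np.isfinite(tr.value)]
        use_tpe = t >= self.n_startup and len(finished) >= 4
        if use_tpe:
            order = sorted(finished, key=lambda tr: tr.value)
            n_good = max(1, int(math.ceil(self.gamma * len(order))))
            good, bad = order[:n_good], order[n_good:]
        for p in self.space:
            if p.condition is not None and not p.condition(params):
                continue
            if not use_tpe:
                params[p.name] = p.sample_uniform(rng)
                continue
            gv = [tr.params[p.name] for tr in good if p.name in tr.params]
            bv = [tr.params[p.name] for tr in bad if p.name in tr.params]
            if len(gv) < 2 or len(bv) < 2:
                params[p.name] = p.sample_uniform(rng)
            elif p.kind == CHOICE:
                params[p.name] = self._suggest_choice(p, gv, bv, rng)
            else:
                params[p.name] = self._suggest_numeric(p, gv, bv, rng)
        return params

    def _suggest_choice(self, p: Param, gv: list, bv: list, rng: np.random.Generator):
        idx = {c: i for i, c in enumerate(p.choices)}
        cg = np.ones(len(p.choices))
        cb = np.ones(len(p.choices))
        for v in gv:
            cg[idx[v]] += 1
        for v in bv:
            cb[idx[v]] += 1
        pg, pb = cg / cg.sum(), cb / cb.sum()
        cands = rng.choice(len(p.choices), size=self.n_candidates, p=pg)
        best = cands[np.argmax(pg[cands] / pb[cands])]
        return p.choices[int(best)]

    def _suggest_numeric(self, p: Param, gv: list, bv: list, rng: np.random.Generator):
        tg = np.array([p.transform(v) for v in gv])
        tb = np.array([p.transform(v) for v in bv])
        lo, hi = p.transform(p.low), p.transform(p.high)
        span = max(hi - lo, 1e-12)
        sg = max(span / (1 + len(tg)), 1e-3 * span)
        sb = max(span / (1 + len(tb)), 1e-3 * span)
        cands = tg[rng.integers(0, len(tg), size=self.n_candidates)]
        cands = cands + rng.normal(0.0, sg, size=self.n_candidates)
        cands = np.clip(cands, lo, hi)
        score = _parzen_logpdf(cands, tg, sg) - _parzen_logpdf(cands, tb, sb)
        return p.inverse(float(cands[int(np.argmax(score))]))

    def tell(self, params: dict, value: float) -> None:
        self.trials.append(Trial(params, float(value)))

    @property
    def best_trial(self) -> Trial:
        finished = [tr for tr in self.trials if np.isfinite(tr.value)]
        return min(finished, key=lambda tr: tr.value)
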