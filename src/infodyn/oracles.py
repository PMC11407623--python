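"""Independent reference implementations used to validate the estimators.

Everything here computes information quantities by exhaustive frequency
counting (plug-in estimates on small alphabets) or closed form, sharing no
code with the k-NN machinery it cross-checks.  Only practical for small
alphabets and short histories; that is the point.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DiscreteSystem",
    "plugin_local_entropy",
    "plugin_local_mi",
    "plugin_local_cmi",
    "plugin_local_cond_entropy",
    "plugin_series_measures",
    "gaussian_te_closed_form",
]


@dataclass
class DiscreteSystem:
    """A small-alphabet multivariate Markov chain with an explicit
    transition rule, for generating exactly analysable samples.

    ``transition(state_history, rng) -> next joint state`` where
    state_history is a list (oldest first) of joint-state tuples of length
    ``order``.
    """

    n_agents: int
    alphabet_size: int
    order: int
    transition: callable
    initial: tuple

    def __post_init__(self):
        if self.alphabet_size > 8 or self.order > 2:
            raise ValueError("oracle systems must stay exhaustively enumerable")

    def sample(self, T: int, seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        out = np.zeros((T, self.n_agents), dtype=np.int64)
        hist = [tuple(self.initial)] * self.order
        for t in range(T):
            state = self.transition(hist, rng)
            out[t] = state
            hist = hist[1:] + [tuple(state)]
        return out


def _rows(x: Optional[np.ndarray]) -> list[tuple]:
    if x is None:
        return None
    x = np.asarray(x)
    if x.ndim == 1:
        x = x[:, None]
    return [tuple(row) for row in x]


def plugin_local_entropy(a: np.ndarray) -> np.ndarray:
    """-log of the empirical probability of each point's value."""
    rows = _rows(a)
    n = len(rows)
    counts = Counter(rows)
    return np.array([-np.log(counts[r] / n) for r in rows])


def plugin_local_cond_entropy(a: np.ndarray, c: Optional[np.ndarray]) -> np.ndarray:
    """-log of the empirical conditional probability p(a | c)."""
    if c is None:
        return plugin_local_entropy(a)
    ra, rc = _rows(a), _rows(c)
    n = len(ra)
    joint = Counter(zip(ra, rc))
    marg = Counter(rc)
    return np.array([
        -np.log(joint[(x, z)] / marg[z]) for x, z in zip(ra, rc)
    ])


def plugin_local_mi(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Local MI log(p(a,b) / (p(a) p(b))) from empirical frequencies."""
    ra, rb = _rows(a), _rows(b)
    n = len(ra)
    joint = Counter(zip(ra, rb))
    ca, cb = Counter(ra), Counter(rb)
    return np.array([
        np.log(joint[(x, y)] * n / (ca[x] * cb[y])) for x, y in zip(ra, rb)
    ])


def plugin_local_cmi(a: np.ndarray, b: np.ndarray, c: Optional[np.ndarray]) -> np.ndarray:
    """Local conditional MI log(p(a|b,c) / p(a|c)) from empirical frequencies."""
    if c is None:
        return plugin_local_mi(a, b)
    ra, rb, rc = _rows(a), _rows(b), _rows(c)
    abc = Counter(zip(ra, rb, rc))
    ac = Counter(zip(ra, rc))
    bc = Counter(zip(rb, rc))
    cc = Counter(rc)
    return np.array([
        np.log((abc[(x, y, z)] * cc[z]) / (ac[(x, z)] * bc[(y, z)]))
        for x, y, z in zip(ra, rb, rc)
    ])


def _embed_rows(x: np.ndarray, n_values: np.ndarray, length: int, at: np.ndarray) -> np.ndarray:
    return np.column_stack([x[at - 1 - j] for j in range(length)])


def plugin_series_measures(
    abundance: np.ndarray,
    dest: int,
    k: int,
    l: int,
    d: int,
) -> dict[str, np.ndarray]:
    """All decomposition terms of a multivariate series by plug-in counting.

    Returns per-step arrays for h, ais, cte, u on the common valid range
    (n from max(k, l+d-1) to T-1) plus the 1-based steps.  The identity
    h = ais + cte + u holds exactly for plug-in estimates on any sample.
    """
    ab = np.asarray(abundance)
    if ab.ndim == 1:
        ab = ab[:, None]
    T, S = ab.shape
    x = ab[:, dest]
    n_min = max(k, l + d - 1) if S > 1 else k
    n_values = np.arange(n_min, T)
    A = x[n_values]
    C = _embed_rows(x, n_values, k, n_values)
    if S > 1:
        m = n_values + 1 - d
        V = np.hstack([
            _embed_rows(ab[:, s], n_values, l, m) for s in range(S) if s != dest
        ])
    else:
        V = np.zeros((len(n_values), 0), dtype=ab.dtype)
    h = plugin_local_entropy(A)
    ais = plugin_local_mi(A, C)
    cte = plugin_local_cmi(A, V, C) if V.shape[1] else np.zeros(len(A))
    cond = np.hstack([C, V])
    u = plugin_local_cond_entropy(A, cond)
    return {"steps": n_values + 1, "h": h, "ais": ais, "cte": cte, "u": u}


def gaussian_te_closed_form(coupling: float, noise_sd: float) -> float:
    """Transfer entropy (nats) of the linear copy-with-noise system
    Y_{n+1} = c X_{n-1} + eps, eps ~ N(0, sigma^2), X i.i.d. standard normal:
    1/2 log(1 + c^2 / sigma^2)."""
    return 0.5 * np.log1p(coupling**2 / noise_sd**2)
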