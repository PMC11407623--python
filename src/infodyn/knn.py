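"""Kraskov-Stögbauer-Grassberger (KSG) k-nearest-neighbour estimation of
local information quantities.

All estimators here operate on a "point cloud": N points whose coordinates
are partitioned into named blocks (e.g. target-next, destination-past,
source-past).  The construction is the classic KSG algorithm 1 with the
Frenzel-Pompe extension for conditioning: for each point, the Chebyshev
(max-norm) distance to its ``knn_k``-th neighbour in the full joint space
sets a radius; neighbour counts strictly within that radius in the marginal
subspaces are combined with digamma terms into per-point *local* values in
nats.  The mean of the local values is the usual average estimate.

A small amount of uniform noise (relative to each coordinate's standard
deviation) is added before any neighbour search.  This is mandatory: the
abundance data the package targets contains long runs of identical values,
and without tie-breaking the neighbour radius degenerates to zero.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import digamma
from sklearn.neighbors import KDTree, NearestNeighbors

__all__ = [
    "TieDegeneracyError",
    "local_cmi",
    "local_conditional_entropy",
    "local_entropy_knn",
    "average_runs",
    "surrogate_pvalue",
]


class TieDegeneracyError(ValueError):
    """Raised when tied coordinates make the neighbour radius zero and noise
    injection has been disabled."""


def _as_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def _prepare(
    blocks: Sequence[np.ndarray],
    noise_amplitude: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Standardise each coordinate and add uniform tie-breaking noise.

    Noise is uniform on [0, noise_amplitude * sd(coordinate)]; coordinates
    with zero spread use a unit scale so that ties are still broken.
    """
    out = []
    for block in blocks:
        if block is None:
            out.append(None)
            continue
        b = _as_2d(block).copy()
        sd = b.std(axis=0)
        mean = b.mean(axis=0)
        scale = np.where(sd > 0, sd, 1.0)
        b = (b - mean) / scale
        if noise_amplitude > 0:
            b = b + rng.uniform(0.0, noise_amplitude, size=b.shape)
        out.append(b)
    return out


def _kth_radius(joint: np.ndarray, knn_k: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=knn_k + 1, metric="chebyshev")
    nn.fit(joint)
    dist, _ = nn.kneighbors(joint)
    eps = dist[:, -1]
    if np.any(eps == 0.0):
        raise TieDegeneracyError(
            "zero k-th neighbour distance: tied points exceed knn_k and no "
            "tie-breaking noise was added (noise_amplitude = 0)"
        )
    return eps


def _count_within(space: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Number of *other* points strictly within ``radii`` of each point."""
    tree = KDTree(space, metric="chebyshev")
    strict = np.nextafter(radii, 0.0)
    counts = tree.query_radius(space, r=strict, count_only=True)
    return counts.astype(float) - 1.0  # exclude the point itself


def local_cmi(
    a: np.ndarray,
    b: np.ndarray,
    c: Optional[np.ndarray] = None,
    knn_k: int = 4,
    noise_amplitude: float = 1e-8,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Per-point local (conditional) mutual information I(a_i; b_i | c_i) in nats.

    With ``c is None`` this is KSG algorithm 1 local MI; otherwise the
    Frenzel-Pompe conditional variant.  The mean over points is the average
    (C)MI estimate.
    """
    rng = np.random.default_rng(seed)
    a2, b2, c2 = _prepare([a, b, c], noise_amplitude, rng)
    n = a2.shape[0]
    if b2.shape[0] != n or (c2 is not None and c2.shape[0] != n):
        raise ValueError("blocks must have equal numbers of points")
    if a2.shape[1] == 0 or b2.shape[1] == 0:
        raise ValueError("blocks A and B must be at least one-dimensional")
    if n <= knn_k:
        raise ValueError(f"need more than knn_k={knn_k} points, got {n}")

    if c2 is None:
        joint = np.hstack([a2, b2])
        eps = _kth_radius(joint, knn_k)
        n_a = _count_within(a2, eps)
        n_b = _count_within(b2, eps)
        return digamma(knn_k) + digamma(n) - digamma(n_a + 1) - digamma(n_b + 1)

    joint = np.hstack([a2, b2, c2])
    eps = _kth_radius(joint, knn_k)
    n_ac = _count_within(np.hstack([a2, c2]), eps)
    n_bc = _count_within(np.hstack([b2, c2]), eps)
    n_c = _count_within(c2, eps)
    return (
        digamma(knn_k)
        - digamma(n_ac + 1)
        - digamma(n_bc + 1)
        + digamma(n_c + 1)
    )


def local_conditional_entropy(
    a: np.ndarray,
    c: Optional[np.ndarray] = None,
    knn_k: int = 4,
    noise_amplitude: float = 1e-8,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Per-point local -log p(a_i | c_i) in nats (differential, on
    standardised coordinates).

    With ``c is None`` this reduces to the Kozachenko-Leonenko local entropy
    -log p(a_i).  Radii come from the k-th neighbour in the (a, c) joint
    space; the conditional density is the ratio of joint and marginal
    k-NN density estimates at that shared radius.
    """
    rng = np.random.default_rng(seed)
    a2, c2 = _prepare([a, c], noise_amplitude, rng)
    n = a2.shape[0]
    if n <= knn_k:
        raise ValueError(f"need more than knn_k={knn_k} points, got {n}")
    d_a = a2.shape[1]
    if c2 is None:
        eps = _kth_radius(a2, knn_k)
        n_c = np.full(n, float(n - 1))
    else:
        joint = np.hstack([a2, c2])
        eps = _kth_radius(joint, knn_k)
        n_c = _count_within(c2, eps)
    return digamma(n_c + 1) - digamma(knn_k) + d_a * np.log(2.0 * eps)


def local_entropy_knn(
    a: np.ndarray,
    knn_k: int = 4,
    noise_amplitude: float = 1e-8,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Kozachenko-Leonenko local entropy -log p(a_i), nats."""
    return local_conditional_entropy(
        a, None, knn_k=knn_k, noise_amplitude=noise_amplitude, seed=seed
    )


def average_runs(
    estimator: Callable[[np.random.Generator], np.ndarray],
    n_runs: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Repeat a noisy local estimate with fresh noise streams and average.

    ``estimator`` is called with an independent child generator per run and
    must return per-point local values.  Returns ``(mean over runs,
    per-run array of shape (n_runs, N))``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    master = np.random.default_rng(seed)
    runs = [estimator(np.random.default_rng(master.integers(2**63))) for _ in range(n_runs)]
    per_run = np.vstack(runs)
    return per_run.mean(axis=0), per_run


def surrogate_pvalue(
    a: np.ndarray,
    b: np.ndarray,
    c: Optional[np.ndarray] = None,
    knn_k: int = 4,
    noise_amplitude: float = 1e-8,
    n_surrogates: int = 100,
    seed: int | np.random.Generator | None = None,
    observed: Optional[float] = None,
) -> float:
    """One-sided permutation p-value for the average (C)MI.

    The source block ``b`` is row-permuted while the destination blocks are
    held fixed, destroying any source-destination relation but preserving
    both marginals.  p = (1 + #{surrogate mean >= observed}) /
    (1 + n_surrogates).
    """
    if n_surrogates < 20:
        raise ValueError("n_surrogates must be >= 20 for a meaningful test")
    rng = np.random.default_rng(seed)
    if observed is None:
        observed = float(
            np.mean(local_cmi(a, b, c, knn_k, noise_amplitude, rng))
        )
    b2 = _as_2d(b)
    exceed = 0
    for _ in range(n_surrogates):
        perm = rng.permutation(b2.shape[0])
        surr = float(
            np.mean(local_cmi(a, b2[perm], c, knn_k, noise_amplitude, rng))
        )
        if surr >= observed:
            exceed += 1
    return (1.0 + exceed) / (1.0 + n_surrogates)
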