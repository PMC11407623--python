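"""Time-delay embeddings of abundance series.

Conventions (1-based time steps throughout, matching how feeding events are
referred to as "after time step 35" etc.):

* the destination history vector at time n with history length k is
  ``x_n^(k) = (x_n, x_{n-1}, ..., x_{n-k+1})``, defined for n >= k;
* each local value predicts the transition to ``x_{n+1}`` and is therefore
  attributed to time step n + 1;
* source histories of length l enter with a source-destination delay d,
  i.e. sampled at time n + 1 - d.

With the standard parameter rule l = k - 1 and d = 2, destination and source
validity coincide and the first well-defined local value sits at step k + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Embedding", "ContributorVector", "embed", "contributor_vector"]


@dataclass
class Embedding:
    """Destination embedding: for each valid n, the pair (x_n^(k), x_{n+1})."""

    k: int
    n_values: np.ndarray  # valid time indices n (1-based), length T - k
    history: np.ndarray   # (T - k, k) rows x_n^(k) = (x_n, ..., x_{n-k+1})
    next_value: np.ndarray  # (T - k,) values x_{n+1}


@dataclass
class ContributorVector:
    """Concatenated delayed source histories v_{X, n+1-d}^(l) per valid n."""

    source_indices: list[int]
    l_per_source: list[int]
    d: int
    n_values: np.ndarray
    vectors: np.ndarray  # (len(n_values), sum(l))


def embed(series: np.ndarray, k: int) -> Embedding:
    """Build the history/next-value pairs of a single series.

    For a series of length T there are T - k pairs, one per n in [k, T-1].
    """
    x = np.asarray(series, dtype=float).ravel()
    T = x.size
    if k < 1:
        raise ValueError("history length k must be >= 1")
    if T < k + 1:
        raise ValueError(f"series of length {T} too short for k={k}")
    n_values = np.arange(k, T)  # 1-based n = k .. T-1
    # row for n: (x_n, x_{n-1}, ..., x_{n-k+1}); x_n is x[n-1] (0-based)
    history = np.column_stack([x[n_values - 1 - j] for j in range(k)])
    next_value = x[n_values]  # x_{n+1} at 0-based index n
    return Embedding(k=k, n_values=n_values, history=history, next_value=next_value)


def contributor_vector(
    abundance: np.ndarray,
    destination: int,
    l_per_source: int | list[int],
    d: int,
    n_values: np.ndarray | None = None,
) -> ContributorVector:
    """Concatenate delayed source histories for every species but the destination.

    ``abundance`` is the (T, S) matrix; sources keep the input species order
    with the destination removed.  The vector at n is sampled at time
    m = n + 1 - d, requiring m >= l, so valid n >= l + d - 1 per source.
    """
    ab = np.asarray(abundance, dtype=float)
    if ab.ndim != 2:
        raise ValueError("abundance must be a (T, S) matrix")
    T, S = ab.shape
    if S < 2:
        raise ValueError("need at least two species to form a contributor vector")
    if d < 1:
        raise ValueError("delay d must be >= 1")
    sources = [s for s in range(S) if s != destination]
    if isinstance(l_per_source, (int, np.integer)):
        ls = [int(l_per_source)] * len(sources)
    else:
        ls = [int(v) for v in l_per_source]
        if len(ls) != len(sources):
            raise ValueError("l_per_source length must match number of sources")
    n_min = max(l + d - 1 for l in ls)
    if n_values is None:
        n_values = np.arange(n_min, T)
    else:
        n_values = np.asarray(n_values)
        n_values = n_values[(n_values >= n_min) & (n_values <= T - 1)]
    cols = []
    for s, l in zip(sources, ls):
        m = n_values + 1 - d  # 1-based sampling time of the source history
        for j in range(l):
            cols.append(ab[m - 1 - j, s])
    vectors = np.column_stack(cols) if cols else np.empty((len(n_values), 0))
    return ContributorVector(
        source_indices=sources,
        l_per_source=ls,
        d=d,
        n_values=n_values,
        vectors=vectors,
    )
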