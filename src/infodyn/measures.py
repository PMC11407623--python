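"""Local information measures on abundance time series.

Implements the information decomposition of a species' next abundance
value: local entropy h, active information storage a (AIS), apparent and
collective transfer entropy t (TE/CTE), and intrinsic uncertainty u, with

    h = a + t + u

per time step.  AIS is the local mutual information between the next value
and the species' own k-step history; TE/CTE condition the source histories
(delayed by d steps) on that own history; u is the residual surprise.  All
quantities are estimated with the KSG k-nearest-neighbour machinery in
:mod:`infodyn.knn` from the *whole* series, in nats, and averaged over
several noise realisations.

Estimating from the whole series is a deliberate convention: the series are
not stationary, so local values at one time can respond to data elsewhere
in the series.  This is a known artefact source and one reason the
effect-classification stage exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import knn
from .community import CommunityTimeSeries
from .embedding import contributor_vector, embed
from .tables import AnalysisConfig

__all__ = [
    "LocalSignal",
    "local_entropy",
    "local_ais",
    "local_apparent_te",
    "local_collective_te",
    "local_intrinsic_uncertainty",
    "decomposition_check",
    "average_over_living",
]


@dataclass
class LocalSignal:
    """Per-time-step values of one information measure for one species.

    ``values[t-1]`` is the local value (nats) at 1-based step t; entries
    outside the validity range are NaN.  ``significant`` is a whole-signal
    flag from the surrogate test (None if the test was not run).
    ``masked`` flags steps suppressed by the effect filter.
    """

    species: str
    measure: str  # one of 'h', 'AIS', 'TE', 'CTE', 'U'
    k: int
    l: Optional[int]
    d: Optional[int]
    values: np.ndarray
    valid: np.ndarray
    significant: Optional[bool] = None
    p_value: Optional[float] = None
    masked: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.masked is None:
            self.masked = np.zeros(self.values.size, dtype=bool)

    @property
    def mean_value(self) -> float:
        return float(np.nanmean(self.values[self.valid]))

    @property
    def n_steps(self) -> int:
        return self.values.size

    def steps(self) -> np.ndarray:
        """1-based time steps where the signal is valid."""
        return np.flatnonzero(self.valid) + 1


def _assemble(T: int, n_values: np.ndarray, local: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.full(T, np.nan)
    valid = np.zeros(T, dtype=bool)
    values[n_values] = local  # local value of transition n -> n+1 at step n+1
    valid[n_values] = True
    return values, valid


def _averaged(estimator, config: AnalysisConfig, seed) -> np.ndarray:
    mean, _ = knn.average_runs(estimator, config.n_estimation_runs, seed)
    return mean


def _series(x) -> np.ndarray:
    return np.asarray(x, dtype=float).ravel()


def local_entropy(
    series,
    k: int = 0,
    config: Optional[AnalysisConfig] = None,
    species: str = "",
    seed: Optional[int] = None,
) -> LocalSignal:
    """Local entropy -log p(x_{n+1}) of the next value, nats.

    ``k`` only restricts the valid range (n >= k) so that h aligns with the
    other measures of a decomposition; the estimate itself uses no history.
    """
    config = config or AnalysisConfig()
    x = _series(series)
    T = x.size
    n_values = np.arange(k, T)
    A = x[n_values]
    local = _averaged(
        lambda rng: knn.local_entropy_knn(A, config.knn_k, config.noise_amplitude, rng),
        config, config.rng_seed if seed is None else seed,
    )
    values, valid = _assemble(T, n_values, local)
    return LocalSignal(species, "h", k, None, None, values, valid)


def local_ais(
    series,
    k: int,
    config: Optional[AnalysisConfig] = None,
    species: str = "",
    seed: Optional[int] = None,
    significance: bool = False,
) -> LocalSignal:
    """Local active information storage a(x_{n+1}, x_n^(k)), nats.

    The local MI between the next value and the own k-step history.
    Negative values flag steps where the history is misinformative.
    """
    config = config or AnalysisConfig()
    x = _series(series)
    if x.size < k + 2:
        raise ValueError(f"series of length {x.size} too short for k={k} (need >= k+2)")
    emb = embed(x, k)
    A, B = emb.next_value, emb.history
    base_seed = config.rng_seed if seed is None else seed
    local = _averaged(
        lambda rng: knn.local_cmi(A, B, None, config.knn_k, config.noise_amplitude, rng),
        config, base_seed,
    )
    values, valid = _assemble(x.size, emb.n_values, local)
    sig = LocalSignal(species, "AIS", k, None, None, values, valid)
    if significance:
        sig.p_value = knn.surrogate_pvalue(
            A, B, None, config.knn_k, config.noise_amplitude,
            config.n_surrogates, base_seed, observed=float(local.mean()),
        )
        sig.significant = sig.p_value <= config.significance_alpha
    return sig


def _te_blocks(dest: np.ndarray, k: int, l: int, d: int):
    T = dest.size
    n_min = max(k, l + d - 1)
    if T < n_min + 2:
        raise ValueError(f"series of length {T} too short for k={k}, l={l}, d={d}")
    emb = embed(dest, k)
    keep = emb.n_values >= n_min
    return emb.n_values[keep], emb.next_value[keep], emb.history[keep]


def local_apparent_te(
    source,
    dest,
    k: int,
    l: Optional[int] = None,
    d: Optional[int] = None,
    config: Optional[AnalysisConfig] = None,
    species: str = "",
    seed: Optional[int] = None,
    significance: bool = False,
) -> LocalSignal:
    """Local apparent transfer entropy from one source to the destination.

    Local conditional MI between x_{n+1} and the source history
    y_{n+1-d}^(l), given the destination's own history x_n^(k).
    """
    config = config or AnalysisConfig()
    x = _series(dest)
    y = _series(source)
    if x.size != y.size:
        raise ValueError("source and destination series must have equal length")
    if np.shares_memory(x, y) or np.array_equal(x, y):
        raise ValueError("source and destination must be different series")
    l = config.source_history(k) if l is None else l
    d = config.delay if d is None else d
    n_values, A, C = _te_blocks(x, k, l, d)
    m = n_values + 1 - d
    B = np.column_stack([y[m - 1 - j] for j in range(l)])
    base_seed = config.rng_seed if seed is None else seed
    local = _averaged(
        lambda rng: knn.local_cmi(A, B, C, config.knn_k, config.noise_amplitude, rng),
        config, base_seed,
    )
    values, valid = _assemble(x.size, n_values, local)
    sig = LocalSignal(species, "TE", k, l, d, values, valid)
    if significance:
        sig.p_value = knn.surrogate_pvalue(
            A, B, C, config.knn_k, config.noise_amplitude,
            config.n_surrogates, base_seed, observed=float(local.mean()),
        )
        sig.significant = sig.p_value <= config.significance_alpha
    return sig


def local_collective_te(
    abundance,
    dest: int,
    k: int,
    l: Optional[int] = None,
    d: Optional[int] = None,
    config: Optional[AnalysisConfig] = None,
    species: str = "",
    seed: Optional[int] = None,
    significance: bool = False,
) -> LocalSignal:
    """Local collective transfer entropy from all other species.

    The contributor vector concatenates every other species' delayed
    l-step history (extinct species included with their zeros, keeping the
    dimension fixed).  Note CTE is a sum of incrementally conditioned TEs,
    not the sum of apparent TEs.
    """
    config = config or AnalysisConfig()
    ab = np.asarray(abundance, dtype=float)
    x = ab[:, dest]
    l = config.source_history(k) if l is None else l
    d = config.delay if d is None else d
    n_values, A, C = _te_blocks(x, k, l, d)
    cv = contributor_vector(ab, dest, l, d, n_values=n_values)
    if not np.array_equal(cv.n_values, n_values):
        raise RuntimeError("contributor vector validity mismatch")
    B = cv.vectors
    base_seed = config.rng_seed if seed is None else seed
    local = _averaged(
        lambda rng: knn.local_cmi(A, B, C, config.knn_k, config.noise_amplitude, rng),
        config, base_seed,
    )
    values, valid = _assemble(x.size, n_values, local)
    sig = LocalSignal(species, "CTE", k, l, d, values, valid)
    if significance:
        sig.p_value = knn.surrogate_pvalue(
            A, B, C, config.knn_k, config.noise_amplitude,
            config.n_surrogates, base_seed, observed=float(local.mean()),
        )
        sig.significant = sig.p_value <= config.significance_alpha
    return sig


def local_intrinsic_uncertainty(
    abundance,
    dest: int,
    k: int,
    l: Optional[int] = None,
    d: Optional[int] = None,
    config: Optional[AnalysisConfig] = None,
    species: str = "",
    seed: Optional[int] = None,
) -> LocalSignal:
    """Local intrinsic uncertainty -log p(x_{n+1} | own past, all sources)."""
    config = config or AnalysisConfig()
    ab = np.asarray(abundance, dtype=float)
    if ab.ndim == 1:
        ab = ab[:, None]
    x = ab[:, dest]
    l = config.source_history(k) if l is None else l
    d = config.delay if d is None else d
    if ab.shape[1] == 1:  # no sources: U reduces to -log p(x | own past)
        n_values, A, C = _te_blocks(x, k, max(l, 1), d)
        cond = C
    else:
        n_values, A, C = _te_blocks(x, k, l, d)
        cv = contributor_vector(ab, dest, l, d, n_values=n_values)
        cond = np.hstack([C, cv.vectors])
    base_seed = config.rng_seed if seed is None else seed
    local = _averaged(
        lambda rng: knn.local_conditional_entropy(
            A, cond, config.knn_k, config.noise_amplitude, rng
        ),
        config, base_seed,
    )
    values, valid = _assemble(x.size, n_values, local)
    return LocalSignal(species, "U", k, l, d, values, valid)


def decomposition_check(
    abundance,
    dest: int,
    k: int,
    l: Optional[int] = None,
    d: Optional[int] = None,
    config: Optional[AnalysisConfig] = None,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-step residual of the identity h = a + t + u.

    Returns (1-based steps, residual in nats).  All four terms are
    estimated on the identical point set, so the residual reflects only the
    disagreement between the k-NN estimators of the different joint spaces.
    """
    config = config or AnalysisConfig()
    ab = np.asarray(abundance, dtype=float)
    if ab.ndim == 1:
        ab = ab[:, None]
    x = ab[:, dest]
    l = config.source_history(k) if l is None else l
    d = config.delay if d is None else d
    base_seed = config.rng_seed if seed is None else seed
    h = local_entropy(x, max(k, l + d - 1), config, seed=base_seed)
    a = local_ais(x, k, config, seed=base_seed)
    u = local_intrinsic_uncertainty(ab, dest, k, l, d, config, seed=base_seed)
    if ab.shape[1] > 1:
        t = local_collective_te(ab, dest, k, l, d, config, seed=base_seed)
        t_values, t_valid = t.values, t.valid
    else:  # no contributors: h = a + u, transfer is identically zero
        t_values, t_valid = np.zeros_like(h.values), np.ones_like(h.valid)
    valid = h.valid & a.valid & t_valid & u.valid
    residual = h.values[valid] - (a.values[valid] + t_values[valid] + u.values[valid])
    return np.flatnonzero(valid) + 1, residual


def average_over_living(
    signals: Sequence[LocalSignal],
    ts: CommunityTimeSeries,
) -> LocalSignal:
    """Average per-species signals over the species alive at each step.

    A species contributes at step t while its abundance there is positive;
    steps where no species is alive (or no signal valid) are invalid.
    """
    if not signals:
        raise ValueError("no signals to average")
    T = signals[0].n_steps
    name_to_col = {n: i for i, n in enumerate(ts.species_names)}
    values = np.full(T, np.nan)
    valid = np.zeros(T, dtype=bool)
    alive = ts.alive()
    for t in range(T):
        contributions = []
        for sig in signals:
            col = name_to_col[sig.species]
            if alive[t, col] and sig.valid[t]:
                contributions.append(sig.values[t])
        if contributions:
            values[t] = float(np.mean(contributions))
            valid[t] = True
    first = signals[0]
    return LocalSignal(
        "living_mean", first.measure, first.k, first.l, first.d, values, valid
    )
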