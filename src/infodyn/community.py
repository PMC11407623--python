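"""Synthetic seven-species gut community simulator.

A deliberately small discrete-time resource-consumer model standing in for
an agent-based metabolic simulation of the SIHUMI community (Anaerostipes,
Bacteroides, Bifidobacterium, Blautia, Clostridium, Escherichia,
Lactobacillus).  The model reproduces the qualitative phases such data
shows: initial growth on a rich medium, plateaus of constant abundance once
nutrients run short, starvation collapse with absorbing extinctions, renewed
growth after feeding events, and a terminal die-off that leaves a single
generalist survivor.

Mechanism, per time step:

* every individual demands a per-capita ``uptake`` from a shared resource
  pool; species are served in order of increasing uptake (efficient
  consumers feed first) and a species either gets its full demand or
  nothing;
* a fully fed species below carrying capacity grows by a binomial draw
  ``Binomial(N, growth_rate)`` (integer abundances, stochastic across
  seeds);
* an underfed species holds its abundance constant (plateau) until it has
  starved for more than ``starvation_tolerance`` consecutive steps, after
  which it loses ``max(1, Binomial(N, death_rate))`` individuals per step;
* abundance 0 is absorbing;
* at each feeding step the pool is replenished by ``resource_refill``.

Two interventions mirror the analysis scenarios: random multiplicative
jitter of abundances inside a window (coherence disturbance), and injection
of a metabolite-producing strain whose product boosts a target species'
growth exactly two steps later (enforced crossfeeding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SIHUMI_SPECIES",
    "CommunityConfig",
    "CommunityTimeSeries",
    "simulate_base",
    "disturb_coherence",
    "enforce_crossfeeding",
    "crossfeeding_config",
    "single_plateau_series",
]

SIHUMI_SPECIES = [
    "Anaerostipes",
    "Bacteroides",
    "Bifidobacterium",
    "Blautia",
    "Clostridium",
    "Escherichia",
    "Lactobacillus",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class CommunityConfig:
    """Parameters of the base community simulation.

    Per-species arrays follow the order of ``species_names``.  Defaults are
    tuned once to reproduce the qualitative phase structure described above
    on a 184-step run with feedings after steps 35, 62 and 121.
    """

    species_names: list[str] = field(default_factory=lambda: list(SIHUMI_SPECIES))
    n_steps: int = 184
    feeding_steps: list[int] = field(default_factory=lambda: [35, 62, 121])
    initial_abundance: int = 10
    carrying_capacity: int = 500
    growth_rate: Sequence[float] = (0.45, 0.55, 0.40, 0.50, 0.35, 0.30, 0.60)
    starvation_tolerance: Sequence[int] = (36, 16, 33, 22, 30, 45, 17)
    death_rate: Sequence[float] = (0.45, 0.50, 0.42, 0.40, 0.35, 0.10, 0.55)
    uptake: Sequence[float] = (1.0, 1.8, 0.9, 1.25, 0.8, 0.45, 1.6)
    resource_refill: float = 14000.0
    rng_seed: int = 0

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def validate(self) -> None:
        s = self.n_species
        for name in ("growth_rate", "death_rate", "uptake", "starvation_tolerance"):
            if len(getattr(self, name)) != s:
                raise ValueError(f"{name} must have one entry per species")
        if self.feeding_steps and self.n_steps <= max(self.feeding_steps):
            raise ValueError("n_steps must exceed every feeding step")
        for r in list(self.growth_rate) + list(self.death_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("growth and death rates must lie in [0, 1]")
        if self.initial_abundance < 0:
            raise ValueError("initial_abundance must be >= 0")
        if min(self.uptake) <= 0:
            raise ValueError("uptake must be positive")


@dataclass
class CommunityTimeSeries:
    """An S-species abundance record over T time steps (1-based steps).

    ``abundance[t-1, s]`` is the count of species s at step t.  Extinction
    is absorbing: once a species hits zero it stays there, and
    ``extinction_step`` records the first zero step (None if it survives).
    ``resource`` optionally tracks the internal nutrient pool.
    """

    species_names: list[str]
    abundance: np.ndarray
    feeding_steps: list[int]
    extinction_step: list[Optional[int]]
    resource: Optional[np.ndarray] = None

    @property
    def n_steps(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_species(self) -> int:
        return self.abundance.shape[1]

    def alive(self) -> np.ndarray:
        """Boolean (T, S) mask of strictly positive abundance."""
        return self.abundance > 0

    def validate(self) -> None:
        ab = self.abundance
        if np.any(ab < 0):
            raise ValueError("abundances must be non-negative")
        if not np.issubdtype(ab.dtype, np.integer):
            raise ValueError("abundances must be integers")
        for s in range(self.n_species):
            col = ab[:, s]
            zeros = np.flatnonzero(col == 0)
            first = int(zeros[0]) + 1 if zeros.size else None
            if first is not None and np.any(col[first - 1:] > 0):
                raise ValueError(
                    f"species {self.species_names[s]} resurrects after step {first}"
                )
            if self.extinction_step[s] != first:
                raise ValueError("extinction_step inconsistent with matrix")


def extinction_steps(abundance: np.ndarray) -> list[Optional[int]]:
    """First step (1-based) of a terminal run of zeros, per species."""
    out: list[Optional[int]] = []
    for s in range(abundance.shape[1]):
        col = abundance[:, s]
        if col[-1] > 0:
            out.append(None)
            continue
        t = abundance.shape[0]
        while t > 1 and col[t - 2] == 0:
            t -= 1
        out.append(t)
    return out


def _simulate(
    config: CommunityConfig,
    rng: np.random.Generator,
    producer: Optional[int] = None,
    target: Optional[int] = None,
    injection_step: Optional[int] = None,
    n_injected: int = 0,
    boost: float = 0.0,
    metabolite_yield: float = 1.0,
    metabolite_threshold: float = 1000.0,
    hyper_production: float = 1000.0,
) -> CommunityTimeSeries:
    config.validate()
    T, S = config.n_steps, config.n_species
    ab = np.zeros((T, S), dtype=np.int64)
    res = np.zeros(T)
    ab[0] = config.initial_abundance
    if injection_step == 1 and producer is not None:
        ab[0, producer] += n_injected
    resource = config.resource_refill
    res[0] = resource
    hungry = np.zeros(S, dtype=int)
    order = np.argsort(config.uptake, kind="stable")
    growth = np.asarray(config.growth_rate)
    death = np.asarray(config.death_rate)
    uptake = np.asarray(config.uptake)
    tol = np.asarray(config.starvation_tolerance)
    metabolite = 0.0

    for t in range(1, T):  # compute row t (step t+1) from row t-1 (step t)
        step = t  # 1-based step of the current state
        if step in config.feeding_steps:
            resource += config.resource_refill
        N = ab[t - 1].astype(float)
        fed = np.zeros(S, dtype=bool)
        for s in order:
            if N[s] == 0:
                continue
            need = N[s] * uptake[s]
            if resource >= need:
                resource -= need
                fed[s] = True
            else:
                # underfed species scavenge what is left without growing,
                # so the pool empties instead of sustaining stragglers
                resource = 0.0
        # crossfeeding: metabolite produced at step `step` is available at
        # step + 1 and, if above threshold, boosts the target's growth in
        # the transition step+1 -> step+2 (an effective lag of two steps).
        # Injected individuals are a hyper-producing strain, so their
        # contribution dwarfs the species' ordinary output and reliably
        # crosses the threshold.
        boost_now = metabolite > metabolite_threshold
        if producer is not None:
            hyper = n_injected if (injection_step is not None and step >= injection_step) else 0
            metabolite = metabolite_yield * (
                N[producer] + (hyper_production - 1.0) * min(hyper, N[producer])
            )
        for s in range(S):
            n = int(N[s])
            if n == 0:
                continue
            if fed[s]:
                hungry[s] = 0
                inc = int(rng.binomial(n, growth[s]))
                n = min(config.carrying_capacity, n + inc)
            else:
                hungry[s] += 1
                if hungry[s] > tol[s]:
                    dec = max(1, int(rng.binomial(n, death[s])))
                    n = max(0, n - dec)
            if boost_now and s == target and n > 0:
                n = min(config.carrying_capacity, n + max(1, _round_half_up(n * boost)))
            ab[t, s] = n
        if injection_step is not None and step + 1 == injection_step and producer is not None:
            ab[t, producer] += n_injected
        res[t] = resource
    return CommunityTimeSeries(
        species_names=list(config.species_names),
        abundance=ab,
        feeding_steps=list(config.feeding_steps),
        extinction_step=extinction_steps(ab),
        resource=res,
    )


def simulate_base(config: Optional[CommunityConfig] = None) -> CommunityTimeSeries:
    """Run the base scenario: three feedings, terminal die-off."""
    config = config or CommunityConfig()
    rng = np.random.default_rng(config.rng_seed)
    return _simulate(config, rng)


def disturb_coherence(
    ts: CommunityTimeSeries,
    window: tuple[int, int],
    jitter: float,
    seed: int = 0,
) -> CommunityTimeSeries:
    """Randomly jitter abundances of living species inside a step window.

    Each living species' count at each window step is independently scaled
    by a factor uniform on [1 - jitter, 1 + jitter] and rounded to a
    positive integer (extinction stays absorbing: dead species remain at 0,
    living ones never jitter down to 0).
    """
    t_start, t_end = window
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    if t_start < 1 or t_end > ts.n_steps or t_start > t_end:
        raise ValueError(f"window {window} not within series of {ts.n_steps} steps")
    rng = np.random.default_rng(seed)
    ab = ts.abundance.copy()
    for t in range(t_start, t_end + 1):
        for s in range(ts.n_species):
            n = ab[t - 1, s]
            if n == 0:
                continue
            factor = rng.uniform(1.0 - jitter, 1.0 + jitter)
            ab[t - 1, s] = max(1, _round_half_up(n * factor))
    return CommunityTimeSeries(
        species_names=list(ts.species_names),
        abundance=ab,
        feeding_steps=list(ts.feeding_steps),
        extinction_step=extinction_steps(ab),
        resource=None,
    )


def crossfeeding_config(rng_seed: int = 0) -> CommunityConfig:
    """Default configuration of the crossfeeding scenario: a short run on a
    quarter of the base medium with no intermediate feedings."""
    return CommunityConfig(
        n_steps=38,
        feeding_steps=[],
        resource_refill=3500.0,
        starvation_tolerance=(40,) * 7,
        rng_seed=rng_seed,
    )


def enforce_crossfeeding(
    ts_config: CommunityConfig,
    producer: int = 4,
    target: int = 1,
    injection_step: int = 28,
    n_injected: int = 20,
    boost: float = 0.3,
    metabolite_yield: float = 1.0,
    metabolite_threshold: float = 1000.0,
    hyper_production: float = 1000.0,
) -> CommunityTimeSeries:
    """Simulate with a producer-strain injection feeding a target species.

    At ``injection_step`` the producer's abundance is raised by
    ``n_injected``.  The producer continuously fills a metabolite pool in
    proportion to its abundance; once the pool exceeds
    ``metabolite_threshold`` the target's growth is boosted.  The pool turns
    over in one step, so the earliest abundance response of the target
    occurs exactly two steps after the injection.
    """
    if producer == target:
        raise ValueError("producer and target must differ")
    if n_injected < 0:
        raise ValueError("n_injected must be >= 0")
    if not (0 <= producer < ts_config.n_species and 0 <= target < ts_config.n_species):
        raise ValueError("invalid species index")
    if injection_step + 2 > ts_config.n_steps:
        raise ValueError("injection_step + 2 must not exceed n_steps")
    rng = np.random.default_rng(ts_config.rng_seed)
    return _simulate(
        ts_config,
        rng,
        producer=producer,
        target=target,
        injection_step=injection_step,
        n_injected=n_injected,
        boost=boost,
        metabolite_yield=metabolite_yield,
        metabolite_threshold=metabolite_threshold,
        hyper_production=hyper_production,
    )


def single_plateau_series(
    length: int = 150,
    change_step: int = 101,
    low: int = 10,
    high: int = 50,
) -> np.ndarray:
    """A single-species series with one abrupt change into a constant plateau.

    The series sits at ``low`` and jumps once, at ``change_step``, to a
    constant plateau at ``high``.  This is the minimal series exhibiting a
    delayed effect: the storage signal's plateau-entry feature appears at
    step ``change_step + k`` (the step where the jump leaves the
    conditioned k-step window) and therefore moves with the history
    length, while the change-step outlier itself stays put.
    """
    x = np.full(length, low, dtype=np.int64)
    x[change_step - 1:] = high
    return x
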