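"""Reading and writing abundance tables and analysis results.

Abundance tables are plain CSVs: a ``time_step`` column (1-based, optional
on input) followed by one integer column per species.  Analysis results use
a long format with one row per (species, measure, k, time step).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from .community import CommunityTimeSeries, extinction_steps

__all__ = [
    "AnalysisConfig",
    "read_abundance",
    "write_abundance",
    "write_signals",
    "read_signals",
]


@dataclass
class AnalysisConfig:
    """Parameters of the information-theoretic estimation.

    History lengths follow the k-variant convention (k = 10, 15, 20); source
    histories use l = k - 1, which together with the source-destination
    delay d = 2 aligns source and destination validity ranges.  Estimates
    are averaged over ``n_estimation_runs`` noise realisations and tested
    against ``n_surrogates`` source permutations at level
    ``significance_alpha``.
    """

    history_lengths: list[int] = field(default_factory=lambda: [10, 15, 20])
    delay: int = 2
    n_estimation_runs: int = 25
    significance_alpha: float = 0.05
    knn_k: int = 4
    noise_amplitude: float = 1e-8
    n_surrogates: int = 100
    rng_seed: int = 0

    def source_history(self, k: int) -> int:
        return k - 1

    def validate(self) -> None:
        if any(k < 1 for k in self.history_lengths):
            raise ValueError("history lengths must be >= 1")
        if self.delay < 1:
            raise ValueError("delay must be >= 1")
        if not 0.0 < self.significance_alpha < 1.0:
            raise ValueError("significance_alpha must be in (0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def read_abundance(
    path: str | Path,
    column_map: Optional[dict[str, str]] = None,
    feeding_steps: Optional[list[int]] = None,
) -> CommunityTimeSeries:
    """Read an abundance CSV into a community time series.

    ``column_map`` renames input columns to species names (and may map a
    differently named step column to ``time_step``), which allows loading
    externally produced tables.  Extinction steps are inferred from the
    first terminal zero.  A zero followed by positive abundance is accepted
    verbatim with a warning, since estimation does not require absorbing
    extinction.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if "time_step" in df.columns:
        df = df.drop(columns=["time_step"])
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric abundance cells")
    if np.any(~np.isfinite(values)):
        raise ValueError(f"{path}: missing or non-finite abundance cells")
    if np.any(values < 0):
        raise ValueError(f"{path}: negative abundances")
    if np.any(values != np.round(values)):
        raise ValueError(f"{path}: abundances must be integer counts")
    ab = values.astype(np.int64)
    for s, name in enumerate(df.columns):
        col = ab[:, s]
        zeros = np.flatnonzero(col == 0)
        if zeros.size and np.any(col[zeros[0]:] > 0):
            warnings.warn(
                f"species {name} has zero abundance followed by positive "
                "values (no absorbing extinction); series accepted verbatim"
            )
    return CommunityTimeSeries(
        species_names=list(df.columns),
        abundance=ab,
        feeding_steps=list(feeding_steps or []),
        extinction_step=extinction_steps(ab),
    )


def write_abundance(ts: CommunityTimeSeries, path: str | Path) -> None:
    """Write the abundance matrix as CSV plus a JSON sidecar of metadata."""
    path = Path(path)
    df = pd.DataFrame(ts.abundance, columns=ts.species_names)
    df.insert(0, "time_step", np.arange(1, ts.n_steps + 1))
    df.to_csv(path, index=False)
    sidecar = {
        "feeding_steps": list(map(int, ts.feeding_steps)),
        "extinction_step": [None if e is None else int(e) for e in ts.extinction_step],
    }
    path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=1))


_SIGNAL_COLUMNS = [
    "species", "measure", "k", "time_step",
    "value_nats", "valid", "significant", "effect_label",
]


def write_signals(signals: Iterable, path: str | Path) -> None:
    """Serialise local signals to long-format CSV (lossless round trip).

    Accepts LocalSignal objects or (signal, labels) pairs where ``labels``
    is a per-step effect annotation array.
    """
    rows = []
    seen = set()
    for item in signals:
        if isinstance(item, tuple):
            sig, labels = item
        else:
            sig, labels = item, None
        key = (sig.species, sig.measure, sig.k)
        if key in seen:
            raise ValueError(f"duplicate signal key {key}")
        seen.add(key)
        T = sig.values.size
        for t in range(1, T + 1):
            rows.append({
                "species": sig.species,
                "measure": sig.measure,
                "k": sig.k,
                "time_step": t,
                "value_nats": sig.values[t - 1],
                "valid": bool(sig.valid[t - 1]),
                "significant": sig.significant,
                "effect_label": labels[t - 1] if labels is not None else "",
            })
    pd.DataFrame(rows, columns=_SIGNAL_COLUMNS).to_csv(path, index=False)


def read_signals(path: str | Path) -> pd.DataFrame:
    """Read a long-format signal table back into a DataFrame."""
    df = pd.read_csv(
        path,
        dtype={"species": str, "measure": str, "effect_label": str},
        keep_default_na=False,
        na_values=[""],
    )
    missing = [c for c in _SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df
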