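"""Ensemble construction: M repeated runs of the base RF clustering.

Each run draws its own cluster count k under one of three schemes —
TrueK (k = the known number of populations), FixedK (k = ceil(sqrt(N)),
deliberately over-produced) or RandomK (k uniform in [2, ceil(sqrt(N))]
per run) — and gets an independent seed derived from the master seed by
counter-based splitting (numpy SeedSequence spawning), so concurrent
and sequential execution produce identical ensembles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .datatypes import Partition
from .errors import ValidationError
from .forest import ForestConfig, rf_cluster_once

__all__ = ["KScheme", "EnsembleConfig", "Ensemble", "choose_k", "build_ensemble"]

_SCHEMES = ("TrueK", "FixedK", "RandomK")


@dataclass
class KScheme:
    """How each ensemble member picks its number of clusters."""

    mode: str = "FixedK"
    true_k: int | None = None

    def __post_init__(self) -> None:
        aliases = {"true": "TrueK", "fixed": "FixedK", "random": "RandomK"}
        self.mode = aliases.get(str(self.mode).lower(), self.mode)
        if self.mode not in _SCHEMES:
            raise ValidationError(f"unknown k scheme {self.mode!r}; use {_SCHEMES}")
        if self.mode == "TrueK":
            if self.true_k is None or self.true_k < 1:
                raise ValidationError("TrueK scheme requires true_k >= 1")


def choose_k(scheme: KScheme, n: int, rng: np.random.Generator) -> int:
    """Cluster count for one run; RandomK draws fresh per call."""
    if n < 2:
        raise ValidationError("need at least 2 individuals")
    ceil_sqrt = math.ceil(math.sqrt(n))
    if scheme.mode == "TrueK":
        return int(scheme.true_k)
    if scheme.mode == "FixedK":
        return ceil_sqrt
    return int(rng.integers(2, ceil_sqrt + 1))


@dataclass
class EnsembleConfig:
    """All tunables of ensemble construction.

    Desk-scale defaults (m=10, ntrees=500) keep experiments minutes-sized;
    the published comparison settings are m=40, ntrees=10000, MN=sqrt(N),
    FixedK (see :func:`paper_scale`).
    """

    forest: ForestConfig = field(default_factory=ForestConfig)
    m: int = 10
    scheme: KScheme = field(default_factory=KScheme)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValidationError("ensemble size m must be >= 1")


def paper_scale(scheme: KScheme | None = None, master_seed: int = 0) -> EnsembleConfig:
    """The published best-performing configuration (m=40, ntrees=10000)."""
    return EnsembleConfig(
        forest=ForestConfig(ntrees=10_000),
        m=40,
        scheme=scheme or KScheme("FixedK"),
        master_seed=master_seed,
    )


@dataclass
class Ensemble:
    """M partitions of the same N individuals, plus the k each run drew."""

    partitions: list[Partition]
    member_ks: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.partitions:
            raise ValidationError("empty ensemble")
        n = len(self.partitions[0])
        if any(len(p) != n for p in self.partitions):
            raise ValidationError("ensemble members cover different individuals")

    def __len__(self) -> int:
        return len(self.partitions)

    @property
    def n_individuals(self) -> int:
        return len(self.partitions[0])


def _run_member(g_values, forest_cfg: ForestConfig, k: int, seed: int) -> Partition:
    return rf_cluster_once(g_values, forest_cfg, k, seed=seed)


def build_ensemble(g, cfg: EnsembleConfig, n_jobs: int = 1) -> Ensemble:
    """Run the base clustering M times with independently split seeds.

    Member i's seed comes from SeedSequence(master_seed).spawn(M)[i], a
    counter-based derivation: results do not depend on worker count or
    execution order, so ``n_jobs > 1`` reproduces the sequential output
    bit for bit.
    """
    from .forest import _as_matrix  # local to avoid cycle at import time

    X = _as_matrix(g)
    n = X.shape[0]
    children = np.random.SeedSequence(cfg.master_seed).spawn(cfg.m)
    ks, seeds = [], []
    for child in children:
        member_rng = np.random.default_rng(child)
        ks.append(choose_k(cfg.scheme, n, member_rng))
        seeds.append(int(child.generate_state(1)[0] % (2**31)))
    if n_jobs == 1:
        parts = [_run_member(X, cfg.forest, k, s) for k, s in zip(ks, seeds)]
    else:
        parts = Parallel(n_jobs=n_jobs)(
            delayed(_run_member)(X, cfg.forest, k, s) for k, s in zip(ks, seeds)
        )
    return Ensemble(list(parts), ks)
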