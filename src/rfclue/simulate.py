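"""Synthetic SNP genotypes for K differentiated subpopulations.

The generator follows the Balding–Nichols model: each marker has an
ancestral minor-allele frequency p drawn uniformly from ``maf_range``;
each subpopulation's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) with
F the divergence parameter (an FST analogue), so that
E[p_k] = p and Var[p_k] = F p(1-p); individual genotypes are
Binomial(2, p_k) counts of the rare allele. Markers are independent —
there is no linkage disequilibrium. An optional duplication knob copies
each marker ``duplicate_factor`` times with flip noise to mimic marker
redundancy crudely.

Presets mirror the shapes (N, l, K) of three published human SNP panels
commonly used to benchmark population-structure methods, scalable down
for desk-sized experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import GenotypeMatrix, PopulationLabels
from .errors import ValidationError

#: (individuals, markers, populations) of the three reference panel shapes.
DATASET_SHAPES = {
    "hapmap": (762, 46_256, 11),
    "panasian": (443, 54_794, 10),
    "shriver": (274, 10_805, 12),
}

__all__ = ["SimulationConfig", "simulate_populations", "sample_shape_like", "latent_fst"]


@dataclass
class SimulationConfig:
    """Parameters of a Balding–Nichols genotype simulation.

    Attributes
    ----------
    n_populations : number of subpopulations K.
    n_per_population : individuals per subpopulation (int, or one per pop).
    n_markers : number of independent SNP markers l.
    fst : divergence F in (0, 1); higher separates populations more.
    maf_range : interval within (0, 0.5] for the ancestral frequency;
        the default floor of 0.05 avoids near-monomorphic markers.
    duplicate_factor : copy each marker this many times (>=1).
    flip_noise : per-copy probability of perturbing a duplicated genotype
        by resampling it from the marker's marginal.
    seed : RNG seed; the simulation is deterministic given the config.
    """

    n_populations: int
    n_per_population: int | list[int]
    n_markers: int
    fst: float = 0.2
    maf_range: tuple[float, float] = (0.05, 0.5)
    duplicate_factor: int = 1
    flip_noise: float = 0.0
    seed: int = 0
    population_names: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValidationError("n_populations must be >= 1")
        if isinstance(self.n_per_population, (int, np.integer)):
            self.n_per_population = [int(self.n_per_population)] * self.n_populations
        self.n_per_population = [int(c) for c in self.n_per_population]
        if len(self.n_per_population) != self.n_populations:
            raise ValidationError(
                f"{len(self.n_per_population)} counts for {self.n_populations} populations"
            )
        if min(self.n_per_population) < 1:
            raise ValidationError("every population needs >= 1 individual")
        if self.n_markers < 1:
            raise ValidationError("n_markers must be >= 1")
        if not 0 < self.fst < 1:
            raise ValidationError(f"fst must be in (0, 1), got {self.fst}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.duplicate_factor < 1:
            raise ValidationError("duplicate_factor must be >= 1")
        if not 0 <= self.flip_noise <= 1:
            raise ValidationError("flip_noise must be in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return sum(self.n_per_population)


def simulate_populations(
    cfg: SimulationConfig, return_frequencies: bool = False
) -> tuple[GenotypeMatrix, PopulationLabels] | tuple[
    GenotypeMatrix, PopulationLabels, np.ndarray, np.ndarray
]:
    """Draw a genotype matrix plus truth labels under ``cfg``.

    With ``return_frequencies=True`` the ancestral frequencies (l,) and the
    per-population latent frequencies (K, l) are returned as well, which is
    what a divergence estimate such as :func:`latent_fst` needs.
    """
    rng = np.random.default_rng(cfg.seed)
    K, l = cfg.n_populations, cfg.n_markers
    lo, hi = cfg.maf_range

    p = rng.uniform(lo, hi, size=l)
    # Degenerate Beta shapes can only arise from p at the boundary; resample.
    while np.any((p <= 0) | (p >= 1)):
        bad = (p <= 0) | (p >= 1)
        p[bad] = rng.uniform(lo, hi, size=bad.sum())

    F = cfg.fst
    pop_freq = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F, size=(K, l))
    pop_freq = np.clip(pop_freq, 0.0, 1.0)

    blocks = []
    for k, count in enumerate(cfg.n_per_population):
        blocks.append(rng.binomial(2, pop_freq[k], size=(count, l)))
    G = np.concatenate(blocks).astype(np.int8)

    if cfg.duplicate_factor > 1:
        copies = [G]
        for _ in range(cfg.duplicate_factor - 1):
            dup = G.copy()
            if cfg.flip_noise > 0:
                flip = rng.random(dup.shape) < cfg.flip_noise
                resampled = np.empty_like(dup)
                for j in range(l):
                    resampled[:, j] = rng.choice(G[:, j], size=dup.shape[0])
                dup[flip] = resampled[flip]
            copies.append(dup)
        G = np.concatenate(copies, axis=1)

    names = cfg.population_names or [f"pop{k + 1}" for k in range(K)]
    labels = np.repeat(names, cfg.n_per_population)
    ids = [f"ind{i}" for i in range(cfg.n_individuals)]
    marker_ids = [f"snp{j}" for j in range(G.shape[1])]
    gm = GenotypeMatrix(G, individual_ids=ids, marker_ids=marker_ids)
    pl = PopulationLabels(labels)
    if return_frequencies:
        return gm, pl, p, pop_freq
    return gm, pl


def latent_fst(ancestral: np.ndarray, pop_freq: np.ndarray) -> float:
    """Ratio-of-averages divergence estimate from the latent frequencies.

    Averages the between-population variance of the per-population
    frequencies over the total variance p(1-p), in the spirit of a
    Weir–Cockerham ratio estimator but computed on the latent (noise-free)
    frequencies, so it converges to the generating F as l grows.
    """
    if pop_freq.shape[0] < 2:
        raise ValidationError("need >= 2 populations to estimate divergence")
    # ddof=1: the K population draws are a sample from the Beta, and the
    # population-variance formula would be biased low by (K-1)/K.
    between = pop_freq.var(axis=0, ddof=1)
    total = ancestral * (1 - ancestral)
    return float(between.sum() / total.sum())


def sample_shape_like(dataset: str, scale: float = 1.0) -> SimulationConfig:
    """A config mirroring a reference panel's (N, l, K) at a reducible scale.

    Individuals are split near-evenly across the K populations; counts and
    marker numbers are rounded to the nearest integer.
    """
    if dataset not in DATASET_SHAPES:
        raise ValidationError(
            f"unknown dataset {dataset!r}; choose from {sorted(DATASET_SHAPES)}"
        )
    if not 0 < scale <= 1:
        raise ValidationError(f"scale must be in (0, 1], got {scale}")
    n, l, k = DATASET_SHAPES[dataset]
    n_scaled = round(scale * n)
    l_scaled = round(scale * l)
    base, extra = divmod(n_scaled, k)
    counts = [base + (1 if i < extra else 0) for i in range(k)]
    if min(counts) < 2:
        raise ValidationError(
            f"scale {scale} leaves fewer than 2 individuals in some population "
            f"({n_scaled} individuals across {k} populations)"
        )
    return SimulationConfig(
        n_populations=k, n_per_population=counts, n_markers=l_scaled
    )
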