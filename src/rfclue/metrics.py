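"""Agreement metrics between partitions and ensemble diagnostics.

All metrics are computed from the contingency table of the two label
vectors. NMI normalizes mutual information by the arithmetic mean of the
two entropies (natural log; 0*log 0 := 0), so identical partitions score
1 and independent ones 0. ARI is the pair-counting Rand index adjusted
for its hypergeometric chance expectation. Accuracy (AC) is cluster
purity: each cluster is assigned its majority truth label and the
fraction of individuals matching their cluster's label is reported.

Ensemble diagnostics: diversity DS(P) is the mean pairwise (1 - NMI)
over members; quality Q(P) the mean NMI of members against truth; the
final quality Q(P*) is NMI of the consensus partition against truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .datatypes import as_labels
from .errors import ValidationError

__all__ = [
    "contingency",
    "nmi",
    "ari",
    "accuracy",
    "ensemble_diversity",
    "ensemble_quality",
    "final_quality",
    "MetricsReport",
    "evaluate_partition",
]


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a, b = as_labels(a), as_labels(b)
    if len(a) != len(b):
        raise ValidationError(f"partition lengths differ: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValidationError("empty partitions")
    return a, b


def contingency(a, b) -> np.ndarray:
    """k_A x k_B table of shared counts N_ij between clusters of a and b."""
    a, b = _check_pair(a, b)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def _mutual_information(table: np.ndarray) -> float:
    n = table.sum()
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    nz = table > 0
    t = table[nz].astype(float)
    outer = (rows @ cols)[nz].astype(float)
    return float((t / n * np.log(t * n / outer)).sum())


def nmi(a, b) -> float:
    """Normalized mutual information, MI / ((H(A)+H(B))/2), in [0, 1]."""
    table = contingency(a, b)
    n = int(table.sum())
    h_a = _entropy(table.sum(axis=1), n)
    h_b = _entropy(table.sum(axis=0), n)
    if h_a == 0.0 and h_b == 0.0:
        # Both partitions are single-cluster, hence identical.
        return 1.0
    mi = _mutual_information(table)
    return float(mi / ((h_a + h_b) / 2))


def nmi_expanded(a, b) -> float:
    """NMI via the single-fraction count form; agrees with :func:`nmi`.

    Numerator -2 * sum N_ij log(N_ij N / (N_i. N_.j)); denominator
    sum N_i. log(N_i./N) + sum N_.j log(N_.j/N). Kept as an internal
    cross-check that the two algebraic forms coincide.
    """
    table = contingency(a, b)
    n = int(table.sum())
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    nz = table > 0
    t = table[nz].astype(float)
    outer = (rows[:, None] @ cols[None, :])[nz].astype(float)
    num = -2.0 * float((t * np.log(t * n / outer)).sum())
    den = float((rows[rows > 0] * np.log(rows[rows > 0] / n)).sum()) + float(
        (cols[cols > 0] * np.log(cols[cols > 0] / n)).sum()
    )
    if den == 0.0:
        return 1.0
    return num / den


def ari(a, b) -> float:
    """Adjusted Rand index; 1 for identical partitions, ~0 for random ones."""
    table = contingency(a, b)
    n = int(table.sum())
    if n < 2:
        raise ValidationError("ARI needs at least 2 individuals")

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table.astype(float)).sum()
    sum_a = comb2(table.sum(axis=1).astype(float)).sum()
    sum_b = comb2(table.sum(axis=0).astype(float)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        # Degenerate margins (both single-cluster or all-singleton): the
        # partitions are forced equal, so agreement is perfect.
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def accuracy(p, truth) -> float:
    """Cluster purity: majority-truth-label agreement fraction."""
    table = contingency(p, truth)
    return float(table.max(axis=1).sum() / table.sum())


def _member_list(ensemble) -> list[np.ndarray]:
    members = getattr(ensemble, "partitions", ensemble)
    return [as_labels(m) for m in members]


def ensemble_diversity(ensemble) -> float:
    """DS(P): mean pairwise (1 - NMI) across the M ensemble members."""
    members = _member_list(ensemble)
    m = len(members)
    if m < 2:
        raise ValidationError("diversity needs at least 2 ensemble members")
    total = 0.0
    for i in range(m - 1):
        for j in range(i + 1, m):
            total += 1.0 - nmi(members[i], members[j])
    return 2.0 * total / (m * (m - 1))


def ensemble_quality(ensemble, truth) -> float:
    """Q(P): mean NMI of ensemble members against the truth labels."""
    members = _member_list(ensemble)
    if not members:
        raise ValidationError("empty ensemble")
    return float(np.mean([nmi(m, truth) for m in members]))


def final_quality(p_star, truth) -> float:
    """Q(P*): NMI of the consensus partition against the truth labels."""
    return nmi(p_star, truth)


@dataclass
class MetricsReport:
    """NMI/ARI/AC of a partition against truth, plus their average."""

    nmi: float
    ari: float
    accuracy: float
    avg: float
    ds_p: float | None = None
    q_p: float | None = None
    q_pstar: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


def evaluate_partition(p, truth, ensemble=None) -> MetricsReport:
    """Score a partition against truth; optionally add ensemble diagnostics."""
    scores = {"nmi": nmi(p, truth), "ari": ari(p, truth), "accuracy": accuracy(p, truth)}
    scores["avg"] = float(np.mean([scores["ari"], scores["nmi"], scores["accuracy"]]))
    if ensemble is not None:
        scores["ds_p"] = ensemble_diversity(ensemble)
        scores["q_p"] = ensemble_quality(ensemble, truth)
        scores["q_pstar"] = scores["nmi"]
    return MetricsReport(**scores)
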