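"""Binary chemical structural & compositional similarity (CSCS) metrics.

Compositional metrics like Sørensen treat two compounds as either identical
or unrelated.  CSCS softens this with the spectral similarity matrix
epsilon: a compound in sample A that is absent from sample B still
contributes its best structural match in B.  Under binary (presence/
absence) abundance:

    CSCS(A, B) = [ sum_{i in A} max_{j in B} eps(i, j)
                 + sum_{j in B} max_{i in A} eps(i, j) ] / (|A| + |B|)

with eps(i, i) = 1, so CSCS(A, A) = 1.  Sample dissimilarity is 1 - CSCS.
Within-sample structural complexity is 1 minus the mean pairwise epsilon
among the compounds of one sample: a sample of structurally disparate
compounds scores high.

All structural metrics are restricted to compounds that have fragmentation
spectra (epsilon is undefined otherwise); the restriction is logged.
1 - CSCS is symmetric and bounded in [0, 1] but is not asserted to satisfy
the triangle inequality (max-based aggregation need not be metric).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from phytodiv.occurrence import DistanceMatrix, FeatureTable
from phytodiv.spectra import CompoundSimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "StructuralComplexityRecord", "binary_cscs", "weighted_cscs",
    "structural_dissimilarity_matrix", "structural_complexity",
    "complexity_records",
]


@dataclass
class StructuralComplexityRecord:
    sample_id: str
    n_compounds_with_spectra: int
    complexity: float  # 1 - mean pairwise epsilon, in [0, 1]


def _restrict(ids: set[str], eps: CompoundSimilarityMatrix, label: str) -> list[str]:
    have = set(eps.compound_ids)
    kept = sorted(ids & have)
    dropped = len(ids) - len(kept)
    if dropped:
        logger.info("%s: dropped %d compound(s) without spectra", label, dropped)
    if not kept:
        raise ValueError(f"sample {label!r} has no spectra-bearing compounds")
    return kept


def binary_cscs(
    set_a: set[str], set_b: set[str], eps: CompoundSimilarityMatrix
) -> float:
    """Binary CSCS similarity between two compound sets, in [0, 1]."""
    a = _restrict(set(set_a), eps, "A")
    b = _restrict(set(set_b), eps, "B")
    ia = [eps.index_of(c) for c in a]
    ib = [eps.index_of(c) for c in b]
    sub = eps.epsilon[np.ix_(ia, ib)]
    num = sub.max(axis=1).sum() + sub.max(axis=0).sum()
    return float(min(1.0, num / (len(a) + len(b))))


def weighted_cscs(
    abundance_a: np.ndarray, abundance_b: np.ndarray, eps: CompoundSimilarityMatrix
) -> float:
    """Abundance-weighted CSCS (secondary variant, not the main pipeline
    path): normalized bilinear form x' eps y / max(x' eps x, y' eps y) over
    relative-abundance vectors aligned to ``eps.compound_ids``."""
    x = np.asarray(abundance_a, float)
    y = np.asarray(abundance_b, float)
    n = len(eps.compound_ids)
    if x.shape != (n,) or y.shape != (n,):
        raise ValueError("abundance vectors must align with eps.compound_ids")
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("abundance vectors must have positive total")
    x = x / x.sum()
    y = y / y.sum()
    e = eps.epsilon
    return float(x @ e @ y / max(x @ e @ x, y @ e @ y))


def structural_dissimilarity_matrix(
    table: FeatureTable, eps: CompoundSimilarityMatrix
) -> DistanceMatrix:
    """1 - CSCS between all sample pairs (vectorized over samples).

    Every sample must retain at least one spectra-bearing compound after
    restriction; a sample losing all compounds aborts with an error rather
    than being silently dropped.
    """
    have = [c for c in table.compound_ids if c in set(eps.compound_ids)]
    n_dropped = table.n_compounds - len(have)
    if n_dropped:
        logger.info("structural matrix: restricted to %d/%d spectra-bearing compounds",
                    len(have), table.n_compounds)
    p = table.presence[have].to_numpy(dtype=float)
    sizes = p.sum(axis=1)
    if (sizes == 0).any():
        sid = table.sample_ids[int(np.argmin(sizes))]
        raise ValueError(f"sample {sid!r} has no spectra-bearing compounds")
    idx = [eps.index_of(c) for c in have]
    e = eps.epsilon[np.ix_(idx, idx)]
    # q[s, i] = max_{j present in sample s} eps(i, j)
    n_samples, m = p.shape
    q = np.empty((n_samples, m))
    for s in range(n_samples):
        q[s] = e[:, p[s].astype(bool)].max(axis=1)
    # num[a, b] = sum_{i in a} q[b, i] + sum_{j in b} q[a, j]
    half = p @ q.T
    cscs = (half + half.T) / (sizes[:, None] + sizes[None, :])
    d = 1.0 - np.minimum(cscs, 1.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against fp jitter
    return DistanceMatrix(sample_ids=table.sample_ids, d=np.clip(d, 0.0, 1.0))


def structural_complexity(
    sample_set: set[str], eps: CompoundSimilarityMatrix, sample_id: str = ""
) -> StructuralComplexityRecord:
    """Within-sample structural complexity 1 - mean pairwise epsilon.

    For n >= 2 compounds: 1 - (2 / (n (n-1))) sum_{i<j} eps(i, j).
    Degenerate sets (n < 2) score 0 with a logged warning.
    """
    kept = sorted(set(sample_set) & set(eps.compound_ids))
    n = len(kept)
    if n < 2:
        logger.warning("sample %r: fewer than 2 spectra-bearing compounds; "
                       "complexity set to 0", sample_id)
        return StructuralComplexityRecord(sample_id, n, 0.0)
    sub = eps.submatrix(kept)
    mean_off = (sub.sum() - n) / (n * (n - 1))
    return StructuralComplexityRecord(
        sample_id, n, float(min(1.0, max(0.0, 1.0 - mean_off))))


def complexity_records(
    table: FeatureTable, eps: CompoundSimilarityMatrix
) -> list[StructuralComplexityRecord]:
    """Per-sample complexity for a whole table."""
    out = []
    cols = np.asarray(table.compound_ids, dtype=object)
    pres = table.presence.to_numpy(bool)
    for i, sid in enumerate(table.sample_ids):
        out.append(structural_complexity(set(cols[pres[i]]), eps, sample_id=sid))
    return out
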