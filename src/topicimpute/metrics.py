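"""Partition-agreement and similarity metrics for imputation evaluation.

All partition metrics are computed from the contingency table of the two
labelings Q (reference) and R (predicted): Rand index and its chance-corrected
form (ARI), mutual information in nats with its normalized (NMI) and
chance-adjusted (AMI, permutation-model expected MI) variants, and the
Fowlkes-Mallows score (geometric mean of pairwise precision and recall).
Cosine similarity is provided at vector and matrix (mean row-wise) level.

Pair counts use exact integer arithmetic until the final division.  Every
metric is invariant to relabeling and symmetric in (Q, R).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import gammaln

logger = logging.getLogger(__name__)


def _contingency(q, r) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    q = np.asarray(q)
    r = np.asarray(r)
    if q.shape != r.shape or q.ndim != 1:
        raise ValueError(f"label vectors must be 1-D and equal length, got {q.shape} vs {r.shape}")
    n = q.size
    _, qi = np.unique(q, return_inverse=True)
    _, ri = np.unique(r, return_inverse=True)
    table = np.zeros((qi.max() + 1, ri.max() + 1), dtype=np.int64)
    np.add.at(table, (qi, ri), 1)
    return table, table.sum(axis=1), table.sum(axis=0), n


def _comb2(x):
    x = np.asarray(x, dtype=np.int64)
    return x * (x - 1) // 2


def _same_partition(q, r) -> bool:
    """True when q and r induce the same partition (relabel-invariant)."""

    def canon(x):
        seen: dict = {}
        return [seen.setdefault(v, len(seen)) for v in np.asarray(x).tolist()]

    return canon(q) == canon(r)


def pair_counts(q, r) -> dict:
    """Counts of cell pairs co-clustered in both (a), separated in both (b)."""
    table, rows, cols, n = _contingency(q, r)
    total = int(_comb2(n))
    same_both = int(_comb2(table).sum())
    same_q = int(_comb2(rows).sum())
    same_r = int(_comb2(cols).sum())
    b = total - same_q - same_r + same_both
    return dict(a=same_both, b=b, same_q=same_q, same_r=same_r, total=total)


def rand_index(q, r) -> float:
    """RI = (a + b) / C(n, 2): fraction of pairs the two partitions agree on."""
    c = pair_counts(q, r)
    if c["total"] == 0:
        raise ValueError("need at least 2 observations")
    return (c["a"] + c["b"]) / c["total"]


def adjusted_rand_index(q, r) -> float:
    """ARI = (RI - E[RI]) / (max(RI) - E[RI]) under the permutation model."""
    c = pair_counts(q, r)
    if c["total"] == 0:
        raise ValueError("need at least 2 observations")
    # exact integer arithmetic until the final division
    numerator = 2 * (c["a"] * c["total"] - c["same_q"] * c["same_r"])
    denominator = c["total"] * (c["same_q"] + c["same_r"]) - 2 * c["same_q"] * c["same_r"]
    if denominator == 0:
        identical = _same_partition(q, r)
        logger.info("degenerate ARI denominator; returning %d by convention", int(identical))
        return 1.0 if identical else 0.0
    return numerator / denominator


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def mutual_information(q, r) -> float:
    """Plug-in MI(Q, R) in nats from the empirical joint distribution."""
    table, rows, cols, n = _contingency(q, r)
    nz = table > 0
    pij = table[nz] / n
    outer = np.outer(rows, cols)[nz] / (n * n)
    return float(np.maximum((pij * np.log(pij / outer)).sum(), 0.0))


def normalized_mutual_information(q, r, norm: str = "arithmetic") -> float:
    """MI divided by a symmetric normalizer of the two label entropies."""
    table, rows, cols, n = _contingency(q, r)
    hq, hr = _entropy(rows, n), _entropy(cols, n)
    if hq == 0.0 and hr == 0.0:
        logger.info("both partitions constant; NMI defined as 1")
        return 1.0
    mi = mutual_information(q, r)
    denom = {
        "arithmetic": 0.5 * (hq + hr),
        "min": min(hq, hr),
        "max": max(hq, hr),
        "sqrt": np.sqrt(hq * hr),
    }[norm]
    if denom == 0.0:
        return 0.0
    return float(mi / denom)


def expected_mutual_information(q, r) -> float:
    """E[MI] over random contingency tables with the observed margins."""
    _, rows, cols, n = _contingency(q, r)
    lgn = gammaln(n + 1)
    emi = 0.0
    for ai in rows:
        for bj in cols:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                term = (nij / n) * np.log(n * nij / (ai * bj))
                logp = (
                    gammaln(ai + 1) + gammaln(bj + 1) + gammaln(n - ai + 1) + gammaln(n - bj + 1)
                    - lgn - gammaln(nij + 1) - gammaln(ai - nij + 1) - gammaln(bj - nij + 1)
                    - gammaln(n - ai - bj + nij + 1)
                )
                emi += term * np.exp(logp)
    return float(emi)


def adjusted_mutual_information(q, r) -> float:
    """AMI = (MI - E[MI]) / (mean(H(Q), H(R)) - E[MI]); 1 for identical partitions."""
    table, rows, cols, n = _contingency(q, r)
    hq, hr = _entropy(rows, n), _entropy(cols, n)
    if hq == 0.0 and hr == 0.0:
        return 1.0
    mi = mutual_information(q, r)
    emi = expected_mutual_information(q, r)
    denom = 0.5 * (hq + hr) - emi
    if abs(denom) < 1e-15:
        return 1.0 if _same_partition(q, r) else 0.0
    return float((mi - emi) / denom)


def fowlkes_mallows(q, r) -> float:
    """FMS = TP / sqrt((TP + FP)(TP + FN)) over co-clustered pairs."""
    c = pair_counts(q, r)
    if c["total"] == 0:
        raise ValueError("need at least 2 observations")
    if c["same_q"] == 0 or c["same_r"] == 0:
        return 0.0
    return float(c["a"] / np.sqrt(c["same_q"] * c["same_r"]))


def cosine_similarity(u, v) -> float:
    """u.v / (|u||v|); 0 by convention when both vectors are zero."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 and nv == 0.0:
        logger.info("both vectors zero; cosine defined as 0")
        return 0.0
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def matrix_mean_cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Mean cosine similarity over corresponding rows; zero-norm rows skipped."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"matrices must share a shape, got {a.shape} vs {b.shape}")
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    keep = (na > 0) & (nb > 0)
    skipped = int((~keep).sum())
    if skipped:
        logger.info("skipping %d zero-norm rows in matrix cosine", skipped)
    if not keep.any():
        return 0.0
    cos = (a[keep] * b[keep]).sum(axis=1) / (na[keep] * nb[keep])
    return float(cos.mean())


def all_partition_metrics(q, r) -> dict[str, float]:
    """One-call summary of every partition metric."""
    return {
        "RI": rand_index(q, r),
        "ARI": adjusted_rand_index(q, r),
        "MI": mutual_information(q, r),
        "NMI": normalized_mutual_information(q, r),
        "AMI": adjusted_mutual_information(q, r),
        "FMS": fowlkes_mallows(q, r),
    }
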