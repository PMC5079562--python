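"""Alpha-diversity indices computed from a single sample's count vector.

Five measures are provided: observed richness, the Shannon and Gini-Simpson
diversity indices, and the Chao1 and ACE nonparametric richness estimators.
Shannon and Gini-Simpson summarise the evenness of the abundance
distribution; Chao1 and ACE extrapolate total richness from the rare tail
(singletons/doubletons for Chao1, all taxa at or below a rare-count
threshold for ACE).

Conventions follow the QIIME-era defaults common in 16S amplicon work:
Shannon in log base 2 (bits), Simpson as the Gini-Simpson form 1 - sum(p^2).
Both are switchable.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import DomainError, EmptySampleError, UndefinedCoverageError

logger = logging.getLogger(__name__)

__all__ = [
    "shannon",
    "gini_simpson",
    "inverse_simpson",
    "observed_richness",
    "chao1",
    "ace",
]


def _as_counts(v) -> np.ndarray:
    """Validate and coerce a count vector to a float array."""
    a = np.asarray(v, dtype=float)
    if a.ndim != 1:
        a = a.ravel()
    if a.size == 0 or np.any(a < 0):
        raise DomainError("counts must be a non-empty vector of non-negative numbers")
    return a


def _proportions(v) -> np.ndarray:
    a = _as_counts(v)
    total = a.sum()
    if total <= 0:
        raise EmptySampleError("all-zero abundance vector")
    return a[a > 0] / total


def shannon(v, log_base: float = 2.0) -> float:
    """Shannon diversity H = -sum(p_i * log_b p_i) over taxa with p_i > 0.

    Parameters
    ----------
    v : array-like of non-negative counts
    log_base : logarithm base; 2 gives bits (the default), ``numpy.e``
        gives nats.
    """
    if log_base <= 0 or log_base == 1:
        raise DomainError("log_base must be positive and != 1")
    p = _proportions(v)
    return float(-(p * (np.log(p) / np.log(log_base))).sum())


def gini_simpson(v) -> float:
    """Gini-Simpson index 1 - sum(p_i^2): probability that two random reads
    belong to different taxa. Bounded in [0, 1 - 1/S_obs]."""
    p = _proportions(v)
    return float(1.0 - (p * p).sum())


def inverse_simpson(v) -> float:
    """Inverse Simpson index 1 / sum(p_i^2) (Hill number of order 2)."""
    p = _proportions(v)
    return float(1.0 / (p * p).sum())


def observed_richness(v) -> int:
    """Number of taxa with count > 0."""
    a = _as_counts(v)
    return int((a > 0).sum())


def chao1(v, bias_corrected: bool = False) -> float:
    """Chao1 richness estimate from singleton (F1) and doubleton (F2) counts.

    Classic form: S_obs + F1^2 / (2 F2); bias-corrected form:
    S_obs + F1 (F1 - 1) / (2 (F2 + 1)). When the classic form is requested
    but F2 = 0, the bias-corrected form is used instead (logged), which is
    also the standard convention. The estimate never falls below S_obs.
    """
    a = _as_counts(v)
    if a.sum() <= 0:
        raise EmptySampleError("all-zero abundance vector")
    s_obs = float((a > 0).sum())
    f1 = float((a == 1).sum())
    f2 = float((a == 2).sum())
    if not bias_corrected and f2 == 0:
        logger.debug("chao1: F2 = 0, falling back to bias-corrected form")
        bias_corrected = True
    if bias_corrected:
        return s_obs + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))
    return s_obs + f1 * f1 / (2.0 * f2)


def ace(v, rare_threshold: int = 10) -> float:
    """ACE (abundance-based coverage estimator) of total richness.

    Taxa with count <= ``rare_threshold`` form the rare group. With
    N_rare rare individuals, F1 singletons, sample coverage
    C = 1 - F1/N_rare and squared coefficient of variation

        gamma^2 = max(S_rare/C * sum_i i(i-1) F_i / (N_rare (N_rare-1)) - 1, 0),

    ACE = S_abund + S_rare/C + F1 * gamma^2 / C. If there are no rare taxa
    the estimate is S_obs; if every rare individual is a singleton the
    coverage is zero and the estimator is undefined.
    """
    if rare_threshold < 1:
        raise DomainError("rare_threshold must be >= 1")
    a = _as_counts(v)
    if a.sum() <= 0:
        raise EmptySampleError("all-zero abundance vector")
    a = a[a > 0]
    rare = a[a <= rare_threshold]
    s_abund = float((a > rare_threshold).sum())
    s_rare = float(rare.size)
    if s_rare == 0:
        return float(a.size)
    n_rare = float(rare.sum())
    f1 = float((rare == 1).sum())
    coverage = 1.0 - f1 / n_rare
    if coverage == 0.0:
        raise UndefinedCoverageError(
            "ACE coverage is zero: every rare individual is a singleton"
        )
    i = np.arange(1, rare_threshold + 1, dtype=float)
    f_i = np.array([(rare == k).sum() for k in range(1, rare_threshold + 1)], dtype=float)
    sum_term = float((i * (i - 1.0) * f_i).sum())
    if n_rare > 1:
        gamma2 = max(s_rare / coverage * sum_term / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    else:
        gamma2 = 0.0
    return s_abund + s_rare / coverage + f1 * gamma2 / coverage
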