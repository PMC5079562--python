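"""Indicator species analysis (IndVal) with a permutation significance test.

For a taxon and a group of samples, specificity A is the taxon's mean
abundance in that group divided by the sum of its group means, and
fidelity B is the fraction of the group's samples where the taxon is
present. The indicator value combines them as sqrt(A * B) (the default,
following the later square-root convention) or as the classic product
A * B. Significance comes from permuting group labels over samples: the
p-value for a taxon is the fraction of relabellings whose best-group
indicator value reaches the observed one. When the number of distinct
relabellings is small the null is enumerated exhaustively; otherwise
Monte-Carlo permutations with the add-one rule (1 + hits)/(n + 1) keep
the test exact.

A *common-taxa restricted* variant drops every taxon absent from any
sample before testing — the guard against indicators that are artefacts
of rare taxa missed by chance.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

logger = logging.getLogger(__name__)

__all__ = ["IndValResult", "indval_scores", "indval_significance"]


@dataclass(frozen=True)
class IndValResult:
    """Indicator statistics for one taxon in its best (or a given) group."""

    taxon: str
    group: str
    a: float  # specificity
    b: float  # fidelity
    indval: float
    p_perm: float = float("nan")


def _group_matrices(table: pd.DataFrame, groups: pd.Series):
    groups = pd.Series(groups)
    missing = [s for s in table.columns if s not in groups.index]
    if missing:
        raise DomainError(f"samples without a group label: {missing}")
    labels = groups.loc[table.columns]
    names = list(pd.unique(labels))
    if len(names) < 2:
        raise DomainError("need at least 2 groups")
    cols = [np.flatnonzero((labels == g).to_numpy()) for g in names]
    for g, c in zip(names, cols):
        if c.size == 0:
            raise DomainError(f"group {g!r} has no samples")
    return names, cols


def _scores_matrix(
    x: np.ndarray, cols: list[np.ndarray], variant: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A, B and indval as taxa x groups arrays for abundance matrix ``x``."""
    means = np.stack([x[:, c].mean(axis=1) for c in cols], axis=1)
    occ = np.stack([(x[:, c] > 0).mean(axis=1) for c in cols], axis=1)
    denom = means.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(denom > 0, means / np.where(denom > 0, denom, 1.0), 0.0)
    iv = a * occ
    if variant == "sqrt":
        iv = np.sqrt(iv)
    elif variant != "classic":
        raise DomainError("variant must be 'sqrt' or 'classic'")
    return a, occ, iv


def indval_scores(
    table: pd.DataFrame, groups: pd.Series, variant: str = "sqrt"
) -> pd.DataFrame:
    """Indicator values of every taxon for every group (no significance).

    ``table`` is taxa x samples (percent or raw counts — the statistic is
    invariant to per-sample rescaling only through A, so percent input is
    conventional); ``groups`` maps sample -> group label. Returns a tidy
    frame with columns taxon, group, A, B, indval.
    """
    names, cols = _group_matrices(table, groups)
    a, b, iv = _scores_matrix(table.to_numpy(dtype=float), cols, variant)
    rows = []
    for i, taxon in enumerate(table.index):
        for j, g in enumerate(names):
            rows.append(
                {"taxon": taxon, "group": g, "A": a[i, j], "B": b[i, j], "indval": iv[i, j]}
            )
    return pd.DataFrame(rows)


def _distinct_relabellings(sizes: list[int]) -> int:
    n = sum(sizes)
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(s)
    return total


def indval_significance(
    table: pd.DataFrame,
    groups: pd.Series,
    variant: str = "sqrt",
    n_permutations: int = 999,
    seed: int = 0,
    restrict_to_common: bool = False,
) -> pd.DataFrame:
    """Best-group indicator value per taxon with a permutation p-value.

    The test statistic for a taxon is its maximum indicator value over
    groups. Under the null, group labels are exchangeable across samples:
    labels are randomly reassigned ``n_permutations`` times and
    p = (1 + #{permuted statistic >= observed}) / (n_permutations + 1).
    If the number of distinct relabellings does not exceed
    ``n_permutations`` the null is enumerated exhaustively (p = hits /
    #relabellings, the observed labelling included). With
    ``restrict_to_common`` taxa absent from any sample are dropped first.
    Deterministic for a fixed seed.
    """
    if n_permutations < 1:
        raise DomainError("n_permutations must be >= 1")
    if restrict_to_common:
        table = table.loc[(table > 0).all(axis=1)]
    names, cols = _group_matrices(table, groups)
    x = table.to_numpy(dtype=float)
    n_samples = x.shape[1]
    a, b, iv = _scores_matrix(x, cols, variant)
    best = iv.argmax(axis=1)
    observed = iv.max(axis=1) if iv.size else np.zeros(0)

    sizes = [c.size for c in cols]
    n_distinct = _distinct_relabellings(sizes)
    exhaustive = n_distinct <= n_permutations
    eps = 1e-12  # tolerate float jitter in >= comparisons

    if exhaustive:
        logger.info(
            "indval: %d distinct relabellings <= %d permutations; "
            "enumerating the null exhaustively",
            n_distinct,
            n_permutations,
        )
        hits = np.zeros(x.shape[0])
        count = 0
        for perm_cols in _enumerate_partitions(n_samples, sizes):
            _, _, iv_p = _scores_matrix(x, perm_cols, variant)
            hits += iv_p.max(axis=1) >= observed - eps
            count += 1
        p = hits / count
    else:
        rng = np.random.default_rng(seed)
        hits = np.zeros(x.shape[0])
        idx = np.arange(n_samples)
        for _ in range(n_permutations):
            rng.shuffle(idx)
            start = 0
            perm_cols = []
            for s in sizes:
                perm_cols.append(idx[start : start + s])
                start += s
            _, _, iv_p = _scores_matrix(x, perm_cols, variant)
            hits += iv_p.max(axis=1) >= observed - eps
        p = (1.0 + hits) / (n_permutations + 1.0)

    rows = []
    for i, taxon in enumerate(table.index):
        j = int(best[i])
        rows.append(
            {
                "taxon": taxon,
                "group": names[j],
                "A": a[i, j],
                "B": b[i, j],
                "indval": observed[i],
                "p_perm": p[i],
            }
        )
    return pd.DataFrame(rows, columns=["taxon", "group", "A", "B", "indval", "p_perm"])


def _enumerate_partitions(n: int, sizes: list[int]):
    """Yield all ordered partitions of range(n) into blocks of the given sizes."""

    def rec(remaining: frozenset[int], k: int):
        if k == len(sizes):
            yield []
            return
        for block in itertools.combinations(sorted(remaining), sizes[k]):
            for rest in rec(remaining - set(block), k + 1):
                yield [np.array(block)] + rest

    yield from rec(frozenset(range(n)), 0)
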