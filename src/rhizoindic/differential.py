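"""Paired treated-vs-control differential taxon screen.

Each treated soil sample is compared exclusively to its own control so
that location, soil and season effects cancel. The screen, per taxonomic
rank:

1. restrict to taxa present (count > 0) in both members of the pair,
   after unspecific-group removal — rare groups missed by chance in one
   sample would otherwise masquerade as treatment effects;
2. omnibus 2 x K likelihood-ratio G-test over the common-taxa profile;
3. if the omnibus rejects, per-taxon 2 x 2 post-hoc tests (taxon vs the
   sum of the other common taxa): two-sided Fisher exact and Pearson
   chi-square;
4. Holm-Bonferroni step-down across the K taxa of the (pair, level)
   family at P < 0.05.

Summaries tally, per treatment / rank / collection time (t1 early, t2
late), how many taxa changed and by how much — the "overall number and
magnitude of changes" indicator of treatment aggressiveness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateTableError, DomainError, LookupError_
from .tables import RANKS, TaxonCountTable, aggregate_to_level, filter_unspecific

__all__ = [
    "PairedComparison",
    "PairResult",
    "paired_common_taxa",
    "g_test",
    "posthoc_2x2",
    "holm_adjust",
    "paired_differential",
    "run_screen",
    "change_summary",
]

TREATMENT_CODES = ("AT", "ATG", "PG", "MSG", "AIM", "G")


@dataclass(frozen=True)
class PairedComparison:
    """One treated sample linked to its control."""

    treated_sample: str
    control_sample: str
    treatment_code: str = "AT"
    time: str = "t1"  # t1 = early collection, t2 = late
    pair_id: str = ""

    def __post_init__(self) -> None:
        if self.treated_sample == self.control_sample:
            raise DomainError("treated and control samples must differ")
        if self.time not in ("t1", "t2"):
            raise DomainError("time must be 't1' or 't2'")


def _pair_counts(
    table: TaxonCountTable, pair: PairedComparison, level: str
) -> pd.DataFrame:
    for s in (pair.treated_sample, pair.control_sample):
        if s not in table.counts.columns:
            raise LookupError_(f"sample {s!r} not found in the table")
    # narrow to the pair's two columns before the (comparatively costly)
    # roll-up and filtering
    sub = TaxonCountTable(
        counts=table.counts[[pair.treated_sample, pair.control_sample]],
        lineages=table.lineages,
        level=table.level,
    )
    leveled = filter_unspecific(aggregate_to_level(sub, level), level)
    return leveled.counts


def paired_common_taxa(
    table: TaxonCountTable, pair: PairedComparison, level: str
) -> list[str]:
    """Taxa with count > 0 in both the treated and the control sample
    (after rolling up to ``level`` and removing unspecific groups)."""
    cnt = _pair_counts(table, pair, level)
    mask = (cnt > 0).all(axis=1)
    return list(cnt.index[mask])


def g_test(table, williams: bool = False) -> tuple[float, int, float]:
    """Likelihood-ratio G-test of independence on an R x C count table.

    G = 2 sum O ln(O/E) with expectations from the independence model;
    df = (R-1)(C-1) (K - 1 for the 2 x K paired profile); p from the
    chi-square upper tail. ``williams=True`` applies the Williams
    small-sample correction.
    """
    obs = np.asarray(table, dtype=float)
    if np.any(obs < 0):
        raise DomainError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise DegenerateTableError("zero marginal total in contingency table")
    g, p, dof, _ = stats.chi2_contingency(
        obs, correction=False, lambda_="log-likelihood"
    )
    if williams:
        n = obs.sum()
        r, c = obs.shape
        q = 1.0 + (
            (n * (1.0 / obs.sum(axis=1)).sum() - 1.0)
            * (n * (1.0 / obs.sum(axis=0)).sum() - 1.0)
        ) / (6.0 * n * (r - 1) * (c - 1))
        g = g / q
        p = float(stats.chi2.sf(g, dof))
    return float(g), int(dof), float(p)


def posthoc_2x2(table, continuity: bool = False) -> tuple[float, float]:
    """Two-sided Fisher exact and Pearson chi-square p-values for a 2 x 2.

    Fisher follows the point-probability rule (sum of tables at most as
    probable as the observed one). A zero row or column makes the table
    deterministic: Fisher p = 1 by convention and the chi-square p is
    flagged undefined (NaN).
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise DomainError("expected a 2x2 table of non-negative integers")
    if obs.sum() == 0:
        raise DomainError("empty table")
    _, p_fisher = stats.fisher_exact(obs, alternative="two-sided")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        return 1.0, float("nan")
    _, p_chi2, _, _ = stats.chi2_contingency(obs, correction=continuity)
    return float(p_fisher), float(p_chi2)


def holm_adjust(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Bonferroni step-down adjustment.

    Returns (adjusted p-values, rejection flags); a hypothesis is
    rejected iff its adjusted p is strictly below ``alpha``. Adjusted
    values are monotone over the sorted raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise DomainError("alpha must be in (0, 1)")
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, p_adj < alpha


@dataclass
class PairResult:
    """Outcome of the screen for one (pair, level) family."""

    pair: PairedComparison
    level: str
    common_taxa: list[str]
    g_stat: float = float("nan")
    g_df: int = 0
    p_g: float = float("nan")
    omnibus_significant: bool = False
    per_taxon: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_significant(self) -> int:
        if self.per_taxon.empty:
            return 0
        return int(self.per_taxon["significant"].sum())


_PER_TAXON_COLS = [
    "taxon",
    "treated_count",
    "control_count",
    "p_fisher",
    "p_chi2",
    "p_posthoc",
    "p_holm",
    "direction",
    "log2_ratio",
    "pct_point_diff",
    "significant",
]


def paired_differential(
    table: TaxonCountTable,
    pair: PairedComparison,
    level: str,
    alpha: float = 0.05,
    williams: bool = False,
    continuity: bool = False,
) -> PairResult:
    """Run the full screen for one pair at one rank.

    The omnibus G-test gates the per-taxon post-hoc testing: if it does
    not reject at ``alpha`` the omnibus statistics are still reported but
    no taxon is flagged. Per-taxon 2 x 2 tables oppose the taxon to the
    sum of the other common taxa; the smaller of the Fisher and
    chi-square p-values is Holm-adjusted across the family's K taxa.
    Direction and magnitude (log2 proportion ratio, percent-point
    difference) are relative to the common-taxa denominator.
    """
    cnt = _pair_counts(table, pair, level)
    mask = (cnt > 0).all(axis=1)
    common = cnt.loc[mask]
    taxa = list(common.index)
    result = PairResult(pair=pair, level=level, common_taxa=taxa)
    if len(taxa) < 2:
        return result  # disjoint or single-taxon profile: nothing testable

    profile = common.to_numpy().T  # rows: treated, control; cols: taxa
    result.g_stat, result.g_df, result.p_g = g_test(profile, williams=williams)
    result.omnibus_significant = result.p_g < alpha
    if not result.omnibus_significant:
        # the omnibus test gates the post-hoc stage: report its statistics
        # but flag no taxa and skip the per-taxon tests
        return result

    t_tot, c_tot = profile.sum(axis=1)
    rows = []
    p_post = np.empty(len(taxa))
    for j, taxon in enumerate(taxa):
        t, c = profile[0, j], profile[1, j]
        sub = np.array([[t, t_tot - t], [c, c_tot - c]])
        p_fisher, p_chi2 = posthoc_2x2(sub, continuity=continuity)
        p_post[j] = np.nanmin([p_fisher, p_chi2])
        pt, pc = t / t_tot, c / c_tot
        rows.append(
            {
                "taxon": taxon,
                "treated_count": int(t),
                "control_count": int(c),
                "p_fisher": p_fisher,
                "p_chi2": p_chi2,
                "p_posthoc": p_post[j],
                "direction": "increase" if pt > pc else ("decrease" if pt < pc else "none"),
                "log2_ratio": math.log2(pt / pc),
                "pct_point_diff": 100.0 * (pt - pc),
            }
        )
    p_holm, reject = holm_adjust(p_post, alpha=alpha)
    per_taxon = pd.DataFrame(rows)
    per_taxon["p_holm"] = p_holm
    per_taxon["significant"] = reject & result.omnibus_significant
    result.per_taxon = per_taxon[_PER_TAXON_COLS]
    return result


def run_screen(
    table: TaxonCountTable,
    pairs: Iterable[PairedComparison],
    levels: Sequence[str] = RANKS[1:],
    alpha: float = 0.05,
    **kwargs,
) -> pd.DataFrame:
    """Screen every pair at every requested rank; long-format results.

    One row per (pair, level, taxon) with the omnibus statistics
    repeated, in the shape of a per-study supplementary change table.
    """
    frames = []
    for pair in pairs:
        for level in levels:
            res = paired_differential(table, pair, level, alpha=alpha, **kwargs)
            if res.per_taxon.empty:
                continue
            df = res.per_taxon.copy()
            df.insert(0, "level", level)
            df.insert(1, "treatment", pair.treatment_code)
            df.insert(2, "time", pair.time)
            df.insert(3, "pair_id", pair.pair_id or pair.treated_sample)
            df["g_stat"] = res.g_stat
            df["p_g"] = res.p_g
            df["omnibus_significant"] = res.omnibus_significant
            df["n_common"] = len(res.common_taxa)
            frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def change_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Tally significant changes per (treatment, level, time).

    Columns: number of significant taxa, share of the tested common taxa
    affected, and mean |log2 ratio| among the affected taxa (NaN when
    none). An empty result frame yields an empty tally.
    """
    if results.empty:
        return pd.DataFrame(
            columns=["treatment", "level", "time", "n_significant", "share_affected", "mean_abs_log2"]
        )
    rows = []
    for (treatment, level, time), grp in results.groupby(
        ["treatment", "level", "time"], sort=False
    ):
        sig = grp[grp["significant"]]
        rows.append(
            {
                "treatment": treatment,
                "level": level,
                "time": time,
                "n_significant": int(len(sig)),
                "share_affected": len(sig) / len(grp) if len(grp) else 0.0,
                "mean_abs_log2": float(sig["log2_ratio"].abs().mean()) if len(sig) else float("nan"),
            }
        )
    return pd.DataFrame(rows)
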