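"""Sample-size sufficiency of a diversity index from its rarefaction curve.

For each sample the curve's *final value* (the value at the deepest
evaluated depth) is the reference; the *recovery depth* n_q is the
smallest scheduled depth from which the curve stays at or above a
fraction q of that final value (sustained, "last-crossing" semantics —
robust to transient dips from replicate noise). The *asymptoticity ratio*
(D_max - n_q)/D_max measures how early the index stabilised: a ratio
above 0.7 means the index changed by less than (1 - q) over the final 70%
of the curve. Samples can be filtered on the ratio before recovery depths
are aggregated as mean, SD and a 95% confidence interval of the mean —
the study design behind "how many reads does this index need".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateCurveError, DomainError, InsufficientDataError
from .rarefaction import RarefactionCurve

__all__ = [
    "AsymptoticityRecord",
    "recovery_depth",
    "asymptoticity_ratio",
    "analyze_curve",
    "filter_asymptotic",
    "aggregate_recovery_depths",
]


@dataclass(frozen=True)
class AsymptoticityRecord:
    """Recovery depths and asymptoticity ratios for one sample's curve."""

    sample_id: str
    final_value: float
    n95: int
    n99: int
    ratio95: float
    ratio99: float
    d_max: int

    def ratio(self, q: float) -> float:
        if math.isclose(q, 0.95):
            return self.ratio95
        if math.isclose(q, 0.99):
            return self.ratio99
        raise DomainError(f"no stored ratio for q={q}; records hold q in {{0.95, 0.99}}")

    def depth(self, q: float) -> int:
        if math.isclose(q, 0.95):
            return self.n95
        if math.isclose(q, 0.99):
            return self.n99
        raise DomainError(f"no stored depth for q={q}; records hold q in {{0.95, 0.99}}")


def recovery_depth(curve: RarefactionCurve, q: float) -> int:
    """Smallest depth d such that curve(d') >= q * final for every d' >= d."""
    if not 0.0 < q <= 1.0:
        raise DomainError("q must be in (0, 1]")
    final = curve.final_value
    if final <= 0:
        raise DegenerateCurveError(
            f"final curve value {final} is not positive (sample {curve.sample_id!r})"
        )
    threshold = q * final
    # Walk from the end: the first point (from the right) that drops below
    # the threshold bounds the sustained-recovery depth.
    ok = curve.values >= threshold
    below = np.nonzero(~ok)[0]
    idx = 0 if below.size == 0 else int(below[-1]) + 1
    return int(curve.depths[idx])


def asymptoticity_ratio(n_q: float, d_max: float) -> float:
    """(D_max - n_q) / D_max: the fraction of the curve after recovery."""
    if d_max <= 0:
        raise DomainError("d_max must be positive")
    if not 0 <= n_q <= d_max:
        raise DomainError("n_q must lie in [0, d_max]")
    return (d_max - n_q) / d_max


def analyze_curve(curve: RarefactionCurve) -> AsymptoticityRecord:
    """Compute the 95%/99% recovery depths and ratios for one curve."""
    n95 = recovery_depth(curve, 0.95)
    n99 = recovery_depth(curve, 0.99)
    d_max = curve.max_depth
    return AsymptoticityRecord(
        sample_id=curve.sample_id,
        final_value=curve.final_value,
        n95=n95,
        n99=n99,
        ratio95=asymptoticity_ratio(n95, d_max),
        ratio99=asymptoticity_ratio(n99, d_max),
        d_max=d_max,
    )


def filter_asymptotic(
    records: Iterable[AsymptoticityRecord], min_ratio: float, q: float = 0.95
) -> list[AsymptoticityRecord]:
    """Keep records whose asymptoticity ratio for ``q`` strictly exceeds
    ``min_ratio``. ``min_ratio = 0`` is the no-filter ("all samples")
    preset and keeps everything; the other presets are 0.5 and 0.7."""
    if not 0.0 <= min_ratio <= 1.0:
        raise DomainError("min_ratio must be in [0, 1]")
    records = list(records)
    if min_ratio == 0.0:
        return records
    return [r for r in records if r.ratio(q) > min_ratio]


def aggregate_recovery_depths(
    records: Sequence[AsymptoticityRecord],
    q: float,
    ci: str = "normal",
) -> tuple[float, float, float, int]:
    """Mean, sample SD, 95% CI half-width and n of the q-recovery depths.

    The half-width is 1.96 * SD / sqrt(n) by default (``ci="normal"``);
    ``ci="t"`` uses the t quantile with n - 1 degrees of freedom. This is
    a between-sample interval: it describes dispersion of the per-sample
    recovery depths, not rarefaction-replicate noise within one sample.
    """
    depths = np.array([r.depth(q) for r in records], dtype=float)
    n = depths.size
    if n < 2:
        raise InsufficientDataError("need at least 2 records to aggregate")
    mean = float(depths.mean())
    sd = float(depths.std(ddof=1))
    if ci == "normal":
        crit = 1.96
    elif ci == "t":
        crit = float(stats.t.ppf(0.975, n - 1))
    else:
        raise DomainError("ci must be 'normal' or 't'")
    return mean, sd, crit * sd / math.sqrt(n), int(n)
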