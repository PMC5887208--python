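"""Stratified proportional reporting ratio, Yates-corrected chi-square, and
the composite signal-intensity score.

All statistics here are computed on the stratum-restricted 2x2 table

                 event C   not C
    with drug A   n_AB1    n_AB2
    without A     n_B1     n_B2

unlike the association-rule statistics, whose consequent baseline spans the
whole dataset.  Default signal criteria: count >= 3, PRR >= 2, chi2 >= 4
(all non-strict).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .contingency import TripleCounts
from .errors import UndefinedStatisticError

__all__ = ["PRRMetrics", "prr", "chi2_yates", "intensity", "prr_metrics",
           "prr_signal"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PRRMetrics:
    prr: float        # nan when undefined (zero comparator margin)
    chi2: float       # nan when undefined (zero table margin)
    intensity: float  # log10(prr) + log10(chi2); nan unless both positive
    rule_count: int


def prr(counts: TripleCounts) -> float:
    """(n_AB1/n_AB+) / (n_B1/n_B+) on the stratum-restricted table."""
    if counts.n_AB_plus < 1 or counts.n_B_plus < 1:
        raise UndefinedStatisticError("empty row in the stratum 2x2 table")
    if counts.n_B1 == 0:
        raise UndefinedStatisticError(
            "n_B1 = 0: comparator never reports the event; PRR undefined")
    return (counts.n_AB1 / counts.n_AB_plus) / (counts.n_B1 / counts.n_B_plus)


def chi2_yates(counts: TripleCounts) -> float:
    """Continuity-corrected chi-square of the stratum 2x2 table.

    N * (|n_AB1*n_B2 - n_AB2*n_B1| - N/2)^2 / (n_AB+ * n_B+ * (n_AB1+n_B1) * (n_AB2+n_B2)),
    N = n_AB+ + n_B+.  Clamped to 0 when the correction exceeds the absolute
    cross-product difference.
    """
    a, b = counts.n_AB1, counts.n_AB2
    c, d = counts.n_B1, counts.n_B2
    n = counts.n_AB_plus + counts.n_B_plus
    margins = (counts.n_AB_plus, counts.n_B_plus, a + c, b + d)
    if min(margins) == 0:
        raise UndefinedStatisticError(f"zero margin in 2x2 table {margins}")
    corrected = abs(a * d - b * c) - n / 2.0
    if corrected <= 0.0:
        return 0.0
    return n * corrected ** 2 / (counts.n_AB_plus * counts.n_B_plus * (a + c) * (b + d))


def intensity(prr_value: float, chi2_value: float) -> float:
    """Composite magnitude log10(PRR) + log10(chi2)."""
    if not (prr_value > 0.0 and chi2_value > 0.0):
        raise UndefinedStatisticError(
            f"intensity needs positive PRR and chi2, got ({prr_value}, {chi2_value})")
    if math.isinf(prr_value) or math.isinf(chi2_value):
        raise UndefinedStatisticError("intensity undefined for infinite inputs")
    return math.log10(prr_value) + math.log10(chi2_value)


def prr_metrics(counts: TripleCounts) -> PRRMetrics:
    """Compute PRR/chi2/intensity, mapping undefined statistics to NaN."""
    try:
        p = prr(counts)
    except UndefinedStatisticError:
        p = math.nan
    try:
        x2 = chi2_yates(counts)
    except UndefinedStatisticError:
        x2 = math.nan
    try:
        inten = intensity(p, x2)
    except UndefinedStatisticError:
        inten = math.nan
    return PRRMetrics(prr=p, chi2=x2, intensity=inten, rule_count=counts.n_AB1)


def prr_signal(metrics: PRRMetrics, min_count: int = 3,
               min_prr: float = 2.0, min_chi2: float = 4.0) -> bool:
    """All thresholds non-strict.  Undefined metrics -> False with a warning."""
    if math.isnan(metrics.prr) or math.isnan(metrics.chi2):
        logger.warning("undefined PRR metrics (count=%d); treating as non-signal",
                       metrics.rule_count)
        return False
    return (metrics.rule_count >= min_count
            and metrics.prr >= min_prr
            and metrics.chi2 >= min_chi2)
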