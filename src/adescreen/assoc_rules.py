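"""Association-rule statistics and signal criteria for A ∩ B → C rules.

lift = confidence / support(C) = (n_AB1/n_AB+) / (n_+1/n_++)
conviction = (1 − support(C)) / (1 − confidence), +inf at confidence = 1.

The default detection criteria are rule count ≥ 3, lift > 1, conviction > 1;
lift and conviction thresholds are strict, the count threshold is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .contingency import TripleCounts, count_triples
from .errors import UndefinedStatisticError
from .srs_io import SRSDataset, annotate_strata

__all__ = ["ARMetrics", "RuleResult", "lift", "conviction", "ar_metrics",
           "ar_signal", "mine_rules"]


@dataclass(frozen=True)
class ARMetrics:
    support_c: float
    confidence: float
    lift: float
    conviction: float  # may be +inf
    rule_count: int


@dataclass(frozen=True)
class RuleResult:
    counts: TripleCounts
    metrics: ARMetrics
    is_signal: bool

    @property
    def triple(self) -> tuple:
        return (self.counts.drug, self.counts.stratum, self.counts.event)


def _check(counts: TripleCounts) -> None:
    if counts.n_AB_plus < 1:
        raise UndefinedStatisticError("n_AB_plus = 0: antecedent never observed")
    if counts.n_plus1 < 1:
        raise UndefinedStatisticError("n_plus1 = 0: event never observed")


def lift(counts: TripleCounts) -> float:
    """(n_AB1/n_AB+) / (n_+1/n_++); 1 under independence of A∩B and C."""
    _check(counts)
    return (counts.n_AB1 / counts.n_AB_plus) / (counts.n_plus1 / counts.n_plusplus)


def conviction(counts: TripleCounts) -> float:
    """(1 − n_+1/n_++) / (1 − n_AB1/n_AB+); +inf when confidence is 1."""
    _check(counts)
    confidence = counts.n_AB1 / counts.n_AB_plus
    if confidence == 1.0:
        return math.inf
    return (1.0 - counts.n_plus1 / counts.n_plusplus) / (1.0 - confidence)


def ar_metrics(counts: TripleCounts) -> ARMetrics:
    _check(counts)
    return ARMetrics(
        support_c=counts.n_plus1 / counts.n_plusplus,
        confidence=counts.n_AB1 / counts.n_AB_plus,
        lift=lift(counts),
        conviction=conviction(counts),
        rule_count=counts.n_AB1,
    )


def ar_signal(metrics: ARMetrics, min_count: int = 3,
              min_lift: float = 1.0, min_conviction: float = 1.0) -> bool:
    """Strict > for lift/conviction, non-strict >= for the rule count."""
    return (metrics.rule_count >= min_count
            and metrics.lift > min_lift
            and metrics.conviction > min_conviction)


def mine_rules(dataset: SRSDataset, strata: Iterable,
               min_count: int = 3, min_lift: float = 1.0,
               min_conviction: float = 1.0) -> list:
    """Mine all A ∩ B → C rules meeting the detection criteria.

    Candidate triples are generated with apriori pruning (no superset of an
    infrequent itemset is ever scanned); the emitted set is identical to
    exhaustive enumeration over all triples with the same thresholds.
    """
    members = annotate_strata(dataset, strata)
    out = []
    for counts in count_triples(dataset, members, min_count=min_count):
        m = ar_metrics(counts)
        if ar_signal(m, min_count=min_count, min_lift=min_lift,
                     min_conviction=min_conviction):
            out.append(RuleResult(counts=counts, metrics=m, is_signal=True))
    return out
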