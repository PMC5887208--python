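"""Per-triple count vectors for (drug A, stratum B, event C).

A transaction is one report; items are the *presence* of a drug, stratum
membership, and an event, so a report contributes at most 1 to any cell.
Two baselines are carried side by side: ``n_plus1``/``n_plusplus`` span the
whole dataset (used by lift/conviction), while ``n_B1``/``n_B_plus`` are
restricted to the stratum (used by PRR and chi-square).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import ValidationError
from .srs_io import SRSDataset

__all__ = ["TripleCounts", "count_triples", "counts_frame"]


@dataclass(frozen=True)
class TripleCounts:
    """The eight counts underlying both detectors for one (A, B, C) triple.

    Cell layout within stratum B::

                     event C   not C    total
        with drug A   n_AB1    n_AB2    n_AB_plus
        without A     n_B1     n_B2     n_B_plus

    plus the whole-dataset margins ``n_plus1`` (reports with C anywhere) and
    ``n_plusplus`` (all reports).
    """

    drug: str
    stratum: str
    event: str
    n_AB1: int
    n_AB2: int
    n_AB_plus: int
    n_B1: int
    n_B2: int
    n_B_plus: int
    n_plus1: int
    n_plusplus: int

    def __post_init__(self):
        c = self
        if min(c.n_AB1, c.n_AB2, c.n_B1, c.n_B2, c.n_plus1, c.n_plusplus) < 0:
            raise ValidationError(f"negative cell in {c}")
        if c.n_AB1 + c.n_AB2 != c.n_AB_plus or c.n_B1 + c.n_B2 != c.n_B_plus:
            raise ValidationError(f"row sums inconsistent in {c}")
        if not (c.n_AB1 <= c.n_plus1 <= c.n_plusplus):
            raise ValidationError(f"whole-dataset margins inconsistent in {c}")
        if c.n_AB1 + c.n_B1 > c.n_plus1:
            raise ValidationError(f"stratum C-count exceeds global C-count in {c}")
        if c.n_AB_plus + c.n_B_plus > c.n_plusplus:
            raise ValidationError(f"stratum size exceeds dataset size in {c}")

    @property
    def stratum_size(self) -> int:
        return self.n_AB_plus + self.n_B_plus


def count_triples(dataset: SRSDataset, stratum_members: Mapping,
                  min_count: int = 1) -> list:
    """Emit one :class:`TripleCounts` per (A, B, C) with ``n_AB1 >= min_count``.

    Candidate generation is apriori-pruned: within each stratum, drugs whose
    in-stratum report count is below ``min_count`` and events whose dataset or
    in-stratum count is below ``min_count`` are discarded before any pair is
    enumerated, since a triple's count can never exceed either sub-itemset's.
    """
    if min_count < 1:
        raise ValidationError("min_count must be >= 1")
    if len(dataset) == 0:
        raise ValidationError("cannot count triples over an empty dataset")

    n_pp = len(dataset)
    event_totals: Counter = Counter()
    for r in dataset:
        event_totals.update(r.events)

    out: list[TripleCounts] = []
    for stratum, members in stratum_members.items():
        in_stratum = [r for r in dataset if r.case_id in members]
        stratum_size = len(in_stratum)
        drug_totals: Counter = Counter()       # n_AB_plus per drug
        event_in_stratum: Counter = Counter()  # reports in B with C
        for r in in_stratum:
            drug_totals.update(r.drugs)
            event_in_stratum.update(r.events)

        frequent_drugs = {d for d, n in drug_totals.items() if n >= min_count}
        frequent_events = {
            e for e, n in event_in_stratum.items()
            if n >= min_count and event_totals[e] >= min_count
        }

        pair_counts: Counter = Counter()       # n_AB1 per (drug, event)
        for r in in_stratum:
            ds = r.drugs & frequent_drugs
            es = r.events & frequent_events
            for d in ds:
                for e in es:
                    pair_counts[(d, e)] += 1

        for (d, e), n_ab1 in sorted(pair_counts.items()):
            if n_ab1 < min_count:
                continue
            n_ab_plus = drug_totals[d]
            n_b_plus = stratum_size - n_ab_plus
            n_b1 = event_in_stratum[e] - n_ab1
            out.append(TripleCounts(
                drug=d, stratum=stratum, event=e,
                n_AB1=n_ab1, n_AB2=n_ab_plus - n_ab1, n_AB_plus=n_ab_plus,
                n_B1=n_b1, n_B2=n_b_plus - n_b1, n_B_plus=n_b_plus,
                n_plus1=event_totals[e], n_plusplus=n_pp,
            ))
    return out


def counts_frame(counts) -> pd.DataFrame:
    """Counts as a table, one row per triple, all eight count columns."""
    cols = ["drug", "stratum", "event", "n_AB1", "n_AB2", "n_AB_plus",
            "n_B1", "n_B2", "n_B_plus", "n_plus1", "n_plusplus"]
    return pd.DataFrame([{c: getattr(t, c) for c in cols} for t in counts],
                        columns=cols)
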