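"""Head-to-head comparison of the two detectors.

The PRR signal set serves as the reference (a methodological comparator, not
biological truth); association-rule signals are scored against it via a
confusion table, a ROC curve over the lift ranking, and an ordinary
least-squares fit of log10(lift) against log10(PRR) + log10(chi2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateError, ValidationError

__all__ = ["ConfusionMetrics", "ROCResult", "RegressionFit",
           "confusion", "roc", "fit_line",
           "StratumEvaluation", "EvaluationReport", "evaluate_rules"]


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    youden: float
    ppv: float
    npv: float


@dataclass(frozen=True)
class ROCResult:
    points: list          # (fpr, tpr) pairs from (0,0) to (1,1)
    auc: float
    score_name: str = "lift"


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def confusion(predicted: set, reference: set, universe: set) -> ConfusionMetrics:
    """Standard 2x2 agreement metrics of ``predicted`` vs ``reference``.

    Undefined ratios (empty reference, empty predicted, ...) come back as NaN
    with a warning rather than raising.
    """
    predicted, reference, universe = set(predicted), set(reference), set(universe)
    if not predicted <= universe:
        raise ValidationError("predicted set is not a subset of the universe")
    if not reference <= universe:
        raise ValidationError("reference set is not a subset of the universe")
    tp = len(predicted & reference)
    fp = len(predicted - reference)
    fn = len(reference - predicted)
    tn = len(universe) - tp - fp - fn

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return math.nan
        return num / den

    sens = _ratio(tp, tp + fn, "sensitivity")
    spec = _ratio(tn, tn + fp, "specificity")
    ppv = _ratio(tp, tp + fp, "ppv")
    npv = _ratio(tn, tn + fn, "npv")
    return ConfusionMetrics(tp=tp, fp=fp, fn=fn, tn=tn,
                            sensitivity=sens, specificity=spec,
                            youden=sens + spec - 1.0, ppv=ppv, npv=npv)


def roc(scores: Mapping, reference: set, universe: set,
        score_name: str = "lift") -> ROCResult:
    """ROC curve from sweeping a threshold over all distinct score values.

    Tied scores share a single threshold step; the AUC is the trapezoidal
    area, which equals the pairwise-concordance (Mann-Whitney) estimate with
    ties counted 1/2.  Scores may be -inf (items ranked below everything,
    e.g. gated out before ranking) but not NaN.
    """
    universe = set(universe)
    reference = set(reference)
    if not reference <= universe:
        raise ValidationError("reference set is not a subset of the universe")
    missing = [k for k in universe if k not in scores]
    if missing:
        raise ValidationError(f"{len(missing)} universe item(s) have no score")
    n_pos = len(reference)
    n_neg = len(universe) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateError("ROC needs at least one positive and one negative")

    vals = np.array([float(scores[k]) for k in universe])
    if np.isnan(vals).any():
        raise ValidationError("NaN score in ROC input")
    labels = np.array([k in reference for k in universe])

    order = np.argsort(-vals, kind="stable")
    vals, labels = vals[order], labels[order]
    # one step per distinct score value, descending
    _, first_idx = np.unique(-vals, return_index=True)
    boundaries = np.sort(first_idx)[1:]  # indices where a new value starts
    cum_tp = np.cumsum(labels)
    cum_fp = np.cumsum(~labels)
    step_ends = np.append(boundaries - 1, len(vals) - 1)
    tpr = np.concatenate(([0.0], cum_tp[step_ends] / n_pos))
    fpr = np.concatenate(([0.0], cum_fp[step_ends] / n_neg))
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(points=list(zip(fpr.tolist(), tpr.tolist())),
                     auc=auc, score_name=score_name)


def fit_line(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Ordinary least squares y = slope*x + intercept with R^2 = 1 - SSR/SST."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d sequences of equal length")
    if len(x) < 3:
        raise DegenerateError("need at least 3 points to fit a line")
    xm, ym = float(x.mean()), float(y.mean())
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise DegenerateError("constant x: slope undefined")
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    ssr = float((resid ** 2).sum())
    sst = float(((y - ym) ** 2).sum())
    r2 = 1.0 if sst == 0.0 else 1.0 - ssr / sst
    # guard tiny negative round-off
    r2 = min(1.0, max(0.0, r2))
    return RegressionFit(slope=slope, intercept=intercept, r_squared=r2,
                         n_points=len(x))


@dataclass
class StratumEvaluation:
    confusion: ConfusionMetrics
    roc: ROCResult | None
    regression: RegressionFit | None
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {"confusion": vars(self.confusion)}
        out["roc"] = None if self.roc is None else {
            "auc": self.roc.auc, "score_name": self.roc.score_name,
            "n_points": len(self.roc.points)}
        out["regression"] = None if self.regression is None else vars(self.regression)
        if self.notes:
            out["notes"] = list(self.notes)
        return out


@dataclass
class EvaluationReport:
    strata: dict  # stratum name -> StratumEvaluation

    def to_dict(self) -> dict:
        return {name: ev.to_dict() for name, ev in self.strata.items()}


_REQUIRED_COLS = {"stratum", "drug", "event", "rule_count", "lift",
                  "conviction", "ar_signal", "prr", "chi2", "prr_signal"}


def evaluate_rules(rules: pd.DataFrame, min_count: int = 3,
                   roc_score: str = "lift", log_base: float = 10.0,
                   universe_min_count: int = 1,
                   regression_min_count: int | None = None) -> EvaluationReport:
    """Evaluate AR signals against PRR signals, one block per stratum.

    The evaluation universe is every triple in ``rules`` with
    ``rule_count >= universe_min_count``.  The ROC ranking score is the
    ``roc_score`` column with the rule-count gate applied before ranking
    (gated-out triples score -inf).  The regression uses triples where lift,
    PRR and chi2 are all positive and finite and whose rule count reaches
    ``regression_min_count`` (default: the ``min_count`` gate, since the
    intensity score is only meaningful at signal-qualifying counts; pass 1
    to regress over the whole universe).
    """
    if regression_min_count is None:
        regression_min_count = min_count
    missing = _REQUIRED_COLS - set(rules.columns)
    if missing:
        raise ValidationError(f"rules table is missing columns {sorted(missing)}")
    if roc_score not in rules.columns:
        raise ValidationError(f"unknown ROC score column {roc_score!r}")
    log = lambda v: np.log(v) / np.log(log_base)

    strata_out: dict[str, StratumEvaluation] = {}
    for stratum, block in rules.groupby("stratum", sort=True):
        block = block[block["rule_count"] >= universe_min_count]
        keys = list(zip(block["drug"], block["event"]))
        universe = set(keys)
        predicted = {k for k, s in zip(keys, block["ar_signal"]) if s}
        reference = {k for k, s in zip(keys, block["prr_signal"]) if s}
        notes: list[str] = []

        conf = confusion(predicted, reference, universe)

        gated = block["rule_count"] >= min_count
        raw = block[roc_score].where(gated, -np.inf)
        scores = dict(zip(keys, raw.astype(float)))
        try:
            roc_res = roc(scores, reference, universe, score_name=roc_score)
        except DegenerateError as exc:
            roc_res = None
            notes.append(f"roc: {exc}")

        ok = (block["lift"] > 0) & (block["prr"] > 0) & (block["chi2"] > 0)
        ok &= np.isfinite(block["lift"]) & np.isfinite(block["prr"]) & np.isfinite(block["chi2"])
        ok &= block["rule_count"] >= regression_min_count
        x = log(block.loc[ok, "lift"].to_numpy(dtype=float))
        y = (log(block.loc[ok, "prr"].to_numpy(dtype=float))
             + log(block.loc[ok, "chi2"].to_numpy(dtype=float)))
        try:
            fit = fit_line(x, y)
        except DegenerateError as exc:
            fit = None
            notes.append(f"regression: {exc}")

        strata_out[str(stratum)] = StratumEvaluation(
            confusion=conf, roc=roc_res, regression=fit, notes=notes)
    return EvaluationReport(strata=strata_out)
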