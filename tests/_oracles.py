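"""Independent brute-force oracles used to cross-check the pipeline.

Everything here recounts from raw Report objects with plain loops and
recomputes statistics with its own arithmetic; nothing is shared with the
package's counting or pruning paths.
"""

import math

import numpy as np


def brute_cells(reports, drug, terms, event):
    """All eight counts for one (drug, stratum-term-set, event) triple by
    scanning the raw reports."""
    terms = set(terms)
    n_pp = len(reports)
    n_p1 = sum(1 for r in reports if event in r.events)
    members = [r for r in reports if set(r.histories) & terms]
    a = sum(1 for r in members if drug in r.drugs and event in r.events)
    ab = sum(1 for r in members if drug in r.drugs)
    c = sum(1 for r in members if drug not in r.drugs and event in r.events)
    bp = sum(1 for r in members if drug not in r.drugs)
    return {"n_AB1": a, "n_AB2": ab - a, "n_AB_plus": ab,
            "n_B1": c, "n_B2": bp - c, "n_B_plus": bp,
            "n_plus1": n_p1, "n_plusplus": n_pp}


def brute_lift(cells):
    return (cells["n_AB1"] / cells["n_AB_plus"]) / (cells["n_plus1"] / cells["n_plusplus"])


def brute_conviction(cells):
    conf = cells["n_AB1"] / cells["n_AB_plus"]
    if conf == 1.0:
        return math.inf
    return (1.0 - cells["n_plus1"] / cells["n_plusplus"]) / (1.0 - conf)


def brute_prr(cells):
    return (cells["n_AB1"] / cells["n_AB_plus"]) / (cells["n_B1"] / cells["n_B_plus"])


def brute_rules(reports, strata, min_count=3, min_lift=1.0, min_conviction=1.0):
    """Exhaustive enumeration over every (drug, stratum, event) combination;
    no pruning of any kind.  Returns {triple: (lift, conviction, count)}."""
    drugs = sorted(set().union(*(r.drugs for r in reports)) or set())
    events = sorted(set().union(*(r.events for r in reports)) or set())
    out = {}
    for s in strata:
        for d in drugs:
            for e in events:
                cells = brute_cells(reports, d, s.terms, e)
                if cells["n_AB1"] < min_count or cells["n_AB_plus"] == 0:
                    continue
                lf = brute_lift(cells)
                cv = brute_conviction(cells)
                if lf > min_lift and cv > min_conviction:
                    out[(d, s.name, e)] = (lf, cv, cells["n_AB1"])
    return out


def mwu_auc(scores, reference, universe):
    """Pairwise-concordance AUC estimate, ties counted 1/2."""
    pos = [scores[k] for k in universe if k in reference]
    neg = [scores[k] for k in universe if k not in reference]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def ols_fit(x, y):
    """Least-squares line via numpy's solver; returns (slope, intercept, r2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    coef, res, *_ = np.linalg.lstsq(np.column_stack([x, np.ones_like(x)]), y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    ssr = float(((y - slope * x - intercept) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - ssr / sst
    return slope, intercept, r2
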