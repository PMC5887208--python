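"""Synthetic spontaneous-report datasets with known injected associations.

Reports are sampled independently: each drug and history term is an
independent Bernoulli draw per report, and each event fires with its baseline
probability unless the report carries the drug and history of an injected
(drug, hist, event, relative-risk) effect, in which case the probability is
baseline * rho (the maximum rho among matching injections).  Everything else
is independent — the minimal structure the two detectors assume.

Ground truth (the injected triples) is returned alongside the data so tests
never have to reverse-engineer the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .srs_io import Report, SRSDataset

__all__ = ["InjectedEffect", "SimConfig", "generate", "export_jader_tables",
           "default_config", "toy_dataset"]


@dataclass(frozen=True)
class InjectedEffect:
    drug: str
    hist: str
    event: str
    relative_risk: float


@dataclass
class SimConfig:
    """Catalogs are ordered name -> probability mappings; ``strata`` maps a
    stratum name to its history-term list (default: one stratum per term)."""

    n_reports: int
    drug_catalog: dict
    hist_catalog: dict
    event_catalog: dict
    injected_effects: list = field(default_factory=list)
    seed: int = 0
    strata: dict | None = None

    def __post_init__(self):
        self.injected_effects = [
            e if isinstance(e, InjectedEffect) else InjectedEffect(*e)
            for e in self.injected_effects
        ]
        if self.strata is None:
            self.strata = {t: [t] for t in self.hist_catalog}
        self.validate()

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ValidationError("n_reports must be >= 0")
        for label, catalog in (("drug", self.drug_catalog),
                               ("hist", self.hist_catalog),
                               ("event", self.event_catalog)):
            for name, p in catalog.items():
                if not (0.0 <= p <= 1.0):
                    raise ValidationError(
                        f"{label} {name!r} probability {p} outside [0, 1]")
        for eff in self.injected_effects:
            if eff.drug not in self.drug_catalog:
                raise ValidationError(f"injected drug {eff.drug!r} not in catalog")
            if eff.hist not in self.hist_catalog:
                raise ValidationError(f"injected hist {eff.hist!r} not in catalog")
            if eff.event not in self.event_catalog:
                raise ValidationError(f"injected event {eff.event!r} not in catalog")
            if eff.relative_risk < 1.0:
                raise ValidationError(
                    f"relative risk {eff.relative_risk} < 1 for {eff}")
            if eff.relative_risk * self.event_catalog[eff.event] > 1.0:
                raise ValidationError(
                    f"rho * baseline > 1 for injected triple {eff}")

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_reports": self.n_reports,
            "drug_catalog": dict(self.drug_catalog),
            "hist_catalog": dict(self.hist_catalog),
            "event_catalog": dict(self.event_catalog),
            "injected_effects": [
                [e.drug, e.hist, e.event, e.relative_risk]
                for e in self.injected_effects
            ],
            "seed": self.seed,
            "strata": {k: list(v) for k, v in self.strata.items()},
        }

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            n_reports=int(raw["n_reports"]),
            drug_catalog={str(k): float(v) for k, v in raw["drug_catalog"].items()},
            hist_catalog={str(k): float(v) for k, v in raw["hist_catalog"].items()},
            event_catalog={str(k): float(v) for k, v in raw["event_catalog"].items()},
            injected_effects=[tuple(e) for e in raw.get("injected_effects", [])],
            seed=int(raw.get("seed", 0)),
            strata=raw.get("strata"),
        )


def generate(config: SimConfig, seed: int | None = None):
    """Sample a dataset; returns ``(SRSDataset, list[InjectedEffect])``.

    Identical config and seed give an identical dataset.  ``seed`` overrides
    ``config.seed`` when given.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_reports
    drugs = list(config.drug_catalog)
    hists = list(config.hist_catalog)
    events = list(config.event_catalog)

    d_mat = rng.random((n, len(drugs))) < np.array(list(config.drug_catalog.values()))
    h_mat = rng.random((n, len(hists))) < np.array(list(config.hist_catalog.values()))

    base = np.array(list(config.event_catalog.values()))
    probs = np.broadcast_to(base, (n, len(events))).copy()
    d_idx = {d: i for i, d in enumerate(drugs)}
    h_idx = {h: i for i, h in enumerate(hists)}
    e_idx = {e: i for i, e in enumerate(events)}
    for eff in config.injected_effects:
        mask = d_mat[:, d_idx[eff.drug]] & h_mat[:, h_idx[eff.hist]]
        j = e_idx[eff.event]
        boosted = min(1.0, eff.relative_risk * base[j])
        probs[mask, j] = np.maximum(probs[mask, j], boosted)
    e_mat = rng.random((n, len(events))) < probs

    drugs_a = np.array(drugs)
    hists_a = np.array(hists)
    events_a = np.array(events)
    reports = [
        Report(
            case_id=f"C{i:06d}",
            drugs=frozenset(drugs_a[d_mat[i]]),
            histories=frozenset(hists_a[h_mat[i]]),
            events=frozenset(events_a[e_mat[i]]),
        )
        for i in range(n)
    ]
    dataset = SRSDataset(
        reports=reports,
        provenance=f"synthetic: n_reports={n}, seed={config.seed if seed is None else seed}, "
                   f"{len(config.injected_effects)} injected effects",
    )
    return dataset, list(config.injected_effects)


def export_jader_tables(dataset: SRSDataset, out_dir) -> dict:
    """Write DEMO/DRUG/REAC/HIST CSVs that round-trip through ``load_dataset``.

    DRUG rows carry role ``suspect`` and route ``oral`` so the default load
    filters keep them.
    """
    if len(dataset) == 0:
        raise ValidationError("refusing to export an empty dataset")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    demo_rows, drug_rows, reac_rows, hist_rows = [], [], [], []
    for r in dataset:
        demo_rows.append({"case_id": r.case_id, "sex": "", "age": "", "weight": ""})
        for d in sorted(r.drugs):
            drug_rows.append({"case_id": r.case_id, "drug_name": d,
                              "role": "suspect", "route": "oral"})
        for e in sorted(r.events):
            reac_rows.append({"case_id": r.case_id, "event_term": e, "outcome": ""})
        for h in sorted(r.histories):
            hist_rows.append({"case_id": r.case_id, "hist_term": h})
    paths = {}
    for name, rows, cols in (
        ("demo", demo_rows, ["case_id", "sex", "age", "weight"]),
        ("drug", drug_rows, ["case_id", "drug_name", "role", "route"]),
        ("reac", reac_rows, ["case_id", "event_term", "outcome"]),
        ("hist", hist_rows, ["case_id", "hist_term"]),
    ):
        path = out_dir / f"{name}.csv"
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        paths[name] = path
    return paths


def default_config(seed: int = 0) -> SimConfig:
    """Packaged default: 18,000 reports, two disease strata, 5% of the
    drug x stratum x event triples injected with relative risk in [2, 10].

    Catalogs are fixed (log-spaced inclusion probabilities, so pair counts
    are skewed toward 1-2 as in real reporting data); the injected-triple
    sample depends on ``seed`` (the same seed drives report sampling).
    Relative risks are drawn from the half-integer grid {2.0, ..., 10.0}.
    Eight fixed rho = 10 anchor triples sit on high-frequency drug/event
    combinations (expected triple count > 10) so strong effects are always
    present for recovery checks.
    """
    n_drugs, n_events = 50, 40
    drug_names = [f"drug_{i:02d}" for i in range(n_drugs)]
    event_names = [f"event_{j:02d}" for j in range(n_events)]
    drug_catalog = dict(zip(drug_names,
                            (float(v) for v in np.geomspace(0.003, 0.08, n_drugs).round(6))))
    event_catalog = dict(zip(event_names,
                             (float(v) for v in np.geomspace(0.0008, 0.015, n_events).round(6))))
    hist_catalog = {"renal disorder": 0.10, "hepatic disorder": 0.12}
    hists = list(hist_catalog)

    # fixed strong anchors: ascending drug paired with descending event keeps
    # the product (hence the expected triple count) roughly level
    anchors = [
        InjectedEffect(drug_names[42 + k], hists[k % 2], event_names[39 - k], 10.0)
        for k in range(8)
    ]
    anchor_keys = {(a.drug, a.hist, a.event) for a in anchors}

    triples = [(d, h, e) for d in drug_catalog for h in hist_catalog
               for e in event_catalog if (d, h, e) not in anchor_keys]
    n_inject = int(round(0.05 * (len(triples) + len(anchors)))) - len(anchors)
    rng = np.random.default_rng([seed, 0xADE])
    picks = rng.choice(len(triples), size=n_inject, replace=False)
    grid = np.arange(2.0, 10.5, 0.5)
    rhos = rng.choice(grid, size=n_inject)
    injected = anchors + [
        InjectedEffect(*triples[i], relative_risk=float(r))
        for i, r in zip(picks, rhos)
    ]
    return SimConfig(
        n_reports=18_000,
        drug_catalog=drug_catalog,
        hist_catalog=hist_catalog,
        event_catalog=event_catalog,
        injected_effects=injected,
        seed=seed,
        strata={"renal": ["renal disorder"], "hepatic": ["hepatic disorder"]},
    )


def toy_dataset() -> SRSDataset:
    """A 12-report worked example with one stratum K (history term H).

    Designed so the two detectors agree exactly: triples (D1, K, E1) and
    (D2, K, E2) are flagged by both criteria sets, while (D3, K, E3) and
    (D4, K, E3) appear once each and are flagged by neither.
    """
    rows = [
        ("T01", {"D1"}, {"E1"}), ("T02", {"D1"}, {"E1"}), ("T03", {"D1"}, {"E1"}),
        ("T04", {"D2"}, {"E2"}), ("T05", {"D2"}, {"E2"}), ("T06", {"D2"}, {"E2"}),
        ("T07", set(), {"E1"}), ("T08", set(), {"E2"}),
        ("T09", {"D3"}, {"E3"}), ("T10", {"D3"}, set()),
        ("T11", set(), set()), ("T12", {"D4"}, {"E3"}),
    ]
    return SRSDataset(
        reports=[Report(cid, frozenset(ds), frozenset({"H"}), frozenset(es))
                 for cid, ds, es in rows],
        provenance="packaged 12-report worked example",
    )
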