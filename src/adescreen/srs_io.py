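"""Read, validate, deduplicate and filter four-table spontaneous-report data.

The canonical input layout mirrors public SRS releases: a DEMO table (one row
per case), a DRUG table (case -> drug, role, route), a REAC table (case ->
adverse-event preferred term) and a HIST table (case -> primary-disease term),
all delimited text with a header row and a shared case-identifier column.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

__all__ = [
    "Report",
    "SRSDataset",
    "StratumDefinition",
    "LoadConfig",
    "load_dataset",
    "annotate_strata",
    "load_strata",
    "to_long_frame",
    "write_long_csv",
]


@dataclass(frozen=True)
class Report:
    """One spontaneous report: a case id plus item sets.

    ``drugs`` and ``events`` may be empty; such reports still count toward the
    whole-database denominator.
    """

    case_id: str
    drugs: frozenset = frozenset()
    histories: frozenset = frozenset()
    events: frozenset = frozenset()


@dataclass
class SRSDataset:
    """Ordered, deduplicated collection of reports."""

    reports: list = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        seen = set()
        for r in self.reports:
            if r.case_id in seen:
                raise ValidationError(f"duplicate case_id {r.case_id!r} in dataset")
            seen.add(r.case_id)

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)

    @property
    def case_ids(self) -> list:
        return [r.case_id for r in self.reports]


@dataclass(frozen=True)
class StratumDefinition:
    """A named primary disease, given as a set of preferred terms."""

    name: str
    terms: frozenset

    def __post_init__(self):
        if not self.terms:
            raise ValidationError(f"stratum {self.name!r} has an empty term set")


@dataclass
class LoadConfig:
    """Column names, filters and parsing options for :func:`load_dataset`.

    ``route_allow`` / ``role_allow`` are allow-lists applied to DRUG rows;
    ``None`` disables the corresponding filter.  Matching is exact string
    equality after whitespace trimming.
    """

    case_id_col: str = "case_id"
    drug_col: str = "drug_name"
    role_col: str = "role"
    route_col: str = "route"
    event_col: str = "event_term"
    hist_col: str = "hist_term"
    route_allow: tuple | None = ("oral",)
    role_allow: tuple | None = None
    delimiter: str = ","
    encoding: str = "utf-8"


def _read_table(path, name: str, cfg: LoadConfig, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.is_file():
        raise OSError(f"{name} table not found: {path}")
    with open(path, encoding=cfg.encoding, newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            raise SchemaError(f"{name} table {path} is empty")
        header = next(csv.reader(io.StringIO(header_line), delimiter=cfg.delimiter))
        header = [h.strip() for h in header]
        if len(set(header)) != len(header):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise SchemaError(f"{name} table has duplicate column headers: {dupes}")
        missing = [c for c in required if c not in header]
        if missing:
            raise SchemaError(f"{name} table is missing column(s) {missing}")
        try:
            df = pd.read_csv(fh, sep=cfg.delimiter, names=header, dtype=str,
                             keep_default_na=False, skip_blank_lines=True)
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=header, dtype=str)
    for col in required:
        df[col] = df[col].str.strip()
    return df


def _item_map(df: pd.DataFrame, cfg: LoadConfig, item_col: str) -> dict:
    """case_id -> set of non-empty item strings."""
    sub = df[df[item_col] != ""]
    return {cid: set(grp) for cid, grp in sub.groupby(cfg.case_id_col)[item_col]}


def load_dataset(demo_path, drug_path, reac_path, hist_path,
                 config: LoadConfig | None = None) -> SRSDataset:
    """Assemble one :class:`Report` per surviving DEMO case.

    Deduplication keeps the first DEMO row per case id in file order.  DRUG
    rows failing the route/role allow-lists are dropped; the case itself is
    retained (possibly with an empty drug set).  Rows in DRUG/REAC/HIST whose
    case id is absent from DEMO are ignored.
    """
    cfg = config or LoadConfig()
    prov: list[str] = []

    demo = _read_table(demo_path, "DEMO", cfg, [cfg.case_id_col])
    n_raw = len(demo)
    demo = demo[demo[cfg.case_id_col] != ""]
    demo = demo.drop_duplicates(subset=cfg.case_id_col, keep="first")
    prov.append(f"DEMO: {n_raw} rows -> {len(demo)} unique cases")

    drug = _read_table(drug_path, "DRUG", cfg, [cfg.case_id_col, cfg.drug_col])
    n_drug_raw = len(drug)
    if cfg.route_allow is not None:
        if cfg.route_col not in drug.columns:
            raise SchemaError(f"DRUG table is missing route column {cfg.route_col!r}")
        allow = {t.strip() for t in cfg.route_allow}
        drug = drug[drug[cfg.route_col].str.strip().isin(allow)]
    if cfg.role_allow is not None:
        if cfg.role_col not in drug.columns:
            raise SchemaError(f"DRUG table is missing role column {cfg.role_col!r}")
        allow = {t.strip() for t in cfg.role_allow}
        drug = drug[drug[cfg.role_col].str.strip().isin(allow)]
    prov.append(f"DRUG: {n_drug_raw} rows -> {len(drug)} after route/role filter")

    reac = _read_table(reac_path, "REAC", cfg, [cfg.case_id_col, cfg.event_col])
    hist = _read_table(hist_path, "HIST", cfg, [cfg.case_id_col, cfg.hist_col])
    prov.append(f"REAC: {len(reac)} rows; HIST: {len(hist)} rows")

    drugs_by_case = _item_map(drug, cfg, cfg.drug_col)
    events_by_case = _item_map(reac, cfg, cfg.event_col)
    hists_by_case = _item_map(hist, cfg, cfg.hist_col)

    reports = [
        Report(
            case_id=cid,
            drugs=frozenset(drugs_by_case.get(cid, ())),
            histories=frozenset(hists_by_case.get(cid, ())),
            events=frozenset(events_by_case.get(cid, ())),
        )
        for cid in demo[cfg.case_id_col]
    ]
    prov.append(f"reports: {len(reports)}")
    provenance = (
        f"load_dataset(demo={demo_path}, drug={drug_path}, reac={reac_path}, "
        f"hist={hist_path}); " + "; ".join(prov)
    )
    return SRSDataset(reports=reports, provenance=provenance)


def annotate_strata(dataset: SRSDataset,
                    strata: Iterable[StratumDefinition]) -> dict:
    """Map each stratum name to the set of member case ids.

    A case belongs to a stratum iff its history terms intersect the stratum's
    term set; membership in several strata is allowed.
    """
    strata = list(strata)
    names = [s.name for s in strata]
    if len(set(names)) != len(names):
        raise ValidationError("stratum names must be unique")
    for s in strata:
        if not s.terms:
            raise ValidationError(f"stratum {s.name!r} has an empty term set")
    return {
        s.name: {r.case_id for r in dataset if r.histories & s.terms}
        for s in strata
    }


def load_strata(path) -> list:
    """Load stratum definitions from YAML (name -> term list) or plain text.

    A plain-text file holds one term per line and defines a single stratum
    named after the file stem.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise SchemaError(f"strata file {path} must be a mapping name -> terms")
        out = []
        for name, terms in raw.items():
            if isinstance(terms, str):
                terms = [terms]
            out.append(StratumDefinition(str(name), frozenset(str(t).strip() for t in terms)))
        return out
    with open(path, encoding="utf-8") as fh:
        terms = [line.strip() for line in fh if line.strip()]
    return [StratumDefinition(path.stem, frozenset(terms))]


_KIND_ORDER = {"drug": 0, "hist": 1, "event": 2}


def to_long_frame(dataset: SRSDataset) -> pd.DataFrame:
    """Serialize the canonical dataset as (case_id, item_kind, item) rows."""
    rows = []
    for r in dataset:
        for kind, items in (("drug", r.drugs), ("hist", r.histories), ("event", r.events)):
            for item in sorted(items):
                rows.append((r.case_id, kind, item))
    df = pd.DataFrame(rows, columns=["case_id", "item_kind", "item"])
    return df


def write_long_csv(dataset: SRSDataset, path) -> None:
    to_long_frame(dataset).to_csv(path, index=False)
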