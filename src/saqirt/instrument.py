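"""Instrument and response-data model: survey structure, CSV I/O, exclusions.

A safety-culture survey instrument is a set of domains (constructs), each
measured by a handful of Likert items.  The bundled SAQ-C layout has five
domains -- teamwork climate (5 items), safety climate (6), job
satisfaction (5), perception of management (10) and working conditions
(4) -- each item on a 5-point agree/disagree scale.

Responses travel as a respondent x item table of ordinal codes 1..K with
an optional hospital-level group label and pass-through demographic
columns.  Because each domain has few items, scoring uses listwise
complete questionnaires only: :func:`filter_complete` applies the same
exclusion rules a multigroup analysis needs (no missing item codes; a
known group label) and accounts for every dropped row.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "InstrumentSpec",
    "ResponseMatrix",
    "ExclusionReport",
    "load_instrument",
    "saqc_instrument",
    "read_responses",
    "write_responses",
    "filter_complete",
    "summarize_sample",
]

#: strings accepted as missing on read; written back as empty cells
NA_MARKERS = ("", "NA")


@dataclass(frozen=True)
class InstrumentSpec:
    """Domain -> item map plus per-item category counts.

    ``domains`` preserves declaration order; every item id is globally
    unique and belongs to exactly one domain.
    """

    domains: tuple[tuple[str, tuple[str, ...]], ...]
    n_categories: Mapping[str, int]
    name: str = "instrument"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        if not self.domains:
            raise ValueError("instrument needs at least one domain")
        for dom, items in self.domains:
            if not items:
                raise ValueError(f"domain {dom!r} declares no items")
            for it in items:
                if it in seen:
                    raise ValueError(f"item {it!r} appears in more than one domain")
                seen.add(it)
        for it in seen:
            k = self.n_categories.get(it)
            if k is None:
                raise ValueError(f"item {it!r} has no category count")
            if k < 2:
                raise ValueError(f"item {it!r}: n_categories must be >= 2, got {k}")

    @property
    def domain_ids(self) -> tuple[str, ...]:
        return tuple(d for d, _ in self.domains)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it for _, items in self.domains for it in items)

    def items_for(self, domain_id: str) -> tuple[str, ...]:
        for dom, items in self.domains:
            if dom == domain_id:
                return items
        raise KeyError(f"unknown domain {domain_id!r}")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)


@dataclass(frozen=True)
class ExclusionReport:
    """Accounting of questionnaires dropped before analysis."""

    n_collected: int
    n_excluded_missing_item: int
    n_excluded_missing_group: int
    n_analyzed: int

    def __post_init__(self) -> None:
        counts = (
            self.n_collected,
            self.n_excluded_missing_item,
            self.n_excluded_missing_group,
            self.n_analyzed,
        )
        if any(c < 0 for c in counts):
            raise ValueError(f"negative count in exclusion report: {counts}")
        if (
            self.n_analyzed
            != self.n_collected - self.n_excluded_missing_item - self.n_excluded_missing_group
        ):
            raise ValueError("exclusion report does not balance")

    def to_dict(self) -> dict[str, int]:
        return {
            "n_collected": self.n_collected,
            "n_excluded_missing_item": self.n_excluded_missing_item,
            "n_excluded_missing_group": self.n_excluded_missing_group,
            "n_analyzed": self.n_analyzed,
        }


@dataclass
class ResponseMatrix:
    """Respondent x item ordinal codes with group labels and metadata.

    ``data`` holds one nullable-integer column per instrument item, indexed
    by respondent id.  ``group`` (nullable strings, same index) carries the
    hospital-level label when present.  ``metadata`` keeps unrecognized
    input columns (gender, age band, job type, ...) untouched.
    """

    data: pd.DataFrame
    group: pd.Series | None = None
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.metadata is None or self.metadata.empty:
            self.metadata = pd.DataFrame(index=self.data.index)
        if self.group is not None and not self.group.index.equals(self.data.index):
            raise ValueError("group labels index does not match response rows")
        if not self.metadata.index.equals(self.data.index):
            raise ValueError("metadata index does not match response rows")

    @property
    def respondent_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n_respondents(self) -> int:
        return len(self.data)

    def codes(self, items: Sequence[str] | None = None) -> np.ndarray:
        """Responses as a float array with NaN for missing codes."""
        frame = self.data if items is None else self.data[list(items)]
        return frame.to_numpy(dtype=float, na_value=np.nan)

    def validate(self, spec: InstrumentSpec) -> None:
        for it in spec.item_ids:
            if it not in self.data.columns:
                raise ValueError(f"missing item column {it!r}")
            col = self.data[it]
            k = spec.n_categories[it]
            bad = col.dropna()
            bad = bad[(bad < 1) | (bad > k)]
            if len(bad):
                ridx = bad.index[0]
                raise ValueError(
                    f"item {it!r}, respondent {ridx!r}: code {bad.iloc[0]} outside 1..{k}"
                )


def _spec_from_mapping(cfg: Mapping) -> InstrumentSpec:
    domains = []
    for dom in cfg["domains"]:
        domains.append((str(dom["id"]), tuple(str(i) for i in dom["items"])))
    default_k = cfg.get("n_categories", 5)
    n_categories: dict[str, int] = {}
    for dom_id, items in domains:
        for it in items:
            n_categories[it] = int(default_k) if not isinstance(default_k, Mapping) else int(
                default_k.get(it, 5)
            )
    if isinstance(cfg.get("item_categories"), Mapping):
        for it, k in cfg["item_categories"].items():
            n_categories[str(it)] = int(k)
    return InstrumentSpec(
        domains=tuple(domains),
        n_categories=n_categories,
        name=str(cfg.get("name", "instrument")),
    )


def load_instrument(source: str | Path | Mapping) -> InstrumentSpec:
    """Load an instrument spec from a JSON/YAML file or an in-memory mapping.

    The config declares ``domains`` (ordered, each with ``id`` and
    ``items``) and an optional ``n_categories`` (scalar default 5, or a
    per-item ``item_categories`` mapping).
    """
    if isinstance(source, Mapping):
        return _spec_from_mapping(source)
    path = Path(source)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return _spec_from_mapping(cfg)


def saqc_instrument() -> InstrumentSpec:
    """The bundled 30-item, five-domain SAQ-C instrument layout."""
    ref = importlib.resources.files("saqirt.data") / "saqc_instrument.json"
    return _spec_from_mapping(json.loads(ref.read_text()))


def read_responses(
    path: str | Path,
    spec: InstrumentSpec,
    group_col: str = "group",
    id_col: str | None = "respondent_id",
) -> ResponseMatrix:
    """Read a responses CSV and validate codes against the instrument.

    The header row must name every instrument item; unknown columns are
    retained as metadata.  Empty cells and ``NA`` read as missing.  Row
    ids come from ``id_col`` when present, else the 0-based row number.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.replace(list(NA_MARKERS), pd.NA)
    if id_col and id_col in raw.columns:
        raw = raw.set_index(id_col)
    missing_cols = [it for it in spec.item_ids if it not in raw.columns]
    if missing_cols:
        raise ValueError(f"responses file lacks item columns: {missing_cols}")

    data = pd.DataFrame(index=raw.index)
    for it in spec.item_ids:
        col = pd.to_numeric(raw[it], errors="raise")
        data[it] = col.astype("Int64")
    group = None
    if group_col in raw.columns:
        group = raw[group_col].astype("string")
        group.name = group_col
    meta_cols = [c for c in raw.columns if c not in spec.item_ids and c != group_col]
    metadata = raw[meta_cols].copy()

    matrix = ResponseMatrix(data=data, group=group, metadata=metadata)
    matrix.validate(spec)
    return matrix


def write_responses(matrix: ResponseMatrix, path: str | Path, group_col: str = "group") -> None:
    """Write responses (plus group and metadata columns) as UTF-8 CSV.

    Missing codes and labels are written as empty cells, so a read/write
    cycle is the identity on valid files.
    """
    out = matrix.data.copy()
    if matrix.group is not None:
        out[group_col] = matrix.group
    for col in matrix.metadata.columns:
        out[col] = matrix.metadata[col]
    out.index.name = out.index.name or "respondent_id"
    out.to_csv(path, na_rep="")


def filter_complete(
    matrix: ResponseMatrix,
    spec: InstrumentSpec,
    require_group: bool = True,
) -> tuple[ResponseMatrix, ExclusionReport]:
    """Apply listwise exclusion rules and account for every dropped row.

    A respondent is excluded if any instrument item is missing (domains
    are too short for partial means or imputation, and partial patterns
    would break summed-score conversion), or -- when ``require_group`` --
    if the group label is absent.  A row failing both rules is counted
    once, under missing-item.
    """
    codes = matrix.codes(spec.item_ids)
    missing_item = np.isnan(codes).any(axis=1)
    if require_group:
        if matrix.group is None:
            raise ValueError("require_group=True but matrix has no group labels")
        missing_group = matrix.group.isna().to_numpy()
    else:
        missing_group = np.zeros(len(codes), dtype=bool)
    missing_group_only = missing_group & ~missing_item
    keep = ~(missing_item | missing_group_only)

    kept = ResponseMatrix(
        data=matrix.data.loc[keep].copy(),
        group=matrix.group.loc[keep].copy() if matrix.group is not None else None,
        metadata=matrix.metadata.loc[keep].copy(),
    )
    report = ExclusionReport(
        n_collected=int(len(codes)),
        n_excluded_missing_item=int(missing_item.sum()),
        n_excluded_missing_group=int(missing_group_only.sum()),
        n_analyzed=int(keep.sum()),
    )
    return kept, report


def summarize_sample(
    matrix: ResponseMatrix,
    fields: Sequence[str],
    group_col: str = "group",
) -> pd.DataFrame:
    """Frequency table (count, percent of all rows to 1 dp) per field category.

    ``fields`` may name metadata columns or the group column; missing
    values tabulate as the category ``"Missing"``.
    """
    total = matrix.n_respondents
    rows = []
    for fieldname in fields:
        if fieldname == group_col and matrix.group is not None:
            col = matrix.group
        elif fieldname in matrix.metadata.columns:
            col = matrix.metadata[fieldname]
        else:
            raise KeyError(f"unknown field {fieldname!r}")
        col = col.astype("string").fillna("Missing")
        counts = col.value_counts(sort=False)
        for category, n in counts.items():
            rows.append(
                {
                    "field": fieldname,
                    "category": category,
                    "n": int(n),
                    "pct": round(100.0 * n / total, 1),
                }
            )
    return pd.DataFrame(rows, columns=["field", "category", "n", "pct"])
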