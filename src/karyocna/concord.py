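"""Direction-concordance of a CNA profile against tumor CNA catalogs.

A tumor catalog is a list of (region label, status) rows where status is
``gain``, ``loss``, ``both`` (the region recurrently shows both
directions in that tumor) or ``none``.  A query region is *concordant*
when its sign matches the catalog direction — ``both`` matches either
sign — *discordant* on a sign mismatch, and *absent* when the catalog
has no CNA there.  Regions are compared by label: the catalogs are
already label-aligned to the query table; coordinate-overlap matching is
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "TumorCNACatalog",
    "ConcordanceReport",
    "CatalogParseError",
    "load_tumor_catalog",
    "write_tumor_catalog",
    "classify_region",
    "concordance_report",
]

_STATUS_ALIASES = {
    "gain": "gain",
    "loss": "loss",
    "loss and gain": "both",
    "gain and loss": "both",
    "both": "both",
    "no cna": "none",
    "none": "none",
}


class CatalogParseError(ValueError):
    pass


@dataclass(frozen=True)
class TumorCNACatalog:
    tumor: str
    rows: tuple[tuple[str, str], ...]  # (region label, normalized status)

    def __post_init__(self):
        labels = [label for label, _ in self.rows]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise CatalogParseError(f"duplicate region labels: {dupes}")
        for label, status in self.rows:
            if status not in ("gain", "loss", "both", "none"):
                raise CatalogParseError(
                    f"row {label!r}: bad status {status!r}")


def _normalize_status(raw: str, label: str) -> str:
    cleaned = str(raw).replace("*", "").strip().lower()
    if cleaned not in _STATUS_ALIASES:
        raise CatalogParseError(
            f"row {label!r}: unknown status string {raw!r}")
    return _STATUS_ALIASES[cleaned]


def load_tumor_catalog(source, tumor: str = "tumor") -> TumorCNACatalog:
    """Read a CSV with columns ``region,status``; status strings are
    case-insensitive and bold markers (``*``) are stripped; row order is
    preserved."""
    df = pd.read_csv(source, dtype=str)
    if df.empty and "region" not in df.columns:
        return TumorCNACatalog(tumor, ())
    if not {"region", "status"} <= set(df.columns):
        raise CatalogParseError("catalog CSV needs columns region,status")
    rows = tuple(
        (str(r.region), _normalize_status(r.status, str(r.region)))
        for r in df.itertuples()
    )
    return TumorCNACatalog(tumor, rows)


def write_tumor_catalog(catalog: TumorCNACatalog, sink) -> None:
    pd.DataFrame(catalog.rows, columns=["region", "status"]).to_csv(
        sink, index=False)


def classify_region(query_delta: int, status: str) -> str:
    """Classification of one region: concordant | discordant | absent."""
    if query_delta == 0:
        raise ValueError("query delta must be nonzero")
    if status == "none":
        return "absent"
    if status == "both":
        return "concordant"
    query_dir = "gain" if query_delta > 0 else "loss"
    return "concordant" if status == query_dir else "discordant"


@dataclass(frozen=True)
class ConcordanceReport:
    tumor: str
    rows: tuple[tuple[str, int, str, str], ...]  # label, delta, status, class
    concordant: int
    discordant: int
    absent: int

    @property
    def total(self) -> int:
        return len(self.rows)

    @property
    def fraction(self) -> float:
        return self.concordant / self.total if self.rows else 0.0

    def to_dict(self) -> dict:
        return {
            "tumor": self.tumor,
            "concordant": self.concordant,
            "discordant": self.discordant,
            "absent": self.absent,
            "total": self.total,
            "fraction": self.fraction,
        }


def concordance_report(query: Sequence[tuple[str, int]],
                       catalog: TumorCNACatalog) -> ConcordanceReport:
    """Score a (label, delta) query list against a catalog.

    Query regions must align 1:1 with catalog rows by label; any
    mismatch raises with the unmatched labels listed.
    """
    query_map = {label: delta for label, delta in query}
    if len(query_map) != len(query):
        raise ValueError("duplicate labels in query")
    catalog_labels = {label for label, _ in catalog.rows}
    missing = sorted(catalog_labels - set(query_map))
    extra = sorted(set(query_map) - catalog_labels)
    if missing or extra:
        raise ValueError(
            f"label mismatch; catalog-only: {missing}; query-only: {extra}")

    rows = []
    counts = {"concordant": 0, "discordant": 0, "absent": 0}
    for label, status in catalog.rows:
        delta = query_map[label]
        cls = classify_region(delta, status)
        counts[cls] += 1
        rows.append((label, delta, status, cls))
    return ConcordanceReport(
        tumor=catalog.tumor,
        rows=tuple(rows),
        concordant=counts["concordant"],
        discordant=counts["discordant"],
        absent=counts["absent"],
    )
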