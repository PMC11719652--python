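"""STR-profile parsing and allele-sharing match scores for cell-line
authentication.

Profiles are per-marker *sets* of allele sizes (a homozygous marker
contributes one entry).  The match statistic is the Tanabe score

    2 x (shared alleles) / (alleles in a + alleles in b)

summed over the markers present in both profiles; markers missing from
either profile are excluded from numerator and denominator.  The
conventional authentication cutoff of 0.8 is a community default, not a
property of any particular panel, and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "STRProfile",
    "MatchResult",
    "STRParseError",
    "read_str_profiles",
    "write_str_profiles",
    "tanabe_score",
    "best_match_report",
]


class STRParseError(ValueError):
    pass


@dataclass(frozen=True)
class STRProfile:
    name: str
    markers: Mapping[str, frozenset[int]]

    def __post_init__(self):
        for marker, alleles in self.markers.items():
            if not alleles:
                raise STRParseError(
                    f"{self.name}: marker {marker!r} has no alleles")

    @property
    def allele_count(self) -> int:
        return sum(len(a) for a in self.markers.values())


def _parse_cell(cell, marker: str, line: str) -> frozenset[int] | None:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    text = str(cell).strip()
    if not text:
        return None
    alleles = set()
    for part in text.replace(",", " ").split():
        try:
            alleles.add(int(part))
        except ValueError:
            raise STRParseError(
                f"non-numeric allele {part!r} at marker {marker!r}, "
                f"line {line!r}") from None
    return frozenset(alleles)


def read_str_profiles(source) -> list[STRProfile]:
    """Read a CSV whose first column is the marker name and every further
    column one cell line; cells hold comma/space-separated allele sizes in
    bp.  Blank cells omit the marker for that line."""
    df = pd.read_csv(source, dtype=str)
    if df.shape[1] < 2:
        raise STRParseError("profile CSV needs a marker column plus lines")
    marker_col = df.columns[0]
    profiles = []
    for line in df.columns[1:]:
        markers = {}
        for _, row in df.iterrows():
            marker = str(row[marker_col])
            alleles = _parse_cell(row[line], marker, line)
            if alleles is not None:
                markers[marker] = alleles
        profiles.append(STRProfile(name=str(line), markers=markers))
    return profiles


def write_str_profiles(profiles: Sequence[STRProfile], sink) -> None:
    markers: list[str] = []
    for p in profiles:
        for m in p.markers:
            if m not in markers:
                markers.append(m)
    data = {"marker": markers}
    for p in profiles:
        data[p.name] = [
            ", ".join(str(a) for a in sorted(p.markers[m]))
            if m in p.markers else ""
            for m in markers
        ]
    pd.DataFrame(data).to_csv(sink, index=False)


def tanabe_score(a: STRProfile, b: STRProfile) -> float:
    """Symmetric allele-sharing fraction in [0, 1]; 1.0 on self-match."""
    shared_markers = set(a.markers) & set(b.markers)
    if not shared_markers:
        raise ValueError(
            f"profiles {a.name!r} and {b.name!r} share no markers; "
            "score undefined")
    shared = sum(len(a.markers[m] & b.markers[m]) for m in shared_markers)
    total = sum(len(a.markers[m]) + len(b.markers[m]) for m in shared_markers)
    return 2 * shared / total


@dataclass(frozen=True)
class MatchResult:
    name: str
    score: float
    flagged: bool


def best_match_report(query: STRProfile, database: Sequence[STRProfile],
                      threshold: float = 0.8) -> list[MatchResult]:
    """Rank database lines by Tanabe score against the query; entries at
    or above ``threshold`` are flagged as authentication matches."""
    if not database:
        raise ValueError("empty profile database")
    scores = [(p.name, tanabe_score(query, p)) for p in database]
    results = [MatchResult(name, s, s >= threshold) for name, s in scores]
    return sorted(results, key=lambda r: r.score, reverse=True)
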