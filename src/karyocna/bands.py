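"""Cytoband coordinate maps and karyotype-to-copy-number derivation.

This is the "virtual CGH" core: a parsed karyotype model is turned into
a per-chromosome piecewise-constant copy-number profile by explicit
bookkeeping over numerical events and derivative-chromosome segments,
and the profile is reduced to a table of copy-number-altered regions.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open.  Human-readable reports
print 1-based inclusive spans (``1-27543415``); BED output stays 0-based
half-open.

Breakpoint semantics
--------------------
A *certain* breakpoint band denotes a break at its centromere-side
boundary (p-arm band -> band end, q-arm band -> band start).  This makes
the two segments of a reciprocal translocation that share one breakpoint
partition the chromosome exactly, which is what banding analysis
reports.  An *uncertain* band (``?``) denotes the full extent of its
policy-resolved band range; ``pter``/``qter``/``cen`` are points.  The
written orientation of a segment is recorded in provenance but does not
affect copy counting (banding cannot resolve orientation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .iscn import (
    BandLocus,
    ExpansionRule,
    KaryotypeModel,
    SegmentSpec,
    UncertaintyPolicy,
    expand_model,
    format_derivative,
    format_segment,
    resolve_uncertain_band,
)

__all__ = [
    "CytobandMap",
    "GenomicInterval",
    "CopyNumberProfile",
    "CNARegion",
    "CytobandValidationError",
    "BandLookupError",
    "InconsistentKaryotypeError",
    "load_cytoband_table",
    "write_cytoband_table",
    "locus_to_coordinate",
    "segment_to_interval",
    "derive_copy_number_profile",
    "profile_to_cna_regions",
    "write_cna_table",
    "write_bed",
    "read_bed",
]


class CytobandValidationError(ValueError):
    pass


class BandLookupError(KeyError):
    pass


class InconsistentKaryotypeError(ValueError):
    """A karyotype implies a negative copy count somewhere."""


@dataclass(frozen=True)
class GenomicInterval:
    chromosome: str
    start: int
    end: int
    build: str = field(default="", compare=False)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad interval {self.chromosome}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def span_1based(self) -> str:
        """Report-style 1-based inclusive span, e.g. ``1-27543415``."""
        return f"{self.start + 1}-{self.end}"


@dataclass(frozen=True)
class CytobandMap:
    """Ordered band -> coordinate registry, one list per chromosome.

    Bands of a chromosome are contiguous, non-overlapping and sorted;
    the first starts at 0 and the last ends at the chromosome length.
    """

    bands: dict[str, tuple[tuple[str, int, int], ...]]
    build: str = "unknown"

    def __post_init__(self):
        for chrom, blist in self.bands.items():
            if not blist:
                raise CytobandValidationError(f"{chrom}: no bands")
            prev_name, prev_end = None, 0
            for name, start, end in blist:
                if start != prev_end:
                    kind = "gap" if start > prev_end else "overlap"
                    raise CytobandValidationError(
                        f"{chrom}: {kind} between band {prev_name!r} and "
                        f"{name!r} ({prev_end} vs {start})")
                if end <= start:
                    raise CytobandValidationError(
                        f"{chrom}: band {name!r} has non-positive length")
                prev_name, prev_end = name, end

    @property
    def chromosomes(self) -> list[str]:
        return list(self.bands)

    def chrom_length(self, chrom: str) -> int:
        return self.bands[chrom][-1][2]

    def band_span(self, chrom: str, name: str) -> Optional[tuple[int, int]]:
        for bname, start, end in self.bands.get(chrom, ()):
            if bname == name:
                return (start, end)
        return None

    def has_p_arm(self, chrom: str) -> bool:
        return any(b[0].startswith("p") for b in self.bands[chrom])

    def centromere(self, chrom: str) -> int:
        """End of the last p band (0 for chromosomes without a p arm)."""
        pos = 0
        for name, start, end in self.bands[chrom]:
            if name.startswith("p"):
                pos = end
        return pos

    def band_at(self, chrom: str, position: int) -> str:
        for name, start, end in self.bands[chrom]:
            if start <= position < end:
                return name
        raise BandLookupError(f"{chrom}:{position} beyond chromosome length")


def load_cytoband_table(source, dialect: str = "ucsc_cytoband",
                        build: str = "unknown") -> CytobandMap:
    """Read a UCSC cytoBand-style TSV (chrom, chromStart, chromEnd, name,
    gieStain; no header, optional ``chr`` prefixes, gieStain optional)."""
    if dialect != "ucsc_cytoband":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(source, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "gieStain"],
                     dtype={"chrom": str, "name": str})
    bands: dict[str, list[tuple[str, int, int]]] = {}
    for _, row in df.iterrows():
        chrom = str(row["chrom"]).removeprefix("chr")
        bands.setdefault(chrom, []).append(
            (str(row["name"]), int(row["start"]), int(row["end"])))
    ordered = {
        chrom: tuple(sorted(blist, key=lambda b: b[1]))
        for chrom, blist in bands.items()
    }
    return CytobandMap(bands=ordered, build=build)


def write_cytoband_table(cmap: CytobandMap, sink) -> None:
    rows = [
        (f"chr{chrom}", start, end, name, "gneg")
        for chrom, blist in cmap.bands.items()
        for name, start, end in blist
    ]
    pd.DataFrame(rows).to_csv(sink, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# locus / segment -> coordinates
# ---------------------------------------------------------------------------

def locus_to_coordinate(cmap: CytobandMap, locus: BandLocus,
                        side: str = "proximal") -> int:
    """Map a resolved (certain) locus to a position.

    pter -> 0, qter -> chromosome length, cen -> p/q boundary; a named
    band maps to its start (``side="proximal"``) or end (``"distal"``).
    Centromeric bands like p11/q11 resolve like any named band.
    """
    if side not in ("proximal", "distal"):
        raise ValueError(f"bad side {side!r}")
    chrom = locus.chromosome
    if chrom not in cmap.bands:
        raise BandLookupError(f"chromosome {chrom!r} not in map")
    if locus.terminal == "pter":
        return 0
    if locus.terminal == "qter":
        return cmap.chrom_length(chrom)
    if locus.terminal == "cen":
        return cmap.centromere(chrom)
    if locus.uncertain:
        raise ValueError(f"uncertain locus {locus.band_name!r} must be "
                         "resolved through a policy first")
    span = cmap.band_span(chrom, locus.band_name)
    if span is None:
        names = [b[0] for b in cmap.bands[chrom]]
        raise BandLookupError(
            f"band {locus.band_name!r} not on chromosome {chrom}; "
            f"known bands: {', '.join(names)}")
    return span[0] if side == "proximal" else span[1]


def _locus_extent(cmap: CytobandMap, locus: BandLocus,
                  policy: UncertaintyPolicy) -> tuple[int, int]:
    """Coordinate extent a locus contributes to its segment.

    Certain band -> a point at its centromere-side boundary; uncertain
    band -> the full span of its resolved band range; terminals -> points.
    """
    chrom = locus.chromosome
    if locus.terminal != "none":
        pos = locus_to_coordinate(cmap, locus)
        return (pos, pos)
    if locus.uncertain:
        first, last = resolve_uncertain_band(locus, policy, cmap)
        s1 = cmap.band_span(chrom, first)
        s2 = cmap.band_span(chrom, last)
        if s1 is None or s2 is None:
            raise BandLookupError(
                f"resolved range ({first},{last}) absent on {chrom}")
        return (s1[0], s2[1])
    span = cmap.band_span(chrom, locus.band_name)
    if span is None:
        raise BandLookupError(
            f"band {locus.band_name!r} not on chromosome {chrom}")
    point = span[1] if locus.arm == "p" else span[0]
    return (point, point)


def segment_to_interval(cmap: CytobandMap, seg: SegmentSpec,
                        policy: UncertaintyPolicy | None = None
                        ) -> GenomicInterval:
    """Genomic interval covered by a derivative segment.

    Spans from the outermost proximal to the outermost distal coordinate
    contributed by the two (possibly uncertainty-resolved) loci.  The
    written orientation does not affect the interval.
    """
    policy = policy or UncertaintyPolicy()
    a = _locus_extent(cmap, seg.start, policy)
    b = _locus_extent(cmap, seg.end, policy)
    start, end = min(a[0], b[0]), max(a[1], b[1])
    if start >= end:
        raise ValueError(
            f"segment {format_segment(seg)} is zero-length at the resolved "
            f"coordinates ({start})")
    return GenomicInterval(seg.chromosome, start, end, build=cmap.build)


# ---------------------------------------------------------------------------
# copy-number profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventAtom:
    """One signed whole-chromosome or segment contribution."""

    chromosome: str
    start: int
    end: int
    delta: int
    token: str


@dataclass(frozen=True)
class CopyNumberProfile:
    """Breakpoint-partitioned copy counts per chromosome plus baseline."""

    baseline: dict[str, int]
    segments: dict[str, tuple[tuple[int, int, int], ...]]  # (start, end, count)
    atoms: tuple[EventAtom, ...]
    build: str = "unknown"

    def count_at(self, chrom: str, position: int) -> int:
        for start, end, count in self.segments[chrom]:
            if start <= position < end:
                return count
        raise KeyError(f"{chrom}:{position} outside profile")

    def total_mass(self) -> int:
        return sum(
            (end - start) * count
            for segs in self.segments.values()
            for start, end, count in segs
        )

    def baseline_mass(self) -> int:
        return sum(
            self.baseline[chrom] * segs[-1][1]
            for chrom, segs in self.segments.items()
        )

    def event_mass(self) -> int:
        return sum(a.delta * (a.end - a.start) for a in self.atoms)


@dataclass(frozen=True)
class CNARegion:
    interval: GenomicInterval
    delta: int
    label: str
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        if self.delta == 0:
            raise ValueError("CNA region delta must be nonzero")


def _baselines(model: KaryotypeModel, cmap: CytobandMap) -> dict[str, int]:
    out = {}
    for chrom in cmap.chromosomes:
        if chrom in ("X", "Y"):
            out[chrom] = model.sex.count(chrom)
        else:
            out[chrom] = model.ploidy_base
    return out


def derive_copy_number_profile(model: KaryotypeModel, cmap: CytobandMap,
                               rule: ExpansionRule | None = None,
                               policy: UncertaintyPolicy | None = None
                               ) -> CopyNumberProfile:
    """Copy-number bookkeeping over all events of a karyotype model.

    Baseline is ``ploidy_base`` per autosome and one copy per sex
    chromosome occurrence in the sex token.  Numerical events adjust
    whole chromosomes by +-1; a replacement derivative removes one whole
    copy of its named chromosome and adds back each expanded segment; a
    supernumerary derivative adds its segments only.  Raises
    :class:`InconsistentKaryotypeError` on a negative count.
    """
    policy = policy or UncertaintyPolicy()
    model = expand_model(model, rule)
    baseline = _baselines(model, cmap)

    atoms: list[EventAtom] = []
    for ev in model.numericals:
        if ev.chromosome not in cmap.bands:
            raise BandLookupError(
                f"numerical event on unknown chromosome {ev.chromosome!r}")
        if baseline[ev.chromosome] == 0:
            raise InconsistentKaryotypeError(
                f"event {'+' if ev.delta > 0 else '-'}{ev.chromosome} touches "
                f"a chromosome absent from the baseline")
        length = cmap.chrom_length(ev.chromosome)
        sign = "+" if ev.delta > 0 else "-"
        atoms.append(EventAtom(ev.chromosome, 0, length, ev.delta,
                               f"{sign}{ev.chromosome}"))

    der_counts: dict[str, int] = {}
    for d in model.derivatives:
        token = format_derivative(d)
        der_counts[token] = der_counts.get(token, 0) + 1
        if der_counts[token] > 1:
            token = f"{token}#{der_counts[token]}"
        if d.prefix == "replacement":
            if d.named_chromosome not in cmap.bands:
                raise BandLookupError(
                    f"derivative names unknown chromosome "
                    f"{d.named_chromosome!r}")
            if baseline[d.named_chromosome] == 0:
                raise InconsistentKaryotypeError(
                    f"{token} replaces a homolog of chromosome "
                    f"{d.named_chromosome}, absent from the baseline")
            atoms.append(EventAtom(
                d.named_chromosome, 0, cmap.chrom_length(d.named_chromosome),
                -1, f"{token} (replaces one chr{d.named_chromosome})"))
        for j, seg in enumerate(d.segments, start=1):
            iv = segment_to_interval(cmap, seg, policy)
            atoms.append(EventAtom(
                iv.chromosome, iv.start, iv.end, +1,
                f"{token} segment {j}: {format_segment(seg)}"))

    segments: dict[str, tuple[tuple[int, int, int], ...]] = {}
    for chrom in cmap.chromosomes:
        length = cmap.chrom_length(chrom)
        cuts = {0, length}
        chrom_atoms = [a for a in atoms if a.chromosome == chrom]
        for a in chrom_atoms:
            cuts.update((a.start, a.end))
        edges = sorted(cuts)
        pieces = []
        for lo, hi in zip(edges, edges[1:]):
            count = baseline[chrom] + sum(
                a.delta for a in chrom_atoms if a.start <= lo and hi <= a.end)
            if count < 0:
                raise InconsistentKaryotypeError(
                    f"inconsistent karyotype: negative copy count on "
                    f"{chrom}:{lo + 1}-{hi}")
            pieces.append((lo, hi, count))
        segments[chrom] = tuple(pieces)

    profile = CopyNumberProfile(baseline=baseline, segments=segments,
                                atoms=tuple(atoms), build=cmap.build)
    # conservation of copy mass is structural; guard against regressions
    assert profile.total_mass() - profile.baseline_mass() == profile.event_mass()
    return profile


# ---------------------------------------------------------------------------
# CNA regions
# ---------------------------------------------------------------------------

def _span_label(cmap: CytobandMap, chrom: str, start: int, end: int) -> str:
    length = cmap.chrom_length(chrom)
    if start == 0:
        first = "pter" if cmap.has_p_arm(chrom) else cmap.band_at(chrom, 0)
    else:
        first = cmap.band_at(chrom, start)
    last = "qter" if end == length else cmap.band_at(chrom, end - 1)
    return f"{chrom}{first}->{chrom}{last}"


def profile_to_cna_regions(profile: CopyNumberProfile, cmap: CytobandMap,
                           stub_tolerance: int = 10_000_000
                           ) -> list[CNARegion]:
    """Reduce a profile to merged, labeled CNA regions.

    Adjacent equal-delta runs merge; a *terminal* run shorter than
    ``stub_tolerance`` whose neighbor has a different delta is absorbed
    into that neighbor (the neighbor's delta wins) so that, e.g., a tiny
    acrocentric p stub left at zero copies does not split an otherwise
    whole-chromosome loss.  ``stub_tolerance=0`` keeps exact bookkeeping.
    """
    regions: list[CNARegion] = []
    for chrom, pieces in profile.segments.items():
        runs: list[list[int]] = []  # [start, end, delta]
        for start, end, count in pieces:
            delta = count - profile.baseline[chrom]
            if runs and runs[-1][2] == delta and runs[-1][1] == start:
                runs[-1][1] = end
            else:
                runs.append([start, end, delta])
        if stub_tolerance > 0:
            if len(runs) > 1 and runs[0][1] - runs[0][0] < stub_tolerance:
                runs[1][0] = runs[0][0]
                runs.pop(0)
            if len(runs) > 1 and runs[-1][1] - runs[-1][0] < stub_tolerance:
                runs[-2][1] = runs[-1][1]
                runs.pop()
            merged: list[list[int]] = []
            for run in runs:
                if merged and merged[-1][2] == run[2]:
                    merged[-1][1] = run[1]
                else:
                    merged.append(run)
            runs = merged
        for start, end, delta in runs:
            if delta == 0:
                continue
            provenance = tuple(
                a.token for a in profile.atoms
                if a.chromosome == chrom and a.start < end and a.end > start
            )
            regions.append(CNARegion(
                interval=GenomicInterval(chrom, start, end,
                                         build=profile.build),
                delta=delta,
                label=_span_label(cmap, chrom, start, end),
                provenance=provenance,
            ))
    return regions


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CNA_COLUMNS = ["chromosome", "span", "delta", "molecular_span",
                "start_1based", "end", "provenance"]


def write_cna_table(regions: Sequence[CNARegion], sink) -> None:
    """TSV report; coordinates printed 1-based inclusive (Table style)."""
    rows = [
        {
            "chromosome": r.interval.chromosome,
            "span": r.label,
            "delta": f"{r.delta:+d}",
            "molecular_span": r.interval.span_1based,
            "start_1based": r.interval.start + 1,
            "end": r.interval.end,
            "provenance": "|".join(r.provenance),
        }
        for r in regions
    ]
    pd.DataFrame(rows, columns=_CNA_COLUMNS).to_csv(sink, sep="\t", index=False)


def write_bed(regions: Sequence[CNARegion], sink) -> None:
    """BED4, 0-based half-open; the name field carries the signed delta."""
    rows = [
        (r.interval.chromosome, r.interval.start, r.interval.end,
         f"{r.delta:+d}")
        for r in regions
    ]
    pd.DataFrame(rows).to_csv(sink, sep="\t", header=False, index=False)


def read_bed(source) -> list[tuple[GenomicInterval, int]]:
    df = pd.read_csv(source, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"],
                     dtype={"chrom": str})
    return [
        (GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"])),
         int(row["name"]))
        for _, row in df.iterrows()
    ]
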