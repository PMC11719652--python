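"""Cross-build / cross-species interval translation over synteny blocks.

A :class:`HomologyMap` is an ordered list of source->target blocks with
strand; queries are intersected with blocks and mapped by affine
(proportional) interpolation within each block, reversed on ``-`` strand
blocks.  This is deliberately band-resolution arithmetic, not base-level
alignment: karyotype-derived CNA regions carry no base-exact breakpoints,
so nothing finer is meaningful.

Two input dialects are supported: a 7-column block TSV and a minimal
subset of the UCSC chain format (each ungapped run of a chain becomes
one block).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .bands import CNARegion, CytobandMap, GenomicInterval

__all__ = [
    "SyntenyBlock",
    "HomologyMap",
    "TranslatedRegion",
    "HomologyValidationError",
    "load_homology_map",
    "write_homology_map",
    "lift_interval",
    "intervals_to_band_span",
    "translate_cna_profile",
]


class HomologyValidationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntenyBlock:
    source: GenomicInterval
    target: GenomicInterval
    strand: str  # '+' or '-'

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class HomologyMap:
    blocks: tuple[SyntenyBlock, ...]
    source_build: str = "unknown"
    target_build: str = "unknown"

    def __post_init__(self):
        ordered = sorted(
            self.blocks,
            key=lambda b: (b.source.chromosome, b.source.start))
        object.__setattr__(self, "blocks", tuple(ordered))
        prev = None
        for b in self.blocks:
            if (prev is not None
                    and prev.source.chromosome == b.source.chromosome
                    and b.source.start < prev.source.end):
                raise HomologyValidationError(
                    f"source blocks overlap on {b.source.chromosome}: "
                    f"{prev.source.span_1based} vs {b.source.span_1based}")
            prev = b

    def inverse(self) -> "HomologyMap":
        """Swap source and target (valid when targets do not overlap)."""
        return HomologyMap(
            blocks=tuple(SyntenyBlock(b.target, b.source, b.strand)
                         for b in self.blocks),
            source_build=self.target_build,
            target_build=self.source_build,
        )


_BLOCK_COLUMNS = ["srcChrom", "srcStart", "srcEnd",
                  "tgtChrom", "tgtStart", "tgtEnd", "strand"]


def load_homology_map(source, dialect: str = "block_tsv",
                      source_build: str = "unknown",
                      target_build: str = "unknown") -> HomologyMap:
    if dialect == "block_tsv":
        df = pd.read_csv(source, sep="\t",
                         dtype={"srcChrom": str, "tgtChrom": str})
        missing = set(_BLOCK_COLUMNS) - set(df.columns)
        if missing:
            raise HomologyValidationError(f"block TSV lacks columns {missing}")
        blocks = tuple(
            SyntenyBlock(
                GenomicInterval(str(r.srcChrom).removeprefix("chr"),
                                int(r.srcStart), int(r.srcEnd)),
                GenomicInterval(str(r.tgtChrom).removeprefix("chr"),
                                int(r.tgtStart), int(r.tgtEnd)),
                str(r.strand),
            )
            for r in df.itertuples()
        )
        return HomologyMap(blocks, source_build, target_build)
    if dialect == "ucsc_chain":
        return _load_chain(source, source_build, target_build)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_homology_map(hmap: HomologyMap, sink) -> None:
    rows = [
        (b.source.chromosome, b.source.start, b.source.end,
         b.target.chromosome, b.target.start, b.target.end, b.strand)
        for b in hmap.blocks
    ]
    pd.DataFrame(rows, columns=_BLOCK_COLUMNS).to_csv(sink, sep="\t",
                                                      index=False)


def _load_chain(source, source_build, target_build) -> HomologyMap:
    """Minimal UCSC chain reader: ``t`` coordinates are the source, ``q``
    the target; each ungapped run becomes one block; ``-``-strand query
    coordinates are flipped to forward-strand positions."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as handle:
            lines = handle.read().splitlines()
    blocks: list[SyntenyBlock] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0] != "chain":
            raise HomologyValidationError(f"expected chain header: {line!r}")
        (_, _score, t_name, _t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end) = fields[:12]
        if t_strand != "+":
            raise HomologyValidationError("chain target strand must be '+'")
        t_pos = int(t_start)
        q_pos = int(q_start)
        q_size = int(q_size)
        while i < len(lines) and lines[i].strip():
            parts = lines[i].split()
            i += 1
            size = int(parts[0])
            src = GenomicInterval(t_name.removeprefix("chr"),
                                  t_pos, t_pos + size)
            if q_strand == "+":
                tgt = GenomicInterval(q_name.removeprefix("chr"),
                                      q_pos, q_pos + size)
                strand = "+"
            else:
                tgt = GenomicInterval(q_name.removeprefix("chr"),
                                      q_size - (q_pos + size),
                                      q_size - q_pos)
                strand = "-"
            blocks.append(SyntenyBlock(src, tgt, strand))
            if len(parts) == 3:
                t_pos += size + int(parts[1])
                q_pos += size + int(parts[2])
            else:
                t_pos += size
                q_pos += size
                break
    return HomologyMap(tuple(blocks), source_build, target_build)


# ---------------------------------------------------------------------------
# lifting
# ---------------------------------------------------------------------------

def _merge_fragments(fragments: list[GenomicInterval],
                     gap_join: int) -> list[GenomicInterval]:
    fragments = sorted(fragments, key=lambda f: (f.chromosome, f.start))
    merged: list[GenomicInterval] = []
    for frag in fragments:
        if (merged and merged[-1].chromosome == frag.chromosome
                and frag.start - merged[-1].end <= gap_join
                and frag.start >= merged[-1].start):
            if frag.end > merged[-1].end:
                merged[-1] = GenomicInterval(
                    frag.chromosome, merged[-1].start, frag.end,
                    build=frag.build)
        else:
            merged.append(frag)
    return merged


def lift_interval(hmap: HomologyMap, query: GenomicInterval,
                  min_fragment: int = 1_000_000,
                  gap_join: int = 1_000_000) -> list[GenomicInterval]:
    """Translate a source interval to target coordinates.

    The query is intersected with every block; within a block positions
    map affinely (proportional interpolation), reversed for ``-`` strand.
    Fragments shorter than ``min_fragment`` are dropped; fragments on the
    same target chromosome closer than ``gap_join`` merge.  A query with
    no block overlap yields an empty list.
    """
    fragments: list[GenomicInterval] = []
    for b in hmap.blocks:
        if b.source.chromosome != query.chromosome:
            continue
        lo = max(query.start, b.source.start)
        hi = min(query.end, b.source.end)
        if lo >= hi:
            continue
        s_len = b.source.end - b.source.start
        t_len = b.target.end - b.target.start
        scale = t_len / s_len
        o1, o2 = lo - b.source.start, hi - b.source.start
        if b.strand == "+":
            t_lo = b.target.start + round(o1 * scale)
            t_hi = b.target.start + round(o2 * scale)
        else:
            t_lo = b.target.start + round((s_len - o2) * scale)
            t_hi = b.target.start + round((s_len - o1) * scale)
        if t_hi > t_lo:
            fragments.append(GenomicInterval(
                b.target.chromosome, t_lo, t_hi,
                build=hmap.target_build))
    fragments = [f for f in fragments if len(f) >= max(min_fragment, 1)]
    return _merge_fragments(fragments, gap_join)


def intervals_to_band_span(target_map: CytobandMap,
                           intervals: Sequence[GenomicInterval]) -> list[str]:
    """Label intervals with target band spans, ``5p15.31p14.1`` style.

    Adjacent (touching) same-chromosome intervals are merged first.  A
    label is ``<chrom><first band><last band>``, collapsed to a single
    band name when the interval stays inside one band; chromosome ends
    print as ``pter``/``qter``.
    """
    merged = _merge_fragments(list(intervals), gap_join=0)
    labels = []
    for iv in merged:
        length = target_map.chrom_length(iv.chromosome)
        if iv.end > length:
            raise ValueError(
                f"interval {iv.chromosome}:{iv.span_1based} beyond "
                f"chromosome length {length}")
        if iv.start == 0 and target_map.has_p_arm(iv.chromosome):
            first = "pter"
        else:
            first = target_map.band_at(iv.chromosome, iv.start)
        last = "qter" if iv.end == length else target_map.band_at(
            iv.chromosome, iv.end - 1)
        if first == last:
            labels.append(f"{iv.chromosome}{first}")
        else:
            labels.append(f"{iv.chromosome}{first}{last}")
    return labels


@dataclass(frozen=True)
class TranslatedRegion:
    interval: GenomicInterval
    delta: int
    label: str

    def __post_init__(self):
        if self.delta == 0:
            raise ValueError("translated region delta must be nonzero")


def translate_cna_profile(regions: Sequence[CNARegion], hmap: HomologyMap,
                          target_bands: CytobandMap,
                          min_fragment: int = 1_000_000,
                          gap_join: int = 1_000_000
                          ) -> list[TranslatedRegion]:
    """Lift every CNA region and label the target fragments; the signed
    delta is inherited from the source region."""
    out: list[TranslatedRegion] = []
    for region in regions:
        fragments = lift_interval(hmap, region.interval,
                                  min_fragment=min_fragment,
                                  gap_join=gap_join)
        labels = intervals_to_band_span(target_bands, fragments)
        merged = _merge_fragments(fragments, gap_join=0)
        for iv, label in zip(merged, labels):
            out.append(TranslatedRegion(iv, region.delta, label))
    return out


def write_translated_table(regions: Sequence[TranslatedRegion], sink) -> None:
    rows = [
        {
            "chromosome": r.interval.chromosome,
            "label": r.label,
            "delta": f"{r.delta:+d}",
            "molecular_span": r.interval.span_1based,
        }
        for r in regions
    ]
    pd.DataFrame(rows, columns=["chromosome", "label", "delta",
                                "molecular_span"]).to_csv(
        sink, sep="\t", index=False)
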