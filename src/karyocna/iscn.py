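"""Parsing and serialization of a compact ISCN karyotype dialect.

The dialect covers the constructs that occur in composite tumor-line
karyotypes of the form::

    37~43<2n>,XY,der(2)t(2;19)(q34;p11),-3,+7,
    +der(12)(12pter->12q1?2::2q?2->2q?2::10q?3->10qter)[cp30]

i.e. a chromosome-count range with ploidy annotation, a sex token,
whole-chromosome gains/losses, derivative chromosomes given either as a
``t(A;B)`` translocation shorthand or as an explicit ``::``-delimited
segment composition, and a composite-cell suffix ``[cpN]``.  Everything
else in ISCN (inversions, insertions, rings, markers, stemlines, ...)
raises :class:`UnsupportedConstructError`.

Coordinates never appear at this level: loci are symbolic cytobands
(possibly with the ``?`` uncertainty glyph) that are resolved against a
cytoband map by :mod:`karyocna.bands`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import yaml

__all__ = [
    "BandLocus",
    "SegmentSpec",
    "Translocation",
    "Derivative",
    "NumericalEvent",
    "KaryotypeModel",
    "UncertaintyPolicy",
    "ExpansionRule",
    "ISCNSyntaxError",
    "UnsupportedConstructError",
    "UnresolvedBandError",
    "parse_karyotype",
    "format_karyotype",
    "parse_segment",
    "format_locus",
    "format_segment",
    "format_derivative",
    "expand_shorthand_derivative",
    "expand_model",
    "resolve_uncertain_band",
    "token_equivalent",
]


class ISCNSyntaxError(ValueError):
    """Malformed karyotype text; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UnsupportedConstructError(ValueError):
    """A valid ISCN construct outside the supported dialect."""


class UnresolvedBandError(KeyError):
    """An uncertain band could not be resolved against the map/policy."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_CHROM_RE = r"(?:\d+|X|Y)"


@dataclass(frozen=True)
class BandLocus:
    """A symbolic cytogenetic locus such as ``2q34``, ``12q1?2`` or ``19pter``.

    ``band`` keeps the raw digit/dot string including any ``?`` glyphs;
    ``uncertain`` is true iff a ``?`` is present.  Terminal loci (pter,
    qter, cen) have an empty band.
    """

    chromosome: str
    arm: Optional[str]  # 'p' or 'q'; None only for 'cen'
    band: str = ""
    terminal: str = "none"  # none | pter | qter | cen

    def __post_init__(self):
        if not self.chromosome:
            raise ValueError("chromosome label must be non-empty")
        if self.terminal not in ("none", "pter", "qter", "cen"):
            raise ValueError(f"bad terminal {self.terminal!r}")
        if self.terminal != "none" and self.band:
            raise ValueError("terminal locus cannot carry a band")
        if self.terminal == "none" and not self.band:
            raise ValueError("non-terminal locus requires a band")
        if self.terminal == "none" and self.arm not in ("p", "q"):
            raise ValueError(f"bad arm {self.arm!r}")

    @property
    def uncertain(self) -> bool:
        return "?" in self.band

    @property
    def band_name(self) -> str:
        """Band name as it appears in a cytoband table, e.g. ``q34``."""
        return f"{self.arm}{self.band}" if self.terminal == "none" else self.terminal


@dataclass(frozen=True)
class SegmentSpec:
    """A directed chromosome segment ``start->end`` on one chromosome."""

    chromosome: str
    start: BandLocus
    end: BandLocus

    def __post_init__(self):
        for locus in (self.start, self.end):
            if locus.chromosome != self.chromosome:
                raise ValueError(
                    f"segment on {self.chromosome} references locus on "
                    f"{locus.chromosome}"
                )


@dataclass(frozen=True)
class Translocation:
    """Shorthand ``t(A;B)(brkA;brkB)`` record attached to a derivative."""

    chrom_a: str
    chrom_b: str
    breakpoint_a: BandLocus
    breakpoint_b: BandLocus


@dataclass(frozen=True)
class Derivative:
    named_chromosome: str
    prefix: str  # replacement | supernumerary
    segments: tuple[SegmentSpec, ...] = ()
    shorthand: Optional[Translocation] = None

    def __post_init__(self):
        if self.prefix not in ("replacement", "supernumerary"):
            raise ValueError(f"bad prefix {self.prefix!r}")
        if not self.segments and self.shorthand is None:
            raise ValueError("derivative needs segments or a shorthand")


@dataclass(frozen=True)
class NumericalEvent:
    chromosome: str
    delta: int

    def __post_init__(self):
        if self.delta not in (-1, 1):
            raise ValueError("numerical delta must be +1 or -1")


@dataclass(frozen=True)
class KaryotypeModel:
    count_min: int
    count_max: int
    ploidy_base: int
    sex: str
    numericals: tuple[NumericalEvent, ...] = ()
    derivatives: tuple[Derivative, ...] = ()
    composite_cells: Optional[int] = None
    raw: str = field(default="", compare=False)

    def __post_init__(self):
        if self.count_min > self.count_max:
            raise ValueError("count_min must be <= count_max")
        if self.ploidy_base < 1:
            raise ValueError("ploidy_base must be >= 1")
        if self.composite_cells is not None and self.composite_cells <= 0:
            raise ValueError("composite_cells must be positive")


@dataclass(frozen=True)
class UncertaintyPolicy:
    """How ``?`` bands resolve to concrete band ranges.

    ``resolution_map`` maps full uncertain locus strings (``"2q?2"``) to a
    (proximal band, distal band) pair of band names on that chromosome.
    Unmatched loci fall back to ``widest_band_group`` (all bands whose
    name starts with the certain digits) or to a hard error.
    """

    resolution_map: Mapping[str, tuple[str, str]] = field(default_factory=dict)
    fallback: str = "widest_band_group"

    def __post_init__(self):
        if self.fallback not in ("widest_band_group", "error"):
            raise ValueError(f"bad fallback {self.fallback!r}")

    @classmethod
    def from_yaml(cls, source) -> "UncertaintyPolicy":
        data = _load_yaml(source)
        resolutions = {
            str(key): (str(value[0]), str(value[1]))
            for key, value in (data.get("resolutions") or {}).items()
        }
        return cls(resolution_map=resolutions,
                   fallback=data.get("fallback", "widest_band_group"))


@dataclass(frozen=True)
class ExpansionRule:
    """Shorthand-derivative expansion: a default rule plus explicit
    per-derivative segment overrides keyed by the derivative token."""

    default: str = "centromere_retention"
    overrides: Mapping[str, tuple[SegmentSpec, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if self.default != "centromere_retention":
            raise ValueError(f"unknown default rule {self.default!r}")

    @classmethod
    def from_yaml(cls, source) -> "ExpansionRule":
        data = _load_yaml(source)
        overrides = {
            str(token): tuple(parse_segment(s) for s in segs)
            for token, segs in (data.get("overrides") or {}).items()
        }
        return cls(default=data.get("default", "centromere_retention"),
                   overrides=overrides)


def _load_yaml(source):
    if hasattr(source, "read"):
        return yaml.safe_load(source) or {}
    text = str(source)
    if "\n" not in text and not text.lstrip().startswith(("{", "-")):
        # looks like a path
        with open(text) as handle:
            return yaml.safe_load(handle) or {}
    return yaml.safe_load(text) or {}


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_UNSUPPORTED_HEADS = (
    "inv", "ins", "mar", "dic", "idem", "del", "dup", "i", "r", "t", "add",
    "trp", "hsr", "sl", "sdl",
)

_COUNT_RE = re.compile(rf"^(\d+)(?:~(\d+))?<(\d+)n>$")
_SEX_RE = re.compile(r"^[XY]{1,4}$")
_NUMERICAL_RE = re.compile(rf"^([+-])({_CHROM_RE})$")
_DER_RE = re.compile(rf"^(\+?)der\(({_CHROM_RE})\)(.*)$")
_SHORTHAND_RE = re.compile(
    rf"^t\(({_CHROM_RE});({_CHROM_RE})\)\(([pq][0-9.?]+);([pq][0-9.?]+)\)$"
)
_LOCUS_RE = re.compile(rf"^({_CHROM_RE})(pter|qter|cen|[pq][0-9.?]+)$")
_CP_RE = re.compile(r"\[cp(\d+)\]$")


def _split_top_level(text: str) -> list[tuple[str, int]]:
    """Split on commas outside parentheses; returns (token, position)."""
    tokens: list[tuple[str, int]] = []
    depth = 0
    start = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ISCNSyntaxError("unbalanced ')'", i)
        elif ch == "," and depth == 0:
            tokens.append((text[start:i], start))
            start = i + 1
    if depth != 0:
        raise ISCNSyntaxError("unbalanced '('", len(text) - 1)
    tokens.append((text[start:], start))
    return tokens


def _parse_band_locus(text: str, pos: int) -> BandLocus:
    m = _LOCUS_RE.match(text)
    if not m:
        raise ISCNSyntaxError(f"cannot parse locus {text!r}", pos)
    chrom, rest = m.group(1), m.group(2)
    if rest in ("pter", "qter"):
        return BandLocus(chrom, rest[0], "", terminal=rest)
    if rest == "cen":
        return BandLocus(chrom, None, "", terminal="cen")
    return BandLocus(chrom, rest[0], rest[1:])


def parse_segment(text: str, pos: int = 0) -> SegmentSpec:
    """Parse ``"2q?2->2q?2"`` into a :class:`SegmentSpec`."""
    text = re.sub(r"\s+", "", text)
    parts = text.split("->")
    if len(parts) != 2:
        raise ISCNSyntaxError(f"segment {text!r} needs exactly one '->'", pos)
    start = _parse_band_locus(parts[0], pos)
    end = _parse_band_locus(parts[1], pos + len(parts[0]) + 2)
    if start.chromosome != end.chromosome:
        raise ISCNSyntaxError(
            f"segment endpoints on different chromosomes in {text!r}", pos)
    return SegmentSpec(start.chromosome, start, end)


def _parse_derivative(token: str, pos: int) -> Derivative:
    m = _DER_RE.match(token)
    assert m is not None
    prefix = "supernumerary" if m.group(1) == "+" else "replacement"
    named = m.group(2)
    rest = m.group(3)
    if not rest:
        raise ISCNSyntaxError(f"derivative {token!r} lacks a composition", pos)
    sh = _SHORTHAND_RE.match(rest)
    if sh:
        brk_a = _parse_band_locus(sh.group(1) + sh.group(3), pos)
        brk_b = _parse_band_locus(sh.group(2) + sh.group(4), pos)
        shorthand = Translocation(sh.group(1), sh.group(2), brk_a, brk_b)
        return Derivative(named, prefix, segments=(), shorthand=shorthand)
    if rest.startswith("(") and rest.endswith(")"):
        body = rest[1:-1]
        segments = tuple(
            parse_segment(part, pos) for part in body.split("::") if part
        )
        if not segments:
            raise ISCNSyntaxError(f"empty composition in {token!r}", pos)
        return Derivative(named, prefix, segments=segments)
    if rest.startswith("t("):
        raise ISCNSyntaxError(
            f"malformed translocation shorthand in {token!r}", pos)
    raise ISCNSyntaxError(f"cannot parse derivative body {rest!r}", pos)


def _check_unsupported(token: str, pos: int) -> None:
    body = token.lstrip("+-")
    for head in _UNSUPPORTED_HEADS:
        if body == head or body.startswith(head + "("):
            raise UnsupportedConstructError(
                f"unsupported construct {head!r} in token {token!r}"
            )


_EVENT_SORT_DER = 0
_EVENT_SORT_NUM = 1


def _chrom_sort_key(label: str):
    if label.isdigit():
        return (0, int(label))
    return (1, {"X": 0, "Y": 1}.get(label, 2))


def parse_karyotype(text: str) -> KaryotypeModel:
    """Parse an ISCN karyotype string of the supported dialect.

    Events are normalized to chromosome order (derivatives before
    numerical events on the same chromosome), so ``parse`` is idempotent
    through :func:`format_karyotype`.
    """
    raw = text
    text = re.sub(r"\s+", "", text)
    if not text:
        raise ISCNSyntaxError("empty karyotype", 0)

    composite = None
    cp = _CP_RE.search(text)
    if cp:
        composite = int(cp.group(1))
        text = text[: cp.start()]

    tokens = _split_top_level(text)
    if len(tokens) < 2:
        raise ISCNSyntaxError("karyotype needs counts and a sex token", 0)

    (count_tok, count_pos), (sex_tok, sex_pos) = tokens[0], tokens[1]
    m = _COUNT_RE.match(count_tok)
    if not m:
        raise ISCNSyntaxError(f"cannot parse count token {count_tok!r}", count_pos)
    count_min = int(m.group(1))
    count_max = int(m.group(2)) if m.group(2) else count_min
    ploidy = int(m.group(3))
    if not _SEX_RE.match(sex_tok):
        raise ISCNSyntaxError(f"cannot parse sex token {sex_tok!r}", sex_pos)

    numericals: list[NumericalEvent] = []
    derivatives: list[Derivative] = []
    order: list[tuple[tuple, int, object]] = []
    for tok, pos in tokens[2:]:
        if not tok:
            raise ISCNSyntaxError("empty token", pos)
        if _DER_RE.match(tok):
            d = _parse_derivative(tok, pos)
            order.append(((_chrom_sort_key(d.named_chromosome), _EVENT_SORT_DER),
                          len(order), d))
            continue
        nm = _NUMERICAL_RE.match(tok)
        if nm:
            ev = NumericalEvent(nm.group(2), 1 if nm.group(1) == "+" else -1)
            order.append(((_chrom_sort_key(ev.chromosome), _EVENT_SORT_NUM),
                          len(order), ev))
            continue
        _check_unsupported(tok, pos)
        raise ISCNSyntaxError(f"cannot parse token {tok!r}", pos)

    for _, _, ev in sorted(order, key=lambda item: (item[0], item[1])):
        if isinstance(ev, Derivative):
            derivatives.append(ev)
        else:
            numericals.append(ev)

    return KaryotypeModel(
        count_min=count_min,
        count_max=count_max,
        ploidy_base=ploidy,
        sex=sex_tok,
        numericals=tuple(numericals),
        derivatives=tuple(derivatives),
        composite_cells=composite,
        raw=raw,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def format_locus(locus: BandLocus) -> str:
    if locus.terminal != "none":
        return f"{locus.chromosome}{locus.terminal}"
    return f"{locus.chromosome}{locus.arm}{locus.band}"


def format_segment(seg: SegmentSpec) -> str:
    return f"{format_locus(seg.start)}->{format_locus(seg.end)}"


def format_derivative(d: Derivative) -> str:
    prefix = "+" if d.prefix == "supernumerary" else ""
    if d.shorthand is not None and not d.segments:
        sh = d.shorthand
        brk_a = f"{sh.breakpoint_a.arm}{sh.breakpoint_a.band}"
        brk_b = f"{sh.breakpoint_b.arm}{sh.breakpoint_b.band}"
        body = f"t({sh.chrom_a};{sh.chrom_b})({brk_a};{brk_b})"
    else:
        body = "(" + "::".join(format_segment(s) for s in d.segments) + ")"
    return f"{prefix}der({d.named_chromosome}){body}"


def format_karyotype(model: KaryotypeModel) -> str:
    """Serialize a model back to ISCN text (inverse of :func:`parse_karyotype`
    on parser/generator output)."""
    if model.count_min == model.count_max:
        counts = str(model.count_min)
    else:
        counts = f"{model.count_min}~{model.count_max}"
    parts = [f"{counts}<{model.ploidy_base}n>", model.sex]

    events: list[tuple[tuple, int, str]] = []
    for i, d in enumerate(model.derivatives):
        events.append(((_chrom_sort_key(d.named_chromosome), _EVENT_SORT_DER),
                       i, format_derivative(d)))
    for i, ev in enumerate(model.numericals):
        sign = "+" if ev.delta > 0 else "-"
        events.append(((_chrom_sort_key(ev.chromosome), _EVENT_SORT_NUM),
                       i, f"{sign}{ev.chromosome}"))
    parts.extend(tok for _, _, tok in sorted(events, key=lambda e: (e[0], e[1])))

    text = ",".join(parts)
    if model.composite_cells is not None:
        text += f"[cp{model.composite_cells}]"
    return text


def token_equivalent(a: str, b: str) -> bool:
    """True when two karyotype strings carry the same multiset of tokens
    (whitespace and token order are immaterial)."""

    def tokens(t: str):
        t = re.sub(r"\s+", "", t)
        cp = _CP_RE.search(t)
        suffix = [cp.group(0)] if cp else []
        if cp:
            t = t[: cp.start()]
        return sorted(tok for tok, _ in _split_top_level(t)) + suffix

    return tokens(a) == tokens(b)


# ---------------------------------------------------------------------------
# shorthand expansion & uncertainty resolution
# ---------------------------------------------------------------------------

def expand_shorthand_derivative(d: Derivative,
                                rule: ExpansionRule | None = None) -> Derivative:
    """Turn a ``der(N)t(A;B)(x;y)`` shorthand into explicit segments.

    The default ``centromere_retention`` rule: the named chromosome
    contributes its centromere-bearing portion (from the terminus of the
    arm opposite the breakpoint, through the centromere, to the
    breakpoint); the partner contributes breakpoint-to-terminus of the
    arm carrying its breakpoint.  Explicit derivatives pass through
    unchanged; overrides (matched on the derivative token) win over the
    default.
    """
    rule = rule or ExpansionRule()
    if d.segments:
        return d

    token = format_derivative(d)
    override = rule.overrides.get(token) or rule.overrides.get(token.lstrip("+"))
    if override is not None:
        return replace(d, segments=tuple(override))

    sh = d.shorthand
    if sh is None:  # unreachable given Derivative invariant, kept for safety
        raise ValueError("derivative has neither segments nor shorthand")
    if d.named_chromosome == sh.chrom_a:
        named_brk, partner, partner_brk = sh.breakpoint_a, sh.chrom_b, sh.breakpoint_b
    elif d.named_chromosome == sh.chrom_b:
        named_brk, partner, partner_brk = sh.breakpoint_b, sh.chrom_a, sh.breakpoint_a
    else:
        raise ValueError(
            f"derivative {token}: named chromosome not part of the "
            f"translocation; breakpoints missing"
        )

    n = d.named_chromosome
    if named_brk.arm == "q":
        named_seg = SegmentSpec(
            n, BandLocus(n, "p", "", terminal="pter"), named_brk)
    else:
        named_seg = SegmentSpec(
            n, BandLocus(n, "q", "", terminal="qter"), named_brk)
    terminus = BandLocus(partner, partner_brk.arm, "",
                         terminal=f"{partner_brk.arm}ter")
    partner_seg = SegmentSpec(partner, partner_brk, terminus)
    return replace(d, segments=(named_seg, partner_seg))


def expand_model(model: KaryotypeModel,
                 rule: ExpansionRule | None = None) -> KaryotypeModel:
    """Expand every shorthand derivative of a model; validates that every
    override references a derivative actually present."""
    rule = rule or ExpansionRule()
    tokens = {format_derivative(d) for d in model.derivatives}
    tokens |= {t.lstrip("+") for t in tokens}
    unknown = [key for key in rule.overrides if key not in tokens]
    if unknown:
        raise ValueError(
            f"expansion overrides reference unknown derivatives: {unknown}")
    return replace(
        model,
        derivatives=tuple(expand_shorthand_derivative(d, rule)
                          for d in model.derivatives),
    )


def resolve_uncertain_band(locus: BandLocus, policy: UncertaintyPolicy,
                           cmap) -> tuple[str, str]:
    """Resolve a locus to a (proximal band, distal band) name pair.

    Certain loci return the singleton range.  Uncertain loci are looked
    up in the policy's resolution map first (key: full locus string such
    as ``"2q?2"``); otherwise the ``widest_band_group`` fallback returns
    the full span of same-arm bands whose names start with the certain
    digits of the pattern.
    """
    if locus.terminal != "none":
        raise ValueError("terminal loci have no band range")
    name = locus.band_name
    if not locus.uncertain:
        return (name, name)

    key = f"{locus.chromosome}{name}"
    if key in policy.resolution_map:
        first, last = policy.resolution_map[key]
        for band in (first, last):
            if cmap.band_span(locus.chromosome, band) is None:
                raise UnresolvedBandError(
                    f"policy resolves {key} to {band!r}, absent from map")
        return (first, last)

    if policy.fallback == "error":
        raise UnresolvedBandError(f"no resolution for uncertain band {key}")

    digits = locus.band.replace("?", "")
    matches = [
        bname for bname, _, _ in cmap.bands[locus.chromosome]
        if bname.startswith(locus.arm) and bname[1:].startswith(digits)
    ]
    if not matches:
        raise UnresolvedBandError(
            f"no bands on {locus.chromosome}{locus.arm} match pattern "
            f"{locus.band!r}")
    return (matches[0], matches[-1])
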