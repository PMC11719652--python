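"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study conditions of a rat fibroblast line:
a male rat-like genome (20 autosome pairs + XY, acrocentric bias, i.e.
most chromosomes carry at most a small p arm), whole-chromosome
gains/losses, replacement derivatives written as translocation
shorthand, and supernumerary derivatives composed of explicit segments.

Ground-truth CNA tables are computed by literal per-base numpy coverage
assembly — a representation deliberately different from the engine's
breakpoint arithmetic — so oracle tests are non-circular.  To keep
per-base arrays cheap, simulated chromosomes are short (hundreds of kb);
nothing in the pipeline depends on absolute scale.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import CytobandMap, derive_copy_number_profile, profile_to_cna_regions
from .iscn import (
    BandLocus,
    Derivative,
    ISCNSyntaxError,
    KaryotypeModel,
    NumericalEvent,
    SegmentSpec,
    Translocation,
    UnsupportedConstructError,
    format_karyotype,
    parse_karyotype,
)
from .strid import STRProfile
from .xmap import HomologyMap, SyntenyBlock
from .bands import GenomicInterval

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_cytoband_map",
    "simulate_karyotype",
    "simulate_homology_map",
    "simulate_str_profiles",
    "recovery_experiment",
]


@dataclass(frozen=True)
class SimConfig:
    # genome shape
    n_autosomes: int = 20
    sex: str = "XY"
    ploidy_base: int = 2
    min_bands: int = 4
    max_bands: int = 8
    min_chrom_len: int = 200_000
    max_chrom_len: int = 800_000
    acrocentric_prob: float = 0.7
    # karyotype event model
    gain_rate: float = 0.08
    loss_rate: float = 0.08
    n_translocations: int = 1
    n_supernumerary: int = 1
    min_segments: int = 1
    max_segments: int = 3
    # homology map
    blocks_per_chromosome: int = 3
    inversion_prob: float = 0.3
    n_target_chromosomes: int = 6
    # STR profiles
    n_markers: int = 31
    n_lines: int = 4
    alleles_per_marker: int = 2
    target_sharing: float = 0.5
    # fault injection for robustness bookkeeping
    unsupported_injection_rate: float = 0.0

    def __post_init__(self):
        for p in (self.acrocentric_prob, self.gain_rate, self.loss_rate,
                  self.inversion_prob, self.target_sharing,
                  self.unsupported_injection_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for n in (self.n_autosomes, self.n_translocations,
                  self.n_supernumerary, self.n_markers, self.n_lines):
            if n < 0:
                raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, computed by construction."""

    model: KaryotypeModel
    karyotype_text: str
    cna: tuple[tuple[str, int, int, int], ...]  # (chrom, start, end, delta)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# cytoband maps
# ---------------------------------------------------------------------------

_Q_GROUP_NAMES = [f"q{g}{s}" for g in (1, 2, 3, 4) for s in (1, 2, 3)]
_P_NAMES = ["p13", "p12", "p11"]


def _arm_boundaries(rng, arm_len: int, n_bands: int) -> list[int]:
    """n_bands contiguous cuts of an arm, each band at least 1 base."""
    if n_bands == 1:
        return [arm_len]
    weights = rng.dirichlet(np.full(n_bands, 2.0))
    sizes = np.maximum(1, np.floor(weights * arm_len).astype(int))
    sizes[-1] = arm_len - int(sizes[:-1].sum())
    if sizes[-1] < 1:  # redistribute if rounding overshot
        sizes = np.full(n_bands, arm_len // n_bands)
        sizes[-1] = arm_len - int(sizes[:-1].sum())
    return list(np.cumsum(sizes))


def simulate_cytoband_map(cfg: SimConfig, seed) -> CytobandMap:
    """Random contiguous per-chromosome band map; deterministic per seed."""
    rng = _rng(seed)
    chroms = [str(i) for i in range(1, cfg.n_autosomes + 1)]
    chroms += sorted(set(cfg.sex))
    bands: dict[str, tuple[tuple[str, int, int], ...]] = {}
    for chrom in chroms:
        length = int(rng.integers(cfg.min_chrom_len, cfg.max_chrom_len + 1))
        acro = rng.random() < cfg.acrocentric_prob
        n_p = 0 if acro else int(rng.integers(1, len(_P_NAMES) + 1))
        n_q = int(rng.integers(cfg.min_bands, cfg.max_bands + 1))
        n_q = min(n_q, len(_Q_GROUP_NAMES))
        blist: list[tuple[str, int, int]] = []
        pos = 0
        if n_p:
            p_len = max(n_p, int(length * rng.uniform(0.05, 0.25)))
            names = _P_NAMES[-n_p:]  # pter-most band has the highest number
            for name, cut in zip(names, _arm_boundaries(rng, p_len, n_p)):
                blist.append((name, pos, cut))
                pos = cut
        q_len = length - pos
        offset = pos
        for name, cut in zip(_Q_GROUP_NAMES[:n_q],
                             _arm_boundaries(rng, q_len, n_q)):
            blist.append((name, pos, offset + cut))
            pos = offset + cut
        bands[chrom] = tuple(blist)
    return CytobandMap(bands=bands, build=f"sim{np.random.SeedSequence(seed).entropy}"
                       if isinstance(seed, int) else "sim")


# ---------------------------------------------------------------------------
# karyotypes with ground truth
# ---------------------------------------------------------------------------

def _truth_point(cmap: CytobandMap, chrom: str, band_name: str) -> int:
    """Break position of a certain band: its centromere-side boundary.

    Independent of the engine: a direct scan of the band list."""
    for name, start, end in cmap.bands[chrom]:
        if name == band_name:
            return end if name.startswith("p") else start
    raise KeyError(f"{chrom}{band_name}")


def _truth_interval(cmap: CytobandMap, seg: SegmentSpec) -> tuple[int, int]:
    points = []
    for locus in (seg.start, seg.end):
        if locus.terminal == "pter":
            points.append((0, 0))
        elif locus.terminal == "qter":
            L = cmap.bands[seg.chromosome][-1][2]
            points.append((L, L))
        else:
            p = _truth_point(cmap, seg.chromosome, locus.band_name)
            points.append((p, p))
    return (min(p[0] for p in points), max(p[1] for p in points))


def _random_segment(rng, cmap: CytobandMap, chrom: str) -> SegmentSpec:
    """A random non-degenerate certain segment on ``chrom``.

    Forms: pter->band, band->qter, band->band (distinct break positions).
    """
    length = cmap.bands[chrom][-1][2]
    candidates = [
        (name, _truth_point(cmap, chrom, name))
        for name, _, _ in cmap.bands[chrom]
    ]
    inner = [(n, p) for n, p in candidates if 0 < p < length]

    def band_locus(name: str) -> BandLocus:
        return BandLocus(chrom, name[0], name[1:])

    pter = BandLocus(chrom, "p", "", terminal="pter")
    qter = BandLocus(chrom, "q", "", terminal="qter")

    forms = []
    if inner:
        forms.extend(["pter_band", "band_qter"])
    distinct = len({p for _, p in inner}) >= 2
    if distinct:
        forms.append("band_band")
    if not forms:
        return SegmentSpec(chrom, pter, qter)  # whole chromosome

    form = forms[int(rng.integers(len(forms)))]
    if form == "pter_band":
        name, _ = inner[int(rng.integers(len(inner)))]
        return SegmentSpec(chrom, pter, band_locus(name))
    if form == "band_qter":
        name, _ = inner[int(rng.integers(len(inner)))]
        return SegmentSpec(chrom, band_locus(name), qter)
    while True:
        (n1, p1) = inner[int(rng.integers(len(inner)))]
        (n2, p2) = inner[int(rng.integers(len(inner)))]
        if p1 != p2:
            a, b = (n1, n2) if p1 < p2 else (n2, n1)
            return SegmentSpec(chrom, band_locus(a), band_locus(b))


def simulate_karyotype(cfg: SimConfig, cmap: CytobandMap,
                       seed) -> tuple[str, GroundTruth]:
    """Random karyotype text plus ground truth.

    The truth CNA list is assembled from per-base numpy coverage of every
    chromosome copy and derivative segment, never by calling the
    copy-number engine.
    """
    rng = _rng(seed)
    autosomes = [str(i) for i in range(1, cfg.n_autosomes + 1)]
    baseline = {c: cfg.ploidy_base for c in autosomes}
    for s in set(cfg.sex):
        baseline[s] = cfg.sex.count(s)

    coverage = {
        chrom: np.full(cmap.bands[chrom][-1][2], baseline.get(chrom, 0),
                       dtype=np.int16)
        for chrom in cmap.chromosomes
    }
    consumable = dict(baseline)  # copies still removable per chromosome

    numericals: list[NumericalEvent] = []
    for chrom in autosomes:
        r = rng.random()
        if r < cfg.gain_rate:
            numericals.append(NumericalEvent(chrom, +1))
            coverage[chrom] += 1
        elif r < cfg.gain_rate + cfg.loss_rate and consumable[chrom] > 1:
            numericals.append(NumericalEvent(chrom, -1))
            coverage[chrom] -= 1
            consumable[chrom] -= 1

    derivatives: list[Derivative] = []
    for _ in range(cfg.n_translocations):
        eligible = [c for c in autosomes if consumable[c] >= 1]
        if len(eligible) < 1 or len(autosomes) < 2:
            break
        named = eligible[int(rng.integers(len(eligible)))]
        partners = [c for c in autosomes if c != named]
        partner = partners[int(rng.integers(len(partners)))]

        def _break_bands(chrom: str, named_side: bool) -> list[str]:
            out = []
            L = cmap.bands[chrom][-1][2]
            for name, _, _ in cmap.bands[chrom]:
                p = _truth_point(cmap, chrom, name)
                if named_side and not 0 < p < L:
                    continue  # named segment would be empty
                if not named_side and not 0 < p < L:
                    continue
                out.append(name)
            return out

        named_bands = _break_bands(named, True)
        partner_bands = _break_bands(partner, False)
        if not named_bands or not partner_bands:
            continue
        nb = named_bands[int(rng.integers(len(named_bands)))]
        pb = partner_bands[int(rng.integers(len(partner_bands)))]
        brk_n = BandLocus(named, nb[0], nb[1:])
        brk_p = BandLocus(partner, pb[0], pb[1:])
        derivatives.append(Derivative(
            named, "replacement", segments=(),
            shorthand=Translocation(named, partner, brk_n, brk_p)))
        consumable[named] -= 1
        # truth: remove one whole named homolog, add back both segments
        coverage[named] -= 1
        pn = _truth_point(cmap, named, nb)
        if nb.startswith("q"):
            coverage[named][:pn] += 1  # pter -> breakpoint
        else:
            coverage[named][pn:] += 1  # breakpoint -> qter (centromere side)
        pp = _truth_point(cmap, partner, pb)
        if pb.startswith("p"):
            coverage[partner][:pp] += 1  # breakpoint -> pter
        else:
            coverage[partner][pp:] += 1  # breakpoint -> qter

    for _ in range(cfg.n_supernumerary):
        n_seg = int(rng.integers(cfg.min_segments, cfg.max_segments + 1))
        segs = []
        for k in range(n_seg):
            chrom = autosomes[int(rng.integers(len(autosomes)))]
            segs.append(_random_segment(rng, cmap, chrom))
        derivatives.append(Derivative(
            segs[0].chromosome, "supernumerary", segments=tuple(segs)))
        for seg in segs:
            lo, hi = _truth_interval(cmap, seg)
            coverage[seg.chromosome][lo:hi] += 1

    count = (cfg.ploidy_base * cfg.n_autosomes + len(cfg.sex)
             + sum(ev.delta for ev in numericals)
             + sum(1 for d in derivatives if d.prefix == "supernumerary"))
    model = parse_karyotype(format_karyotype(KaryotypeModel(
        count_min=count, count_max=count, ploidy_base=cfg.ploidy_base,
        sex=cfg.sex, numericals=tuple(numericals),
        derivatives=tuple(derivatives))))

    cna: list[tuple[str, int, int, int]] = []
    for chrom in cmap.chromosomes:
        delta = coverage[chrom].astype(np.int32) - baseline.get(chrom, 0)
        edges = np.flatnonzero(np.diff(delta)) + 1
        bounds = np.concatenate(([0], edges, [len(delta)]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            d = int(delta[lo])
            if d != 0:
                cna.append((chrom, int(lo), int(hi), d))

    text = format_karyotype(model)
    return text, GroundTruth(model=model, karyotype_text=text,
                             cna=tuple(cna))


# ---------------------------------------------------------------------------
# homology maps
# ---------------------------------------------------------------------------

def simulate_homology_map(cfg: SimConfig, cmap: CytobandMap,
                          seed) -> tuple[HomologyMap, HomologyMap]:
    """Length-preserving block tiling of every source chromosome onto a
    shuffled target genome; returns (forward, exact inverse)."""
    rng = _rng(seed)
    pieces: list[tuple[str, int, int]] = []
    for chrom in cmap.chromosomes:
        length = cmap.bands[chrom][-1][2]
        k = min(cfg.blocks_per_chromosome, length)
        if k <= 1:
            cuts = []
        else:
            cuts = sorted(rng.choice(np.arange(1, length), size=k - 1,
                                     replace=False).tolist())
        edges = [0] + cuts + [length]
        pieces.extend((chrom, lo, hi) for lo, hi in zip(edges, edges[1:]))

    order = rng.permutation(len(pieces))
    n_targets = max(1, cfg.n_target_chromosomes)
    offsets = {f"t{i + 1}": 0 for i in range(n_targets)}
    blocks = []
    for idx in order:
        chrom, lo, hi = pieces[idx]
        tgt = f"t{int(rng.integers(n_targets)) + 1}"
        strand = "-" if rng.random() < cfg.inversion_prob else "+"
        size = hi - lo
        blocks.append(SyntenyBlock(
            GenomicInterval(chrom, lo, hi),
            GenomicInterval(tgt, offsets[tgt], offsets[tgt] + size),
            strand))
        offsets[tgt] += size
    fwd = HomologyMap(tuple(blocks), source_build="simA", target_build="simB")
    return fwd, fwd.inverse()


# ---------------------------------------------------------------------------
# STR profiles
# ---------------------------------------------------------------------------

def simulate_str_profiles(cfg: SimConfig, seed
                          ) -> tuple[list[STRProfile], dict]:
    """Profiles with planted allele sharing against a reference line.

    Line 0 is the reference; every other line copies the reference's
    alleles at a random subset of ``round(target_sharing * n_markers)``
    markers and draws private (globally disjoint) alleles elsewhere.
    Returns the profiles and the by-construction expected pairwise Tanabe
    scores, keyed by (i, j) index pairs.
    """
    rng = _rng(seed)
    m = cfg.n_markers
    markers = [f"M{i + 1}" for i in range(m)]
    k = int(round(cfg.target_sharing * m))

    def private_alleles(line_idx: int, marker_idx: int) -> frozenset[int]:
        base = 10_000 * (line_idx + 1) + 100 * marker_idx
        return frozenset(
            int(base + a) for a in
            rng.choice(np.arange(1, 50), size=cfg.alleles_per_marker,
                       replace=False)
        )

    reference = {markers[i]: private_alleles(0, i) for i in range(m)}
    profiles = [STRProfile("line0", reference)]
    shared_sets: list[set[int]] = [set(range(m))]
    for i in range(1, cfg.n_lines):
        shared = set(rng.choice(np.arange(m), size=k, replace=False).tolist())
        shared_sets.append(shared)
        markers_i = {
            markers[j]: (reference[markers[j]] if j in shared
                         else private_alleles(i, j))
            for j in range(m)
        }
        profiles.append(STRProfile(f"line{i}", markers_i))

    truth = {}
    for i in range(cfg.n_lines):
        for j in range(i + 1, cfg.n_lines):
            if i == 0:
                expected = len(shared_sets[j]) / m
            else:
                expected = len(shared_sets[i] & shared_sets[j]) / m
            truth[(i, j)] = expected
    return profiles, truth


# ---------------------------------------------------------------------------
# end-to-end recovery harness
# ---------------------------------------------------------------------------

def recovery_experiment(n_replicates: int, cfg: SimConfig, seed: int) -> dict:
    """simulate -> parse -> derive -> compare, over ``n_replicates`` maps
    and karyotypes; reports the exact-recovery fraction (stub_tolerance 0)
    and diagnostics.  Injected unsupported constructs are counted as parse
    errors, never crashes."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    n_exact = 0
    n_parsed = 0
    parse_errors = 0
    mismatches = []
    rng = _rng(seed)
    for r in range(n_replicates):
        cmap = simulate_cytoband_map(cfg, seed=[seed, r, 0])
        text, truth = simulate_karyotype(cfg, cmap, seed=[seed, r, 1])
        if (cfg.unsupported_injection_rate
                and rng.random() < cfg.unsupported_injection_rate):
            head, _, tail = text.partition("[")
            text = head + ",inv(3)(p11q21)" + ("[" + tail if tail else "")
        try:
            model = parse_karyotype(text)
        except (ISCNSyntaxError, UnsupportedConstructError):
            parse_errors += 1
            continue
        n_parsed += 1
        profile = derive_copy_number_profile(model, cmap)
        regions = profile_to_cna_regions(profile, cmap, stub_tolerance=0)
        got = sorted(
            (r2.interval.chromosome, r2.interval.start, r2.interval.end,
             r2.delta)
            for r2 in regions
        )
        expected = sorted(truth.cna)
        if got == expected:
            n_exact += 1
        elif len(mismatches) < 5:
            mismatches.append({"replicate": r, "expected": expected,
                               "observed": got})
    return {
        "n_replicates": n_replicates,
        "n_parsed": n_parsed,
        "parse_errors": parse_errors,
        "n_exact": n_exact,
        "recovery_fraction": (n_exact / n_parsed) if n_parsed else 0.0,
        "mismatches": mismatches,
    }
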