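# Methods

## The karyotype model and its dialect

The parser covers exactly the ISCN constructs that occur in composite
mFISH/banding karyotypes of the kind this package analyzes: a chromosome
count or count range with ploidy annotation (`37~43<2n>`), a sex token,
whole-chromosome gains/losses (`+7`, `-8`), derivative chromosomes as
translocation shorthand (`der(2)t(2;19)(q34;p11)`) or as explicit
`::`-delimited segment compositions, and a composite-cell suffix
(`[cp30]`). Everything else in ISCN — inversions, insertions, rings,
markers, isochromosomes, stemline references — raises a clean
"unsupported construct" error rather than being half-interpreted. The
`?` glyph is the only uncertainty marker handled; whitespace is ignored;
tokens are case-sensitive; chromosome labels are strings so `X`/`Y` need
no special casing.

A composite `[cpN]` karyotype is modeled as a clone-level consensus: the
event list is the union over cells, the count range is stored, and no
per-cell model is built. This matches how such karyotypes are reported
(one consensus CNA table), at the cost of occasionally over-counting an
event that is only subclonal — see "Known divergences" below.

An unprefixed `der(N)` *replaces* one homolog of N; `+der(N)` is
*supernumerary*. This distinction is what makes, e.g., loss of the
distal arm of the named chromosome fall out of the bookkeeping
automatically.

Parsing normalizes event order (by chromosome, derivatives before
numerical events on the same chromosome), so parse∘format is the
identity on parser and generator output and format∘parse is
token-equivalent to the input. An expanded derivative (shorthand plus
explicit segments) serializes in explicit form; expansion is an analysis
step, not part of the serialized dialect.

## Breakpoint semantics

Coordinates are internal 0-based half-open; all human-readable reports
are 1-based inclusive; BED stays 0-based half-open.

A segment's genomic interval is determined by the extents its two loci
contribute:

- `pter` → position 0, `qter` → chromosome length, `cen` → p/q boundary;
- a **certain** band denotes a break at its **centromere-side boundary**
  (p-arm band → band end, q-arm band → band start);
- an **uncertain** band (`?`) denotes the **full span** of its resolved
  band range.

The interval runs from the outermost proximal to the outermost distal of
these extents; written orientation is recorded in provenance but ignored
for copy counting, since banding cannot resolve segment orientation.

The centromere-side-point rule for certain bands is deliberate: the two
products of a reciprocal translocation share one physical breakpoint, so
`19p11->19pter` (in a der(2) product) and `19qter->19p11` (in a der(19)
product) must tile chromosome 19 without overlap. Treating certain
breakpoint bands as full spans would instead create a spurious
double-counted sliver inside the breakpoint band. A side effect is that
a segment written `Apter->Aq22` excludes band q22 itself while the
complementary loss `q22->qter` includes it; region labels can therefore
shift by one band relative to a hand-written table even when the
molecular span is identical.

Uncertain bands resolve through an `UncertaintyPolicy`: an explicit
resolution map (e.g. `2q?2 → (q22, q25)`) consulted first, then a
`widest_band_group` fallback that returns all same-arm bands whose names
start with the certain digits of the pattern (`10q?3` → q31…q33), or a
hard error if configured so.

Shorthand derivatives expand by **centromere retention**: the named
chromosome contributes terminus→breakpoint through its centromere, the
partner contributes breakpoint→terminus of the arm carrying its
breakpoint. Overrides keyed by the derivative token supply explicit
compositions where banding evidence contradicts the default; the
packaged Rat-1 overrides pin both der(2) (identical to the default) and
der(4) (where the evidence — monosomy 3 with a distal-3q loss and a
whole-chromosome-4 loss — implies the derivative keeps proximal 3 and
distal 4, which no plain centromere-retention reading of a der(4)
produces).

## Copy-number bookkeeping

Baseline is `ploidy_base` per autosome and one copy per occurrence of a
sex chromosome in the sex token; events touching a chromosome with zero
baseline are errors, never clamped. Numerical events add ±1 genome-wide
on their chromosome; a replacement derivative subtracts one whole copy
of its named chromosome and adds every expanded segment; a supernumerary
derivative adds its segments. Counts are computed exactly on the
partition induced by all event endpoints; a negative count anywhere is
an "inconsistent karyotype" error naming the interval. Conservation —
total copy mass minus baseline mass equals the signed sum of event
lengths — holds as an integer identity and is asserted after every
derivation.

CNA regions are count-minus-baseline runs with zero-delta runs dropped
and equal-delta neighbors merged. The **stub tolerance** (default 10 Mb,
configurable to 0 for exact bookkeeping) absorbs a *terminal* run
shorter than the tolerance into its neighbor, neighbor's delta winning.
Rationale: rat chromosomes are largely acrocentric, and a derivative
like `der(4)(…::4p11->4qter)` leaves a few-Mb p stub at zero copies that
a banding analyst reads as a whole-chromosome loss; the published
consensus tables report it that way. The threshold such an analyst uses
is not stated anywhere; 10 Mb was chosen as comfortably above
acrocentric stub size and below any band group of interest, and the
default is not load-bearing for anything except that folding. Every
region carries provenance: the tokens of all events overlapping it.

### Known divergences on the packaged case study

- The two supernumerary der(12)s each carry `12pter->12q1?2`, so
  mechanical bookkeeping reports that region at +2 where the published
  consensus lists +1 — plausibly a subclonal composite-karyotype call.
  The engine reports the mechanical value; the provenance column names
  both contributing derivatives. It is not "corrected".
- The engine labels the distal chromosome-3 loss `3q23->3qter` and the
  19q gain `19q11->19qter`; hand-written tables label the same molecular
  spans `3q22->3qter` / `19p11->19qter` (breakpoint-band naming). Labels
  differ by the breakpoint band only; spans and deltas agree.

## Cytoband fixtures

The packaged rn5-like and hg19-like cytoband tables are **synthetic**:
chromosome lengths and the band boundaries pinned by published molecular
spans are real, every other band is invented at plausible scale. Real
genome annotation is deliberately not downloaded or redistributed.
Within a chromosome, bands are contiguous, non-overlapping, start at 0
and end at the chromosome length; the loader validates this and names
the offending bands on a gap or overlap.

## Cross-genome translation

Lifting uses affine (proportional) interpolation within each synteny
block, reversed on `-` strand — band-resolution arithmetic, not
base-level alignment, because karyotype-derived regions have no
base-exact breakpoints. Defaults `min_fragment` = 1 Mb and `gap_join` =
1 Mb produce coarse, band-scale output; both are configurable and the
property tests run them at 0 for exactness. Real rat→human chains are
not packaged: the packaged coarse homology map is a hand-made synthetic
stand-in covering three representative regions, so the human-side output
is validated qualitatively (representative labels and deltas) plus
exhaustively on synthetic maps — per-point oracle agreement, exact
inverse round trips, and total-lifted-length ≤ query-length over
hundreds of random intervals. Base-exact liftover fidelity and chain/net
reconstruction are non-goals.

## Concordance scoring

Catalog statuses normalize case-insensitively with bold markers
stripped; `loss and gain` → `both`. `both` counts as concordant with
either query direction — the only reading consistent with how mixed
entries are tallied in the source catalogs — and `none` rows are
`absent`, counted in the denominator. The score is concordant/total;
no significance testing is attempted (the comparison tables are too
coarse for a meaningful null).

## STR matching

Alleles are per-marker integer sets; markers absent from either profile
are excluded from numerator and denominator (intersection-of-markers
convention). The Tanabe score is symmetric, 1.0 on self-match, and
monotone in the expected directions (property-tested). The 0.8
authentication threshold is a community convention, configurable; the
packaged four-line rat panel scores 0.22–0.31 for the query line against
the others, far below any match call.

## Synthetic data and what it does (not) show

`simdata` generates: contiguous random cytoband maps over a rat-like
genome (20 autosomes + XY, 70% acrocentric, 4–8 q bands, chromosomes
0.2–0.8 Mb so that ground truth can be literal per-base numpy coverage);
karyotypes from a configurable event model (whole-chromosome gain/loss
rates 8%/8%, one shorthand translocation and one supernumerary
derivative of 1–3 segments by default, bounded so no region can go below
zero copies); length-preserving, possibly inverted synteny-block tilings
with an exact inverse map; and STR profiles with planted pairwise
sharing. All generators are deterministic per seed.

Ground-truth CNA tables are assembled by adding ±1 over per-base arrays
for every chromosome copy and segment — structurally independent of the
engine's breakpoint/partition arithmetic — so the noiseless
recovery experiment (simulate → parse → derive → compare, exact match at
stub tolerance 0) is a non-circular oracle; it recovers 200/200
replicates exactly. Fault injection (appending an unsupported ISCN
token) confirms parse failures are counted, not crashed on.

Limits of what passing tests show: the generator emits only certain
bands (uncertainty resolution is exercised on the packaged case study,
not at random); chromosomes are short, so nothing probes numeric
overflow at real genome scale (all arithmetic is arbitrary-precision
integer anyway); segment orientation is never informative; and the
homology simulator produces perfect tilings, whereas real chain sets
have gaps — partial coverage is tested only through hand-built maps.

## Numerical choices

Integer coordinates end to end; the only rounding is in affine lifting
across blocks of unequal length (`round`, with zero-length results
dropped). Degenerate zero-length segments are errors. Region merging is
order-independent because profiles are computed from event sums, not
sequential application. Seeds are passed explicitly everywhere;
composite seeds (`[seed, replicate, stage]`) keep replicates independent
without seed arithmetic.
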