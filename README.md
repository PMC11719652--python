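# karyocna — virtual CGH from ISCN karyotypes

`karyocna` turns a cytogenetic karyotype — the kind of composite ISCN
string produced by mFISH plus inverted DAPI-banding of a tumor or
immortalized cell line — into a genomic copy-number alteration (CNA)
profile, projects those alterations onto another genome build or species
over a synteny-block homology map, scores their direction-concordance
against published tumor CNA catalogs, and authenticates cell lines by
STR allele sharing. It was built around the characterization of the
Rat-1 fibroblast line (male rat, 37–43 chromosomes, five derivative
chromosomes), whose inputs are packaged as fixtures, but every stage is
generic and is exercised on synthetic data with known ground truth.

## The method

**Karyotype → copy numbers.** An ISCN karyotype like

```
37~43<2n>,XY,der(2)t(2;19)(q34;p11),-3,der(4)t(3;4)(q?22;p11),-4,+7,-8,
+der(12)(12pter->12q1?2::2q?2->2q?2::10q?3->10qter),…[cp30]
```

is parsed into counts, sex, numerical events (±whole chromosomes) and
derivative chromosomes. Shorthand `der(N)t(A;B)(x;y)` derivatives expand
by centromere retention (the named chromosome keeps its
centromere-bearing portion up to the breakpoint; the partner contributes
breakpoint→arm terminus), with per-derivative overrides available when
the banding evidence implies a different composition. Each segment is
mapped to genome coordinates through a cytoband table: a certain
breakpoint band breaks at its centromere-side boundary (so the two
products of a reciprocal translocation partition the chromosome
exactly), while an uncertain band (`?`) covers its whole policy-resolved
band range. Copy counts are then pure bookkeeping on the partition
induced by all segment endpoints: baseline (2 per autosome for `<2n>`,
one per sex chromosome in the sex token), ±1 for numerical events, −1
whole chromosome plus the retained segments for a replacement
derivative, +1 per segment for a supernumerary derivative. Copy mass is
conserved exactly and negative counts are rejected as inconsistent.
Regions where the count differs from baseline are merged and labeled;
terminal stubs shorter than a configurable tolerance (default 10 Mb) are
absorbed into their neighbor so that, e.g., an acrocentric p stub does
not split a whole-chromosome loss.

**Cross-genome projection.** CNA regions are lifted through an ordered
list of source→target synteny blocks with strand (block TSV or a minimal
UCSC chain subset); positions map affinely within a block, fragments
below 1 Mb are dropped and fragments closer than 1 Mb merge (both
configurable). Lifted fragments are labeled with target cytoband spans
(`5p15.31p14.1` style).

**Tumor concordance.** Human-labeled CNA regions are compared 1:1 by
label against tumor catalogs with statuses gain / loss / both / none;
a region counts as concordant on a direction match (catalog "both"
matches either direction), and the report is the concordant fraction.

**STR authentication.** Profiles are per-marker allele-size sets; the
match statistic is the Tanabe score `2·shared / (alleles_a + alleles_b)`
over markers present in both profiles, with the conventional 0.8
authentication threshold.

## Worked example

```python
from karyocna import rat1
from karyocna.concord import concordance_report

for r in rat1.cna_regions():
    print(f"{r.label:<18}{r.delta:>+3}  {r.interval.span_1based}")
rep = concordance_report(rat1.human_cna_query(),
                         rat1.epithelioid_sarcoma_catalog())
print(rep.concordant, "/", rep.total, f"= {rep.fraction:.1%}")
```

prints

```
2q22->2q25         +4  80406983-139816749
2q34->2qter        -1  192680326-285068071
3q23->3qter        -1  58164792-183740530
4pter->4qter       -1  1-248343840
6q11->6qter        +1  1-156897508
7pter->7qter       +1  1-143501887
8pter->8qter       -1  1-132457389
10q32.1->10qter    +1  89211697-112200500
12pter->12q12      +2  1-31247709
19pter->19p11      +2  1-27543415
19q11->19qter      +1  27543416-72914587
17 / 40 = 42.5%
```

Reading: the 2q22–q25 band group is present in four extra copies (it
recurs in four derivative-chromosome segments), the 19p arm in two; one
chromosome-2 homolog lost its distal arm beyond 2q34 to the
der(2)t(2;19) translocation; chromosomes 4 and 8 are monosomic and 7 is
trisomic; and 17 of the 40 human-projected regions change in the same
direction as epithelioid sarcoma (15/40 for liposarcoma).

The same steps are available as numbered drivers under `analysis/`
(parse → derive → translate → concordance → STR → simulation
validation), each writing tables under `results/`, and as a `karyocna`
CLI (`parse`, `derive`, `translate`, `compare`, `strmatch`, `simulate`).

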