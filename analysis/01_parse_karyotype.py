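#!/usr/bin/env python
"""Parse the published Rat-1 karyotype string and report its structure.

The mFISH/inverted-DAPI consensus karyotype is a composite over 30 cells
with 37-43 chromosomes.  This step parses it into an explicit model:
chromosome counts, sex, whole-chromosome gains/losses, and the five
derivative chromosomes, and verifies the serialization round trip.
Writes results/karyotype_model.json.
"""

import dataclasses
import json
from pathlib import Path

from karyocna import rat1
from karyocna.iscn import format_karyotype, format_derivative, token_equivalent

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    text = rat1.karyotype_text()
    model = rat1.karyotype_model()
    print(f"karyotype: {text}\n")
    print(f"chromosome count range : {model.count_min}-{model.count_max} "
          f"(ploidy {model.ploidy_base}n, sex {model.sex}, "
          f"composite of {model.composite_cells} cells)")
    print("numerical events       : "
          + ", ".join(f"{'+' if e.delta > 0 else '-'}{e.chromosome}"
                      for e in model.numericals))
    for d in model.derivatives:
        print(f"  {d.prefix:<13} {format_derivative(d)}")
    assert token_equivalent(format_karyotype(model), text)
    print("\nserialization round trip: OK (token-equivalent)")

    OUT.mkdir(exist_ok=True)
    with open(OUT / "karyotype_model.json", "w") as handle:
        json.dump(dataclasses.asdict(model), handle, indent=2)
    print(f"wrote {OUT / 'karyotype_model.json'}")


if __name__ == "__main__":
    main()
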