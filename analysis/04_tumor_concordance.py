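#!/usr/bin/env python
"""Score Rat-1 CNA directions against two human sarcoma CNA catalogs.

Compares the 40 human-labeled Rat-1 regions with published epithelioid
sarcoma and liposarcoma catalogs: a region is concordant when its
direction matches (a catalog region recurrently showing both directions
matches either sign).  Writes results/concordance.json and per-catalog
row tables.
"""

import json
from pathlib import Path

import pandas as pd

from karyocna import rat1
from karyocna.concord import concordance_report

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    query = rat1.human_cna_query()
    OUT.mkdir(exist_ok=True)
    summary = {}
    for catalog in (rat1.epithelioid_sarcoma_catalog(),
                    rat1.liposarcoma_catalog()):
        rep = concordance_report(query, catalog)
        summary[catalog.tumor] = rep.to_dict()
        print(f"{catalog.tumor}: {rep.concordant}/{rep.total} concordant "
              f"({100 * rep.fraction:.1f}%), {rep.discordant} discordant, "
              f"{rep.absent} without catalog CNA")
        slug = catalog.tumor.replace(" ", "_")
        pd.DataFrame(rep.rows, columns=[
            "region", "rat1_delta", "catalog_status", "classification"
        ]).to_csv(OUT / f"concordance_{slug}.tsv", sep="\t", index=False)
    with open(OUT / "concordance.json", "w") as handle:
        json.dump(summary, handle, indent=2)
    print(f"wrote {OUT / 'concordance.json'} and per-catalog tables")


if __name__ == "__main__":
    main()
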