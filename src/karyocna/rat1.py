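"""Packaged Rat-1 case-study inputs and convenience pipeline entries.

The cytoband tables packaged here are *synthetic* rn5-like / hg19-like
fixtures: chromosome lengths and the handful of band boundaries that the
published molecular spans pin down are real, every other band is
invented at plausible scale.  The coarse homology map is likewise a
hand-made synthetic stand-in for a real rn5->hg19 chain set and is only
meant to reproduce representative translated labels.
"""

from __future__ import annotations

from importlib import resources

from .bands import (
    CNARegion,
    CytobandMap,
    CopyNumberProfile,
    derive_copy_number_profile,
    load_cytoband_table,
    profile_to_cna_regions,
)
from .concord import TumorCNACatalog, load_tumor_catalog
from .iscn import ExpansionRule, KaryotypeModel, UncertaintyPolicy, parse_karyotype
from .strid import STRProfile, read_str_profiles
from .xmap import HomologyMap, load_homology_map

__all__ = [
    "karyotype_text",
    "karyotype_model",
    "cytobands",
    "policy",
    "overrides",
    "copy_number_profile",
    "cna_regions",
    "human_cna_query",
    "epithelioid_sarcoma_catalog",
    "liposarcoma_catalog",
    "str_profiles",
    "coarse_homology_map",
    "human_cytobands",
]

_FIXTURES = resources.files("karyocna") / "fixtures"


def _open(name: str):
    return (_FIXTURES / name).open("r")


def karyotype_text() -> str:
    return (_FIXTURES / "rat1_karyotype.txt").read_text().strip()


def karyotype_model() -> KaryotypeModel:
    return parse_karyotype(karyotype_text())


def cytobands() -> CytobandMap:
    with _open("rn5_cytobands_synthetic.tsv") as handle:
        return load_cytoband_table(handle, build="rn5-like (synthetic)")


def human_cytobands() -> CytobandMap:
    with _open("hg19_cytobands_synthetic.tsv") as handle:
        return load_cytoband_table(handle, build="hg19-like (synthetic)")


def policy() -> UncertaintyPolicy:
    with _open("rat1_policy.yaml") as handle:
        return UncertaintyPolicy.from_yaml(handle)


def overrides() -> ExpansionRule:
    with _open("rat1_overrides.yaml") as handle:
        return ExpansionRule.from_yaml(handle)


def copy_number_profile() -> CopyNumberProfile:
    return derive_copy_number_profile(
        karyotype_model(), cytobands(), rule=overrides(), policy=policy())


def cna_regions(stub_tolerance: int = 10_000_000) -> list[CNARegion]:
    """The full Rat-1 virtual-CGH pipeline on packaged inputs."""
    return profile_to_cna_regions(copy_number_profile(), cytobands(),
                                  stub_tolerance=stub_tolerance)


def coarse_homology_map() -> HomologyMap:
    with _open("homology_rn5_hg19_coarse.tsv") as handle:
        return load_homology_map(handle, source_build="rn5-like (synthetic)",
                                 target_build="hg19-like (synthetic)")


def human_cna_query() -> list[tuple[str, int]]:
    """The Rat-1 CNA directions on human region labels (40 regions)."""
    import pandas as pd

    with _open("rat1_human_cna.csv") as handle:
        df = pd.read_csv(handle, dtype={"region": str})
    return [(str(r.region), int(r.delta)) for r in df.itertuples()]


def epithelioid_sarcoma_catalog() -> TumorCNACatalog:
    with _open("epithelioid_sarcoma.csv") as handle:
        return load_tumor_catalog(handle, tumor="epithelioid sarcoma")


def liposarcoma_catalog() -> TumorCNACatalog:
    with _open("liposarcoma.csv") as handle:
        return load_tumor_catalog(handle, tumor="liposarcoma")


def str_profiles() -> list[STRProfile]:
    with _open("str_profiles.csv") as handle:
        return read_str_profiles(handle)
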